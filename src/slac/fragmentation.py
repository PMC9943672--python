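"""Modification-fragmentation crosstalks on 5' tRNA fragments.

Only 5' tRFs are analyzable: a 3' fragment cannot be told apart from a
reverse-transcription stop.  Reads anchored at the tRNA 5' end are binned by
their 3' terminus into tRFs ending at transcript positions 30-39 (anticodon /
C-loop), 40-49 (variable loop), 50-59 (T-loop), and full-length reads ending
past position 60.  Position 60 itself falls in no bin and such reads are
UNCLASSIFIED.  For each candidate modified site and each tRF class, the odds
ratio contrasts modification in the fragment class versus full-length reads:

    OR = (tRF with mod) * (full-length without mod)
         ------------------------------------------
         (tRF without mod) * (full-length with mod)
"""

from __future__ import annotations

import enum
import itertools
import logging
import math

import pandas as pd

from .crosstalk_core import (
    DEFAULT_ALPHA,
    DEFAULT_MIN_PAIR_READS,
    ContingencyTable,
    _log2_or,
    corrected_odds_ratio,
    direction_of,
    fdr_correct,
    fisher_test,
    odds_ratio,
)
from .read_model import ReadSet, SingleReadRecord
from .site_detection import (
    DEFAULT_MIN_COVERAGE,
    DEFAULT_MIN_FRACTION,
    candidate_sites,
    pileup,
)

log = logging.getLogger(__name__)

__all__ = ["FragmentClass", "classify_fragment", "class_summary", "frag_crosstalks"]

DEFAULT_MAX_START = 5

#: Lower bound of the 3'-terminus bin for each tRF class.
_CLASS_LOWER = {"TRF_30_39": 30, "TRF_40_49": 40, "TRF_50_59": 50}


class FragmentClass(str, enum.Enum):
    TRF_30_39 = "TRF_30_39"
    TRF_40_49 = "TRF_40_49"
    TRF_50_59 = "TRF_50_59"
    FULL_LENGTH = "FULL_LENGTH"
    UNCLASSIFIED = "UNCLASSIFIED"


def classify_fragment(
    read: SingleReadRecord, max_start: int = DEFAULT_MAX_START
) -> FragmentClass:
    """Bin a read by its 3' terminus.

    Reads must be 5'-anchored (align_start <= max_start) to count as a 5' tRF
    or a full-length molecule; anything else is UNCLASSIFIED, as are reads
    ending before position 30 or exactly at position 60.
    """
    if read.align_start > max_start:
        return FragmentClass.UNCLASSIFIED
    end = read.align_end
    if 30 <= end <= 39:
        return FragmentClass.TRF_30_39
    if 40 <= end <= 49:
        return FragmentClass.TRF_40_49
    if 50 <= end <= 59:
        return FragmentClass.TRF_50_59
    if end > 60:
        return FragmentClass.FULL_LENGTH
    return FragmentClass.UNCLASSIFIED


def class_summary(reads: ReadSet, max_start: int = DEFAULT_MAX_START) -> pd.DataFrame:
    """Per-transcript read counts in each fragment class."""
    rows: dict[str, dict[str, int]] = {}
    for r in reads.records:
        d = rows.setdefault(r.transcript_id, {c.value: 0 for c in FragmentClass})
        d[classify_fragment(r, max_start).value] += 1
    return (
        pd.DataFrame.from_dict(rows, orient="index")
        .rename_axis("transcript")
        .reset_index()
    )


def frag_crosstalks(
    reads: ReadSet,
    sites: set[tuple[str, int]] | None = None,
    max_start: int = DEFAULT_MAX_START,
    alpha: float = DEFAULT_ALPHA,
    min_pair_reads: int = DEFAULT_MIN_PAIR_READS,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Odds ratio of each candidate site versus each tRF class.

    A site pairs with a class only when every read of that class can cover it,
    i.e. site position <= the class's lower bin bound (a site at 58 cannot be
    scored in reads ending at 30-39); other pairs are skipped and logged.
    Within a pair, reads not covering the site (or with it deleted) are
    dropped.  Charging is never a fragmentation feature: truncated reads have
    no 3' CCA context.  BH correction runs over all (transcript, site, class)
    tests of the sample.
    """
    if sites is None:
        sites = candidate_sites(pileup(reads), min_fraction, min_coverage)
    by_transcript: dict[str, list[int]] = {}
    for t, p in sorted(sites):
        by_transcript.setdefault(t, []).append(p)

    rows: list[dict] = []
    for transcript, positions in by_transcript.items():
        buckets: dict[FragmentClass, list[SingleReadRecord]] = {
            c: [] for c in FragmentClass
        }
        for r in reads.records_for(transcript):
            buckets[classify_fragment(r, max_start)].append(r)
        full = buckets[FragmentClass.FULL_LENGTH]
        for site, frag_class in itertools.product(
            positions, (FragmentClass.TRF_30_39, FragmentClass.TRF_40_49, FragmentClass.TRF_50_59)
        ):
            if site > _CLASS_LOWER[frag_class.value]:
                log.debug(
                    "site %s:%d not covered by %s reads; pair skipped",
                    transcript,
                    site,
                    frag_class.value,
                )
                continue
            trf = [r for r in buckets[frag_class] if r.covers(site)]
            full_cov = [r for r in full if r.covers(site)]
            if not trf:
                continue
            trf_mod = sum(site in r.mismatch_positions for r in trf)
            full_mod = sum(site in r.mismatch_positions for r in full_cov)
            # arranged so that the cross-product ratio is
            # (tRF mod * full unmod) / (tRF unmod * full mod)
            table = ContingencyTable(
                n11=trf_mod,
                n10=len(trf) - trf_mod,
                n01=full_mod,
                n00=len(full_cov) - full_mod,
            )
            if table.total < min_pair_reads:
                continue
            or_raw = odds_ratio(table)
            rows.append(
                {
                    "sample": reads.sample_id,
                    "transcript": transcript,
                    "position": site,
                    "frag_class": frag_class.value,
                    "n_trf_mod": table.n11,
                    "n_trf_unmod": table.n10,
                    "n_full_mod": table.n01,
                    "n_full_unmod": table.n00,
                    "or_raw": or_raw,
                    "or_corrected": corrected_odds_ratio(table),
                    "log2_or": _log2_or(or_raw),
                    "p": fisher_test(table),
                    "direction": direction_of(or_raw).value,
                }
            )
    columns = [
        "sample",
        "transcript",
        "position",
        "frag_class",
        "n_trf_mod",
        "n_trf_unmod",
        "n_full_mod",
        "n_full_unmod",
        "or_raw",
        "or_corrected",
        "log2_or",
        "p",
        "q",
        "direction",
        "significant",
    ]
    df = pd.DataFrame(rows, columns=[c for c in columns if c not in ("q", "significant")])
    if df.empty:
        df["q"] = []
        df["significant"] = []
        return df[columns]
    df = df.sort_values(
        ["p", "transcript", "position", "frag_class"], kind="mergesort"
    ).reset_index(drop=True)
    df["q"] = fdr_correct(df["p"].to_numpy())
    df["significant"] = df["q"] <= alpha
    return df[columns]
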