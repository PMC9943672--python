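"""Pairwise crosstalk detection on single reads.

For every pair of features on a transcript -- two candidate modified sites, or
a site and the aminoacylation state -- a 2x2 contingency table is built over
the reads that are informative for both features, and the interdependence is
quantified by the odds ratio

    OR = (n reads with both A and B) * (n reads with neither)
         ---------------------------------------------------
         (n reads with A not B)     * (n reads with B not A)

OR > 1 is a stimulatory crosstalk (features co-occur on the same molecules),
OR < 1 inhibitory (mutually exclusive).  Significance is a two-sided Fisher
exact test, corrected across all tested pairs with Benjamini-Hochberg.
"""

from __future__ import annotations

import enum
import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .read_model import EndCall, ReadSet
from .site_detection import (
    DEFAULT_MIN_COVERAGE,
    DEFAULT_MIN_FRACTION,
    candidate_sites,
    pileup,
)

log = logging.getLogger(__name__)

__all__ = [
    "CHARGING",
    "Direction",
    "ContingencyTable",
    "build_table",
    "odds_ratio",
    "corrected_odds_ratio",
    "fisher_test",
    "fdr_correct",
    "all_crosstalks",
    "consensus_crosstalks",
    "CROSSTALK_COLUMNS",
]

#: Feature token for the per-read aminoacylation state.
CHARGING = "CHARGING"

DEFAULT_MIN_PAIR_READS = 50
DEFAULT_ALPHA = 0.05

CROSSTALK_COLUMNS = [
    "sample",
    "transcript",
    "feature_a",
    "feature_b",
    "n11",
    "n10",
    "n01",
    "n00",
    "or_raw",
    "or_corrected",
    "log2_or",
    "p",
    "q",
    "direction",
    "significant",
]


class Direction(str, enum.Enum):
    STIMULATORY = "STIMULATORY"
    INHIBITORY = "INHIBITORY"
    NONE = "NONE"


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """2x2 counts over reads informative for both features of a pair."""

    n11: int
    n10: int
    n01: int
    n00: int

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    def as_array(self) -> np.ndarray:
        return np.array([[self.n11, self.n10], [self.n01, self.n00]], dtype=np.int64)


def odds_ratio(table: ContingencyTable) -> float:
    """Raw cross-product odds ratio; 0 / +inf when exactly the numerator /
    denominator vanishes, NaN when the table is degenerate (both zero)."""
    num = table.n11 * table.n00
    den = table.n10 * table.n01
    if num == 0 and den == 0:
        return math.nan
    if den == 0:
        return math.inf
    return num / den


def corrected_odds_ratio(table: ContingencyTable) -> float:
    """Haldane-Anscombe estimate: add 0.5 to every cell when any cell is zero,
    otherwise identical to the raw odds ratio.  Used for reporting a finite
    effect size; the Fisher test always runs on the raw counts."""
    if min(table.n11, table.n10, table.n01, table.n00) > 0:
        return odds_ratio(table)
    return ((table.n11 + 0.5) * (table.n00 + 0.5)) / (
        (table.n10 + 0.5) * (table.n01 + 0.5)
    )


def fisher_test(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value on the raw counts."""
    if table.total == 0:
        raise ValueError("Fisher test on an empty table")
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def _log2_or(or_value: float) -> float:
    if math.isnan(or_value):
        return math.nan
    if or_value == 0:
        return -math.inf
    if math.isinf(or_value):
        return math.inf
    return math.log2(or_value)


def direction_of(or_value: float) -> Direction:
    if math.isnan(or_value) or or_value == 1:
        return Direction.NONE
    return Direction.STIMULATORY if or_value > 1 else Direction.INHIBITORY


def fdr_correct(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for one correction family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


class _TranscriptFeatures:
    """Columnar view of one transcript's reads for fast table building."""

    def __init__(self, reads: ReadSet, transcript: str, positions: Sequence[int]):
        recs = reads.records_for(transcript)
        n = len(recs)
        self.positions = list(dict.fromkeys(positions))
        idx = {p: j for j, p in enumerate(self.positions)}
        starts = np.empty(n, dtype=np.int32)
        ends = np.empty(n, dtype=np.int32)
        mism = np.zeros((n, len(idx)), dtype=bool)
        deleted = np.zeros((n, len(idx)), dtype=bool)
        charge = np.full(n, -1, dtype=np.int8)
        for i, r in enumerate(recs):
            starts[i] = r.align_start
            ends[i] = r.align_end
            for p in r.mismatch_positions:
                j = idx.get(p)
                if j is not None:
                    mism[i, j] = True
            for p in r.deletions:
                j = idx.get(p)
                if j is not None:
                    deleted[i, j] = True
            if r.end_call is EndCall.CCA:
                charge[i] = 1
            elif r.end_call is EndCall.CC:
                charge[i] = 0
        self._idx = idx
        self._covers = {
            p: (starts <= p) & (ends >= p) & ~deleted[:, j] for p, j in idx.items()
        }
        self._mism = mism
        self.charge = charge

    def feature_vectors(self, feature: int | str) -> tuple[np.ndarray, np.ndarray]:
        """(informative mask, has-feature vector) for one feature."""
        if feature == CHARGING:
            return self.charge >= 0, self.charge == 1
        return self._covers[feature], self._mism[:, self._idx[feature]]

    def table(self, feature_a: int | str, feature_b: int | str) -> ContingencyTable:
        if feature_a == feature_b:
            raise ValueError(f"feature pair must be distinct, got {feature_a!r} twice")
        info_a, has_a = self.feature_vectors(feature_a)
        info_b, has_b = self.feature_vectors(feature_b)
        m = info_a & info_b
        a = has_a[m]
        b = has_b[m]
        n11 = int(np.count_nonzero(a & b))
        n10 = int(np.count_nonzero(a & ~b))
        n01 = int(np.count_nonzero(~a & b))
        n00 = int(m.sum()) - n11 - n10 - n01
        return ContingencyTable(n11, n10, n01, n00)


def build_table(
    reads: ReadSet,
    transcript: str,
    feature_a: int | str,
    feature_b: int | str,
) -> ContingencyTable:
    """2x2 table for one feature pair.  A read is informative iff it covers
    both site positions (and has a determined charging call when one feature
    is CHARGING); "has feature" means a mismatch at the site, or CHARGED."""
    if feature_a == feature_b:
        raise ValueError(f"feature pair must be distinct, got {feature_a!r} twice")
    positions = [f for f in (feature_a, feature_b) if f != CHARGING]
    return _TranscriptFeatures(reads, transcript, positions).table(feature_a, feature_b)


def _feature_sort_key(f: int | str) -> tuple[int, int]:
    return (1, 0) if f == CHARGING else (0, int(f))


def all_crosstalks(
    reads: ReadSet,
    sites: set[tuple[str, int]] | None = None,
    include_charging: bool = True,
    alpha: float = DEFAULT_ALPHA,
    min_pair_reads: int = DEFAULT_MIN_PAIR_READS,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    fdr_family: str = "global",
) -> pd.DataFrame:
    """Test every unordered feature pair per transcript.

    ``sites`` defaults to the candidate modified sites of this sample
    (mismatch fraction >= min_fraction, coverage >= min_coverage).  Pairs with
    fewer than ``min_pair_reads`` informative reads are skipped.  BH q-values
    are computed within one family: all tested pairs of the sample
    (fdr_family="global", default) or per transcript ("transcript").
    """
    if fdr_family not in ("global", "transcript"):
        raise ValueError(f"fdr_family must be 'global' or 'transcript', got {fdr_family!r}")
    if sites is None:
        sites = candidate_sites(pileup(reads), min_fraction, min_coverage)
    by_transcript: dict[str, list[int]] = {}
    for t, p in sorted(sites):
        by_transcript.setdefault(t, []).append(p)

    rows: list[dict] = []
    for transcript, positions in by_transcript.items():
        features: list[int | str] = sorted(positions)
        feats = _TranscriptFeatures(reads, transcript, positions)
        if include_charging and np.any(feats.charge >= 0):
            features.append(CHARGING)
        for fa, fb in itertools.combinations(features, 2):
            table = feats.table(fa, fb)
            if table.total < min_pair_reads:
                continue
            or_raw = odds_ratio(table)
            rows.append(
                {
                    "sample": reads.sample_id,
                    "transcript": transcript,
                    "feature_a": fa,
                    "feature_b": fb,
                    "n11": table.n11,
                    "n10": table.n10,
                    "n01": table.n01,
                    "n00": table.n00,
                    "or_raw": or_raw,
                    "or_corrected": corrected_odds_ratio(table),
                    "log2_or": _log2_or(or_raw),
                    "p": fisher_test(table),
                    "direction": direction_of(or_raw).value,
                }
            )
    df = pd.DataFrame(rows, columns=[c for c in CROSSTALK_COLUMNS if c not in ("q", "significant")])
    if df.empty:
        df["q"] = []
        df["significant"] = []
        return df[CROSSTALK_COLUMNS]
    # stable ordering for reproducible BH tie handling and output
    df = df.sort_values(
        ["p", "transcript", "feature_a", "feature_b"],
        key=lambda s: s.map(str) if s.name in ("feature_a", "feature_b") else s,
        kind="mergesort",
    ).reset_index(drop=True)
    if fdr_family == "global":
        df["q"] = fdr_correct(df["p"].to_numpy())
    else:
        df["q"] = np.nan
        for _, idx in df.groupby("transcript").groups.items():
            df.loc[idx, "q"] = fdr_correct(df.loc[idx, "p"].to_numpy())
    df["significant"] = df["q"] <= alpha
    return df[CROSSTALK_COLUMNS]


def consensus_crosstalks(
    per_replicate: Sequence[pd.DataFrame],
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Crosstalks significant with the same direction in >= min_replicates
    biological replicates.

    Pairs significant with conflicting directions across replicates are
    excluded and logged.  Returns columns transcript, feature_a, feature_b,
    direction, n_replicates.
    """
    if len(per_replicate) < min_replicates:
        raise ValueError(
            f"need at least {min_replicates} replicate result sets, "
            f"got {len(per_replicate)}"
        )
    votes: dict[tuple, dict[str, int]] = {}
    for rep in per_replicate:
        sig = rep[rep["significant"]]
        for row in sig.itertuples(index=False):
            key = (row.transcript, str(row.feature_a), str(row.feature_b))
            votes.setdefault(key, {})
            votes[key][row.direction] = votes[key].get(row.direction, 0) + 1
    rows = []
    for key, dirs in sorted(votes.items()):
        if len(dirs) > 1:
            log.warning(
                "crosstalk %s significant with conflicting directions %s; excluded",
                key,
                dirs,
            )
            continue
        direction, count = next(iter(dirs.items()))
        if count >= min_replicates:
            rows.append(
                {
                    "transcript": key[0],
                    "feature_a": key[1],
                    "feature_b": key[2],
                    "direction": direction,
                    "n_replicates": count,
                }
            )
    return pd.DataFrame(
        rows, columns=["transcript", "feature_a", "feature_b", "direction", "n_replicates"]
    )
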