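"""Per-position mismatch pileups, candidate modified sites, charging calls.

Modifications that perturb Watson-Crick pairing (m1A, m2,2G, m1G, m3C, ...)
leave misincorporation signatures during reverse transcription.  A position is
treated as a candidate modified site when at least 5% of covering reads carry
a mismatch there (inclusive threshold).  Charging is read off the 3' terminus:
after periodate oxidation / beta-elimination library chemistry, aminoacylated
tRNAs end 3'-CCA and deacylated ones 3'-CC.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .read_model import EndCall, ReadSet, SingleReadRecord

__all__ = [
    "SiteProfile",
    "ChargingState",
    "pileup",
    "candidate_sites",
    "call_charging",
    "charging_summary",
    "write_site_profiles",
]

DEFAULT_MIN_FRACTION = 0.05
DEFAULT_MIN_COVERAGE = 50

PILEUP_COLUMNS = ["transcript", "position", "coverage", "mismatch_count", "mismatch_fraction"]


@dataclass(frozen=True, slots=True)
class SiteProfile:
    """Mismatch pileup at one (transcript, position)."""

    transcript_id: str
    position: int
    coverage: int
    mismatch_count: int

    @property
    def mismatch_fraction(self) -> float:
        return self.mismatch_count / self.coverage


class ChargingState(str, enum.Enum):
    CHARGED = "CHARGED"
    UNCHARGED = "UNCHARGED"
    UNDETERMINED = "UNDETERMINED"


def pileup(reads: ReadSet) -> pd.DataFrame:
    """Per-position coverage and mismatch counts for every transcript.

    A read covers position p iff align_start <= p <= align_end and p is not
    deleted in the read.  Positions with zero coverage are omitted.  Returns a
    DataFrame with columns transcript, position, coverage, mismatch_count,
    mismatch_fraction.
    """
    if not reads.records:
        raise ValueError("pileup requires a nonempty ReadSet")
    frames = []
    for transcript in reads.transcripts():
        recs = reads.records_for(transcript)
        if reads.reference:
            length = len(reads.reference[transcript])
        else:
            length = max(r.align_end for r in recs)
        # coverage by difference array over the aligned span, minus deletions
        delta = np.zeros(length + 2, dtype=np.int64)
        mism = np.zeros(length + 1, dtype=np.int64)
        for r in recs:
            delta[r.align_start] += 1
            delta[r.align_end + 1] -= 1
            for p in r.deletions:
                delta[p] -= 1
                delta[p + 1] += 1
            for p in r.mismatch_positions:
                mism[p] += 1
        coverage = np.cumsum(delta)[1 : length + 1]
        positions = np.arange(1, length + 1)
        keep = coverage > 0
        frames.append(
            pd.DataFrame(
                {
                    "transcript": transcript,
                    "position": positions[keep],
                    "coverage": coverage[keep],
                    "mismatch_count": mism[1:][keep],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["mismatch_fraction"] = out["mismatch_count"] / out["coverage"]
    return out


def candidate_sites(
    profiles: pd.DataFrame,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> set[tuple[str, int]]:
    """Positions with mismatch_fraction >= min_fraction (inclusive) and
    coverage >= min_coverage."""
    if not 0 < min_fraction < 1:
        raise ValueError(f"min_fraction must be in (0, 1), got {min_fraction}")
    keep = (profiles["mismatch_fraction"] >= min_fraction) & (
        profiles["coverage"] >= min_coverage
    )
    return {
        (t, int(p))
        for t, p in zip(profiles.loc[keep, "transcript"], profiles.loc[keep, "position"])
    }


def call_charging(read: SingleReadRecord) -> ChargingState:
    """Map the read's 3'-terminus call to an aminoacylation state.

    CCA -> CHARGED, CC -> UNCHARGED; anything else (truncated reads, mismatched
    terminal bases) is UNDETERMINED.
    """
    if read.end_call is EndCall.CCA:
        return ChargingState.CHARGED
    if read.end_call is EndCall.CC:
        return ChargingState.UNCHARGED
    return ChargingState.UNDETERMINED


def charging_summary(reads: ReadSet) -> pd.DataFrame:
    """Per-transcript counts of charged / uncharged / undetermined reads and
    the charging fraction CHARGED / (CHARGED + UNCHARGED)."""
    rows: dict[str, dict[str, int]] = {}
    for r in reads.records:
        d = rows.setdefault(
            r.transcript_id, {"charged": 0, "uncharged": 0, "undetermined": 0}
        )
        state = call_charging(r)
        if state is ChargingState.CHARGED:
            d["charged"] += 1
        elif state is ChargingState.UNCHARGED:
            d["uncharged"] += 1
        else:
            d["undetermined"] += 1
    out = pd.DataFrame.from_dict(rows, orient="index").rename_axis("transcript")
    determined = out["charged"] + out["uncharged"]
    with np.errstate(invalid="ignore"):
        out["charging_fraction"] = np.where(
            determined > 0, out["charged"] / determined, np.nan
        )
    return out.reset_index()


def write_site_profiles(profiles: pd.DataFrame, path: str | Path) -> None:
    profiles.to_csv(path, sep="\t", index=False)
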