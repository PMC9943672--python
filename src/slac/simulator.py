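"""Synthetic single-read tRNA datasets with a prescribed pairwise odds ratio.

The generator plants Bernoulli misincorporation signatures at two positions of
a fixed tRNA template (defaults: 26 and 58 of the 76-nt mature yeast
tRNA-Phe-GAA, the classic m2,2G26 / m1A58 pair) with marginal probabilities
p_A, p_B and a target odds ratio.  The joint probability of carrying both
marks is the closed-form root of the odds-ratio identity

    OR = p_AB (1 - p_A - p_B + p_AB) / ((p_A - p_AB)(p_B - p_AB))

which is quadratic in p_AB; the "-sqrt" root is the valid one.  Optional
layers add an aminoacylation state (CCA vs CC 3' end) and 3' truncation into
tRF classes, optionally conditional on the modification state, so every
downstream module can be exercised against known ground truth.

The default validation experiment draws one 20,000-read sample for every
combination of 10 marginal probabilities (0.075 ... 0.975) x 10 x 7 log2(OR)
values (-1, -0.5, -0.25, 0, 0.25, 0.5, 1), i.e. 700 samples, and runs each
through the crosstalk pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .crosstalk_core import all_crosstalks
from .read_model import EndCall, ReadSet, SingleReadRecord

__all__ = [
    "YEAST_PHE_GAA_ID",
    "YEAST_PHE_GAA_SEQ",
    "DEFAULT_GRID_P",
    "DEFAULT_GRID_LOG2_OR",
    "SimSpec",
    "SimTruth",
    "solve_p_ab",
    "joint_cell_probabilities",
    "simulate_sample",
    "mutate_sequence",
    "write_fastq",
    "write_sam",
    "write_truth_table",
    "run_grid",
    "sensitivity_floor",
]

YEAST_PHE_GAA_ID = "tRNA-Phe-GAA-2"
#: Mature yeast phenylalanine tRNA (DNA alphabet), 73 nt + 3' CCA = 76 nt.
#: Position 26 is the m2,2G site (G) and position 58 the m1A site (A).
YEAST_PHE_GAA_SEQ = (
    "GCGGATTTAGCTCAGTTGGGAGAGCGCCAGACTGAAGATCTGGAGGTCCTGTGTTCGATCCACAGAATTCGCACCA"
)

DEFAULT_GRID_P = [0.075, 0.175, 0.275, 0.375, 0.475, 0.575, 0.675, 0.775, 0.875, 0.975]
DEFAULT_GRID_LOG2_OR = [-1.0, -0.5, -0.25, 0.0, 0.25, 0.5, 1.0]

_TRF_BINS = {"TRF_30_39": (30, 39), "TRF_40_49": (40, 49), "TRF_50_59": (50, 59)}


@dataclass(slots=True)
class SimSpec:
    """Parameters of one simulated sample.

    ``truncation`` maps a tRF class label to the probability that a read is
    truncated into that bin; a value may be a single float or an
    (unmodified, modified) pair making truncation conditional on the
    modification state at ``positions[0]``.  ``seed`` may be an int or a
    tuple of ints (entropy sequence), both deterministic.
    """

    p_a: float
    p_b: float
    target_or: float
    positions: tuple[int, int] = (26, 58)
    n_reads: int = 20_000
    transcript_id: str = YEAST_PHE_GAA_ID
    reference_seq: str = YEAST_PHE_GAA_SEQ
    charging_prob: float | None = None
    truncation: Mapping[str, float | tuple[float, float]] | None = None
    seed: int | tuple[int, ...] = 0


@dataclass(slots=True)
class SimTruth:
    """Latent per-read ground truth of a simulated sample."""

    mod_a: np.ndarray  # bool, latent modification state at positions[0]
    mod_b: np.ndarray  # bool, at positions[1]
    charged: np.ndarray  # bool (all True when charging not simulated)
    frag_class: np.ndarray  # str labels, "FULL_LENGTH" or a tRF class
    align_end: np.ndarray  # int, emitted 3' terminus
    spec: SimSpec = field(repr=False)


def solve_p_ab(p_a: float, p_b: float, target_or: float) -> float:
    """Joint probability of both marks for given marginals and odds ratio.

    Uses the closed-form "-sqrt" root of the quadratic odds-ratio identity;
    the independence limit (OR = 1) is p_a * p_b.  The returned value is
    validated: all four joint cells must lie in [0, 1] and back-substitution
    must recover ``target_or`` to within 1e-9.
    """
    if not (0 < p_a < 1 and 0 < p_b < 1):
        raise ValueError(f"marginals must be in (0, 1), got ({p_a}, {p_b})")
    if target_or <= 0:
        raise ValueError(f"target odds ratio must be positive, got {target_or}")
    if abs(target_or - 1.0) < 1e-12:
        p_ab = p_a * p_b
    else:
        b = 1.0 + (p_a + p_b) * (target_or - 1.0)
        disc = b * b + 4.0 * target_or * (1.0 - target_or) * p_a * p_b
        p_ab = (b - math.sqrt(disc)) / (2.0 * (target_or - 1.0))
        # the closed form cancels catastrophically as OR -> 1; polish the
        # root of g(p) = p(1-p_a-p_b+p) - OR(p_a-p)(p_b-p) with Newton steps
        p_ab = min(max(p_ab, max(0.0, p_a + p_b - 1.0)), min(p_a, p_b))
        for _ in range(50):
            g = p_ab * (1.0 - p_a - p_b + p_ab) - target_or * (p_a - p_ab) * (
                p_b - p_ab
            )
            dg = 1.0 - p_a - p_b + 2.0 * p_ab + target_or * (p_a + p_b - 2.0 * p_ab)
            step = g / dg
            p_ab -= step
            if abs(step) < 1e-15:
                break
    cells = {
        "p_AB": p_ab,
        "p_A_only": p_a - p_ab,
        "p_B_only": p_b - p_ab,
        "p_neither": 1.0 - p_a - p_b + p_ab,
    }
    for name, value in cells.items():
        if not -1e-12 <= value <= 1.0 + 1e-12:
            raise ValueError(
                f"joint cell {name} = {value:.6g} outside [0, 1] for "
                f"(p_a={p_a}, p_b={p_b}, OR={target_or})"
            )
    if abs(target_or - 1.0) >= 1e-12:
        implied = (p_ab * cells["p_neither"]) / (
            cells["p_A_only"] * cells["p_B_only"]
        )
        if not math.isclose(implied, target_or, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(
                f"root failed the odds-ratio identity: implied {implied!r} "
                f"vs target {target_or!r}"
            )
    return p_ab


def joint_cell_probabilities(p_a: float, p_b: float, target_or: float) -> np.ndarray:
    """[p_both, p_A_only, p_B_only, p_neither], clipped of float dust.

    Degenerate marginals (p_a or p_b equal to 0 or 1) are allowed here: the
    joint cell is then fully determined by the marginals and the odds ratio
    is irrelevant.
    """
    if p_a == 0.0 or p_b == 0.0:
        p_ab = 0.0
    elif p_a == 1.0 or p_b == 1.0:
        p_ab = min(p_a, p_b)
    else:
        p_ab = solve_p_ab(p_a, p_b, target_or)
    cells = np.array([p_ab, p_a - p_ab, p_b - p_ab, 1.0 - p_a - p_b + p_ab])
    cells = np.clip(cells, 0.0, 1.0)
    return cells / cells.sum()


_ALT_BASE = {"A": "C", "C": "A", "G": "A", "T": "A", "N": "A"}


def mutate_sequence(reference_seq: str, mismatch_positions: Sequence[int]) -> str:
    """Substitute the first non-reference base (alphabetical) at each 1-based
    position; base identity is irrelevant downstream, so the choice is simply
    deterministic."""
    seq = list(reference_seq)
    for p in mismatch_positions:
        seq[p - 1] = _ALT_BASE[seq[p - 1]]
    return "".join(seq)


def simulate_sample(spec: SimSpec) -> tuple[ReadSet, SimTruth]:
    """Draw one sample of ``spec.n_reads`` single-read records.

    Modification states come from the four-cell joint distribution; charging
    (if configured) is an independent Bernoulli realised as a CC 3' end on
    uncharged reads; truncation (if configured) draws a tRF bin per read --
    possibly conditional on the latent state at ``positions[0]`` -- and a
    uniform 3' terminus within the bin.  A mismatch is *observed* on a read
    only when its position lies within the aligned span.  Identical spec
    (including seed) reproduces the identical sample.
    """
    rng = np.random.default_rng(spec.seed)
    pos_a, pos_b = spec.positions
    length = len(spec.reference_seq)
    if not 1 <= pos_a < pos_b <= length:
        raise ValueError(f"positions {spec.positions} invalid for length {length}")
    n = spec.n_reads
    cells = joint_cell_probabilities(spec.p_a, spec.p_b, spec.target_or)
    counts = rng.multinomial(n, cells)
    state = np.repeat(np.arange(4), counts)
    rng.shuffle(state)
    mod_a = (state == 0) | (state == 1)
    mod_b = (state == 0) | (state == 2)

    if spec.charging_prob is not None:
        if not 0 <= spec.charging_prob <= 1:
            raise ValueError(f"charging_prob {spec.charging_prob} outside [0, 1]")
        charged = rng.random(n) < spec.charging_prob
    else:
        charged = np.ones(n, dtype=bool)
    align_end = np.where(charged, length, length - 1)
    frag_class = np.full(n, "FULL_LENGTH", dtype=object)

    if spec.truncation:
        probs = np.zeros((n, len(spec.truncation)))
        labels = list(spec.truncation)
        for j, label in enumerate(labels):
            if label not in _TRF_BINS:
                raise ValueError(f"unknown tRF class {label!r}")
            value = spec.truncation[label]
            if isinstance(value, (tuple, list)):
                p_unmod, p_mod = value
            else:
                p_unmod = p_mod = float(value)
            probs[:, j] = np.where(mod_a, p_mod, p_unmod)
        total = probs.sum(axis=1)
        if np.any(total > 1):
            raise ValueError("truncation probabilities sum above 1 for some reads")
        u = rng.random(n)
        cum = np.cumsum(probs, axis=1)
        for j, label in enumerate(labels):
            lo = cum[:, j - 1] if j else np.zeros(n)
            hit = (u >= lo) & (u < cum[:, j])
            if not hit.any():
                continue
            low, high = _TRF_BINS[label]
            align_end[hit] = rng.integers(low, high + 1, size=int(hit.sum()))
            frag_class[hit] = label
            charged[hit] = False  # a truncated read carries no CCA context

    records = []
    ref_len = length
    for i in range(n):
        end = int(align_end[i])
        mism = []
        if mod_a[i] and pos_a <= end:
            mism.append(pos_a)
        if mod_b[i] and pos_b <= end:
            mism.append(pos_b)
        if end == ref_len:
            end_call = EndCall.CCA
        elif end == ref_len - 1:
            end_call = EndCall.CC
        else:
            end_call = EndCall.UNREACHED
        records.append(
            SingleReadRecord(
                read_id=f"sim{i}",
                transcript_id=spec.transcript_id,
                align_start=1,
                align_end=end,
                mismatch_positions=frozenset(mism),
                end_call=end_call,
            )
        )
    readset = ReadSet(
        sample_id=f"sim_pa{spec.p_a}_pb{spec.p_b}_or{spec.target_or}",
        records=records,
        reference={spec.transcript_id: spec.reference_seq},
    )
    truth = SimTruth(
        mod_a=mod_a,
        mod_b=mod_b,
        charged=charged,
        frag_class=np.asarray(frag_class),
        align_end=align_end.astype(int),
        spec=spec,
    )
    return readset, truth


def write_truth_table(truth: SimTruth, path: str | Path) -> None:
    pd.DataFrame(
        {
            "read_id": [f"sim{i}" for i in range(len(truth.mod_a))],
            "mod_a": truth.mod_a.astype(int),
            "mod_b": truth.mod_b.astype(int),
            "charged": truth.charged.astype(int),
            "frag_class": truth.frag_class,
            "align_end": truth.align_end,
        }
    ).to_csv(path, sep="\t", index=False)


def _read_sequence(read: SingleReadRecord, reference_seq: str) -> str:
    seq = mutate_sequence(reference_seq, sorted(read.mismatch_positions))
    return seq[read.align_start - 1 : read.align_end]


def write_fastq(readset: ReadSet, path: str | Path) -> None:
    """Emit reads as FASTQ (uniform qualities) for alignment-path testing."""
    with open(path, "w") as out:
        for r in readset.records:
            seq = _read_sequence(r, readset.reference[r.transcript_id])
            out.write(f"@{r.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_sam(readset: ReadSet, path: str | Path) -> None:
    """Emit reads as a text SAM with full-match CIGARs against the reference."""
    with open(path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:coordinate\n")
        for tid, seq in readset.reference.items():
            out.write(f"@SQ\tSN:{tid}\tLN:{len(seq)}\n")
        for r in sorted(readset.records, key=lambda r: (r.transcript_id, r.align_start)):
            seq = _read_sequence(r, readset.reference[r.transcript_id])
            out.write(
                f"{r.read_id}\t0\t{r.transcript_id}\t{r.align_start}\t60\t"
                f"{len(seq)}M\t*\t0\t0\t{seq}\t{'I' * len(seq)}\n"
            )


def run_grid(
    p_values: Sequence[float] | None = None,
    log2_or_values: Sequence[float] | None = None,
    n_reads: int = 20_000,
    seed: int = 0,
    positions: tuple[int, int] = (26, 58),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Simulate and analyze the full (p_A, p_B, OR) validation grid.

    One sample per combination (10 x 10 x 7 = 700 by default), each pushed
    through pileup -> candidate sites -> pairwise crosstalk testing.  Returns
    one row per sample with the generating parameters and the estimate,
    p-value and q-value for the planted pair (NaN / detected=False when the
    pair did not reach the pipeline's filters).  Per-sample seeds are derived
    from (seed, i, j, k), so the grid is reproducible and order-independent.
    """
    p_values = list(DEFAULT_GRID_P if p_values is None else p_values)
    log2_or_values = list(
        DEFAULT_GRID_LOG2_OR if log2_or_values is None else log2_or_values
    )
    pos_a, pos_b = positions
    rows = []
    for i, p_a in enumerate(p_values):
        for j, p_b in enumerate(p_values):
            for k, log2_or in enumerate(log2_or_values):
                target_or = 2.0**log2_or
                spec = SimSpec(
                    p_a=p_a,
                    p_b=p_b,
                    target_or=target_or,
                    positions=positions,
                    n_reads=n_reads,
                    seed=(seed, i, j, k),
                )
                readset, _ = simulate_sample(spec)
                results = all_crosstalks(
                    readset, include_charging=False, alpha=alpha
                )
                hit = results[
                    (results["feature_a"] == pos_a) & (results["feature_b"] == pos_b)
                ]
                row = {
                    "p_a": p_a,
                    "p_b": p_b,
                    "log2_or": log2_or,
                    "target_or": target_or,
                    "n_reads": n_reads,
                }
                if len(hit):
                    h = hit.iloc[0]
                    row.update(
                        or_raw=h["or_raw"],
                        or_corrected=h["or_corrected"],
                        log2_or_est=math.log2(h["or_corrected"])
                        if h["or_corrected"] > 0
                        else math.nan,
                        p=h["p"],
                        q=h["q"],
                        detected=bool(h["significant"]),
                    )
                else:
                    row.update(
                        or_raw=math.nan,
                        or_corrected=math.nan,
                        log2_or_est=math.nan,
                        p=math.nan,
                        q=math.nan,
                        detected=False,
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def sensitivity_floor(
    grid: pd.DataFrame,
    marginal_range: tuple[float, float] = (0.075, 0.875),
    majority: float = 0.75,
) -> float | None:
    """Smallest positive-association grid odds ratio detected in at least a
    ``majority`` fraction of cells whose marginals both lie in
    ``marginal_range`` (inclusive).  None when no positive OR qualifies."""
    lo, hi = marginal_range
    sub = grid[
        (grid["p_a"] >= lo)
        & (grid["p_a"] <= hi)
        & (grid["p_b"] >= lo)
        & (grid["p_b"] <= hi)
        & (grid["log2_or"] > 0)
    ]
    for log2_or in sorted(sub["log2_or"].unique()):
        cells = sub[sub["log2_or"] == log2_or]
        if cells["detected"].mean() >= majority:
            return float(2.0**log2_or)
    return None
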