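"""Condition-versus-condition tests and crosstalk-consistency analysis.

Two layers:

* :func:`differential_test` asks whether the level of a feature (mismatch
  fraction at a modified site, or charging) differs between two samples.  The
  effect size is the ratio of odds

      OR = (modified_A / unmodified_A) / (modified_B / unmodified_B)

  tested with a Pearson chi-square on the 2x2 table (Fisher fallback when a
  marginal is zero), BH-corrected across features.

* :func:`consistency_analysis` asks whether condition-induced changes respect
  previously detected crosstalks: for a stimulatory pair (OR > 1) both
  endpoints should move in the same direction, for an inhibitory pair
  (OR < 1) in opposite directions.  Each evaluable crosstalk gets a
  TRUE/FALSE verdict and the TRUE count is tested against chance with a
  one-sided binomial test (null p = 0.5).
"""

from __future__ import annotations

import enum
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .crosstalk_core import (
    CHARGING,
    DEFAULT_ALPHA,
    ContingencyTable,
    Direction,
    fdr_correct,
    fisher_test,
)
from .read_model import ReadSet
from .site_detection import (
    DEFAULT_MIN_COVERAGE,
    DEFAULT_MIN_FRACTION,
    ChargingState,
    call_charging,
    candidate_sites,
    pileup,
)

__all__ = [
    "Verdict",
    "feature_counts",
    "differential_test",
    "consistency_analysis",
    "binomial_consistency_p",
]

DEFAULT_MIN_DELTA = 0.03

DIFF_COLUMNS = [
    "transcript",
    "feature",
    "mod_a",
    "unmod_a",
    "mod_b",
    "unmod_b",
    "fraction_a",
    "fraction_b",
    "delta_fraction",
    "odds_ratio",
    "p",
    "q",
    "test",
    "significant",
]


class Verdict(str, enum.Enum):
    TRUE = "TRUE"
    FALSE = "FALSE"
    NOT_EVALUABLE = "NOT_EVALUABLE"


def feature_counts(reads: ReadSet, transcript: str, feature: int | str) -> tuple[int, int]:
    """(with-feature, without-feature) read counts for one feature.

    For a site: mismatched vs matched among reads covering the position.  For
    CHARGING: CCA- vs CC-ending reads; undetermined reads are excluded.
    """
    recs = reads.records_for(transcript)
    if feature == CHARGING:
        states = [call_charging(r) for r in recs]
        return (
            sum(s is ChargingState.CHARGED for s in states),
            sum(s is ChargingState.UNCHARGED for s in states),
        )
    pos = int(feature)
    covering = [r for r in recs if r.covers(pos)]
    n_mod = sum(pos in r.mismatch_positions for r in covering)
    return n_mod, len(covering) - n_mod


def _diff_or(mod_a: int, unmod_a: int, mod_b: int, unmod_b: int) -> float:
    num_num = mod_a * unmod_b
    den = unmod_a * mod_b
    if num_num == 0 and den == 0:
        return math.nan
    if den == 0:
        return math.inf
    return num_num / den


def differential_test(
    reads_a: ReadSet,
    reads_b: ReadSet,
    features: Sequence[tuple[str, int | str]] | None = None,
    include_charging: bool = True,
    alpha: float = DEFAULT_ALPHA,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    yates: bool = False,
) -> pd.DataFrame:
    """Per-feature condition A vs condition B comparison.

    ``features`` is a sequence of (transcript, feature) with feature a site
    position or the CHARGING token; by default it is the union of candidate
    sites of the two samples plus CHARGING for transcripts where both samples
    have determined charging calls.  ``delta_fraction`` is fraction_A -
    fraction_B.  Chi-square is computed without Yates continuity correction
    unless ``yates`` is set; tables with a zero marginal fall back to Fisher
    (flagged in the ``test`` column).
    """
    if features is None:
        feats: set[tuple[str, int | str]] = set()
        feats |= candidate_sites(pileup(reads_a), min_fraction, min_coverage)
        feats |= candidate_sites(pileup(reads_b), min_fraction, min_coverage)
        if include_charging:
            for t in set(reads_a.transcripts()) & set(reads_b.transcripts()):
                ca = feature_counts(reads_a, t, CHARGING)
                cb = feature_counts(reads_b, t, CHARGING)
                if sum(ca) > 0 and sum(cb) > 0:
                    feats.add((t, CHARGING))
        features = sorted(feats, key=lambda tf: (tf[0], str(tf[1])))

    rows = []
    for transcript, feature in features:
        mod_a, unmod_a = feature_counts(reads_a, transcript, feature)
        mod_b, unmod_b = feature_counts(reads_b, transcript, feature)
        table = np.array([[mod_a, unmod_a], [mod_b, unmod_b]], dtype=np.int64)
        frac_a = mod_a / (mod_a + unmod_a) if mod_a + unmod_a else math.nan
        frac_b = mod_b / (mod_b + unmod_b) if mod_b + unmod_b else math.nan
        if table.sum() == 0:
            p, test = math.nan, "none"
        elif 0 in table.sum(axis=0) or 0 in table.sum(axis=1):
            # chi-square undefined with a zero marginal
            p = fisher_test(ContingencyTable(mod_a, unmod_a, mod_b, unmod_b))
            test = "fisher"
        else:
            p = float(stats.chi2_contingency(table, correction=yates)[1])
            test = "chi2"
        rows.append(
            {
                "transcript": transcript,
                "feature": feature,
                "mod_a": mod_a,
                "unmod_a": unmod_a,
                "mod_b": mod_b,
                "unmod_b": unmod_b,
                "fraction_a": frac_a,
                "fraction_b": frac_b,
                "delta_fraction": frac_a - frac_b,
                "odds_ratio": _diff_or(mod_a, unmod_a, mod_b, unmod_b),
                "p": p,
                "test": test,
            }
        )
    df = pd.DataFrame(rows, columns=[c for c in DIFF_COLUMNS if c not in ("q", "significant")])
    if df.empty:
        df["q"] = []
        df["significant"] = []
        return df[DIFF_COLUMNS]
    tested = df["p"].notna()
    df["q"] = np.nan
    df.loc[tested, "q"] = fdr_correct(df.loc[tested, "p"].to_numpy())
    df["significant"] = df["q"] <= alpha
    return df[DIFF_COLUMNS]


def binomial_consistency_p(n_true: int, n_evaluable: int) -> float:
    """Exact one-sided binomial tail P(X >= n_true | n, p=0.5)."""
    return float(
        stats.binomtest(n_true, n_evaluable, 0.5, alternative="greater").pvalue
    )


def consistency_analysis(
    crosstalks: pd.DataFrame,
    diffs: pd.DataFrame,
    min_delta: float = DEFAULT_MIN_DELTA,
    alpha: float = DEFAULT_ALPHA,
    require_both: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Score each crosstalk against the observed condition-induced changes.

    ``crosstalks`` needs columns transcript, feature_a, feature_b, direction
    (e.g. a consensus set); ``diffs`` is a :func:`differential_test` output.
    Both endpoints must have a significant differential test (q <= alpha).
    The >min_delta magnitude filter applies to both endpoints when
    ``require_both`` (default, stricter), or to at least one endpoint when
    relaxed.  Anything else is NOT_EVALUABLE.  Verdict TRUE iff the signs of
    the two deltas agree for stimulatory crosstalks and disagree for
    inhibitory ones.  Returns (records, summary) where summary has the
    TRUE/FALSE counts and the one-sided binomial p (None when nothing is
    evaluable).
    """
    changed: dict[tuple[str, str], float] = {}
    for row in diffs.itertuples(index=False):
        if (
            not math.isnan(row.delta_fraction)
            and row.q == row.q
            and row.q <= alpha
            and row.delta_fraction != 0
        ):
            changed[(row.transcript, str(row.feature))] = row.delta_fraction

    records = []
    for row in crosstalks.itertuples(index=False):
        da = changed.get((row.transcript, str(row.feature_a)))
        db = changed.get((row.transcript, str(row.feature_b)))
        if da is None or db is None:
            verdict = Verdict.NOT_EVALUABLE
        elif require_both and not (abs(da) > min_delta and abs(db) > min_delta):
            verdict = Verdict.NOT_EVALUABLE
        elif not require_both and not (abs(da) > min_delta or abs(db) > min_delta):
            verdict = Verdict.NOT_EVALUABLE
        else:
            same_sign = (da > 0) == (db > 0)
            expected_same = row.direction == Direction.STIMULATORY.value
            verdict = Verdict.TRUE if same_sign == expected_same else Verdict.FALSE
        records.append(
            {
                "transcript": row.transcript,
                "feature_a": row.feature_a,
                "feature_b": row.feature_b,
                "direction": row.direction,
                "delta_a": da if da is not None else math.nan,
                "delta_b": db if db is not None else math.nan,
                "verdict": verdict.value,
            }
        )
    records_df = pd.DataFrame(
        records,
        columns=[
            "transcript",
            "feature_a",
            "feature_b",
            "direction",
            "delta_a",
            "delta_b",
            "verdict",
        ],
    )
    n_true = int((records_df["verdict"] == Verdict.TRUE.value).sum())
    n_false = int((records_df["verdict"] == Verdict.FALSE.value).sum())
    n_evaluable = n_true + n_false
    summary = {
        "n_true": n_true,
        "n_false": n_false,
        "n_evaluable": n_evaluable,
        "p_value": binomial_consistency_p(n_true, n_evaluable) if n_evaluable else None,
    }
    return records_df, summary
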