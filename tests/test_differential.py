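"""Condition comparisons and crosstalk-consistency scoring."""

import math

import numpy as np
import pandas as pd
import pytest

from slac.crosstalk_core import CHARGING
from slac.differential import (
    Verdict,
    binomial_consistency_p,
    consistency_analysis,
    differential_test,
    feature_counts,
)
from slac.simulator import YEAST_PHE_GAA_ID, SimSpec, simulate_sample

from conftest import make_read


def _site_readset(make_readset, n_mod, n_unmod, sample="s"):
    reads = [make_read(i, {26} if i < n_mod else ()) for i in range(n_mod + n_unmod)]
    return make_readset(reads, sample_id=sample)


FEATURES = [(YEAST_PHE_GAA_ID, 26)]


class TestDifferentialTest:
    def test_hand_arithmetic_or(self, make_readset):
        a = _site_readset(make_readset, 60, 40, "a")
        b = _site_readset(make_readset, 30, 70, "b")
        res = differential_test(a, b, features=FEATURES)
        row = res.iloc[0]
        assert row.odds_ratio == pytest.approx((60 / 40) / (30 / 70))
        assert row.delta_fraction == pytest.approx(0.30)
        assert row.test == "chi2"

    def test_identical_conditions_null(self, make_readset):
        a = _site_readset(make_readset, 50, 50, "a")
        b = _site_readset(make_readset, 50, 50, "b")
        row = differential_test(a, b, features=FEATURES).iloc[0]
        assert row.odds_ratio == pytest.approx(1.0)
        assert row.p == pytest.approx(1.0)

    def test_antisymmetric_under_condition_swap(self, make_readset):
        a = _site_readset(make_readset, 63, 37, "a")
        b = _site_readset(make_readset, 22, 78, "b")
        ab = differential_test(a, b, features=FEATURES).iloc[0]
        ba = differential_test(b, a, features=FEATURES).iloc[0]
        assert ab.odds_ratio == pytest.approx(1.0 / ba.odds_ratio)
        assert ab.delta_fraction == pytest.approx(-ba.delta_fraction)

    def test_zero_marginal_falls_back_to_fisher(self, make_readset):
        a = _site_readset(make_readset, 0, 100, "a")
        b = _site_readset(make_readset, 0, 100, "b")
        row = differential_test(a, b, features=FEATURES).iloc[0]
        assert row.test == "fisher"
        assert row.p == pytest.approx(1.0)

    def test_charging_shift_detected_at_power_scale(self):
        a, _ = simulate_sample(
            SimSpec(p_a=0.2, p_b=0.2, target_or=1.0, n_reads=5_000,
                    charging_prob=0.70, seed=10)
        )
        b, _ = simulate_sample(
            SimSpec(p_a=0.2, p_b=0.2, target_or=1.0, n_reads=5_000,
                    charging_prob=0.60, seed=11)
        )
        res = differential_test(a, b, features=[(YEAST_PHE_GAA_ID, CHARGING)])
        row = res.iloc[0]
        assert row.q < 0.05
        assert row.delta_fraction == pytest.approx(0.10, abs=0.03)

    def test_auto_features_include_sites_and_charging(self):
        a, _ = simulate_sample(
            SimSpec(p_a=0.2, p_b=0.3, target_or=1.0, n_reads=2_000,
                    charging_prob=0.7, seed=12)
        )
        b, _ = simulate_sample(
            SimSpec(p_a=0.3, p_b=0.2, target_or=1.0, n_reads=2_000,
                    charging_prob=0.5, seed=13)
        )
        res = differential_test(a, b)
        feats = set(res.feature)
        assert feats == {26, 58, CHARGING}


class TestConsistency:
    @staticmethod
    def _crosstalks(rows):
        return pd.DataFrame(
            rows, columns=["transcript", "feature_a", "feature_b", "direction"]
        )

    @staticmethod
    def _diffs(rows):
        return pd.DataFrame(
            rows, columns=["transcript", "feature", "delta_fraction", "q"]
        )

    def test_stimulatory_same_direction_true(self):
        ct = self._crosstalks([("t1", 26, 58, "STIMULATORY")])
        df = self._diffs([("t1", 26, 0.10, 0.01), ("t1", 58, 0.08, 0.01)])
        records, summary = consistency_analysis(ct, df)
        assert records.iloc[0].verdict == Verdict.TRUE.value
        assert summary["n_evaluable"] == 1

    def test_inhibitory_same_direction_false(self):
        ct = self._crosstalks([("t1", 26, 58, "INHIBITORY")])
        df = self._diffs([("t1", 26, 0.10, 0.01), ("t1", 58, 0.08, 0.01)])
        records, _ = consistency_analysis(ct, df)
        assert records.iloc[0].verdict == Verdict.FALSE.value

    def test_inhibitory_opposite_direction_true(self):
        ct = self._crosstalks([("t1", 26, 58, "INHIBITORY")])
        df = self._diffs([("t1", 26, 0.10, 0.01), ("t1", 58, -0.08, 0.01)])
        records, _ = consistency_analysis(ct, df)
        assert records.iloc[0].verdict == Verdict.TRUE.value

    def test_small_or_nonsignificant_changes_not_evaluable(self):
        ct = self._crosstalks([("t1", 26, 58, "STIMULATORY")] * 1)
        below_delta = self._diffs([("t1", 26, 0.02, 0.01), ("t1", 58, 0.08, 0.01)])
        records, summary = consistency_analysis(ct, below_delta)
        assert records.iloc[0].verdict == Verdict.NOT_EVALUABLE.value
        assert summary["p_value"] is None
        not_sig = self._diffs([("t1", 26, 0.10, 0.50), ("t1", 58, 0.08, 0.01)])
        records, _ = consistency_analysis(ct, not_sig)
        assert records.iloc[0].verdict == Verdict.NOT_EVALUABLE.value

    def test_either_endpoint_relaxation(self):
        ct = self._crosstalks([("t1", 26, 58, "STIMULATORY")])
        df = self._diffs([("t1", 26, 0.02, 0.01), ("t1", 58, 0.08, 0.01)])
        records, _ = consistency_analysis(ct, df, require_both=False)
        assert records.iloc[0].verdict == Verdict.TRUE.value

    def test_binomial_matches_exact_tail(self):
        for n in (1, 5, 12, 20, 30):
            for k in range(n + 1):
                exact = sum(math.comb(n, j) for j in range(k, n + 1)) / 2**n
                assert binomial_consistency_p(k, n) == pytest.approx(exact, abs=1e-12)

    def test_latent_shift_respecting_crosstalk_signs_is_mostly_true(self):
        # a shared shift raising both endpoints of stimulatory pairs and
        # opposite endpoints of inhibitory pairs should score mostly TRUE
        rng = np.random.default_rng(5)
        ct_rows, diff_rows = [], []
        for i in range(24):
            t = f"t{i}"
            direction = "STIMULATORY" if i % 2 else "INHIBITORY"
            da = 0.05 + rng.uniform(0, 0.05)
            db = da if direction == "STIMULATORY" else -da
            if rng.random() < 0.1:  # occasional violation
                db = -db
            ct_rows.append((t, 26, 58, direction))
            diff_rows.append((t, 26, da, 0.001))
            diff_rows.append((t, 58, db, 0.001))
        records, summary = consistency_analysis(
            self._crosstalks(ct_rows), self._diffs(diff_rows)
        )
        assert summary["n_true"] > summary["n_false"]
        assert summary["p_value"] < 0.05
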