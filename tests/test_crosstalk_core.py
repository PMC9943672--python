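"""Contingency tables, odds ratios, Fisher testing, FDR, and consensus."""

import math

import numpy as np
import pandas as pd
import pytest

from slac.crosstalk_core import (
    CHARGING,
    ContingencyTable,
    all_crosstalks,
    build_table,
    consensus_crosstalks,
    corrected_odds_ratio,
    fdr_correct,
    fisher_test,
    odds_ratio,
)
from slac.read_model import EndCall
from slac.simulator import YEAST_PHE_GAA_ID, SimSpec, simulate_sample

from conftest import make_read


class TestBuildTable:
    def test_four_read_enumeration(self, make_readset):
        reads = [
            make_read(0, {26, 58}),
            make_read(1, {26}),
            make_read(2, {58}),
            make_read(3, ()),
        ]
        t = build_table(make_readset(reads), YEAST_PHE_GAA_ID, 26, 58)
        assert (t.n11, t.n10, t.n01, t.n00) == (1, 1, 1, 1)

    def test_noncovering_reads_excluded(self, make_readset):
        reads = [
            make_read(0, {26, 58}),
            make_read(1, {26}, end=40),  # never reaches 58
            make_read(2, {26}, deletions={58}),  # 58 deleted
        ]
        t = build_table(make_readset(reads), YEAST_PHE_GAA_ID, 26, 58)
        assert t.total == 1

    def test_charging_feature_uses_determined_reads_only(self, make_readset):
        reads = [
            make_read(0, {26}, end_call=EndCall.CCA),
            make_read(1, (), end_call=EndCall.CC, end=75),
            make_read(2, {26}, end_call=EndCall.OTHER),
        ]
        t = build_table(make_readset(reads), YEAST_PHE_GAA_ID, 26, CHARGING)
        assert t.total == 2
        assert t.n11 == 1  # modified and charged

    def test_identical_features_rejected(self, make_readset):
        with pytest.raises(ValueError):
            build_table(make_readset([make_read(0)]), YEAST_PHE_GAA_ID, 26, 26)

    def test_simulated_or_near_target(self):
        rs, _ = simulate_sample(
            SimSpec(p_a=0.5, p_b=0.5, target_or=2.0, n_reads=20_000, seed=8)
        )
        t = build_table(rs, YEAST_PHE_GAA_ID, 26, 58)
        assert odds_ratio(t) == pytest.approx(2.0, abs=0.1)


class TestOddsRatio:
    def test_symmetric_table_is_one(self):
        assert odds_ratio(ContingencyTable(10, 10, 10, 10)) == 1.0

    def test_hand_arithmetic(self):
        assert odds_ratio(ContingencyTable(30, 10, 10, 30)) == pytest.approx(9.0)

    def test_zero_cell_raw_and_corrected(self):
        t = ContingencyTable(5, 0, 3, 7)
        assert odds_ratio(t) == math.inf
        assert corrected_odds_ratio(t) == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))

    def test_zero_numerator(self):
        assert odds_ratio(ContingencyTable(0, 3, 5, 7)) == 0.0

    def test_degenerate_table_flagged_nan(self):
        # numerator and denominator products both vanish: undefined
        assert math.isnan(odds_ratio(ContingencyTable(0, 3, 0, 5)))

    def test_symmetry_under_feature_swap(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n11, n10, n01, n00 = rng.integers(0, 40, size=4)
            t = ContingencyTable(int(n11), int(n10), int(n01), int(n00))
            swapped = ContingencyTable(t.n11, t.n01, t.n10, t.n00)  # A <-> B
            flipped = ContingencyTable(t.n00, t.n01, t.n10, t.n11)  # 11<->00, 10<->01
            for other in (swapped, flipped):
                a, b = odds_ratio(t), odds_ratio(other)
                assert (a == b) or (math.isnan(a) and math.isnan(b))


class TestFisher:
    def test_null_table_p_one(self):
        assert fisher_test(ContingencyTable(10, 10, 10, 10)) == pytest.approx(1.0)

    def test_perfect_association_tiny_p(self):
        assert fisher_test(ContingencyTable(20, 0, 0, 20)) < 1e-9

    def test_matches_exact_enumeration_spot_checks(self):
        # exhaustive totals<=50 sweep lives in the acceptance suite; here a
        # random spot check against the exact integer hypergeometric oracle
        rng = np.random.default_rng(1)
        for _ in range(200):
            n11, n10, n01, n00 = (int(x) for x in rng.integers(0, 13, size=4))
            if n11 + n10 + n01 + n00 == 0:
                continue
            t = ContingencyTable(n11, n10, n01, n00)
            N, r, c = t.total, n11 + n10, n11 + n01
            ws = {
                k: math.comb(r, k) * math.comb(N - r, c - k)
                for k in range(max(0, r + c - N), min(r, c) + 1)
            }
            p_exact = sum(w for w in ws.values() if w <= ws[n11]) / math.comb(N, c)
            assert fisher_test(t) == pytest.approx(p_exact, abs=1e-10)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_test(ContingencyTable(0, 0, 0, 0))


class TestFdr:
    def test_single_test_q_equals_p(self):
        assert fdr_correct([0.013])[0] == pytest.approx(0.013)

    def test_step_up_hand_computation(self):
        q = fdr_correct([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_q_nondecreasing_in_p(self):
        rng = np.random.default_rng(2)
        p = np.sort(rng.uniform(size=100))
        q = fdr_correct(p)
        assert np.all(np.diff(q) >= -1e-15)
        assert np.all(q >= p)


class TestAllCrosstalks:
    def test_pair_count_three_sites_plus_charging(self, make_readset):
        rng = np.random.default_rng(3)
        reads = []
        for i in range(400):
            mism = {p for p in (20, 26, 58) if rng.random() < 0.3}
            end_call = EndCall.CCA if rng.random() < 0.6 else EndCall.CC
            end = 76 if end_call is EndCall.CCA else 75
            reads.append(make_read(i, mism, end=end, end_call=end_call))
        res = all_crosstalks(make_readset(reads), min_coverage=10)
        assert len(res) == 6  # C(4, 2)

    def test_planted_crosstalk_significant(self):
        rs, _ = simulate_sample(
            SimSpec(p_a=0.475, p_b=0.475, target_or=2.0, n_reads=20_000, seed=9)
        )
        res = all_crosstalks(rs, include_charging=False)
        row = res[(res.feature_a == 26) & (res.feature_b == 58)].iloc[0]
        assert row.significant
        assert row.q < 0.05
        assert row.direction == "STIMULATORY"

    def test_min_pair_reads_floor(self, make_readset):
        reads = [make_read(i, {26} if i % 2 else {58}) for i in range(30)]
        res = all_crosstalks(
            make_readset(reads), min_coverage=10, min_pair_reads=50
        )
        assert res.empty

    def test_fdr_family_flag(self, make_readset):
        rng = np.random.default_rng(4)
        reads = []
        for t in ("tRNA-A", "tRNA-B"):
            for i in range(200):
                mism = {p for p in (26, 58) if rng.random() < 0.3}
                reads.append(make_read(f"{t}:{i}", mism, transcript=t))
        rs = make_readset(reads)
        rs.reference = {}  # synthetic transcripts; infer lengths from reads
        global_q = all_crosstalks(
            rs, min_coverage=10, include_charging=False, fdr_family="global"
        )
        per_t = all_crosstalks(
            rs, min_coverage=10, include_charging=False, fdr_family="transcript"
        )
        assert len(global_q) == len(per_t) == 2
        with pytest.raises(ValueError):
            all_crosstalks(rs, fdr_family="bonferroni")


class TestConsensus:
    @staticmethod
    def _rep(rows):
        return pd.DataFrame(
            rows,
            columns=["transcript", "feature_a", "feature_b", "direction", "significant"],
        )

    def test_two_of_three_same_direction_kept(self):
        hit = ("t1", 26, 58, "STIMULATORY", True)
        miss = ("t1", 26, 58, "STIMULATORY", False)
        reps = [self._rep([hit]), self._rep([hit]), self._rep([miss])]
        out = consensus_crosstalks(reps)
        assert len(out) == 1
        assert out.iloc[0].n_replicates == 2

    def test_one_of_three_dropped(self):
        hit = ("t1", 26, 58, "STIMULATORY", True)
        miss = ("t1", 26, 58, "STIMULATORY", False)
        reps = [self._rep([hit]), self._rep([miss]), self._rep([miss])]
        assert consensus_crosstalks(reps).empty

    def test_direction_conflict_excluded(self, caplog):
        up = ("t1", 26, 58, "STIMULATORY", True)
        down = ("t1", 26, 58, "INHIBITORY", True)
        with caplog.at_level("WARNING"):
            out = consensus_crosstalks([self._rep([up]), self._rep([down]), self._rep([up])])
        assert out.empty
        assert "conflicting directions" in caplog.text

    def test_requires_enough_replicates(self):
        with pytest.raises(ValueError):
            consensus_crosstalks([self._rep([])], min_replicates=2)
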