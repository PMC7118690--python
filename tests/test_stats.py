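"""Permutation tests, FDR, effect sizes, diagnosis regression, validations."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phasedyn import stats


class TestPermutationTtest:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0])
        t, p = stats.permutation_ttest(a, a.copy(), seed=0)
        assert t == 0.0 and p == 1.0

    def test_exhaustive_three_vs_three(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([101.0, 102.0, 103.0])
        _, p = stats.permutation_ttest(a, b, n_perm=10_000, seed=0)
        assert p == pytest.approx(2 / 20)  # smallest attainable two-sided value

    def test_exhaustive_paired_all_positive(self):
        a = np.arange(10, dtype=float) + 1.0
        b = np.arange(10, dtype=float)
        _, p = stats.permutation_ttest(a, b, n_perm=10_000, paired=True, seed=0)
        assert p == pytest.approx(2 / 2**10)

    def test_monte_carlo_p_bounded_below(self, rng):
        a = rng.standard_normal(30) + 5
        b = rng.standard_normal(30)
        _, p = stats.permutation_ttest(a, b, n_perm=500, seed=1)
        assert p >= 1 / 501

    def test_matches_enumeration_oracle(self, rng):
        """Independent brute-force enumeration over all label splits."""
        a = rng.standard_normal(3) + 0.8
        b = rng.standard_normal(3)
        t_obs, p = stats.permutation_ttest(a, b, n_perm=10_000, seed=0)
        pooled = np.r_[a, b]
        count = 0
        for idx in combinations(range(6), 3):
            rest = [i for i in range(6) if i not in idx]
            t_perm = sps.ttest_ind(pooled[list(idx)], pooled[rest], equal_var=False)[0]
            if abs(t_perm) >= abs(t_obs) - 1e-12:
                count += 1
        assert p == pytest.approx(count / 20)

    def test_zero_variance_flat_case(self):
        a = np.array([2.0, 2.0, 2.0])
        t, p = stats.permutation_ttest(a, a.copy())
        assert (t, p) == (0.0, 1.0)


class TestFdrBH:
    def test_textbook_example(self):
        q = stats.fdr_bh([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert stats.fdr_bh([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        np.testing.assert_allclose(stats.fdr_bh([1, 1, 1]), 1.0)

    def test_matches_stepup_formula(self, rng):
        p = rng.uniform(size=12)
        q = stats.fdr_bh(p)
        m = p.size
        order = np.argsort(p)
        expect = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            expect[i] = running
        np.testing.assert_allclose(q, expect, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.fdr_bh([0.5, 1.2])


class TestEffectSizes:
    def test_hand_computed_d(self):
        d = stats.cohens_d([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert d == pytest.approx(-1.0)

    def test_identical_groups_zero(self):
        assert stats.cohens_d([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_scale_invariance(self, rng):
        a, b = rng.standard_normal(20), rng.standard_normal(20) + 1
        assert stats.cohens_d(a, b) == pytest.approx(stats.cohens_d(10 * a, 10 * b))

    def test_zero_pooled_sd_flagged(self):
        with pytest.warns(UserWarning, match="zero pooled SD"):
            d = stats.cohens_d([1.0, 1.0], [2.0, 2.0])
        assert np.isnan(d)


class TestBootstrapCI:
    def test_constant_data_zero_width(self):
        with pytest.warns(UserWarning, match="zero-width"):
            lo, hi = stats.bootstrap_ci(np.full(10, 3.0), np.mean, seed=0)
        assert (lo, hi) == (3.0, 3.0)

    def test_mean_inside_interval(self, rng):
        x = rng.standard_normal(40)
        lo, hi = stats.bootstrap_ci(x, np.mean, seed=2)
        assert lo <= x.mean() <= hi

    def test_wider_level_nests(self, rng):
        x = rng.standard_normal(40)
        lo95, hi95 = stats.bootstrap_ci(x, np.mean, level=0.95, seed=3)
        lo99, hi99 = stats.bootstrap_ci(x, np.mean, level=0.99, seed=3)
        assert lo99 <= lo95 and hi99 >= hi95


class TestRegressDiagnosis:
    def test_perfect_predictor(self):
        y = np.array([0, 0, 0, 1, 1, 1, 0, 1])
        res = stats.regress_diagnosis(y.astype(float), y)
        assert res.adjusted_r2 == pytest.approx(1.0)
        assert res.beta_measure == pytest.approx(1.0)

    def test_null_predictor_small_r2(self, rng):
        y = np.r_[np.zeros(30), np.ones(30)]
        res = stats.regress_diagnosis(rng.standard_normal(60), y)
        assert res.adjusted_r2 < 0.15
        assert res.p_f > 0.01

    def test_inverse_linear_relation(self, rng):
        y = np.r_[np.zeros(40), np.ones(40)]
        measure = 2 * y + 0.01 * rng.standard_normal(80)
        res = stats.regress_diagnosis(measure, y)
        assert res.beta_measure == pytest.approx(0.5, abs=0.01)

    def test_confounds_enter_design(self, rng):
        y = np.r_[np.zeros(25), np.ones(25)]
        res = stats.regress_diagnosis(
            rng.standard_normal(50),
            y,
            age=rng.uniform(20, 60, 50),
            gender=rng.integers(0, 2, 50).astype(float),
            mfd=rng.uniform(0, 1, 50),
        )
        assert res.beta_age is not None
        assert res.beta_gender is not None
        assert res.beta_mfd is not None

    def test_collinear_column_dropped(self, rng):
        y = np.r_[np.zeros(20), np.ones(20)]
        age = rng.uniform(20, 60, 40)
        with pytest.warns(UserWarning, match="collinear"):
            res = stats.regress_diagnosis(
                rng.standard_normal(40), y, age=age, gender=2 * age
            )
        assert res.beta_gender is None


class TestDrowsinessTrend:
    def test_second_half_state_positive_slope(self):
        seqs = [np.r_[np.ones(50, int), np.full(50, 2, int)] for _ in range(12)]
        table = stats.drowsiness_trend(seqs, k=2)
        row = table.set_index("state").loc[2]
        assert row["mean_slope"] > 0
        assert row["p"] < 1e-6

    def test_first_half_state_negative_slope(self):
        seqs = [np.r_[np.ones(50, int), np.full(50, 2, int)] for _ in range(12)]
        table = stats.drowsiness_trend(seqs, k=2)
        assert table.set_index("state").loc[1, "mean_slope"] < 0

    def test_stationary_chain_no_state_significant(self, rng):
        seqs = [rng.integers(1, 5, 100) for _ in range(15)]
        table = stats.drowsiness_trend(seqs, k=4)
        q = stats.fdr_bh(table["p"].to_numpy())
        assert np.all(q > 0.05)

    def test_short_sessions_rejected(self):
        with pytest.raises(ValueError, match="T >="):
            stats.drowsiness_trend([np.ones(10, int)], k=1)


class TestMotionAssociation:
    def test_planted_fd_state_coupling(self, rng):
        seqs, fds = [], []
        for _ in range(10):
            seq = rng.integers(1, 4, 120)
            fd = 0.1 * rng.random(120)
            fd[seq == 1] += 1.0
            seqs.append(seq)
            fds.append(fd)
        table, f_stat, p, _ = stats.motion_association(seqs, fds, k=3)
        assert table.set_index("state").loc[1, "r"] > 0.8
        assert p < 1e-6

    def test_independent_fd_null(self, rng):
        seqs = [rng.integers(1, 4, 150) for _ in range(12)]
        fds = [0.2 + 0.05 * rng.standard_normal(150) for _ in range(12)]
        table, _, p, _ = stats.motion_association(seqs, fds, k=3)
        assert np.all(np.abs(table["r"]) < 0.1)
        assert p > 0.05

    def test_constant_fd_degenerate(self):
        seqs = [np.array([1, 2, 1, 2, 3, 3] * 10) for _ in range(4)]
        fds = [np.full(60, 0.3) for _ in range(4)]
        table, f_stat, _, _ = stats.motion_association(seqs, fds, k=3)
        assert table["degenerate"].all()
        assert f_stat == 0.0

    def test_matches_pingouin_rm_anova(self, rng):
        pingouin = pytest.importorskip("pingouin")
        seqs = [rng.integers(1, 4, 200) for _ in range(8)]
        fds = [rng.random(200) for _ in range(8)]
        _, f_stat, p, (df1, df2) = stats.motion_association(seqs, fds, k=3)
        rows = []
        for i, (seq, fd) in enumerate(zip(seqs, fds)):
            for s in (1, 2, 3):
                rows.append({"subject": i, "state": s, "fd": fd[seq == s].mean()})
        df = pd.DataFrame(rows)
        res = pingouin.rm_anova(data=df, dv="fd", within="state", subject="subject")
        assert f_stat == pytest.approx(float(res["F"][0]), rel=1e-6)
        assert (df1, df2) == (int(res["ddof1"][0]), int(res["ddof2"][0]))

    def test_misaligned_series_rejected(self):
        with pytest.raises(ValueError, match="align"):
            stats.motion_association([np.ones(10, int)], [np.ones(9)], k=1)


class TestSignedNeglogQ:
    @pytest.mark.parametrize(
        "q, sign, expected",
        [(0.01, 1.0, 20.0), (1.0, -1.0, 0.0), (0.05, -1.0, -13.0103)],
    )
    def test_values(self, q, sign, expected):
        assert stats.signed_neglog_q(q, sign) == pytest.approx(expected, abs=1e-4)

    def test_zero_q_capped(self):
        with pytest.warns(UserWarning, match="capped"):
            assert stats.signed_neglog_q(0.0, 1.0, cap=60.0) == 60.0


class TestCompareGroups:
    def test_planted_difference_detected_and_fdr_ordered(self, rng):
        df = pd.DataFrame(
            {
                "group": np.r_[np.zeros(15, int), np.ones(15, int)],
                "shifted": np.r_[rng.standard_normal(15), rng.standard_normal(15) + 3],
                "null": rng.standard_normal(30),
            }
        )
        res = stats.compare_groups(df, n_perm=500, seed=0).set_index("measure")
        assert res.loc["shifted", "q_fdr"] < 0.05
        assert np.all(res["q_fdr"] >= res["p_perm"] - 1e-12)

    def test_nan_rows_dropped_per_measure(self, rng):
        df = pd.DataFrame(
            {
                "group": np.r_[np.zeros(10, int), np.ones(10, int)],
                "m": np.r_[rng.standard_normal(19), np.nan],
            }
        )
        res = stats.compare_groups(df, n_perm=200, seed=0)
        assert np.isfinite(res["t"]).all()
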