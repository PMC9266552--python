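"""Jackknife, permutation tests and rank correlation."""

import numpy as np
import pytest
from scipy import stats

from axondd import (
    GroupParams,
    fit_lognormal_mle,
    jackknife_feature,
    permutation_anova,
    permutation_ttest,
    permutation_two_way,
    simulate_cohort,
    spearman,
)


def pooled_gm(per_animal):
    return fit_lognormal_mle(np.concatenate(per_animal)).gm


class TestJackknife:
    def test_identical_animals_degenerate(self):
        data = [np.array([1.0, 2.0, 3.0])] * 4
        est = jackknife_feature(data, pooled_gm, log_scale=True)
        assert est.se == pytest.approx(0.0, abs=1e-12)
        assert est.ci_lo == pytest.approx(est.point)
        assert est.ci_hi == pytest.approx(est.point)

    def test_mean_of_means_hand_computation(self):
        # per-animal means 1, 2, 3: leave-out means (2.5, 2, 1.5),
        # jackknife var = (2/3) * 0.5 = 1/3, se = 1/sqrt(3)
        data = [np.array([1.0]), np.array([2.0]), np.array([3.0])]
        fn = lambda vecs: np.mean([v.mean() for v in vecs])
        est = jackknife_feature(data, fn)
        assert est.point == pytest.approx(2.0)
        assert est.se == pytest.approx(1.0 / np.sqrt(3))

    def test_se_of_mean_equals_classical_se(self, rng):
        # algebraic identity: jackknife se of the sample mean is s/sqrt(n)
        x = rng.normal(size=12)
        data = [np.array([v]) for v in x]
        fn = lambda vecs: np.mean([v[0] for v in vecs])
        est = jackknife_feature(data, fn)
        assert est.se == pytest.approx(x.std(ddof=1) / np.sqrt(12), abs=1e-12)

    def test_sham_cohort_gm_ci_halfwidth(self):
        params = GroupParams(name="sham", gm=0.69, gsd=2.10, n_animals=7)
        cohort = simulate_cohort(params, seed=42)
        per_animal = [
            s["diameter_um"].to_numpy()
            for _, s in cohort.groupby("animal_id", sort=False)
        ]
        est = jackknife_feature(per_animal, pooled_gm, log_scale=True)
        halfwidth = (est.ci_hi - est.ci_lo) / 2
        # the generator is calibrated so this is ~0.075 μm; tolerance is wide
        # because a jackknife halfwidth from 7 animals is itself noisy
        assert 0.0375 <= halfwidth <= 0.1125

    def test_needs_three_animals(self):
        with pytest.raises(ValueError):
            jackknife_feature([np.ones(3)] * 2, pooled_gm)

    def test_failing_feature_reports_leaveout(self):
        def bad(vecs):
            if len(vecs) == 2:
                raise RuntimeError("boom")
            return 1.0

        with pytest.raises(RuntimeError, match="leave-out"):
            jackknife_feature([np.ones(3)] * 3, bad)


class TestPermutationAnova:
    def test_two_groups_of_two_exact(self):
        # enumeration over C(4,2) = 6 partitions; 2 reach |delta mean| >= 2
        res = permutation_anova([1.0, 2.0, 3.0, 4.0], ["a", "a", "b", "b"])
        assert res.exact
        assert res.n_perms == 6
        assert res.p == pytest.approx(1.0 / 3.0)

    def test_f_statistic_matches_scipy(self, rng):
        vals = rng.normal(size=20)
        labels = np.repeat(["a", "b", "c"], [7, 7, 6])
        res = permutation_anova(vals, labels, n_perms=100, seed=1)
        f_ref = stats.f_oneway(vals[:7], vals[7:14], vals[14:]).statistic
        assert res.statistic == pytest.approx(f_ref, rel=1e-10)
        assert res.df == (2, 17)

    def test_invariance_to_shift_and_label_names(self, rng):
        # exact enumeration (9!/(3!3!3!) = 1680 arrangements), so the
        # invariances hold identically, not just in distribution
        vals = rng.normal(size=9)
        labels = np.repeat(["a", "b", "c"], 3)
        p1 = permutation_anova(vals, labels).p
        p2 = permutation_anova(vals + 100.0, labels).p
        p3 = permutation_anova(vals, np.repeat(["z", "m", "k"], 3)).p
        assert p1 == p2
        assert p1 == p3

    def test_separated_group_means_significant(self, rng):
        # group-level means at the observed GM values with realistic spread
        vals = np.concatenate(
            [
                rng.normal(0.69, 0.05, 7),
                rng.normal(0.65, 0.05, 7),
                rng.normal(0.51, 0.05, 6),
            ]
        )
        labels = np.repeat(["sham", "day7", "day21"], [7, 7, 6])
        res = permutation_anova(vals, labels, n_perms=2000, seed=4)
        assert res.p < 0.05

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError):
            permutation_anova([1.0] * 6, ["a", "a", "a", "b", "b", "b"])


class TestPermutationTTest:
    def test_identical_groups_p_one(self):
        res = permutation_ttest([1.0, 2.0], [1.0, 2.0])
        assert res.p == 1.0

    def test_small_exact_case(self):
        res = permutation_ttest([1.0, 2.0], [3.0, 4.0])
        assert res.exact
        assert res.p == pytest.approx(1.0 / 3.0)

    def test_fully_separated_groups_extreme_arrangements(self):
        # equal sizes: the complement relabeling mirrors t exactly, so two
        # of C(14,7) arrangements reach |t|
        a = np.arange(7, dtype=float)
        b = np.arange(10, 17, dtype=float)
        res = permutation_ttest(a, b)
        assert res.exact and res.n_perms == 3432
        assert res.p == pytest.approx(2.0 / 3432.0)
        # unequal sizes (7 vs 6): no mirror arrangement exists for the
        # pooled-variance t, so only the identity is as extreme
        res76 = permutation_ttest(np.arange(7.0), np.arange(10.0, 16.0))
        assert res76.exact and res76.n_perms == 1716
        assert res76.p == pytest.approx(1.0 / 1716.0)

    def test_statistic_matches_scipy_pooled(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=6)
        res = permutation_ttest(a, b, n_perms=10)
        t_ref = stats.ttest_ind(a, b, equal_var=True).statistic
        assert res.statistic == pytest.approx(t_ref, rel=1e-10)

    def test_paired_signflip(self, rng):
        a = rng.normal(size=8)
        b = a + 1.0 + rng.normal(0, 0.1, size=8)
        res = permutation_ttest(a, b, paired=True)
        assert res.exact and res.n_perms == 256
        assert res.p <= 2 / 256 + 1e-12


class TestPermutationTwoWay:
    @staticmethod
    def design(n_per_cell=3):
        time = np.repeat(["day7", "day21"], 2 * n_per_cell)
        apnea = np.tile(np.repeat([False, True], n_per_cell), 2)
        return time, apnea

    def test_identical_cells_all_null(self):
        time, apnea = self.design(3)
        vals = np.ones(12)
        res = permutation_two_way(vals, time, apnea, n_perms=200, seed=0)
        for r in res.values():
            assert r.statistic == 0.0
            assert r.p == 1.0

    def test_main_effect_detected_others_null(self, rng):
        time, apnea = self.design(4)
        vals = rng.normal(size=16) + np.where(time == "day21", 3.0, 0.0)
        res = permutation_two_way(vals, time, apnea, n_perms=500, seed=1)
        assert res["a"].p < 0.05
        assert res["b"].p > 0.05

    def test_f_matches_balanced_classical_anova(self, rng):
        # on a balanced 2x2, effect-coded type-III F equals the classical
        # two-way decomposition; oracle computed from cell means by hand
        time, apnea = self.design(4)
        vals = rng.normal(size=16)
        res = permutation_two_way(vals, time, apnea, n_perms=10, seed=2)
        y = vals.reshape(2, 2, 4)  # [time, apnea, rep]
        grand = y.mean()
        a_eff = y.mean(axis=(1, 2)) - grand
        b_eff = y.mean(axis=(0, 2)) - grand
        cell = y.mean(axis=2)
        inter = cell - grand - a_eff[:, None] - b_eff[None, :]
        ss_a = 8 * np.sum(a_eff**2)
        ss_b = 8 * np.sum(b_eff**2)
        ss_i = 4 * np.sum(inter**2)
        ss_e = np.sum((y - cell[:, :, None]) ** 2)
        assert res["a"].statistic == pytest.approx(ss_a / (ss_e / 12), rel=1e-9)
        assert res["b"].statistic == pytest.approx(ss_b / (ss_e / 12), rel=1e-9)
        assert res["interaction"].statistic == pytest.approx(
            ss_i / (ss_e / 12), rel=1e-9
        )

    def test_empty_cell_rejected(self):
        time = np.array(["day7"] * 4 + ["day21"] * 2)
        apnea = np.array([False, False, True, True, False, False])
        with pytest.raises(ValueError, match="empty cell"):
            permutation_two_way(np.arange(6.0), time, apnea)


class TestSpearman:
    def test_perfect_negative(self):
        res = spearman([1, 2, 3, 4], [8, 6, 4, 2])
        assert res.rho == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        res = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.rho == pytest.approx(0.8)

    def test_ci_brackets_rho(self, rng):
        x = rng.normal(size=30)
        y = -x + rng.normal(0, 0.4, 30)
        res = spearman(x, y)
        assert res.ci_lo <= res.rho <= res.ci_hi
        assert res.ci_lo > -1.0

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestMonteCarloAgreement:
    def test_exact_and_mc_paths_agree(self, rng):
        vals = rng.normal(size=10)
        labels = np.repeat(["a", "b"], 5)
        exact = permutation_anova(vals, labels)
        mc = permutation_anova(vals, labels, exact_limit=1, n_perms=4000, seed=9)
        assert exact.exact and not mc.exact
        se = np.sqrt(exact.p * (1 - exact.p) / 4000)
        assert abs(mc.p - exact.p) < 3 * se + 1e-3
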