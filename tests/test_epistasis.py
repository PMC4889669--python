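"""Two-/three-locus nonindependence tests, IPF, enumeration and thresholds."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dmscan import (
    ConfigError,
    CrossDesign,
    CrossKind,
    DataError,
    DegenerateStatisticError,
    GenotypeTable,
    MarkerDef,
    MarkerPanel,
    SimConfig,
    ViabilityModel,
    bonferroni_alpha,
    chi2_upper_quantile,
    chi2_upper_tail,
    enumerate_tests,
    interaction_scan,
    ipf_fit_no_three_way,
    joint_counts,
    permutation_p,
    simulate_cross,
    three_locus_test,
    two_locus_test,
)
from dmscan.epistasis import JointCounts2, JointCounts3
from conftest import make_meta


class TestJointCounts:
    def test_complete_cases_sum(self, tiny_table):
        jc = joint_counts(tiny_table, ("A", "B"))
        assert jc.n == 2  # the individual missing at B is excluded
        assert jc.counts[0, 1] == 1 and jc.counts[2, 2] == 1

    def test_missing_excluded_from_pair_but_not_marginal(self, tiny_table):
        from dmscan import marginal_counts

        assert joint_counts(tiny_table, ("A", "B")).n == 2
        assert marginal_counts(tiny_table, "A").total == 3

    def test_duplicate_markers_rejected(self, tiny_table):
        with pytest.raises(DataError, match="duplicate"):
            joint_counts(tiny_table, ("A", "A"))

    def test_null_f2_cells_within_multinomial_envelope(self, panel2):
        cfg = SimConfig(
            panel=panel2,
            design=CrossDesign(kind=CrossKind.F2_INTERCROSS),
            n_offspring=1000,
            seed=99,
        )
        jc = joint_counts(simulate_cross(cfg), ("A", "B"))
        probs = np.outer([0.25, 0.5, 0.25], [0.25, 0.5, 0.25])
        for i in range(3):
            for j in range(3):
                lo, hi = stats.binom.interval(0.999, 1000, probs[i, j])
                assert lo <= jc.counts[i, j] <= hi


class TestTwoLocusTest:
    def test_outer_product_table_gives_zero(self):
        marg = np.array([8, 16, 8], dtype=float)
        cells = np.outer(marg, marg) / marg.sum()
        assert np.allclose(cells, np.round(cells))
        jc = JointCounts2(cells.astype(int), int(cells.sum()))
        assert two_locus_test(jc).statistic == pytest.approx(0.0)

    def test_diagonal_table_hand_value(self):
        jc = JointCounts2(np.diag([10, 20, 10]), 40)
        res = two_locus_test(jc)
        assert res.statistic == pytest.approx(80.0)
        assert res.df == 4

    def test_matches_scipy_contingency(self):
        rng = np.random.default_rng(5)
        c = rng.integers(1, 30, size=(3, 3))
        res = two_locus_test(JointCounts2(c, int(c.sum())))
        oracle = stats.chi2_contingency(c, correction=False)
        assert res.statistic == pytest.approx(oracle.statistic)
        assert res.df == oracle.dof
        assert res.p_value == pytest.approx(oracle.pvalue)

    def test_single_class_axis_degenerate(self):
        c = np.zeros((3, 3), dtype=int)
        c[1, :] = [5, 5, 5]
        with pytest.raises(DegenerateStatisticError):
            two_locus_test(JointCounts2(c, 15))

    def test_backcross_style_collapse_df1(self):
        c = np.zeros((3, 3), dtype=int)
        c[1:, 1:] = [[20, 10], [10, 20]]
        assert two_locus_test(JointCounts2(c, 60)).df == 1


class TestIPF:
    def test_uniform_table_is_fixed_point(self):
        c = np.full((3, 3, 3), 4, dtype=int)
        fit = ipf_fit_no_three_way(JointCounts3(c, 108))
        assert np.allclose(fit, 4.0, atol=1e-8)

    def test_independence_table_is_its_own_fit(self):
        w = np.array([1, 2, 1])
        c = w[:, None, None] * w[None, :, None] * w[None, None, :]  # integral
        jc = JointCounts3(c, int(c.sum()))
        fit = ipf_fit_no_three_way(jc)
        assert np.allclose(fit, c, atol=1e-6)

    def test_margins_reproduced_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            c = rng.integers(0, 25, size=(3, 3, 3))
            if c.sum() == 0:
                continue
            jc = JointCounts3(c, int(c.sum()))
            fit = ipf_fit_no_three_way(jc, tol=1e-10)
            assert np.abs(fit.sum(axis=2) - c.sum(axis=2)).max() < 1e-8
            assert np.abs(fit.sum(axis=1) - c.sum(axis=1)).max() < 1e-8
            assert np.abs(fit.sum(axis=0) - c.sum(axis=0)).max() < 1e-8
            assert fit.min() >= 0
            assert fit.sum() == pytest.approx(c.sum())

    def test_idempotent_on_model_members(self):
        rng = np.random.default_rng(7)
        c = rng.integers(1, 25, size=(3, 3, 3))
        jc = JointCounts3(c, int(c.sum()))
        fit1 = ipf_fit_no_three_way(jc, tol=1e-12)
        jc2 = JointCounts3.__new__(JointCounts3)
        object.__setattr__(jc2, "counts", fit1)
        object.__setattr__(jc2, "n", int(round(fit1.sum())))
        fit2 = ipf_fit_no_three_way(jc2, tol=1e-12)
        assert np.allclose(fit1, fit2, atol=1e-6)


class TestThreeLocusTest:
    def test_model_member_gives_zero_under_both_policies(self):
        p = np.array([0.25, 0.5, 0.25])
        cube = 6400 * p[:, None, None] * p[None, :, None] * p[None, None, :]
        c = np.round(cube).astype(int)
        jc = JointCounts3(c, int(c.sum()))
        for policy in ("paper_12", "loglinear_8"):
            res = three_locus_test(jc, df_policy=policy)
            assert res.statistic < 0.2
            assert res.p_value > 0.99

    def test_df_policies(self):
        rng = np.random.default_rng(3)
        c = rng.integers(1, 20, size=(3, 3, 3))
        jc = JointCounts3(c, int(c.sum()))
        assert three_locus_test(jc, "paper_12").df == 12
        assert three_locus_test(jc, "loglinear_8").df == 8
        with pytest.raises(ConfigError):
            three_locus_test(jc, "bogus")

    def test_null_mean_statistic_near_loglinear_df(self):
        """Three unlinked loci with independent single-locus distortion only:
        the statistic's mean matches the log-linear df (8), diagnosing the
        12-df convention as conservative."""
        panel = MarkerPanel(
            [MarkerDef("A", "1", 0.0), MarkerDef("B", "2", 0.0), MarkerDef("C", "3", 0.0)]
        )
        w = (1.0, 1.0, 0.5)
        vm = ViabilityModel(single_locus={"A": w, "B": w, "C": w})
        stats_ = []
        for i in range(300):
            cfg = SimConfig(
                panel=panel,
                design=CrossDesign(kind=CrossKind.F2_INTERCROSS),
                n_offspring=300,
                seed=50_000 + i,
                viability=vm,
            )
            jc = joint_counts(simulate_cross(cfg), ("A", "B", "C"))
            stats_.append(three_locus_test(jc).statistic)
        mean = float(np.mean(stats_))
        # SE of the mean ~ sqrt(2*8)/sqrt(300) ~ 0.23
        assert 7.2 <= mean <= 8.8


class TestPermutation:
    def test_zero_statistic_gives_p_one(self, panel2):
        marg = [8, 16, 8]
        cells = np.outer(marg, marg) // 32
        rows = []
        for i in range(3):
            for j in range(3):
                rows += [[i, j]] * int(cells[i, j])
        calls = np.array(rows, dtype=np.int8)
        t = GenotypeTable(panel2, make_meta(len(calls)), calls)
        res = permutation_p(t, ("A", "B"), n_perm=99, seed=1)
        assert res.p_value == pytest.approx(1.0)

    def test_p_bounds_and_seed_required(self, f2_table):
        res = permutation_p(f2_table, ("1", "2a"), n_perm=49, seed=3)
        assert 1 / 50 <= res.p_value <= 1.0
        with pytest.raises(ConfigError):
            permutation_p(f2_table, ("1", "2a"), n_perm=49)

    def test_detects_lethal_pair(self, panel2):
        tab = np.ones((3, 3))
        tab[2, 2] = 0.0
        vm = ViabilityModel(epistatic=[(("A", "B"), tab)])
        cfg = SimConfig(
            panel=panel2,
            design=CrossDesign(kind=CrossKind.F2_INTERCROSS),
            n_offspring=500,
            seed=17,
            viability=vm,
        )
        res = permutation_p(simulate_cross(cfg), ("A", "B"), n_perm=199, seed=2)
        assert res.p_value <= 0.01


def symmetric_polynomial_oracle(sizes, order):
    """Elementary symmetric polynomial e_order of per-chromosome counts."""
    total = 0
    for combo in itertools.combinations(sizes, order):
        prod = 1
        for s in combo:
            prod *= s
        total += prod
    return total


class TestEnumeration:
    def test_study_panel_counts(self, panel25):
        assert enumerate_tests(panel25, 2).n_tests == 276
        assert enumerate_tests(panel25, 3).n_tests == 1780

    def test_all_policy_counts_all_combinations(self, panel25):
        assert enumerate_tests(panel25, 2, "all").n_tests == 300

    def test_single_chromosome_panel_yields_zero(self):
        panel = MarkerPanel([MarkerDef("a", "1", 0.0), MarkerDef("b", "1", 5.0)])
        assert enumerate_tests(panel, 2).n_tests == 0

    @given(st.lists(st.integers(1, 4), min_size=2, max_size=8), st.sampled_from([2, 3]))
    @settings(max_examples=40, deadline=None)
    def test_matches_symmetric_polynomial_oracle(self, sizes, order):
        markers = []
        for c, k in enumerate(sizes):
            for i in range(k):
                markers.append(MarkerDef(f"m{c}_{i}", str(c), float(i)))
        panel = MarkerPanel(markers)
        assert enumerate_tests(panel, order).n_tests == symmetric_polynomial_oracle(
            sizes, order
        )

    def test_tuples_are_inter_chromosomal(self, panel25):
        enum = enumerate_tests(panel25, 3)
        for tup in enum.tuples:
            chroms = {panel25.chromosome_of(m) for m in tup}
            assert len(chroms) == 3


class TestThresholds:
    def test_bonferroni_values(self):
        assert bonferroni_alpha(0.05, 25) == pytest.approx(0.002)
        assert bonferroni_alpha(0.05, 276) == pytest.approx(0.000181159, abs=1e-8)
        assert bonferroni_alpha(0.05, 19) == pytest.approx(0.002631579, abs=1e-8)
        with pytest.raises(ConfigError):
            bonferroni_alpha(0.05, 0)
        with pytest.raises(ConfigError):
            bonferroni_alpha(1.5, 10)

    def test_quantile_tail_are_mutual_inverses(self):
        for p in (0.5, 0.05, 0.001, 1e-5):
            for df in (1, 2, 4, 12):
                x = chi2_upper_quantile(p, df)
                assert chi2_upper_tail(x, df) == pytest.approx(p, rel=1e-9)

    def test_tail_strictly_decreasing(self):
        xs = np.linspace(0, 40, 30)
        tails = [chi2_upper_tail(float(x), 4) for x in xs]
        assert all(a > b for a, b in zip(tails, tails[1:]))

    def test_domain_errors(self):
        with pytest.raises(ConfigError):
            chi2_upper_quantile(0.0, 4)
        with pytest.raises(ConfigError):
            chi2_upper_tail(-1.0, 4)


class TestInteractionScan:
    def test_triples_scan_has_1780_rows_per_stratum(self, f2_table):
        df = interaction_scan(f2_table, 3)
        assert len(df) == 1780
        assert (df["n_tests"] == 1780).all()

    def test_pairs_scan_rows_and_ranking(self, f2_table):
        df = interaction_scan(f2_table, 2)
        assert len(df) == 276
        chi2s = df["chi2"].to_numpy()
        assert np.all(np.diff(chi2s[~np.isnan(chi2s)]) <= 1e-9)

    def test_lethal_pair_ranks_first(self):
        panel = MarkerPanel(
            [MarkerDef(m, str(i + 1), 0.0) for i, m in enumerate("ABCD")]
        )
        tab = np.ones((3, 3))
        tab[2, 2] = 0.0
        vm = ViabilityModel(epistatic=[(("A", "B"), tab)])
        wins = 0
        for i in range(10):
            cfg = SimConfig(
                panel=panel,
                design=CrossDesign(kind=CrossKind.F2_INTERCROSS),
                n_offspring=500,
                seed=80_000 + i,
                viability=vm,
            )
            df = interaction_scan(simulate_cross(cfg), 2)
            top = {df.iloc[0]["locus1"], df.iloc[0]["locus2"]}
            wins += top == {"A", "B"}
        assert wins >= 9
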