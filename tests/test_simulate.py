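"""Forward cross simulator: transmission, recombination, selection, sex."""

import numpy as np
import pytest

from dmscan import (
    ConfigError,
    CrossDesign,
    CrossKind,
    DataError,
    MarkerDef,
    MarkerPanel,
    RecombinationModel,
    SexModel,
    SimConfig,
    ViabilityModel,
    f1_genome,
    haldane_r,
    make_gametes,
    marginal_counts,
    purebred_genome,
    relative_viability,
    simulate_backcross_panel,
    simulate_bc2_intercross,
    simulate_cross,
    write_genotype_table,
)
from dmscan.experiments import cosegregation_exact


def f2_config(panel, n, seed, **kw):
    return SimConfig(
        panel=panel,
        design=CrossDesign(kind=CrossKind.F2_INTERCROSS),
        n_offspring=n,
        seed=seed,
        **kw,
    )


class TestGametes:
    def test_achiasmatic_female_transmits_intact_chromosomes(self, panel25):
        parent = f1_genome(panel25, "P2", sex="F")
        g = make_gametes(parent, panel25, RecombinationModel(), np.random.default_rng(0), 500)
        for chrom, block in g.items():
            # every gamete chromosome all-P1 or all-P2, never mixed
            assert np.all((block.min(axis=1) == block.max(axis=1)))

    def test_male_recombinant_fraction_matches_haldane(self):
        panel = MarkerPanel([MarkerDef("a", "1", 0.0), MarkerDef("b", "1", 50.0)])
        parent = f1_genome(panel, "P2", sex="M")
        g = make_gametes(parent, panel, RecombinationModel(), np.random.default_rng(1), 20000)
        rec = np.mean(g["1"][:, 0] != g["1"][:, 1])
        r = haldane_r(50.0)
        se = np.sqrt(r * (1 - r) / 20000)
        assert abs(rec - r) < 3 * se

    def test_homozygous_parent_gametes_constant(self, panel25):
        parent = purebred_genome(panel25, "P1", sex="M")
        g = make_gametes(parent, panel25, RecombinationModel(), np.random.default_rng(2), 100)
        assert all(np.all(block == 0) for block in g.values())


class TestSimulateCross:
    def test_deterministic_given_seed(self, panel25, tmp_path):
        t1 = simulate_cross(f2_config(panel25, 150, 42))
        t2 = simulate_cross(f2_config(panel25, 150, 42))
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_genotype_table(t1, p1)
        write_genotype_table(t2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_seed_changes_output(self, panel25):
        t1 = simulate_cross(f2_config(panel25, 150, 42))
        t2 = simulate_cross(f2_config(panel25, 150, 43))
        assert not np.array_equal(t1.calls, t2.calls)

    def test_f2_allele_frequency_near_half(self, f2_table):
        freq = f2_table.calls.mean(axis=0) / 2  # P2 allele frequency
        se = np.sqrt(0.5 * 0.5 / (2 * f2_table.n_individuals))
        assert np.all(np.abs(freq - 0.5) < 4 * se)

    def test_backcross_to_p2_has_no_p1_homozygotes(self, panel25):
        cfg = SimConfig(
            panel=panel25,
            design=CrossDesign(
                kind=CrossKind.BACKCROSS, f1_parent_sex="M", recurrent_population="P2"
            ),
            n_offspring=200,
            seed=5,
        )
        table = simulate_cross(cfg)
        assert not np.any(table.calls == 0)

    def test_lethal_homozygote_class_absent_at_all_chr3_markers(self, panel25):
        chr3 = [m.marker_id for m in panel25.markers if m.chromosome == "3"]
        vm = ViabilityModel(single_locus={m: (1.0, 1.0, 0.0) for m in chr3})
        table = simulate_cross(f2_config(panel25, 400, 9, viability=vm))
        for m in chr3:
            c = marginal_counts(table, m)
            assert c.n[2] == 0
            assert relative_viability(c).w_hom_p2 == 0.0

    def test_single_locus_lethality_leaves_1_to_2_ratio(self, panel25):
        # selection at one marker only: survivors at that marker are 1:2
        vm = ViabilityModel(single_locus={"3c": (1.0, 1.0, 0.0)})
        table = simulate_cross(f2_config(panel25, 600, 9, viability=vm))
        rv = relative_viability(marginal_counts(table, "3c"))
        assert rv.w_hom_p2 == 0.0
        assert abs(rv.w_hom_p1 - 1.0) < 3 * rv.se_p1

    def test_impossible_viability_model_errors(self, panel25):
        # backcross to P2 only produces HET/HOM_P2, both given fitness 0
        vm = ViabilityModel(single_locus={"3a": (1.0, 0.0, 0.0)})
        cfg = SimConfig(
            panel=panel25,
            design=CrossDesign(
                kind=CrossKind.BACKCROSS, f1_parent_sex="F", recurrent_population="P2"
            ),
            n_offspring=10,
            seed=1,
            viability=vm,
        )
        with pytest.raises(DataError, match="rejected"):
            simulate_cross(cfg)

    def test_seed_required(self, panel25):
        with pytest.raises(ConfigError):
            SimConfig(
                panel=panel25,
                design=CrossDesign(kind=CrossKind.F2_INTERCROSS),
                n_offspring=10,
                seed=None,
            )

    def test_chromosome_wide_cosegregation_without_female_recombination(self):
        assert cosegregation_exact(seed=123)


class TestSexModels:
    def test_bernoulli_sex_ratio(self, panel25):
        table = simulate_cross(f2_config(panel25, 10000, 21))
        f = np.mean(table.meta["sex"] == "F")
        assert abs(f - 0.5) < 3 * np.sqrt(0.25 / 10000)

    def test_zero_effects_polygenic_equals_fair_coin(self, panel25):
        sm = SexModel(kind="polygenic", effects=(("2a", 0.0),))
        p = sm.p_female(np.array([[1] * 25]), panel25)
        assert p[0] == pytest.approx(0.5)

    def test_female_fraction_monotone_in_dosage(self, panel25):
        sm = SexModel(kind="polygenic", effects=(("2a", 2.0),))
        table = simulate_cross(f2_config(panel25, 10000, 31, sex_model=sm))
        j = panel25.index_of("2a")
        fractions = []
        for g in (0, 1, 2):
            rows = table.calls[:, j] == g
            fractions.append(np.mean(table.meta["sex"][rows] == "F"))
        assert fractions[0] < fractions[1] < fractions[2]


class TestBackcrossPanel:
    def test_eight_distinct_crosses(self, panel25):
        tables = simulate_backcross_panel(panel25, 50, seed=7)
        assert len(tables) == 8
        keys = {
            (
                t.meta["maternal_population"].iloc[0],
                t.meta["f1_parent_sex"].iloc[0],
                t.meta["recurrent_population"].iloc[0],
            )
            for t in tables.values()
        }
        # f1 origin is observable via label; (f1_sex, recurrent) pairs repeat
        assert len(tables) == 8 and len({k[1:] for k in keys}) == 4

    def test_no_selection_passes_1to1_gof(self, panel25):
        from dmscan import gof_test

        tables = simulate_backcross_panel(panel25, 200, seed=13)
        for label, t in tables.items():
            design = t.design_of(0)
            res = gof_test(marginal_counts(t, "3c"), design.expected_ratio())
            assert res.p_value > 0.05 / 8 or res.statistic < 12


class TestBc2Intercross:
    def test_parents_heterozygous_across_whole_focal_chromosome(self, panel25):
        lines, dropped = simulate_bc2_intercross(
            panel25, "3c", n_lines=3, n_progeny=40, seed=77
        )
        assert lines, "all lines dropped"
        chr3 = panel25.chrom_indices()["3"]
        for line in lines:
            assert np.all(line.mother_calls[chr3] == 1)
            assert np.all(line.father_calls[chr3] == 1)

    def test_neutral_model_focal_ratio_mendelian(self, panel25):
        from dmscan import gof_test

        lines, _ = simulate_bc2_intercross(
            panel25, "3c", n_lines=2, n_progeny=100, seed=91
        )
        for line in lines:
            res = gof_test(
                marginal_counts(line.progeny, "3c"), (0.25, 0.5, 0.25)
            )
            assert res.p_value > 0.001

    def test_focal_lethal_model_shows_zero_viability(self, panel25):
        vm = ViabilityModel(single_locus={"3c": (1.0, 1.0, 0.0)})
        lines, _ = simulate_bc2_intercross(
            panel25, "3c", n_lines=2, n_progeny=60, seed=55, viability=vm
        )
        assert lines
        for line in lines:
            rv = relative_viability(marginal_counts(line.progeny, "3c"))
            assert rv.w_hom_p2 == 0.0
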