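"""Targeting-shift statistic, permutation null and exact oracle."""

import numpy as np
import pytest

from mirshift.diffexp import unique_family_sets
from mirshift.errors import ConfigError, EnumerationBoundError
from mirshift.io_formats import GeneExpressionTable, TargetIncidenceTable
from mirshift.targeting import (
    ShiftConfig,
    TargetingShiftResult,
    apply_expression_gate,
    bh_adjust,
    exact_pvalues_small,
    observed_deltas,
    permutation_pvalues,
    rank_genes,
    run_targeting_shift,
    targeting_delta,
)


def random_instance(seed, n_genes=12, max_families=8):
    """Small random gene x family incidence with observed strata."""
    rng = np.random.default_rng(seed)
    n_fams = int(rng.integers(4, max_families + 1))
    fams = [f"f{j}" for j in range(n_fams)]
    n_up = int(rng.integers(1, 4))
    n_down = int(rng.integers(0, 3))
    if n_up + n_down == 0:
        n_up = 1
    sites = {}
    for g in range(n_genes):
        row = {f: int(rng.integers(1, 4)) for f in fams if rng.random() < 0.4}
        if row:
            sites[f"g{g}"] = row
    strata = rng.choice(fams, n_up + n_down, replace=False)
    up, down = set(strata[:n_up]), set(strata[n_up:])
    return TargetIncidenceTable(sites), fams, up, down, n_up, n_down


class TestTargetingDelta:
    def test_dcx_delta_is_ten(self, cortical_records, dcx_lis1_sites):
        up, down = unique_family_sets(cortical_records)
        assert targeting_delta(dcx_lis1_sites.families_of("DCX"), up, down) == 10

    def test_lis1_delta_is_zero(self, cortical_records, dcx_lis1_sites):
        up, down = unique_family_sets(cortical_records)
        # two up families and two down families hit LIS1: 2 - 2 = 0
        assert targeting_delta(dcx_lis1_sites.families_of("LIS1"), up, down) == 0

    def test_untargeted_gene_delta_zero(self):
        assert targeting_delta(set(), {"a"}, {"b"}) == 0

    def test_site_multiplicity_ignored(self):
        table = TargetIncidenceTable({"g": {"a": 3}})
        assert observed_deltas(table, {"a"}, set()) == {"g": 1}

    def test_bounds_and_monotonicity(self):
        rng = np.random.default_rng(0)
        fams = [f"f{j}" for j in range(10)]
        for _ in range(200):
            gene = {f for f in fams if rng.random() < 0.5}
            up = {f for f in fams if rng.random() < 0.3}
            down = {f for f in fams if rng.random() < 0.2}
            d = targeting_delta(gene, up, down)
            assert -len(down) <= d <= len(up)
            extra = rng.choice(fams)
            d_more = targeting_delta(gene | {extra}, up, down)
            if extra in up and extra not in down:
                assert d_more >= d
            if extra in down and extra not in up:
                assert d_more <= d


class TestExactOracle:
    TABLE = TargetIncidenceTable({"g": {"A": 1}})

    def test_three_family_case_exactly_two_ninths(self):
        cfg = ShiftConfig(n_up=1, n_down=1, iterations=1)
        exact = exact_pvalues_small(self.TABLE, "ABC", {"A"}, {"B"}, cfg)
        assert exact["g"] == pytest.approx(2 / 9)

    def test_up_equals_universe_no_down_all_p_one(self):
        cfg = ShiftConfig(n_up=3, n_down=0, iterations=1)
        exact = exact_pvalues_small(
            self.TABLE, "ABC", {"A", "B", "C"}, set(), cfg
        )
        assert exact["g"] == 1.0

    def test_gene_targeted_by_every_family_p_one(self):
        table = TargetIncidenceTable({"g": {"A": 1, "B": 1, "C": 1}})
        cfg = ShiftConfig(n_up=2, n_down=1, iterations=1)
        exact = exact_pvalues_small(table, "ABC", {"A", "B"}, {"C"}, cfg)
        assert exact["g"] == 1.0

    def test_combinatorial_bound_enforced(self):
        fams = [f"f{j}" for j in range(40)]
        table = TargetIncidenceTable({"g": {fams[0]: 1}})
        cfg = ShiftConfig(n_up=10, n_down=5, iterations=1)
        with pytest.raises(EnumerationBoundError):
            exact_pvalues_small(table, fams, set(fams[:10]), set(fams[10:15]), cfg)


class TestPermutationPvalues:
    def test_three_family_case_within_monte_carlo_error(self):
        table = TargetIncidenceTable({"g": {"A": 1}})
        cfg = ShiftConfig(n_up=1, n_down=1, iterations=100_000, rng_seed=42)
        (_, p) = permutation_pvalues(table, "ABC", {"A"}, {"B"}, cfg)["g"]
        se = np.sqrt((2 / 9) * (7 / 9) / 100_000)
        assert abs(p - 2 / 9) <= 3 * se

    def test_delta_zero_with_no_down_families_gives_p_one(self):
        table = TargetIncidenceTable({"hit": {"A": 1}, "miss": {"B": 1}})
        cfg = ShiftConfig(n_up=1, n_down=0, iterations=500, rng_seed=0)
        out = permutation_pvalues(table, "ABC", {"A"}, set(), cfg, genes=["miss"])
        assert out["miss"] == (0, 1.0)  # delta_perm >= 0 always

    def test_single_iteration_p_in_zero_one(self):
        table = TargetIncidenceTable({"g": {"A": 1}})
        for seed in range(5):
            cfg = ShiftConfig(n_up=1, n_down=1, iterations=1, rng_seed=seed)
            (_, p) = permutation_pvalues(table, "ABC", {"A"}, {"B"}, cfg)["g"]
            assert p in (0.0, 1.0)

    def test_seed_reproducibility_bit_exact(self):
        table, fams, up, down, n_up, n_down = random_instance(3)
        cfg = ShiftConfig(n_up=n_up, n_down=n_down, iterations=3000, rng_seed=11)
        a = permutation_pvalues(table, fams, up, down, cfg)
        b = permutation_pvalues(table, fams, up, down, cfg)
        assert a == b

    def test_stratum_larger_than_universe_rejected(self):
        table = TargetIncidenceTable({"g": {"A": 1}})
        cfg = ShiftConfig(n_up=4, n_down=0, iterations=10)
        with pytest.raises(ConfigError):
            permutation_pvalues(table, "ABC", {"A", "B", "C", "X"}, set(), cfg)

    @pytest.mark.parametrize("sampling", ["independent_overlap_allowed", "disjoint"])
    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_exact_oracle_small_instances(self, sampling, seed):
        table, fams, up, down, n_up, n_down = random_instance(seed)
        if sampling == "disjoint" and n_up + n_down > len(fams):
            pytest.skip("strata exceed universe for disjoint draw")
        cfg = ShiftConfig(
            n_up=n_up, n_down=n_down, iterations=20_000,
            rng_seed=seed, sampling=sampling,
        )
        exact = exact_pvalues_small(table, fams, up, down, cfg)
        perm = permutation_pvalues(table, fams, up, down, cfg)
        for gene, p_exact in exact.items():
            se = max(np.sqrt(p_exact * (1 - p_exact) / cfg.iterations), 1e-12)
            assert abs(perm[gene][1] - p_exact) <= 4 * se + 1e-9

    def test_add_one_estimator_never_zero(self):
        table = TargetIncidenceTable({"g": {"A": 1}})
        universe = [f"f{j}" for j in range(20)] + ["A"]
        cfg = ShiftConfig(
            n_up=1, n_down=0, iterations=50, rng_seed=1, p_estimator="add_one"
        )
        (_, p) = permutation_pvalues(table, universe, {"A"}, set(), cfg)["g"]
        assert p >= 1 / 51

    def test_null_pvalues_are_super_uniform(self):
        """Inclusive empirical p-values of an integer statistic satisfy
        P(p <= a) <= a; on a dense null instance the attained level
        approaches a from below."""
        rng = np.random.default_rng(0)
        fams = [f"f{j}" for j in range(80)]
        sites = {
            f"g{g}": {f: 1 for f in fams if rng.random() < 0.3}
            for g in range(400)
        }
        sites = {g: row for g, row in sites.items() if row}
        up = set(rng.choice(fams, 26, replace=False))
        down = set(rng.choice(fams, 2, replace=False))
        cfg = ShiftConfig(
            n_up=26, n_down=2, iterations=4000, rng_seed=0,
            p_estimator="add_one",
        )
        out = permutation_pvalues(
            TargetIncidenceTable(sites), fams, up, down, cfg
        )
        ps = np.array([p for _, p in out.values()])
        for level in (0.05, 0.1, 0.25):
            frac = (ps <= level).mean()
            mc_slack = 3 * np.sqrt(level * (1 - level) / len(ps))
            assert frac <= level + mc_slack


class TestGateAndRanking:
    RESULTS = [
        TargetingShiftResult("g1", 3, 0.001, 1000),
        TargetingShiftResult("g2", 1, 0.5, 1000),
        TargetingShiftResult("g3", 4, 0.05, 1000),
        TargetingShiftResult("g4", 2, 0.05, 1000),
    ]

    def test_fpkm_gate_closed_at_one(self):
        expr = GeneExpressionTable({"g1": 1.0, "g2": 0.999, "g3": 50.0})
        kept = apply_expression_gate(self.RESULTS, expr, 1.0)
        assert [r.gene_id for r in kept] == ["g1", "g3"]  # g4 absent, g2 below

    def test_empty_fpkm_table_empties_results(self):
        assert apply_expression_gate(self.RESULTS, GeneExpressionTable({})) == []

    def test_rank_by_p_then_delta_then_id(self):
        ranked = rank_genes(self.RESULTS)
        assert [r.gene_id for r in ranked] == ["g1", "g3", "g4", "g2"]
        assert [r.rank for r in ranked] == [1, 2, 3, 4]

    def test_empty_input(self):
        assert rank_genes([]) == []

    def test_bh_adjustment_monotone_and_bounded(self):
        adjusted = bh_adjust(rank_genes(self.RESULTS))
        assert all(0 <= r.p_adjusted <= 1 for r in adjusted)
        assert all(r.p_adjusted >= r.p_value for r in adjusted)


class TestFullShiftPipeline:
    def test_planted_enrichment_ranks_first(self):
        """A gene stacked with up families outranks background genes."""
        rng = np.random.default_rng(4)
        fams = [f"f{j}" for j in range(30)]
        up = set(fams[:10])
        down = {fams[10]}
        sites = {"planted": {f: 1 for f in list(up)[:8]}}
        for g in range(30):
            row = {f: 1 for f in fams if rng.random() < 0.1}
            if row:
                sites[f"bg{g}"] = row
        expr = GeneExpressionTable({g: 10.0 for g in sites})
        cfg = ShiftConfig(n_up=10, n_down=1, iterations=4000, rng_seed=7,
                          p_estimator="add_one")
        results = run_targeting_shift(
            TargetIncidenceTable(sites), fams, up, down, cfg, expr
        )
        assert results[0].gene_id == "planted"
        assert results[0].rank == 1
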