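"""Trajectory profiles, GSEA, hypergeometric overlap, candidate filter."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from prelsc.errors import InputError
from prelsc.expression import transition_fold_changes
from prelsc.regulome import TFSignature
from prelsc.setscan import (
    FilterReport,
    GeneSet,
    StageExclusionRule,
    candidate_filter,
    gsea,
    gsea_collection,
    overlap_enrichment,
    read_gmt,
    trajectory_profile,
    write_gmt_sets,
)
from prelsc.simulate import PlantedSet, simulate_stage_expression


class TestTrajectoryProfile:
    def test_constant_matrix_gives_zero_everywhere(self):
        m, _ = simulate_stage_expression(
            n_genes=50, planted_sets=(), noise_sd=0.0, seed=0
        )
        fc = transition_fold_changes(m)
        gs = GeneSet("any", frozenset(list(m.genes)[:10]))
        profile = trajectory_profile(gs, fc)
        assert (profile.pct_up == 0).all()
        assert (profile.background_pct_up == 0).all()

    def test_manual_count(self):
        # 10-gene set, 3 genes above threshold at one transition -> 30%
        genes = [f"g{i}" for i in range(10)]
        values = pd.DataFrame({"A": [10.0] * 10, "B": [10.0] * 10}, index=genes)
        values.loc[["g0", "g1", "g2"], "B"] = 20.0
        from prelsc.expression import StageExpressionMatrix

        fc = transition_fold_changes(StageExpressionMatrix(values, ("A", "B")))
        profile = trajectory_profile(GeneSet("s", frozenset(genes)), fc)
        assert profile.pct_up["A->B"] == pytest.approx(30.0)

    def test_threshold_is_strict(self):
        genes = ["at_threshold", "above"]
        values = pd.DataFrame({"A": [10.0, 10.0], "B": [13.0, 13.1]}, index=genes)
        from prelsc.expression import StageExpressionMatrix

        fc = transition_fold_changes(StageExpressionMatrix(values, ("A", "B")))
        profile = trajectory_profile(GeneSet("s", frozenset(genes)), fc, threshold=1.3)
        assert profile.pct_up["A->B"] == pytest.approx(50.0)  # only "above" counts

    def test_detected_members_denominator(self):
        genes = [f"g{i}" for i in range(5)]
        values = pd.DataFrame({"A": [10.0] * 5, "B": [20.0] * 5}, index=genes)
        from prelsc.expression import StageExpressionMatrix

        fc = transition_fold_changes(StageExpressionMatrix(values, ("A", "B")))
        # set has 10 members but only 5 are in the matrix: denominator is 5
        gs = GeneSet("s", frozenset(genes + [f"x{i}" for i in range(5)]))
        profile = trajectory_profile(gs, fc)
        assert profile.n_set == 5
        assert profile.pct_up["A->B"] == pytest.approx(100.0)

    def test_no_overlap_rejected(self):
        values = pd.DataFrame({"A": [10.0], "B": [20.0]}, index=["g"])
        from prelsc.expression import StageExpressionMatrix

        fc = transition_fold_changes(StageExpressionMatrix(values, ("A", "B")))
        with pytest.raises(InputError):
            trajectory_profile(GeneSet("s", frozenset(["zzz"])), fc)


class TestCandidateFilter:
    def _fc(self):
        from prelsc.expression import StageExpressionMatrix

        genes = list("ABCDE")
        values = pd.DataFrame(
            {
                "DN2": [10.0, 10.0, 10.0, 10.0, 10.0],
                "DN3a": [20.0, 20.0, 10.0, 10.0, 20.0],
            },
            index=genes,
        )
        return transition_fold_changes(StageExpressionMatrix(values, ("DN2", "DN3a")))

    def test_documented_toy_counts(self):
        # bound {A,B,C,D}, responsive {A,B,C}, fc>threshold {A,B},
        # resources {B,E}  ->  counts 4 -> 3 -> 2 -> 1, survivor {B}
        report = candidate_filter(
            TFSignature("TF", frozenset("ABCD")),
            GeneSet("responsive", frozenset("ABC")),
            self._fc(),
            transition="DN2->DN3a",
            resources=[GeneSet("resource", frozenset("BE"))],
        )
        assert report.steps[0].n_input == 4
        assert report.counts == [3, 2, 1]
        assert report.survivors == {"B"}

    def test_survivor_chains_nested(self):
        report = candidate_filter(
            TFSignature("TF", frozenset("ABCDE")),
            GeneSet("responsive", frozenset("ABCDE")),
            self._fc(),
            transition="DN2->DN3a",
            resources=[GeneSet("r", frozenset("ABE"))],
        )
        chain = [s.survivors for s in report.steps]
        for prev, nxt in zip(chain, chain[1:]):
            assert nxt <= prev

    def test_empty_resources_empties_step3(self):
        report = candidate_filter(
            TFSignature("TF", frozenset("AB")),
            GeneSet("responsive", frozenset("AB")),
            self._fc(),
            transition="DN2->DN3a",
            resources=[],
        )
        assert report.survivors == set()

    def test_unknown_transition_rejected(self):
        with pytest.raises(InputError):
            candidate_filter(
                TFSignature("TF", frozenset("AB")),
                GeneSet("responsive", frozenset("AB")),
                self._fc(),
                transition="DP->SP",
                resources=[],
            )

    def test_stage_exclusion_drops_genes_high_at_stage(self):
        # planted genes fall after the peak; a gene kept high at DP is excluded
        m, truth = simulate_stage_expression(
            n_genes=30, noise_sd=0.0, seed=1, planted_sets=(PlantedSet("peaked", 5),)
        )
        values = m.values.copy()
        high_gene = truth["peaked"][0]
        values.loc[high_gene, "DP"] = values.loc[high_gene].max()  # stays high in DP
        from prelsc.expression import StageExpressionMatrix

        m2 = StageExpressionMatrix(values, m.stages, dict(m.replicate_map))
        rule = StageExclusionRule(stage="DP", fraction_of_max=0.8)
        excluded = rule.excluded(m2, set(truth["peaked"]))
        assert excluded == {high_gene}

    def test_report_nesting_violation_raises(self):
        report = FilterReport()
        report.add("s1", 3, {"A", "B"})
        with pytest.raises(AssertionError):
            report.add("s2", 2, {"C"})


def brute_force_es(order_in_set: list[bool]) -> float:
    """Classic KS running-sum statistic (uniform weights), independent impl."""
    n_hit = sum(order_in_set)
    n_miss = len(order_in_set) - n_hit
    best, run = 0.0, 0.0
    for is_hit in order_in_set:
        run += 1.0 / n_hit if is_hit else -1.0 / n_miss
        if abs(run) > abs(best):
            best = run
    return best


class TestGsea:
    def _ranking(self):
        return pd.Series(
            [3.0, 2.5, 2.0, 1.5, 1.0, 0.5], index=list("ABCDEF"), name="score"
        )

    def test_top_k_set_has_maximal_positive_es(self):
        ranking = self._ranking()
        res_top = gsea(ranking, GeneSet("top", frozenset("AB")), 0.0, n_perm=100)
        assert res_top.es > 0
        for combo in itertools.combinations("ABCDEF", 2):
            res = gsea(ranking, GeneSet("s", frozenset(combo)), 0.0, n_perm=100)
            assert res.es <= res_top.es + 1e-12

    def test_exhaustive_enumeration_matches_brute_force(self):
        ranking = self._ranking()
        res = gsea(ranking, GeneSet("s", frozenset("AD")), 0.0, n_perm=100)
        assert res.exhaustive and res.n_perm_used == math.comb(6, 2)
        # independent oracle: running sum and exact p over all 15 placements
        obs = brute_force_es([g in "AD" for g in "ABCDEF"])
        assert res.es == pytest.approx(obs)
        null = [
            brute_force_es([g in combo for g in "ABCDEF"])
            for combo in itertools.combinations("ABCDEF", 2)
        ]
        if obs >= 0:
            p_exact = sum(e >= obs - 1e-12 for e in null) / len(null)
        else:
            p_exact = sum(e <= obs + 1e-12 for e in null) / len(null)
        assert res.p == pytest.approx(p_exact)

    def test_es_bounded_by_one(self, rng):
        genes = [f"g{i}" for i in range(40)]
        ranking = pd.Series(rng.normal(size=40), index=genes)
        res = gsea(ranking, GeneSet("s", frozenset(genes[5:15])), 1.0, n_perm=200, seed=0)
        assert -1.0 <= res.es <= 1.0

    def test_monte_carlo_seed_stability(self, rng):
        genes = [f"g{i}" for i in range(50)]
        scores = np.sort(rng.normal(size=50))[::-1]
        ranking = pd.Series(scores, index=genes)
        gs = GeneSet("s", frozenset(genes[:8]))
        p1 = gsea(ranking, gs, 1.0, n_perm=10_000, seed=1).p
        p2 = gsea(ranking, gs, 1.0, n_perm=10_000, seed=2).p
        assert abs(p1 - p2) < 0.01

    def test_no_overlap_rejected(self):
        with pytest.raises(InputError):
            gsea(self._ranking(), GeneSet("s", frozenset(["zzz"])), 0.0, n_perm=100)

    def test_collection_applies_bh_and_keeps_order(self):
        ranking = self._ranking()
        sets = [
            GeneSet("top", frozenset("AB")),
            GeneSet("bottom", frozenset("EF")),
            GeneSet("mixed", frozenset("AF")),
        ]
        df = gsea_collection(ranking, sets, weight_exponent=0.0, n_perm=100, seed=0)
        assert (df["fdr"] >= df["p"] - 1e-12).all()
        # BH never inverts the significance order
        sorted_p = df.sort_values("p")
        assert sorted_p["fdr"].is_monotonic_increasing


def hypergeom_tail_factorial(x: int, universe: int, set_size: int, query: int) -> float:
    """P(X >= x) by the direct factorial formula (independent oracle)."""
    total = 0.0
    for k in range(x, min(set_size, query) + 1):
        total += (
            math.comb(set_size, k)
            * math.comb(universe - set_size, query - k)
            / math.comb(universe, query)
        )
    return total


class TestOverlapEnrichment:
    def test_matches_factorial_tail(self):
        query = GeneSet("q", frozenset([f"q{i}" for i in range(2)] + ["s0", "s1", "s2"]))
        comp = GeneSet("c", frozenset([f"s{i}" for i in range(10)]))
        df = overlap_enrichment(query, [comp], universe_size=100)
        assert df.loc["c", "overlap"] == 3
        assert df.loc["c", "p"] == pytest.approx(
            hypergeom_tail_factorial(3, 100, 10, 5), rel=1e-12
        )

    def test_perfect_overlap_extreme(self):
        genes = frozenset(f"s{i}" for i in range(10))
        df = overlap_enrichment(
            GeneSet("q", genes), [GeneSet("c", genes)], universe_size=1000
        )
        assert df.loc["c", "p"] == pytest.approx(1 / math.comb(1000, 10), rel=1e-6)
        assert bool(df.loc["c", "enriched"])

    def test_zero_overlap_gives_p_one(self):
        df = overlap_enrichment(
            GeneSet("q", frozenset(["a", "b"])),
            [GeneSet("c", frozenset(["x", "y"]))],
            universe_size=50,
        )
        assert df.loc["c", "p"] == pytest.approx(1.0)
        assert not bool(df.loc["c", "enriched"])

    def test_set_larger_than_universe_rejected(self):
        with pytest.raises(InputError):
            overlap_enrichment(
                GeneSet("q", frozenset(["a"])),
                [GeneSet("c", frozenset(f"g{i}" for i in range(20)))],
                universe_size=10,
            )

    def test_enrichment_threshold_is_strict(self):
        # a set whose adjusted p equals alpha exactly is NOT called enriched
        query = GeneSet("q", frozenset(["a", "b"]))
        comp = [GeneSet("c", frozenset(["a", "x"]))]
        df = overlap_enrichment(query, comp, universe_size=4)
        alpha = float(df.loc["c", "p_adj"])
        df2 = overlap_enrichment(query, comp, universe_size=4, alpha=alpha)
        assert not bool(df2.loc["c", "enriched"])


def test_gmt_roundtrip(tmp_path):
    sets = [
        GeneSet("s1", frozenset(["a", "b"]), category="stem cells"),
        GeneSet("s2", frozenset(["c"]), category=None),
    ]
    path = tmp_path / "sets.gmt"
    write_gmt_sets(sets, path)
    again = read_gmt(path)
    assert {s.name: s.genes for s in again} == {s.name: s.genes for s in sets}
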