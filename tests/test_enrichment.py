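"""Correlation ranking, weighted enrichment, strata and KS comparisons."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from halfcell import (
    CorrelationRanking,
    correlate_to_mirna,
    es_permutation_p,
    ks_compare,
    select_targets,
    stratify_by_expression,
    weighted_es,
)
from conftest import make_matrix


def ranking_from_r(r_by_gene: dict[str, float], means=None) -> CorrelationRanking:
    table = pd.DataFrame(
        {
            "gene": list(r_by_gene),
            "r": list(r_by_gene.values()),
            "mean_expr_log2": [0.0 if means is None else means[g] for g in r_by_gene],
        }
    ).sort_values(["r", "gene"], ascending=[False, True]).reset_index(drop=True)
    return CorrelationRanking(mirna="miR-x", table=table)


class TestCorrelateToMirna:
    def test_perfect_positive_ranks_first(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        mat = make_matrix(np.vstack([v, -v + 10, v * 0 + 1]),
                          features=["pos", "neg", "flat"])
        ranking = correlate_to_mirna(mat, v, "m")
        assert ranking.genes[0] == "pos"
        assert ranking.table.loc[0, "r"] == pytest.approx(1.0)
        assert ranking.genes[-1] == "neg"
        assert ranking.table.iloc[-1]["r"] == pytest.approx(-1.0)
        assert ranking.excluded_genes == ["flat"]

    def test_constant_mirna_rejected(self):
        mat = make_matrix(np.random.default_rng(0).normal(0, 1, (3, 4)))
        with pytest.raises(ValueError, match="constant"):
            correlate_to_mirna(mat, np.ones(4), "m")

    def test_tie_break_by_gene_id(self):
        v = np.array([1.0, 2.0, 3.0])
        mat = make_matrix(np.vstack([v, v]), features=["b", "a"])
        ranking = correlate_to_mirna(mat, v, "m")
        assert ranking.genes == ["a", "b"]


class TestSelectTargets:
    def test_strict_cutoff_boundary_excluded(self):
        table = pd.DataFrame({
            "mirna": ["m"] * 3,
            "gene": ["g1", "g2", "g3"],
            "total_context_score": [-0.05, -0.1, -0.2],
        })
        assert select_targets(table, "m", -0.1) == {"g3"}

    def test_extreme_cutoff_empty(self):
        table = pd.DataFrame({"mirna": ["m"], "gene": ["g"],
                              "total_context_score": [-0.5]})
        assert select_targets(table, "m", -1e9) == set()

    def test_all_below_cutoff_full_list(self):
        table = pd.DataFrame({"mirna": ["m"] * 2, "gene": ["g1", "g2"],
                              "total_context_score": [-0.5, -0.9]})
        assert select_targets(table, "m", -0.1) == {"g1", "g2"}

    def test_absent_mirna_warns_and_returns_empty(self):
        table = pd.DataFrame({"mirna": ["m"], "gene": ["g"],
                              "total_context_score": [-0.5]})
        with pytest.warns(UserWarning, match="absent"):
            assert select_targets(table, "other") == set()


class TestStratify:
    def test_default_edge_four(self):
        ranking = ranking_from_r({"g1": 0.5, "g2": -0.5}, means={"g1": 5.0, "g2": 3.0})
        strata = stratify_by_expression({"g1", "g2"}, ranking)
        assert strata["gt_4"] == {"g1"}
        assert strata["le_4"] == {"g2"}

    def test_boundary_goes_to_low_stratum(self):
        ranking = ranking_from_r({"g1": 0.1}, means={"g1": 4.0})
        strata = stratify_by_expression({"g1"}, ranking)
        assert strata["le_4"] == {"g1"}
        assert strata["gt_4"] == set()

    def test_multiple_edges_partition(self):
        means = {"a": -1.0, "b": 1.0, "c": 3.0, "d": 10.0}
        ranking = ranking_from_r({g: 0.0 for g in means}, means=means)
        strata = stratify_by_expression(set(means), ranking, edges=(0.0, 2.0, 4.0))
        merged = set().union(*strata.values())
        assert merged == set(means)
        assert sum(len(s) for s in strata.values()) == 4

    def test_missing_gene_dropped_with_warning(self):
        ranking = ranking_from_r({"g1": 0.2}, means={"g1": 1.0})
        with pytest.warns(UserWarning, match="absent"):
            strata = stratify_by_expression({"g1", "ghost"}, ranking)
        assert strata["le_4"] == {"g1"}


class TestWeightedES:
    def test_hand_enumerated_running_sum(self):
        # set = the bottom-ranked gene: running sum -1/3, -2/3, -1, 0 -> es -1
        ranking = ranking_from_r({"g1": 0.9, "g2": 0.1, "g3": -0.2, "g4": -0.8})
        res = weighted_es(ranking, {"g4"})
        assert res.es == pytest.approx(-1.0)
        assert res.direction == -1

    def test_top_singleton_gives_plus_one(self):
        ranking = ranking_from_r({"g1": 0.9, "g2": 0.1, "g3": -0.2, "g4": -0.8})
        res = weighted_es(ranking, {"g1"})
        assert res.es == pytest.approx(1.0)

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(4)
        r = dict(zip("abcdefgh", np.sort(rng.uniform(-1, 1, 8))[::-1]))
        ranking = ranking_from_r(r)
        reversed_ranking = ranking_from_r({g: -v for g, v in r.items()})
        for subset in (["a", "d"], ["g", "h"], ["b"]):
            es_fwd = weighted_es(ranking, set(subset)).es
            es_rev = weighted_es(reversed_ranking, set(subset)).es
            assert es_fwd == pytest.approx(-es_rev, abs=1e-9)

    def test_empty_or_full_set_rejected(self):
        ranking = ranking_from_r({"g1": 0.5, "g2": -0.5})
        with pytest.raises(ValueError):
            weighted_es(ranking, {"ghost"})
        with pytest.raises(ValueError):
            weighted_es(ranking, {"g1", "g2"})

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.integers(6, 40),
        st.integers(1, 5),
        st.integers(0, 2**31 - 1),
    )
    def test_bounded_and_running_sum_terminates_at_zero(self, n, n_set, seed):
        rng = np.random.default_rng(seed)
        r = dict(zip([f"g{i}" for i in range(n)],
                     np.sort(rng.uniform(-1, 1, n))[::-1]))
        ranking = ranking_from_r(r)
        genes = list(r)
        subset = set(rng.choice(genes, size=min(n_set, n - 1), replace=False))
        res = weighted_es(ranking, subset)
        assert -1.0 - 1e-9 <= res.es <= 1.0 + 1e-9
        # hit mass 1 and miss mass 1: the running sum must end at 0
        from halfcell.enrichment import _running_sum

        hit = np.array([g in subset for g in ranking.genes])
        run = _running_sum(ranking.r, hit)
        assert run[-1] == pytest.approx(0.0, abs=1e-9)


class TestESPermutation:
    def test_extreme_tail_set_is_significant(self):
        rng = np.random.default_rng(2)
        r = np.sort(rng.uniform(-1, 1, 1000))[::-1]
        ranking = ranking_from_r(dict(zip([f"g{i:04d}" for i in range(1000)], r)))
        tail = set(ranking.genes[-5:])
        res = es_permutation_p(ranking, tail, n_perm=1000, seed=0)
        assert res.es < 0
        assert res.p_perm <= 0.01

    def test_matches_exhaustive_subset_enumeration(self):
        """Monte-Carlo p on a 6-gene ranking converges to the exact fraction
        over all C(6,2) = 15 subsets."""
        r = {"a": 0.8, "b": 0.5, "c": 0.2, "d": -0.1, "e": -0.4, "f": -0.9}
        ranking = ranking_from_r(r)
        observed = weighted_es(ranking, {"e", "f"})
        genes = list(ranking.genes)
        null = []
        for combo in itertools.combinations(genes, 2):
            null.append(weighted_es(ranking, set(combo)).es)
        null = np.array(null)
        if observed.es >= 0:
            exact = np.sum(null >= observed.es) / np.sum(null >= 0)
        else:
            exact = np.sum(null <= observed.es) / np.sum(null < 0)
        res = es_permutation_p(ranking, {"e", "f"}, n_perm=3000, seed=5)
        assert res.p_perm == pytest.approx(exact, abs=0.04)

    def test_random_set_on_random_ranking_is_null(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(200):
            r = np.sort(rng.uniform(-1, 1, 60))[::-1]
            ranking = ranking_from_r(dict(zip([f"g{i}" for i in range(60)], r)))
            subset = set(rng.choice(ranking.genes, 6, replace=False))
            ps.append(es_permutation_p(ranking, subset, n_perm=60,
                                       seed=int(rng.integers(2**31))).p_perm)
        assert 0.4 < np.mean(ps) < 0.6


def _ks_oracle(a, b):
    """Textbook two-sample KS: sup-difference of empirical CDFs plus the
    exact tail probability by lattice-path counting (no ties assumed)."""
    from math import comb

    a, b = np.sort(a), np.sort(b)
    allv = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, allv, side="right") / a.size
    cdf_b = np.searchsorted(b, allv, side="right") / b.size
    d = np.max(np.abs(cdf_a - cdf_b))
    m, n = a.size, b.size
    # paths (0,0)->(m,n) whose every lattice point keeps |i/m - j/n| < d
    paths = np.zeros((m + 1, n + 1))
    paths[0, 0] = 1.0
    for i in range(m + 1):
        for j in range(n + 1):
            if i == 0 and j == 0:
                continue
            if abs(i / m - j / n) >= d - 1e-12:
                continue
            paths[i, j] = (paths[i - 1, j] if i > 0 else 0.0) + (
                paths[i, j - 1] if j > 0 else 0.0
            )
    p = 1.0 - paths[m, n] / comb(m + n, m)
    return d, min(max(p, 0.0), 1.0)


class TestKSCompare:
    def test_identical_distributions(self):
        r = dict(zip("abcdef", [0.3, 0.2, 0.1, 0.3, 0.2, 0.1]))
        ranking = ranking_from_r(r)
        res = ks_compare(ranking, {"a", "b", "c"})
        assert res.d == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_disjoint_supports_give_d_one(self):
        r = {"t1": -0.9, "t2": -0.8, "n1": 0.1, "n2": 0.2, "n3": 0.3}
        res = ks_compare(ranking_from_r(r), {"t1", "t2"})
        assert res.d == pytest.approx(1.0)

    def test_hand_enumerated_cdf_difference(self):
        r = {"a1": 0.1, "a2": 0.2, "a3": 0.3, "b1": 0.15, "b2": 0.25}
        res = ks_compare(ranking_from_r(r), {"a1", "a2", "a3"})
        assert res.d == pytest.approx(1 / 3)

    def test_agrees_with_textbook_implementation_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n_t = int(rng.integers(6, 25))
            n_n = int(rng.integers(6, 25))
            rvals = rng.normal(0, 0.3, n_t + n_n)
            names = [f"g{i}" for i in range(n_t + n_n)]
            ranking = ranking_from_r(dict(zip(names, rvals)))
            targets = set(names[:n_t])
            res = ks_compare(ranking, targets)
            d_ref, p_ref = _ks_oracle(ranking.r_of(targets),
                                      np.array([v for g, v in zip(names, rvals)
                                                if g not in targets]))
            assert res.d == pytest.approx(d_ref, abs=1e-12)
            assert res.p == pytest.approx(p_ref, abs=1e-6)

    def test_empty_stratum_rejected(self):
        ranking = ranking_from_r({"a": 0.1, "b": 0.2})
        with pytest.raises(ValueError, match="stratum"):
            ks_compare(ranking, set())
        with pytest.raises(ValueError, match="stratum"):
            ks_compare(ranking, {"a", "b"})


class TestExpressionDependentRecovery:
    def test_high_abundance_stratum_significant_low_not(self):
        """With repression planted only on high-baseline targets, the > 4
        stratum shows the anti-correlation signal while the <= 4 stratum
        stays null (seed-averaged)."""
        from halfcell import (SimConfig, default_config, floor_and_log2,
                              generate_paired_profiles, generate_target_table,
                              plant_repression)

        table = generate_target_table(1, 300, 60, seed=1)
        high_sig, low_sig = 0, 0
        n_rep = 20
        for seed in range(n_rep):
            cfg = default_config(seed=seed, n_cells=19, n_mirnas=2, n_genes=300,
                                 biological_sd_log2=0.2, tech_sd_log2=0.2)
            baselines = dict(zip(cfg.gene_ids, cfg.gene_baseline_log2))
            targets_all = set(table["gene"])
            high = [g for g in targets_all if baselines[g] > 4.5]
            cfg = SimConfig(**{**cfg.__dict__,
                               "mirna_sd_log2": (1.0, 0.1),
                               "mirna_mean_log2": (2.0, 0.0),
                               "target_edges": plant_repression(table, "miR-001",
                                                                1.0, genes=high)})
            mi, mr, _ = generate_paired_profiles(cfg)
            from halfcell import correlate_to_mirna, ks_compare, stratify_by_expression

            mr_log = floor_and_log2(mr, 1e-3)
            vec = np.log2(np.clip(mi.values[0], 1e-12, None))
            ranking = correlate_to_mirna(mr_log, vec, "miR-001")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                strata = stratify_by_expression(targets_all, ranking)
            if strata["gt_4"] and ks_compare(ranking, strata["gt_4"]).p < 0.05:
                high_sig += 1
            if strata["le_4"] and ks_compare(ranking, strata["le_4"]).p < 0.05:
                low_sig += 1
        assert high_sig >= 0.8 * n_rep
        assert low_sig <= 0.3 * n_rep
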