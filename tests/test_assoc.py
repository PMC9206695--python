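"""Pairwise Pearson correlation, BH-FDR and network construction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from huangjiu_core import AlignmentError, DataError, SimConfig
from huangjiu_core import generate_community, generate_ha
from huangjiu_core.assoc import (
    AssocConfig,
    bh_adjust,
    cooccurrence_network,
    filter_edges,
    ha_sample_matrix,
    pearson_pairwise,
)
from huangjiu_core.community import AbundanceTable, to_relative


def _frame(rows: dict, samples):
    return pd.DataFrame.from_dict(rows, orient="index", dtype=float)\
        .set_axis(samples, axis=1)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Literal step-up: q_(i) = min_{j>=i} m p_(j)/j, capped at 1."""
    m = len(p)
    order = np.argsort(p)
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestPearsonPairwise:
    def test_exact_linear_relation(self):
        samples = [f"D0R{i}" for i in (1, 2, 3)] + ["D2R1"]
        x = _frame({"x": [1, 2, 3, 4]}, samples)
        y = _frame({"y": [3, 5, 7, 9]}, samples)  # y = 2x + 1
        edge = pearson_pairwise(x, y).edges.iloc[0]
        assert edge["r"] == pytest.approx(1.0)
        assert edge["p"] == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_vectors(self):
        samples = ["a", "b", "c"]
        x = _frame({"x": [-1, 0, 1]}, samples)
        y = _frame({"y": [1, -2, 1]}, samples)
        assert pearson_pairwise(x, y).edges.iloc[0]["r"] == pytest.approx(0.0,
                                                                          abs=1e-12)

    def test_hand_computed_point_eight(self):
        samples = list("abcde")
        x = _frame({"x": [1, 2, 3, 4, 5]}, samples)
        y = _frame({"y": [2, 1, 4, 3, 5]}, samples)
        assert pearson_pairwise(x, y).edges.iloc[0]["r"] == pytest.approx(0.8)

    def test_matches_scipy_per_pair(self, rng):
        """Vectorized r/p agree with scipy.stats.pearsonr pair by pair."""
        samples = [f"s{i}" for i in range(6)]
        X = pd.DataFrame(rng.normal(size=(4, 6)),
                         index=list("wxyz"), columns=samples)
        Y = pd.DataFrame(rng.normal(size=(3, 6)),
                         index=list("abc"), columns=samples)
        res = pearson_pairwise(X, Y)
        for _, e in res.edges.iterrows():
            ref = stats.pearsonr(X.loc[e["source"]], Y.loc[e["target"]])
            assert e["r"] == pytest.approx(ref.statistic, abs=1e-12)
            assert e["p"] == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-12)

    def test_sample_axis_mismatch(self):
        x = _frame({"x": [1, 2, 3]}, ["a", "b", "c"])
        y = _frame({"y": [1, 2, 3]}, ["a", "c", "b"])
        with pytest.raises(AlignmentError):
            pearson_pairwise(x, y)

    def test_too_few_samples(self):
        x = _frame({"x": [1, 2]}, ["a", "b"])
        with pytest.raises(DataError):
            pearson_pairwise(x, x)

    def test_zero_variance_feature_yields_no_edge(self, rng):
        samples = [f"s{i}" for i in range(5)]
        X = pd.DataFrame({"flat": [1.0] * 5,
                          "var": rng.normal(size=5)}).T.set_axis(samples, axis=1)
        Y = pd.DataFrame(rng.normal(size=(1, 5)), index=["y"], columns=samples)
        res = pearson_pairwise(X, Y)
        assert set(res.edges["source"]) == {"var"}


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_stepup_evaluations(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert bh_adjust([0.5, 0.01]) == pytest.approx([0.5, 0.02])

    def test_matches_brute_force_on_permutations(self, rng):
        base = rng.uniform(0, 1, size=5)
        for perm in itertools.permutations(base):
            p = np.array(perm)
            assert bh_adjust(p) == pytest.approx(brute_force_bh(p), rel=1e-12)

    def test_monotone_in_sorted_order(self, rng):
        p = np.sort(rng.uniform(0, 1, size=20))
        q = bh_adjust(p)
        assert np.all(np.diff(q) >= -1e-12)
        assert np.all(q >= p - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            bh_adjust([0.5, 1.5])


class TestFilterEdges:
    def _result(self, rows):
        edges = pd.DataFrame(rows, columns=["source", "target", "r", "p", "q"])
        edges["robust"] = False
        edges["sign"] = np.where(edges["r"] >= 0, "+", "-")
        nodes = pd.DataFrame({"id": [], "type": [], "mean_value": []})
        from huangjiu_core.assoc import AssocResult
        return AssocResult(edges=edges, nodes=nodes)

    def test_strong_edge_retained_and_robust(self):
        res = filter_edges(self._result([("a", "h", 0.99, 0.001, 0.004)]),
                           AssocConfig())
        assert len(res.edges) == 1
        assert bool(res.edges.iloc[0]["robust"])

    def test_fdr_gate_drops_marginal_edge(self):
        res = filter_edges(self._result([("a", "h", 0.5, 0.04, 0.08)]),
                           AssocConfig(use_fdr=True))
        assert len(res.edges) == 0

    def test_planted_pair_retained_across_seeds(self):
        hits = 0
        for seed in range(20):
            sim = SimConfig(n_taxa=20, n_producers=2, n_has=4,
                            noise_sd=0.05, seed=seed)
            abundance, truth = generate_community(sim)
            ha = generate_ha(abundance, truth, sim)
            rel = to_relative(abundance)
            config = AssocConfig()
            matrix = ha_sample_matrix(ha, config)
            res = filter_edges(pearson_pairwise(rel.data, matrix, config), config)
            pairs = set(zip(res.edges["source"], res.edges["target"]))
            planted = {
                (p, h)
                for p in truth.producer_ids
                for h in truth.effect_matrix.columns
                if truth.effect_matrix.loc[p, h] != 0
            }
            hits += planted <= pairs
        assert hits >= 18


class TestCooccurrence:
    def test_identical_rows_perfect_positive(self):
        samples = [f"D0R{i}" for i in (1, 2, 3)]
        table = AbundanceTable(data=_frame({"a": [1, 2, 3], "b": [2, 4, 6],
                                            "c": [5, 1, 2]}, samples))
        res = cooccurrence_network(table)
        edge = res.edges[(res.edges.source == "a") & (res.edges.target == "b")]
        assert edge.iloc[0]["r"] == pytest.approx(1.0)
        assert edge.iloc[0]["sign"] == "+"

    def test_two_taxon_composition_anticorrelated(self):
        samples = ["s1", "s2", "s3", "s4"]
        table = AbundanceTable(
            data=_frame({"a": [0.2, 0.5, 0.7, 0.4],
                         "b": [0.8, 0.5, 0.3, 0.6]}, samples))
        res = cooccurrence_network(table)
        assert res.edges.iloc[0]["r"] == pytest.approx(-1.0)

    def test_edges_are_unique_unordered_pairs(self, rng):
        samples = [f"s{i}" for i in range(6)]
        table = AbundanceTable(data=pd.DataFrame(
            rng.uniform(0.1, 1, size=(5, 6)),
            index=list("abcde"), columns=samples))
        res = cooccurrence_network(table)
        assert len(res.edges) == 5 * 4 // 2
        assert len(res.nodes) == 5

    def test_dominant_taxon_mostly_negative_edges(self):
        table, truth = generate_community(SimConfig(seed=1))
        res = cooccurrence_network(table)
        e = res.edges
        mine = e[(e.source == truth.dominant_taxon)
                 | (e.target == truth.dominant_taxon)]
        assert (mine["sign"] == "-").mean() > 0.5


class TestNullCalibration:
    def test_retained_fraction_near_alpha_without_fdr(self):
        """Under independent X and Y the raw-p gate keeps ~5% of edges."""
        config = AssocConfig(use_fdr=False)
        kept = total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            samples = [f"s{i}" for i in range(20)]
            X = pd.DataFrame(rng.normal(size=(10, 20)),
                             index=[f"x{i}" for i in range(10)], columns=samples)
            Y = pd.DataFrame(rng.normal(size=(8, 20)),
                             index=[f"y{i}" for i in range(8)], columns=samples)
            res = filter_edges(pearson_pairwise(X, Y, config), config)
            kept += len(res.edges)
            total += 80
        rate = kept / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert abs(rate - 0.05) < 3 * se
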