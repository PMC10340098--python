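"""Network metrics against independent oracles and closed forms."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from netdr.metrics import (
    ScoreTable,
    adamic_adar_scores,
    adjust_exponential,
    adjust_multiplicative,
    neighborhood_scores,
    pagerank_scores,
)
from conftest import make_module, random_weighted_module

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def aa_oracle(module, weighted_degree=False):
    """Brute-force triple loop: pairs × common neighbors."""
    g = module.subnetwork.graph

    def k(z):
        if weighted_degree:
            return sum(g[z][nb]["weight"] for nb in g.neighbors(z))
        return g.degree(z)

    def inv_log(kz):
        return 1.0 / math.log1p(kz) if kz <= 1.0 else 1.0 / math.log(kz)

    nodes = list(g.nodes)
    scores = {v: 0.0 for v in nodes}
    for x in nodes:
        for y in nodes:
            if x == y:
                continue
            for z in nodes:
                if z != x and z != y and g.has_edge(x, z) and g.has_edge(y, z):
                    scores[x] += inv_log(k(z))
    return scores


def pagerank_oracle(module, damping):
    """Closed-form stationary vector by dense linear solve (no power iteration)."""
    g = module.subnetwork.graph
    nodes = sorted(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    W = np.zeros((n, n))
    for a, b, d in g.edges(data="weight"):
        W[idx[a], idx[b]] = W[idx[b], idx[a]] = d
    out = W.sum(axis=1)
    P = W / out[:, None]
    r = np.linalg.solve(np.eye(n) - damping * P.T, np.full(n, (1 - damping) / n))
    r = r / r.sum()
    return {v: r[idx[v]] for v in nodes}


# ---------------------------------------------------------------------------
# Adamic-Adar
# ---------------------------------------------------------------------------

class TestAdamicAdar:
    def test_path_common_neighbor(self):
        mod = make_module([("A", "C", 1.0), ("C", "B", 1.0)], {"A", "B", "C"})
        scores = adamic_adar_scores(mod)
        assert scores["A"] == pytest.approx(1 / LN2, abs=1e-12)
        assert scores["B"] == pytest.approx(1 / LN2, abs=1e-12)
        assert scores["C"] == 0.0

    def test_triangle_matches_brute_force(self, triangle_module):
        scores = adamic_adar_scores(triangle_module)
        oracle = aa_oracle(triangle_module)
        assert scores == pytest.approx(oracle, abs=1e-12)
        assert scores["A"] == pytest.approx(2 / LN2, abs=1e-12)

    def test_single_edge_all_zero(self):
        mod = make_module([("A", "B", 0.7)], {"A", "B"})
        assert set(adamic_adar_scores(mod).values()) == {0.0}

    @pytest.mark.parametrize("weighted", [False, True], ids=["degree", "strength"])
    def test_random_graphs_match_triple_loop_oracle(self, weighted):
        rng = np.random.default_rng(42)
        for _ in range(25):
            mod = random_weighted_module(rng, int(rng.integers(4, 21)))
            got = adamic_adar_scores(mod, weighted_degree=weighted)
            want = aa_oracle(mod, weighted_degree=weighted)
            assert got == pytest.approx(want, abs=1e-10)

    def test_low_strength_safeguard_is_finite(self):
        # strengths well below 1 would make log(k) negative without the floor
        mod = make_module([("A", "C", 0.15), ("C", "B", 0.15)], {"A", "B", "C"})
        scores = adamic_adar_scores(mod, weighted_degree=True)
        assert all(math.isfinite(s) and s >= 0 for s in scores.values())
        assert scores["A"] == pytest.approx(1 / math.log1p(0.3), abs=1e-12)

    def test_too_small_module_rejected(self):
        mod = make_module([("A", "B", 0.5)], {"A"})
        # module has 2 nodes; shrink artificially via a 1-node check
        with pytest.raises(ValueError):
            adamic_adar_scores(
                type(mod)(
                    seeds=frozenset({"A"}),
                    members=frozenset({"A"}),
                    subnetwork=type(mod.subnetwork)(nx.Graph([("A", "A")])),
                )
            )


# ---------------------------------------------------------------------------
# PageRank
# ---------------------------------------------------------------------------

class TestPageRank:
    def test_triangle_uniform(self, triangle_module):
        scores = pagerank_scores(triangle_module, damping=0.75)
        assert list(scores.values()) == pytest.approx([1 / 3] * 3, abs=1e-9)

    def test_star_center_dominates(self, star_module):
        scores = pagerank_scores(star_module, damping=0.75)
        leaves = [scores[f"L{i}"] for i in (1, 2, 3)]
        assert scores["H"] > max(leaves)
        assert leaves == pytest.approx([leaves[0]] * 3, abs=1e-12)

    def test_random_graphs_match_dense_solve_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            mod = random_weighted_module(rng, int(rng.integers(3, 16)))
            got = pagerank_scores(mod, damping=0.75)
            want = pagerank_oracle(mod, damping=0.75)
            assert got == pytest.approx(want, abs=1e-8)
            assert sum(got.values()) == pytest.approx(1.0, abs=1e-9)

    def test_matches_networkx_cross_check(self, star_module):
        ours = pagerank_scores(star_module, damping=0.75)
        theirs = nx.pagerank(
            star_module.subnetwork.graph, alpha=0.75, weight="weight", tol=1e-12, max_iter=500
        )
        assert ours == pytest.approx(theirs, abs=1e-8)

    def test_bad_damping_rejected(self, triangle_module):
        with pytest.raises(ValueError):
            pagerank_scores(triangle_module, damping=1.0)


# ---------------------------------------------------------------------------
# z-score adjustments
# ---------------------------------------------------------------------------

def two_modules():
    shared = make_module([("X", "Y", 1.0), ("Y", "Z", 1.0)], {"X", "Y", "Z"})
    other = make_module([("X", "Y", 1.0)], {"X", "Y"})
    return shared, other  # members {X,Y,Z} vs {X,Y}; Z is self-only


class TestAdjustments:
    def test_canceling_z_is_identity(self):
        mod, other = two_modules()
        base = {g: 1.4427 for g in mod.members}
        out = adjust_multiplicative(base, mod, other, {"X": 1.2}, {"X": -1.2})
        assert out["X"] == pytest.approx(1.4427, abs=1e-12)

    def test_self_only_gene_uses_own_z(self):
        mod, other = two_modules()
        base = {g: 2.0 for g in mod.members}
        m = adjust_multiplicative(base, mod, other, {"Z": 2.0}, {})
        e = adjust_exponential(base, mod, other, {"Z": 2.0}, {})
        assert m["Z"] == pytest.approx(2.0 * 0.5**2, abs=1e-12)  # 0.5
        assert e["Z"] == pytest.approx(2.0 / math.e**2, abs=1e-12)  # ≈ 0.2707

    def test_unmeasured_gene_unchanged(self):
        mod, other = two_modules()
        base = {g: 2.0 for g in mod.members}
        for adjust in (adjust_multiplicative, adjust_exponential):
            assert adjust(base, mod, other, {}, {})["Y"] == pytest.approx(2.0)

    def test_zero_base_stays_zero(self):
        mod, other = two_modules()
        base = {g: 0.0 for g in mod.members}
        out = adjust_exponential(base, mod, other, {"X": 3.0}, {"X": 4.0})
        assert out["X"] == 0.0

    def test_factors_strictly_decreasing_in_zsum(self):
        mod, other = two_modules()
        base = {g: 2.0 for g in mod.members}
        grid = np.linspace(0.0, 10.0, 100)
        for adjust in (adjust_multiplicative, adjust_exponential):
            vals = [adjust(base, mod, other, {"Z": float(s)}, {})["Z"] for s in grid]
            assert all(a > b for a, b in zip(vals, vals[1:]))

    @given(st.lists(st.floats(-4, 4), min_size=2, max_size=2))
    def test_equal_bases_give_same_rank_order(self, zs):
        """With equal base scores the two damping flavours rank identically."""
        mod, other = two_modules()
        base = {g: 3.0 for g in mod.members}
        z_self = {"X": zs[0], "Z": zs[1]}
        m = adjust_multiplicative(base, mod, other, z_self, {})
        e = adjust_exponential(base, mod, other, z_self, {})
        order = lambda d: sorted(d, key=lambda g: (-d[g], g))
        assert order(m) == order(e)

    def test_signature_objects_accepted(self):
        from netdr.signatures import DrugSignature

        mod, other = two_modules()
        base = {g: 2.0 for g in mod.members}
        sig = DrugSignature("d", {"Z": 2.0})
        assert adjust_multiplicative(base, mod, other, sig, {})["Z"] == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# neighborhood scoring
# ---------------------------------------------------------------------------

class TestNeighborhoodScoring:
    def test_hand_computed_blend(self):
        mod = make_module([("i", "a", 0.5), ("i", "b", 0.9)], {"i"})
        z = {"i": 2.0, "a": -1.0, "b": 3.0}
        scores = neighborhood_scores(mod, z, alpha=0.7, epsilon=0.1)
        assert scores["i"] == pytest.approx(1.7, abs=1e-12)

    def test_isolated_gene_keeps_alpha_fraction(self):
        # neighbors exist but all below the weight threshold
        mod = make_module([("i", "a", 0.05)], {"i", "a"})
        scores = neighborhood_scores(mod, {"i": 4.0}, alpha=0.7, epsilon=0.1)
        assert scores["i"] == pytest.approx(2.8, abs=1e-12)

    def test_all_zero_z(self, triangle_module):
        scores = neighborhood_scores(triangle_module, {})
        assert set(scores.values()) == {0.0}

    def test_epsilon_is_strict(self):
        mod = make_module([("i", "a", 0.1)], {"i", "a"})
        scores = neighborhood_scores(mod, {"i": 1.0, "a": 5.0}, alpha=0.7, epsilon=0.1)
        assert scores["i"] == pytest.approx(0.7, abs=1e-12)  # w == ε does not count

    @given(st.floats(-3, 3, allow_nan=False))
    def test_linear_in_z(self, c):
        mod = make_module([("i", "a", 0.5), ("a", "b", 0.8)], {"i", "a", "b"})
        z = {"i": 1.5, "a": -2.0, "b": 0.5}
        base = neighborhood_scores(mod, z)
        scaled = neighborhood_scores(mod, {g: c * v for g, v in z.items()})
        for g in base:
            assert scaled[g] == pytest.approx(c * base[g], abs=1e-9)


class TestScoreTable:
    def test_directions_fixed_per_metric(self):
        assert ScoreTable("AA1", {"a": 1.0}).rank_direction == "descending"
        assert ScoreTable("NS", {"a": 1.0}).rank_direction == "ascending"
        with pytest.raises(ValueError):
            ScoreTable("NS", {"a": 1.0}, rank_direction="descending")
        with pytest.raises(ValueError):
            ScoreTable("XX", {"a": 1.0})
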