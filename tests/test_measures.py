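"""Graph statistics against independent brute-force oracles: summary
counts, motif census, rewiring null, clique census, RMS log-ratio,
spectral measure, and the connection-probability GLM."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from edrnet import (
    Connectome,
    DistanceMatrix,
    EDRParameters,
    clique_census,
    connection_probability_fit,
    motif_census,
    motif_log_residuals,
    rewire_degree_preserving,
    rms_log_ratio,
    sample_cdr,
    sample_edr,
    second_eigenvalue,
    summarize,
)
from edrnet.measures import MOTIF_CLASSES

from conftest import random_connectome


# --- independent 3-node isomorphism oracle ---------------------------

_EDGE_SLOTS = [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)]


def _canonical(pattern: int) -> int:
    """Smallest 6-bit encoding over the 6 relabelings of 3 nodes."""
    best = 64
    edges = {_EDGE_SLOTS[b] for b in range(6) if pattern >> b & 1}
    for perm in itertools.permutations(range(3)):
        enc = 0
        for b, (u, v) in enumerate(_EDGE_SLOTS):
            if (perm[u], perm[v]) in edges:
                enc |= 1 << b
        best = min(best, enc)
    return best


def oracle_census(a: np.ndarray) -> dict[int, int]:
    """Triple-by-triple census keyed by canonical form."""
    n = a.shape[0]
    out: dict[int, int] = {}
    for i, j, k in itertools.combinations(range(n), 3):
        pat = 0
        nodes = (i, j, k)
        for b, (u, v) in enumerate(_EDGE_SLOTS):
            if a[nodes[u], nodes[v]]:
                pat |= 1 << b
        c = _canonical(pat)
        out[c] = out.get(c, 0) + 1
    return out


def census_by_canonical(counts: np.ndarray) -> dict[int, int]:
    """Regroup a 16-class census by oracle canonical form for comparison."""
    reps: dict[int, int] = {}
    for pat in range(64):
        c = _canonical(pat)
        reps.setdefault(c, pat)
    # map each class index to the canonical forms it contains
    from edrnet.measures import _pattern_class_table

    table = _pattern_class_table()
    out: dict[int, int] = {}
    for c in reps:
        if counts[table[c]]:
            out[c] = int(counts[table[c]])
    return out


class TestSummarize:
    def test_published_density(self):
        # 33 areas, 719 pathways -> density 0.68
        a = np.zeros((33, 33))
        iu = np.nonzero(~np.eye(33, dtype=bool))
        a[iu[0][:719], iu[1][:719]] = 1
        s = summarize(Connectome(tuple(f"a{i}" for i in range(33)), a))
        assert round(s.density, 2) == 0.68

    def test_complete_bidirectional(self):
        n = 6
        a = np.ones((n, n)) - np.eye(n)
        s = summarize(Connectome(tuple("abcdef"), a))
        assert s.density == 1.0
        assert s.m1 == 0
        assert s.m2 == n * (n - 1) // 2

    def test_m1_m2_against_double_loop(self, rng):
        for _ in range(50):
            g = random_connectome(10, rng.uniform(0.1, 0.9), rng)
            s = summarize(g)
            a = g.adjacency
            m1 = m2 = 0
            for i in range(10):
                for j in range(i + 1, 10):
                    if a[i, j] and a[j, i]:
                        m2 += 1
                    elif a[i, j] or a[j, i]:
                        m1 += 1
            assert (s.m1, s.m2) == (m1, m2)
            assert s.m == s.m1 + 2 * s.m2


class TestMotifCensus:
    def test_all_64_labeled_triads(self):
        # every labeled 3-node digraph, classified by the isomorphism oracle
        totals = np.zeros(16, dtype=int)
        for pattern in range(64):
            a = np.zeros((3, 3))
            for b, (u, v) in enumerate(_EDGE_SLOTS):
                if pattern >> b & 1:
                    a[u, v] = 1
            c = motif_census(Connectome(("x", "y", "z"), a))
            assert c.n_triplets == 1
            totals += c.counts
            assert census_by_canonical(c.counts) == oracle_census(a)
        assert totals.sum() == 64

    def test_named_classes(self):
        # lone reciprocal pair -> class 3; directed 3-cycle -> class 10
        recip = np.zeros((3, 3))
        recip[0, 1] = recip[1, 0] = 1
        c = motif_census(Connectome(("x", "y", "z"), recip))
        assert c.counts[2] == 1 and MOTIF_CLASSES[2] == "102"
        cyc = np.zeros((3, 3))
        cyc[0, 1] = cyc[1, 2] = cyc[2, 0] = 1
        c = motif_census(Connectome(("x", "y", "z"), cyc))
        assert c.counts[9] == 1 and MOTIF_CLASSES[9] == "030C"

    def test_random_graphs_match_oracle(self, rng):
        for _ in range(50):
            g = random_connectome(8, rng.uniform(0.1, 0.9), rng)
            c = motif_census(g)
            assert census_by_canonical(c.counts) == oracle_census(g.adjacency)
            assert c.n_triplets == 8 * 7 * 6 // 6

    def test_mouse_scale_total(self, mouse_fixture):
        assert motif_census(mouse_fixture.connectome).n_triplets == 5456

    @given(st.integers(0, 2**20 - 1))
    def test_total_conservation(self, bits):
        n = 5
        a = np.zeros((n, n))
        slots = [(i, j) for i in range(n) for j in range(n) if i != j]
        for b, (i, j) in enumerate(slots):
            if bits >> b & 1:
                a[i, j] = 1
        c = motif_census(Connectome(tuple("abcde"), a))
        assert c.counts.sum() == 10


class TestRewiring:
    def test_degrees_preserved_exactly(self, rng):
        for _ in range(20):
            g = random_connectome(12, 0.3, rng)
            h = rewire_degree_preserving(g, seed=rng)
            np.testing.assert_array_equal(
                g.adjacency.sum(axis=0), h.adjacency.sum(axis=0)
            )
            np.testing.assert_array_equal(
                g.adjacency.sum(axis=1), h.adjacency.sum(axis=1)
            )
            assert h.n_edges == g.n_edges
            assert np.diag(h.weights).sum() == 0

    def test_two_cycle_frozen(self):
        a = np.array([[0.0, 1.0, 0], [1.0, 0, 0], [0, 0, 0]])
        g = Connectome(("x", "y", "z"), a)
        h = rewire_degree_preserving(g, n_swaps=100, seed=0)
        np.testing.assert_array_equal(h.adjacency, g.adjacency)

    def test_ensemble_randomizes_motifs(self, rng):
        g = random_connectome(8, 0.45, rng)
        base = motif_census(g).counts
        changed = 0
        for _ in range(50):
            h = rewire_degree_preserving(g, seed=rng)
            if not np.array_equal(motif_census(h).counts, base):
                changed += 1
        assert changed > 25


class TestMotifResiduals:
    def test_self_null_residuals_near_zero(self, rng):
        # a graph compared against its own rewiring family
        g = random_connectome(12, 0.4, rng)
        h = rewire_degree_preserving(g, seed=1)  # a typical family member
        res = motif_log_residuals(h, n_null=200, seed=2)
        ok = res["defined"] & np.isfinite(res["ci_low"])
        within = (res["residual"][ok] >= res["ci_low"][ok]) & (
            res["residual"][ok] <= res["ci_high"][ok]
        )
        assert within.mean() >= 0.8

    def test_hand_computed_residual(self):
        counts_data = np.array([4.0, 2.0])
        counts_null = [np.array([2.0, 2.0]), np.array([6.0, 2.0])]
        # mean null = [4, 2] -> residuals ln(1) = 0
        assert np.log(counts_data / np.mean(counts_null, axis=0)) == pytest.approx(
            [0.0, 0.0]
        )

    def test_sign_pattern_stable_across_seeds(self, mouse_fixture):
        g = mouse_fixture.connectome
        r1 = motif_log_residuals(g, n_null=100, seed=1)
        r2 = motif_log_residuals(g, n_null=100, seed=2)
        ok = r1["defined"] & r2["defined"]
        agree = np.sign(r1["residual"][ok]) == np.sign(r2["residual"][ok])
        assert agree.sum() >= ok.sum() - 2


def oracle_clique_counts(adj_sym: np.ndarray) -> dict[int, int]:
    """Power-set enumeration of complete subgraphs (N <= 12)."""
    n = adj_sym.shape[0]
    counts: dict[int, int] = {}
    for size in range(1, n + 1):
        for nodes in itertools.combinations(range(n), size):
            if all(
                adj_sym[u, v] for u, v in itertools.combinations(nodes, 2)
            ):
                counts[size] = counts.get(size, 0) + 1
    return counts


class TestCliqueCensus:
    def test_bidirectional_triangle(self):
        a = np.ones((3, 3)) - np.eye(3)
        c = clique_census(Connectome(("x", "y", "z"), a))
        assert c.counts == {1: 3, 2: 3, 3: 1}

    def test_single_missing_directed_link_breaks_top_clique(self):
        # 12 reciprocally complete areas minus one directed link:
        # the 12-set is not a clique, max size drops to 11
        a = np.ones((12, 12)) - np.eye(12)
        a[0, 1] = 0
        c = clique_census(Connectome(tuple(f"a{i}" for i in range(12)), a))
        assert c.max_size == 11
        assert c.counts[11] == 2

    def test_matches_power_set_oracle(self, rng):
        for _ in range(10):
            g = random_connectome(10, rng.uniform(0.3, 0.8), rng)
            sym = (g.adjacency & g.adjacency.T).astype(bool)
            assert clique_census(g).counts == oracle_clique_counts(sym)

    def test_hereditary_count_bound(self, mouse_fixture):
        c = clique_census(mouse_fixture.connectome).counts
        for k in sorted(c):
            if k + 1 in c:
                assert c[k] >= k + 1 or c[k + 1] == 0


class TestRmsLogRatio:
    def test_identity_and_scale(self):
        a = np.array([3.0, 5.0, 7.0])
        assert rms_log_ratio(a, a)[0] == 0.0
        assert rms_log_ratio(np.e * a, a)[0] == pytest.approx(1.0)

    @given(
        st.lists(st.floats(0.1, 1e4), min_size=2, max_size=10),
        st.lists(st.floats(0.1, 1e4), min_size=2, max_size=10),
    )
    def test_matches_direct_formula(self, xs, ys):
        k = min(len(xs), len(ys))
        a, b = np.array(xs[:k]), np.array(ys[:k])
        sigma, dropped = rms_log_ratio(a, b)
        assert dropped == 0
        assert sigma == pytest.approx(
            np.sqrt(np.mean(np.log(a / b) ** 2))
        )

    def test_zero_handling(self):
        sigma, dropped = rms_log_ratio(
            np.array([1.0, 0.0, 2.0]), np.array([1.0, 5.0, 0.0])
        )
        assert dropped == 2
        with pytest.raises(ValueError):
            rms_log_ratio(np.array([0.0, 1.0]), np.array([1.0, 0.0]))


class TestSecondEigenvalue:
    def test_empty_graph(self):
        g = Connectome(("x", "y", "z"), np.zeros((3, 3)))
        assert second_eigenvalue(g) == pytest.approx(0.0)

    def test_complete_digraph_closed_form(self):
        # A = J - I on 3 nodes: A A^T = J + I with spectrum {4, 1, 1}
        a = np.ones((3, 3)) - np.eye(3)
        assert second_eigenvalue(Connectome(("x", "y", "z"), a)) == pytest.approx(1.0)

    def test_relabel_invariance(self, rng):
        g = random_connectome(9, 0.4, rng)
        perm = rng.permutation(9)
        h = Connectome(
            tuple(g.labels[i] for i in perm), g.weights[np.ix_(perm, perm)]
        )
        assert second_eigenvalue(h) == pytest.approx(second_eigenvalue(g))


class TestConnectionProbabilityFit:
    def test_edr_negative_slope(self, mouse_fixture):
        D = mouse_fixture.distances
        g = sample_edr(
            D,
            EDRParameters(lambda_=1.1, binwidth=0.4, target_density=0.5),
            seed=0,
        )
        fit = connection_probability_fit(g, D)
        assert not fit["separable"]
        assert fit["beta1"] < 0

    def test_cdr_flat(self, mouse_fixture):
        D = mouse_fixture.distances
        flat = 0
        rng = np.random.default_rng(3)
        for _ in range(10):
            g = sample_cdr(
                D,
                EDRParameters(lambda_=0.0, binwidth=0.4, target_density=0.5),
                seed=rng,
            )
            fit = connection_probability_fit(g, D)
            flat += abs(fit["beta1"] / fit["se_beta1"]) < 2
        assert flat >= 9

    def test_logistic_recovery(self, mouse_fixture, rng):
        D = mouse_fixture.distances
        b0, b1 = 2.0, -0.5
        n = D.n_areas
        mask = ~np.eye(n, dtype=bool)
        p = 1 / (1 + np.exp(-(b0 + b1 * D.values)))
        a = np.zeros((n, n))
        a[mask] = rng.random(mask.sum()) < p[mask]
        fit = connection_probability_fit(Connectome(D.labels, a), D)
        assert fit["beta0"] == pytest.approx(b0, abs=3 * fit["se_beta0"])
        assert fit["beta1"] == pytest.approx(b1, abs=3 * fit["se_beta1"])
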