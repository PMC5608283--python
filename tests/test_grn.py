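import itertools

import numpy as np
import pandas as pd
import pytest

from tripla import (
    ExpressionMatrix,
    GeneNetwork,
    aracne_network,
    mi_threshold,
    mutual_information,
    trace_triplets_in_grn,
)
from tripla.grn import n_bins_for, null_mi_sample


class TestMutualInformation:
    def test_symmetry_exact(self):
        x, y = np.random.default_rng(0).normal(size=(2, 100))
        assert mutual_information(x, y) == mutual_information(y, x)

    def test_independent_vectors_near_zero(self):
        x, y = np.random.default_rng(1).normal(size=(2, 1000))
        assert mutual_information(x, y) < 0.05

    def test_identical_vectors_hit_grid_ceiling(self):
        """y = x at n = 1000, B = 10: diagonal table gives log(10) plus the
        Miller-Madow term (10 + 10 - 10 - 1)/(2n), frozen arithmetic."""
        x = np.arange(1000, dtype=float)
        expected = np.log(10) + 9 / 2000
        assert mutual_information(x, x) == pytest.approx(expected, abs=1e-12)

    def test_self_mi_is_maximal(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        self_mi = mutual_information(x, x)
        assert all(mutual_information(x, rng.normal(size=200)) < self_mi for _ in range(5))

    def test_constant_vector_convention_and_validation(self):
        x = np.random.default_rng(3).normal(size=50)
        assert mutual_information(x, np.ones(50)) == 0.0
        with pytest.raises(ValueError):
            mutual_information(x[:5], x[:5])

    def test_bin_count_rule(self):
        assert n_bins_for(30) == 2
        assert n_bins_for(200) == 6
        assert n_bins_for(10000) == 10


class TestMiThreshold:
    def test_alpha_half_is_the_null_median(self):
        """Independent re-simulation via mutual_information agrees with the
        internal permutation-pattern sampler."""
        rng = np.random.default_rng(4)
        ref = np.median([mutual_information(rng.normal(size=30), rng.normal(size=30)) for _ in range(2000)])
        thr = mi_threshold(30, alpha=0.5, n_perm=20000, seed=5)
        assert thr == pytest.approx(ref, abs=0.01)

    def test_monotone_in_alpha(self):
        thrs = [mi_threshold(30, a, n_perm=5000, seed=6) for a in (0.5, 0.1, 0.01, 1e-3, 1e-5)]
        assert all(a <= b + 1e-12 for a, b in zip(thrs, thrs[1:]))

    def test_tail_extrapolation_consistent_with_large_run(self):
        """Exponential-tail threshold from a small run tracks the direct
        empirical quantile of a 40x larger run."""
        direct = mi_threshold(30, 1e-3, n_perm=120000, seed=7)   # empirical quantile
        extrapolated = mi_threshold(30, 1e-3, n_perm=3000, seed=8)  # fitted tail
        assert extrapolated == pytest.approx(direct, rel=0.15)

    def test_deterministic(self):
        assert mi_threshold(30, 0.01, n_perm=2000, seed=9) == mi_threshold(30, 0.01, n_perm=2000, seed=9)

    def test_null_sampler_matches_estimator_law(self):
        """Null MI sampled by label-pattern permutation has the same
        distribution as MI of independent continuous draws (KS check)."""
        from scipy.stats import ks_2samp

        rng = np.random.default_rng(10)
        direct = np.array(
            [mutual_information(rng.normal(size=40), rng.normal(size=40)) for _ in range(1500)]
        )
        sampled = null_mi_sample(40, 1500, seed=11)
        assert ks_2samp(direct, sampled).pvalue > 0.01


def _matrix_from(rows: dict[str, np.ndarray]) -> ExpressionMatrix:
    data = pd.DataFrame(rows).T
    data.columns = [f"s{j}" for j in range(data.shape[1])]
    return ExpressionMatrix(data)


class TestAracne:
    def test_dpi_prunes_markov_chain_shortcut(self):
        """x -> y -> z: the indirect (x, z) edge is the triangle's weakest and is removed."""
        rng = np.random.default_rng(12)
        x = rng.normal(size=400)
        y = x + 0.4 * rng.normal(size=400)
        z = y + 0.4 * rng.normal(size=400)
        m = _matrix_from({"x": x, "y": y, "z": z})
        net = aracne_network(m, hubs=["x", "y", "z"], alpha=0.01, seed=13)
        pairs = {frozenset((s, t)) for s, t in zip(net.edges.source, net.edges.target)}
        assert frozenset(("x", "y")) in pairs
        assert frozenset(("y", "z")) in pairs
        assert frozenset(("x", "z")) not in pairs

    def test_tolerance_one_disables_dpi(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=400)
        y = x + 0.4 * rng.normal(size=400)
        z = y + 0.4 * rng.normal(size=400)
        m = _matrix_from({"x": x, "y": y, "z": z})
        net = aracne_network(m, hubs=["x", "y", "z"], alpha=0.01, dpi_tolerance=1.0, seed=15)
        pairs = {frozenset((s, t)) for s, t in zip(net.edges.source, net.edges.target)}
        assert frozenset(("x", "z")) in pairs  # kept: tolerance 1 never prunes

    def test_hub_and_spoke_recovery(self):
        """A hub driving 4 targets among decoys is recovered at n = 200."""
        rng = np.random.default_rng(16)
        hub = rng.normal(size=200)
        rows = {"hub": hub}
        for i in range(4):
            rows[f"t{i}"] = hub + 0.5 * rng.normal(size=200)
        for i in range(8):
            rows[f"d{i}"] = rng.normal(size=200)
        net = aracne_network(_matrix_from(rows), hubs=["hub"], alpha=0.01, seed=17)
        recovered = {t for s, t in zip(net.edges.source, net.edges.target) if s == "hub"}
        truth = {f"t{i}" for i in range(4)}
        assert truth <= recovered
        precision = len(recovered & truth) / len(recovered)
        assert precision >= 0.8

    def test_edges_touch_hubs_and_point_away(self):
        rng = np.random.default_rng(18)
        hub = rng.normal(size=100)
        rows = {"hub": hub, "a": hub + 0.3 * rng.normal(size=100), "b": rng.normal(size=100)}
        net = aracne_network(_matrix_from(rows), hubs=["hub"], alpha=0.05, seed=19)
        assert net.directed
        assert (net.edges.source == "hub").all()
        assert (net.edges.mi >= 0).all()

    def test_empty_hub_list_rejected(self, toy_matrix):
        with pytest.raises(ValueError):
            aracne_network(toy_matrix, hubs=[])


def _toy_network(edges):
    nodes = sorted({n for e in edges for n in e[:2]})
    frame = pd.DataFrame(
        [(s, t, 1.0, 1e-5) for s, t in edges], columns=["source", "target", "mi", "p_value"]
    )
    return GeneNetwork(nodes=nodes, edges=frame, directed=True)


def _brute_force_paths(edges, start, end, max_len):
    """Exhaustive DFS enumeration of simple directed paths."""
    adj = {}
    for s, t in edges:
        adj.setdefault(s, set()).add(t)
    found = []

    def walk(path):
        if len(path) - 1 > max_len:
            return
        if path[-1] == end and len(path) > 1:
            found.append(tuple(path))
            return
        for nxt in sorted(adj.get(path[-1], ())):
            if nxt not in path:
                walk(path + [nxt])

    walk([start])
    return {p for p in found if len(p) - 1 <= max_len}


class TestTraceTriplets:
    @staticmethod
    def _triplets(rows):
        return pd.DataFrame(rows, columns=["x3", "x1", "x2"])

    def test_direct_edge_reported_as_length_one(self):
        net = _toy_network([("S", "A")])
        out = trace_triplets_in_grn(net, self._triplets([("S", "A", "B")]))
        assert list(out.paths.length) == [1]
        assert out.paths.path.iloc[0] == "S->A"

    def test_one_intermediate_path(self):
        net = _toy_network([("S", "M"), ("M", "A"), ("M", "B")])
        out = trace_triplets_in_grn(net, self._triplets([("S", "A", "B")]), max_path_len=2)
        assert set(out.paths.path) == {"S->M->A", "S->M->B"}
        sub_pairs = set(zip(out.subnetwork.edges.source, out.subnetwork.edges.target))
        assert sub_pairs == {("S", "M"), ("M", "A"), ("M", "B")}

    def test_matches_exhaustive_path_oracle(self):
        rng = np.random.default_rng(20)
        nodes = [f"n{i}" for i in range(10)]
        edges = {
            (a, b)
            for a, b in itertools.permutations(nodes, 2)
            if rng.random() < 0.25
        }
        net = _toy_network(sorted(edges))
        trip = self._triplets([("n0", "n5", "n7")])
        out = trace_triplets_in_grn(net, trip, max_path_len=2)
        got = {tuple(p.split("->")) for p in out.paths.path}
        expected = _brute_force_paths(edges, "n0", "n5", 2) | _brute_force_paths(edges, "n0", "n7", 2)
        assert got == expected

    def test_empty_network_gives_empty_trace(self):
        net = GeneNetwork(nodes=[], edges=pd.DataFrame(columns=["source", "target", "mi", "p_value"]), directed=True)
        out = trace_triplets_in_grn(net, self._triplets([("S", "A", "B")]))
        assert out.paths.empty


class TestGeneNetworkInvariants:
    def test_rejects_self_edges_and_negative_mi(self):
        with pytest.raises(ValueError):
            GeneNetwork(["a"], pd.DataFrame({"source": ["a"], "target": ["a"], "mi": [1.0], "p_value": [0.1]}))
        with pytest.raises(ValueError):
            GeneNetwork(["a", "b"], pd.DataFrame({"source": ["a"], "target": ["b"], "mi": [-0.1], "p_value": [0.1]}))
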