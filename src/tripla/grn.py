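"""ARACNE-style regulatory network inference restricted to hub markers.

Pairwise dependence is measured by plug-in mutual information on an
equal-frequency B x B discretization (B = floor(sqrt(n/5)), bounded to
[2, 10]) with the Miller-Madow bias correction, in nats.  The significance
threshold is the empirical (1 - alpha) quantile of the permutation null at
the same sample size, with a fitted exponential right tail for alpha below
the permutation resolution.  Edges surviving the threshold are pruned by
the data-processing inequality (DPI): in every triangle the weakest edge
is removed when its MI falls below (1 - tolerance) times the smaller of
the other two.  Surviving edges incident to a hub are directed
hub -> target (hub-hub pairs keep both directions); this encodes the
hub-marker convention, not causal inference.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import xlogy

from .matrix import ExpressionMatrix
from .scan import ScanResult

log = logging.getLogger(__name__)


# -- discretization and MI ----------------------------------------------

def _label_pattern(n: int, b: int) -> np.ndarray:
    """Equal-frequency bin label for each sorted position (remainder first)."""
    base, extra = divmod(n, b)
    sizes = [base + 1] * extra + [base] * (b - extra)
    return np.repeat(np.arange(b), sizes)


def _discretize(x: np.ndarray, b: int) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    labels = np.empty(x.size, dtype=np.int64)
    labels[order] = _label_pattern(x.size, b)
    return labels


def n_bins_for(n: int) -> int:
    return int(min(10, max(2, np.floor(np.sqrt(n / 5)))))


def _mi_from_labels(lx: np.ndarray, ly: np.ndarray, b: int) -> float:
    n = lx.size
    counts = np.bincount(lx * b + ly, minlength=b * b).astype(float)
    cx = counts.reshape(b, b).sum(axis=1)
    cy = counts.reshape(b, b).sum(axis=0)
    h_xy = -np.sum(xlogy(counts, counts / n)) / n
    h_x = -np.sum(xlogy(cx, cx / n)) / n
    h_y = -np.sum(xlogy(cy, cy / n)) / n
    k_x = int(np.count_nonzero(cx))
    k_y = int(np.count_nonzero(cy))
    k_xy = int(np.count_nonzero(counts))
    mi = h_x + h_y - h_xy + (k_x + k_y - k_xy - 1) / (2.0 * n)
    return max(float(mi), 0.0)


def mutual_information(x, y) -> float:
    """Bias-corrected plug-in MI (nats) on equal-frequency bins.

    A constant vector carries no information: MI = 0 by convention (logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("constant vector: MI set to 0 by convention")
        return 0.0
    b = n_bins_for(n)
    return _mi_from_labels(_discretize(x, b), _discretize(y, b), b)


# -- permutation null and threshold -------------------------------------

def null_mi_sample(n: int, n_perm: int, seed: int = 0, b: int | None = None) -> np.ndarray:
    """Sample the null MI distribution at sample size ``n``.

    For independent continuous vectors the joint bin table depends only on
    a uniform random permutation pairing the two equal-frequency label
    patterns, so the null is sampled by permuting the label pattern —
    exactly the law of :func:`mutual_information` on independent draws.
    """
    if b is None:
        b = n_bins_for(n)
    rng = np.random.default_rng(seed)
    lab = _label_pattern(n, b)
    perms = rng.permuted(np.tile(lab, (n_perm, 1)), axis=1)
    code = lab[None, :] * b + perms
    counts = np.zeros((n_perm, b * b))
    rows = np.repeat(np.arange(n_perm), n)
    np.add.at(counts, (rows, code.ravel()), 1.0)
    h_xy = -np.sum(xlogy(counts, counts / n), axis=1) / n
    cx = np.bincount(lab, minlength=b).astype(float)
    h_marg = -np.sum(xlogy(cx, cx / n)) / n
    k_xy = (counts > 0).sum(axis=1)
    k_marg = int(np.count_nonzero(cx))
    mi = 2 * h_marg - h_xy + (2 * k_marg - k_xy - 1) / (2.0 * n)
    return np.maximum(mi, 0.0)


def _threshold_from_null(null_sorted: np.ndarray, alpha: float) -> float:
    n_perm = null_sorted.size
    if alpha * n_perm >= 10:
        return float(np.quantile(null_sorted, 1.0 - alpha))
    # exponential right-tail fit on the top exceedances
    k = max(100, n_perm // 20)
    u = null_sorted[-k - 1]
    exc = null_sorted[-k:] - u
    lam = 1.0 / max(float(exc.mean()), 1e-12)
    p_u = k / n_perm
    return float(u + np.log(p_u / alpha) / lam)


def mi_threshold(n: int, alpha: float, n_perm: int = 10000, seed: int = 0) -> float:
    """MI value exceeded with probability ``alpha`` under independence."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    null = np.sort(null_mi_sample(n, n_perm, seed=seed))
    return _threshold_from_null(null, alpha)


# -- network construction ------------------------------------------------

@dataclass
class GeneNetwork:
    """Weighted gene network; directed edges run hub -> target."""

    nodes: list[str]
    edges: pd.DataFrame  # columns: source, target, mi, p_value
    directed: bool = True

    def __post_init__(self) -> None:
        if len(self.edges):
            if (self.edges["source"] == self.edges["target"]).any():
                raise ValueError("self-edges are not allowed")
            if (self.edges["mi"] < 0).any():
                raise ValueError("mutual information must be non-negative")

    def to_networkx(self) -> nx.DiGraph | nx.Graph:
        graph = nx.DiGraph() if self.directed else nx.Graph()
        graph.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            graph.add_edge(row.source, row.target, mi=row.mi, p_value=row.p_value)
        return graph

    def to_tsv(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))


def aracne_network(
    matrix: ExpressionMatrix,
    hubs: list[str],
    alpha: float = 1e-4,
    dpi_tolerance: float = 0.15,
    seed: int = 0,
    n_perm: int | None = None,
    targets: list[str] | None = None,
) -> GeneNetwork:
    """Infer a hub-marker regulatory network by thresholded MI plus DPI.

    ``targets`` defaults to every non-hub gene in the matrix.  MI is
    computed for all pairs among hubs and targets; DPI triangles may
    therefore involve two targets even though only hub-incident edges are
    reported.  Deterministic given ``seed``.
    """
    if not hubs:
        raise ValueError("empty hub list")
    gene_set = set(matrix.gene_ids)
    missing = [h for h in hubs if h not in gene_set]
    if missing:
        raise ValueError(f"hubs absent from matrix: {missing[:5]}")
    if targets is None:
        targets = [g for g in matrix.gene_ids if g not in set(hubs)]
    nodes = list(dict.fromkeys(list(hubs) + list(targets)))
    n = matrix.n_samples
    b = n_bins_for(n)
    if n_perm is None:
        n_perm = int(min(200000, max(2000, np.ceil(10.0 / alpha))))
    null = np.sort(null_mi_sample(n, n_perm, seed=seed, b=b))
    threshold = _threshold_from_null(null, alpha)

    labels = {}
    for g in nodes:
        x = matrix.row(g)
        labels[g] = None if np.ptp(x) == 0 else _discretize(x, b)
    mi_of: dict[tuple[str, str], float] = {}
    for ga, gb in itertools.combinations(nodes, 2):
        la, lb = labels[ga], labels[gb]
        mi = 0.0 if la is None or lb is None else _mi_from_labels(la, lb, b)
        if mi >= threshold:
            mi_of[(ga, gb)] = mi

    # DPI on the thresholded graph
    neighbours: dict[str, set[str]] = {g: set() for g in nodes}
    for ga, gb in mi_of:
        neighbours[ga].add(gb)
        neighbours[gb].add(ga)

    def weight(a: str, c: str) -> float:
        return mi_of[(a, c)] if (a, c) in mi_of else mi_of[(c, a)]

    removed: set[tuple[str, str]] = set()
    for ga, gb in list(mi_of):
        for gc in neighbours[ga] & neighbours[gb]:
            w = sorted(
                [(weight(ga, gb), (ga, gb)), (weight(ga, gc), (ga, gc)), (weight(gb, gc), (gb, gc))],
                key=lambda t: t[0],
            )
            if w[0][0] < (1.0 - dpi_tolerance) * w[1][0]:
                a, c = w[0][1]
                removed.add((a, c) if (a, c) in mi_of else (c, a))

    hub_set = set(hubs)
    rows = []
    for (ga, gb), mi in mi_of.items():
        if (ga, gb) in removed:
            continue
        a_hub, b_hub = ga in hub_set, gb in hub_set
        if not (a_hub or b_hub):
            continue
        n_exceed = n_perm - int(np.searchsorted(null, mi, side="left"))
        p = (1 + n_exceed) / (n_perm + 1)
        if a_hub:
            rows.append((ga, gb, mi, p))
        if b_hub:
            rows.append((gb, ga, mi, p))
    edges = pd.DataFrame(rows, columns=["source", "target", "mi", "p_value"])
    edges = edges.sort_values(["source", "target"], kind="stable", ignore_index=True)
    return GeneNetwork(nodes=nodes, edges=edges, directed=True)


@dataclass
class TraceResult:
    """Paths linking each significant triplet's X3 to its pair genes."""

    paths: pd.DataFrame  # columns: x3, endpoint_role, endpoint, path, length
    subnetwork: GeneNetwork


def trace_triplets_in_grn(
    network: GeneNetwork,
    scan: ScanResult | pd.DataFrame,
    max_path_len: int = 2,
) -> TraceResult:
    """Find directed paths X3 -> ... -> X1/X2 of length <= ``max_path_len``.

    The default length 2 admits one intermediate regulator.  Triplets whose
    genes are absent from the network contribute no paths.
    """
    if isinstance(scan, ScanResult):
        triplets = scan.significant
    else:
        triplets = scan
        if "significant" in triplets.columns:
            triplets = triplets.loc[triplets["significant"]]
    graph = network.to_networkx()
    rows = []
    used_edges: set[tuple[str, str]] = set()
    for row in triplets.itertuples(index=False):
        for role, endpoint in (("x1", row.x1), ("x2", row.x2)):
            if row.x3 not in graph or endpoint not in graph:
                continue
            for path in nx.all_simple_paths(graph, row.x3, endpoint, cutoff=max_path_len):
                rows.append(
                    {
                        "x3": row.x3,
                        "endpoint_role": role,
                        "endpoint": endpoint,
                        "path": "->".join(path),
                        "length": len(path) - 1,
                    }
                )
                used_edges.update(zip(path[:-1], path[1:]))
    paths = pd.DataFrame(rows, columns=["x3", "endpoint_role", "endpoint", "path", "length"])
    if len(network.edges):
        keep = [
            (s, t) in used_edges
            for s, t in zip(network.edges["source"], network.edges["target"])
        ]
        sub_edges = network.edges.loc[keep].reset_index(drop=True)
    else:
        sub_edges = network.edges.copy()
    sub_nodes = sorted(set(sub_edges["source"]) | set(sub_edges["target"]))
    return TraceResult(paths, GeneNetwork(sub_nodes, sub_edges, directed=network.directed))
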