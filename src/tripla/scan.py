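"""Genome-scale triplet enumeration, FDR control and conditioned correlations.

For every candidate switching gene X3 and every unordered pair of other
genes, the binned liquid-association statistic is computed; its null SD
under permutation of X3 is estimated from a pilot permutation set shared
across all pairs of that X3 (each permutation re-scores every pair), giving
a two-sided normal p-value per triplet.  The most significant ``top_k``
triplets are retained and BH-corrected within the retained set, mirroring
the top-K convention of genome-scale scans; an optional flag corrects over
the full enumeration count instead (statistically safer).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import ndtr

from .de import benjamini_hochberg
from .liquid import _MIN_P, _bin_slices, _pearson
from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class ScanResult:
    """Ranked triplet table plus scan parameters and summary counts.

    ``triplets`` columns: x3, x1, x2 (pair in sorted-id order), mla,
    p_value, q_value, significant.  Rows are ranked by \\|mla\\| descending,
    then p ascending.
    """

    triplets: pd.DataFrame
    params: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    @property
    def significant(self) -> pd.DataFrame:
        return self.triplets.loc[self.triplets["significant"]]

    def to_tsv(self, path) -> None:
        self.triplets.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _mla_matrix(
    values: np.ndarray, x3: np.ndarray, n_bins: int, with_se: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """All-pairs MLA against one conditioning vector.

    ``values`` is genes x samples; returns a symmetric genes x genes matrix
    whose (i, j) entry is MLA(gene_i, gene_j | x3).  Zero-variance bins
    contribute correlation 0 (their rows are zeroed before the product).
    With ``with_se`` the delta-method SE matrix (plug-in per-bin
    correlation variances) is returned as well.
    """
    n = values.shape[1]
    order = np.argsort(x3, kind="stable")
    acc = np.zeros((values.shape[0], values.shape[0]))
    se2 = np.zeros_like(acc) if with_se else None
    for sl in _bin_slices(n, n_bins):
        idx = order[sl]
        sub = values[:, idx]
        sub = sub - sub.mean(axis=1, keepdims=True)
        norms = np.sqrt((sub * sub).sum(axis=1))
        z = np.zeros_like(sub)
        good = norms > 0
        z[good] = sub[good] / norms[good, None]
        corr = np.clip(z @ z.T, -1.0, 1.0)
        mean_x3 = x3[idx].mean()
        acc += corr * mean_x3
        if with_se:
            se2 += mean_x3**2 * (1.0 - corr**2) ** 2 / (idx.size - 1)
    if with_se:
        return acc / n_bins, np.sqrt(se2) / n_bins
    return acc / n_bins


def enumerate_triplet_count(n_genes: int, candidates: list[str], gene_ids: list[str]) -> int:
    """Number of scored triplets: per candidate, C(G-1, 2) pairs."""
    g = len(gene_ids)
    return sum((g - 1) * (g - 2) // 2 for _ in candidates)


def scan_triplets(
    matrix: ExpressionMatrix,
    candidates: list[str],
    n_bins: int = 3,
    top_k: int = 300000,
    fdr: float = 0.05,
    seed: int = 0,
    method: str = "analytic",
    n_pilot: int = 200,
    correct_full: bool = False,
) -> ScanResult:
    """Score all (candidate X3) x (unordered gene pair) triplets.

    ``matrix`` must already be quantile-transformed and standardized.
    Pairs may themselves contain candidate genes; a triplet never repeats a
    gene.  Deterministic given ``seed``.

    ``method`` selects the per-triplet p-value: ``analytic`` (delta-method
    SE; resolves p far below permutation resolution but with
    anti-conservative extreme tails — the convention genome-scale LA scans
    use) or ``normal_approx`` (null SD from ``n_pilot`` permutations of X3
    per candidate, shared across that candidate's pairs; calibrated, but
    cannot fall much below the permutation-normal tail).
    """
    if method not in ("analytic", "normal_approx"):
        raise ValueError("method must be 'analytic' or 'normal_approx'")
    if not candidates:
        raise ValueError("empty candidate list")
    gene_ids = matrix.gene_ids
    missing = [c for c in candidates if c not in set(gene_ids)]
    if missing:
        raise ValueError(f"candidates absent from matrix: {missing[:5]}")
    if matrix.n_genes < 3:
        raise ValueError("need at least 3 genes")
    values = matrix.values
    n = matrix.n_samples
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    rng = np.random.default_rng(seed)

    frames = []
    iu = np.triu_indices(len(gene_ids), k=1)
    for x3_id in candidates:
        i3 = gene_index[x3_id]
        x3 = values[i3]
        if method == "analytic":
            observed, sd = _mla_matrix(values, x3, n_bins, with_se=True)
        else:
            observed = _mla_matrix(values, x3, n_bins)
            acc = np.zeros_like(observed)
            acc_sq = np.zeros_like(observed)
            for _ in range(n_pilot):
                null = _mla_matrix(values, x3[rng.permutation(n)], n_bins)
                acc += null
                acc_sq += null * null
            var = acc_sq / n_pilot - (acc / n_pilot) ** 2
            sd = np.sqrt(np.clip(var, 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, observed / np.where(sd > 0, sd, 1.0), 0.0)
        p = np.maximum(2.0 * ndtr(-np.abs(z)), _MIN_P)

        keep = (iu[0] != i3) & (iu[1] != i3)
        ii, jj = iu[0][keep], iu[1][keep]
        pair_a = np.array([gene_ids[i] for i in ii])
        pair_b = np.array([gene_ids[j] for j in jj])
        swap = pair_a > pair_b  # canonical sorted-id pair order
        x1 = np.where(swap, pair_b, pair_a)
        x2 = np.where(swap, pair_a, pair_b)
        frames.append(
            pd.DataFrame(
                {
                    "x3": x3_id,
                    "x1": x1,
                    "x2": x2,
                    "mla": observed[ii, jj],
                    "p_value": p[ii, jj],
                }
            )
        )

    table = pd.concat(frames, ignore_index=True)
    n_enumerated = len(table)
    table = table.sort_values(["p_value", "x3", "x1", "x2"], kind="stable", ignore_index=True)
    table = table.iloc[:top_k].copy()
    m_total = n_enumerated if correct_full else None
    table["q_value"] = benjamini_hochberg(table["p_value"].to_numpy(), m_total=m_total)
    table["significant"] = table["q_value"] < fdr
    table["abs_mla"] = table["mla"].abs()
    table = table.sort_values(
        ["abs_mla", "p_value", "x3", "x1", "x2"],
        ascending=[False, True, True, True, True],
        kind="stable",
        ignore_index=True,
    ).drop(columns="abs_mla")

    sig = table.loc[table["significant"]]
    pair_genes = set(sig["x1"]) | set(sig["x2"])
    summary = {
        "n_enumerated": int(n_enumerated),
        "n_retained": int(len(table)),
        "n_significant": int(sig.shape[0]),
        "n_unique_genes": len(pair_genes | set(sig["x3"])),
        "n_unique_x3": int(sig["x3"].nunique()),
        "n_unique_pair_genes": len(pair_genes),
    }
    params = {
        "n_bins": n_bins,
        "top_k": top_k,
        "fdr": fdr,
        "seed": seed,
        "method": method,
        "n_pilot": n_pilot,
        "correct_full": correct_full,
    }
    return ScanResult(table, params, summary)


def triplet_network(scan: ScanResult) -> tuple[nx.Graph, pd.DataFrame]:
    """Undirected network of significant triplets plus per-X3 triplet counts.

    Each significant triplet contributes edges X3-X1 and X3-X2 and a pair
    edge X1-X2 flagged ``switched_pair``.
    """
    sig = scan.significant
    if sig.empty:
        raise ValueError("scan has no significant triplet")
    graph = nx.Graph()
    for row in sig.itertuples(index=False):
        graph.add_edge(row.x3, row.x1, kind="x3_link")
        graph.add_edge(row.x3, row.x2, kind="x3_link")
        graph.add_edge(row.x1, row.x2, kind="switched_pair")
    counts = (
        sig.groupby("x3")
        .size()
        .rename("n_triplets")
        .sort_values(ascending=False)
        .rename_axis("x3")
        .reset_index()
    )
    return graph, counts


@dataclass
class ConditionedCorrelation:
    """Pair correlations within low / middle / high strata of X3.

    ``boundaries`` are the transformed-X3 values at the ends of the middle
    stratum (for tie-free n = 30 tertiles: -0.372 and +0.372); ``extremes``
    are the smallest and largest transformed X3 values (+-1.849 at n = 30).
    Undefined (zero-variance) stratum correlations are NaN, never 0.
    """

    x3_id: str
    x1_id: str
    x2_id: str
    boundaries: tuple[float, float]
    extremes: tuple[float, float]
    corr_low: float
    corr_mid: float
    corr_high: float
    n_low: int
    n_mid: int
    n_high: int


def default_strata(n: int) -> tuple[int, int, int]:
    """Tertile sizes; remainder 1 goes to the middle, remainder 2 to the outer strata."""
    base, rem = divmod(n, 3)
    if rem == 0:
        return base, base, base
    if rem == 1:
        return base, base + 1, base
    return base + 1, base, base + 1


def conditioned_correlations(
    x1,
    x2,
    x3,
    n_low: int | None = None,
    n_mid: int | None = None,
    n_high: int | None = None,
    x1_id: str = "x1",
    x2_id: str = "x2",
    x3_id: str = "x3",
) -> ConditionedCorrelation:
    """Decompose a triplet into correlations over rank strata of X3."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    x3 = np.asarray(x3, dtype=float)
    n = x3.size
    if x1.size != n or x2.size != n:
        raise ValueError("vectors must have equal length")
    if n_low is None or n_mid is None or n_high is None:
        n_low, n_mid, n_high = default_strata(n)
    if n_low + n_mid + n_high != n:
        raise ValueError("stratum sizes must sum to n")
    if min(n_low, n_mid, n_high) < 3:
        raise ValueError("each stratum needs at least 3 samples")
    order = np.argsort(x3, kind="stable")
    strata = (order[:n_low], order[n_low : n_low + n_mid], order[n_low + n_mid :])
    corrs = []
    for idx in strata:
        rho = _pearson(x1[idx], x2[idx])
        if rho is None:
            log.warning("zero-variance stratum for (%s, %s | %s); correlation undefined", x1_id, x2_id, x3_id)
            rho = float("nan")
        corrs.append(rho)
    x3_sorted = x3[order]
    return ConditionedCorrelation(
        x3_id=x3_id,
        x1_id=x1_id,
        x2_id=x2_id,
        boundaries=(float(x3_sorted[n_low]), float(x3_sorted[n_low + n_mid - 1])),
        extremes=(float(x3_sorted[0]), float(x3_sorted[-1])),
        corr_low=corrs[0],
        corr_mid=corrs[1],
        corr_high=corrs[2],
        n_low=n_low,
        n_mid=n_mid,
        n_high=n_high,
    )


def brute_force_enumerate(candidates: list[str], gene_ids: list[str]) -> list[tuple[str, str, str]]:
    """Reference enumerator for toy sizes: every (X3; sorted pair) triplet."""
    out = []
    for x3 in candidates:
        others = [g for g in gene_ids if g != x3]
        for a, b in itertools.combinations(sorted(others), 2):
            out.append((x3, a, b))
    return out
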