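"""Candidate switching-gene selection via empirical-Bayes moderated t-tests.

A switching gene is required to be differentially expressed between the two
sample groups.  Each gene gets an ordinary two-group linear-model fit; the
residual variances are then shrunk toward a pooled prior estimated by
Smyth's closed-form method of moments on the log variances, which adds
``d0`` prior degrees of freedom to the ``n - 2`` residual ones.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, ndtr, polygamma

from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        step = tri * (1.0 - tri / y) / polygamma(2, x)
        x += step
        if -step / x < tol:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df_residual: float) -> tuple[float, float]:
    """Estimate prior df ``d0`` and prior variance ``s0^2`` from gene variances.

    Method of moments on ``log s_g^2`` (zero variances are excluded).
    Returns ``(inf, s0^2)`` when the log-variances are underdispersed
    relative to a chi-square with ``df_residual`` df, and ``(0, 0)`` when
    fewer than two positive variances are available (no moderation).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return 0.0, 0.0
    z = np.log(s2[ok])
    e = z - digamma(df_residual / 2.0) + np.log(df_residual / 2.0)
    e_mean = e.mean()
    e_var = np.sum((e - e_mean) ** 2) / (e.size - 1) - polygamma(1, df_residual / 2.0)
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(float(e_var))
        s02 = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        return d0, s02
    return float(np.inf), float(np.exp(e_mean))


def moderated_t_test(matrix: ExpressionMatrix, labels=None) -> pd.DataFrame:
    """Per-gene moderated two-group t-test with BH-adjusted p-values.

    ``labels`` defaults to ``matrix.groups``.  The two group levels are
    taken in sorted order; ``log_fold_change`` is mean(level2) - mean(level1)
    on the (log-scale) expression values.  Returns a frame indexed by gene
    id with columns ``mean_<level>``, ``log_fold_change``, ``s2``,
    ``t_moderated``, ``df_total``, ``p_value`` and ``q_value``; the fitted
    prior is stored in ``frame.attrs["d0"]`` / ``attrs["s02"]``.
    """
    if labels is None:
        labels = matrix.groups
    if labels is None:
        raise ValueError("no group labels supplied")
    labels = pd.Series(labels)
    if labels.index.equals(pd.RangeIndex(len(labels))):
        labels.index = matrix.data.columns
    labels = labels.reindex(matrix.data.columns)
    if labels.isna().any():
        raise ValueError("every sample needs a group label")
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError("exactly two group levels are required")
    mask2 = (labels == levels[1]).to_numpy()
    a = matrix.values[:, ~mask2]
    b = matrix.values[:, mask2]
    n1, n2 = a.shape[1], b.shape[1]
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 samples")

    mean1 = a.mean(axis=1)
    mean2 = b.mean(axis=1)
    lfc = mean2 - mean1
    df_res = n1 + n2 - 2
    ss = ((a - mean1[:, None]) ** 2).sum(axis=1) + ((b - mean2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_res
    if np.all(s2 == 0):
        raise ValueError("zero residual variance for every gene")

    d0, s02 = fit_variance_prior(s2, df_res)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
    else:
        s2_post = (d0 * s02 + df_res * s2) / (d0 + df_res)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), np.where(lfc == 0, 0.0, np.inf) * np.sign(lfc))
    df_total = d0 + df_res
    if np.isinf(df_total):
        p = 2.0 * ndtr(-np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = benjamini_hochberg(p)

    out = pd.DataFrame(
        {
            f"mean_{levels[0]}": mean1,
            f"mean_{levels[1]}": mean2,
            "log_fold_change": lfc,
            "s2": s2,
            "t_moderated": t,
            "df_total": df_total,
            "p_value": p,
            "q_value": q,
        },
        index=matrix.data.index.rename("gene_id"),
    )
    out.attrs["d0"] = d0
    out.attrs["s02"] = s02
    out.attrs["levels"] = levels
    return out


def benjamini_hochberg(p, m_total: int | None = None) -> np.ndarray:
    """Step-up BH adjustment: q_(i) = min_{j>=i}(p_(j) * m / j), clipped to 1.

    ``m_total`` lets the correction count more tests than supplied (used
    when only a top-K slice of a larger scan is retained, and the smallest
    p-values are guaranteed to be in that slice).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = int(m_total) if m_total is not None else p.size
    if m < p.size:
        raise ValueError("m_total cannot be smaller than the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def select_switching_candidates(results: pd.DataFrame, fdr: float = 0.05) -> list[str]:
    """Gene ids with q < fdr, sorted by ascending p-value."""
    if results.empty:
        raise ValueError("empty DE results")
    hits = results.loc[results["q_value"] < fdr]
    hits = hits.sort_values(["p_value", "q_value"], kind="stable")
    return [str(g) for g in hits.index]
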