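"""Probe collapsing and the two transforms required before liquid association.

Liquid-association statistics assume each gene's expression has been
(1) replaced by standard-normal quantiles of its ranks and (2) standardized
to zero mean and unit sample standard deviation.  The rank plotting
position is ``r / (n + 1)``: at n = 30 this puts the boundary between the
middle and top tertile at Phi^-1(20/31) = 0.372 and the largest value at
Phi^-1(30/31) = 1.849.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)


def collapse_duplicate_probes(
    matrix: ExpressionMatrix, probe_to_gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Keep, for each gene, the probe with the largest interquartile range.

    Quartiles use linear interpolation.  IQR ties are broken by the
    lexicographically smallest probe id.  Probes absent from the mapping are
    dropped with a logged count; an empty mapping or a fully unmapped matrix
    is an error.  Output rows are verbatim input rows, one per gene, sorted
    by gene id.
    """
    if not probe_to_gene:
        raise ValueError("probe-to-gene mapping is empty")
    if matrix.data.index.has_duplicates:
        raise ValueError("probe ids must be unique")
    probes = [str(p) for p in matrix.data.index]
    mapped = [p for p in probes if p in probe_to_gene]
    n_unmapped = len(probes) - len(mapped)
    if n_unmapped:
        log.info("dropping %d probes with no gene mapping", n_unmapped)
    if not mapped:
        raise ValueError("no probe maps to a gene")
    sub = matrix.data.loc[mapped]
    vals = sub.to_numpy()
    q75 = np.percentile(vals, 75, axis=1)  # linear interpolation
    q25 = np.percentile(vals, 25, axis=1)
    choice = pd.DataFrame(
        {
            "probe": mapped,
            "gene": [probe_to_gene[p] for p in mapped],
            "iqr": q75 - q25,
        }
    )
    choice = choice.sort_values(["gene", "iqr", "probe"], ascending=[True, False, True])
    winners = choice.drop_duplicates("gene", keep="first")
    collapsed = sub.loc[winners["probe"]].copy()
    collapsed.index = pd.Index(winners["gene"].to_numpy(), name="gene_id")
    collapsed = collapsed.sort_index()
    return ExpressionMatrix(collapsed, matrix.groups)


def normal_quantile_transform(x) -> np.ndarray:
    """Map a vector to standard-normal quantiles of its ranks.

    ``out_i = Phi^-1(r_i / (n + 1))`` with average ranks on ties.  Depends
    on the input only through its ranks, so any strictly increasing
    transform of ``x`` yields identical output.  A constant vector has all
    ranks tied and is rejected.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant vector cannot be quantile-transformed")
    ranks = rankdata(x, method="average")
    return ndtri(ranks / (n + 1))


def standardize(x) -> np.ndarray:
    """Center to zero mean and scale to unit sample SD (n-1 denominator)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if not sd > 0:
        raise ValueError("zero-variance vector cannot be standardized")
    return (x - x.mean()) / sd


def transform_matrix(matrix: ExpressionMatrix, standardize_rows: bool = True) -> ExpressionMatrix:
    """Apply quantile transform, then (optionally) standardization, per gene row.

    Constant rows are non-transformable and dropped with a logged count.
    ``standardize_rows=False`` stops after the quantile transform, leaving
    values on the standard-normal quantile scale (the scale on which the
    tertile boundaries print as +-0.37 and the extremes as +-1.85 at n=30;
    at finite n the sample SD of those quantiles is slightly below 1, so
    full standardization stretches them).
    """
    vals = matrix.values
    n = vals.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    keep = np.ptp(vals, axis=1) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("dropping %d constant rows before transformation", n_dropped)
    if not keep.any():
        raise ValueError("no transformable rows")
    vals = vals[keep]
    ranks = rankdata(vals, axis=1, method="average")
    t = ndtri(ranks / (n + 1))
    if standardize_rows:
        t = (t - t.mean(axis=1, keepdims=True)) / t.std(axis=1, ddof=1, keepdims=True)
    out = pd.DataFrame(t, index=matrix.data.index[keep], columns=matrix.data.columns)
    return ExpressionMatrix(out, matrix.groups)
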