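"""Gene-by-sample expression container and plain-text I/O.

The on-disk format is a TSV with the first column holding probe/gene
identifiers and the header row holding sample identifiers.  Group labels
travel in a separate two-column TSV (sample id, group).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Expression values for probes/genes (rows) across samples (columns).

    Parameters
    ----------
    data
        Real-valued frame, rows indexed by probe or gene id, columns by
        sample id.  Rows containing missing values are dropped on
        construction (with a logged count).  Duplicate row ids are allowed
        before probe collapsing.
    groups
        Optional two-level sample grouping (e.g. wild type vs transgenic),
        indexed by sample id.  When present it must cover every sample.
    """

    data: pd.DataFrame
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame")
        incomplete = self.data.isna().any(axis=1)
        if incomplete.any():
            log.warning("dropping %d rows with missing values", int(incomplete.sum()))
            self.data = self.data.loc[~incomplete]
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("expression matrix has no complete rows/samples")
        self.data = self.data.astype(float)
        if self.groups is not None:
            groups = pd.Series(self.groups)
            groups = groups.reindex(self.data.columns)
            if groups.isna().any():
                raise ValueError("every sample needs a group label")
            if groups.nunique() != 2:
                raise ValueError("group labels must have exactly two levels")
            self.groups = groups

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def row(self, gene_id: str) -> np.ndarray:
        """Expression vector of a single gene (error on duplicated ids)."""
        sel = self.data.loc[gene_id]
        if isinstance(sel, pd.DataFrame):
            raise ValueError(f"gene id {gene_id!r} is duplicated; collapse probes first")
        return sel.to_numpy()

    def subset(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids)].copy(), self.groups)

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.10g")

    def write_labels(self, path: str | Path) -> None:
        if self.groups is None:
            raise ValueError("matrix carries no group labels")
        lab = self.groups.rename("group").rename_axis("sample_id")
        lab.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, labels_path: str | Path | None = None) -> "ExpressionMatrix":
        data = pd.read_csv(path, sep="\t", index_col=0)
        data.index = data.index.astype(str)
        groups = read_labels_tsv(labels_path) if labels_path is not None else None
        return cls(data, groups)


def read_labels_tsv(path: str | Path) -> pd.Series:
    """Read a two-column (sample id, group) TSV into a Series."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.shape[1] != 1:
        raise ValueError("labels file must have exactly two columns")
    return frame.iloc[:, 0].astype(str)


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (probe id, gene id) TSV into a dict."""
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if frame.shape[1] < 2:
        raise ValueError("probe map must have two columns (probe, gene)")
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))
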