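"""Synthetic expression data with planted switching triplets.

Emulates the statistical structure of a two-group (wild type vs
transgenic) microarray study with ~30 samples split 15/15: a small set of
differentially expressed genes, and planted triplets in which the
conditional correlation of a gene pair flips sign with the level of a
switching gene X3.  The modulation law is

    rho(z) = rho_max * tanh(gamma * z)

with z the observed X3 value; the pair (X1, X2) given z is bivariate
normal with unit variances and correlation rho(z), sampled exactly via the
2x2 Cholesky factor.  Planted X3 genes always receive the group-mean shift
so the differential-expression filter can find them.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

GROUP1, GROUP2 = "WT", "TG"


@dataclass
class SyntheticConfig:
    """Generative parameters; defaults mirror the emulated study design."""

    n_genes: int = 1000
    n_samples: int = 30
    n_group1: int = 15
    n_planted_triplets: int = 5
    n_de_genes: int = 20
    de_shift: float = 1.5          # group-2 mean shift, in SD units
    modulation_strength: float = 5.0   # gamma
    max_abs_corr: float = 0.9      # rho_max in [0, 1)
    noise_sd: float = 1.0          # SD of background genes
    shared_x3: bool = False        # all planted triplets share one X3
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.max_abs_corr < 1:
            raise ValueError("max_abs_corr must lie in [0, 1)")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if self.modulation_strength < 0:
            raise ValueError("modulation_strength must be >= 0")
        if not 2 <= self.n_group1 <= self.n_samples - 2:
            raise ValueError("need at least 2 samples per group")
        n_x3 = self.n_x3
        if self.n_de_genes < n_x3:
            raise ValueError("every planted X3 must be a DE gene: n_de_genes too small")
        if self.n_structured_genes > self.n_genes:
            raise ValueError("n_genes too small for the requested planted structure")

    @property
    def n_x3(self) -> int:
        if self.n_planted_triplets == 0:
            return 0
        return 1 if self.shared_x3 else self.n_planted_triplets

    @property
    def n_structured_genes(self) -> int:
        return self.n_x3 + 2 * self.n_planted_triplets + (self.n_de_genes - self.n_x3)


@dataclass
class PlantedTriplet:
    x3_id: str
    x1_id: str
    x2_id: str
    gamma: float
    rho_max: float


@dataclass
class SyntheticTruth:
    """Planted structure for recovery scoring, plus the generating config."""

    planted_triplets: list[PlantedTriplet]
    de_genes: list[tuple[str, float]]
    config: SyntheticConfig = field(repr=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_triplets": [asdict(t) for t in self.planted_triplets],
            "de_genes": [[g, s] for g, s in self.de_genes],
            "config": asdict(self.config),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_triplets=[PlantedTriplet(**t) for t in payload["planted_triplets"]],
            de_genes=[(g, float(s)) for g, s in payload["de_genes"]],
            config=SyntheticConfig(**payload["config"]),
        )


def generate_switching_dataset(config: SyntheticConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw one dataset under the planted-triplet generative law.

    Deterministic given ``config.seed`` (byte-identical output).  Row order
    is switching genes, pair genes, extra DE genes, background genes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    group2 = np.zeros(n, dtype=bool)
    group2[config.n_group1:] = True
    sample_ids = [f"S{i + 1:02d}" for i in range(n)]
    groups = pd.Series(np.where(group2, GROUP2, GROUP1), index=sample_ids)

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    planted: list[PlantedTriplet] = []
    de_genes: list[tuple[str, float]] = []

    # switching genes (standard normal + shift in group 2; always DE)
    x3_ids = [f"SW{k + 1:02d}" for k in range(config.n_x3)]
    x3_values: dict[str, np.ndarray] = {}
    for gid in x3_ids:
        z = rng.standard_normal(n)
        z[group2] += config.de_shift
        x3_values[gid] = z
        gene_ids.append(gid)
        rows.append(z)
        de_genes.append((gid, config.de_shift))

    # switched pairs: conditional bivariate normal with rho(z)
    for k in range(config.n_planted_triplets):
        x3_id = x3_ids[0] if config.shared_x3 else x3_ids[k]
        z = x3_values[x3_id]
        rho = config.max_abs_corr * np.tanh(config.modulation_strength * z)
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        x1 = a
        x2 = rho * a + np.sqrt(1.0 - rho**2) * b  # per-sample Cholesky
        x1_id, x2_id = f"PA{k + 1:02d}", f"PB{k + 1:02d}"
        gene_ids += [x1_id, x2_id]
        rows += [x1, x2]
        planted.append(
            PlantedTriplet(x3_id, x1_id, x2_id, config.modulation_strength, config.max_abs_corr)
        )

    # extra DE genes beyond the planted switching genes
    for k in range(config.n_de_genes - config.n_x3):
        z = rng.standard_normal(n)
        z[group2] += config.de_shift
        gid = f"DE{k + 1:02d}"
        gene_ids.append(gid)
        rows.append(z)
        de_genes.append((gid, config.de_shift))

    # independent background noise
    n_bg = config.n_genes - len(gene_ids)
    bg = rng.standard_normal((n_bg, n)) * config.noise_sd
    gene_ids += [f"BG{k + 1:04d}" for k in range(n_bg)]
    rows += list(bg)

    data = pd.DataFrame(np.vstack(rows), index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    matrix = ExpressionMatrix(data, groups)
    truth = SyntheticTruth(planted, de_genes, config)
    return matrix, truth


def generate_null_dataset(n_samples: int, n_genes: int, seed: int = 0) -> ExpressionMatrix:
    """All genes mutually independent standard normal; no group structure."""
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    if n_genes < 1:
        raise ValueError("need at least 1 gene")
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        rng.standard_normal((n_genes, n_samples)),
        index=pd.Index([f"G{k + 1:04d}" for k in range(n_genes)], name="gene_id"),
        columns=[f"S{i + 1:02d}" for i in range(n_samples)],
    )
    return ExpressionMatrix(data)
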