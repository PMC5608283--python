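"""End-to-end orchestration: preprocess -> DE -> scan -> condition -> enrich -> GRN -> trace.

Every stage is also callable standalone through the library; the pipeline
adds file plumbing, stage toggles and a JSON manifest recording parameters,
seeds and row counts.  Re-running an identical configuration reproduces
identical outputs (the manifest carries no timestamps).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .de import moderated_t_test, select_switching_candidates
from .enrichment import GeneSetAnnotation, group_term_overlap, hypergeometric_enrichment, random_subset_control
from .grn import aracne_network, trace_triplets_in_grn
from .matrix import ExpressionMatrix, read_probe_map
from .preprocess import collapse_duplicate_probes, transform_matrix
from .scan import conditioned_correlations, scan_triplets, triplet_network

log = logging.getLogger(__name__)

ALL_STAGES = ("preprocess", "de", "scan", "condition", "enrich", "grn", "trace")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    matrix: str
    labels: str | None = None
    probe_map: str | None = None
    gmt: str | None = None
    out_dir: str = "tripla_out"
    stages: tuple[str, ...] = ALL_STAGES
    # stage parameters
    de_fdr: float = 0.05
    n_bins: int = 3
    top_k: int = 300000
    scan_fdr: float = 0.05
    n_pilot: int = 200
    correct_full: bool = False
    enrich_p_max: float = 0.05
    enrich_fdr_max: float = 0.1
    control_subset_size: int = 35
    control_reps: int = 30
    grn_alpha: float = 1e-4
    dpi_tolerance: float = 0.15
    grn_n_perm: int | None = None
    max_path_len: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_fdr", "scan_fdr", "enrich_p_max", "enrich_fdr_max", "grn_alpha"):
            value = getattr(self, name)
            if not 0 < value < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(self.stages)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in payload:
            payload["stages"] = tuple(payload["stages"])
        return cls(**payload)


def _write(frame: pd.DataFrame, path: Path, **kwargs) -> int:
    frame.to_csv(path, sep="\t", float_format="%.6g", **kwargs)
    return len(frame)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order and return the output manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "stages": {},
    }

    def record(stage: str, outputs: dict[str, int], **extra) -> None:
        manifest["stages"][stage] = {"outputs": outputs, **extra}

    matrix = ExpressionMatrix.from_tsv(config.matrix, config.labels)
    transformed = None
    de_table = None
    candidates: list[str] = []
    scan = None

    # ---- preprocess ----------------------------------------------------
    if "preprocess" in config.stages:
        try:
            if config.probe_map:
                matrix = collapse_duplicate_probes(matrix, read_probe_map(config.probe_map))
            transformed = transform_matrix(matrix)
            transformed.to_tsv(out / "transformed.tsv")
            record(
                "preprocess",
                {"transformed.tsv": transformed.n_genes},
                n_genes=matrix.n_genes,
                n_samples=matrix.n_samples,
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"preprocess: {exc}") from exc

    # ---- differential expression --------------------------------------
    if "de" in config.stages:
        try:
            de_table = moderated_t_test(matrix)
            candidates = select_switching_candidates(de_table, fdr=config.de_fdr)
            n_rows = _write(de_table, out / "de_results.tsv", index=True)
            (out / "candidates.txt").write_text("\n".join(candidates) + "\n")
            record(
                "de",
                {"de_results.tsv": n_rows, "candidates.txt": len(candidates)},
                fdr=config.de_fdr,
                n_candidates=len(candidates),
            )
            log.info("selected %d candidate switching genes at FDR < %g", len(candidates), config.de_fdr)
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"de: {exc}") from exc

    # ---- triplet scan --------------------------------------------------
    if "scan" in config.stages:
        try:
            if transformed is None:
                transformed = transform_matrix(matrix)
            if not candidates:
                raise ValueError("no candidate switching genes (run the 'de' stage or lower de_fdr)")
            scan = scan_triplets(
                transformed,
                candidates,
                n_bins=config.n_bins,
                top_k=config.top_k,
                fdr=config.scan_fdr,
                seed=config.seed,
                n_pilot=config.n_pilot,
                correct_full=config.correct_full,
            )
            n_rows = _write(scan.triplets, out / "triplets.tsv")
            outputs = {"triplets.tsv": n_rows}
            if scan.summary["n_significant"]:
                graph, counts = triplet_network(scan)
                edges = pd.DataFrame(
                    [(u, v, d.get("kind", "")) for u, v, d in graph.edges(data=True)],
                    columns=["source", "target", "kind"],
                )
                outputs["triplet_edges.tsv"] = _write(edges, out / "triplet_edges.tsv")
                outputs["x3_counts.tsv"] = _write(counts, out / "x3_counts.tsv")
            record("scan", outputs, **scan.summary)
            log.info("scan: %(n_significant)d significant of %(n_enumerated)d triplets", scan.summary)
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"scan: {exc}") from exc

    # ---- tertile-conditioned correlations ------------------------------
    if "condition" in config.stages and scan is not None:
        try:
            # quantile scale (no standardization): boundaries print as +-0.37 at n = 30
            quantile = transform_matrix(matrix, standardize_rows=False)
            rows = []
            for row in scan.significant.itertuples(index=False):
                cc = conditioned_correlations(
                    quantile.row(row.x1),
                    quantile.row(row.x2),
                    quantile.row(row.x3),
                    x1_id=row.x1,
                    x2_id=row.x2,
                    x3_id=row.x3,
                )
                rows.append(
                    {
                        "x3": cc.x3_id,
                        "x1": cc.x1_id,
                        "x2": cc.x2_id,
                        "boundary_low": cc.boundaries[0],
                        "boundary_high": cc.boundaries[1],
                        "corr_low": cc.corr_low,
                        "corr_mid": cc.corr_mid,
                        "corr_high": cc.corr_high,
                    }
                )
            frame = pd.DataFrame(
                rows,
                columns=["x3", "x1", "x2", "boundary_low", "boundary_high", "corr_low", "corr_mid", "corr_high"],
            )
            record("condition", {"conditioned.tsv": _write(frame, out / "conditioned.tsv")})
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"condition: {exc}") from exc

    # ---- enrichment ----------------------------------------------------
    if "enrich" in config.stages:
        if config.gmt is None:
            record("enrich", {}, skipped="no GMT annotation supplied")
        else:
            try:
                annotation = GeneSetAnnotation.from_gmt(config.gmt).restrict_universe(matrix.gene_ids)
                sig = scan.significant if scan is not None else pd.DataFrame(columns=["x3", "x1", "x2"])
                group1 = sorted(set(sig["x3"]))
                group2 = sorted(set(sig["x3"]) | set(sig["x1"]) | set(sig["x2"]))
                rows1 = hypergeometric_enrichment(group1, annotation, config.enrich_p_max, config.enrich_fdr_max)
                rows2 = hypergeometric_enrichment(group2, annotation, config.enrich_p_max, config.enrich_fdr_max)
                common = sorted(group_term_overlap(rows1, rows2))
                counts = random_subset_control(
                    group2,
                    annotation,
                    reference_terms=set(rows2["term_id"]),
                    subset_size=min(config.control_subset_size, len(group2)),
                    n_reps=config.control_reps,
                    seed=config.seed,
                    p_max=config.enrich_p_max,
                    fdr_max=config.enrich_fdr_max,
                )
                outputs = {
                    "enrichment_x3.tsv": _write(rows1, out / "enrichment_x3.tsv"),
                    "enrichment_all.tsv": _write(rows2, out / "enrichment_all.tsv"),
                }
                (out / "enrichment_common_terms.txt").write_text("\n".join(common) + "\n")
                (out / "random_control_counts.json").write_text(json.dumps(counts.tolist()))
                record(
                    "enrich",
                    outputs,
                    n_common_terms=len(common),
                    control_median_overlap=float(pd.Series(counts).median()),
                )
            except Exception as exc:  # noqa: BLE001
                raise StageError(f"enrich: {exc}") from exc

    # ---- regulatory network -------------------------------------------
    network = None
    if "grn" in config.stages and scan is not None:
        try:
            sig = scan.significant
            hubs = [g for g in candidates if g in set(matrix.gene_ids)]
            targets = sorted((set(sig["x1"]) | set(sig["x2"]) | set(sig["x3"])) - set(hubs))
            network = aracne_network(
                matrix,
                hubs,
                alpha=config.grn_alpha,
                dpi_tolerance=config.dpi_tolerance,
                seed=config.seed,
                n_perm=config.grn_n_perm,
                targets=targets,
            )
            record(
                "grn",
                {"grn_edges.tsv": _write(network.edges, out / "grn_edges.tsv")},
                n_nodes=len(network.nodes),
                alpha=config.grn_alpha,
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"grn: {exc}") from exc

    # ---- triplet tracing ----------------------------------------------
    if "trace" in config.stages and network is not None and scan is not None:
        try:
            trace = trace_triplets_in_grn(network, scan, max_path_len=config.max_path_len)
            record(
                "trace",
                {"trace_paths.tsv": _write(trace.paths, out / "trace_paths.tsv")},
                max_path_len=config.max_path_len,
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"trace: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
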