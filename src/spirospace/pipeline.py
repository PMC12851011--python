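"""End-to-end orchestration: library → geometry → descriptors → prep → cluster → report.

A run is fully described by its :class:`RunConfig`; every stage output is
persisted under the run directory together with a manifest (config, registry
hash, output checksums), so re-running from the same config reproduces all
numeric outputs bit-for-bit on the same platform.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import components_for_variance, fit_pca, select_k
from .descriptors import DescriptorVector, compute_descriptor_vector, registry_hash
from .feature_prep import DescriptorMatrix, drop_constant_columns, prune_by_vif, standardize
from .geometry import embed_and_optimize
from .library import ScaffoldRecord, builtin_default_library, find_by_name, load_library
from .report import build_similarity_report

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """All knobs of one pipeline run; defaults match the documented conventions."""

    library_path: str | None = None  # None -> builtin default library
    seed: int = 2025
    n_starts: int = 10
    grid_spacing: float = 0.2
    vif_threshold_log10: float = 5.0
    n_components_distance: int = 3  # distance/report space
    variance_cutoff: float = 0.90  # cluster-fit dimensionality
    k_range: tuple[int, int] = (2, 10)
    reference: str = "piperidine"
    output_dir: str = "runs/latest"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: RunConfig
    records: list[ScaffoldRecord]
    vectors: dict[str, DescriptorVector]
    matrix: DescriptorMatrix  # standardized, VIF-pruned
    pca: object
    best_k: int
    cluster_model: object
    silhouette_curve: dict[int, float]
    report: object
    manifest: dict = field(default_factory=dict)


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage and persist matrices, models, reports and a manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # 1. library
    records = (
        load_library(config.library_path)
        if config.library_path
        else builtin_default_library()
    )

    # 2. geometry + 3. descriptors
    vectors: dict[str, DescriptorVector] = {}
    for rec in records:
        try:
            conf = embed_and_optimize(rec, n_starts=config.n_starts, seed=config.seed)
            vectors[rec.id] = compute_descriptor_vector(
                rec, conf, grid_spacing=config.grid_spacing
            )
        except Exception as exc:  # annotate which stage/input failed
            raise RuntimeError(f"stage geometry/descriptors failed for {rec.id!r}") from exc
    wide = pd.DataFrame({rid: v.values for rid, v in vectors.items()}).T
    wide.index.name = "scaffold_id"
    raw = DescriptorMatrix.from_dataframe(
        wide, provenance={"registry_hash": registry_hash()}
    )
    raw.to_csv(outdir / "descriptors_raw.csv")

    # 4. prep
    clean, dropped = drop_constant_columns(raw)
    std = standardize(clean)
    pruned, vif_report = prune_by_vif(std, config.vif_threshold_log10)
    pruned.to_csv(outdir / "descriptors_pruned.csv")
    (outdir / "vif_report.json").write_text(
        json.dumps(
            {
                "threshold_log10": vif_report.threshold,
                "removed": [[n, v] for n, v in vif_report.removal_order],
                "dropped_constant": dropped,
                "final_log10_vif": {
                    k: (None if np.isinf(v) else v) for k, v in vif_report.log10_vif.items()
                },
            },
            indent=2,
        )
    )

    # 5. cluster
    pca = fit_pca(pruned)
    n_fit = max(components_for_variance(pca, config.variance_cutoff),
                config.n_components_distance)
    best_k, model, curve = select_k(pca.scores[:, :n_fit], config.k_range)
    scores_df = pd.DataFrame(
        pca.scores,
        index=pruned.scaffold_ids,
        columns=[f"PC{i + 1}" for i in range(pca.scores.shape[1])],
    )
    scores_df.index.name = "scaffold_id"
    scores_df.to_csv(outdir / "pca_scores.csv", float_format="%.12g")
    (outdir / "cluster_model.json").write_text(
        json.dumps(
            {
                "k": best_k,
                "medoids": [pruned.scaffold_ids[i] for i in model.medoid_indices],
                "assignments": dict(zip(pruned.scaffold_ids, map(int, model.assignments))),
                "mean_silhouette": model.mean_silhouette,
                "silhouette_curve": {str(k): v for k, v in curve.items()},
                "total_cost": model.total_cost,
                "cluster_fit_components": n_fit,
            },
            indent=2,
        )
    )

    # 6. report
    reference = find_by_name(records, config.reference).id
    spiro_ids = [r.id for r in records if r.category == "spirohexane"]
    report = build_similarity_report(
        reference=reference,
        candidates=spiro_ids,
        scores=pca.scores,
        ids=pruned.scaffold_ids,
        model=model,
        vectors=vectors,
        n_components=config.n_components_distance,
    )
    report.pairwise.to_csv(outdir / "distance_matrix.csv", float_format="%.12g")
    report.intra_cluster.to_csv(outdir / "intra_cluster_stats.csv", float_format="%.12g")
    report.delta_values.to_csv(outdir / "delta_value_percent.csv", float_format="%.12g")
    report.ranking.to_csv(outdir / "bioisostere_ranking.csv", float_format="%.12g")

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "registry_hash": registry_hash(),
        "n_scaffolds": len(records),
        "reference_id": reference,
        "best_k": best_k,
        "outputs": {
            p.name: _sha256_file(p) for p in sorted(outdir.glob("*.csv"))
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return PipelineResult(
        config=config,
        records=records,
        vectors=vectors,
        matrix=pruned,
        pca=pca,
        best_k=best_k,
        cluster_model=model,
        silhouette_curve=curve,
        report=report,
        manifest=manifest,
    )


def run_from_manifest(manifest_path: str | Path) -> PipelineResult:
    """Re-execute a run from its persisted manifest (same config, fresh outputs)."""
    manifest = json.loads(Path(manifest_path).read_text())
    cfg = manifest["config"]
    cfg["k_range"] = tuple(cfg["k_range"])
    return run_pipeline(RunConfig(**cfg))
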