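"""Bioisostere scoring from the fitted chemical-space model.

A candidate replacement ring is judged by (i) how close it sits to the
reference ring in the leading principal-component space, relative to the
spread of each ring's own cluster, and (ii) how little its key 3D descriptors
(plane of best fit, volume, dipole, strain energy) change, expressed as
percentage differences (Δ Value %).  Distances use the first three principal
components by default; the component count is configurable and recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import ClusterModel
from .descriptors import DescriptorVector

__all__ = [
    "SimilarityReport",
    "ReportError",
    "intra_cluster_stats",
    "scaffold_distance",
    "delta_value_table",
    "rank_bioisosteres",
    "build_similarity_report",
]

DELTA_DESCRIPTORS = ("pbf", "volume", "dipole", "strain_energy")


class ReportError(ValueError):
    pass


@dataclass
class SimilarityReport:
    """Distance statistics, Δ-Value-% table and candidate ranking for one reference."""

    reference: str
    n_components: int
    intra_cluster: pd.DataFrame  # per scaffold: mean, sd, n_neighbors, cluster
    pairwise: pd.DataFrame  # scaffold x scaffold distances
    delta_values: pd.DataFrame  # descriptor x candidate, Δ%
    ranking: pd.DataFrame  # candidates sorted by distance to the reference
    notes: dict = field(default_factory=dict)


def _score_frame(scores: np.ndarray, ids: list[str], n_components: int) -> np.ndarray:
    scores = np.asarray(scores, float)
    if scores.shape[0] != len(ids):
        raise ReportError("scores row count does not match scaffold ids")
    if scores.shape[1] < n_components:
        raise ReportError(
            f"scores have {scores.shape[1]} components, need {n_components}"
        )
    return scores[:, :n_components]


def intra_cluster_stats(
    model: ClusterModel, scores: np.ndarray, ids: list[str], n_components: int = 3
) -> pd.DataFrame:
    """Per-scaffold mean ± sample-sd distance to the other members of its cluster.

    Singleton clusters have no within-cluster distances: flagged with NaN and
    ``n_neighbors = 0``.  A two-point cluster has a mean but no sd.
    """
    if len(model.assignments) != len(ids):
        raise ReportError("cluster model was fitted on a different scaffold order")
    s = _score_frame(scores, ids, n_components)
    rows = []
    for i, sid in enumerate(ids):
        mates = np.flatnonzero(model.assignments == model.assignments[i])
        mates = mates[mates != i]
        d = np.linalg.norm(s[mates] - s[i], axis=1)
        rows.append(
            {
                "scaffold_id": sid,
                "cluster": int(model.assignments[i]),
                "n_neighbors": len(mates),
                "mean_dist": float(d.mean()) if len(d) else np.nan,
                "sd_dist": float(d.std(ddof=1)) if len(d) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("scaffold_id")


def scaffold_distance(
    a: str, b: str, scores: np.ndarray, ids: list[str], n_components: int = 3
) -> float:
    """Euclidean distance between two scaffolds in the leading PCA components."""
    s = _score_frame(scores, ids, n_components)
    try:
        ia, ib = ids.index(a), ids.index(b)
    except ValueError as exc:
        raise ReportError(f"unknown scaffold id in ({a!r}, {b!r})") from exc
    return float(np.linalg.norm(s[ia] - s[ib]))


def pairwise_table(scores: np.ndarray, ids: list[str], n_components: int = 3) -> pd.DataFrame:
    s = _score_frame(scores, ids, n_components)
    d = np.linalg.norm(s[:, None, :] - s[None, :, :], axis=-1)
    return pd.DataFrame(d, index=ids, columns=ids)


def delta_value_table(
    reference: str,
    candidates: list[str],
    vectors: dict[str, DescriptorVector],
    descriptors: tuple[str, ...] = DELTA_DESCRIPTORS,
) -> pd.DataFrame:
    """Δ% = 100 · (candidate − reference) / |reference| per descriptor.

    The absolute reference in the denominator keeps the sign meaningful: a
    positive entry is an increase relative to the reference.  A zero reference
    value makes the percentage undefined; those cells are NaN.
    """
    if reference not in vectors:
        raise ReportError(f"reference {reference!r} has no descriptor vector")
    table = {}
    for cand in candidates:
        if cand not in vectors:
            raise ReportError(f"candidate {cand!r} has no descriptor vector")
        col = {}
        for desc in descriptors:
            if desc not in vectors[reference].values or desc not in vectors[cand].values:
                raise ReportError(f"descriptor {desc!r} missing")
            ref_v = vectors[reference][desc]
            col[desc] = (
                np.nan if ref_v == 0 else 100.0 * (vectors[cand][desc] - ref_v) / abs(ref_v)
            )
        table[cand] = col
    return pd.DataFrame(table).reindex(list(descriptors))


def rank_bioisosteres(
    reference: str,
    scores: np.ndarray,
    ids: list[str],
    model: ClusterModel,
    n_components: int = 3,
) -> pd.DataFrame:
    """All other scaffolds sorted by distance to the reference (ties: id order).

    Each candidate is annotated with cluster co-membership with the reference
    and its intra-cluster distance statistics.
    """
    if reference not in ids:
        raise ReportError(f"reference {reference!r} not in scores")
    s = _score_frame(scores, ids, n_components)
    stats = intra_cluster_stats(model, scores, ids, n_components)
    ref_idx = ids.index(reference)
    ref_cluster = int(model.assignments[ref_idx])
    rows = []
    for i, sid in enumerate(ids):
        if sid == reference:
            continue
        rows.append(
            {
                "scaffold_id": sid,
                "distance": float(np.linalg.norm(s[i] - s[ref_idx])),
                "same_cluster": int(model.assignments[i]) == ref_cluster,
                "cluster": int(model.assignments[i]),
                "intra_mean": stats.loc[sid, "mean_dist"],
                "intra_sd": stats.loc[sid, "sd_dist"],
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["distance", "scaffold_id"], kind="mergesort").set_index(
        "scaffold_id"
    )


def build_similarity_report(
    reference: str,
    candidates: list[str],
    scores: np.ndarray,
    ids: list[str],
    model: ClusterModel,
    vectors: dict[str, DescriptorVector] | None = None,
    n_components: int = 3,
) -> SimilarityReport:
    """Assemble the full similarity report for one reference scaffold."""
    return SimilarityReport(
        reference=reference,
        n_components=n_components,
        intra_cluster=intra_cluster_stats(model, scores, ids, n_components),
        pairwise=pairwise_table(scores, ids, n_components),
        delta_values=(
            delta_value_table(reference, candidates, vectors) if vectors else pd.DataFrame()
        ),
        ranking=rank_bioisosteres(reference, scores, ids, model, n_components),
        notes={"metric": "euclidean", "distance_components": n_components},
    )
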