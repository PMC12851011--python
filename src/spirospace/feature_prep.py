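"""Descriptor-matrix preparation: standardization and collinearity pruning.

Descriptors live on wildly different scales (Daltons, Å³, Debye, counts), so
the matrix is z-scored column-wise before any distance computation.  Strongly
multicollinear descriptors are then removed by the variance-inflation-factor
rule: a descriptor is dropped when log10(VIF) ≥ 5, i.e. when a regression of
it on the remaining descriptors reaches R² ≥ 1 − 10⁻⁵.  Removal is iterative —
worst offender first, VIFs recomputed after each removal — which keeps the
surviving set maximal and the procedure deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorMatrix",
    "VIFReport",
    "FeaturePrepError",
    "standardize",
    "drop_constant_columns",
    "compute_vif",
    "prune_by_vif",
]

_VIF_INF_TOL = 1e-14  # 1 - R² below this is treated as perfect collinearity


class FeaturePrepError(ValueError):
    pass


@dataclass
class DescriptorMatrix:
    """Scaffolds × descriptors numeric table with standardization state."""

    scaffold_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    standardized: bool = False
    provenance: dict = field(default_factory=dict)
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if len(self.scaffold_ids) != n or len(self.descriptor_names) != p:
            raise FeaturePrepError("shape mismatch between labels and values")
        if not np.all(np.isfinite(self.values)):
            raise FeaturePrepError("matrix contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.scaffold_ids, columns=self.descriptor_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "DescriptorMatrix":
        return cls(
            scaffold_ids=[str(i) for i in df.index],
            descriptor_names=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            **kwargs,
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="scaffold_id", float_format="%.12g")

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "DescriptorMatrix":
        return cls.from_dataframe(pd.read_csv(path, index_col="scaffold_id"), **kwargs)

    def select_columns(self, names: list[str]) -> "DescriptorMatrix":
        idx = [self.descriptor_names.index(n) for n in names]
        return replace(
            self,
            descriptor_names=list(names),
            values=self.values[:, idx],
            column_means=None if self.column_means is None else self.column_means[idx],
            column_sds=None if self.column_sds is None else self.column_sds[idx],
        )


@dataclass
class VIFReport:
    """Per-descriptor VIFs plus the iterative removal log."""

    vif: dict[str, float]
    log10_vif: dict[str, float]
    removal_order: list[tuple[str, float]] = field(default_factory=list)
    threshold: float = 5.0


def drop_constant_columns(m: DescriptorMatrix, tol: float = 1e-12) -> tuple[DescriptorMatrix, list[str]]:
    """Remove zero-variance columns (they carry no comparative information)."""
    sds = m.values.std(axis=0, ddof=1) if m.n > 1 else np.zeros(m.p)
    keep = [name for name, s in zip(m.descriptor_names, sds) if s > tol]
    dropped = [name for name in m.descriptor_names if name not in keep]
    out = m.select_columns(keep)
    if dropped:
        out.provenance = {**m.provenance, "dropped_constant": dropped}
    return out, dropped


def standardize(m: DescriptorMatrix) -> DescriptorMatrix:
    """Column-wise z-score using the sample standard deviation (divisor n−1)."""
    if m.n < 2:
        raise FeaturePrepError("standardization needs at least 2 rows")
    means = m.values.mean(axis=0)
    sds = m.values.std(axis=0, ddof=1)
    constant = [name for name, s in zip(m.descriptor_names, sds) if s <= 1e-12]
    if constant:
        raise FeaturePrepError(
            f"constant column(s) {constant}; drop them first (drop_constant_columns)"
        )
    z = (m.values - means) / sds
    return DescriptorMatrix(
        scaffold_ids=list(m.scaffold_ids),
        descriptor_names=list(m.descriptor_names),
        values=z,
        standardized=True,
        provenance={**m.provenance, "standardization": "zscore/sample-sd"},
        column_means=means,
        column_sds=sds,
    )


def _vif_one(x: np.ndarray, j: int) -> float:
    """VIF of column j regressed (with intercept) on all other columns."""
    y = x[:, j]
    others = np.delete(x, j, axis=1)
    design = np.column_stack([np.ones(len(y)), others])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sst = float(((y - y.mean()) ** 2).sum())
    if sst <= 0:
        return float("inf")
    one_minus_r2 = float((resid**2).sum()) / sst
    if one_minus_r2 < _VIF_INF_TOL:
        return float("inf")
    return 1.0 / one_minus_r2


def compute_vif(m: DescriptorMatrix) -> VIFReport:
    """Variance inflation factors for every column of a standardized matrix.

    Rank-deficient designs are handled by the least-squares pseudoinverse;
    perfect collinearity is reported as VIF = +inf (log10 = +inf).
    """
    if not m.standardized:
        raise FeaturePrepError("compute_vif expects a standardized matrix")
    if m.p < 2:
        raise FeaturePrepError("VIF needs at least 2 columns")
    vifs = {name: _vif_one(m.values, j) for j, name in enumerate(m.descriptor_names)}
    log10 = {k: (float("inf") if np.isinf(v) else float(np.log10(v))) for k, v in vifs.items()}
    return VIFReport(vif=vifs, log10_vif=log10)


def prune_by_vif(
    m: DescriptorMatrix, threshold_log10: float = 5.0
) -> tuple[DescriptorMatrix, VIFReport]:
    """Iteratively remove the worst-VIF descriptor while any log10(VIF) ≥ threshold.

    Ties (e.g. several infinite VIFs) are broken toward the larger VIF, then the
    alphabetically first descriptor name, so pruning is deterministic.
    """
    if not m.standardized:
        raise FeaturePrepError("prune_by_vif expects a standardized matrix")
    current = m
    removal_order: list[tuple[str, float]] = []
    while current.p >= 2:
        report = compute_vif(current)
        name, lv = min(report.log10_vif.items(), key=lambda kv: (-kv[1], kv[0]))
        if lv < threshold_log10:
            break
        removal_order.append((name, lv))
        survivors = [c for c in current.descriptor_names if c != name]
        if not survivors:
            break
        current = current.select_columns(survivors)
    # a lone survivor has VIF = 1 (log10 = 0); if even that breaches the
    # threshold, the rule would empty the matrix
    if current.p == 1 and 0.0 >= threshold_log10:
        raise FeaturePrepError("VIF pruning removed every descriptor (threshold too strict)")
    final = compute_vif(current) if current.p >= 2 else VIFReport(
        vif={current.descriptor_names[0]: 1.0},
        log10_vif={current.descriptor_names[0]: 0.0},
    )
    final.removal_order = removal_order
    final.threshold = threshold_log10
    current.provenance = {
        **current.provenance,
        "vif_pruned": [name for name, _ in removal_order],
        "vif_threshold_log10": threshold_log10,
    }
    return current, final
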