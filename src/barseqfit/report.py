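"""Downstream reporting: OD calibration, tolerance calls, clustering,
cross-batch correlation.

The OD600 calibration is the log-log line log10(cells) = a*log10(abs) + b
with the assay's fitted coefficients a = 1.011, b = 7.489 as defaults.
Tolerance calls follow the replicated-contrast rule: a strain is tolerant
(sensitive) in a condition group when it shows a significant positive
(negative) log2 fold-change in at least ``min_support`` of the group's
contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy


@dataclass(frozen=True)
class CalibrationModel:
    """log10(cell number) = slope * log10(absorbance) + intercept."""

    slope: float = 1.011
    intercept: float = 7.489

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("calibration slope must be positive")


def od_to_cells(absorbance: float, model: CalibrationModel | None = None) -> float:
    """Estimated cell number from OD600 via the log-log calibration line."""
    if model is None:
        model = CalibrationModel()
    absorbance = np.asarray(absorbance, dtype=float)
    if np.any(absorbance <= 0):
        raise ValueError("absorbance must be positive")
    out = 10.0 ** (model.slope * np.log10(absorbance) + model.intercept)
    return float(out) if out.ndim == 0 else out


def fit_calibration(
    absorbance: np.ndarray, cell_counts: np.ndarray
) -> CalibrationModel:
    """Least-squares fit of the log-log OD-to-cells line.

    Ordinary least squares on (log10 abs, log10 cells); two distinct points
    give the exact interpolating line.
    """
    x = np.log10(np.asarray(absorbance, dtype=float))
    y = np.log10(np.asarray(cell_counts, dtype=float))
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need at least 2 (absorbance, cells) pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("absorbance and cell counts must be positive and finite")
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate calibration: no variance in absorbance")
    slope, intercept = np.polyfit(x, y, 1)
    return CalibrationModel(slope=float(slope), intercept=float(intercept))


def classify_tolerance(
    results: pd.DataFrame,
    contrast_group: list[str],
    min_support: int = 2,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Tolerance calls from replicated contrasts of one condition group.

    ``results`` is the tidy fitness table (strain_id, contrast, logFC, FDR).
    A strain is ``tolerant`` when >= min_support of the group's contrasts
    are significant (FDR < fdr) with logFC > 0, ``sensitive`` likewise with
    logFC < 0, and ``unclassified`` otherwise (including mixed-sign
    significance).  Contrasts missing a strain are ignored for it without
    lowering the support requirement.  Reports mean +- SD of the group's
    logFCs per strain.
    """
    if not contrast_group:
        raise ValueError("contrast_group must be non-empty")
    if min_support > len(contrast_group):
        raise ValueError("min_support exceeds the number of contrasts in the group")
    sub = results[results["contrast"].isin(contrast_group)]
    if sub.empty:
        raise ValueError(f"none of the contrasts {contrast_group} appear in results")
    rows = []
    for sid, g in sub.groupby("strain_id"):
        sig = g[(g["FDR"] < fdr) & g["FDR"].notna()]
        n_pos = int((sig["logFC"] > 0).sum())
        n_neg = int((sig["logFC"] < 0).sum())
        if n_pos >= min_support and n_neg == 0:
            label = "tolerant"
            support = n_pos
        elif n_neg >= min_support and n_pos == 0:
            label = "sensitive"
            support = n_neg
        else:
            label = "unclassified"
            support = 0
        lfc = g["logFC"].astype(float)
        rows.append(
            (
                sid,
                label,
                support,
                float(lfc.mean()),
                float(lfc.std(ddof=1)) if len(lfc) > 1 else np.nan,
            )
        )
    return pd.DataFrame(
        rows, columns=["strain_id", "label", "support", "mean_logFC", "sd_logFC"]
    ).set_index("strain_id")


@dataclass
class ClusterResult:
    """Two-way hierarchical clustering of the fitness matrix."""

    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[str]
    col_order: list[str]
    imputed: int

    def reordered(self, matrix: pd.DataFrame) -> pd.DataFrame:
        return matrix.loc[self.row_order, self.col_order]


def cluster_fitness(
    fitness_matrix: pd.DataFrame, impute_missing: bool = True
) -> ClusterResult:
    """Ward (ward.D2 convention) / Euclidean clustering on both axes.

    Missing values are imputed with 0 (neutral fitness) when
    ``impute_missing``; otherwise any NaN fails.  Deterministic: scipy's
    nearest-neighbor-chain agglomeration with its documented tie-break.
    """
    m = fitness_matrix.astype(float)
    if m.shape[0] < 2:
        raise ValueError("need at least 2 strains to cluster")
    n_missing = int(m.isna().to_numpy().sum())
    if n_missing:
        if not impute_missing:
            raise ValueError(f"{n_missing} missing values in fitness matrix")
        m = m.fillna(0.0)
    row_link = hierarchy.linkage(m.to_numpy(), method="ward", metric="euclidean")
    row_order = [m.index[i] for i in hierarchy.leaves_list(row_link)]
    if m.shape[1] >= 2:
        col_link = hierarchy.linkage(m.to_numpy().T, method="ward", metric="euclidean")
        col_order = [m.columns[i] for i in hierarchy.leaves_list(col_link)]
    else:
        col_link = np.empty((0, 4))
        col_order = list(m.columns)
    return ClusterResult(row_link, col_link, row_order, col_order, n_missing)


def cross_batch_correlation(
    reference_fitness_by_batch: dict[str, pd.Series],
    min_shared: int = 3,
) -> pd.DataFrame:
    """Pairwise Spearman correlation of reference fitness across batches.

    Strains are intersected per batch pair; pairs sharing fewer than
    ``min_shared`` strains give NaN with a warning.  The diagonal is 1.
    """
    batches = list(reference_fitness_by_batch)
    if len(batches) < 2:
        raise ValueError("need at least 2 batches")
    out = pd.DataFrame(np.eye(len(batches)), index=batches, columns=batches)
    for a, b in combinations(batches, 2):
        sa, sb = reference_fitness_by_batch[a], reference_fitness_by_batch[b]
        shared = sa.dropna().index.intersection(sb.dropna().index)
        if len(shared) < min_shared:
            import warnings

            warnings.warn(
                f"batches {a!r} and {b!r} share only {len(shared)} strains; rho = NA"
            )
            rho = np.nan
        else:
            rho = stats.spearmanr(sa[shared], sb[shared]).statistic
        out.loc[a, b] = out.loc[b, a] = rho
    return out
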