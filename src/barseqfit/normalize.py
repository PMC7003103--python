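"""Count filtering and RLE (median-of-ratios) normalization.

Samples with fewer than 15 assigned reads and strains with fewer than 3
reads carry little information and are dropped before normalization.  Size
factors follow the relative-log-expression (median-of-ratios) method: the
per-strain geometric mean across samples is the reference, and each
sample's factor is the median of its count-to-reference ratios over strains
with no zero counts.

Factors are reported raw (not rescaled to geometric mean 1); the GLM uses
offsets where any global rescaling cancels in every contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counting import CountMatrix


@dataclass
class FilterResult:
    matrix: CountMatrix
    dropped_samples: list[str]
    dropped_strains: list[str]


def filter_counts(
    matrix: CountMatrix,
    min_sample_reads: int = 15,
    min_strain_reads: int = 3,
) -> FilterResult:
    """Drop low-information samples, then strains.

    A sample is dropped when its total assigned reads are below
    ``min_sample_reads``; a strain is then dropped when its total across the
    remaining samples is below ``min_strain_reads``.
    """
    if min_sample_reads < 0 or min_strain_reads < 0:
        raise ValueError("thresholds must be >= 0")
    totals = matrix.library_sizes()
    keep_samples = totals[totals >= min_sample_reads].index
    dropped_samples = [s for s in matrix.samples if s not in set(keep_samples)]
    if len(keep_samples) == 0:
        raise ValueError(
            f"all {len(matrix.samples)} samples fall below "
            f"{min_sample_reads} assigned reads (max total "
            f"{int(totals.max()) if len(totals) else 0})"
        )
    sub = matrix.counts[keep_samples]
    strain_totals = sub.sum(axis=1)
    keep_strains = strain_totals[strain_totals >= min_strain_reads].index
    dropped_strains = [s for s in matrix.strains if s not in set(keep_strains)]
    out = CountMatrix(
        sub.loc[keep_strains],
        unassigned=matrix.unassigned[keep_samples],
        ambiguous=matrix.ambiguous[keep_samples],
    )
    return FilterResult(out, dropped_samples, dropped_strains)


def rle_size_factors(
    matrix: CountMatrix | pd.DataFrame, pseudo_reference: bool = False
) -> pd.Series:
    """Median-of-ratios size factor per sample.

    The reference for strain i is the geometric mean of its counts across
    samples; c_j is the median over all-nonzero strains of count_ij / ref_i.
    With ``pseudo_reference=True`` the geometric mean and the median are
    taken over positive counts only, for matrices where every strain has
    at least one zero.
    """
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    arr = counts.to_numpy(dtype=float)
    if arr.size == 0:
        raise ValueError("empty count matrix")
    nonzero_rows = (arr > 0).all(axis=1)
    if not nonzero_rows.any() and not pseudo_reference:
        raise ValueError(
            "no strain has nonzero counts in every sample; re-run with "
            "pseudo_reference=True to use a positive-counts-only reference"
        )
    if pseudo_reference:
        logs = np.full(arr.shape, np.nan)
        np.log(arr, out=logs, where=arr > 0)
        ref = np.exp(np.nanmean(logs, axis=1))
        use = (arr > 0).any(axis=1)
        ratios = np.where(arr > 0, arr / ref[:, None], np.nan)[use]
        factors = np.nanmedian(ratios, axis=0)
    else:
        sub = arr[nonzero_rows]
        ref = np.exp(np.log(sub).mean(axis=1))
        factors = np.median(sub / ref[:, None], axis=0)
    if not np.isfinite(factors).all() or (factors <= 0).any():
        raise ValueError("degenerate size factors; check the count matrix")
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_log_counts(
    matrix: CountMatrix | pd.DataFrame,
    factors: pd.Series,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2((count + prior) / c_j) — descriptive only, never used for inference."""
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    if not (factors.loc[counts.columns] > 0).all():
        raise ValueError("size factors must be positive")
    return np.log2(
        (counts + prior_count).div(factors.loc[counts.columns], axis=1)
    )


def glm_offsets(matrix: CountMatrix, factors: pd.Series) -> pd.Series:
    """Per-sample log effective library size offsets for the NB GLM.

    Effective library size N_j * nf_j where nf_j = (c_j / N_j) rescaled to
    geometric mean 1 across samples — the edgeR convention.  Equal to
    log(c_j) plus a constant, which cancels in every contrast.
    """
    lib = matrix.library_sizes().astype(float)
    if (lib <= 0).any():
        raise ValueError("samples with zero assigned reads have no offset")
    nf = factors.loc[lib.index] / lib
    nf = nf / np.exp(np.log(nf).mean())
    return pd.Series(np.log(lib * nf), index=lib.index, name="offset")
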