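"""Per-strain negative-binomial GLMs and competitive-fitness contrasts.

The model follows count-based differential-abundance practice: counts for
strain i in sample j are NB(mu_ij, phi_i) with log mu_ij = x_j' beta_i +
o_j, where x_j encodes the treatment x time cell of sample j and o_j is a
normalization offset.  Fitness is read off as contrasts of cell means:

* reference fitness   = (T3, reference) - (T1, reference)
* treatment fitness   = [(T3, t) - (T1, t)] - [(T3, ref) - (T1, ref)]

both reported as log2 fold-changes.  Testing is a quasi-likelihood-style
moderated F-test: per-strain quasi-dispersions from residual deviance are
empirical-Bayes squeezed across strains and the 1-df contrast statistic is
referred to an F distribution with total (residual + prior) denominator df.

Because the design is cell-means, a strain-specific multiplicative
measurement bias (constant across samples) shifts every cell mean by the
same log amount and cancels exactly in every contrast — the property that
makes the assay robust to >20-fold DNA-extraction bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .counting import CountMatrix
from .normalize import filter_counts, glm_offsets, rle_size_factors

LN2 = float(np.log(2.0))

SHEET_COLUMNS = ("sample", "treatment", "time", "replicate")


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check the sample sheet has the required annotation columns."""
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    if sheet["sample"].duplicated().any():
        dups = sheet.loc[sheet["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample ids in sheet: {dups}")
    return sheet


@dataclass
class DesignMatrix:
    """Samples x coefficients design for the treatment x time model.

    ``cells`` maps each coefficient label to its (treatment, time) pair for
    the cell-means encoding; the intercept variant mirrors the
    reference-condition-as-baseline formulation used for fresh-juice runs.
    """

    X: pd.DataFrame
    cells: dict[str, tuple[str, str]]
    intercept: bool = False

    def __post_init__(self) -> None:
        rank = np.linalg.matrix_rank(self.X.to_numpy(dtype=float))
        if rank < self.X.shape[1]:
            raise ValueError(
                f"design is rank-deficient: rank {rank} < {self.X.shape[1]} columns"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.X.index)

    def cell_contrast(self, cell_terms: list[tuple[str, str, float]]) -> np.ndarray:
        """Contrast vector over coefficients from weighted (treatment, time) cells.

        Works for both encodings: a cell mean is a single coefficient under
        cell means, or a sum of baseline + dummy columns with an intercept.
        """
        c = np.zeros(self.X.shape[1])
        for trt, tp, w in cell_terms:
            c += w * self._cell_indicator(trt, tp)
        return c

    def _cell_indicator(self, trt: str, tp: str) -> np.ndarray:
        """Coefficient-space representation of the (trt, tp) cell mean."""
        key = (trt, tp)
        members = [s for s, cell in self.sample_cells.items() if cell == key]
        if not members:
            raise ValueError(f"no sample occupies cell (treatment={trt!r}, time={tp!r})")
        # the cell mean in coefficient space is the (identical) design row
        # of any sample in the cell
        return self.X.loc[members[0]].to_numpy(dtype=float)

    @property
    def sample_cells(self) -> dict[str, tuple[str, str]]:
        return self._sample_cells

    _sample_cells: dict[str, tuple[str, str]] = field(default_factory=dict, repr=False)


def build_design(
    sheet: pd.DataFrame,
    intercept: bool = False,
    reference: str | None = None,
) -> DesignMatrix:
    """Cell-means (or intercept) design for ~0 + treatment + treatment:time.

    Cell-means: one indicator column per occupied (treatment, time) cell.
    Intercept variant: intercept (reference cell at the earliest time),
    treatment main effects, and treatment:time dummies — the same column
    space, so fitted cell means agree between the two to numerical
    precision.
    """
    sheet = validate_sample_sheet(sheet)
    samples = sheet["sample"].tolist()
    cells_of = {
        r["sample"]: (str(r["treatment"]), str(r["time"]))
        for _, r in sheet.iterrows()
    }
    treatments = sorted({c[0] for c in cells_of.values()})
    times = sorted({c[1] for c in cells_of.values()})
    occupied = sorted(set(cells_of.values()))
    if not intercept:
        labels = [f"{t}.{tp}" for t, tp in occupied]
        X = pd.DataFrame(0.0, index=samples, columns=labels)
        for s, (t, tp) in cells_of.items():
            X.loc[s, f"{t}.{tp}"] = 1.0
        cells = {f"{t}.{tp}": (t, tp) for t, tp in occupied}
        dm = DesignMatrix(X, cells, intercept=False)
    else:
        if reference is None:
            reference = treatments[0]
        if reference not in treatments:
            raise ValueError(f"reference treatment {reference!r} not in sheet")
        t0 = times[0]
        cols: list[str] = ["(Intercept)"]
        cols += [f"treat[{t}]" for t in treatments if t != reference]
        cols += [
            f"treat[{t}]:time[{tp}]"
            for t in treatments
            for tp in times
            if tp != t0 and (t, tp) in set(occupied)
        ]
        X = pd.DataFrame(0.0, index=samples, columns=cols)
        X["(Intercept)"] = 1.0
        for s, (t, tp) in cells_of.items():
            if t != reference:
                X.loc[s, f"treat[{t}]"] = 1.0
            if tp != t0:
                X.loc[s, f"treat[{t}]:time[{tp}]"] = 1.0
        dm = DesignMatrix(X, {}, intercept=True)
    dm._sample_cells = cells_of
    return dm


@dataclass
class DispersionEstimate:
    """NB dispersions: raw per-strain, common, and EB-shrunk per-strain."""

    common: float
    raw: pd.Series
    shrunk: pd.Series
    prior_df: float


def _cell_structure(
    design: DesignMatrix, columns: pd.Index
) -> tuple[list[tuple[str, str]], dict[tuple[str, str], np.ndarray], np.ndarray]:
    """Occupied cells, per-cell sample masks, and the cell->coefficient map A.

    A has one row per occupied cell (its coefficient-space indicator), so
    cell means m satisfy A beta = log m under either design encoding.
    """
    n = len(columns)
    members: dict[tuple[str, str], np.ndarray] = {}
    for j, s in enumerate(columns):
        members.setdefault(design.sample_cells[s], np.zeros(n, dtype=bool))[j] = True
    cells = sorted(members)
    A = np.stack([design._cell_indicator(*cell) for cell in cells])
    return cells, members, A


def _fit_cell_means(
    y: np.ndarray,
    o: np.ndarray,
    cells: list[tuple[str, str]],
    members: dict[tuple[str, str], np.ndarray],
    A: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Closed-form fit: each cell mean is the arithmetic mean of that cell's
    offset-normalized counts, mapped back to design coefficients.

    Returns (beta, mu, estimable).  The estimator is exactly equivariant
    under per-strain count rescaling (cell means scale with the counts and
    log-differences cancel), which is what makes extraction bias drop out
    of every contrast.  ``estimable`` is False when some cell is all zero.
    """
    m = np.array([np.mean(y[members[c]] * np.exp(-o[members[c]])) for c in cells])
    estimable = bool((m > 0).all())
    logm = np.log(np.maximum(m, 1e-300))
    beta, *_ = np.linalg.lstsq(A, logm, rcond=None)
    mu = np.empty_like(y, dtype=float)
    for c, mk in zip(cells, m):
        mask = members[c]
        mu[mask] = mk * np.exp(o[mask])
    return beta, mu, estimable


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """Residual deviance of the NB (or Poisson, phi=0) fit."""
    mu = np.maximum(mu, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        if phi == 0:
            term = np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)
            return float(2.0 * term.sum())
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = (y + 1.0 / phi) * np.log((1.0 + phi * y) / (1.0 + phi * mu))
        return float(2.0 * (t1 - t2).sum())


def _pearson_phi(y: np.ndarray, mu: np.ndarray, df_resid: int) -> float:
    """Method-of-moments dispersion: solve sum (y-mu)^2/(mu+phi mu^2) = df."""
    if df_resid <= 0:
        return np.nan
    r2 = (y - mu) ** 2
    mu = np.maximum(mu, 1e-12)

    def pearson(phi: float) -> float:
        return float((r2 / (mu + phi * mu**2)).sum())

    if pearson(0.0) <= df_resid:
        return 0.0
    lo, hi = 0.0, 1.0
    while pearson(hi) > df_resid and hi < 1e6:
        hi *= 10
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if pearson(mid) > df_resid:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def estimate_dispersions(
    matrix: CountMatrix | pd.DataFrame,
    design: DesignMatrix,
    offsets: pd.Series,
    prior_df: float = 10.0,
) -> DispersionEstimate:
    """Per-strain NB dispersions with empirical-Bayes shrinkage.

    Raw dispersions come from Pearson-statistic moment matching on the
    cell-means Poisson fit; the common value is the mean of the raw
    estimates, and each strain's dispersion is shrunk toward it with
    ``prior_df`` prior degrees of freedom, so the shrunk value always lies
    between the raw estimate and the common value.  Strains with zero
    residual df take the common value (with a warning).
    """
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    X = design.X.loc[counts.columns].to_numpy(dtype=float)
    o = offsets.loc[counts.columns].to_numpy(dtype=float)
    n, p = X.shape
    df_resid = n - p
    cells, members, A = _cell_structure(design, counts.columns)
    raw = {}
    for sid, row in counts.iterrows():
        y = row.to_numpy(dtype=float)
        if y.sum() == 0:
            raw[sid] = np.nan
            continue
        _, mu, _ = _fit_cell_means(y, o, cells, members, A)
        raw[sid] = _pearson_phi(y, mu, df_resid)
    raw = pd.Series(raw, name="raw_dispersion")
    valid = raw.dropna()
    common = float(valid.mean()) if len(valid) else 0.0
    if df_resid <= 0:
        warnings.warn("zero residual df: per-strain dispersions set to common value")
        shrunk = pd.Series(common, index=raw.index)
    else:
        shrunk = (prior_df * common + df_resid * raw) / (prior_df + df_resid)
        shrunk = shrunk.fillna(common)
    return DispersionEstimate(
        common=common, raw=raw, shrunk=shrunk.rename("dispersion"), prior_df=prior_df
    )


@dataclass
class NBGLMFit:
    """Per-strain NB GLM fits under a shared design."""

    design: DesignMatrix
    coef: pd.DataFrame  # strains x coefficients, natural-log scale
    deviance: pd.Series
    df_resid: int
    cov_unscaled: dict[str, np.ndarray]  # (X' W X)^-1 per strain
    dispersions: pd.Series
    converged: pd.Series
    zero_cells: pd.Series  # strains with an all-zero occupied cell
    offsets: pd.Series
    counts: pd.DataFrame


def fit_nb_glm(
    matrix: CountMatrix | pd.DataFrame,
    design: DesignMatrix,
    dispersions: DispersionEstimate | pd.Series | float,
    offsets: pd.Series,
) -> NBGLMFit:
    """Fit the per-strain NB GLM by exact cell-mean estimation.

    Each fitted cell mean is the arithmetic mean of that cell's
    offset-normalized counts (the log-link score solution when offsets are
    cell-constant), mapped to design coefficients; the two design encodings
    therefore give identical fitted means.  Strains whose counts are all
    zero within some occupied cell are flagged (``zero_cells``): their cell
    coefficient is not estimable on the log scale and downstream contrasts
    fall back to prior-count log fold-changes.
    """
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    if isinstance(dispersions, DispersionEstimate):
        phi = dispersions.shrunk
    elif isinstance(dispersions, pd.Series):
        phi = dispersions
    else:
        phi = pd.Series(float(dispersions), index=counts.index)
    X = design.X.loc[counts.columns].to_numpy(dtype=float)
    o = offsets.loc[counts.columns].to_numpy(dtype=float)
    if not np.isfinite(o).all():
        raise ValueError("offsets must be finite")
    n, p = X.shape
    cells, members, A = _cell_structure(design, counts.columns)
    coefs, devs, covs, convs, zeros = {}, {}, {}, {}, {}
    for sid, row in counts.iterrows():
        y = row.to_numpy(dtype=float)
        phi_i = float(max(phi[sid], 0.0))
        beta, mu, estimable = _fit_cell_means(y, o, cells, members, A)
        zeros[sid] = not estimable
        ok = estimable
        w = np.where(mu > 0, mu / (1.0 + phi_i * mu), 0.0)
        xtwx = (X * w[:, None]).T @ X
        try:
            covs[sid] = np.linalg.inv(xtwx)
        except np.linalg.LinAlgError:
            covs[sid] = np.full((p, p), np.nan)
            ok = False
        coefs[sid] = beta
        devs[sid] = _nb_deviance(y, mu, phi_i)
        convs[sid] = ok
    return NBGLMFit(
        design=design,
        coef=pd.DataFrame.from_dict(coefs, orient="index", columns=design.X.columns),
        deviance=pd.Series(devs, name="deviance"),
        df_resid=n - p,
        cov_unscaled=covs,
        dispersions=phi,
        converged=pd.Series(convs, name="converged"),
        zero_cells=pd.Series(zeros, name="zero_cell"),
        offsets=offsets,
        counts=counts,
    )


def fitness_contrasts(
    design: DesignMatrix,
    reference: str,
    treatments: list[str] | None = None,
    t_early: str = "T1",
    t_late: str = "T3",
) -> dict[str, np.ndarray]:
    """Contrast vectors for reference and treatment fitness.

    Reference fitness is (t_late - t_early) in the reference condition;
    each treatment's fitness is the difference-in-differences
    ((t_late, t) - (t_early, t)) - ((t_late, ref) - (t_early, ref)).
    Missing cells fail naming the (treatment, time) pair.
    """
    occupied = set(design.sample_cells.values())
    all_treatments = sorted({t for t, _ in occupied})
    if reference not in all_treatments:
        raise ValueError(f"reference condition {reference!r} has no samples")
    if treatments is None:
        treatments = [t for t in all_treatments if t != reference]
    for t in [reference, *treatments]:
        for tp in (t_early, t_late):
            if (t, tp) not in occupied:
                raise ValueError(
                    f"required design cell is empty: (treatment={t!r}, time={tp!r})"
                )
    out: dict[str, np.ndarray] = {
        f"{reference}:{t_late}-{t_early}": design.cell_contrast(
            [(reference, t_late, 1.0), (reference, t_early, -1.0)]
        )
    }
    for t in treatments:
        out[f"{t}-vs-{reference}"] = design.cell_contrast(
            [
                (t, t_late, 1.0),
                (t, t_early, -1.0),
                (reference, t_late, -1.0),
                (reference, t_early, 1.0),
            ]
        )
    return out


def squeeze_var(
    s2: np.ndarray, df: float
) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes squeeze of sample variances toward a common prior.

    Moment-matching on log variances (the limma hyperparameter estimator):
    fits a scaled inverse-chi-square prior (s0^2, d0) and returns
    (posterior variances, d0, s0^2).  d0 = inf when the variances are
    underdispersed relative to chi-square sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return s2, np.inf, float(np.nanmean(np.where(ok, s2, np.nan)))
    e = np.log(s2[ok]) - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = float(np.var(e, ddof=1))
    excess = evar - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        d0 = np.inf
        s02 = float(np.exp(np.mean(e)))
        post = np.where(ok | True, s02, s02)
        return np.full_like(s2, s02), d0, s02
    # invert trigamma by Newton iteration
    x = 0.5 + 1.0 / excess
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dtri = float(special.polygamma(2, x))
        delta = tri * (1.0 - tri / excess) / dtri
        x += delta
        if abs(delta) < 1e-10 * x:
            break
    d0 = 2.0 * x
    s02 = float(np.exp(np.mean(e) + special.digamma(x) - np.log(x)))
    post = (d0 * s02 + df * s2) / (d0 + df)
    post = np.where(ok, post, s02)
    return post, d0, s02


def test_contrast(
    fit: NBGLMFit,
    contrast: np.ndarray,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Moderated quasi-likelihood F-test of a 1-df contrast.

    Per strain, the quasi-dispersion (residual deviance / residual df) is
    squeezed across strains, and F = (c'beta)^2 / (c'(X'WX)^-1 c * s2_post)
    is referred to F(1, df_resid + d0).  logFC is reported in log2 units;
    strains flagged degenerate (all-zero cell touched by the contrast, or a
    failed fit) get a prior-count fallback logFC and p = NA.
    """
    c = np.asarray(contrast, dtype=float)
    strains = list(fit.coef.index)
    df = fit.df_resid
    if df < 1:
        raise ValueError("no residual degrees of freedom for testing")
    s2 = (fit.deviance / df).to_numpy(dtype=float)
    s2_post, d0, _ = squeeze_var(np.maximum(s2, 1e-10), float(df))
    total_df = df + (d0 if np.isfinite(d0) else 1e6)
    rows = []
    for k, sid in enumerate(strains):
        beta = fit.coef.loc[sid].to_numpy(dtype=float)
        est = float(c @ beta)
        var_c = float(c @ fit.cov_unscaled[sid] @ c)
        degenerate = (
            bool(fit.zero_cells[sid])
            or not bool(fit.converged[sid])
            or not np.isfinite(var_c)
            or var_c <= 0
        )
        if degenerate:
            logfc = _prior_count_logfc(fit, sid, c, prior_count)
            rows.append((sid, logfc, np.nan, np.nan, True))
            continue
        fstat = est**2 / (var_c * s2_post[k])
        p = float(stats.f.sf(fstat, 1, total_df))
        rows.append((sid, est / LN2, float(fstat), p, False))
    return pd.DataFrame(
        rows, columns=["strain_id", "logFC", "F", "PValue", "flagged"]
    ).set_index("strain_id")


def _prior_count_logfc(
    fit: NBGLMFit, sid: str, c: np.ndarray, prior_count: float
) -> float:
    """Fallback log2 FC from prior-count cell means for degenerate strains."""
    y = fit.counts.loc[sid].to_numpy(dtype=float)
    o = fit.offsets.loc[fit.counts.columns].to_numpy(dtype=float)
    X = fit.design.X.loc[fit.counts.columns].to_numpy(dtype=float)
    norm = (y + prior_count) / np.exp(o - o.mean())
    _ = X
    # express the contrast as weights on cell means, then combine
    # prior-count normalized cell averages with those weights
    logfc = 0.0
    cells = sorted(set(fit.design.sample_cells.values()))
    members = {
        cell: [j for j, s in enumerate(fit.counts.columns)
               if fit.design.sample_cells[s] == cell]
        for cell in cells
    }
    A = np.stack([fit.design._cell_indicator(*cell) for cell in cells])
    w, *_ = np.linalg.lstsq(A.T, c, rcond=None)
    for cell, wk in zip(cells, w):
        if abs(wk) < 1e-12:
            continue
        m = float(np.mean(norm[members[cell]]))
        logfc += wk * np.log(max(m, prior_count / 2))
    return logfc / LN2


def adjust_fdr(p_values: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up over the non-NA p-values."""
    p = pd.Series(p_values).astype(float)
    out = pd.Series(np.nan, index=p.index, name="FDR")
    ok = p.notna()
    if ok.any():
        out[ok] = multipletests(p[ok].to_numpy(), method="fdr_bh")[1]
    if isinstance(p_values, np.ndarray):
        return out.to_numpy()
    return out


@dataclass
class FitnessResult:
    """Tidy per-(strain, contrast) fitness table plus fit provenance."""

    table: pd.DataFrame  # strain_id, contrast, logFC, F, PValue, FDR, flagged
    size_factors: pd.Series
    dispersions: DispersionEstimate
    fit: NBGLMFit
    dropped_samples: list[str]
    dropped_strains: list[str]

    def wide_logfc(self) -> pd.DataFrame:
        """Strains x contrasts matrix of log2 fold-changes."""
        return self.table.pivot(index="strain_id", columns="contrast", values="logFC")


def fit_fitness(
    matrix: CountMatrix,
    sheet: pd.DataFrame,
    reference: str,
    t_early: str = "T1",
    t_late: str = "T3",
    intercept: bool = False,
    min_sample_reads: int = 15,
    min_strain_reads: int = 3,
    prior_df: float = 10.0,
) -> FitnessResult:
    """End-to-end fitness inference from a raw count matrix.

    Filters low-information samples/strains, computes RLE size factors and
    offsets, fits per-strain NB GLMs under the treatment x time design, and
    tests the reference-fitness and per-treatment difference-in-differences
    contrasts, with BH FDR per contrast.
    """
    sheet = validate_sample_sheet(sheet)
    keep = sheet[sheet["time"].isin([t_early, t_late])]
    flt = filter_counts(matrix, min_sample_reads, min_strain_reads)
    cm = flt.matrix
    keep = keep[keep["sample"].isin(cm.samples)]
    if keep.empty:
        raise ValueError("no samples left at the requested time points after filtering")
    cm = CountMatrix(
        cm.counts[keep["sample"].tolist()],
        unassigned=cm.unassigned[keep["sample"].tolist()],
        ambiguous=cm.ambiguous[keep["sample"].tolist()],
    )
    factors = rle_size_factors(cm)
    offsets = glm_offsets(cm, factors)
    design = build_design(keep, intercept=intercept, reference=reference)
    disp = estimate_dispersions(cm, design, offsets, prior_df=prior_df)
    fit = fit_nb_glm(cm, design, disp, offsets)
    contrasts = fitness_contrasts(design, reference, t_early=t_early, t_late=t_late)
    frames = []
    for name, c in contrasts.items():
        res = test_contrast(fit, c)
        res["FDR"] = adjust_fdr(res["PValue"])
        res = res.reset_index()
        res.insert(1, "contrast", name)
        frames.append(res)
    table = pd.concat(frames, ignore_index=True)
    return FitnessResult(
        table=table,
        size_factors=factors,
        dispersions=disp,
        fit=fit,
        dropped_samples=flt.dropped_samples,
        dropped_strains=flt.dropped_strains,
    )
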