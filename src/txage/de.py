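"""Negative-binomial Wald differential-expression engine.

A self-contained, deliberately simple re-implementation of the standard
bulk RNA-seq workflow: median-of-ratios size factors, method-of-moments
dispersions shrunk toward a mean-dispersion trend, per-gene NB log-link
regression fitted by iteratively reweighted least squares (vectorised over
genes), a normal-tail Wald test on the contrast coefficient, Cook's-distance
outlier flagging, and Benjamini-Hochberg adjustment. There is no fold-change
shrinkage and no independent filtering beyond the stated mean-count rule;
downstream stages need only a calibrated (p, log2fc) table.

Sign convention: the contrast coefficient is the log fold change of the
second-listed level over the first, so positive log2fc means higher
expression in the second level ("high" group for quartile contrasts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datamodel import CountMatrix, GeneAnnotation, SampleMetadata, ValidationError

LN2 = np.log(2.0)

DE_COLUMNS = [
    "base_mean", "log2fc", "se", "wald_stat", "p", "p_adj",
    "outlier_flag", "tested_flag",
]


@dataclass
class ContrastSpec:
    """What to compare and what to adjust for.

    mode 'binary' compares the two observed levels of a binary covariate
    (lexicographic order by default, second level is the "treatment");
    mode 'quartile' compares samples in the lowest quartile of a continuous
    covariate to those in the highest.
    """

    covariate: str
    mode: str = "binary"
    adjustment_covariates: list[str] = field(default_factory=list)
    alpha: float = 0.01
    level_order: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("binary", "quartile"):
            raise ValueError(f"unknown contrast mode {self.mode!r}")
        if self.covariate in self.adjustment_covariates:
            raise ValueError(
                f"contrast covariate {self.covariate!r} cannot also be adjusted for"
            )


# ---------------------------------------------------------------------------
# building blocks


def filter_genes_for_de(counts: CountMatrix, annotation: GeneAnnotation) -> CountMatrix:
    """Keep protein-coding genes with a mean raw count per sample strictly > 1."""
    biotypes = annotation.biotypes_for(counts.gene_ids)
    keep = (biotypes.to_numpy() == "protein_coding") & (
        counts.counts.mean(axis=1).to_numpy() > 1.0
    )
    if not keep.any():
        raise ValidationError("no genes pass the coding + mean>1 expression filter")
    return CountMatrix(counts.counts.loc[keep])


def size_factors(counts) -> pd.Series:
    """Median-of-ratios size factors.

    Reference genes are those with strictly positive counts in every sample;
    each sample's factor is the median over reference genes of
    count / geometric mean of that gene across samples.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    values = df.to_numpy(dtype=float)
    reference = (values > 0).all(axis=1)
    if not reference.any():
        raise ValidationError(
            "no gene has positive counts in every sample; cannot compute "
            "median-of-ratios size factors (pseudo-reference fallback is disabled)"
        )
    ref = values[reference]
    log_geomean = np.mean(np.log(ref), axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=df.columns, name="size_factor")


def normalized_counts(counts, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts divided by per-sample size factors."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if factors is None:
        factors = size_factors(df)
    return df / factors.to_numpy()[None, :]


def estimate_dispersions(
    counts,
    factors: pd.Series | None = None,
    floor: float = 1e-8,
    trend_weight: float = 0.5,
) -> pd.Series:
    """Per-gene NB dispersion: method of moments plus trend shrinkage.

    On size-factor-normalised counts, the raw estimate is
    ``max(floor, (s^2 - mean) / mean^2)``; it is then shrunk toward a fitted
    a0 + a1/mean trend (least squares over genes with excess variance) with
    weight ``trend_weight``.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if df.shape[1] < 2:
        raise ValidationError("dispersion estimation needs at least 2 samples")
    q = normalized_counts(df, factors).to_numpy()
    mean = q.mean(axis=1)
    var = q.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var - mean) / mean**2
    raw = np.where(np.isfinite(raw), raw, floor)
    raw = np.maximum(raw, floor)

    informative = (raw > floor) & (mean > 0)
    if informative.sum() >= 10:
        design = np.column_stack([np.ones(informative.sum()), 1.0 / mean[informative]])
        coef, *_ = np.linalg.lstsq(design, raw[informative], rcond=None)
        with np.errstate(divide="ignore"):
            trend = coef[0] + coef[1] / mean
        trend = np.maximum(np.where(np.isfinite(trend), trend, floor), floor)
    else:
        trend = np.full_like(raw, np.median(raw))
    alpha = (1.0 - trend_weight) * raw + trend_weight * trend
    alpha = np.maximum(alpha, floor)
    return pd.Series(alpha, index=df.index, name="dispersion")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, NaN passed through.

    Sort ascending, q_i = p_i * m / i, enforce monotonicity by cumulative
    minimum from the largest, cap at 1, return in input order.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    vals = p[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = vals.size
    if m == 0:
        return out
    order = np.argsort(vals, kind="mergesort")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    result = np.empty(m)
    result[order] = adjusted
    out[mask] = result
    return out


def quartile_groups(
    metadata: SampleMetadata, covariate: str
) -> tuple[list[str], list[str]]:
    """Sample ids in the lowest and highest quartile of a continuous covariate.

    Q1/Q3 use the linear-interpolation quantile convention; low = value <= Q1,
    high = value >= Q3 (ties included on both sides).
    """
    values = pd.to_numeric(metadata.table[covariate], errors="coerce").dropna()
    if len(values) < 8:
        raise ValidationError(
            f"quartile contrast on {covariate!r} needs >= 8 non-missing values"
        )
    q1, q3 = np.quantile(values.to_numpy(), [0.25, 0.75], method="linear")
    if q1 == q3:
        raise ValidationError(f"degenerate spread for {covariate!r}: Q1 == Q3 == {q1}")
    low = list(values.index[values <= q1])
    high = list(values.index[values >= q3])
    return low, high


# ---------------------------------------------------------------------------
# vectorised IRLS fit


def _irls_nb(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
):
    """Fit per-gene NB log-link regressions, vectorised over genes.

    y : (G, n) counts; X : (n, p) design; offset : (n,) log size factors;
    alpha : (G,) fixed dispersions. Returns (beta (G,p), cov (G,p,p),
    mu (G,n), W (G,n), converged (G,)).
    """
    G, n = y.shape
    p = X.shape[1]
    # start from an intercept-only fit on normalised counts
    beta = np.zeros((G, p))
    beta[:, 0] = np.log(np.maximum(y.mean(axis=1) / np.exp(offset).mean(), 1e-8))
    converged = np.zeros(G, dtype=bool)
    ridge = 1e-10 * np.eye(p)

    active = np.arange(G)
    for _ in range(max_iter):
        eta = np.clip(beta[active] @ X.T + offset[None, :], -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[active, None] * mu)
        z = eta - offset[None, :] + (y[active] - mu) / mu
        XtWX = np.einsum("ni,gn,nj->gij", X, W, X, optimize=True) + ridge
        XtWz = np.einsum("ni,gn,gn->gi", X, W, z, optimize=True)
        try:
            new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            break
        step = np.abs(new - beta[active]).max(axis=1)
        beta[active] = new
        done = step < tol
        converged[active[done]] = True
        active = active[~done]
        if active.size == 0:
            break

    eta = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha[:, None] * mu)
    XtWX = np.einsum("ni,gn,nj->gij", X, W, X, optimize=True) + ridge
    cov = np.linalg.inv(XtWX)
    return beta, cov, mu, W, converged


def _cooks_distance(y, X, mu, W, cov, alpha):
    """Per-observation Cook's distance from the final IRLS weights.

    D_i = r_i^2 h_ii / (p (1 - h_ii)^2) with Pearson residuals r and
    leverages h from the weighted hat matrix.
    """
    p = X.shape[1]
    # h_gi = w_gi * x_i' (X'WX)^-1 x_i
    h = W * np.einsum("ni,gij,nj->gn", X, cov, X, optimize=True)
    h = np.clip(h, 0.0, 1.0 - 1e-8)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (y - mu) ** 2 / (mu * (1.0 + alpha[:, None] * mu))
    return r2 * h / (p * (1.0 - h) ** 2)


def fit_nb_wald(
    counts,
    design: pd.DataFrame,
    contrast_col: str,
    factors: pd.Series,
    dispersions: pd.Series,
    cooks_cutoff: float | None = 0.2,
) -> pd.DataFrame:
    """Wald test per gene for the coefficient of ``contrast_col``.

    ``design`` is the numeric design matrix (samples x columns, no
    intercept column; one is added) aligned with ``counts`` columns.
    Genes where any observation's Cook's distance exceeds ``cooks_cutoff``
    are flagged and removed from testing (and from the BH denominator).
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if list(design.index) != list(df.columns):
        design = design.loc[df.columns]
    X = np.column_stack([np.ones(len(design)), design.to_numpy(dtype=float)])
    colnames = ["intercept", *design.columns]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # report which columns are linearly dependent on the preceding ones
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                bad.append(colnames[j])
        raise ValidationError(f"rank-deficient design; collinear columns: {bad}")
    cidx = colnames.index(contrast_col)

    y = df.to_numpy(dtype=float)
    alpha = dispersions.loc[df.index].to_numpy()
    offset = np.log(factors.loc[df.columns].to_numpy())

    nonzero = y.sum(axis=1) > 0
    result = pd.DataFrame(index=df.index, columns=DE_COLUMNS, dtype=float)
    result["base_mean"] = normalized_counts(df, factors).mean(axis=1)
    result["outlier_flag"] = False
    result["tested_flag"] = False

    if nonzero.any():
        beta, cov, mu, W, converged = _irls_nb(
            y[nonzero], X, offset, alpha[nonzero]
        )
        se = np.sqrt(np.maximum(cov[:, cidx, cidx], 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            wald = beta[:, cidx] / se
        from scipy.stats import norm

        pvals = 2.0 * norm.sf(np.abs(wald))

        outlier = np.zeros(nonzero.sum(), dtype=bool)
        if cooks_cutoff is not None and np.isfinite(cooks_cutoff):
            cooks = _cooks_distance(y[nonzero], X, mu, W, cov, alpha[nonzero])
            outlier = (cooks > cooks_cutoff).any(axis=1)

        tested = converged & ~outlier & (se > 0)
        idx = df.index[nonzero]
        result.loc[idx, "log2fc"] = beta[:, cidx] / LN2
        result.loc[idx, "se"] = se / LN2
        result.loc[idx, "wald_stat"] = wald
        result.loc[idx, "outlier_flag"] = outlier
        result.loc[idx, "tested_flag"] = tested
        result.loc[idx[tested], "p"] = pvals[tested]

    result["p_adj"] = bh_adjust(result["p"].to_numpy())
    result["outlier_flag"] = result["outlier_flag"].astype(bool)
    result["tested_flag"] = result["tested_flag"].astype(bool)
    result.loc[~result["tested_flag"], ["p", "p_adj"]] = np.nan
    return result


# ---------------------------------------------------------------------------
# contrast assembly


def _binary_indicator(series: pd.Series, level_order=None) -> pd.Series:
    levels = sorted(series.dropna().unique(), key=str)
    if level_order is not None:
        if set(level_order) != set(levels):
            raise ValidationError(
                f"level_order {level_order} does not match observed levels {levels}"
            )
        levels = list(level_order)
    if len(levels) != 2:
        raise ValidationError(
            f"binary contrast needs exactly 2 levels, got {levels}"
        )
    return (series == levels[1]).astype(float), tuple(levels)


def build_design(
    metadata: SampleMetadata, covariates: list[str], samples: list[str]
) -> pd.DataFrame:
    """Numeric design columns for adjustment covariates (no intercept)."""
    cols = {}
    table = metadata.table.loc[samples]
    for name in covariates:
        kind = metadata.kind_of(name)
        if kind == "continuous":
            cols[name] = pd.to_numeric(table[name], errors="coerce")
        elif kind == "binary":
            indicator, _ = _binary_indicator(table[name])
            cols[name] = indicator
        else:  # categorical: dummy-code all but the first level
            levels = sorted(table[name].dropna().unique(), key=str)
            for level in levels[1:]:
                cols[f"{name}[{level}]"] = (table[name] == level).astype(float)
    return pd.DataFrame(cols, index=samples)


def run_de(
    counts,
    metadata: SampleMetadata,
    contrast: ContrastSpec,
    annotation: GeneAnnotation | None = None,
    cooks_cutoff: float | None = 0.2,
    dispersions: pd.Series | None = None,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Full DE contrast: sample selection, design, fit, outliers, BH.

    Samples with missing values in the contrast or adjustment covariates are
    dropped from this contrast only. Size factors and dispersions are
    computed on the included samples unless supplied.
    """
    cm = counts if isinstance(counts, CountMatrix) else CountMatrix(counts)
    if annotation is not None:
        cm = filter_genes_for_de(cm, annotation)
    metadata = metadata.aligned_to(cm)

    if contrast.mode == "quartile":
        if metadata.kind_of(contrast.covariate) != "continuous":
            raise ValidationError(
                f"quartile contrast requires a continuous covariate, "
                f"{contrast.covariate!r} is {metadata.kind_of(contrast.covariate)}"
            )
        low, high = quartile_groups(metadata, contrast.covariate)
        samples = low + high
        indicator = pd.Series(
            [0.0] * len(low) + [1.0] * len(high), index=samples
        )
    else:
        series = metadata.table[contrast.covariate]
        samples = list(series.dropna().index)
        indicator, _ = _binary_indicator(
            series.loc[samples], contrast.level_order
        )
        indicator = indicator.loc[samples]

    # drop samples missing any adjustment covariate
    adj_table = metadata.table.loc[samples, contrast.adjustment_covariates]
    keep = adj_table.notna().all(axis=1)
    samples = list(pd.Index(samples)[keep.to_numpy()])
    # preserve original column order of the count matrix
    samples = [s for s in cm.sample_ids if s in set(samples)]

    design = build_design(metadata, contrast.adjustment_covariates, samples)
    design[contrast.covariate] = indicator.loc[samples]

    sub = cm.counts[samples]
    if factors is None:
        factors = size_factors(sub)
    else:
        factors = factors.loc[samples]
    if dispersions is None:
        dispersions = estimate_dispersions(sub, factors)
    return fit_nb_wald(
        sub, design, contrast.covariate, factors, dispersions, cooks_cutoff
    )


def significant_genes(result: pd.DataFrame, alpha: float = 0.01) -> list[str]:
    mask = result["tested_flag"] & (result["p_adj"] < alpha)
    return list(result.index[mask.fillna(False)])


# ---------------------------------------------------------------------------
# sklearn-style estimator


class NBWaldDE(BaseEstimator):
    """Negative-binomial Wald differential expression as an sklearn estimator.

    fit(X, y) takes X = samples x genes counts (DataFrame or array) and
    y = binary group labels; fitted attributes are ``results_`` (per-gene
    table), ``size_factors_`` and ``dispersions_``.
    """

    def __init__(self, alpha=0.01, cooks_cutoff=0.2, trend_weight=0.5,
                 dispersion_floor=1e-8):
        self.alpha = alpha
        self.cooks_cutoff = cooks_cutoff
        self.trend_weight = trend_weight
        self.dispersion_floor = dispersion_floor

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different numbers of samples")
        levels = np.unique(y)
        if levels.size != 2:
            raise ValueError(f"y must be binary, got levels {levels}")
        counts = X.T  # genes x samples internally
        factors = size_factors(counts)
        dispersions = estimate_dispersions(
            counts, factors, floor=self.dispersion_floor,
            trend_weight=self.trend_weight,
        )
        design = pd.DataFrame(
            {"group": (y == levels[1]).astype(float)}, index=counts.columns
        )
        self.classes_ = levels
        self.size_factors_ = factors
        self.dispersions_ = dispersions
        self.results_ = fit_nb_wald(
            counts, design, "group", factors, dispersions, self.cooks_cutoff
        )
        self.n_features_in_ = X.shape[1]
        return self

    def significant_(self):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "results_")
        return significant_genes(self.results_, self.alpha)
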