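"""Transcriptional biological age.

The signature is the set of genes differentially expressed between the
youngest and oldest age-quartile samples (adjusted p and |log2FC| cutoffs),
each carrying the sign of its association with age. A sample's biological
age is the mean, over signature genes, of the sign-aligned per-gene z-score
of its (size-factor-normalised, log2, outlier-capped) expression — so a
sample whose age-up genes are high and age-down genes are low scores old.
Cutoffs are chosen by grid search for the signature whose scores correlate
best (Spearman) with chronological age.

The case/control question is then asymmetry around the pooled regression
line biological ~ chronological age: per group, count samples above and
below the line and test the 2x2 table with Fisher's exact test. Cases
sitting above the line more often than controls is the accelerated-ageing
signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, spearmanr
from sklearn.base import BaseEstimator, RegressorMixin

from .datamodel import CountMatrix, SampleMetadata, ValidationError
from .de import (
    ContrastSpec,
    normalized_counts,
    run_de,
    size_factors,
)
from .coexpression import zscore_genes

DEFAULT_P_GRID = (0.01, 0.05, 0.1)
DEFAULT_LFC_GRID = (0.0, 0.3, 0.6, 1.0)
MIN_SIGNATURE_SIZE = 10


@dataclass
class AgeSignature:
    """Signed age-associated gene list and the cutoffs that produced it."""

    genes: pd.Series          # index gene_id, values +1 / -1
    p_cutoff: float
    lfc_cutoff: float
    spearman_vs_age: float = np.nan

    def __post_init__(self) -> None:
        if not set(np.unique(self.genes)).issubset({-1, 1}):
            raise ValidationError("signature signs must be +1 or -1")
        if len(self.genes) < MIN_SIGNATURE_SIZE:
            raise ValidationError(
                f"signature has {len(self.genes)} genes "
                f"(minimum {MIN_SIGNATURE_SIZE})"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class BioAgeResult:
    """Per-sample scores/residuals and the group asymmetry test."""

    samples: pd.DataFrame     # biological_age, age, group, residual, above_line
    slope: float
    intercept: float
    spearman: float
    spearman_p: float
    table: pd.DataFrame       # groups x (below, above)
    fisher_p: float


# ---------------------------------------------------------------------------
# primitives


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative integers.

    Sums the hypergeometric point probabilities of every table with the
    same margins that is no more probable than the observed one (relative
    tolerance 1e-7). All four margins must be positive.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("need a 2x2 table of non-negative integers")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValidationError("Fisher test undefined for a zero margin")
    n = int(t.sum())
    # support of the (0,0) cell given the margins
    lo = max(0, row[0] - col[1])
    hi = min(row[0], col[0])
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, col[0], row[0])
    p_obs = hypergeom.pmf(t[0, 0], n, col[0], row[0])
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(p, 1.0)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (ties mid-ranked) with its t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("spearman needs two equal-length vectors, n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValidationError("spearman undefined for zero rank variance")
    rho, p = spearmanr(x, y)
    return float(rho), float(p)


def cap_outliers(expr: pd.DataFrame, z_cap: float = 3.0) -> pd.DataFrame:
    """Winsorise per gene: values beyond mean +/- z_cap * sd (moments of the
    input) are set to the boundary.

    A single pass: data already within its bounds is returned unchanged, and
    the clipped value equals exactly the pre-cap mean + z_cap * sd. Because
    clipping shrinks the recomputed standard deviation, a second application
    can clip a little further; only in-bounds data is a strict fixed point.
    """
    out = expr.astype(float)
    mean = out.mean(axis=1)
    sd = out.std(axis=1, ddof=1)
    return out.clip(lower=mean - z_cap * sd, upper=mean + z_cap * sd, axis=0)


def scoring_expression(counts, factors=None, z_cap: float = 3.0) -> pd.DataFrame:
    """Expression used for biological-age scoring: size-factor-normalised
    counts on a log2(x+1) scale, outlier-capped, not covariate-corrected."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if factors is None:
        factors = size_factors(df)
    expr = np.log2(normalized_counts(df, factors) + 1.0)
    return cap_outliers(expr, z_cap=z_cap)


# ---------------------------------------------------------------------------
# signature construction and scoring


def age_de(
    counts,
    metadata: SampleMetadata,
    cooks_cutoff: float | None = 0.2,
) -> pd.DataFrame:
    """Differential expression between the lowest and highest age quartiles
    (no adjustment covariates). Positive log2fc = up with age."""
    metadata.require_age()
    return run_de(
        counts,
        metadata,
        ContrastSpec(covariate="age", mode="quartile"),
        cooks_cutoff=cooks_cutoff,
    )


def signature_from_de(
    de_table: pd.DataFrame, p_cutoff: float, lfc_cutoff: float
) -> AgeSignature:
    """Signature = tested genes with p_adj < p_cutoff and |log2fc| > lfc_cutoff;
    sign is the direction of the old-vs-young fold change."""
    mask = (
        de_table["tested_flag"]
        & (de_table["p_adj"] < p_cutoff)
        & (de_table["log2fc"].abs() > lfc_cutoff)
    ).fillna(False)
    genes = np.sign(de_table.loc[mask, "log2fc"]).astype(int)
    genes = genes[genes != 0]
    return AgeSignature(genes=genes, p_cutoff=p_cutoff, lfc_cutoff=lfc_cutoff)


def bioage_scores(expr: pd.DataFrame, signature: AgeSignature) -> pd.Series:
    """Per-sample biological age: mean sign-aligned z-score over signature
    genes, z computed across all samples jointly."""
    present = signature.genes.index.intersection(expr.index)
    if len(present) < MIN_SIGNATURE_SIZE:
        raise ValidationError(
            f"only {len(present)} signature genes present in the expression "
            f"matrix (minimum {MIN_SIGNATURE_SIZE})"
        )
    z = zscore_genes(expr.loc[present])
    usable = ~z.isna().all(axis=1)
    z = z.loc[usable]
    signs = signature.genes.loc[z.index].to_numpy()[:, None]
    scores = (z.to_numpy() * signs).mean(axis=0)
    return pd.Series(scores, index=expr.columns, name="biological_age")


def optimize_signature(
    de_table: pd.DataFrame,
    expr: pd.DataFrame,
    ages: pd.Series,
    p_grid=DEFAULT_P_GRID,
    lfc_grid=DEFAULT_LFC_GRID,
) -> tuple[AgeSignature, pd.DataFrame]:
    """Grid-search (p_adj, |log2fc|) cutoffs for the signature whose scores
    have the greatest Spearman correlation with chronological age.

    Ties prefer fewer genes, then the smaller p cutoff. Returns the winning
    signature and the full grid table (p_cutoff, lfc_cutoff, n_genes, rho).
    """
    ages = ages.loc[expr.columns]
    rows = []
    candidates = {}
    for p_cut in p_grid:
        for lfc_cut in lfc_grid:
            try:
                sig = signature_from_de(de_table, p_cut, lfc_cut)
                scores = bioage_scores(expr, sig)
                rho, _ = spearman(scores.to_numpy(), ages.to_numpy())
            except ValidationError:
                rows.append((p_cut, lfc_cut, 0, np.nan))
                continue
            sig.spearman_vs_age = rho
            candidates[(p_cut, lfc_cut)] = sig
            rows.append((p_cut, lfc_cut, sig.n_genes, rho))
    grid = pd.DataFrame(rows, columns=["p_cutoff", "lfc_cutoff", "n_genes", "rho"])
    if not candidates:
        raise ValidationError("no grid cell yields a signature above minimum size")
    best = min(
        candidates,
        key=lambda key: (-candidates[key].spearman_vs_age,
                         candidates[key].n_genes, key[0]),
    )
    return candidates[best], grid


def residual_asymmetry(
    scores: pd.Series,
    ages: pd.Series,
    groups: pd.Series,
    group_a: str = "HC",
) -> BioAgeResult:
    """Asymmetry of the two groups around the pooled biological ~ chronological
    regression line.

    OLS is fitted on all samples pooled; a sample is "above" when its
    residual is strictly positive (exactly zero counts as below). The
    groups x {below, above} table is tested two-sided with Fisher's exact
    test.
    """
    ages = ages.loc[scores.index].astype(float)
    groups = groups.loc[scores.index]
    labels = [lab for lab in pd.unique(groups)]
    if group_a not in labels:
        raise ValidationError(f"group {group_a!r} absent")
    group_b_mask = groups != group_a
    if (~group_b_mask).sum() < 2 or group_b_mask.sum() < 2:
        raise ValidationError("both groups need at least 2 samples")
    if np.unique(ages).size < 2:
        raise ValidationError("degenerate age: zero variance")

    slope, intercept = np.polyfit(ages.to_numpy(), scores.to_numpy(), deg=1)
    residual = scores - (intercept + slope * ages)
    above = residual > 0

    group_label = np.where(group_b_mask, "case", group_a)
    table = pd.DataFrame(
        {
            "below": [
                int((~above[group_label == group_a]).sum()),
                int((~above[group_label == "case"]).sum()),
            ],
            "above": [
                int(above[group_label == group_a].sum()),
                int(above[group_label == "case"].sum()),
            ],
        },
        index=[group_a, "case"],
    )
    fisher_p = fisher_exact_2x2(table.to_numpy())
    rho, rho_p = spearman(scores.to_numpy(), ages.to_numpy())
    samples = pd.DataFrame(
        {
            "biological_age": scores,
            "age": ages,
            "group": groups,
            "residual": residual,
            "above_line": above,
        }
    )
    return BioAgeResult(
        samples=samples,
        slope=float(slope),
        intercept=float(intercept),
        spearman=rho,
        spearman_p=rho_p,
        table=table,
        fisher_p=fisher_p,
    )


def run_bioage(
    counts,
    metadata: SampleMetadata,
    p_grid=DEFAULT_P_GRID,
    lfc_grid=DEFAULT_LFC_GRID,
    z_cap: float = 3.0,
    group_a: str = "HC",
) -> tuple[AgeSignature, BioAgeResult, pd.DataFrame]:
    """End-to-end: age-quartile DE, signature optimisation, scoring, and the
    residual-asymmetry test. ``counts`` should already be DE-filtered."""
    metadata = metadata.aligned_to(
        counts if isinstance(counts, CountMatrix) else CountMatrix(counts)
    )
    metadata.require_age()
    de_table = age_de(counts, metadata)
    expr = scoring_expression(counts, z_cap=z_cap)
    ages = metadata.table["age"]
    signature, grid = optimize_signature(de_table, expr, ages, p_grid, lfc_grid)
    scores = bioage_scores(expr, signature)
    result = residual_asymmetry(
        scores, ages, metadata.table["group"], group_a=group_a
    )
    return signature, result, grid


# ---------------------------------------------------------------------------
# sklearn-style estimator


class BiologicalAgeClock(BaseEstimator, RegressorMixin):
    """Transcriptional age clock as an sklearn estimator.

    fit(X, y): X = samples x genes raw counts (DataFrame), y = chronological
    ages. Learns ``signature_`` by age-quartile DE plus grid search.
    predict(X) returns the biological-age score of each sample, z-scored
    within the prediction cohort. ``score`` (from RegressorMixin) is R^2
    against chronological age and is not the headline metric; use
    ``spearman_vs_age_``.
    """

    def __init__(self, p_grid=DEFAULT_P_GRID, lfc_grid=DEFAULT_LFC_GRID,
                 z_cap=3.0, cooks_cutoff=0.2):
        self.p_grid = p_grid
        self.lfc_grid = lfc_grid
        self.z_cap = z_cap
        self.cooks_cutoff = cooks_cutoff

    def fit(self, X, y):
        X = pd.DataFrame(X)
        ages = pd.Series(np.asarray(y, dtype=float), index=X.index)
        counts = CountMatrix(X.T)
        metadata = SampleMetadata(
            pd.DataFrame({"group": "HC", "age": ages}, index=X.index)
        )
        de_table = age_de(counts, metadata, cooks_cutoff=self.cooks_cutoff)
        expr = scoring_expression(counts, z_cap=self.z_cap)
        self.signature_, self.grid_ = optimize_signature(
            de_table, expr, ages, self.p_grid, self.lfc_grid
        )
        self.spearman_vs_age_ = self.signature_.spearman_vs_age
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "signature_")
        expr = scoring_expression(CountMatrix(pd.DataFrame(X).T), z_cap=self.z_cap)
        return bioage_scores(expr, self.signature_).to_numpy()
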