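"""Randomised case/control false-positive null.

Repeatedly relabel the cohort at random into pseudo-case and pseudo-control
groups of the real design's sizes, rerun the full differential-expression
contrast, and record how many genes reach significance at each threshold —
an empirical estimate of the expected false-positive count. Genes that are
recurrently near-significant across randomisations (smallest mean raw p)
expose the non-random structure of false positives, which a hypergeometric
over-representation test then characterises against user gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .datamodel import CountMatrix, GeneSetCollection, ValidationError
from .de import bh_adjust, estimate_dispersions, fit_nb_wald, size_factors

DEFAULT_THRESHOLDS = (0.01, 0.05, 0.1, 0.25)


@dataclass
class RandomizationSummary:
    thresholds: tuple[float, ...]
    counts: pd.DataFrame        # iterations x thresholds significant-gene counts
    gene_mean_p: pd.Series      # per-gene mean raw p over iterations
    n_iterations: int
    n_case: int
    n_total: int
    seed: int

    @property
    def median_counts(self) -> pd.Series:
        return self.counts.median(axis=0)

    @property
    def max_counts(self) -> pd.Series:
        return self.counts.max(axis=0)


def random_split(sample_ids, n_case: int, seed) -> tuple[list[str], list[str]]:
    """Uniform random partition into ``n_case`` pseudo-cases and the rest.

    ``seed`` may be an int or a numpy Generator.
    """
    sample_ids = list(sample_ids)
    if not 0 < n_case < len(sample_ids):
        raise ValidationError(
            f"n_case must be in (0, {len(sample_ids)}), got {n_case}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(len(sample_ids))
    case = [sample_ids[i] for i in sorted(order[:n_case])]
    control = [sample_ids[i] for i in sorted(order[n_case:])]
    return case, control


def fp_expectation(
    counts,
    n_case: int,
    n_iter: int = 50,
    thresholds=DEFAULT_THRESHOLDS,
    seed: int = 0,
    cooks_cutoff: float | None = 0.2,
) -> RandomizationSummary:
    """Expected false-positive counts from ``n_iter`` randomised contrasts.

    ``counts`` should already be filtered for DE. Each iteration runs the
    full NB Wald contrast (no adjustment covariates) on a fresh random
    split; size factors and dispersions depend only on the counts and are
    computed once. One master seed deterministically spawns per-iteration
    seeds, so runs are bit-reproducible.
    """
    if n_iter < 2:
        raise ValidationError("n_iter must be >= 2")
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    thresholds = tuple(sorted(thresholds))
    factors = size_factors(df)
    dispersions = estimate_dispersions(df, factors)

    streams = np.random.SeedSequence(seed).spawn(n_iter)
    count_rows = np.zeros((n_iter, len(thresholds)), dtype=int)
    p_sum = np.zeros(df.shape[0])
    p_n = np.zeros(df.shape[0])
    for it, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        case, _ = random_split(df.columns, n_case, rng)
        design = pd.DataFrame(
            {"pseudo_group": df.columns.isin(case).astype(float)}, index=df.columns
        )
        result = fit_nb_wald(
            df, design, "pseudo_group", factors, dispersions, cooks_cutoff
        )
        padj = result["p_adj"].to_numpy()
        for j, thr in enumerate(thresholds):
            count_rows[it, j] = int(np.nansum(padj < thr))
        p = result["p"].to_numpy()
        ok = ~np.isnan(p)
        p_sum[ok] += p[ok]
        p_n[ok] += 1

    mean_p = np.where(p_n > 0, p_sum / np.maximum(p_n, 1), np.nan)
    return RandomizationSummary(
        thresholds=thresholds,
        counts=pd.DataFrame(
            count_rows, columns=[str(t) for t in thresholds]
        ).rename_axis("iteration"),
        gene_mean_p=pd.Series(mean_p, index=df.index, name="mean_p"),
        n_iterations=n_iter,
        n_case=n_case,
        n_total=df.shape[1],
        seed=seed,
    )


def recurrent_fp_genes(summary: RandomizationSummary, k: int = 50) -> list[str]:
    """The k genes with smallest mean raw p over the randomised contrasts;
    ties broken lexicographically by gene id."""
    mean_p = summary.gene_mean_p.dropna()
    if k > len(mean_p):
        raise ValidationError(f"k={k} exceeds {len(mean_p)} genes with mean p")
    order = sorted(mean_p.index, key=lambda g: (mean_p[g], g))
    return order[:k]


def hypergeom_ora(
    query,
    sets: GeneSetCollection,
    background,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query`` in each set.

    Sets are intersected with the background before testing; the tail is
    P(X >= k) for overlap k, set size K, query size n, background size N.
    """
    background = list(dict.fromkeys(background))
    if not background:
        raise ValidationError("empty background")
    bg = set(background)
    query = [g for g in dict.fromkeys(query)]
    stray = set(query) - bg
    if stray:
        raise ValidationError(f"query genes outside background: {sorted(stray)[:5]}")
    N, n = len(bg), len(query)
    qset = set(query)
    rows = []
    for name, members in sets.items():
        in_bg = [g for g in members if g in bg]
        K = len(in_bg)
        k = len(qset.intersection(in_bg))
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, k, K, n, N, min(p, 1.0)))
    table = pd.DataFrame(
        rows, columns=["set_name", "overlap", "set_size", "query_size",
                       "background_size", "p"],
    ).set_index("set_name")
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["p_adj"] < fdr
    return table.sort_values(["p", "set_name"])
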