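"""Seeded synthetic PBMC-style count data with a ground-truth ledger.

Counts are negative binomial (gamma-Poisson) per gene and sample with

    log2 mu_gs = log2(size factor_s) + log2(baseline_g)
                 + sum_c effect_cg * x_cs            (sex, BMI, batch)
                 + sign_g * age_lfc * (effective_age_s - mid_age)/10
                 + loading * f_{block(g), s}         (co-expression blocks)

where effective age = chronological age + an optional ageing offset applied
only to case (non-HC) samples — the alternative hypothesis that cases look
transcriptionally older than their years. Metadata always records
chronological age. Continuous covariate effects (BMI, age) are centred so
that planted effects do not shift baseline expression. The cluster latent
factor is standard normal per block and sample, shared by all block members,
which induces the block-correlation structure the co-expression stage looks
for. Dispersions are log-normal across genes; baseline means log-uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    CountMatrix,
    GeneAnnotation,
    SampleMetadata,
    ValidationError,
)

DEFAULT_GROUP_SIZES = {
    "HC": 44,
    "MDD_resistant": 94,
    "MDD_responsive": 47,
    "MDD_untreated": 46,
}


@dataclass
class CovariateEffect:
    """Number of affected genes and per-unit log2 fold change for one covariate."""

    n_genes: int
    log2fc: float


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    age_range: tuple[float, float] = (25.0, 50.0)
    n_age_genes: int = 500
    age_log2fc_per_decade: float = 0.5
    n_cluster_blocks: int = 2
    cluster_block_size: int = 60
    cluster_loading: float = 0.15
    cluster_baseline_range: tuple[float, float] = (300.0, 600.0)
    cluster_dispersion: float = 0.003
    ageing_offset_years: float = 0.0
    covariate_effects: dict[str, CovariateEffect] = field(
        default_factory=lambda: {
            "sex": CovariateEffect(100, 1.0),
            "bmi": CovariateEffect(100, 0.5),
            "batch": CovariateEffect(100, 0.5),
        }
    )
    dispersion_shape: tuple[float, float] = (np.log(0.05), 0.5)  # lognormal (mu, sigma)
    baseline_mean_range: tuple[float, float] = (5.0, 500.0)
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    noncoding_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        planted = self.planted_genes
        if planted > self.n_genes:
            raise ValidationError(
                f"gene budget infeasible: {planted} planted genes > "
                f"{self.n_genes} total"
            )
        for name, rng in [
            ("age_range", self.age_range),
            ("baseline_mean_range", self.baseline_mean_range),
            ("size_factor_range", self.size_factor_range),
        ]:
            if rng[0] > rng[1]:
                raise ValidationError(f"{name} is not ordered: {rng}")
        if not (0 <= self.noncoding_fraction < 1):
            raise ValidationError("noncoding_fraction must be in [0, 1)")
        if self.n_genes <= 0 or any(v <= 0 for v in self.group_sizes.values()):
            raise ValidationError("gene and group counts must be positive")
        free = self.n_genes - planted
        if int(self.noncoding_fraction * self.n_genes) > free:
            raise ValidationError(
                "noncoding_fraction leaves no room for planted coding genes"
            )

    @property
    def planted_genes(self) -> int:
        return (
            self.n_age_genes
            + sum(e.n_genes for e in self.covariate_effects.values())
            + self.n_cluster_blocks * self.cluster_block_size
        )

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes.values())


@dataclass
class SimulationTruth:
    """Planted per-gene and per-sample parameters, sufficient to score recovery."""

    genes: pd.DataFrame    # index gene_id
    samples: pd.DataFrame  # index sample_id

    @property
    def age_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["age_sign"] != 0])

    @property
    def cluster_blocks(self) -> dict[int, list[str]]:
        blocks = {}
        for block, sub in self.genes[self.genes["cluster"] >= 0].groupby("cluster"):
            blocks[int(block)] = list(sub.index)
        return blocks


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[CountMatrix, SampleMetadata, GeneAnnotation, SimulationTruth]:
    """Draw one synthetic cohort; identical seed gives bit-identical output."""
    rng = np.random.default_rng(config.seed)
    n_genes, n_samples = config.n_genes, config.n_samples

    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]

    # --- samples ----------------------------------------------------------
    groups = np.repeat(
        list(config.group_sizes), list(config.group_sizes.values())
    )
    age = rng.uniform(*config.age_range, size=n_samples)
    sex = rng.choice(["F", "M"], size=n_samples)
    bmi = rng.normal(25.0, 4.0, size=n_samples)
    batch = rng.choice(["b1", "b2"], size=n_samples)
    lo, hi = config.size_factor_range
    sf = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))
    effective_age = age + np.where(groups == "HC", 0.0, config.ageing_offset_years)

    # --- gene roles (sequential, disjoint) --------------------------------
    age_sign = np.zeros(n_genes, dtype=int)
    cov_name = np.array([""] * n_genes, dtype=object)
    cov_lfc = np.zeros(n_genes)
    cluster = np.full(n_genes, -1, dtype=int)

    cursor = 0
    if config.n_age_genes:
        signs = rng.choice([-1, 1], size=config.n_age_genes)
        age_sign[cursor : cursor + config.n_age_genes] = signs
        cursor += config.n_age_genes
    for name, effect in config.covariate_effects.items():
        cov_name[cursor : cursor + effect.n_genes] = name
        cov_lfc[cursor : cursor + effect.n_genes] = effect.log2fc
        cursor += effect.n_genes
    for b in range(config.n_cluster_blocks):
        cluster[cursor : cursor + config.cluster_block_size] = b
        cursor += config.cluster_block_size

    n_noncoding = int(config.noncoding_fraction * n_genes)
    biotype = np.array(["protein_coding"] * n_genes, dtype=object)
    if n_noncoding:
        biotype[n_genes - n_noncoding :] = "lincRNA"  # only unplanted tail genes

    baseline = np.exp(
        rng.uniform(
            np.log(config.baseline_mean_range[0]),
            np.log(config.baseline_mean_range[1]),
            size=n_genes,
        )
    )
    mu_log, sigma_log = config.dispersion_shape
    dispersion = rng.lognormal(mu_log, sigma_log, size=n_genes)
    # block members are stable, highly expressed "module" genes — the stratum
    # the co-expression mean/CV filter retains
    in_block = cluster >= 0
    if in_block.any():
        baseline[in_block] = np.exp(
            rng.uniform(
                np.log(config.cluster_baseline_range[0]),
                np.log(config.cluster_baseline_range[1]),
                size=in_block.sum(),
            )
        )
        dispersion[in_block] = config.cluster_dispersion

    # --- mean model (log2 space) ------------------------------------------
    log2mu = np.log2(baseline)[:, None] + np.log2(sf)[None, :]

    sex_x = (sex == "M").astype(float)
    batch_x = (batch == "b2").astype(float)
    bmi_x = (bmi - bmi.mean()) / bmi.std()
    covariate_values = {"sex": sex_x, "bmi": bmi_x, "batch": batch_x}
    for name in config.covariate_effects:
        if name not in covariate_values:
            raise ValidationError(f"no simulated covariate named {name!r}")
        mask = cov_name == name
        log2mu[mask] += np.outer(cov_lfc[mask], covariate_values[name])

    mid_age = np.mean(config.age_range)
    age_x = (effective_age - mid_age) / 10.0  # decades, centred
    mask = age_sign != 0
    log2mu[mask] += np.outer(
        age_sign[mask] * config.age_log2fc_per_decade, age_x
    )

    if config.n_cluster_blocks and config.cluster_loading:
        factors = rng.normal(size=(config.n_cluster_blocks, n_samples))
        for b in range(config.n_cluster_blocks):
            log2mu[cluster == b] += config.cluster_loading * factors[b][None, :]

    mu = np.exp2(np.clip(log2mu, -30, 30))

    # --- gamma-Poisson sampling -------------------------------------------
    counts = np.empty((n_genes, n_samples), dtype=np.int64)
    tiny = 1e-12
    poisson_like = dispersion < tiny
    if poisson_like.any():
        counts[poisson_like] = rng.poisson(mu[poisson_like])
    nb = ~poisson_like
    if nb.any():
        shape = 1.0 / dispersion[nb]
        lam = rng.gamma(shape[:, None], dispersion[nb][:, None] * mu[nb])
        counts[nb] = rng.poisson(lam)

    count_matrix = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    )
    metadata = SampleMetadata(
        pd.DataFrame(
            {
                "group": groups,
                "age": age,  # chronological, never the offset age
                "sex": sex,
                "bmi": bmi,
                "batch": batch,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        ),
        {"sex": "binary", "bmi": "continuous", "batch": "binary"},
    )
    annotation = GeneAnnotation(
        pd.DataFrame(
            {"biotype": biotype}, index=pd.Index(gene_ids, name="gene_id")
        )
    )
    truth = SimulationTruth(
        genes=pd.DataFrame(
            {
                "baseline_mean": baseline,
                "dispersion": dispersion,
                "age_sign": age_sign,
                "covariate": cov_name,
                "covariate_log2fc": cov_lfc,
                "cluster": cluster,
                "biotype": biotype,
            },
            index=pd.Index(gene_ids, name="gene_id"),
        ),
        samples=pd.DataFrame(
            {
                "group": groups,
                "age": age,
                "effective_age": effective_age,
                "size_factor": sf,
                "sex": sex,
                "bmi": bmi,
                "batch": batch,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        ),
    )
    return count_matrix, metadata, annotation, truth


def truth_report(truth: SimulationTruth, path) -> None:
    """Write the ground-truth ledger: one row per gene and per sample.

    Rows are tagged by ``record_type``; columns not applicable to a record
    type are NA.
    """
    genes = truth.genes.reset_index().rename(columns={"gene_id": "id"})
    genes.insert(0, "record_type", "gene")
    samples = truth.samples.reset_index().rename(columns={"sample_id": "id"})
    samples.insert(0, "record_type", "sample")
    pd.concat([genes, samples], ignore_index=True).to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )


def read_truth(path) -> SimulationTruth:
    """Read a ledger written by :func:`truth_report`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    genes = (
        df[df["record_type"] == "gene"]
        .dropna(axis=1, how="all")
        .drop(columns="record_type")
        .set_index("id")
        .rename_axis("gene_id")
    )
    genes["covariate"] = genes["covariate"].fillna("")
    for col in ("age_sign", "cluster"):
        genes[col] = genes[col].astype(int)
    samples = (
        df[df["record_type"] == "sample"]
        .dropna(axis=1, how="all")
        .drop(columns="record_type")
        .set_index("id")
        .rename_axis("sample_id")
    )
    return SimulationTruth(genes=genes, samples=samples)
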