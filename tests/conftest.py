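import numpy as np
import pandas as pd
import pytest

import txage


@pytest.fixture(scope="session")
def default_cohort():
    """One realistic cohort at the default study conditions (no ageing offset)."""
    return txage.simulate_dataset(txage.SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def null_cohort():
    """Global-null cohort: no planted effects of any kind."""
    cfg = txage.SimulationConfig(
        seed=7,
        n_age_genes=0,
        age_log2fc_per_decade=0.0,
        n_cluster_blocks=0,
        cluster_loading=0.0,
        covariate_effects={},
        ageing_offset_years=0.0,
    )
    return txage.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def null_filtered(null_cohort):
    counts, metadata, annotation, _ = null_cohort
    return txage.filter_genes_for_de(counts, annotation), metadata


@pytest.fixture()
def tiny_counts():
    return txage.CountMatrix(
        pd.DataFrame(
            [[1, 2], [3, 4]], index=["g1", "g2"], columns=["s1", "s2"]
        )
    )


def make_group_metadata(sample_ids, n_a, label_a="HC", label_b="MDD_untreated"):
    """Two-group metadata over the given samples, first n_a in group A."""
    n = len(sample_ids)
    return txage.SampleMetadata(
        pd.DataFrame(
            {
                "group": [label_a] * n_a + [label_b] * (n - n_a),
                "age": np.linspace(25, 50, n),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )


def nb_counts(rng, mu, alpha, size):
    """Direct gamma-Poisson draws used as an independent count oracle."""
    mu = np.broadcast_to(mu, size).astype(float)
    if alpha <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(1.0 / alpha, alpha * mu)
    return rng.poisson(lam)
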