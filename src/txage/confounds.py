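"""Clinical covariate confounder screen.

Each covariate in the panel is tested marginally (no mutual adjustment):
binary covariates by a two-group contrast, continuous ones by comparing the
lowest to the highest quartile. A covariate is flagged as a potential
confounder when it has strictly more than ``flag_threshold`` significant
genes at the adjusted-p cutoff. Marginal screening mirrors the original
two-step design and is a known statistical limitation, not an endorsement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import CountMatrix, SampleMetadata, ValidationError
from .de import ContrastSpec, run_de, significant_genes


@dataclass
class ConfounderReport:
    table: pd.DataFrame                    # index covariate; n_significant, flagged, mode
    skipped: dict[str, str] = field(default_factory=dict)
    alpha: float = 0.01
    flag_threshold: int = 5

    @property
    def flagged(self) -> list[str]:
        return list(self.table.index[self.table["flagged"]])


def screen_covariates(
    counts,
    metadata: SampleMetadata,
    panel,
    alpha: float = 0.01,
    flag_threshold: int = 5,
    cooks_cutoff: float | None = 0.2,
) -> ConfounderReport:
    """Count significant genes per panel covariate and flag confounders.

    ``counts`` should already be filtered for DE. Categorical covariates
    with more than 2 levels and degenerate (constant / too-sparse)
    covariates are skipped with a warning. The report is sorted by
    significant-gene count, descending.
    """
    cm = counts if isinstance(counts, CountMatrix) else CountMatrix(counts)
    rows = []
    skipped: dict[str, str] = {}
    for name in panel:
        try:
            kind = metadata.kind_of(name)
        except KeyError:
            skipped[name] = "no declared kind"
            warnings.warn(f"covariate {name!r} skipped: no declared kind")
            continue
        observed = metadata.table[name].dropna()
        if observed.nunique() < 2:
            skipped[name] = "constant"
            warnings.warn(f"covariate {name!r} skipped: constant")
            continue
        if kind == "categorical" or (kind == "binary" and observed.nunique() > 2):
            if observed.nunique() > 2:
                skipped[name] = ">2 levels"
                warnings.warn(f"covariate {name!r} skipped: >2 levels")
                continue
            kind = "binary"
        mode = "quartile" if kind == "continuous" else "binary"
        try:
            result = run_de(
                cm,
                metadata,
                ContrastSpec(covariate=name, mode=mode, alpha=alpha),
                cooks_cutoff=cooks_cutoff,
            )
        except ValidationError as err:
            skipped[name] = str(err)
            warnings.warn(f"covariate {name!r} skipped: {err}")
            continue
        n_sig = len(significant_genes(result, alpha))
        rows.append((name, n_sig, n_sig > flag_threshold, mode))

    table = pd.DataFrame(
        rows, columns=["covariate", "n_significant", "flagged", "mode"]
    ).set_index("covariate")
    table = table.sort_values(
        ["n_significant", "covariate"], ascending=[False, True]
    )
    return ConfounderReport(
        table=table, skipped=skipped, alpha=alpha, flag_threshold=flag_threshold
    )
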