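"""Shared in-memory containers for the pipeline.

Everything is a thin, validated wrapper around a pandas object. Count and
expression matrices are genes-in-rows, samples-in-columns throughout the
package (the orientation of the usual genes x samples heatmap); sklearn-style
estimators transpose at their own boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The four cohort strata: healthy controls plus the three depression groups
#: (treatment-resistant, treatment-responsive, untreated).
GROUP_LABELS = ("HC", "MDD_resistant", "MDD_responsive", "MDD_untreated")

#: Covariate kinds the metadata reader understands.
COVARIATE_KINDS = ("binary", "continuous", "categorical")


class ValidationError(ValueError):
    """Raised when an input table violates the data model."""


def _check_unique(values, what: str) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class CountMatrix:
    """Raw integer counts, genes x samples.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integers; index = gene ids, columns = sample ids,
        both unique.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene_ids")
        _check_unique(self.counts.columns, "sample_ids")
        values = self.counts.to_numpy()
        if values.size == 0:
            raise ValidationError("empty count matrix")
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("count matrix contains non-numeric entries")
        if not np.isfinite(values).all():
            raise ValidationError("count matrix contains non-finite entries")
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        if not np.allclose(values, np.round(values)):
            g, s = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise ValidationError(
                f"non-integer count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        self.counts = self.counts.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass
class SampleMetadata:
    """Per-sample group label, age and typed covariates.

    ``table`` is indexed by sample_id with at least columns ``group`` and
    ``age``; ``covariate_kinds`` declares every additional column as
    binary, continuous or categorical. Missing values are NaN (written as
    "NA" on disk).
    """

    table: pd.DataFrame
    covariate_kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample_ids")
        if "group" not in self.table.columns:
            raise ValidationError("metadata must have a 'group' column")
        bad = set(self.table["group"].dropna()) - set(GROUP_LABELS)
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        for name, kind in self.covariate_kinds.items():
            if kind not in COVARIATE_KINDS:
                raise ValidationError(f"unknown covariate kind {kind!r} for {name!r}")
            if name not in self.table.columns:
                raise ValidationError(f"declared covariate {name!r} missing from table")
            values = self.table[name].dropna()
            if kind == "binary" and values.nunique() > 2:
                raise ValidationError(
                    f"covariate {name!r} declared binary but has "
                    f"{values.nunique()} observed levels"
                )
            if kind == "continuous":
                numeric = pd.to_numeric(values, errors="coerce")
                if numeric.isna().any():
                    raise ValidationError(
                        f"covariate {name!r} declared continuous but is non-numeric"
                    )
                self.table[name] = pd.to_numeric(self.table[name], errors="coerce")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def kind_of(self, covariate: str) -> str:
        if covariate == "age":
            return "continuous"
        if covariate == "group":
            return "categorical"
        try:
            return self.covariate_kinds[covariate]
        except KeyError:
            raise KeyError(f"covariate {covariate!r} has no declared kind") from None

    def require_age(self) -> None:
        if "age" not in self.table.columns or self.table["age"].isna().any():
            missing = (
                list(self.table.index[self.table["age"].isna()])
                if "age" in self.table.columns
                else self.sample_ids
            )
            raise ValidationError(f"samples missing age: {missing[:5]}")

    def aligned_to(self, counts: CountMatrix) -> "SampleMetadata":
        """Check 1:1 pairing with a count matrix and return metadata in its order."""
        missing = set(counts.sample_ids) - set(self.table.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)[:5]}")
        return SampleMetadata(
            self.table.loc[counts.sample_ids].copy(), dict(self.covariate_kinds)
        )


@dataclass
class GeneAnnotation:
    """gene_id -> biotype table (one row per gene)."""

    table: pd.DataFrame  # index gene_id, column 'biotype'

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "gene_ids")
        if "biotype" not in self.table.columns:
            raise ValidationError("annotation must have a 'biotype' column")

    def biotypes_for(self, gene_ids) -> pd.Series:
        missing = set(gene_ids) - set(self.table.index)
        if missing:
            raise ValidationError(f"genes without annotation: {sorted(missing)[:5]}")
        return self.table.loc[list(gene_ids), "biotype"]


@dataclass
class GeneSetCollection:
    """Ordered mapping set_name -> member gene ids (unique within a set)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(set(members)) != len(members):
                raise ValidationError(f"duplicate members in gene set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()
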