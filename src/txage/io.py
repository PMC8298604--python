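"""Readers and writers for every on-disk format the pipeline touches.

TSV is the interchange format (tab-separated, UTF-8, '.' decimal, "NA" for
missing). Counts may alternatively arrive as MatrixMarket triplets with
sidecar gene/sample name files. Gene sets use the standard GMT layout.
Readers never reorder genes or samples.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datamodel import (
    CountMatrix,
    GeneAnnotation,
    GeneSetCollection,
    SampleMetadata,
    ValidationError,
)

NA_VALUES = ["NA"]


def read_counts(path, format: str = "tsv") -> CountMatrix:
    """Read a genes x samples count matrix.

    ``format='tsv'``: header row of sample ids, first column gene ids.
    ``format='mtx'``: MatrixMarket triplet at ``path`` plus sidecar files
    ``<path stem>.genes.txt`` and ``<path stem>.samples.txt`` holding one
    id per line (rows = genes, columns = samples).
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=[], keep_default_na=False)
        for col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                row = df.index[vals.isna()][0]
                raise ValidationError(
                    f"non-numeric count at gene {row!r}, sample {col!r} in {path}"
                )
            df[col] = vals
        return CountMatrix(df)
    if format == "mtx":
        matrix = scipy.io.mmread(path)
        if scipy.sparse.issparse(matrix):
            matrix = matrix.toarray()
        stem = path.with_suffix("") if path.suffix == ".mtx" else path
        genes = Path(f"{stem}.genes.txt").read_text().split()
        samples = Path(f"{stem}.samples.txt").read_text().split()
        df = pd.DataFrame(np.asarray(matrix), index=genes, columns=samples)
        return CountMatrix(df)
    raise ValueError(f"unknown counts format {format!r}")


def write_counts(counts: CountMatrix, path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        counts.counts.to_csv(path, sep="\t", index_label="gene_id")
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(counts.counts.to_numpy()))
        stem = path.with_suffix("") if path.suffix == ".mtx" else path
        Path(f"{stem}.genes.txt").write_text("\n".join(counts.gene_ids) + "\n")
        Path(f"{stem}.samples.txt").write_text("\n".join(counts.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown counts format {format!r}")


def read_metadata(path, covariate_spec: dict[str, str] | None = None) -> SampleMetadata:
    """Read a sample metadata TSV (sample_id, group, age, covariates).

    ``covariate_spec`` maps covariate column names to their declared kind
    (binary / continuous / categorical); undeclared extra columns are kept
    but unusable in contrasts until declared.
    """
    df = pd.read_csv(
        Path(path), sep="\t", index_col="sample_id",
        na_values=NA_VALUES, keep_default_na=False,
    )
    if "age" in df.columns:
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
    return SampleMetadata(df, dict(covariate_spec or {}))


def write_metadata(metadata: SampleMetadata, path) -> None:
    metadata.table.to_csv(Path(path), sep="\t", index_label="sample_id", na_rep="NA")


def read_annotation(path) -> GeneAnnotation:
    df = pd.read_csv(Path(path), sep="\t", index_col="gene_id",
                     na_values=NA_VALUES, keep_default_na=False)
    return GeneAnnotation(df)


def write_annotation(annotation: GeneAnnotation, path) -> None:
    annotation.table.to_csv(Path(path), sep="\t", index_label="gene_id")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file: name TAB description TAB member ids.

    Duplicate members within a set are dropped with a warning (first
    occurrence kept); a line with fewer than three fields is an error.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(Path(path)) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"GMT line {lineno} has {len(fields)} fields (expected >= 3)"
                )
            name, desc, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                warnings.warn(
                    f"gene set {name!r}: {len(members) - len(unique)} duplicate "
                    "members dropped"
                )
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(Path(path), "w") as handle:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            handle.write("\t".join([name, desc, *members]) + "\n")


def write_table(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    """Write a result table as TSV with NA for missing values."""
    df.to_csv(Path(path), sep="\t", index_label=index_label,
              index=index_label is not None, na_rep="NA")
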