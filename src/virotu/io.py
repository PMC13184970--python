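"""Tabular I/O for every artifact the pipeline consumes or emits.

Conventions
-----------
* Abundance matrices: TSV, first column vOTU ids, header row sample ids,
  values are normalized relative abundances per metagenome gigabase.
* Sample metadata: CSV with columns ``sample_id``, ``ecosystem``
  (``lagoon`` or ``open_sea``), ``date`` (ISO-8601), ``total_bases``
  (quality-trimmed bp); any further columns are carried through as
  environmental variables (temperature, salinity, Iz_percent, nutrient
  concentrations, cell counts, ...).
* Annotations and pairwise contig similarities: TSV.

All downstream modules consume the objects returned here (DataFrames with
fixed orientations) and never touch files themselves.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("virotu")

ECOSYSTEM_LABELS = ("lagoon", "open_sea")

#: columns required in a sample-metadata table; everything else is treated
#: as an environmental variable.
METADATA_REQUIRED = ("sample_id", "ecosystem", "date", "total_bases")

SIMILARITY_REQUIRED = ("contig_a", "contig_b", "ani_percent", "aligned_fraction_shorter")


class SchemaError(ValueError):
    """A table does not conform to the expected schema."""


def read_abundance_matrix(path) -> pd.DataFrame:
    """Read a vOTU × sample abundance matrix from TSV.

    Returns a DataFrame with vOTU ids as the index and sample ids as
    columns. Values must be numeric and non-negative; duplicated vOTU or
    sample ids are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise SchemaError(f"duplicated vOTU id {dup!r} in {path}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise SchemaError(f"duplicated sample id {dup!r} in {path}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise SchemaError(f"non-numeric cell in abundance matrix {path}: {exc}") from exc
    if (values.to_numpy() < 0).any():
        row, col = np.argwhere(values.to_numpy() < 0)[0]
        raise SchemaError(
            f"negative abundance at vOTU {values.index[row]!r}, "
            f"sample {values.columns[col]!r}"
        )
    logger.info("read abundance matrix %s: %d vOTUs x %d samples", path, *values.shape)
    return values


def write_abundance_matrix(matrix: pd.DataFrame, path, producer: str = "virotu") -> None:
    """Write a vOTU × sample matrix as TSV with a producer header comment."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# produced by {producer}\n")
        matrix.to_csv(fh, sep="\t", index_label="votu_id")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata from CSV, indexed by ``sample_id``.

    Validates ecosystem labels, date parseability, positive ``total_bases``
    and sample-id uniqueness; unknown columns are kept as environmental
    variables.
    """
    df = pd.read_csv(path, comment="#")
    for col in METADATA_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"metadata {path} is missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SchemaError(f"duplicated sample id {dup!r}")
    bad = set(df["ecosystem"]) - set(ECOSYSTEM_LABELS)
    if bad:
        raise SchemaError(
            f"unknown ecosystem label(s) {sorted(bad)}; expected {ECOSYSTEM_LABELS}"
        )
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    if (df["total_bases"] <= 0).any():
        raise SchemaError("total_bases must be > 0 for every sample")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    logger.info("read metadata %s: %d samples, %d env variables",
                path, len(df), df.shape[1] - 3)
    return df


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index_label="sample_id")


def env_columns(metadata: pd.DataFrame) -> list[str]:
    """Names of the environmental-variable columns of a metadata table."""
    return [c for c in metadata.columns if c not in ("ecosystem", "date", "total_bases")]


def read_annotations(path) -> pd.DataFrame:
    """Read a vOTU/contig annotation table from TSV.

    An empty file (header only, or zero bytes) yields an empty DataFrame.
    ``lifestyle_probability``, if present, must lie in [0, 1].
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
    if "lifestyle_probability" in df.columns:
        probs = df["lifestyle_probability"].dropna()
        if ((probs < 0) | (probs > 1)).any():
            raise SchemaError("lifestyle_probability outside [0, 1]")
    logger.info("read annotations %s: %d rows", path, len(df))
    return df


def write_annotations(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, sep="\t", index=False)


def read_pairwise_similarity(path) -> pd.DataFrame:
    """Read pairwise contig similarities (ANI %, aligned fraction) from TSV."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in SIMILARITY_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"similarity table {path} is missing column {col!r}")
    if ((df["ani_percent"] < 0) | (df["ani_percent"] > 100)).any():
        raise SchemaError("ani_percent outside [0, 100]")
    if ((df["aligned_fraction_shorter"] < 0) | (df["aligned_fraction_shorter"] > 1)).any():
        raise SchemaError("aligned_fraction_shorter outside [0, 1]")
    logger.info("read similarities %s: %d pairs", path, len(df))
    return df


def write_pairwise_similarity(similarities: pd.DataFrame, path) -> None:
    similarities.to_csv(path, sep="\t", index=False)


def read_coverage_summary(path) -> pd.DataFrame:
    """Read a per-contig, per-sample coverage summary table from TSV.

    Required columns: contig_id, sample_id, trimmed_mean_depth, breadth,
    contig_length.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ("contig_id", "sample_id", "trimmed_mean_depth", "breadth", "contig_length")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"coverage summary {path} is missing column {col!r}")
    if ((df["breadth"] < 0) | (df["breadth"] > 1)).any():
        raise SchemaError("breadth outside [0, 1]")
    if (df["trimmed_mean_depth"] < 0).any():
        raise SchemaError("trimmed_mean_depth must be >= 0")
    return df


def write_coverage_summary(coverage: pd.DataFrame, path) -> None:
    coverage.to_csv(path, sep="\t", index=False)
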