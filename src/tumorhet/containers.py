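"""Core in-memory containers and table schemas.

Matrices are pandas DataFrames (genes as rows, samples as columns) with a
thin wrapper recording the measurement scale; tabular inputs (variants,
copy-number segments, subclone clusters, sample sheets) are plain
DataFrames with declared column schemas, validated on entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Somatic single-nucleotide variant table, one row per variant per piece.
#: Coordinates are 1-based; ``alt_fwd``/``alt_rev`` are strand-resolved alt
#: read counts, ``control_alt_reads`` the alt support in the matched normal.
VARIANT_COLUMNS = [
    "tumor_id",
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "vaf",
    "alt_fwd",
    "alt_rev",
    "in_cosmic",
    "control_alt_reads",
]

#: Absolute copy-number segments, 1-based inclusive intervals per sample.
SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "abs_cn"]

#: Gene intervals, 1-based inclusive.
GENE_COLUMNS = ["gene_id", "chrom", "start", "end"]

#: Subclone clusters in long form: one row per (cluster, sample) with the
#: cluster's mutation count and mean cellular prevalence in that sample.
CLUSTER_COLUMNS = ["tumor_id", "cluster_id", "n_mutations", "sample_id", "prevalence"]

#: Piece-to-tumor mapping with per-sample purity/ploidy and clinical flags.
SAMPLESHEET_COLUMNS = ["sample_id", "tumor_id", "purity", "ploidy", "relapse5y"]

_NUCLEOTIDES = frozenset("ACGT")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with an explicit scale.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with one column per sample.
    scale
        ``"counts"`` for raw (nonnegative) counts, ``"log"`` for log2
        expression values.
    """

    data: pd.DataFrame
    scale: str = "counts"

    def __post_init__(self) -> None:
        if self.scale not in ("counts", "log"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        if self.scale == "counts" and (self.data.to_numpy() < 0).any():
            raise ValueError("raw counts must be nonnegative")

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class CentroidSet:
    """Signature-gene centroids, one column per class.

    ``centroids`` is a DataFrame indexed by signature gene id; column order
    is the declared tie-break order for classification.
    """

    centroids: pd.DataFrame

    def __post_init__(self) -> None:
        if self.centroids.index.duplicated().any():
            raise ValueError("duplicate signature gene ids in centroid set")
        if self.centroids.columns.duplicated().any():
            raise ValueError("duplicate class names in centroid set")

    @property
    def signature_gene_ids(self) -> list:
        return list(self.centroids.index)

    @property
    def class_names(self) -> list:
        return list(self.centroids.columns)


def _as_frame(expr) -> pd.DataFrame:
    """Accept an ExpressionMatrix or a bare DataFrame."""
    if isinstance(expr, ExpressionMatrix):
        return expr.data
    return expr


def validate_variants(variants: pd.DataFrame) -> pd.DataFrame:
    """Check a variant table against the declared schema.

    Verifies required columns, single-nucleotide ref/alt with ref != alt,
    VAF in [0, 1] and nonnegative read counts.  Returns the table unchanged.
    """
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    if len(variants) == 0:
        return variants
    ref = variants["ref"].astype(str)
    alt = variants["alt"].astype(str)
    bad = ~(ref.isin(_NUCLEOTIDES) & alt.isin(_NUCLEOTIDES))
    if bad.any():
        raise ValueError("only single-nucleotide substitutions are supported")
    if (ref == alt).any():
        raise ValueError("ref and alt alleles must differ")
    vaf = variants["vaf"].to_numpy(dtype=float)
    if np.any((vaf < 0) | (vaf > 1)):
        raise ValueError("VAF must lie in [0, 1]")
    for col in ("alt_fwd", "alt_rev", "control_alt_reads"):
        if (variants[col].to_numpy() < 0).any():
            raise ValueError(f"{col} must be nonnegative")
    return variants


def validate_intervals(table: pd.DataFrame, what: str = "interval") -> pd.DataFrame:
    """Raise if any 1-based inclusive interval has start > end."""
    bad = table["start"] > table["end"]
    if bad.any():
        row = table[bad].iloc[0]
        raise ValueError(
            f"malformed {what}: start {row['start']} > end {row['end']} "
            f"on {row['chrom']}"
        )
    return table
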