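"""Readers and writers for the pipeline's on-disk formats.

Plain-text formats throughout: counts and sample sheets as TSV, variant
tables as TSV or minimal VCF (INFO keys VAF, ALT_F, ALT_R, COSMIC,
CTRL_ALT; FILTER holds the removal reason codes), copy-number segments
as BED-like TSV with 1-based inclusive coordinates, subclone clusters as
long-form TSV, ground truth as JSON.  VCF reading goes through pysam.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import ExpressionMatrix, CentroidSet, validate_variants
from .synthetic import GENOME_CONTIGS, GroundTruth

__all__ = [
    "write_counts_tsv",
    "read_counts_tsv",
    "write_sample_sheet",
    "read_sample_sheet",
    "write_centroids_tsv",
    "read_centroids_tsv",
    "write_variants_tsv",
    "read_variants_tsv",
    "write_variants_vcf",
    "read_variants_vcf",
    "write_segments_tsv",
    "read_segments_tsv",
    "write_clusters_tsv",
    "read_clusters_tsv",
    "write_truth_json",
    "read_truth_json",
]


def write_counts_tsv(counts, path) -> None:
    df = counts.data if isinstance(counts, ExpressionMatrix) else counts
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path, scale: str = "counts") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    df.index.name = None
    return ExpressionMatrix(df, scale=scale)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_centroids_tsv(centroids: CentroidSet, path) -> None:
    centroids.centroids.to_csv(path, sep="\t", index_label="gene_id")


def read_centroids_tsv(path) -> CentroidSet:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    df.index.name = None
    return CentroidSet(df)


def write_variants_tsv(variants: pd.DataFrame, path) -> None:
    variants.to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["in_cosmic"] = df["in_cosmic"].astype(bool)
    return validate_variants(df)


def write_segments_tsv(segments: pd.DataFrame, path) -> None:
    segments.to_csv(path, sep="\t", index=False)


def read_segments_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_clusters_tsv(clusters: pd.DataFrame, path) -> None:
    clusters.to_csv(path, sep="\t", index=False)


def read_clusters_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


_VCF_HEADER_LINES = [
    '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">',
    '##INFO=<ID=ALT_F,Number=1,Type=Integer,Description="Alt reads, forward strand">',
    '##INFO=<ID=ALT_R,Number=1,Type=Integer,Description="Alt reads, reverse strand">',
    '##INFO=<ID=COSMIC,Number=0,Type=Flag,Description="Reported in COSMIC">',
    '##INFO=<ID=CTRL_ALT,Number=1,Type=Integer,Description="Alt reads in matched control">',
    '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Tumor piece id">',
    '##INFO=<ID=TUMOR,Number=1,Type=String,Description="Tumor id">',
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Overlapping gene id">',
    '##FILTER=<ID=ffpe_private_cT,Description="Private C>T/G>A below VAF 0.15, no rescue">',
    '##FILTER=<ID=shared_ctrl_support,Description="Shared low-VAF variant with control alt support">',
]


def write_variants_vcf(variants: pd.DataFrame, path, removed: pd.DataFrame | None = None) -> None:
    """Write variants (optionally plus removed ones) as a minimal VCF.

    Kept variants get FILTER ``PASS``; rows of ``removed`` carry their
    ``reason`` code in FILTER.  One record per variant per piece, the
    piece encoded in INFO/SAMPLE.
    """
    frames = [variants.assign(vcf_filter="PASS")]
    if removed is not None and len(removed):
        frames.append(removed.assign(vcf_filter=removed["reason"]))
    allv = pd.concat(frames, ignore_index=True)
    chrom_order = {c: i for i, c in enumerate(GENOME_CONTIGS)}
    allv = allv.sort_values(
        ["chrom", "pos", "sample_id"],
        key=lambda s: s.map(chrom_order).fillna(-1) if s.name == "chrom" else s,
    )
    has_gene = "gene_id" in allv.columns
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        seen = set()
        for c in allv["chrom"]:
            if c not in seen:
                seen.add(c)
                length = GENOME_CONTIGS.get(c)
                fh.write(
                    f"##contig=<ID={c},length={length}>\n" if length else f"##contig=<ID={c}>\n"
                )
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in allv.itertuples():
            info = (
                f"VAF={row.vaf:.6g};ALT_F={row.alt_fwd};ALT_R={row.alt_rev};"
                f"CTRL_ALT={row.control_alt_reads};SAMPLE={row.sample_id};TUMOR={row.tumor_id}"
            )
            if row.in_cosmic:
                info += ";COSMIC"
            if has_gene and isinstance(row.gene_id, str):
                info += f";GENE={row.gene_id}"
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t{row.vcf_filter}\t{info}\n"
            )


def read_variants_vcf(path) -> pd.DataFrame:
    """Read a minimal VCF back into the variant table schema.

    The returned table includes a ``filter`` column (``PASS`` or a
    removal reason code) and ``gene_id`` where annotated.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            filters = list(rec.filter.keys())
            rows.append(
                {
                    "tumor_id": info.get("TUMOR"),
                    "sample_id": info.get("SAMPLE"),
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "vaf": float(info.get("VAF")),
                    "alt_fwd": int(info.get("ALT_F")),
                    "alt_rev": int(info.get("ALT_R")),
                    "in_cosmic": bool(info.get("COSMIC", False)),
                    "control_alt_reads": int(info.get("CTRL_ALT")),
                    "gene_id": info.get("GENE"),
                    "filter": filters[0] if filters else "PASS",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
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
            "gene_id",
            "filter",
        ],
    )


def _stringify_keys(d: dict) -> dict:
    return {"|".join(map(str, k)) if isinstance(k, tuple) else str(k): v for k, v in d.items()}


def write_truth_json(truth: GroundTruth, path) -> None:
    payload = {
        "subtype": truth.subtype,
        "grade": truth.grade,
        "discordant": truth.discordant,
        "variant_origin": _stringify_keys(truth.variant_origin),
        "cluster_prevalence": _stringify_keys(truth.cluster_prevalence),
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_truth_json(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())

    def _untuple(d, n):
        out = {}
        for k, v in d.items():
            parts = k.split("|")
            parts = [int(p) if p.isdigit() else p for p in parts]
            out[tuple(parts) if n > 1 else parts[0]] = v
        return out

    return GroundTruth(
        subtype=payload["subtype"],
        grade=payload["grade"],
        discordant=payload["discordant"],
        variant_origin=_untuple(payload["variant_origin"], 5),
        cluster_prevalence=_untuple(payload["cluster_prevalence"], 2),
    )
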