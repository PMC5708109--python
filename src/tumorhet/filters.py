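"""Genomic filtering rules for multi-region FFPE tumor cohorts.

Implements the FFPE deamination-artifact filter with its COSMIC and
strand-support rescue rules, gene-level absolute copy-number assignment
by maximal segment overlap with ploidy-relative amplification/deletion
calls, purity correction of variant allele frequencies, and
mutation-count / cellular-prevalence filtering of subclone clusters.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import (
    CLUSTER_COLUMNS,
    GENE_COLUMNS,
    SEGMENT_COLUMNS,
    validate_intervals,
    validate_variants,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FFPE_PRIVATE_REASON",
    "SHARED_CTRL_REASON",
    "ffpe_artifact_filter",
    "assign_gene_copy_number",
    "call_amplification_deletion",
    "purity_adjust_vaf",
    "filter_subclone_clusters",
    "MIN_CLUSTER_MUTATIONS",
    "MIN_CELLULAR_PREVALENCE",
]

#: Reason code: private C>T/G>A below the VAF threshold, no rescue.
FFPE_PRIVATE_REASON = "ffpe_private_cT"
#: Reason code: shared low-VAF variant with alt support in the control.
SHARED_CTRL_REASON = "shared_ctrl_support"

#: VAF threshold (strict <) of both artifact rules.
FFPE_VAF_THRESHOLD = 0.15
#: Minimum mutations for a subclone cluster to be considered at all.
MIN_CLUSTER_MUTATIONS = 10
#: Minimum mean cellular prevalence (inclusive) for a cluster in a sample.
MIN_CELLULAR_PREVALENCE = 0.05


def ffpe_artifact_filter(
    variants: pd.DataFrame,
    vaf_threshold: float = FFPE_VAF_THRESHOLD,
    sample_sheet: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove likely FFPE deamination artifacts from a somatic variant table.

    "Private" means the identical substitution (chrom, pos, ref, alt) is
    observed in exactly one piece of its tumor; "shared" in two or more.

    Rule 1 (artifact): remove a variant iff it is a C>T or G>A change,
    private, with VAF strictly below ``vaf_threshold`` — unless rescued
    by COSMIC membership or by >= 2 alt reads on *each* strand.

    Rule 2 (control support): remove a variant iff it is shared, with VAF
    strictly below the threshold, and the matched control carries any alt
    reads.  No rescue applies.

    Returns ``(kept, removed)``; ``removed`` carries a ``reason`` column
    with the machine-readable rule code.
    """
    validate_variants(variants)
    if sample_sheet is not None:
        known = set(sample_sheet["sample_id"])
        unknown = set(variants["sample_id"]) - known
        if unknown:
            raise ValueError(f"variant sample ids absent from sample sheet: {sorted(unknown)}")
    if len(variants) == 0:
        removed = variants.copy()
        removed["reason"] = pd.Series(dtype=object)
        return variants.copy(), removed

    df = variants
    # pieces of a tumor carrying the identical substitution
    key_cols = ["tumor_id", "chrom", "pos", "ref", "alt"]
    n_pieces = df.groupby(key_cols)["sample_id"].transform("nunique")
    private = n_pieces == 1
    shared = n_pieces >= 2

    sub = df["ref"].astype(str) + ">" + df["alt"].astype(str)
    deamination = sub.isin(["C>T", "G>A"])
    low_vaf = df["vaf"] < vaf_threshold
    strand_rescue = (df["alt_fwd"] >= 2) & (df["alt_rev"] >= 2)
    cosmic_rescue = df["in_cosmic"].astype(bool)

    rule1 = deamination & private & low_vaf & ~cosmic_rescue & ~strand_rescue
    rule2 = shared & low_vaf & (df["control_alt_reads"] >= 1)

    reason = pd.Series(pd.NA, index=df.index, dtype=object)
    reason[rule2] = SHARED_CTRL_REASON
    reason[rule1] = FFPE_PRIVATE_REASON  # rule 1 takes precedence (disjoint anyway)

    drop = rule1 | rule2
    kept = df[~drop].copy()
    removed = df[drop].copy()
    removed["reason"] = reason[drop]
    return kept, removed


def assign_gene_copy_number(
    segments: pd.DataFrame, genes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each gene the copy number of its most-overlapping segment.

    Overlap is computed on 1-based inclusive intervals:
    ``max(0, min(ends) - max(starts) + 1)``.  A gene with zero overlap
    against every segment of a sample gets a missing value.  Equal
    maximal overlaps are broken toward the segment with the smaller start
    coordinate, with the tie flagged.

    Returns ``(cn, tie)``: two genes x samples DataFrames, absolute copy
    number (NaN = no overlap) and tie-break flags.
    """
    for col in SEGMENT_COLUMNS:
        if col not in segments.columns:
            raise ValueError(f"segment table missing column {col!r}")
    for col in GENE_COLUMNS:
        if col not in genes.columns:
            raise ValueError(f"gene table missing column {col!r}")
    validate_intervals(segments, "segment")
    validate_intervals(genes, "gene interval")
    if (segments["abs_cn"] < 0).any():
        raise ValueError("absolute copy number must be nonnegative")

    samples = list(pd.unique(segments["sample_id"]))
    gene_ids = list(genes["gene_id"])
    cn = pd.DataFrame(np.nan, index=gene_ids, columns=samples)
    tie = pd.DataFrame(False, index=gene_ids, columns=samples)

    for sample, seg_s in segments.groupby("sample_id", sort=False):
        _check_nonoverlap(seg_s, sample)
        for chrom, seg_c in seg_s.groupby("chrom", sort=False):
            gen_c = genes[genes["chrom"] == chrom]
            if gen_c.empty:
                continue
            s_start = seg_c["start"].to_numpy()
            s_end = seg_c["end"].to_numpy()
            s_cn = seg_c["abs_cn"].to_numpy(dtype=float)
            g_start = gen_c["start"].to_numpy()[:, None]
            g_end = gen_c["end"].to_numpy()[:, None]
            ov = np.maximum(
                0, np.minimum(g_end, s_end[None, :]) - np.maximum(g_start, s_start[None, :]) + 1
            )
            best = ov.max(axis=1)
            hit = best > 0
            if not hit.any():
                continue
            # tie-break: among maximal overlaps, smallest segment start
            for gi, gene_id in zip(np.where(hit)[0], gen_c["gene_id"].to_numpy()[hit]):
                winners = np.where(ov[gi] == best[gi])[0]
                if len(winners) > 1:
                    winners = winners[np.argsort(s_start[winners], kind="stable")]
                    tie.loc[gene_id, sample] = True
                cn.loc[gene_id, sample] = s_cn[winners[0]]
    return cn, tie


def _check_nonoverlap(segments: pd.DataFrame, sample) -> None:
    for _, seg_c in segments.groupby("chrom", sort=False):
        ordered = seg_c.sort_values("start")
        starts = ordered["start"].to_numpy()
        ends = ordered["end"].to_numpy()
        if np.any(starts[1:] <= ends[:-1]):
            raise ValueError(f"overlapping segments for sample {sample!r}")


def call_amplification_deletion(gene_cn, ploidy: float):
    """Ploidy-relative amplification/deletion call.

    ``amplified`` iff cn > 1.5 x ploidy (strict), ``deleted`` iff
    cn < 0.5 x ploidy (strict), otherwise ``neutral``.  Missing copy
    numbers (NaN) yield a missing call.  Accepts a scalar or array.
    """
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    cn = np.asarray(gene_cn, dtype=float)
    if np.any(cn[~np.isnan(cn)] < 0):
        raise ValueError("copy number must be nonnegative")
    call = np.where(cn > 1.5 * ploidy, "amplified", np.where(cn < 0.5 * ploidy, "deleted", "neutral"))
    call = np.where(np.isnan(cn), None, call)
    if cn.ndim == 0:
        return call.item()
    return call


def purity_adjust_vaf(vaf, purity):
    """Purity-corrected VAF: vaf / purity, capped at 1.

    Returns ``(adjusted, overflow)`` where ``overflow`` flags quotients
    that exceeded 1 before capping (frequencies above 1 are biologically
    impossible).  Accepts scalars or arrays; purity must be in (0, 1].
    """
    p = np.asarray(purity, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("purity must lie in (0, 1]")
    v = np.asarray(vaf, dtype=float)
    q = v / p
    overflow = q > 1.0
    adj = np.minimum(q, 1.0)
    if adj.ndim == 0:
        return float(adj), bool(overflow)
    return adj, overflow


def filter_subclone_clusters(
    clusters: pd.DataFrame,
    min_mutations: int = MIN_CLUSTER_MUTATIONS,
    min_prevalence: float = MIN_CELLULAR_PREVALENCE,
) -> pd.DataFrame:
    """Filter subclone clusters by size and per-sample cellular prevalence.

    A cluster is dropped in every sample iff it has fewer than
    ``min_mutations`` mutations; otherwise it is retained in sample *s*
    iff its mean cellular prevalence in *s* is >= ``min_prevalence``
    (both bounds inclusive on the retained side of >=).  A missing
    prevalence entry counts as 0 and is logged.

    Input is the long-form cluster table (one row per cluster x sample);
    output is the same table completed to all cluster x sample pairs
    within each tumor, with a boolean ``retained`` column.
    """
    for col in CLUSTER_COLUMNS:
        if col not in clusters.columns:
            raise ValueError(f"cluster table missing column {col!r}")
    bad = (clusters["prevalence"] < 0) | (clusters["prevalence"] > 1)
    if bad.any():
        raise ValueError("cellular prevalence must lie in [0, 1]")

    pieces = []
    for (tumor, cluster), rows in clusters.groupby(["tumor_id", "cluster_id"], sort=False):
        tumor_samples = pd.unique(clusters.loc[clusters["tumor_id"] == tumor, "sample_id"])
        n_mut = int(rows["n_mutations"].iloc[0])
        prev = dict(zip(rows["sample_id"], rows["prevalence"]))
        for s in tumor_samples:
            if s not in prev:
                logger.warning(
                    "cluster %s has no prevalence entry for sample %s; treating as 0",
                    cluster,
                    s,
                )
            p = float(prev.get(s, 0.0))
            pieces.append(
                {
                    "tumor_id": tumor,
                    "cluster_id": cluster,
                    "n_mutations": n_mut,
                    "sample_id": s,
                    "prevalence": p,
                    "retained": n_mut >= min_mutations and p >= min_prevalence,
                }
            )
    return pd.DataFrame(
        pieces, columns=CLUSTER_COLUMNS + ["retained"]
    )
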