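"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately re-state the filtering rules as
plain per-row conditionals, independent of the vectorized package code
they are used to check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tumorhet import (
    CentroidSet,
    CohortConfig,
    classify_subtype,
    log_cpm,
    simulate_expression,
    subgroup_gene_center,
    tmm_factors,
)

# ---------------------------------------------------------------- oracles


def brute_force_ffpe(variants: pd.DataFrame, vaf_threshold: float = 0.15):
    """Plain-Python restatement of the FFPE artifact filter rules."""
    records = variants.to_dict(orient="index")
    carriers: dict[tuple, set] = {}
    for row in records.values():
        key = (row["tumor_id"], row["chrom"], row["pos"], row["ref"], row["alt"])
        carriers.setdefault(key, set()).add(row["sample_id"])
    reasons = {}
    for i, row in records.items():
        key = (row["tumor_id"], row["chrom"], row["pos"], row["ref"], row["alt"])
        n_pieces = len(carriers[key])
        sub = f"{row['ref']}>{row['alt']}"
        if n_pieces == 1:
            if (
                sub in ("C>T", "G>A")
                and row["vaf"] < vaf_threshold
                and not bool(row["in_cosmic"])
                and not (row["alt_fwd"] >= 2 and row["alt_rev"] >= 2)
            ):
                reasons[i] = "ffpe_private_cT"
        else:
            if row["vaf"] < vaf_threshold and row["control_alt_reads"] >= 1:
                reasons[i] = "shared_ctrl_support"
    return reasons


def brute_force_gene_cn(segments: pd.DataFrame, genes: pd.DataFrame):
    """All-pairs maximal-overlap gene copy-number assignment."""
    out = {}
    seg_records = segments.to_dict(orient="records")
    gene_records = genes.to_dict(orient="records")
    for sample in segments["sample_id"].unique():
        seg_s = [s for s in seg_records if s["sample_id"] == sample]
        for g in gene_records:
            best_len, best_cn, best_start, n_best = 0, np.nan, None, 0
            for s in seg_s:
                if s["chrom"] != g["chrom"]:
                    continue
                ov = max(0, min(g["end"], s["end"]) - max(g["start"], s["start"]) + 1)
                if ov == 0:
                    continue
                if ov > best_len:
                    best_len, best_cn, best_start, n_best = ov, s["abs_cn"], s["start"], 1
                elif ov == best_len:
                    n_best += 1
                    if s["start"] < best_start:
                        best_cn, best_start = s["abs_cn"], s["start"]
            out[(g["gene_id"], sample)] = (best_cn, n_best > 1)
    return out


def brute_force_cluster_filter(clusters: pd.DataFrame):
    """Per (cluster, sample) retention by plain conditionals."""
    out = {}
    for tumor in clusters["tumor_id"].unique():
        sub = clusters[clusters["tumor_id"] == tumor]
        samples = sub["sample_id"].unique()
        for cluster in sub["cluster_id"].unique():
            rows = sub[sub["cluster_id"] == cluster]
            n_mut = rows["n_mutations"].iloc[0]
            for s in samples:
                entry = rows[rows["sample_id"] == s]
                prev = float(entry["prevalence"].iloc[0]) if len(entry) else 0.0
                out[(tumor, cluster, s)] = n_mut >= 10 and prev >= 0.05
    return out


def random_variant_table(rng: np.random.Generator, n_variants=None, n_pieces=None):
    """Random variant table exercising every branch of the filter rules."""
    if n_variants is None:
        n_variants = int(rng.integers(50, 201))
    if n_pieces is None:
        n_pieces = int(rng.integers(2, 7))
    pieces = [f"p{i}" for i in range(n_pieces)]
    bases = np.array(list("ACGT"))
    rows = []
    for v in range(n_variants):
        ref = bases[rng.integers(4)]
        alt = rng.choice([b for b in bases if b != ref])
        # bias toward deamination changes so rule 1 fires often
        if rng.random() < 0.5:
            ref, alt = ("C", "T") if rng.random() < 0.5 else ("G", "A")
        carriers = rng.choice(pieces, size=int(rng.integers(1, n_pieces + 1)), replace=False)
        cosmic = bool(rng.random() < 0.3)
        for p in carriers:
            fwd, rev = int(rng.integers(0, 5)), int(rng.integers(0, 5))
            rows.append(
                {
                    "tumor_id": "T1",
                    "sample_id": p,
                    "chrom": "sim1",
                    "pos": 1000 + v,
                    "ref": ref,
                    "alt": alt,
                    # cluster near the 0.15 threshold
                    "vaf": float(np.clip(rng.normal(0.15, 0.1), 0.0, 1.0)),
                    "alt_fwd": fwd,
                    "alt_rev": rev,
                    "in_cosmic": cosmic,
                    "control_alt_reads": int(rng.integers(0, 3)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- pipeline


def pipeline_subtype_labels(cohort, method: str = "spearman") -> pd.Series:
    """Counts -> TMM -> log-CPM -> full-cohort gene centering -> classify."""
    factors = tmm_factors(cohort.counts)
    lc = log_cpm(cohort.counts, factors)
    centered = subgroup_gene_center(lc, lc)
    cen = cohort.centroids.centroids
    centered_centroids = CentroidSet(cen.sub(cen.mean(axis=1), axis=0))
    return classify_subtype(centered, centered_centroids, method=method)["subtype"]


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(n_tumors=4, n_genes=300, library_size_range=(50_000, 100_000), seed=11)


@pytest.fixture(scope="session")
def small_expression(small_config):
    return simulate_expression(small_config)


@pytest.fixture(scope="session")
def small_genomic(small_config):
    from tumorhet import simulate_genomic

    return simulate_genomic(small_config)
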