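"""Synthetic multi-region tumor cohorts with full ground truth.

Generates paired expression and genomic data for multi-piece tumors so
that every downstream stage — normalization, subtype/grade calling,
artifact filtering, copy-number calling, subclone summaries and the
concordance report — can be exercised and scored against known truth.

Expression: each tumor draws a molecular subtype; each piece's signature
gene log2 expression is the subtype centroid plus tumor-level noise plus
piece-level noise (intra-tumor noise is kept well below inter-tumor
noise, as observed in multi-region cohorts); a configurable fraction of
tumors is made discordant by redrawing exactly one piece from a
different subtype.  Counts arise by exponentiating the log means and
multinomial sampling to a drawn library size.

Genomics: clonal mutations shared by all pieces of a tumor; subclones
confined to subsets of pieces at drawn cellular prevalences; expected
VAF = purity x prevalence / 2 (heterozygous diploid model, matching the
plain purity-division used downstream) with binomially sampled read
support; low-VAF C>T/G>A artifacts injected privately per piece to mimic
FFPE deamination; copy-number segments tiling a small artificial genome
with occasional ploidy-relative gains and losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CentroidSet, ExpressionMatrix

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "ExpressionCohort",
    "GenomicCohort",
    "simulate_expression",
    "simulate_genomic",
    "inject_ffpe_artifacts",
    "GENOME_CONTIGS",
]

#: Artificial genome used for simulated variants and segments
#: (1-based inclusive coordinates; declared in written VCF headers).
GENOME_CONTIGS = {"sim1": 50_000_000, "sim2": 40_000_000, "sim3": 30_000_000}

_SUBTYPES = ("LumA", "LumB", "HER2", "Basal", "Normal")


@dataclass
class CohortConfig:
    """Parameters of the synthetic multi-region cohort.

    Expression noise is in log2 units.  ``pieces_per_tumor`` is an
    inclusive integer range; multi-region analysis needs >= 2 pieces.
    ``artifact_rate`` is the expected number of injected FFPE artifacts
    per piece; injected artifacts have VAF uniform below
    ``artifact_vaf_max``.
    """

    n_tumors: int = 12
    pieces_per_tumor: tuple[int, int] = (2, 6)
    n_genes: int = 1000
    n_signature_genes: int = 50
    subtype_labels: tuple[str, ...] = _SUBTYPES
    n_grade_genes: int = 30
    inter_tumor_sd: float = 1.2
    intra_tumor_sd: float = 0.15
    centroid_sd: float = 1.5
    grade_effect: float = 1.0
    background_mean: float = 6.0
    background_sd: float = 1.5
    library_size_range: tuple[int, int] = (200_000, 500_000)
    discordant_tumor_fraction: float = 1.0 / 12.0
    n_clonal_mutations: int = 30
    n_subclones: int = 3
    subclone_mutations_range: tuple[int, int] = (5, 40)
    subclone_prevalence_range: tuple[float, float] = (0.1, 0.9)
    purity_range: tuple[float, float] = (0.3, 0.9)
    ploidy_choices: tuple[float, ...] = (2.0, 3.0, 4.0)
    sequencing_depth: int = 80
    artifact_rate: float = 5.0
    artifact_vaf_max: float = 0.15
    count_dispersion: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumors < 1:
            raise ValueError("n_tumors must be positive")
        lo, hi = self.pieces_per_tumor
        if lo < 2:
            raise ValueError("a multi-region cohort needs at least 2 pieces per tumor")
        for name in (
            "pieces_per_tumor",
            "library_size_range",
            "subclone_prevalence_range",
            "purity_range",
            "subclone_mutations_range",
        ):
            a, b = getattr(self, name)
            if a > b:
                raise ValueError(f"{name} must be ordered low <= high")
        for name in ("inter_tumor_sd", "intra_tumor_sd", "centroid_sd", "background_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0.0 <= self.discordant_tumor_fraction <= 1.0):
            raise ValueError("discordant_tumor_fraction must lie in [0, 1]")
        p_lo, p_hi = self.purity_range
        if not (0.0 < p_lo <= p_hi <= 1.0):
            raise ValueError("purity_range must lie in (0, 1]")
        s_lo, s_hi = self.subclone_prevalence_range
        if not (0.0 < s_lo <= s_hi <= 1.0):
            raise ValueError("subclone_prevalence_range must lie in (0, 1]")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be nonnegative")
        if self.artifact_vaf_max <= 0:
            raise ValueError("artifact_vaf_max must be positive")
        if self.n_signature_genes + self.n_grade_genes > self.n_genes:
            raise ValueError("signature and grade genes exceed total gene count")
        if any(p <= 0 for p in self.ploidy_choices):
            raise ValueError("ploidy choices must be positive")


@dataclass
class GroundTruth:
    """Generative truth of a simulated cohort.

    ``variant_origin`` maps (tumor_id, chrom, pos, ref, alt) to one of
    ``"clonal"``, ``"subclone-<k>"`` or ``"artifact"``;
    ``cluster_prevalence`` maps (tumor_id, cluster_id) to the per-piece
    true cellular prevalence.
    """

    subtype: dict = field(default_factory=dict)
    grade: dict = field(default_factory=dict)
    discordant: dict = field(default_factory=dict)
    variant_origin: dict = field(default_factory=dict)
    cluster_prevalence: dict = field(default_factory=dict)


@dataclass
class ExpressionCohort:
    counts: ExpressionMatrix
    sample_sheet: pd.DataFrame
    centroids: CentroidSet
    grade_centroids: CentroidSet
    truth: GroundTruth
    #: generative per-piece log2 expression means (pre count sampling)
    log_means: pd.DataFrame | None = None


@dataclass
class GenomicCohort:
    variants: pd.DataFrame
    segments: pd.DataFrame
    sample_sheet: pd.DataFrame
    clusters: pd.DataFrame
    genes: pd.DataFrame
    truth: GroundTruth


def _piece_layout(config: CohortConfig, rng: np.random.Generator):
    """Tumor ids, piece ids and per-piece purity/ploidy shared by both sims."""
    tumors = [f"T{i + 1:03d}" for i in range(config.n_tumors)]
    lo, hi = config.pieces_per_tumor
    layout = {}
    rows = []
    for t in tumors:
        n = int(rng.integers(lo, hi + 1))
        pieces = [f"{t}_p{j + 1}" for j in range(n)]
        layout[t] = pieces
        for p in pieces:
            rows.append(
                {
                    "sample_id": p,
                    "tumor_id": t,
                    "purity": float(rng.uniform(*config.purity_range)),
                    "ploidy": float(rng.choice(config.ploidy_choices)),
                    "relapse5y": bool(rng.random() < 0.3),
                }
            )
    sheet = pd.DataFrame(rows, columns=["sample_id", "tumor_id", "purity", "ploidy", "relapse5y"])
    return tumors, layout, sheet


def simulate_expression(config: CohortConfig) -> ExpressionCohort:
    """Simulate a multi-region expression cohort with known labels.

    Returns counts, sample sheet, subtype and grade centroid sets (on
    the absolute log2 expression scale of the generative means) and the
    ground truth.  Identical config (including seed) gives bit-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    tumors, layout, sheet = _piece_layout(config, rng)
    pieces = list(sheet["sample_id"])

    genes = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    sig_genes = genes[: config.n_signature_genes]
    grade_genes = genes[config.n_signature_genes : config.n_signature_genes + config.n_grade_genes]

    baseline = rng.normal(config.background_mean, config.background_sd, config.n_genes)
    subtypes = list(config.subtype_labels)
    # centered offsets per subtype over signature genes
    offsets = rng.normal(0.0, config.centroid_sd, (config.n_signature_genes, len(subtypes)))
    offsets -= offsets.mean(axis=1, keepdims=True)
    grade_dir = rng.normal(0.0, 1.0, config.n_grade_genes)
    grade_dir /= max(np.linalg.norm(grade_dir) / np.sqrt(config.n_grade_genes), 1e-12)

    centroids = pd.DataFrame(
        baseline[: config.n_signature_genes, None] + offsets, index=sig_genes, columns=subtypes
    )
    gb = baseline[config.n_signature_genes : config.n_signature_genes + config.n_grade_genes]
    grade_centroids = pd.DataFrame(
        {
            "low": gb - config.grade_effect * grade_dir / 2.0,
            "high": gb + config.grade_effect * grade_dir / 2.0,
        },
        index=grade_genes,
    )

    truth = GroundTruth()
    log_means = np.empty((config.n_genes, len(pieces)))
    col = 0
    sig_sl = slice(0, config.n_signature_genes)
    grd_sl = slice(config.n_signature_genes, config.n_signature_genes + config.n_grade_genes)
    for t in tumors:
        t_pieces = layout[t]
        subtype_idx = int(rng.integers(len(subtypes)))
        grade_label = "high" if rng.random() < 0.5 else "low"
        tumor_noise = rng.normal(0.0, config.inter_tumor_sd, config.n_genes)
        discordant = bool(rng.random() < config.discordant_tumor_fraction)
        odd_piece = int(rng.integers(len(t_pieces))) if discordant else -1
        odd_subtype = subtype_idx
        if discordant:
            others = [k for k in range(len(subtypes)) if k != subtype_idx]
            odd_subtype = int(rng.choice(others))
        truth.discordant[t] = discordant
        for j, p in enumerate(t_pieces):
            k = odd_subtype if j == odd_piece else subtype_idx
            mu = baseline + tumor_noise + rng.normal(0.0, config.intra_tumor_sd, config.n_genes)
            mu[sig_sl] += offsets[:, k]
            mu[grd_sl] += (1 if grade_label == "high" else -1) * config.grade_effect * grade_dir / 2.0
            log_means[:, col] = mu
            truth.subtype[p] = subtypes[k]
            truth.grade[p] = grade_label
            col += 1

    # counts: multinomial sampling of exponentiated log2 means
    counts = np.empty_like(log_means, dtype=np.int64)
    lib_lo, lib_hi = config.library_size_range
    for j in range(len(pieces)):
        w = np.exp2(log_means[:, j])
        if config.count_dispersion:
            w = w * rng.gamma(1.0 / config.count_dispersion, config.count_dispersion, w.size)
        lib = int(rng.integers(lib_lo, lib_hi + 1))
        counts[:, j] = rng.multinomial(lib, w / w.sum())

    return ExpressionCohort(
        counts=ExpressionMatrix(pd.DataFrame(counts, index=genes, columns=pieces), scale="counts"),
        sample_sheet=sheet,
        centroids=CentroidSet(centroids),
        grade_centroids=CentroidSet(grade_centroids),
        truth=truth,
        log_means=pd.DataFrame(log_means, index=genes, columns=pieces),
    )


def _random_substitution(rng: np.random.Generator) -> tuple[str, str]:
    ref = "ACGT"[int(rng.integers(4))]
    alt = rng.choice([b for b in "ACGT" if b != ref])
    return ref, str(alt)


def _simulate_gene_intervals(rng: np.random.Generator, n_genes: int = 200) -> pd.DataFrame:
    """Evenly spaced artificial gene intervals over the simulated genome."""
    rows = []
    contigs = list(GENOME_CONTIGS.items())
    per_contig = int(np.ceil(n_genes / len(contigs)))
    g = 0
    for chrom, length in contigs:
        spacing = length // (per_contig + 1)
        for i in range(per_contig):
            if g >= n_genes:
                break
            start = (i + 1) * spacing
            rows.append(
                {
                    "gene_id": f"DRV{g + 1:03d}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + 20_000 - 1,
                }
            )
            g += 1
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def _draw_read_support(rng, expected_vaf: float, depth: int):
    """Observed VAF and strand-split alt reads under binomial sampling."""
    alt = int(rng.binomial(depth, min(expected_vaf, 1.0)))
    fwd = int(rng.binomial(alt, 0.5)) if alt else 0
    return alt / depth, fwd, alt - fwd


def simulate_genomic(config: CohortConfig) -> GenomicCohort:
    """Simulate multi-region somatic variants, segments and subclones.

    Clonal mutations appear in every piece of a tumor; each subclone
    occupies a subset of pieces at drawn cellular prevalences.  Expected
    VAF in piece p is purity_p x prevalence_p / 2; read support is
    binomial at the configured depth.  FFPE artifacts are appended via
    :func:`inject_ffpe_artifacts`.  Segment tables tile the artificial
    genome with occasional gains/losses relative to the drawn ploidy.
    """
    rng = np.random.default_rng(config.seed)
    tumors, layout, sheet = _piece_layout(config, rng)
    purity = sheet.set_index("sample_id")["purity"]
    ploidy = sheet.set_index("sample_id")["ploidy"]
    genes = _simulate_gene_intervals(rng)
    depth = config.sequencing_depth

    contigs = list(GENOME_CONTIGS.items())
    used_positions: set[tuple[str, int]] = set()

    def _new_site(inside_gene_prob: float = 0.5):
        while True:
            if rng.random() < inside_gene_prob:
                row = genes.iloc[int(rng.integers(len(genes)))]
                chrom = row["chrom"]
                pos = int(rng.integers(row["start"], row["end"] + 1))
            else:
                chrom, length = contigs[int(rng.integers(len(contigs)))]
                pos = int(rng.integers(1, length + 1))
            if (chrom, pos) not in used_positions:
                used_positions.add((chrom, pos))
                return chrom, pos

    truth = GroundTruth()
    var_rows = []
    cluster_rows = []
    gene_lookup = genes.set_index("gene_id")

    def _gene_at(chrom: str, pos: int):
        hit = gene_lookup[
            (gene_lookup["chrom"] == chrom)
            & (gene_lookup["start"] <= pos)
            & (gene_lookup["end"] >= pos)
        ]
        return hit.index[0] if len(hit) else None

    for t in tumors:
        t_pieces = layout[t]
        # clonal cluster: prevalence 1 in every piece
        clonal_sites = [
            (_new_site(), _random_substitution(rng)) for _ in range(config.n_clonal_mutations)
        ]
        cid = f"{t}_clonal"
        truth.cluster_prevalence[(t, cid)] = {p: 1.0 for p in t_pieces}
        for p in t_pieces:
            cluster_rows.append(
                {
                    "tumor_id": t,
                    "cluster_id": cid,
                    "n_mutations": config.n_clonal_mutations,
                    "sample_id": p,
                    "prevalence": 1.0,
                }
            )
        for (chrom, pos), (ref, alt) in clonal_sites:
            truth.variant_origin[(t, chrom, pos, ref, alt)] = "clonal"
            cosmic = bool(rng.random() < 0.2)
            for p in t_pieces:
                evaf = purity[p] / 2.0
                vaf, fwd, rev = _draw_read_support(rng, evaf, depth)
                if fwd + rev == 0:
                    # clonal variants are defined as present in all pieces;
                    # guarantee at least one supporting read
                    fwd = 1
                    vaf = 1.0 / depth
                var_rows.append(
                    dict(
                        tumor_id=t,
                        sample_id=p,
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        vaf=vaf,
                        alt_fwd=fwd,
                        alt_rev=rev,
                        in_cosmic=cosmic,
                        control_alt_reads=0,
                        gene_id=_gene_at(chrom, pos),
                    )
                )

        # subclones on subsets of pieces
        for k in range(config.n_subclones):
            n_member = int(rng.integers(1, len(t_pieces) + 1))
            members = list(rng.choice(t_pieces, size=n_member, replace=False))
            prev = {
                p: (float(rng.uniform(*config.subclone_prevalence_range)) if p in members else 0.0)
                for p in t_pieces
            }
            n_mut = int(rng.integers(*config.subclone_mutations_range, endpoint=True))
            cid = f"{t}_sc{k + 1}"
            truth.cluster_prevalence[(t, cid)] = prev
            for p in t_pieces:
                cluster_rows.append(
                    {
                        "tumor_id": t,
                        "cluster_id": cid,
                        "n_mutations": n_mut,
                        "sample_id": p,
                        "prevalence": prev[p],
                    }
                )
            for _ in range(n_mut):
                (chrom, pos), (ref, alt) = _new_site(), _random_substitution(rng)
                truth.variant_origin[(t, chrom, pos, ref, alt)] = f"subclone-{k + 1}"
                for p in members:
                    evaf = purity[p] * prev[p] / 2.0
                    vaf, fwd, rev = _draw_read_support(rng, evaf, depth)
                    if fwd + rev == 0:
                        continue  # not observed in this piece
                    var_rows.append(
                        dict(
                            tumor_id=t,
                            sample_id=p,
                            chrom=chrom,
                            pos=pos,
                            ref=ref,
                            alt=alt,
                            vaf=vaf,
                            alt_fwd=fwd,
                            alt_rev=rev,
                            in_cosmic=False,
                            control_alt_reads=0,
                            gene_id=_gene_at(chrom, pos),
                        )
                    )

    variants = pd.DataFrame(
        var_rows,
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
        ],
    )

    # copy-number segments tiling the genome, per piece
    seg_rows = []
    for p in sheet["sample_id"]:
        pl = ploidy[p]
        for chrom, length in contigs:
            n_seg = 5
            cuts = np.sort(rng.integers(1, length, n_seg - 1))
            bounds = np.concatenate([[1], cuts + 1, [length + 1]])
            for a, b in zip(bounds[:-1], bounds[1:]):
                if b - a < 1:
                    continue
                u = rng.random()
                if u < 0.1:
                    cn = 2.0 * pl  # > 1.5 x ploidy: amplified
                elif u < 0.2:
                    cn = 0.3 * pl  # < 0.5 x ploidy: deleted
                else:
                    cn = pl
                seg_rows.append(
                    {
                        "sample_id": p,
                        "chrom": chrom,
                        "start": int(a),
                        "end": int(b - 1),
                        "abs_cn": cn,
                    }
                )
    segments = pd.DataFrame(seg_rows, columns=["sample_id", "chrom", "start", "end", "abs_cn"])

    clusters = pd.DataFrame(
        cluster_rows, columns=["tumor_id", "cluster_id", "n_mutations", "sample_id", "prevalence"]
    )

    if config.artifact_rate > 0:
        variants, injected = inject_ffpe_artifacts(
            variants,
            rate=config.artifact_rate,
            vaf_max=config.artifact_vaf_max,
            seed=int(rng.integers(2**31)),
            sample_sheet=sheet,
            depth=depth,
            used_positions=used_positions,
        )
        for row in injected.itertuples():
            truth.variant_origin[(row.tumor_id, row.chrom, row.pos, row.ref, row.alt)] = "artifact"

    return GenomicCohort(
        variants=variants,
        segments=segments,
        sample_sheet=sheet,
        clusters=clusters,
        genes=genes,
        truth=truth,
    )


def inject_ffpe_artifacts(
    variants: pd.DataFrame,
    rate: float,
    vaf_max: float = 0.15,
    seed: int | None = None,
    sample_sheet: pd.DataFrame | None = None,
    depth: int = 80,
    used_positions: set | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Append FFPE deamination artifact records to a variant table.

    Artifacts are C>T or G>A substitutions private to one piece, with
    VAF uniform on (0, ``vaf_max``), no COSMIC membership, no control
    support, and strand support with at most one strand carrying >= 2
    alt reads — so neither rescue rule of the artifact filter can fire.
    The number of artifacts per piece is Poisson(``rate``).

    Returns ``(variants_with_artifacts, injected)``.  With ``rate == 0``
    the input is returned unchanged (empty ``injected``).
    """
    if rate < 0:
        raise ValueError("artifact rate must be nonnegative")
    if vaf_max <= 0:
        raise ValueError("vaf_max must be positive")
    if rate == 0:
        return variants, variants.iloc[0:0].copy()

    rng = np.random.default_rng(seed)
    if sample_sheet is not None:
        piece_map = list(sample_sheet[["sample_id", "tumor_id"]].itertuples(index=False))
    else:
        piece_map = list(
            variants[["sample_id", "tumor_id"]].drop_duplicates().itertuples(index=False)
        )
    used = set(used_positions) if used_positions is not None else set(
        zip(variants["chrom"], variants["pos"])
    )
    contigs = list(GENOME_CONTIGS.items())
    has_gene = "gene_id" in variants.columns

    rows = []
    for sample_id, tumor_id in piece_map:
        for _ in range(int(rng.poisson(rate))):
            while True:
                chrom, length = contigs[int(rng.integers(len(contigs)))]
                pos = int(rng.integers(1, length + 1))
                if (chrom, pos) not in used:
                    used.add((chrom, pos))
                    break
            ref, alt = ("C", "T") if rng.random() < 0.5 else ("G", "A")
            vaf = float(rng.uniform(np.finfo(float).tiny, vaf_max))
            total_alt = max(1, int(round(vaf * depth)))
            minor = int(rng.integers(0, 2))  # one strand capped below 2 reads
            fwd = max(total_alt - minor, minor)
            rev = total_alt - fwd
            if rng.random() < 0.5:
                fwd, rev = rev, fwd
            row = dict(
                tumor_id=tumor_id,
                sample_id=sample_id,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                vaf=vaf,
                alt_fwd=fwd,
                alt_rev=rev,
                in_cosmic=False,
                control_alt_reads=0,
            )
            if has_gene:
                row["gene_id"] = None
            rows.append(row)
    injected = pd.DataFrame(rows, columns=list(variants.columns))
    combined = pd.concat([variants, injected], ignore_index=True)
    return combined, injected
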