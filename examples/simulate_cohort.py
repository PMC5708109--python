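"""Generate a synthetic multi-region cohort and write it to disk.

Builds a 12-tumor cohort (2-6 pieces each) with paired expression and
genomic data plus ground truth, and writes the standard text formats
(counts TSV, sample sheet, variants TSV/VCF, segments, clusters, truth
JSON) under scratch/cohort/.
"""

from pathlib import Path

from tumorhet import CohortConfig, simulate_expression, simulate_genomic
from tumorhet.io import (
    write_centroids_tsv,
    write_clusters_tsv,
    write_counts_tsv,
    write_sample_sheet,
    write_segments_tsv,
    write_truth_json,
    write_variants_tsv,
    write_variants_vcf,
)

outdir = Path("scratch/cohort")
outdir.mkdir(parents=True, exist_ok=True)

config = CohortConfig(seed=42)
expr = simulate_expression(config)
geno = simulate_genomic(config)

write_counts_tsv(expr.counts, outdir / "counts.tsv")
write_sample_sheet(expr.sample_sheet, outdir / "samples.tsv")
write_centroids_tsv(expr.centroids, outdir / "centroids.tsv")
write_truth_json(expr.truth, outdir / "expression_truth.json")
write_variants_tsv(geno.variants, outdir / "variants.tsv")
write_variants_vcf(geno.variants, outdir / "variants.vcf")
write_segments_tsv(geno.segments, outdir / "segments.tsv")
write_clusters_tsv(geno.clusters, outdir / "clusters.tsv")
write_truth_json(geno.truth, outdir / "genomic_truth.json")

n_disc = sum(expr.truth.discordant.values())
n_art = sum(1 for v in geno.truth.variant_origin.values() if v == "artifact")
print(f"wrote cohort to {outdir}/")
print(f"  pieces: {expr.counts.n_samples} across {config.n_tumors} tumors")
print(f"  truly subtype-discordant tumors: {n_disc} "
      "(one piece redrawn from another subtype's centroid)")
print(f"  somatic variant records: {len(geno.variants)}, "
      f"of which {n_art} sites are injected FFPE artifacts")
print(f"  subclone clusters: {geno.clusters['cluster_id'].nunique()} "
      "(one clonal cluster per tumor plus piece-restricted subclones)")
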