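"""Full heterogeneity report: concordance + driver VAFs + subclones.

Runs both arms of the pipeline on a simulated cohort and renders the
versioned JSON report with its companion plots (PCA with tumor pieces
connected, driver-gene VAF heatmap, subclone sharing bars).
"""

from pathlib import Path

from tumorhet import (
    CentroidSet,
    CohortConfig,
    build_driver_vaf_matrix,
    classify_subtype,
    concordance,
    ffpe_artifact_filter,
    filter_subclone_clusters,
    log_cpm,
    render_report,
    signature_pca,
    simulate_expression,
    simulate_genomic,
    subclone_presence_table,
    subgroup_gene_center,
    tmm_factors,
)

cfg = CohortConfig(seed=5)
expr = simulate_expression(cfg)
geno = simulate_genomic(cfg)

# expression arm
logexpr = log_cpm(expr.counts, tmm_factors(expr.counts))
centered = subgroup_gene_center(logexpr, logexpr)
cen = expr.centroids.centroids
profiles = classify_subtype(centered, CentroidSet(cen.sub(cen.mean(axis=1), axis=0)))
conc = concordance(profiles["subtype"].to_dict(), expr.sample_sheet, "subtype")
pca = signature_pca(centered, expr.centroids.signature_gene_ids)

# genomic arm
kept, _ = ffpe_artifact_filter(geno.variants)
panel = sorted(kept["gene_id"].dropna().unique())[:20]
vaf_matrix, _ = build_driver_vaf_matrix(kept, panel, geno.sample_sheet)
filtered = filter_subclone_clusters(geno.clusters)
_, subclones = subclone_presence_table(filtered, geno.sample_sheet)

outdir = Path("scratch/report")
path = render_report(
    outdir,
    concordance_results=[conc],
    driver_vaf=vaf_matrix,
    subclone_summary=subclones,
    pca_scores=pca.scores,
    sample_sheet=expr.sample_sheet,
)
print(f"wrote {path} and plots to {outdir}/")
print(f"  subtype concordance: {conc[1]['n_concordant']} of {conc[1]['n_tumors']} tumors")
print(f"  PC1 explains {100 * pca.explained_variance_ratio[0]:.1f}% of signature-gene variance")
print(f"  driver panel: {len(panel)} genes x {vaf_matrix.shape[1]} pieces, "
      f"{int(vaf_matrix.notna().sum().sum())} mutated (gene, piece) cells")
print("(the JSON report is the machine-readable artifact; the plots mirror")
print(" the usual multi-region views: connected PCA points per tumor and a")
print(" purity-adjusted VAF heatmap over driver genes)")
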