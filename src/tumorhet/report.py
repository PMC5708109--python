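"""Per-tumor heterogeneity summaries and the machine-readable report.

Aggregates per-piece molecular calls into tumor-level concordance
classifications, decomposes expression variability into intra- vs
inter-tumor components, builds purity-adjusted driver-gene VAF matrices,
tabulates subclone presence across pieces, and renders everything into a
versioned JSON report with companion plots.
"""

from __future__ import annotations

import datetime
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import _as_frame
from .filters import purity_adjust_vaf

__all__ = [
    "concordance",
    "variability_decomposition",
    "VarianceDecomposition",
    "build_driver_vaf_matrix",
    "subclone_presence_table",
    "render_report",
    "validate_report",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = "1.0"


def concordance(labels, sample_sheet: pd.DataFrame, attribute: str = "subtype"):
    """Classify each multi-piece tumor as label-concordant or discordant.

    ``labels`` maps piece (sample id) to its assigned label (a Series or
    dict).  A tumor is concordant iff all its pieces carry the same
    label.  Tumors with a single piece are excluded from the denominator
    and listed in the summary.  Majority label is by count; ties go to
    the lexicographically first label with a flag.

    Returns ``(per_tumor, summary)``: a DataFrame with one row per
    multi-piece tumor and a dict with the cohort counts
    (``n_concordant`` of ``n_tumors`` plus the concordant fraction).
    """
    labels = pd.Series(labels)
    mapping = sample_sheet.set_index("sample_id")["tumor_id"]
    unmapped = [s for s in labels.index if s not in mapping.index]
    if unmapped:
        raise ValueError(f"pieces not mapped to a tumor: {unmapped}")

    rows, excluded = [], []
    for tumor, piece_ids in labels.groupby(mapping.reindex(labels.index)).groups.items():
        piece_labels = labels.loc[list(piece_ids)]
        if len(piece_labels) < 2:
            excluded.append(tumor)
            continue
        counts = piece_labels.value_counts()
        top = counts.max()
        winners = sorted(counts[counts == top].index)
        rows.append(
            {
                "tumor_id": tumor,
                "attribute": attribute,
                "n_pieces": int(len(piece_labels)),
                "labels": ";".join(str(x) for x in piece_labels),
                "concordant": bool(piece_labels.nunique() == 1),
                "majority_label": winners[0],
                "majority_tie": len(winners) > 1,
            }
        )
    per_tumor = pd.DataFrame(
        rows,
        columns=[
            "tumor_id",
            "attribute",
            "n_pieces",
            "labels",
            "concordant",
            "majority_label",
            "majority_tie",
        ],
    )
    n = len(per_tumor)
    k = int(per_tumor["concordant"].sum()) if n else 0
    summary = {
        "attribute": attribute,
        "n_tumors": n,
        "n_concordant": k,
        "concordant_fraction": (k / n) if n else float("nan"),
        "excluded_single_piece": sorted(excluded),
    }
    return per_tumor, summary


@dataclass
class VarianceDecomposition:
    """One-way variance decomposition of one gene across tumors.

    ``intra_var`` is the mean squared deviation of pieces from their
    tumor mean (SS_within / N); ``inter_var`` the sample variance of the
    tumor means.  The sums of squares satisfy
    ``ss_total = ss_within + ss_between`` exactly.
    """

    gene_id: str
    intra_var: float
    inter_var: float
    ss_within: float
    ss_between: float
    ss_total: float
    n_pieces: int
    n_tumors: int


def variability_decomposition(expr, sample_sheet: pd.DataFrame, gene_id) -> VarianceDecomposition:
    """Intra- vs inter-tumor variability of one gene's log expression."""
    df = _as_frame(expr)
    if gene_id not in df.index:
        raise KeyError(f"gene {gene_id!r} not in matrix")
    mapping = sample_sheet.set_index("sample_id")["tumor_id"]
    values = df.loc[gene_id]
    tumors = mapping.reindex(values.index)
    if tumors.isna().any():
        raise ValueError("matrix contains pieces absent from the sample sheet")
    sizes = values.groupby(tumors).size()
    if (sizes >= 2).sum() < 2:
        raise ValueError("need at least two tumors with at least two pieces")

    x = values.to_numpy(dtype=float)
    grand = x.mean()
    tumor_means = values.groupby(tumors).mean()
    centered = x - tumor_means.reindex(tumors).to_numpy()
    ss_within = float((centered**2).sum())
    ss_between = float((sizes * (tumor_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    return VarianceDecomposition(
        gene_id=str(gene_id),
        intra_var=ss_within / len(x),
        inter_var=float(tumor_means.var(ddof=1)),
        ss_within=ss_within,
        ss_between=ss_between,
        ss_total=ss_total,
        n_pieces=int(len(x)),
        n_tumors=int(len(tumor_means)),
    )


def build_driver_vaf_matrix(
    variants: pd.DataFrame,
    driver_panel,
    sample_sheet: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Purity-adjusted VAF matrix over a driver-gene panel.

    ``variants`` must already be FFPE-filtered and carry a ``gene_id``
    column.  For each (driver gene, piece), reports the purity-adjusted
    VAF of the gene's mutation in that piece; when a gene carries several
    mutations in one piece the maximum adjusted VAF is reported and the
    multiplicity flagged.  Genes without a mutation in a piece are
    missing (NaN).

    Returns ``(matrix, multi)``: genes x pieces adjusted VAFs and the
    multiple-mutation flags.
    """
    if "gene_id" not in variants.columns:
        raise ValueError("variant table needs a 'gene_id' column for driver analysis")
    purity = sample_sheet.set_index("sample_id")["purity"]
    samples = list(sample_sheet["sample_id"])
    genes = list(driver_panel)
    matrix = pd.DataFrame(np.nan, index=genes, columns=samples)
    multi = pd.DataFrame(False, index=genes, columns=samples)

    hits = variants[variants["gene_id"].isin(genes)]
    missing_purity = set(hits["sample_id"]) - set(purity.dropna().index)
    if missing_purity:
        raise ValueError(f"pieces missing purity: {sorted(missing_purity)}")
    for (gene, sample), rows in hits.groupby(["gene_id", "sample_id"], sort=False):
        adj, _ = purity_adjust_vaf(rows["vaf"].to_numpy(), purity[sample])
        matrix.loc[gene, sample] = float(np.max(adj))
        multi.loc[gene, sample] = len(rows) > 1
    return matrix, multi


def subclone_presence_table(filtered_clusters: pd.DataFrame, sample_sheet: pd.DataFrame):
    """Per-tumor subclone presence across pieces.

    Input is the output of :func:`~tumorhet.filters.filter_subclone_clusters`
    (long table with a ``retained`` column).  Returns ``(presence,
    cluster_summary)``: the long table restricted to each tumor's pieces,
    and a per-cluster summary with the number of pieces the cluster is
    retained in and a category — ``piece-private`` (exactly one piece),
    ``shared-all`` (every piece of the tumor) or ``shared`` (in between);
    clusters retained nowhere are ``absent``.
    """
    pieces_per_tumor = sample_sheet.groupby("tumor_id")["sample_id"].nunique()
    rows = []
    for (tumor, cluster), sub in filtered_clusters.groupby(["tumor_id", "cluster_id"], sort=False):
        n_present = int(sub["retained"].sum())
        n_pieces = int(pieces_per_tumor.get(tumor, sub["sample_id"].nunique()))
        if n_present == 0:
            category = "absent"
        elif n_present == 1:
            category = "piece-private"
        elif n_present == n_pieces:
            category = "shared-all"
        else:
            category = "shared"
        rows.append(
            {
                "tumor_id": tumor,
                "cluster_id": cluster,
                "n_mutations": int(sub["n_mutations"].iloc[0]),
                "n_pieces_present": n_present,
                "n_pieces": n_pieces,
                "category": category,
                "max_prevalence": float(sub["prevalence"].max()),
            }
        )
    summary = pd.DataFrame(
        rows,
        columns=[
            "tumor_id",
            "cluster_id",
            "n_mutations",
            "n_pieces_present",
            "n_pieces",
            "category",
            "max_prevalence",
        ],
    )
    return filtered_clusters, summary


def validate_report(report: dict) -> dict:
    """Validate the JSON report structure; returns the report unchanged."""
    if not isinstance(report, dict):
        raise ValueError("report must be a JSON object")
    for key in ("schema_version", "generated", "concordance"):
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
    if report["schema_version"] != REPORT_SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {report['schema_version']!r}")
    if not isinstance(report["concordance"], list):
        raise ValueError("'concordance' must be a list")
    for entry in report["concordance"]:
        for key in ("attribute", "n_tumors", "n_concordant", "per_tumor"):
            if key not in entry:
                raise ValueError(f"concordance entry missing {key!r}")
        if not isinstance(entry["per_tumor"], list):
            raise ValueError("'per_tumor' must be a list")
    for key in ("driver_vaf", "subclones"):
        if key in report and report[key] is not None and not isinstance(report[key], (dict, list)):
            raise ValueError(f"{key!r} must be an object or list")
    return report


def render_report(
    outdir,
    concordance_results=None,
    driver_vaf: pd.DataFrame | None = None,
    subclone_summary: pd.DataFrame | None = None,
    pca_scores: pd.DataFrame | None = None,
    sample_sheet: pd.DataFrame | None = None,
    plots: bool = True,
    timestamp: str | None = None,
) -> Path:
    """Write the heterogeneity report (JSON + optional plots) to ``outdir``.

    ``concordance_results`` is a list of ``(per_tumor, summary)`` pairs
    from :func:`concordance`.  Outputs are deterministic for fixed inputs
    except the ``generated`` timestamp field (overridable for testing).
    An empty call still writes a valid (empty) report with a warning.

    Returns the path of the written ``report.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not concordance_results and driver_vaf is None and subclone_summary is None:
        warnings.warn("rendering an empty report: no results supplied", stacklevel=2)

    conc_entries = []
    for per_tumor, summary in concordance_results or []:
        conc_entries.append(
            {
                "attribute": summary["attribute"],
                "n_tumors": summary["n_tumors"],
                "n_concordant": summary["n_concordant"],
                "concordant_fraction": summary["concordant_fraction"],
                "excluded_single_piece": summary["excluded_single_piece"],
                "per_tumor": per_tumor.to_dict(orient="records"),
            }
        )
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "generated": timestamp
        or datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds"),
        "concordance": conc_entries,
        "driver_vaf": None
        if driver_vaf is None
        else {
            "genes": list(map(str, driver_vaf.index)),
            "pieces": list(map(str, driver_vaf.columns)),
            "values": [
                [None if np.isnan(v) else round(float(v), 6) for v in row]
                for row in driver_vaf.to_numpy()
            ],
        },
        "subclones": None
        if subclone_summary is None
        else subclone_summary.to_dict(orient="records"),
    }
    validate_report(report)
    path = outdir / "report.json"
    path.write_text(json.dumps(report, indent=2, allow_nan=False) + "\n")

    if plots:
        _render_plots(outdir, driver_vaf, subclone_summary, pca_scores, sample_sheet)
    return path


def _render_plots(outdir, driver_vaf, subclone_summary, pca_scores, sample_sheet):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if pca_scores is not None and sample_sheet is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        mapping = sample_sheet.set_index("sample_id")["tumor_id"]
        tumors = mapping.reindex(pca_scores.index)
        for tumor, idx in pca_scores.groupby(tumors).groups.items():
            pts = pca_scores.loc[list(idx)]
            ax.plot(pts.iloc[:, 0], pts.iloc[:, 1], marker="o", ms=4, lw=0.8, label=str(tumor))
        ax.set_xlabel(pca_scores.columns[0])
        ax.set_ylabel(pca_scores.columns[1])
        ax.set_title("Signature-gene PCA (pieces of a tumor connected)")
        fig.tight_layout()
        fig.savefig(outdir / "pca_pieces.png", dpi=120)
        plt.close(fig)

    if driver_vaf is not None and driver_vaf.size:
        fig, ax = plt.subplots(figsize=(6, max(2, 0.25 * len(driver_vaf))))
        im = ax.imshow(driver_vaf.to_numpy(dtype=float), aspect="auto", cmap="viridis", vmin=0, vmax=1)
        ax.set_xticks(range(driver_vaf.shape[1]), driver_vaf.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(driver_vaf.shape[0]), driver_vaf.index, fontsize=6)
        fig.colorbar(im, ax=ax, label="purity-adjusted VAF")
        ax.set_title("Driver-gene VAF across pieces")
        fig.tight_layout()
        fig.savefig(outdir / "driver_vaf.png", dpi=120)
        plt.close(fig)

    if subclone_summary is not None and len(subclone_summary):
        fig, ax = plt.subplots(figsize=(6, 3))
        counts = subclone_summary.groupby(["tumor_id", "category"]).size().unstack(fill_value=0)
        counts.plot.bar(stacked=True, ax=ax)
        ax.set_ylabel("clusters")
        ax.set_title("Subclone sharing across pieces")
        fig.tight_layout()
        fig.savefig(outdir / "subclone_sharing.png", dpi=120)
        plt.close(fig)
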