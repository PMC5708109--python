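"""Per-piece molecular profiling from expression.

Nearest-centroid molecular subtype assignment (PAM50-style), a
two-centroid transcriptomic grade score, univariate logistic models for
receptor status (ER/PR/HER2), subgroup-specific gene-centering, and a
signature-gene PCA.  Classification correlates each sample's signature
gene expression with class centroids (Spearman by default) and assigns
the argmax class; all tie-breaks are explicit and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .containers import CentroidSet, ExpressionMatrix, _as_frame

__all__ = [
    "ReceptorModel",
    "subgroup_gene_center",
    "classify_subtype",
    "transcriptomic_grade",
    "fit_receptor_model",
    "predict_receptor_status",
    "signature_pca",
    "PCAResult",
]

#: |coefficient| above which a maximum-likelihood logistic fit is treated
#: as (quasi-)separated and refit with L2 regularization.
_SEPARATION_COEF_LIMIT = 25.0
#: Inverse regularization strength (sklearn ``C``) of the fallback fit.
_SEPARABLE_C = 1.0


def subgroup_gene_center(test, train, subgroup_mask=None) -> pd.DataFrame:
    """Center test-cohort genes on a training-cohort subgroup.

    For each gene shared between ``test`` and ``train``, subtracts the
    gene's mean over the selected training subgroup from every test
    sample.  Both matrices must be on the log scale.  ``subgroup_mask``
    is a boolean sequence/Series over training samples; all-true by
    default (full-cohort centering).

    Returns the centered test matrix restricted to shared genes.
    """
    for m, name in ((test, "test"), (train, "train")):
        if isinstance(m, ExpressionMatrix) and m.scale != "log":
            raise ValueError(f"{name} matrix must be on the log scale")
    test_df = _as_frame(test)
    train_df = _as_frame(train)

    if subgroup_mask is None:
        mask = np.ones(train_df.shape[1], dtype=bool)
    elif isinstance(subgroup_mask, pd.Series):
        mask = subgroup_mask.reindex(train_df.columns).fillna(False).to_numpy(dtype=bool)
    else:
        mask = np.asarray(subgroup_mask, dtype=bool)
        if mask.size != train_df.shape[1]:
            raise ValueError("subgroup mask length does not match training samples")
    if not mask.any():
        raise ValueError("training subgroup is empty")

    shared = [g for g in test_df.index if g in set(train_df.index)]
    if not shared:
        raise ValueError("no shared genes between test and training matrices")
    sub_means = train_df.loc[shared, train_df.columns[mask]].mean(axis=1)
    return test_df.loc[shared].sub(sub_means, axis=0)


def _correlation_matrix(x: np.ndarray, c: np.ndarray, method: str) -> np.ndarray:
    """Columnwise correlations between samples (x) and centroids (c).

    Both arrays are genes x k; returns samples x classes.  Zero-variance
    columns yield NaN correlations.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    if method == "spearman":
        x = np.apply_along_axis(rankdata, 0, x)
        c = np.apply_along_axis(rankdata, 0, c)

    def _standardize(a: np.ndarray) -> np.ndarray:
        a = a - a.mean(axis=0, keepdims=True)
        norm = np.sqrt((a**2).sum(axis=0, keepdims=True))
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(norm > 0, a / norm, np.nan)

    return _standardize(x).T @ _standardize(c)


def _centroid_correlations(expr, centroids: CentroidSet, method: str):
    df = _as_frame(expr)
    sig = centroids.signature_gene_ids
    missing = [g for g in sig if g not in df.index]
    if missing:
        raise ValueError(f"signature genes missing from matrix: {missing}")
    if len(sig) < 3:
        raise ValueError("need at least 3 signature genes for correlation")
    x = df.loc[sig].to_numpy(dtype=float)
    c = centroids.centroids.to_numpy(dtype=float)
    return _correlation_matrix(x, c, method), df.columns, centroids.class_names


def classify_subtype(expr, centroids: CentroidSet, method: str = "spearman") -> pd.DataFrame:
    """Assign each sample the centroid class with maximal correlation.

    Returns a DataFrame indexed by sample with columns ``subtype``,
    ``tie`` (True when >1 class attains the maximal correlation; the
    first class in the centroid-set column order is chosen), and one
    ``corr_<class>`` column per class.  A sample with zero variance over
    the signature genes gets the label ``"undetermined"`` with NaN
    correlations and the tie flag set.
    """
    corr, samples, classes = _centroid_correlations(expr, centroids, method)
    labels, ties = [], []
    for i in range(corr.shape[0]):
        row = corr[i]
        if np.isnan(row).all():
            labels.append("undetermined")
            ties.append(True)
            continue
        best = np.nanmax(row)
        winners = np.where(np.isclose(row, best, rtol=0.0, atol=1e-12))[0]
        labels.append(classes[winners[0]])
        ties.append(len(winners) > 1)
    out = pd.DataFrame({"subtype": labels, "tie": ties}, index=pd.Index(samples, name="sample_id"))
    for j, cls in enumerate(classes):
        out[f"corr_{cls}"] = corr[:, j]
    return out


def transcriptomic_grade(expr, grade_signature: CentroidSet, method: str = "spearman") -> pd.DataFrame:
    """Binary low/high transcriptomic grade from a two-centroid score.

    grade score = corr(sample, high centroid) - corr(sample, low
    centroid); label ``high`` iff score > 0 (a score of exactly 0 maps to
    ``low`` with the tie flag set).  The signature must have exactly the
    two classes ``low`` and ``high``.
    """
    if sorted(grade_signature.class_names) != ["high", "low"]:
        raise ValueError("grade signature needs exactly the classes 'low' and 'high'")
    corr, samples, classes = _centroid_correlations(expr, grade_signature, method)
    hi = corr[:, classes.index("high")]
    lo = corr[:, classes.index("low")]
    score = hi - lo
    labels, ties = [], []
    for s in score:
        if np.isnan(s):
            labels.append("undetermined")
            ties.append(True)
        else:
            labels.append("high" if s > 0 else "low")
            ties.append(s == 0)
    return pd.DataFrame(
        {"grade": labels, "grade_score": score, "tie": ties},
        index=pd.Index(samples, name="sample_id"),
    )


@dataclass
class ReceptorModel:
    """Univariate logistic model for receptor status from one gene.

    ``P(positive) = logistic(intercept + slope * x)`` with ``x`` the
    gene's log expression; status is positive iff the probability reaches
    ``threshold``.  ``separable`` marks models refit under L2
    regularization because the maximum-likelihood fit (quasi-)separated.
    """

    gene_id: str
    intercept: float
    slope: float
    threshold: float = 0.5
    separable: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")
        if not np.isfinite(self.slope) or not np.isfinite(self.intercept):
            raise ValueError("model coefficients must be finite")


def fit_receptor_model(values, labels, gene_id: str = "gene", threshold: float = 0.5) -> ReceptorModel:
    """Fit a single-gene logistic model for a binary receptor status.

    ``values`` is the gene's log expression per sample, ``labels`` the
    binary status (0/1).  Maximum-likelihood fit; if the data are
    (quasi-)separable — fit failure or coefficients beyond a declared
    cap — the model is refit with L2 regularization and flagged.
    """
    import statsmodels.api as sm

    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("values and labels must be 1-d and aligned")
    if len(np.unique(y)) < 2:
        raise ValueError("both receptor classes must be represented")

    design = sm.add_constant(x)
    coef = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        if res.mle_retvals.get("converged", False):
            coef = np.asarray(res.params, dtype=float)
    except Exception:
        coef = None
    separable = coef is None or not np.all(np.isfinite(coef)) or np.any(
        np.abs(coef) > _SEPARATION_COEF_LIMIT
    )
    if separable:
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=_SEPARABLE_C, solver="lbfgs", max_iter=1000)
        lr.fit(x.reshape(-1, 1), y.astype(int))
        coef = np.array([lr.intercept_[0], lr.coef_[0, 0]])
    return ReceptorModel(
        gene_id=gene_id,
        intercept=float(coef[0]),
        slope=float(coef[1]),
        threshold=threshold,
        separable=bool(separable),
    )


def predict_receptor_status(value, model: ReceptorModel):
    """Receptor status and probability for log expression value(s).

    Returns ``(status, probability)`` where status is ``"pos"`` iff the
    logistic probability is >= the model threshold (boundary counts as
    positive).  Accepts a scalar or an array.
    """
    v = np.asarray(value, dtype=float)
    p = expit(model.intercept + model.slope * v)
    status = np.where(p >= model.threshold, "pos", "neg")
    if v.ndim == 0:
        return str(status), float(p)
    return status, p


@dataclass
class PCAResult:
    """Scores (samples x components), loadings (genes x components) and
    explained variance ratios from a signature-gene PCA."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


def signature_pca(expr, signature_gene_ids, n_components: int | None = 2) -> PCAResult:
    """PCA of samples over a signature gene set.

    Genes (variables) are mean-centered across samples — no scaling —
    and scores come from the SVD of the centered samples x genes matrix.
    Each component's sign is fixed by making the gene with the largest
    absolute loading carry a positive loading.
    """
    df = _as_frame(expr)
    missing = [g for g in signature_gene_ids if g not in df.index]
    if missing:
        raise ValueError(f"signature genes missing from matrix: {missing}")
    if df.shape[1] < 2:
        raise ValueError("PCA needs at least two samples")
    x = df.loc[signature_gene_ids].to_numpy(dtype=float).T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = s.size if n_components is None else min(n_components, s.size)
    # sign convention: dominant loading positive
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u[:, :k] * s[:k]
    total = (s**2).sum()
    evr = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    comp = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=df.columns, columns=comp),
        loadings=pd.DataFrame(vt[:k].T, index=signature_gene_ids, columns=comp),
        explained_variance_ratio=evr,
    )
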