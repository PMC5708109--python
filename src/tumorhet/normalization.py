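"""Between-sample count normalization.

Implements trimmed-mean-of-M-values (TMM) scaling factors and the
companion log2-CPM transform.  The TMM algorithm follows the canonical
formulation used for RNA-seq count data: per-gene log ratios (M) and
average log abundances (A) are computed against a reference sample on
library-size-normalized fractions, doubly trimmed (30% on M, 5% on A),
and combined as a precision-weighted mean; factors are normalized to
geometric mean one, so they multiply library sizes to give effective
library sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix, _as_frame

__all__ = ["tmm_factors", "log_cpm"]


def _tmm_pairwise(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    sum_trim: float,
    do_weighting: bool,
    a_cutoff: float = -1e10,
) -> float:
    """TMM factor of one sample against the reference sample."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / lib_obs
        p_ref = ref / lib_ref
        log_r = np.log2(p_obs / p_ref)
        abs_e = (np.log2(p_obs) + np.log2(p_ref)) / 2.0
        # delta-method asymptotic variance of M under binomial sampling
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)

    fin = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > a_cutoff)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0

    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    if do_weighting:
        f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        f = np.mean(log_r[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_factors(
    counts,
    ref_sample=None,
    lib_sizes=None,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
    do_weighting: bool = True,
) -> pd.Series:
    """Compute TMM scaling factors for a raw-count matrix.

    Parameters
    ----------
    counts
        :class:`~tumorhet.containers.ExpressionMatrix` on the ``counts``
        scale, or a genes x samples DataFrame of raw counts.
    ref_sample
        Sample id to use as reference.  Default: the sample whose
        75th-percentile count fraction is closest to the mean of those
        fractions across samples.
    lib_sizes
        Optional mapping or Series of library sizes per sample; defaults
        to column sums.
    logratio_trim, sum_trim
        Trim fractions applied to the M values (log ratios) and the A
        values (average log abundance).

    Returns
    -------
    pandas.Series
        Positive factors per sample whose product (geometric mean) is one.
        Effective library size = library size x factor.
    """
    if isinstance(counts, ExpressionMatrix) and counts.scale != "counts":
        raise ValueError("tmm_factors requires raw counts")
    x = _as_frame(counts)
    if x.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    mat = x.to_numpy(dtype=float)
    samples = list(x.columns)

    if lib_sizes is None:
        lib = mat.sum(axis=0)
    else:
        lib = np.asarray([float(lib_sizes[s]) for s in samples])
    zero = np.where(lib == 0)[0]
    if zero.size:
        raise ValueError(f"sample {samples[zero[0]]!r} has all-zero counts")

    if ref_sample is None:
        f75 = np.quantile(mat, 0.75, axis=0) / lib
        if np.median(f75) < 1e-20:
            ref_idx = int(np.argmax(np.sqrt(mat).sum(axis=0)))
        else:
            ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        if ref_sample not in samples:
            raise KeyError(f"reference sample {ref_sample!r} not in matrix")
        ref_idx = samples.index(ref_sample)

    ref = mat[:, ref_idx]
    lib_ref = lib[ref_idx]
    f = np.array(
        [
            _tmm_pairwise(
                mat[:, j], ref, lib[j], lib_ref, logratio_trim, sum_trim, do_weighting
            )
            for j in range(mat.shape[1])
        ]
    )
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=samples, name="tmm_factor")


def log_cpm(counts, factors=None, prior: float = 0.5) -> ExpressionMatrix:
    """log2 counts-per-million with a prior count.

    ``log2((count + prior) / (library_size * factor) * 1e6)``; with no
    factors given, all factors are one (plain CPM).
    """
    if prior <= 0:
        raise ValueError("prior count must be positive")
    if isinstance(counts, ExpressionMatrix) and counts.scale != "counts":
        raise ValueError("log_cpm requires raw counts")
    x = _as_frame(counts)
    lib = x.sum(axis=0).to_numpy(dtype=float)
    if factors is None:
        f = np.ones(x.shape[1])
    else:
        f = np.asarray([float(factors[s]) for s in x.columns])
        if np.any(f <= 0):
            raise ValueError("scaling factors must be positive")
    eff = lib * f
    vals = np.log2((x.to_numpy(dtype=float) + prior) / eff * 1e6)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=x.index, columns=x.columns), scale="log"
    )
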