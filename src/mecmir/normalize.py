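"""Normalization paths: array filtering + quantile, RNA-seq TMM + log-CPM
with precision weights, and qPCR delta-Ct centering.

All outputs are log2-scale :class:`~mecmir.io_formats.ExpressionMatrix`
objects; each function records enough provenance to reproduce the result
from raw input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io_formats import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class NormalizationResult:
    matrix: ExpressionMatrix
    weights: pd.DataFrame | None = None
    size_factors: pd.Series | None = None
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# feature filtering
# ---------------------------------------------------------------------------

def filter_features(matrix: ExpressionMatrix,
                    min_present_fraction: float = 0.5,
                    present: pd.DataFrame | None = None,
                    ) -> ExpressionMatrix:
    """Keep features present in at least ``min_present_fraction`` of the
    samples of at least one age x layer group.

    ``present`` is a boolean feature x sample indicator; by default a count
    matrix uses ``count > 0`` and any other matrix uses non-missing values.
    """
    if present is None:
        if matrix.scale_tag == "counts":
            present = matrix.values > 0
        else:
            present = matrix.values.notna()
    present = present.astype(bool)
    groups = [f"{s.age}|{s.layer}" for s in matrix.samples]
    frac = present.T.groupby(np.asarray(groups)).mean().T  # feature x group
    keep = (frac >= min_present_fraction).any(axis=1)
    if not keep.any():
        log.warning("filter_features removed every feature")
    return matrix.subset_features(matrix.values.index[keep])


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to the mean empirical distribution.

    After normalization each column's sorted values equal the mean of the
    column-sorted values; ties within a column receive the mean of the
    quantile values their positions span.
    """
    values = matrix.values.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("quantile normalization requires a complete matrix")
    order = np.argsort(values, axis=0, kind="stable")
    mean_quantiles = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        ranked = np.empty(n)
        ranked[order[:, j]] = mean_quantiles
        # average quantile values over ties within the column
        col = values[:, j]
        if np.unique(col).size != n:
            df = pd.DataFrame({"v": col, "q": ranked})
            ranked = df.groupby("v")["q"].transform("mean").to_numpy()
        out[:, j] = ranked
    frame = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(frame, "log2")


# ---------------------------------------------------------------------------
# TMM scale factors and log-CPM
# ---------------------------------------------------------------------------

def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
              trim_M: float, trim_A: float) -> float:
    """Weighted doubly trimmed mean of M-values of one sample vs the reference."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / lib_obs, ref / lib_ref
    M = np.log2(p_obs / p_ref)
    A = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic (delta-method) inverse variances of M
    w = 1.0 / ((lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref))
    if np.allclose(M, M[0], atol=1e-10):
        return float(2.0 ** np.average(M, weights=w))
    n = M.size
    lo_M, hi_M = np.floor(n * trim_M) + 1, n + 1 - (np.floor(n * trim_M) + 1)
    lo_A, hi_A = np.floor(n * trim_A) + 1, n + 1 - (np.floor(n * trim_A) + 1)
    rank_M = pd.Series(M).rank().to_numpy()
    rank_A = pd.Series(A).rank().to_numpy()
    keep = (rank_M >= lo_M) & (rank_M <= hi_M) & (rank_A >= lo_A) & (rank_A <= hi_A)
    if not keep.any():
        return 1.0
    return float(2.0 ** np.average(M[keep], weights=w[keep]))


def tmm_factors(counts: ExpressionMatrix, trim_M: float = 0.30,
                trim_A: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors, geometric mean 1.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean of those fractions; zero-count features are excluded
    pairwise before trimming 2 x ``trim_M`` of the log-ratios and
    2 x ``trim_A`` of the average log-intensities.
    """
    values = counts.values.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    lib = values.sum(axis=0)
    if np.any(lib <= 0):
        bad = [counts.sample_ids[j] for j in np.where(lib <= 0)[0]]
        raise ValueError(f"samples with zero total count: {bad}")
    uq = np.array([np.percentile(values[:, j][values[:, j] > 0], 75) / lib[j]
                   if (values[:, j] > 0).any() else 0.0
                   for j in range(values.shape[1])])
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array([
        1.0 if j == ref_j else _tmm_pair(values[:, j], values[:, ref_j],
                                         lib[j], lib[ref_j], trim_M, trim_A)
        for j in range(values.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="tmm_factor")


def log_cpm(counts: ExpressionMatrix, factors: pd.Series | None = None,
            prior: float = 0.5) -> ExpressionMatrix:
    """log2 counts per million on effective (TMM-scaled) library sizes:
    ``log2((count + prior) / (lib * factor + 1) * 1e6)``."""
    values = counts.values.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("negative counts")
    lib = values.sum(axis=0)
    f = (factors.reindex(counts.sample_ids).to_numpy()
         if factors is not None else np.ones_like(lib))
    eff = lib * f
    out = np.log2((values + prior) / (eff + 1.0)[None, :] * 1e6)
    frame = pd.DataFrame(out, index=counts.values.index, columns=counts.values.columns)
    return counts.with_values(frame, "log2")


# ---------------------------------------------------------------------------
# precision weights (mean-variance trend)
# ---------------------------------------------------------------------------

def precision_weights(logcpm: ExpressionMatrix, design: pd.DataFrame,
                      span: float = 0.5) -> pd.DataFrame:
    """Inverse fourth-power weights from a lowess fit of sqrt(residual sd)
    against mean log-CPM, after a per-feature fit of ``design``.

    With a single feature (no trend to fit) unit weights are returned.
    """
    Y = logcpm.values.to_numpy(dtype=float)
    X = design.reindex(logcpm.sample_ids).to_numpy(dtype=float)
    n, p = X.shape
    df_resid = n - np.linalg.matrix_rank(X)
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    if Y.shape[0] < 2:
        log.warning("precision_weights: single feature, returning unit weights")
        return pd.DataFrame(1.0, index=logcpm.values.index, columns=logcpm.sample_ids)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta
    sigma = np.sqrt((resid ** 2).sum(axis=0) / df_resid)
    mean_expr = Y.mean(axis=1)
    trend = lowess(np.sqrt(sigma), mean_expr, frac=span, return_sorted=True)
    pred = np.interp(mean_expr, trend[:, 0], trend[:, 1])
    pred = np.clip(pred, 1e-3, None)
    w = np.clip(pred ** -4.0, 1e-6, 1e6)
    weights = np.repeat(w[:, None], n, axis=1)
    return pd.DataFrame(weights, index=logcpm.values.index, columns=logcpm.sample_ids)


# ---------------------------------------------------------------------------
# delta-Ct normalization
# ---------------------------------------------------------------------------

def delta_ct_normalize(ct: ExpressionMatrix, mask: pd.DataFrame | None = None,
                       ) -> ExpressionMatrix:
    """Center each sample on its mean Ct over universally reliable features
    and negate, so higher output = more expressed.

    Features flagged (or missing) in any sample are dropped first; the
    reference mean is taken over the retained features of each sample.
    """
    values = ct.values
    bad = values.isna()
    if mask is not None:
        bad = bad | mask.astype(bool)
    keep = ~bad.any(axis=1)
    if not keep.any():
        raise ValueError("no feature is reliably detected in every sample")
    retained = values.loc[keep]
    centered = retained - retained.mean(axis=0)
    out = -centered
    dropped = int((~keep).sum())
    if dropped:
        log.info("delta_ct_normalize dropped %d flagged features", dropped)
    filtered = ct.subset_features(retained.index)
    return filtered.with_values(out, "log2")
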