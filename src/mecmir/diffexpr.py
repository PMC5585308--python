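"""Linear-model differential expression with empirical-Bayes moderated
t-statistics and Benjamini-Hochberg adjustment.

Per feature, a (weighted) least-squares fit of a design matrix is followed
by shrinkage of the residual variances s^2 toward a pooled prior s0^2 with
prior degrees of freedom d0, both estimated by the method of moments on
log-variances (digamma/trigamma equations; trigamma inversion by Newton
iteration).  The moderated t uses the posterior variance

    s~^2 = (d0 * s0^2 + df * s^2) / (d0 + df)

on df + d0 total degrees of freedom.

The standard contrasts of a two-layer, four-age paired design are built in
:func:`run_all_contrasts`: ages pooled late (P23/P45) vs early (P2/P9), and
layer LII vs LDeep pooled over ages and within each age, with animal as a
fixed blocking factor for the layer contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_formats import ExpressionMatrix

log = logging.getLogger(__name__)

EARLY_AGES = ("P2", "P9")
LATE_AGES = ("P23", "P45")


@dataclass(frozen=True)
class EBayesParams:
    """Prior degrees of freedom (possibly infinite) and prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be >= 0")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be > 0")


@dataclass
class DETable:
    """Per-feature DE results for one named contrast."""

    contrast_name: str
    table: pd.DataFrame  # index feature_id; lfc, t_mod, p_raw, p_adj, mean_expr, df_total

    def significant(self, alpha: float = 0.05, lfc_min: float = 0.0) -> pd.DataFrame:
        t = self.table
        return t[(t["p_adj"] < alpha) & (t["lfc"].abs() > lfc_min)]


# ---------------------------------------------------------------------------
# empirical-Bayes variance moments
# ---------------------------------------------------------------------------

def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(variances: np.ndarray, df_resid: float) -> EBayesParams:
    """Method-of-moments fit of the scaled-F model to residual variances.

    Zero variances must be removed by the caller.
    """
    x = np.asarray(variances, dtype=float)
    if x.size < 2:
        return EBayesParams(0.0, float(x.mean()) if x.size else 1.0)
    z = np.log(x)
    e = z - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    emean = e.mean()
    evar = np.mean((e - emean) ** 2) * x.size / (x.size - 1)
    evar -= float(special.polygamma(1, df_resid / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        if np.isfinite(d0):
            s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        else:
            s0_sq = np.exp(emean)
    else:
        d0, s0_sq = np.inf, np.exp(emean)
    return EBayesParams(float(d0), float(s0_sq))


def posterior_variances(variances: np.ndarray, df_resid: float,
                        params: EBayesParams) -> np.ndarray:
    s2 = np.asarray(variances, dtype=float)
    if np.isinf(params.d0):
        return np.full_like(s2, params.s0_sq)
    if params.d0 == 0:
        return s2.copy()
    return (params.d0 * params.s0_sq + df_resid * s2) / (params.d0 + df_resid)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_and_moderate(matrix: ExpressionMatrix, design: pd.DataFrame,
                     contrast: pd.Series, contrast_name: str = "contrast",
                     weights: pd.DataFrame | None = None,
                     eb_params: EBayesParams | None = None,
                     ) -> tuple[DETable, EBayesParams]:
    """Weighted least squares per feature, then empirical-Bayes moderation.

    ``design`` is samples x coefficients, ``contrast`` a vector over the
    coefficients (log2-fold-change scale: numerator minus denominator).
    ``eb_params`` forces the prior instead of estimating it.
    """
    Y = matrix.values.to_numpy(dtype=float)
    X = design.reindex(matrix.sample_ids).to_numpy(dtype=float)
    c = contrast.reindex(design.columns).fillna(0.0).to_numpy(dtype=float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(f"design is rank deficient (rank {rank} < {p} columns)")
    df_resid = n - p
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")

    W = (weights.reindex(index=matrix.values.index, columns=matrix.sample_ids)
         .to_numpy(dtype=float) if weights is not None else None)
    G = Y.shape[0]
    lfc = np.empty(G)
    sigma2 = np.empty(G)
    vunscaled = np.empty(G)
    if W is None:
        XtX_inv = np.linalg.inv(X.T @ X)
        H = XtX_inv @ X.T
        beta = H @ Y.T                       # p x G
        resid = Y.T - X @ beta
        sigma2[:] = (resid ** 2).sum(axis=0) / df_resid
        lfc[:] = c @ beta
        vunscaled[:] = float(c @ XtX_inv @ c)
    else:
        for g in range(G):
            w = W[g]
            if np.any(w <= 0):
                raise ValueError("weights must be strictly positive")
            sw = np.sqrt(w)
            Xw = X * sw[:, None]
            yw = Y[g] * sw
            XtX_inv = np.linalg.inv(Xw.T @ Xw)
            b = XtX_inv @ (Xw.T @ yw)
            r = yw - Xw @ b
            sigma2[g] = float(r @ r) / df_resid
            lfc[g] = float(c @ b)
            vunscaled[g] = float(c @ XtX_inv @ c)

    positive = sigma2 > 0
    if not positive.all():
        log.info("fit_and_moderate: %d zero-variance features reinstated at s0^2",
                 int((~positive).sum()))
    if eb_params is None:
        if positive.sum() < 2:
            raise ValueError("too few positive-variance features for moderation")
        eb_params = estimate_prior(sigma2[positive], df_resid)
    s2_work = np.where(positive, sigma2,
                       eb_params.s0_sq if np.isfinite(eb_params.s0_sq) else 1.0)
    s2_post = posterior_variances(s2_work, df_resid, eb_params)
    df_total = df_resid + eb_params.d0
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = lfc / np.sqrt(s2_post * vunscaled)
    if np.isfinite(df_total):
        p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    else:
        p_raw = 2.0 * stats.norm.sf(np.abs(t_mod))
    table = pd.DataFrame({
        "lfc": lfc,
        "t_mod": t_mod,
        "p_raw": p_raw,
        "p_adj": bh_adjust(p_raw),
        "mean_expr": np.median(Y, axis=1),
        "df_total": df_total,
    }, index=matrix.values.index)
    table.index.name = "feature_id"
    return DETable(contrast_name, table), eb_params


# ---------------------------------------------------------------------------
# BH adjustment and calling
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def call_de(de: DETable, alpha: float = 0.05, lfc_min: float = 0.0,
            ) -> tuple[set[str], pd.Series]:
    """Features with adjusted p below ``alpha`` and |lfc| above ``lfc_min``,
    plus per-feature direction ('up' = higher in the contrast numerator)."""
    hits = de.significant(alpha, lfc_min)
    direction = pd.Series(np.where(hits["lfc"] > 0, "up", "down"),
                          index=hits.index, name="direction")
    return set(hits.index), direction


# ---------------------------------------------------------------------------
# study contrasts
# ---------------------------------------------------------------------------

def age_design(matrix: ExpressionMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """Group-means design over ages; contrast = late (P23/P45) vs early (P2/P9)."""
    ages = [s.age for s in matrix.samples]
    present = [a for a in ("P2", "P9", "P23", "P45") if a in ages]
    X = pd.DataFrame({f"age{a}": [1.0 if x == a else 0.0 for x in ages]
                      for a in present}, index=matrix.sample_ids)
    early = [a for a in present if a in EARLY_AGES]
    late = [a for a in present if a in LATE_AGES]
    if not early or not late:
        raise ValueError("age contrast needs samples on both sides")
    c = pd.Series(0.0, index=X.columns)
    for a in late:
        c[f"age{a}"] = 1.0 / len(late)
    for a in early:
        c[f"age{a}"] = -1.0 / len(early)
    return X, c


def layer_design(matrix: ExpressionMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Animal-blocked design with a per-age LII effect.

    Columns: one indicator per animal plus one ``LII:age`` column per age,
    so per-age layer contrasts are single coefficients and the pooled layer
    contrast is their average.
    """
    animals = sorted({s.animal_id for s in matrix.samples})
    ages = [a for a in ("P2", "P9", "P23", "P45")
            if a in {s.age for s in matrix.samples}]
    cols = {}
    for an in animals:
        cols[f"animal_{an}"] = [1.0 if s.animal_id == an else 0.0
                                for s in matrix.samples]
    for a in ages:
        cols[f"LII:{a}"] = [1.0 if (s.age == a and s.layer == "LII") else 0.0
                            for s in matrix.samples]
    return pd.DataFrame(cols, index=matrix.sample_ids), ages


def group_design(matrix: ExpressionMatrix, group_field: str = "group_extra",
                 numerator: str = "stellate", denominator: str = "rest",
                 ) -> tuple[pd.DataFrame, pd.Series]:
    """Two-group means design on an extra grouping column (e.g. stellate
    cells vs the rest of the tissue)."""
    groups = [getattr(s, group_field) for s in matrix.samples]
    if numerator not in groups or denominator not in groups:
        raise ValueError("both groups must be present")
    X = pd.DataFrame({
        numerator: [1.0 if g == numerator else 0.0 for g in groups],
        denominator: [1.0 if g == denominator else 0.0 for g in groups],
    }, index=matrix.sample_ids)
    c = pd.Series({numerator: 1.0, denominator: -1.0})
    return X, c


def run_all_contrasts(matrix: ExpressionMatrix,
                      weights: pd.DataFrame | None = None,
                      alpha: float = 0.05, lfc_min: float = 0.0,
                      ) -> tuple[dict[str, DETable], dict]:
    """Fit the study's contrasts and report DE-set overlap counts.

    Emits the age contrast, the pooled layer contrast, and a layer contrast
    within each age; a contrast whose sides are empty is skipped with a
    warning.  Returns (tables by name, summary with per-contrast counts and
    the age/layer overlap).
    """
    tables: dict[str, DETable] = {}
    try:
        X_age, c_age = age_design(matrix)
        tables["age_late_vs_early"], _ = fit_and_moderate(
            matrix, X_age, c_age, "age_late_vs_early", weights)
    except ValueError as exc:
        log.warning("skipping age contrast: %s", exc)

    X_layer, ages = layer_design(matrix)
    lii_cols = [f"LII:{a}" for a in ages]
    if all(X_layer[c].sum() > 0 for c in lii_cols) and len(ages) > 0:
        pooled = pd.Series(0.0, index=X_layer.columns)
        for col in lii_cols:
            pooled[col] = 1.0 / len(lii_cols)
        tables["layer_LII_vs_LDeep"], _ = fit_and_moderate(
            matrix, X_layer, pooled, "layer_LII_vs_LDeep", weights)
        for a in ages:
            single = pd.Series(0.0, index=X_layer.columns)
            single[f"LII:{a}"] = 1.0
            name = f"layer_LII_vs_LDeep@{a}"
            tables[name], _ = fit_and_moderate(matrix, X_layer, single, name, weights)
    else:
        log.warning("skipping layer contrasts: a layer side is empty")

    de_sets = {name: call_de(t, alpha, lfc_min)[0] for name, t in tables.items()}
    summary = {
        "n_de": {name: len(s) for name, s in de_sets.items()},
        "age_layer_overlap": len(de_sets.get("age_late_vs_early", set())
                                 & de_sets.get("layer_LII_vs_LDeep", set())),
        "per_age_layer_union": len(set().union(*(
            de_sets[n] for n in de_sets if n.startswith("layer_LII_vs_LDeep@")))
            if any(n.startswith("layer_LII_vs_LDeep@") for n in de_sets) else set()),
    }
    return tables, summary


def de_union(tables: dict[str, DETable], alpha: float = 0.05,
             lfc_min: float = 0.0) -> set[str]:
    """Union of DE features over every fitted contrast (the clustering input)."""
    out: set[str] = set()
    for t in tables.values():
        out |= call_de(t, alpha, lfc_min)[0]
    return out
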