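"""Negatively correlated miRNA target integration.

Joins differential-expression results, matched expression matrices and
predicted/validated target tables into candidate targets via a
three-requirement filter:

1. the gene is a predicted, conserved target (context score strictly below
   the conservation threshold) or a database-validated target of the miRNA;
2. both the miRNA and the gene are differentially expressed in the same
   contrast (between layers, or between early and late ages);
3. their expression profiles are negatively correlated, Spearman rho
   strictly below -0.5.

Also provides the candidate ranking used for per-miRNA target shortlists
and the correlation-skew analysis: a one-sided Mann-Whitney U test of
whether conserved-target correlations are stochastically smaller (more
negative) than those of all predicted targets, optionally after stacking
stringency filters (stricter context score, top-quartile miRNA expression,
same-module site fraction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import OUTLIER_LABEL, ModuleAssignment
from .diffexpr import DETable, call_de
from .io_formats import ExpressionMatrix, TargetRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairCorrelation:
    mirna_id: str
    gene_id: str
    rho: float
    n_samples: int
    source: str
    context_score: float | None = None


@dataclass
class CandidateTarget:
    mirna_id: str
    gene_id: str
    rho: float
    n_samples: int
    sources: frozenset[str]
    context_score: float | None
    de_flags: dict[str, bool]  # mirna_age, mirna_layer, gene_age, gene_layer
    gene_median_expr: float


# ---------------------------------------------------------------------------
# pairwise Spearman correlations
# ---------------------------------------------------------------------------

def pair_correlations(mirna_matrix: ExpressionMatrix,
                      mrna_matrix: ExpressionMatrix,
                      target_records: list[TargetRecord],
                      ) -> list[PairCorrelation]:
    """Spearman rho (average ranks for ties) over the shared samples for
    every target record whose miRNA and gene are both measured."""
    shared = [s for s in mirna_matrix.sample_ids if s in set(mrna_matrix.sample_ids)]
    if len(shared) < 3:
        raise ValueError("need at least three shared samples")
    mirna_ranks = pd.DataFrame(
        stats.rankdata(mirna_matrix.values[shared].to_numpy(dtype=float), axis=1),
        index=mirna_matrix.values.index, columns=shared)
    gene_ranks = pd.DataFrame(
        stats.rankdata(mrna_matrix.values[shared].to_numpy(dtype=float), axis=1),
        index=mrna_matrix.values.index, columns=shared)

    out = []
    for rec in target_records:
        if rec.mirna_id not in mirna_ranks.index or rec.gene_id not in gene_ranks.index:
            continue
        x = mirna_ranks.loc[rec.mirna_id].to_numpy()
        y = gene_ranks.loc[rec.gene_id].to_numpy()
        sx, sy = x.std(), y.std()
        rho = float(np.corrcoef(x, y)[0, 1]) if sx > 0 and sy > 0 else 0.0
        out.append(PairCorrelation(rec.mirna_id, rec.gene_id, rho, len(shared),
                                   rec.source, rec.context_score))
    return out


# ---------------------------------------------------------------------------
# the three-requirement filter
# ---------------------------------------------------------------------------

def three_requirement_filter(pairs: list[PairCorrelation],
                             mirna_de: dict[str, DETable],
                             gene_de: dict[str, DETable],
                             rho_max: float = -0.5,
                             alpha: float = 0.05,
                             ) -> list[CandidateTarget]:
    """Apply the three requirements; all inequalities are strict.

    ``mirna_de`` and ``gene_de`` map ``"age"`` and ``"layer"`` to DE tables.
    A pair qualifies if it has a conserved-predicted or validated source,
    both members are DE in the age contrast or both in the layer contrast,
    and rho < ``rho_max``.
    """
    de_sets = {}
    for side, tables in (("mirna", mirna_de), ("gene", gene_de)):
        for contrast in ("age", "layer"):
            t = tables.get(contrast)
            de_sets[f"{side}_{contrast}"] = call_de(t, alpha)[0] if t is not None else set()
    median_expr = {}
    for t in gene_de.values():
        median_expr.update(t.table["mean_expr"].to_dict())

    merged: dict[tuple[str, str], dict] = {}
    for p in pairs:
        entry = merged.setdefault((p.mirna_id, p.gene_id), {
            "rho": p.rho, "n": p.n_samples, "sources": set(), "score": None})
        entry["sources"].add(p.source)
        if p.context_score is not None:
            entry["score"] = (p.context_score if entry["score"] is None
                              else min(entry["score"], p.context_score))

    candidates = []
    for (mirna, gene), entry in sorted(merged.items()):
        if not (entry["sources"] & {"predicted_conserved", "validated"}):
            continue
        flags = {
            "mirna_age": mirna in de_sets["mirna_age"],
            "mirna_layer": mirna in de_sets["mirna_layer"],
            "gene_age": gene in de_sets["gene_age"],
            "gene_layer": gene in de_sets["gene_layer"],
        }
        same_contrast = ((flags["mirna_age"] and flags["gene_age"])
                         or (flags["mirna_layer"] and flags["gene_layer"]))
        if not same_contrast:
            continue
        if not entry["rho"] < rho_max:  # strict
            continue
        candidates.append(CandidateTarget(
            mirna, gene, entry["rho"], entry["n"], frozenset(entry["sources"]),
            entry["score"], flags, float(median_expr.get(gene, np.nan))))
    return candidates


def rank_candidates(candidates: list[CandidateTarget],
                    min_median_expr: float = 5.0,
                    require_both_contrasts: bool = True,
                    ) -> list[CandidateTarget]:
    """Shortlist ranking: keep candidates whose gene median normalized log2
    expression is at least ``min_median_expr`` and (optionally) whose gene
    is DE in both the age and the layer contrast; order by best (most
    negative) context score, then most negative rho, then gene id."""
    kept = []
    for c in candidates:
        if not (c.gene_median_expr >= min_median_expr):
            continue
        if require_both_contrasts and not (c.de_flags["gene_age"]
                                           and c.de_flags["gene_layer"]):
            continue
        kept.append(c)
    return sorted(kept, key=lambda c: (
        c.context_score if c.context_score is not None else np.inf,
        c.rho, c.gene_id))


# ---------------------------------------------------------------------------
# skew-analysis filters
# ---------------------------------------------------------------------------

def expression_quartile_filter(mirna_matrix: ExpressionMatrix,
                               q: float = 0.25) -> set[str]:
    """miRNAs whose median expression lies in the top ``q`` fraction;
    boundary ties are all included."""
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    medians = mirna_matrix.values.median(axis=1)
    threshold = float(np.quantile(medians.to_numpy(), 1.0 - q))
    return set(medians.index[medians >= threshold])


def same_module_site_fraction(gene_id: str,
                              target_records: list[TargetRecord],
                              assignment: ModuleAssignment) -> float | None:
    """Fraction of a gene's predicted targeting miRNAs (with module labels)
    that belong to the modal module; ``None`` with no labelled site."""
    mirnas = {r.mirna_id for r in target_records
              if r.gene_id == gene_id and r.source.startswith("predicted")}
    labels = [assignment.labels[m] for m in mirnas
              if assignment.labels.get(m, OUTLIER_LABEL) != OUTLIER_LABEL]
    if not labels:
        return None
    counts = pd.Series(labels).value_counts()
    return float(counts.iloc[0] / len(labels))


def all_same_module_fractions(target_records: list[TargetRecord],
                              assignment: ModuleAssignment) -> dict[str, float]:
    by_gene: dict[str, set[str]] = {}
    for r in target_records:
        if r.source.startswith("predicted"):
            by_gene.setdefault(r.gene_id, set()).add(r.mirna_id)
    out = {}
    for gene, mirnas in by_gene.items():
        labels = [assignment.labels[m] for m in mirnas
                  if assignment.labels.get(m, OUTLIER_LABEL) != OUTLIER_LABEL]
        if labels:
            counts = pd.Series(labels).value_counts()
            out[gene] = float(counts.iloc[0] / len(labels))
    return out


def apply_skew_filters(pairs: list[PairCorrelation],
                       context_max: float | None = None,
                       mirna_whitelist: set[str] | None = None,
                       min_same_module_fraction: float | None = None,
                       same_module_fractions: dict[str, float] | None = None,
                       ) -> list[PairCorrelation]:
    """Stacked stringency filters for the skew analysis (order-independent)."""
    out = pairs
    if context_max is not None:
        out = [p for p in out
               if p.context_score is not None and p.context_score < context_max]
    if mirna_whitelist is not None:
        out = [p for p in out if p.mirna_id in mirna_whitelist]
    if min_same_module_fraction is not None:
        fractions = same_module_fractions or {}
        out = [p for p in out
               if fractions.get(p.gene_id, 0.0) >= min_same_module_fraction]
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U counting pairs with x below y (ties count one half)."""
    less = (x[:, None] < y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    return float(less) + 0.5 * float(ties)


def mann_whitney_u(x, y, exact_max_n: int = 8) -> tuple[float, float, str]:
    """One-sided Mann-Whitney U test that ``x`` is stochastically smaller.

    Exact enumeration of all group assignments when both sides have at most
    ``exact_max_n`` observations (correct under ties); otherwise the
    tie-corrected normal approximation with continuity correction.
    Returns (U, one-sided p, method).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    U = _u_statistic(x, y)
    if n1 <= exact_max_n and n2 <= exact_max_n:
        pooled = np.concatenate([x, y])
        idx = range(n1 + n2)
        total = comb(n1 + n2, n1)
        hits = 0
        for chosen in combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(chosen)] = True
            if _u_statistic(pooled[mask], pooled[~mask]) >= U:
                hits += 1
        return U, hits / total, "exact"
    N = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return U, 0.5, "normal"
    z = (U - mu - 0.5) / np.sqrt(var)
    return U, float(stats.norm.sf(z)), "normal"


@dataclass
class SkewResult:
    U: float
    p_one_sided: float
    n_conserved: int
    n_control: int
    method: str
    median_conserved_rho: float
    median_control_rho: float


def correlation_skew_test(conserved_pairs: list[PairCorrelation],
                          control_pairs: list[PairCorrelation],
                          **filter_kwargs) -> SkewResult:
    """Test whether conserved-target correlations are skewed negative
    relative to the control distribution of all predicted targets.

    Keyword arguments are passed to :func:`apply_skew_filters` and act on
    the conserved side only.
    """
    conserved = apply_skew_filters(conserved_pairs, **filter_kwargs)
    if not conserved or not control_pairs:
        raise ValueError("a side of the skew test is empty after filtering")
    x = np.array([p.rho for p in conserved])
    y = np.array([p.rho for p in control_pairs])
    U, p, method = mann_whitney_u(x, y)
    return SkewResult(U, p, x.size, y.size, method,
                      float(np.median(x)), float(np.median(y)))
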