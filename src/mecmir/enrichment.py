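"""Local over-representation analysis: one-sided Fisher's exact test per
term with sample odds ratios, BH adjustment, input and term-size filters,
and the capped long-format export used for dot-matrix plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DETable, bh_adjust

log = logging.getLogger(__name__)


@dataclass
class EnrichmentRecord:
    term_id: str
    term_name: str
    term_size: int
    universe_size: int
    overlap: int
    query_size: int
    odds_ratio: float
    p_raw: float
    p_adj: float
    significant: bool


def select_query_genes(de_table: DETable, lfc_min: float = 0.5,
                       direction: str = "up", alpha: float = 0.05) -> set[str]:
    """Genes with |log fold change| strictly above ``lfc_min`` in the stated
    direction among the BH-significant genes of a contrast.

    ``direction`` is 'up' (higher in the contrast numerator) or 'down'.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    t = de_table.significant(alpha)
    if direction == "up":
        return set(t.index[t["lfc"] > lfc_min])
    return set(t.index[t["lfc"] < -lfc_min])


def fisher_enrichment(query: set[str], universe: set[str], terms,
                      max_term_size: int = 2500, alpha: float = 0.05,
                      ) -> list[EnrichmentRecord]:
    """One-sided hypergeometric enrichment over ``terms``.

    Terms are intersected with the universe; terms with more than
    ``max_term_size`` universe genes are removed before testing.  The
    sample odds ratio is ad/bc with the Haldane-Anscombe 0.5 correction
    when any cell is zero.  BH adjustment runs over the tested terms only.
    """
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")
    N = len(universe)
    n_query = len(query)
    tested = []
    for term in terms:
        in_universe = term.gene_ids & universe
        if not in_universe or len(in_universe) > max_term_size:
            continue
        overlap = len(in_universe & query)
        tested.append((term, len(in_universe), overlap))
    if not tested:
        return []
    p_raw = np.array([
        float(stats.hypergeom.sf(overlap - 1, N, size, n_query))
        for _, size, overlap in tested
    ])
    p_adj = bh_adjust(p_raw)
    records = []
    for (term, size, overlap), pr, pa in zip(tested, p_raw, p_adj):
        a = overlap
        b = n_query - overlap
        c = size - overlap
        d = N - n_query - size + overlap
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        odds_ratio = (a * d) / (b * c)
        records.append(EnrichmentRecord(
            term.term_id, term.term_name, size, N, overlap, n_query,
            float(odds_ratio), float(pr), float(pa), bool(pa < alpha)))
    return records


def export_dot_matrix(records_by_geneset: dict[str, list[EnrichmentRecord]],
                      or_cap: float = 12.0, neg_log_p_cap: float = 15.0,
                      significant_only: bool = True) -> pd.DataFrame:
    """Long-format (gene set, term) table with -log10 adjusted p and odds
    ratio, each rounded down to its cap; uncapped values are kept in
    separate columns."""
    rows = []
    for geneset, records in records_by_geneset.items():
        for r in records:
            if significant_only and not r.significant:
                continue
            neg_log_p = -np.log10(r.p_adj) if r.p_adj > 0 else np.inf
            rows.append({
                "gene_set": geneset,
                "term_id": r.term_id,
                "term_name": r.term_name,
                "odds_ratio": r.odds_ratio,
                "neg_log10_p_adj": neg_log_p,
                "or_capped": min(r.odds_ratio, or_cap),
                "neg_log10_p_capped": min(neg_log_p, neg_log_p_cap),
                "overlap": r.overlap,
                "term_size": r.term_size,
            })
    return pd.DataFrame(rows, columns=[
        "gene_set", "term_id", "term_name", "odds_ratio", "neg_log10_p_adj",
        "or_capped", "neg_log10_p_capped", "overlap", "term_size"])
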