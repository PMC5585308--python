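"""Genomic miRNA clusters by the 10-kb chain rule and their association
with co-expression module co-membership.

A cluster is a maximal chain of two or more miRNA loci on one chromosome in
which each consecutive pair is separated by at most ``max_gap`` bp.  Gaps
are measured between intervals (next start minus previous end, floored at 0
for overlapping loci) and the boundary is inclusive: a 10,000-bp gap joins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .coexpression import OUTLIER_LABEL, ModuleAssignment
from .io_formats import GenomicLocus

log = logging.getLogger(__name__)


@dataclass
class GenomicCluster:
    cluster_id: str
    member_ids: list[str]  # ordered by coordinate
    chrom: str
    span_bp: int


def call_clusters(loci: list[GenomicLocus], max_gap: int = 10_000,
                  ) -> list[GenomicCluster]:
    """Chain coordinate-sorted loci per chromosome while the inter-locus gap
    is at most ``max_gap``; emit maximal chains with >= 2 members."""
    by_chrom: dict[str, list[GenomicLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chrom, []).append(locus)
    clusters: list[GenomicCluster] = []
    for chrom in sorted(by_chrom):
        chain: list[GenomicLocus] = []
        for locus in sorted(by_chrom[chrom], key=lambda l: (l.start, l.end, l.mirna_id)):
            if chain and max(locus.start - chain[-1].end, 0) <= max_gap:
                chain.append(locus)
            else:
                if len(chain) >= 2:
                    clusters.append(_emit(chain, len(clusters)))
                chain = [locus]
        if len(chain) >= 2:
            clusters.append(_emit(chain, len(clusters)))
    return clusters


def _emit(chain: list[GenomicLocus], n_existing: int) -> GenomicCluster:
    return GenomicCluster(
        cluster_id=f"cluster_{n_existing + 1}",
        member_ids=[l.mirna_id for l in chain],
        chrom=chain[0].chrom,
        span_bp=max(l.end for l in chain) - min(l.start for l in chain),
    )


# ---------------------------------------------------------------------------
# association with co-expression modules
# ---------------------------------------------------------------------------

@dataclass
class CoMembershipResult:
    table: list[list[int]]  # [[both, cluster_only], [module_only, neither]]
    odds_ratio: float | None
    fisher_p: float
    perm_p: float | None = None


def _pair_counts(cluster_of: dict[str, int], module_of: dict[str, int],
                 ids: list[str]) -> np.ndarray:
    same_c = np.zeros((len(ids), len(ids)), dtype=bool)
    same_m = np.zeros_like(same_c)
    c = np.array([cluster_of.get(i, -1) for i in ids])
    m = np.array([module_of[i] for i in ids])
    same_c = (c[:, None] == c[None, :]) & (c[:, None] >= 0)
    same_m = m[:, None] == m[None, :]
    iu = np.triu_indices(len(ids), k=1)
    sc, sm = same_c[iu], same_m[iu]
    return np.array([[int((sc & sm).sum()), int((sc & ~sm).sum())],
                     [int((~sc & sm).sum()), int((~sc & ~sm).sum())]])


def co_membership_test(clusters: list[GenomicCluster],
                       assignment: ModuleAssignment,
                       n_permutations: int = 1000,
                       seed: int = 0,
                       randomize_ties: bool = False) -> CoMembershipResult:
    """Fisher's exact test on pairs of module-labelled miRNAs, crossing
    same-genomic-cluster with same-co-expression-module.

    Pairs are not independent, so the hypergeometric p is descriptive; a
    label-permutation p (module labels shuffled over the same features)
    calibrates it.  With ``randomize_ties`` the permutation p breaks ties
    on the discrete statistic uniformly at random, which makes it exactly
    uniform under the null (useful for calibration checks); the default is
    the usual conservative (1 + #>=obs) / (1 + B) estimate.  A degenerate
    table margin yields an undefined odds ratio (reported as ``None``).
    """
    module_of = {f: l for f, l in assignment.labels.items() if l != OUTLIER_LABEL}
    cluster_of: dict[str, int] = {}
    for ci, cl in enumerate(clusters):
        for mid in cl.member_ids:
            cluster_of[mid] = ci
    ids = sorted(module_of)
    if len([i for i in ids if i in cluster_of]) < 2:
        raise ValueError("need at least two clustered, module-labelled miRNAs")

    table = _pair_counts(cluster_of, module_of, ids)
    a, b = table[0]
    c, d = table[1]
    if min(a + b, c + d, a + c, b + d) == 0:
        odds_ratio = None
    else:
        odds_ratio = float(a * d) / (b * c) if b * c > 0 else np.inf
    fisher_p = float(stats.fisher_exact(table, alternative="greater")[1])

    perm_p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        labels = np.array([module_of[i] for i in ids])
        obs = table[0][0]
        greater = 0
        equal = 0
        cvec = np.array([cluster_of.get(i, -1) for i in ids])
        iu = np.triu_indices(len(ids), k=1)
        same_c = ((cvec[:, None] == cvec[None, :]) & (cvec[:, None] >= 0))[iu]
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            same_m = (perm[:, None] == perm[None, :])[iu]
            stat = int((same_c & same_m).sum())
            if stat > obs:
                greater += 1
            elif stat == obs:
                equal += 1
        if randomize_ties:
            perm_p = (greater + rng.uniform() * (1.0 + equal)) / (1.0 + n_permutations)
        else:
            perm_p = (1.0 + greater + equal) / (1.0 + n_permutations)
    return CoMembershipResult([[int(a), int(b)], [int(c), int(d)]],
                              odds_ratio, fisher_p, perm_p)
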