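"""Co-expression modules by hierarchical clustering with recursive
gap-statistic thresholding (PART-style).

Features (typically the union of all differentially expressed miRNAs) are
clustered on correlation distance d = 1 - Pearson r with average linkage.
The dendrogram is then cut recursively: at each subtree the number of
clusters k is chosen by the gap statistic against B reference datasets
drawn uniformly over the per-sample range of the current data, using the
standard one-standard-error rule; k = 1 stops the recursion and emits a
module, and any part smaller than ``min_size`` is labelled an outlier
(label 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_formats import ExpressionMatrix

log = logging.getLogger(__name__)

OUTLIER_LABEL = 0


@dataclass
class Dendrogram:
    """Average-linkage tree over correlation distance."""

    linkage: np.ndarray
    feature_ids: list[str]
    distances: np.ndarray  # condensed pairwise 1 - r

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return self.feature_ids[node.id]
            left, right = node.get_left(), node.get_right()
            ld = node.dist - left.dist
            rd = node.dist - right.dist
            return f"({render(left)}:{ld:.6g},{render(right)}:{rd:.6g})"

        return render(tree) + ";"


@dataclass
class ModuleAssignment:
    """feature -> module label; label 0 marks outliers."""

    labels: dict[str, int]

    def members(self, label: int) -> list[str]:
        return [f for f, l in self.labels.items() if l == label]

    def module_labels(self) -> list[int]:
        return sorted({l for l in self.labels.values() if l != OUTLIER_LABEL})

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for l in self.labels.values():
            out[l] = out.get(l, 0) + 1
        return out


@dataclass
class ModuleProfile:
    module_label: int
    representative: pd.Series  # per-sample mean of z-scored member profiles
    n_members: int


# ---------------------------------------------------------------------------
# dendrogram
# ---------------------------------------------------------------------------

def _correlation_condensed(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance feature profile")
    corr = np.corrcoef(values)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return squareform(dist, checks=False)


def correlation_dendrogram(matrix: ExpressionMatrix,
                           features: list[str] | None = None) -> Dendrogram:
    """Average-linkage dendrogram on d = 1 - Pearson r across all samples.

    Features are processed in sorted-id order so that the result does not
    depend on input order (deterministic tie-breaking).
    """
    ids = sorted(features) if features is not None else sorted(matrix.feature_ids)
    if len(ids) < 2:
        raise ValueError("need at least two features")
    values = matrix.values.loc[ids].to_numpy(dtype=float)
    condensed = _correlation_condensed(values)
    Z = hierarchy.linkage(condensed, method="average")
    return Dendrogram(Z, ids, condensed)


# ---------------------------------------------------------------------------
# gap statistic and recursive partitioning
# ---------------------------------------------------------------------------

def _within_dispersion(condensed: np.ndarray, labels: np.ndarray) -> float:
    """W = sum over clusters of (sum of within-cluster pairwise d) / n_r."""
    n = labels.size
    d = squareform(condensed, checks=False)
    W = 0.0
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        if idx.size > 1:
            W += d[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return W


def _cut_labels(Z: np.ndarray, k: int) -> np.ndarray:
    return hierarchy.fcluster(Z, t=k, criterion="maxclust")


def _gap_select_k(values: np.ndarray, condensed: np.ndarray, Z: np.ndarray,
                  max_k: int, B: int, rng: np.random.Generator) -> int:
    """Gap-statistic choice of k with the one-standard-error rule."""
    m = values.shape[0]
    ks = range(1, min(max_k, m) + 1)
    eps = 1e-12

    def dispersions(cond: np.ndarray, Zl: np.ndarray) -> np.ndarray:
        return np.array([
            max(_within_dispersion(cond, _cut_labels(Zl, k)), eps) for k in ks
        ])

    logW = np.log(dispersions(condensed, Z))
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    ref_logW = np.empty((B, len(logW)))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=values.shape)
        ref = ref + rng.normal(0.0, 1e-9, size=ref.shape)  # guard zero variance
        cond_ref = _correlation_condensed(ref)
        Z_ref = hierarchy.linkage(cond_ref, method="average")
        ref_logW[b] = np.log(dispersions(cond_ref, Z_ref))
    gap = ref_logW.mean(axis=0) - logW
    s = ref_logW.std(axis=0, ddof=1) * np.sqrt(1.0 + 1.0 / B)
    for i, k in enumerate(ks):
        if i + 1 >= len(gap) or gap[i] >= gap[i + 1] - s[i + 1]:
            return k
    return max(ks)


def part_partition(matrix: ExpressionMatrix, dendrogram: Dendrogram | None = None,
                   min_size: int = 5, max_k: int = 10, B: int = 50,
                   seed: int = 0, features: list[str] | None = None,
                   ) -> ModuleAssignment:
    """Recursive gap-thresholded partition of the correlation dendrogram.

    Returns a :class:`ModuleAssignment` whose positive labels number the
    emitted modules in discovery order; features in parts smaller than
    ``min_size`` get the outlier label 0.
    """
    if dendrogram is None:
        dendrogram = correlation_dendrogram(matrix, features)
    ids = dendrogram.feature_ids
    all_values = matrix.values.loc[ids].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    labels = {fid: OUTLIER_LABEL for fid in ids}
    next_label = 1

    def recurse(index: np.ndarray, condensed: np.ndarray, Z: np.ndarray) -> None:
        nonlocal next_label
        if index.size < min_size:
            return  # stays outlier
        if index.size < 2:
            return
        vals = all_values[index]
        k = _gap_select_k(vals, condensed, Z, max_k, B, rng)
        if k == 1:
            for i in index:
                labels[ids[i]] = next_label
            next_label += 1
            return
        parts = _cut_labels(Z, k)
        for lab in np.unique(parts):
            sub = index[parts == lab]
            if sub.size < min_size:
                continue  # outliers
            if sub.size == index.size:
                # cut failed to split; emit as one module
                for i in sub:
                    labels[ids[i]] = next_label
                next_label += 1
                return
            vals_sub = all_values[sub]
            try:
                cond_sub = _correlation_condensed(vals_sub)
            except ValueError:
                continue
            Z_sub = hierarchy.linkage(cond_sub, method="average")
            recurse(sub, cond_sub, Z_sub)

    root = np.arange(len(ids))
    if root.size >= min_size:
        recurse(root, dendrogram.distances, dendrogram.linkage)
    return ModuleAssignment(labels)


# ---------------------------------------------------------------------------
# module profiles
# ---------------------------------------------------------------------------

def module_profiles(matrix: ExpressionMatrix, assignment: ModuleAssignment,
                    ) -> list[ModuleProfile]:
    """Per-module representative profile: mean of the z-scored (across
    samples) member profiles.  Outliers are excluded."""
    profiles = []
    for label in assignment.module_labels():
        members = assignment.members(label)
        if not members:
            raise ValueError(f"module {label} is empty")
        values = matrix.values.loc[members]
        z = values.sub(values.mean(axis=1), axis=0)
        sd = values.std(axis=1, ddof=0)
        if np.any(sd == 0):
            raise ValueError("zero-variance member profile")
        z = z.div(sd, axis=0)
        profiles.append(ModuleProfile(label, z.mean(axis=0), len(members)))
    return profiles
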