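"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates the design of a postnatal laminar expression study:
two cortical layers (LII, LDeep) sampled at four postnatal ages (P2, P9,
P23, P45) with paired within-animal layer samples.  It plants

* age and layer effects organised into co-expression modules with eight
  canonical profile shapes (sharp late increase/decrease, laminar with
  opposing age trends, single-age laminar spikes, gradual decline, ...),
* anti-correlated miRNA -> mRNA regulation for a configurable fraction of
  genes, with repression slope modestly stronger for more highly expressed
  miRNAs,
* genomically clustered co-module miRNA loci,
* a stellate-vs-rest qPCR Ct contrast with reliability flags,

and returns ground-truth tables so that every downstream stage can be
scored against what was planted.

miRNA (array-like) data are Gaussian on the log2 scale; mRNA (RNA-seq-like)
data are negative-binomial counts around the exponentiated log2 means, so
the TMM / log-CPM / precision-weight path is exercised end to end.

All draws come from one :class:`numpy.random.Generator` stream in the fixed
order: baselines, module amplitudes, miRNA noise, target assignment and
scores, decoy sites, gene noise, sequencing depths, counts, loci, Ct data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (AGES, LAYERS, ExpressionMatrix, GenomicLocus,
                         SampleAnnotation, TargetRecord, TermAnnotation)

# Eight canonical module profile shapes: per-module mean log2 shift (in units
# of ``profile_scale``) for each (age, layer) cell; rows P2,P9,P23,P45,
# columns LII,LDeep.
DEFAULT_MODULE_PROFILES: tuple[np.ndarray, ...] = tuple(
    np.array(shape, dtype=float) for shape in (
        [[0, 0], [1, 0], [0, 0], [0, 0]],        # 1: LII spike at P9
        [[-1, -1], [-1, -1], [1, 1], [1, 1]],    # 2: sharp increase P9->P23
        [[1, 0], [1, 0], [0, -1], [0, -1]],      # 3: LII-up, falling with age
        [[0, 0], [0, 1], [0, 0], [0, 0]],        # 4: LDeep spike at P9
        [[0, 0], [0, 0], [-1, 0], [-1, 0]],      # 5: LII-down at P23/P45
        [[1, 1], [1, 1], [-1, -1], [-1, -1]],    # 6: sharp decrease P9->P23
        [[0, -1], [0, -1], [1, 0], [1, 0]],      # 7: LII-up, rising with age
        [[1, 1], [0, 0], [0, 0], [-1, -1]],      # 8: gradual decline
    )
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Effect sizes and noise are in log2 units.  ``target_slope`` is the
    planted regression slope of a target gene on its miRNA (negative:
    repression); the realised slope for a given pair is
    ``target_slope * (0.5 + p)`` where ``p`` is the miRNA's baseline
    expression percentile, so targets of highly expressed miRNAs are more
    strongly repressed.
    """

    n_animals_per_age: int = 3
    ages: tuple[str, ...] = AGES
    layers: tuple[str, ...] = LAYERS
    n_mirna: int = 80
    n_mrna: int = 400
    n_modules: int = 8
    module_profiles: tuple[np.ndarray, ...] = DEFAULT_MODULE_PROFILES
    profile_scale: float = 2.0          # planted shift magnitude, log2
    effect_sd: float = 0.2              # per-feature amplitude jitter
    noise_sd: float = 0.5               # residual sd, log2
    frac_true_targets: float = 0.2      # fraction of genes under miRNA control
    target_slope: float = -1.0
    #: 'weighted' favours abundant miRNAs (weight ~ percentile^2);
    #: 'round_robin' deals targets out evenly (one per miRNA first)
    target_assignment: str = "weighted"
    frac_validated: float = 0.1         # planted pairs also tagged validated
    decoy_sites_per_mirna: int = 5      # predicted sites on unregulated genes
    decoy_gene_pool_fraction: float = 0.25  # unregulated genes carrying decoys
    decoy_conserved_fraction: float = 0.25  # decoy sites drawn in conserved range
    comodule_sites_per_target: int = 1  # extra same-module, non-conserved sites
    frac_de_mrna: float = 0.15          # unregulated genes with direct effects
    baseline_range: tuple[float, float] = (4.0, 12.0)
    target_gene_baseline_range: tuple[float, float] = (6.0, 12.0)
    nb_dispersion: float = 0.1
    depth_log_sd: float = 0.3
    cluster_fraction: float = 0.5
    max_intra_cluster_gap_bp: int = 10_000
    # stellate-vs-rest qPCR contrast
    n_ct_features: int = 48
    ct_replicates: int = 5
    ct_frac_up: float = 0.25
    ct_effect: float = -3.0             # delta Ct in the stellate group (lower = up)
    ct_noise_sd: float = 0.3
    ct_flag_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_animals_per_age", "n_mirna", "n_mrna", "n_modules",
                     "n_ct_features", "ct_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.target_slope >= 0:
            raise ValueError("target_slope must be negative (repression)")
        if not 0 <= self.frac_true_targets <= 1:
            raise ValueError("frac_true_targets must be in [0, 1]")
        if round(self.frac_true_targets * self.n_mrna) > self.n_mrna:
            raise ValueError("more planted targets than genes")

    def null(self) -> "SimulationConfig":
        """A copy with every planted effect removed (pure noise)."""
        return replace(self, profile_scale=0.0, frac_true_targets=0.0,
                       frac_de_mrna=0.0, ct_frac_up=0.0, cluster_fraction=0.0)


@dataclass
class GroundTruth:
    """What was planted, keyed by the generated feature ids."""

    true_module: dict[str, int] = field(default_factory=dict)
    true_targets: set[tuple[str, str]] = field(default_factory=set)
    true_de_age: set[str] = field(default_factory=set)
    true_de_layer: set[str] = field(default_factory=set)
    true_genomic_clusters: list[list[str]] = field(default_factory=list)
    mirna_baseline: dict[str, float] = field(default_factory=dict)
    target_records: list[TargetRecord] = field(default_factory=list)
    #: planted per-miRNA strongest target (best context score among its pairs)
    strongest_target: dict[str, str] = field(default_factory=dict)
    #: realised log2-scale Pearson r of each planted pair (before counts)
    true_pair_rho: dict[tuple[str, str], float] = field(default_factory=dict)


def _rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng(config.seed)


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def simulate_design(config: SimulationConfig) -> list[SampleAnnotation]:
    """Paired design: each animal contributes one LII and one LDeep sample."""
    samples = []
    for age in config.ages:
        for a in range(1, config.n_animals_per_age + 1):
            animal = f"{age}_a{a}"
            for layer in config.layers:
                samples.append(SampleAnnotation(
                    sample_id=f"{animal}_{layer}", age=age, layer=layer,
                    animal_id=animal, platform="array"))
    return samples


def _cell_index(config: SimulationConfig, design: Sequence[SampleAnnotation]
                ) -> tuple[np.ndarray, np.ndarray]:
    age_ix = np.array([config.ages.index(s.age) for s in design])
    layer_ix = np.array([config.layers.index(s.layer) for s in design])
    return age_ix, layer_ix


def _age_layer_contrasts(config: SimulationConfig, noiseless: np.ndarray,
                         design: Sequence[SampleAnnotation]
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Exact age (late vs early) and layer (LII vs LDeep) mean contrasts."""
    ages = np.array([s.age for s in design])
    layers = np.array([s.layer for s in design])
    early = np.isin(ages, ("P2", "P9"))
    lii = layers == "LII"
    age_lfc = noiseless[:, ~early].mean(axis=1) - noiseless[:, early].mean(axis=1)
    layer_lfc = noiseless[:, lii].mean(axis=1) - noiseless[:, ~lii].mean(axis=1)
    return age_lfc, layer_lfc


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(config: SimulationConfig,
                        design: Sequence[SampleAnnotation] | None = None,
                        de_truth_min: float = 1.0,
                        ) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Generate the miRNA (log2, array-like) and mRNA (counts, RNA-seq-like)
    matrices plus ground truth.

    Features whose exact planted contrast reaches ``de_truth_min`` (log2;
    default a two-fold change) enter the true DE sets.
    """
    if design is None:
        design = simulate_design(config)
    rng = _rng(config)
    n_samples = len(design)
    age_ix, layer_ix = _cell_index(config, design)

    profiles = [config.module_profiles[m % len(config.module_profiles)]
                for m in range(config.n_modules)]

    mirna_ids = [f"mir-{i + 1}" for i in range(config.n_mirna)]
    gene_ids = [f"gene-{j + 1}" for j in range(config.n_mrna)]
    truth = GroundTruth()

    # --- miRNAs -----------------------------------------------------------
    baselines = rng.uniform(*config.baseline_range, size=config.n_mirna)
    amplitudes = np.clip(1.0 + config.effect_sd * rng.standard_normal(config.n_mirna),
                         0.2, None)
    modules = np.arange(config.n_mirna) % config.n_modules  # round-robin
    noiseless_mirna = np.empty((config.n_mirna, n_samples))
    for i in range(config.n_mirna):
        shift = profiles[modules[i]][age_ix, layer_ix]
        noiseless_mirna[i] = baselines[i] + amplitudes[i] * config.profile_scale * shift
    mirna_values = noiseless_mirna + rng.normal(0.0, config.noise_sd,
                                                size=noiseless_mirna.shape)
    truth.true_module = {mid: int(m) + 1 for mid, m in zip(mirna_ids, modules)}
    truth.mirna_baseline = dict(zip(mirna_ids, baselines))

    # Repression is abundance-dependent: the planted slope scales with the
    # miRNA's baseline-expression percentile, and targets are assigned
    # preferentially (weight ~ percentile^2) to well-expressed miRNAs, so
    # only abundant miRNAs maintain strong detectable repression.
    pct = baselines.argsort().argsort() / max(config.n_mirna - 1, 1)
    slope_mult = 0.2 + 1.6 * pct

    # --- target assignment ------------------------------------------------
    n_true = int(round(config.frac_true_targets * config.n_mrna))
    weights = pct ** 2 + 0.05
    weights /= weights.sum()
    target_of = {}           # gene index -> miRNA index
    for j in range(n_true):
        if config.target_assignment == "round_robin":
            target_of[j] = j % config.n_mirna
        else:
            target_of[j] = int(rng.choice(config.n_mirna, p=weights))

    # context scores: planted pairs get strong (conserved-range) scores,
    # decoy sites on unregulated genes sit near the conservation boundary.
    records: list[TargetRecord] = []
    per_mirna_scores: dict[int, list[tuple[float, str]]] = {}
    for j, i in target_of.items():
        score = float(rng.uniform(-0.6, -0.15))
        records.append(TargetRecord(mirna_ids[i], gene_ids[j], "predicted_all", score))
        if score < -0.1:
            records.append(TargetRecord(mirna_ids[i], gene_ids[j],
                                        "predicted_conserved", score))
        if rng.uniform() < config.frac_validated:
            records.append(TargetRecord(mirna_ids[i], gene_ids[j], "validated"))
        per_mirna_scores.setdefault(i, []).append((score, gene_ids[j]))
        truth.true_targets.add((mirna_ids[i], gene_ids[j]))
        # extra predicted sites from same-module miRNAs, kept non-conserved
        mates = [k for k in range(config.n_mirna)
                 if modules[k] == modules[i] and k != i]
        if mates:
            picks = rng.choice(len(mates),
                               size=min(config.comodule_sites_per_target, len(mates)),
                               replace=False)
            for p in np.atleast_1d(picks):
                records.append(TargetRecord(mirna_ids[mates[int(p)]], gene_ids[j],
                                            "predicted_all",
                                            float(rng.uniform(-0.09, -0.01))))
    for i, scored in per_mirna_scores.items():
        truth.strongest_target[mirna_ids[i]] = min(scored)[1]

    # Decoy (unregulated) predicted sites are concentrated on a pool of
    # unregulated genes, so decoy genes carry several sites from unrelated
    # modules (informative for the same-module-fraction filter) while true
    # target genes keep a coherent same-module site profile.
    nontarget = [j for j in range(config.n_mrna) if j not in target_of]
    pool = nontarget[:max(1, int(round(config.decoy_gene_pool_fraction
                                       * len(nontarget))))] if nontarget else []
    seen_pairs = {(r.mirna_id, r.gene_id) for r in records}
    if pool:
        for i in range(config.n_mirna):
            picks = rng.choice(len(pool),
                               size=min(config.decoy_sites_per_mirna, len(pool)),
                               replace=False)
            for p in np.atleast_1d(picks):
                j = pool[int(p)]
                if (mirna_ids[i], gene_ids[j]) in seen_pairs:
                    continue
                seen_pairs.add((mirna_ids[i], gene_ids[j]))
                if rng.uniform() < config.decoy_conserved_fraction:
                    score = float(rng.uniform(-0.35, -0.101))
                else:
                    score = float(rng.uniform(-0.095, -0.001))
                records.append(TargetRecord(mirna_ids[i], gene_ids[j],
                                            "predicted_all", score))
                if score < -0.1:
                    records.append(TargetRecord(mirna_ids[i], gene_ids[j],
                                                "predicted_conserved", score))
    truth.target_records = records

    # --- genes ------------------------------------------------------------
    noiseless_gene = np.empty((config.n_mrna, n_samples))
    gene_log2 = np.empty((config.n_mrna, n_samples))
    # direct-effect genes are disjoint from the decoy pool: decoy sites model
    # spurious predictions on genes without planted expression structure
    n_de_direct = int(round(config.frac_de_mrna * config.n_mrna))
    direct_de = set(nontarget[len(nontarget) - n_de_direct:])
    for j in range(config.n_mrna):
        if j in target_of:
            i = target_of[j]
            slope = config.target_slope * slope_mult[i]
            gbase = rng.uniform(*config.target_gene_baseline_range)
            intercept = gbase - slope * baselines[i]
            noiseless_gene[j] = intercept + slope * noiseless_mirna[i]
            gene_log2[j] = intercept + slope * mirna_values[i] + rng.normal(
                0.0, config.noise_sd, size=n_samples)
            truth.true_pair_rho[(mirna_ids[i], gene_ids[j])] = float(
                np.corrcoef(mirna_values[i], gene_log2[j])[0, 1])
        else:
            gbase = rng.uniform(*config.baseline_range)
            if j in direct_de:
                m = j % config.n_modules
                amp = np.clip(1.0 + config.effect_sd * rng.standard_normal(), 0.2, None)
                shift = profiles[m][age_ix, layer_ix]
                noiseless_gene[j] = gbase + amp * config.profile_scale * shift
            else:
                noiseless_gene[j] = gbase
            gene_log2[j] = noiseless_gene[j] + rng.normal(
                0.0, config.noise_sd, size=n_samples)

    # --- counts -----------------------------------------------------------
    depths = np.exp(rng.normal(0.0, config.depth_log_sd, size=n_samples))
    mu = np.power(2.0, gene_log2) * depths[None, :]
    phi = config.nb_dispersion
    if phi > 0:
        counts = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu))
    else:
        counts = rng.poisson(mu)
    counts = counts.astype(float)

    # --- truth DE sets ----------------------------------------------------
    for ids, noiseless in ((mirna_ids, noiseless_mirna), (gene_ids, noiseless_gene)):
        age_lfc, layer_lfc = _age_layer_contrasts(config, noiseless, design)
        for fid, a, l in zip(ids, age_lfc, layer_lfc):
            if abs(a) >= de_truth_min:
                truth.true_de_age.add(fid)
            if abs(l) >= de_truth_min:
                truth.true_de_layer.add(fid)

    sample_ids = [s.sample_id for s in design]
    mirna = ExpressionMatrix(
        pd.DataFrame(mirna_values, index=mirna_ids, columns=sample_ids),
        list(design), "log2")
    rnaseq_design = [replace(s, platform="rnaseq") for s in design]
    mrna = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        rnaseq_design, "counts")
    return mirna, mrna, truth


# ---------------------------------------------------------------------------
# genomic loci
# ---------------------------------------------------------------------------

def simulate_loci(config: SimulationConfig, truth: GroundTruth) -> list[GenomicLocus]:
    """Place a ``cluster_fraction`` of each module's miRNAs in one genomic
    cluster (consecutive gaps strictly below the 10-kb rule); the rest are
    isolated by at least ten times the maximum gap."""
    rng = np.random.default_rng(config.seed + 1)
    gap = config.max_intra_cluster_gap_bp
    by_module: dict[int, list[str]] = {}
    for mid, m in truth.true_module.items():
        by_module.setdefault(m, []).append(mid)

    loci: list[GenomicLocus] = []
    singletons: list[str] = []
    truth.true_genomic_clusters = []
    for m in sorted(by_module):
        members = sorted(by_module[m], key=lambda s: int(s.split("-")[1]))
        k = int(round(config.cluster_fraction * len(members)))
        if k >= 2:
            pos = int(rng.integers(10_000, 50_000))
            cluster_ids = members[:k]
            for mid in cluster_ids:
                length = int(rng.integers(60, 120))
                loci.append(GenomicLocus(mid, f"chr{m}", pos, pos + length, "+"))
                pos += length + int(rng.integers(200, gap))  # gap < max gap
            truth.true_genomic_clusters.append(list(cluster_ids))
            singletons.extend(members[k:])
        else:
            singletons.extend(members)
    pos = 1_000_000
    for mid in singletons:
        length = int(rng.integers(60, 120))
        loci.append(GenomicLocus(mid, "chrS", pos, pos + length, "+"))
        pos += length + 10 * gap + int(rng.integers(0, gap))
    return loci


# ---------------------------------------------------------------------------
# stellate-vs-rest qPCR contrast
# ---------------------------------------------------------------------------

def simulate_ct(config: SimulationConfig,
                truth: GroundTruth | None = None,
                ) -> tuple[ExpressionMatrix, pd.DataFrame, set[str]]:
    """Two groups (stellate / rest) x ``ct_replicates`` qPCR samples.

    Planted up-regulated miRNAs get ``ct_effect`` lower Ct in the stellate
    group; a ``ct_flag_fraction`` of cells is flagged Undetermined at random.
    Returns (Ct matrix, flag mask, planted up-regulated id set).
    """
    rng = np.random.default_rng(config.seed + 2)
    n = config.n_ct_features
    if truth is not None and truth.mirna_baseline:
        ids = list(truth.mirna_baseline)[:n]
        base_expr = np.array([truth.mirna_baseline[i] for i in ids])
    else:
        ids = [f"mir-{i + 1}" for i in range(n)]
        base_expr = rng.uniform(*config.baseline_range, size=n)
    n = len(ids)

    samples = []
    for group in ("stellate", "rest"):
        for r in range(1, config.ct_replicates + 1):
            samples.append(SampleAnnotation(
                sample_id=f"{group}_{r}", age="P2", layer="NA",
                animal_id=f"{group}_{r}", platform="qpcr", group_extra=group))
    stellate = np.array([s.group_extra == "stellate" for s in samples])

    n_up = int(round(config.ct_frac_up * n))
    up_ids = set(ids[:n_up])
    ct = np.empty((n, len(samples)))
    for i, fid in enumerate(ids):
        base_ct = 38.0 - base_expr[i]
        row = base_ct + rng.normal(0.0, config.ct_noise_sd, size=len(samples))
        if fid in up_ids:
            row[stellate] += config.ct_effect
        ct[i] = row
    mask = rng.uniform(size=ct.shape) < config.ct_flag_fraction
    values = pd.DataFrame(ct, index=ids, columns=[s.sample_id for s in samples])
    values = values.where(~mask)
    mask_df = pd.DataFrame(mask, index=values.index, columns=values.columns)
    return ExpressionMatrix(values, samples, "ct"), mask_df, up_ids


# ---------------------------------------------------------------------------
# term annotations
# ---------------------------------------------------------------------------

def simulate_terms(config: SimulationConfig, truth: GroundTruth,
                   n_enriched: int = 10, n_random: int = 10,
                   term_size: int = 40, enriched_fraction: float = 0.75,
                   ) -> list[TermAnnotation]:
    """Terms for the enrichment stage: ``n_enriched`` terms drawn mostly from
    the planted age-DE genes, ``n_random`` from the whole gene universe."""
    rng = np.random.default_rng(config.seed + 3)
    universe = [f"gene-{j + 1}" for j in range(config.n_mrna)]
    de_genes = sorted(g for g in truth.true_de_age if g.startswith("gene-"))
    terms = []
    for t in range(n_enriched):
        n_de = min(int(round(enriched_fraction * term_size)), len(de_genes))
        picks = set()
        if n_de:
            picks |= {de_genes[int(i)] for i in
                      rng.choice(len(de_genes), size=n_de, replace=False)}
        while len(picks) < term_size:
            picks.add(universe[int(rng.integers(len(universe)))])
        terms.append(TermAnnotation(f"T_DE_{t + 1}", f"planted term {t + 1}",
                                    frozenset(picks)))
    for t in range(n_random):
        picks = {universe[int(i)] for i in
                 rng.choice(len(universe), size=term_size, replace=False)}
        terms.append(TermAnnotation(f"T_RND_{t + 1}", f"background term {t + 1}",
                                    frozenset(picks)))
    return terms
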