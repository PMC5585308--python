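"""End-to-end orchestration: simulate (or load) -> normalize -> differential
expression -> co-expression modules -> genomic clusters -> target
integration -> enrichment, with QC helpers and a machine-readable report.

Each randomized stage draws from a stage-specific child seed derived from
the run seed, so adding one stage never perturbs another stage's stream.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import coexpression, diffexpr, enrichment, genomic_clusters, normalize
from . import synthetic, target_integration
from .io_formats import ExpressionMatrix, write_expression, write_gmt, \
    write_mirbase_gff, write_target_records

log = logging.getLogger(__name__)

# fixed offsets for stage-specific child seeds
STAGE_SEEDS = {"simulate": 0, "modules": 1, "clusters": 2, "skew": 3}


def stage_seed(run_seed: int, stage: str) -> int:
    return int(np.random.SeedSequence([run_seed, STAGE_SEEDS[stage]])
               .generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Everything a run needs: a simulation block (or real-input paths),
    per-stage parameters, a seed, and an output directory."""

    simulation: synthetic.SimulationConfig | None = None
    input_paths: dict[str, str] = field(default_factory=dict)
    outdir: str = "mecmir_run"
    seed: int = 0
    alpha: float = 0.05
    lfc_min_enrichment: float = 0.5
    rho_max: float = -0.5
    min_median_expr: float = 5.0
    part_min_size: int = 5
    part_max_k: int = 10
    part_B: int = 50
    max_gap_bp: int = 10_000
    n_permutations: int = 1000
    skew_context_max: float = -0.25
    skew_top_fraction: float = 0.25
    skew_min_same_module_fraction: float = 0.75
    max_term_size: int = 2500

    def validate(self) -> None:
        if self.simulation is None and not self.input_paths:
            raise ValueError("config needs a simulation block or input paths")


@dataclass
class RunReport:
    de_counts: dict = field(default_factory=dict)
    de_overlaps: dict = field(default_factory=dict)
    module_sizes: dict = field(default_factory=dict)
    n_modules: int = 0
    n_outliers: int = 0
    module_recovery_ari: float | None = None
    genomic_clusters: dict = field(default_factory=dict)
    candidate_targets: dict = field(default_factory=dict)
    skew: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    stellate: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# QC operations
# ---------------------------------------------------------------------------

def pca_qc(matrix: ExpressionMatrix) -> tuple[np.ndarray, pd.DataFrame]:
    """Principal components of the samples after per-feature centering.

    Returns (variance fractions summing to 1, sample x component scores).
    """
    values = matrix.values.to_numpy(dtype=float)
    centered = values - values.mean(axis=1, keepdims=True)
    # samples as observations
    U, s, Vt = np.linalg.svd(centered.T, full_matrices=False)
    var = s ** 2
    total = var.sum()
    fractions = var / total if total > 0 else var
    scores = pd.DataFrame(U * s, index=matrix.sample_ids,
                          columns=[f"PC{i + 1}" for i in range(s.size)])
    return fractions, scores


def platform_concordance(matrix_a: ExpressionMatrix, matrix_b: ExpressionMatrix,
                         feature_map: dict[str, str] | None = None,
                         min_shared: int = 10) -> tuple[float, float]:
    """Spearman correlation of per-feature median expression across two
    platforms; ``feature_map`` maps ids of ``matrix_a`` to ids of
    ``matrix_b`` (identity by default)."""
    ids_b = set(matrix_b.feature_ids)
    if feature_map is None:
        feature_map = {f: f for f in matrix_a.feature_ids}
    pairs = [(a, b) for a, b in feature_map.items()
             if a in matrix_a.values.index and b in ids_b]
    if len(pairs) < min_shared:
        raise ValueError(f"only {len(pairs)} shared features (need {min_shared})")
    med_a = matrix_a.values.median(axis=1)
    med_b = matrix_b.values.median(axis=1)
    x = np.array([med_a[a] for a, _ in pairs])
    y = np.array([med_b[b] for _, b in pairs])
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def adjusted_rand_index(labels_a: dict[str, int], labels_b: dict[str, int]) -> float:
    """ARI between two labelings over their shared keys."""
    keys = sorted(set(labels_a) & set(labels_b))
    a = pd.Categorical([labels_a[k] for k in keys]).codes
    b = pd.Categorical([labels_b[k] for k in keys]).codes
    n = len(keys)
    ct = pd.crosstab(a, b).to_numpy()
    sum_comb = sum(v * (v - 1) / 2 for v in ct.ravel())
    sum_a = sum(v * (v - 1) / 2 for v in ct.sum(axis=1))
    sum_b = sum(v * (v - 1) / 2 for v in ct.sum(axis=0))
    total = n * (n - 1) / 2
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> RunReport:
    """Run every stage in order, writing TSV/GFF3/Newick/JSON outputs under
    ``config.outdir`` and returning the report."""
    config.validate()
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    report.provenance = {"seed": config.seed, "stages": {}}

    def tick(stage: str, start: float) -> None:
        report.provenance["stages"][stage] = round(time.time() - start, 3)
        log.info("stage %s finished in %.2fs", stage, time.time() - start)

    # --- simulate / load --------------------------------------------------
    t = time.time()
    if config.simulation is not None:
        sim = config.simulation
        sim = synthetic.SimulationConfig(**{**asdict_safe(sim), "seed":
                                            stage_seed(config.seed, "simulate")})
        design = synthetic.simulate_design(sim)
        mirna, mrna_counts, truth = synthetic.simulate_expression(sim, design)
        loci = synthetic.simulate_loci(sim, truth)
        ct, ct_mask, ct_up = synthetic.simulate_ct(sim, truth)
        terms = synthetic.simulate_terms(sim, truth)
        targets = truth.target_records
        write_expression(mirna, outdir / "mirna.tsv", outdir / "samples.tsv")
        write_expression(mrna_counts, outdir / "mrna_counts.tsv")
        write_target_records(targets, outdir / "targets.tsv")
        write_mirbase_gff(loci, outdir / "loci.gff3")
        write_gmt(terms, outdir / "terms.gmt")
    else:
        raise NotImplementedError("external-input runs are configured via the "
                                  "library readers; see io_formats")
    tick("simulate", t)

    # --- normalize --------------------------------------------------------
    t = time.time()
    mirna_f = normalize.filter_features(mirna)
    mirna_norm = normalize.quantile_normalize(mirna_f)
    counts_f = normalize.filter_features(mrna_counts)
    factors = normalize.tmm_factors(counts_f)
    logcpm = normalize.log_cpm(counts_f, factors)
    logcpm_q = normalize.quantile_normalize(logcpm)
    age_X, _ = diffexpr.age_design(logcpm_q)
    weights = normalize.precision_weights(logcpm_q, age_X)
    factors.to_csv(outdir / "tmm_factors.tsv", sep="\t")
    write_expression(mirna_norm, outdir / "mirna_normalized.tsv")
    write_expression(logcpm_q, outdir / "mrna_logcpm.tsv")
    tick("normalize", t)

    # --- differential expression -----------------------------------------
    t = time.time()
    mirna_tables, mirna_summary = diffexpr.run_all_contrasts(mirna_norm,
                                                             alpha=config.alpha)
    gene_tables, gene_summary = diffexpr.run_all_contrasts(logcpm_q, weights,
                                                           alpha=config.alpha)
    for name, tab in {**{f"mirna_{k}": v for k, v in mirna_tables.items()},
                      **{f"mrna_{k}": v for k, v in gene_tables.items()}}.items():
        tab.table.to_csv(outdir / f"de_{name}.tsv", sep="\t")
    report.de_counts = {"mirna": mirna_summary["n_de"], "mrna": gene_summary["n_de"]}
    report.de_overlaps = {
        "mirna_age_layer": mirna_summary["age_layer_overlap"],
        "mrna_age_layer": gene_summary["age_layer_overlap"],
    }
    tick("diffexpr", t)

    # --- co-expression modules -------------------------------------------
    t = time.time()
    de_mirnas = sorted(diffexpr.de_union(mirna_tables, config.alpha))
    assignment = None
    if len(de_mirnas) >= config.part_min_size:
        dendro = coexpression.correlation_dendrogram(mirna_norm, de_mirnas)
        assignment = coexpression.part_partition(
            mirna_norm, dendro, min_size=config.part_min_size,
            max_k=config.part_max_k, B=config.part_B,
            seed=stage_seed(config.seed, "modules"))
        profiles = coexpression.module_profiles(mirna_norm, assignment)
        pd.Series(assignment.labels, name="module").rename_axis("feature_id") \
            .to_csv(outdir / "modules.tsv", sep="\t")
        pd.DataFrame({f"module_{p.module_label}": p.representative
                      for p in profiles}).to_csv(outdir / "module_profiles.tsv", sep="\t")
        (outdir / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
        sizes = assignment.sizes()
        report.n_modules = len(assignment.module_labels())
        report.n_outliers = sizes.get(coexpression.OUTLIER_LABEL, 0)
        report.module_sizes = {str(k): v for k, v in sizes.items()
                               if k != coexpression.OUTLIER_LABEL}
        if config.simulation is not None:
            report.module_recovery_ari = adjusted_rand_index(
                {f: l for f, l in assignment.labels.items()
                 if l != coexpression.OUTLIER_LABEL},
                truth.true_module)
    else:
        log.warning("too few DE miRNAs for module discovery")
    tick("modules", t)

    # --- genomic clusters -------------------------------------------------
    t = time.time()
    clusters = genomic_clusters.call_clusters(loci, config.max_gap_bp)
    rows = [{"cluster_id": c.cluster_id, "chrom": c.chrom, "span_bp": c.span_bp,
             "members": ",".join(c.member_ids)} for c in clusters]
    pd.DataFrame(rows, columns=["cluster_id", "chrom", "span_bp", "members"]) \
        .to_csv(outdir / "genomic_clusters.tsv", sep="\t", index=False)
    report.genomic_clusters = {"n_clusters": len(clusters),
                               "n_clustered_mirnas": sum(len(c.member_ids)
                                                         for c in clusters)}
    if assignment is not None and clusters:
        try:
            assoc = genomic_clusters.co_membership_test(
                clusters, assignment, n_permutations=config.n_permutations,
                seed=stage_seed(config.seed, "clusters"))
            report.genomic_clusters.update({
                "table": assoc.table, "odds_ratio": assoc.odds_ratio,
                "fisher_p": assoc.fisher_p, "perm_p": assoc.perm_p})
            with open(outdir / "cluster_association.json", "w") as handle:
                json.dump(report.genomic_clusters, handle, indent=2,
                          default=_jsonable)
        except ValueError as exc:
            log.warning("co-membership test skipped: %s", exc)
    tick("clusters", t)

    # --- target integration ----------------------------------------------
    t = time.time()
    pairs = target_integration.pair_correlations(mirna_norm, logcpm_q, targets)
    mirna_de = {"age": mirna_tables.get("age_late_vs_early"),
                "layer": mirna_tables.get("layer_LII_vs_LDeep")}
    gene_de = {"age": gene_tables.get("age_late_vs_early"),
               "layer": gene_tables.get("layer_LII_vs_LDeep")}
    candidates = target_integration.three_requirement_filter(
        pairs, mirna_de, gene_de, rho_max=config.rho_max, alpha=config.alpha)
    ranked = target_integration.rank_candidates(candidates, config.min_median_expr)
    cand_frame = pd.DataFrame([{
        "mirna_id": c.mirna_id, "gene_id": c.gene_id, "rho": c.rho,
        "context_score": c.context_score, "sources": ";".join(sorted(c.sources)),
        "gene_median_expr": c.gene_median_expr, **c.de_flags,
    } for c in ranked])
    cand_frame.to_csv(outdir / "candidate_targets.tsv", sep="\t", index=False)
    report.candidate_targets = {"n_pass_filter": len(candidates),
                                "n_ranked": len(ranked),
                                "table_path": str(outdir / "candidate_targets.tsv")}

    conserved = [p for p in pairs if p.source == "predicted_conserved"]
    control = [p for p in pairs if p.source == "predicted_all"]
    if conserved and control:
        fractions = target_integration.all_same_module_fractions(
            targets, assignment) if assignment is not None else {}
        top = target_integration.expression_quartile_filter(
            mirna_norm, config.skew_top_fraction)
        stages = {
            "baseline": {},
            "context": {"context_max": config.skew_context_max},
            "context+top": {"context_max": config.skew_context_max,
                            "mirna_whitelist": top},
            "context+top+module": {
                "context_max": config.skew_context_max, "mirna_whitelist": top,
                "min_same_module_fraction": config.skew_min_same_module_fraction,
                "same_module_fractions": fractions},
        }
        for name, kwargs in stages.items():
            try:
                res = target_integration.correlation_skew_test(
                    conserved, control, **kwargs)
                report.skew[name] = {
                    "U": res.U, "p": res.p_one_sided, "n_conserved": res.n_conserved,
                    "n_control": res.n_control,
                    "median_conserved_rho": res.median_conserved_rho,
                    "median_control_rho": res.median_control_rho}
            except ValueError as exc:
                log.warning("skew stage %s skipped: %s", name, exc)
        with open(outdir / "skew.json", "w") as handle:
            json.dump(report.skew, handle, indent=2, default=_jsonable)
    tick("targets", t)

    # --- enrichment -------------------------------------------------------
    t = time.time()
    universe = set(logcpm_q.feature_ids)
    records_by_set = {}
    age_table = gene_tables.get("age_late_vs_early")
    if age_table is not None:
        for direction in ("up", "down"):
            query = enrichment.select_query_genes(
                age_table, config.lfc_min_enrichment, direction, config.alpha)
            if query:
                records_by_set[f"age_{direction}"] = enrichment.fisher_enrichment(
                    query, universe, terms, config.max_term_size, config.alpha)
    dot = enrichment.export_dot_matrix(records_by_set)
    dot.to_csv(outdir / "enrichment_dot_matrix.tsv", sep="\t", index=False)
    report.enrichment = {
        name: {"n_tested": len(recs),
               "n_significant": sum(r.significant for r in recs)}
        for name, recs in records_by_set.items()}
    tick("enrichment", t)

    # --- QC ---------------------------------------------------------------
    t = time.time()
    fractions, scores = pca_qc(mirna_norm)
    report.qc["pca_variance_fractions"] = [round(float(f), 6)
                                           for f in fractions[:5]]
    scores.iloc[:, :5].to_csv(outdir / "pca_scores.tsv", sep="\t")

    # stellate-vs-rest qPCR arm + cross-platform concordance
    ct_norm = normalize.delta_ct_normalize(ct, ct_mask)
    X, c = diffexpr.group_design(ct_norm)
    if ct_norm.values.shape[0] >= 2:
        ct_table, _ = diffexpr.fit_and_moderate(ct_norm, X, c, "stellate_vs_rest")
        up, _ = diffexpr.call_de(ct_table, config.alpha)
        up = {f for f in up if ct_table.table.loc[f, "lfc"] > 0}
        report.stellate = {
            "n_up_in_stellate": len(up),
            "recovered_planted_up": len(up & ct_up) if config.simulation else None,
            "n_planted_up": len(ct_up) if config.simulation else None,
        }
        ct_table.table.to_csv(outdir / "de_stellate_vs_rest.tsv", sep="\t")
    try:
        rho, p = platform_concordance(mirna_norm, ct_norm)
        report.qc["platform_concordance_rho"] = rho
        report.qc["platform_concordance_p"] = p
    except ValueError as exc:
        log.warning("platform concordance skipped: %s", exc)
    tick("qc", t)

    report.provenance["runtime_s"] = round(time.time() - t0, 3)
    report.to_json(outdir / "report.json")
    return report


def asdict_safe(config: synthetic.SimulationConfig) -> dict:
    """dataclasses.asdict minus numpy arrays (module profiles kept as-is)."""
    out = {}
    for name in config.__dataclass_fields__:
        out[name] = getattr(config, name)
    return out
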