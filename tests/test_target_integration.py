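from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mecmir as m
from mecmir import diffexpr, normalize, target_integration as ti
from tests.conftest import normalized_views


def _pair(mirna, gene, rho, source="predicted_conserved", score=-0.3):
    return ti.PairCorrelation(mirna, gene, rho, 10, source,
                              None if source == "validated" else score)


def _matrices(mirna_rows, gene_rows):
    samples = [m.SampleAnnotation(f"s{i}", "P2", "LII", f"a{i}", "array")
               for i in range(len(next(iter(mirna_rows.values()))))]
    def build(rows, platform):
        frame = pd.DataFrame(rows).T
        frame.columns = [s.sample_id for s in samples]
        return m.ExpressionMatrix(frame.astype(float), samples, "log2")
    return build(mirna_rows, "array"), build(gene_rows, "rnaseq")


# ---------------------------------------------------------------------------
# Spearman correlations
# ---------------------------------------------------------------------------

def test_perfect_antimonotone_rho():
    mirna, genes = _matrices({"mir": [1.0, 2.0, 3.0]}, {"g": [6.0, 5.0, 4.0]})
    pairs = ti.pair_correlations(mirna, genes,
                                 [m.TargetRecord("mir", "g", "validated")])
    assert np.isclose(pairs[0].rho, -1.0)


def test_tied_data_matches_scipy_oracle():
    rng = np.random.default_rng(0)
    for _ in range(50):
        x = np.round(rng.normal(size=8), 0)   # heavy ties
        y = np.round(rng.normal(size=8), 0)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        mirna, genes = _matrices({"mir": x}, {"g": y})
        pairs = ti.pair_correlations(mirna, genes,
                                     [m.TargetRecord("mir", "g", "validated")])
        oracle = stats.spearmanr(x, y).statistic
        assert abs(pairs[0].rho - oracle) < 1e-12


def test_requires_three_shared_samples():
    mirna, genes = _matrices({"mir": [1.0, 2.0]}, {"g": [2.0, 1.0]})
    with pytest.raises(ValueError, match="three shared"):
        ti.pair_correlations(mirna, genes,
                             [m.TargetRecord("mir", "g", "validated")])


# ---------------------------------------------------------------------------
# three-requirement filter
# ---------------------------------------------------------------------------

def _de_tables(mirna_hits, gene_hits):
    def table(hits, other):
        idx = sorted(set(hits) | set(other))
        frame = pd.DataFrame({
            "lfc": [1.0] * len(idx),
            "t_mod": [5.0] * len(idx),
            "p_raw": [0.001 if f in hits else 0.9 for f in idx],
            "p_adj": [0.001 if f in hits else 0.9 for f in idx],
            "mean_expr": [6.0] * len(idx),
            "df_total": 10.0,
        }, index=idx)
        return diffexpr.DETable("t", frame)
    mirna_de = {"age": table(mirna_hits.get("age", []), mirna_hits.get("layer", [])),
                "layer": table(mirna_hits.get("layer", []), mirna_hits.get("age", []))}
    gene_de = {"age": table(gene_hits.get("age", []), gene_hits.get("layer", [])),
               "layer": table(gene_hits.get("layer", []), gene_hits.get("age", []))}
    return mirna_de, gene_de


def test_rho_boundary_strictly_below():
    mirna_de, gene_de = _de_tables({"age": ["mir"]}, {"age": ["g"]})
    at = ti.three_requirement_filter([_pair("mir", "g", -0.5)], mirna_de, gene_de)
    below = ti.three_requirement_filter([_pair("mir", "g", -0.50001)],
                                        mirna_de, gene_de)
    assert at == [] and len(below) == 1


def test_validated_pair_both_de_retained():
    mirna_de, gene_de = _de_tables({"layer": ["mir"]}, {"layer": ["g"]})
    out = ti.three_requirement_filter([_pair("mir", "g", -0.9, "validated")],
                                      mirna_de, gene_de)
    assert len(out) == 1 and out[0].de_flags["mirna_layer"]


def test_mixed_contrast_de_not_sufficient():
    """miRNA DE in age only and gene DE in layer only fails requirement 2."""
    mirna_de, gene_de = _de_tables({"age": ["mir"]}, {"layer": ["g"]})
    out = ti.three_requirement_filter([_pair("mir", "g", -0.9)],
                                      mirna_de, gene_de)
    assert out == []


def test_predicted_all_only_source_rejected():
    mirna_de, gene_de = _de_tables({"age": ["mir"]}, {"age": ["g"]})
    out = ti.three_requirement_filter(
        [_pair("mir", "g", -0.9, "predicted_all", -0.05)], mirna_de, gene_de)
    assert out == []


def test_relaxing_any_requirement_never_shrinks_output(default_sim):
    _, mirna, mrna, truth = default_sim
    mn, lc = normalized_views(mirna, mrna)
    mt, _ = diffexpr.run_all_contrasts(mn)
    gt, _ = diffexpr.run_all_contrasts(lc)
    pairs = ti.pair_correlations(mn, lc, truth.target_records)
    mirna_de = {"age": mt["age_late_vs_early"], "layer": mt["layer_LII_vs_LDeep"]}
    gene_de = {"age": gt["age_late_vs_early"], "layer": gt["layer_LII_vs_LDeep"]}
    strict = ti.three_requirement_filter(pairs, mirna_de, gene_de)
    keys = {(c.mirna_id, c.gene_id) for c in strict}
    in_keys = {(p.mirna_id, p.gene_id) for p in pairs}
    assert keys <= in_keys
    # relax rho
    relaxed_rho = ti.three_requirement_filter(pairs, mirna_de, gene_de,
                                              rho_max=0.99)
    assert keys <= {(c.mirna_id, c.gene_id) for c in relaxed_rho}
    # relax DE (alpha = 1 makes everything DE)
    relaxed_de = ti.three_requirement_filter(pairs, mirna_de, gene_de, alpha=1.1)
    assert keys <= {(c.mirna_id, c.gene_id) for c in relaxed_de}


def test_rank_candidates_ordering_and_expression_floor():
    mirna_de, gene_de = _de_tables({"age": ["mir"], "layer": ["mir"]},
                                   {"age": ["g1", "g2", "g3"],
                                    "layer": ["g1", "g2", "g3"]})
    pairs = [_pair("mir", "g1", -0.6, score=-0.2),
             _pair("mir", "g2", -0.55, score=-0.4),
             _pair("mir", "g3", -0.9, score=-0.3)]
    cands = ti.three_requirement_filter(pairs, mirna_de, gene_de)
    low = [c for c in cands if c.gene_id == "g1"]
    for c in low:
        c.gene_median_expr = 4.9   # below the floor
    ranked = ti.rank_candidates(cands, min_median_expr=5.0)
    assert [c.gene_id for c in ranked] == ["g2", "g3"]  # best score first


# ---------------------------------------------------------------------------
# quartile and same-module filters
# ---------------------------------------------------------------------------

def test_expression_quartile_filter():
    rows = {f"mir{i}": [float(i)] * 4 for i in range(4)}
    mat, _ = _matrices(rows, {"g": [1.0] * 4})
    assert ti.expression_quartile_filter(mat, q=1.0) == set(rows)
    assert ti.expression_quartile_filter(mat, q=0.25) == {"mir3"}
    with pytest.raises(ValueError):
        ti.expression_quartile_filter(mat, q=0.0)


def test_expression_quartile_boundary_ties_included():
    rows = {"a": [3.0] * 4, "b": [3.0] * 4, "c": [1.0] * 4, "d": [2.0] * 4}
    mat, _ = _matrices(rows, {"g": [1.0] * 4})
    assert ti.expression_quartile_filter(mat, q=0.25) == {"a", "b"}


def test_same_module_site_fraction_counts():
    records = [m.TargetRecord(f"mir{i}", "g", "predicted_all", -0.2)
               for i in range(4)]
    asg = m.ModuleAssignment({"mir0": 2, "mir1": 2, "mir2": 1, "mir3": 3})
    assert ti.same_module_site_fraction("g", records, asg) == 0.5
    asg_all = m.ModuleAssignment({f"mir{i}": 2 for i in range(4)})
    assert ti.same_module_site_fraction("g", records[:3], asg_all) == 1.0
    asg_none = m.ModuleAssignment({f"mir{i}": 0 for i in range(4)})
    assert ti.same_module_site_fraction("g", records, asg_none) is None


def test_skew_filters_commute(default_sim):
    _, mirna, mrna, truth = default_sim
    mn, lc = normalized_views(mirna, mrna)
    pairs = ti.pair_correlations(mn, lc, truth.target_records)
    conserved = [p for p in pairs if p.source == "predicted_conserved"]
    top = ti.expression_quartile_filter(mn, 0.25)
    fr = ti.all_same_module_fractions(truth.target_records,
                                      m.ModuleAssignment(truth.true_module))
    filters = [
        dict(context_max=-0.25),
        dict(mirna_whitelist=top),
        dict(min_same_module_fraction=0.75, same_module_fractions=fr),
    ]
    results = []
    for order in permutations(range(3)):
        out = conserved
        for i in order:
            out = ti.apply_skew_filters(out, **filters[i])
        results.append({(p.mirna_id, p.gene_id) for p in out})
    assert all(r == results[0] for r in results)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def test_mw_exact_enumeration_example():
    U, p, method = ti.mann_whitney_u([1, 2], [3, 4])
    assert method == "exact"
    assert U == 4.0
    assert np.isclose(p, 1 / 6)


def test_mw_identical_samples_near_half():
    rng = np.random.default_rng(2)
    x = rng.normal(size=30)
    U, p, method = ti.mann_whitney_u(x, x.copy())
    assert method == "normal"
    assert 0.4 < p < 0.6


def _mw_rank_sum_oracle(x, y):
    """Independent enumeration via rank sums."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    W_obs = ranks[:n1].sum()
    # U = W - n1(n1+1)/2 counts pairs x > y; x smaller <-> small W
    hits = total = 0
    for chosen in combinations(range(len(pooled)), n1):
        total += 1
        if ranks[list(chosen)].sum() <= W_obs:
            hits += 1
    return hits / total


def test_mw_exact_matches_rank_sum_oracle_with_ties():
    rng = np.random.default_rng(3)
    for _ in range(30):
        n1, n2 = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        x = np.round(rng.normal(size=n1), 0)
        y = np.round(rng.normal(0.5, 1, size=n2), 0)
        _, p, method = ti.mann_whitney_u(x, y)
        assert method == "exact"
        assert np.isclose(p, _mw_rank_sum_oracle(x, y), atol=1e-12)


def test_mw_exact_vs_normal_agreement_n8():
    rng = np.random.default_rng(4)
    diffs = []
    for _ in range(100):
        x = rng.normal(size=8)
        y = rng.normal(0.5, 1, size=8)
        _, p_exact, _ = ti.mann_whitney_u(x, y, exact_max_n=8)
        _, p_norm, _ = ti.mann_whitney_u(x, y, exact_max_n=0)
        diffs.append(abs(p_exact - p_norm))
    assert max(diffs) < 0.02


def test_skew_test_empty_side_errors():
    with pytest.raises(ValueError, match="empty"):
        ti.correlation_skew_test([], [_pair("m", "g", 0.0)])
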