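import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

import mecmir as m
from mecmir import diffexpr, normalize


def _gaussian_matrix(seed, n_features=200):
    rng = np.random.default_rng(seed)
    samples = [m.SampleAnnotation(f"s{i}", "P2" if i < 4 else "P23", "LII",
                                  f"a{i}", "array") for i in range(8)]
    vals = rng.normal(size=(n_features, 8))
    frame = pd.DataFrame(vals, index=[f"f{i}" for i in range(n_features)],
                         columns=[s.sample_id for s in samples])
    return m.ExpressionMatrix(frame, samples, "log2")


def _two_group_design(matrix):
    g = np.array([s.age == "P23" for s in matrix.samples], dtype=float)
    X = pd.DataFrame({"g0": 1 - g, "g1": g}, index=matrix.sample_ids)
    c = pd.Series({"g0": -1.0, "g1": 1.0})
    return X, c


def _ordinary_t(matrix, X, c):
    Y = matrix.values.to_numpy()
    Xn = X.to_numpy()
    cn = c.reindex(X.columns).to_numpy()
    XtX_inv = np.linalg.inv(Xn.T @ Xn)
    beta = XtX_inv @ Xn.T @ Y.T
    resid = Y.T - Xn @ beta
    df = Xn.shape[0] - Xn.shape[1]
    s2 = (resid ** 2).sum(axis=0) / df
    return (cn @ beta) / np.sqrt(s2 * float(cn @ XtX_inv @ cn))


def test_d0_zero_equals_ordinary_t():
    mat = _gaussian_matrix(0)
    X, c = _two_group_design(mat)
    table, _ = diffexpr.fit_and_moderate(
        mat, X, c, eb_params=diffexpr.EBayesParams(0.0, 1.0))
    assert np.abs(table.table["t_mod"].to_numpy()
                  - _ordinary_t(mat, X, c)).max() < 1e-10


def test_d0_infinite_shares_one_variance():
    mat = _gaussian_matrix(1)
    X, c = _two_group_design(mat)
    s0 = 0.7
    table, _ = diffexpr.fit_and_moderate(
        mat, X, c, eb_params=diffexpr.EBayesParams(np.inf, s0))
    # t_mod * sqrt(s0 * vunscaled) recovers lfc for every feature
    XtX_inv = np.linalg.inv(X.to_numpy().T @ X.to_numpy())
    cn = c.reindex(X.columns).to_numpy()
    vu = float(cn @ XtX_inv @ cn)
    recon = table.table["t_mod"] * np.sqrt(s0 * vu)
    assert np.allclose(recon, table.table["lfc"], atol=1e-10)


def test_moment_estimators_match_direct_transcription():
    """Moderated t agrees with an independent coding of the moment equations."""
    mat = _gaussian_matrix(2, n_features=200)
    rng = np.random.default_rng(22)
    sds = np.exp(rng.normal(0.0, 0.6, size=200))  # heteroskedastic features
    mat.values.iloc[:, :] = mat.values.to_numpy() * sds[:, None]
    X, c = _two_group_design(mat)
    table, params = diffexpr.fit_and_moderate(mat, X, c)

    # independent oracle: direct transcription, scalar loops
    Y = mat.values.to_numpy()
    Xn, cn = X.to_numpy(), c.reindex(X.columns).to_numpy()
    df = Xn.shape[0] - Xn.shape[1]
    XtX_inv = np.linalg.inv(Xn.T @ Xn)
    s2 = []
    lfc = []
    for row in Y:
        b = XtX_inv @ Xn.T @ row
        r = row - Xn @ b
        s2.append(float(r @ r) / df)
        lfc.append(float(cn @ b))
    s2 = np.array(s2)
    e = np.log(s2) - special.digamma(df / 2) + np.log(df / 2)
    evar = e.var(ddof=1) - float(special.polygamma(1, df / 2))
    # independent trigamma inversion by bracketing root-finder
    from scipy.optimize import brentq
    y = evar
    x = brentq(lambda v: float(special.polygamma(1, v)) - y, 1e-6, 1e8)
    d0 = 2 * x
    s0 = np.exp(e.mean() + special.digamma(x) - np.log(x))
    assert np.isclose(params.d0, d0, rtol=1e-8)
    assert np.isclose(params.s0_sq, s0, rtol=1e-8)
    post = (d0 * s0 + df * s2) / (d0 + df)
    vu = float(cn @ XtX_inv @ cn)
    t_oracle = np.array(lfc) / np.sqrt(post * vu)
    p_oracle = 2 * stats.t.sf(np.abs(t_oracle), df + d0)
    assert np.abs(table.table["t_mod"].to_numpy() - t_oracle).max() < 1e-8
    assert np.abs(table.table["p_raw"].to_numpy() - p_oracle).max() < 1e-8


def test_zero_variance_feature_handled():
    mat = _gaussian_matrix(3, n_features=50)
    mat.values.iloc[0] = 5.0  # constant feature
    X, c = _two_group_design(mat)
    table, params = diffexpr.fit_and_moderate(mat, X, c)
    assert np.isfinite(table.table["t_mod"]).all()
    assert table.table.loc["f0", "p_raw"] > 0.9


def test_rank_deficient_design_rejected():
    mat = _gaussian_matrix(4, n_features=20)
    X, c = _two_group_design(mat)
    X["dup"] = X["g1"]
    with pytest.raises(ValueError, match="rank deficient"):
        diffexpr.fit_and_moderate(mat, X, c)


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def _bh_brute_force(p):
    m_ = len(p)
    order = sorted(range(m_), key=lambda i: p[i])
    adj = [None] * m_
    for rank_pos, i in enumerate(order, start=1):
        candidates = [p[j] * m_ / (sorted_rank + 1)
                      for sorted_rank, j in enumerate(order)
                      if sorted_rank + 1 >= rank_pos]
        adj[i] = min(1.0, min(candidates))
    return np.array(adj)


def test_bh_hand_example():
    out = diffexpr.bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])


def test_bh_single_and_constant():
    assert diffexpr.bh_adjust([0.3])[0] == 0.3
    assert np.allclose(diffexpr.bh_adjust([0.2, 0.2, 0.2]), 0.2)


def test_bh_matches_brute_force_on_random_vectors():
    rng = np.random.default_rng(7)
    for _ in range(200):
        n = int(rng.integers(1, 50))
        p = rng.uniform(size=n)
        if rng.uniform() < 0.3:
            p = np.round(p, 1)  # force ties
        assert np.allclose(diffexpr.bh_adjust(p), _bh_brute_force(p), atol=1e-12)


def test_bh_rejects_invalid():
    with pytest.raises(ValueError):
        diffexpr.bh_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# contrasts on the synthetic design
# ---------------------------------------------------------------------------

def test_p_monotone_in_abs_t():
    mat = _gaussian_matrix(5)
    X, c = _two_group_design(mat)
    table, _ = diffexpr.fit_and_moderate(mat, X, c)
    t = table.table.sort_values("p_raw")
    assert (t["t_mod"].abs().diff().dropna() <= 1e-12).all()


def test_layer_de_largest_at_p9_with_p9_only_effect():
    """A layer effect planted only at P9 dominates that age's DE set."""
    profile = np.array([[0, 0], [1, -1], [0, 0], [0, 0]], dtype=float)
    cfg = m.SimulationConfig(seed=6, n_modules=1, module_profiles=(profile,),
                             n_mirna=60, n_mrna=20, frac_true_targets=0.0)
    mirna, _, _ = m.simulate_expression(cfg)
    tables, _ = diffexpr.run_all_contrasts(normalize.quantile_normalize(mirna))
    counts = {a: len(diffexpr.call_de(tables[f"layer_LII_vs_LDeep@{a}"])[0])
              for a in ("P2", "P9", "P23", "P45")}
    assert counts["P9"] == max(counts.values())
    assert counts["P9"] > counts["P2"]


def test_overlap_counts_are_set_algebra(default_sim):
    _, mirna, _, truth = default_sim
    tables, summary = diffexpr.run_all_contrasts(
        normalize.quantile_normalize(mirna))
    age = diffexpr.call_de(tables["age_late_vs_early"])[0]
    layer = diffexpr.call_de(tables["layer_LII_vs_LDeep"])[0]
    assert summary["age_layer_overlap"] == len(age & layer)
    assert summary["n_de"]["age_late_vs_early"] == len(age)


def test_blocking_increases_power_with_animal_effects():
    """Per-animal offsets: the animal-blocked layer fit beats a group fit."""
    rng = np.random.default_rng(8)
    cfg = m.SimulationConfig(seed=8, n_mirna=100, n_mrna=20,
                             frac_true_targets=0.0, profile_scale=0.0)
    design = m.simulate_design(cfg)
    mirna, _, _ = m.simulate_expression(cfg, design)
    vals = mirna.values.to_numpy().copy()
    animals = sorted({s.animal_id for s in design})
    offsets = dict(zip(animals, rng.normal(0, 2.0, size=len(animals))))
    lii = np.array([s.layer == "LII" for s in design], dtype=float)
    for j, s in enumerate(design):
        vals[:, j] += offsets[s.animal_id] + 0.6 * lii[j]
    mat = mirna.with_values(pd.DataFrame(vals, index=mirna.values.index,
                                         columns=mirna.values.columns))
    X_blocked, ages = diffexpr.layer_design(mat)
    pooled = pd.Series(0.0, index=X_blocked.columns)
    for a in ages:
        pooled[f"LII:{a}"] = 1.0 / len(ages)
    blocked, _ = diffexpr.fit_and_moderate(mat, X_blocked, pooled)
    X_naive = pd.DataFrame({"LII": lii, "LDeep": 1 - lii}, index=mat.sample_ids)
    naive, _ = diffexpr.fit_and_moderate(
        mat, X_naive, pd.Series({"LII": 1.0, "LDeep": -1.0}))
    assert (blocked.table["p_adj"] < 0.05).sum() > (naive.table["p_adj"] < 0.05).sum()


def test_call_de_alpha_zero_empty(default_sim):
    _, mirna, _, _ = default_sim
    tables, _ = diffexpr.run_all_contrasts(normalize.quantile_normalize(mirna))
    called, _ = diffexpr.call_de(tables["age_late_vs_early"], alpha=0.0)
    assert called == set()
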