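import numpy as np
import pandas as pd
import pytest

import mecmir as m
from mecmir import normalize


def _matrix(values, samples, scale="log2"):
    frame = pd.DataFrame(values, columns=[s.sample_id for s in samples])
    frame.index = [f"f{i}" for i in range(frame.shape[0])]
    return m.ExpressionMatrix(frame, samples, scale)


# ---------------------------------------------------------------------------
# feature filtering
# ---------------------------------------------------------------------------

def test_filter_features_presence_rule(small_samples):
    counts = _matrix([[5, 5, 5, 5],     # everywhere -> kept
                      [0, 0, 0, 0],     # nowhere -> dropped
                      [3, 0, 0, 0]],    # all of group P2/LII only -> kept
                     small_samples, "counts")
    kept = normalize.filter_features(counts, min_present_fraction=0.5)
    assert kept.feature_ids == ["f0", "f2"]


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def test_quantile_hand_oracle(small_samples):
    """Columns (2,6) and (4,8): sort, average quantiles, remap -> (3,7)."""
    samples = small_samples[:2]
    mat = _matrix([[2.0, 4.0], [6.0, 8.0]], samples)
    out = normalize.quantile_normalize(mat).values.to_numpy()
    assert np.allclose(out, [[3.0, 3.0], [7.0, 7.0]])


def test_quantile_identical_columns_unchanged(small_samples):
    mat = _matrix(np.tile([[1.0], [5.0], [2.0]], (1, 4)), small_samples)
    out = normalize.quantile_normalize(mat)
    assert np.allclose(out.values.to_numpy(), mat.values.to_numpy())


def test_quantile_single_column_unchanged(small_samples):
    mat = _matrix([[3.0], [1.0], [2.0]], small_samples[:1])
    out = normalize.quantile_normalize(mat)
    assert np.allclose(out.values.to_numpy(), mat.values.to_numpy())


def test_quantile_columns_are_permutations_and_idempotent():
    rng = np.random.default_rng(0)
    samples = [m.SampleAnnotation(f"s{i}", "P2", "LII", f"a{i}", "array")
               for i in range(5)]
    mat = _matrix(rng.normal(size=(40, 5)), samples)
    out = normalize.quantile_normalize(mat)
    cols = [np.sort(out.values[c].to_numpy()) for c in out.values.columns]
    for c in cols[1:]:
        assert np.allclose(c, cols[0])
    again = normalize.quantile_normalize(out)
    assert np.allclose(again.values.to_numpy(), out.values.to_numpy(), atol=1e-12)


def test_quantile_ties_get_mean_of_quantiles(small_samples):
    samples = small_samples[:2]
    mat = _matrix([[1.0, 1.0], [1.0, 2.0], [3.0, 3.0]], samples)
    out = normalize.quantile_normalize(mat).values
    # first column has a tie at 1.0 spanning the two lowest quantiles
    assert out.iloc[0, 0] == out.iloc[1, 0]


def test_quantile_rejects_missing(small_samples):
    mat = _matrix([[1.0, np.nan, 1.0, 1.0]], small_samples)
    with pytest.raises(ValueError):
        normalize.quantile_normalize(mat)


# ---------------------------------------------------------------------------
# TMM and log-CPM
# ---------------------------------------------------------------------------

def test_tmm_identical_columns(small_samples):
    counts = _matrix(np.tile([[10.0], [20.0], [5.0]], (1, 4)),
                     small_samples, "counts")
    f = normalize.tmm_factors(counts)
    assert np.allclose(f.to_numpy(), 1.0)


def test_tmm_pure_depth_difference(small_samples):
    """Doubling a library changes depth, not composition: factors stay 1."""
    rng = np.random.default_rng(1)
    base = rng.integers(1, 500, size=50).astype(float)
    counts = _matrix(np.column_stack([base, 2 * base, base, 3 * base]),
                     small_samples, "counts")
    f = normalize.tmm_factors(counts)
    assert np.allclose(f.to_numpy(), 1.0, atol=1e-8)
    assert np.isclose(np.exp(np.mean(np.log(f))), 1.0, atol=1e-12)


def test_tmm_permutation_symmetry(small_samples):
    rng = np.random.default_rng(2)
    vals = rng.integers(1, 1000, size=(60, 4)).astype(float)
    counts = _matrix(vals, small_samples, "counts")
    f = normalize.tmm_factors(counts)
    perm = [2, 0, 3, 1]
    samples_p = [small_samples[i] for i in perm]
    counts_p = _matrix(vals[:, perm], samples_p, "counts")
    f_p = normalize.tmm_factors(counts_p)
    for i, j in enumerate(perm):
        assert np.isclose(f_p.iloc[i], f.iloc[j], atol=1e-12)


def test_tmm_zero_library_errors(small_samples):
    counts = _matrix([[0.0, 1.0, 1.0, 1.0]], small_samples, "counts")
    with pytest.raises(ValueError, match="zero total"):
        normalize.tmm_factors(counts)


def test_log_cpm_closed_form(small_samples):
    lib = 1_000_000.0
    vals = np.zeros((2, 4))
    vals[0] = 500.0
    vals[1] = lib - 500.0
    counts = _matrix(vals, small_samples, "counts")
    out = normalize.log_cpm(counts, prior=0.5)
    expected = np.log2(500.5 / (lib + 1.0) * 1e6)
    assert np.allclose(out.values.iloc[0].to_numpy(), expected)


def test_log_cpm_zero_count_finite_and_depth_invariance(small_samples):
    rng = np.random.default_rng(3)
    vals = rng.integers(0, 200, size=(30, 4)).astype(float)
    vals[0] = 0.0
    counts = _matrix(vals, small_samples, "counts")
    assert np.isfinite(normalize.log_cpm(counts).values.to_numpy()).all()
    # depth invariance holds where the prior is negligible
    vals_nz = vals[1:] + 50.0
    out1 = normalize.log_cpm(_matrix(vals_nz, small_samples, "counts"))
    out2 = normalize.log_cpm(_matrix(2 * vals_nz, small_samples, "counts"))
    assert np.abs(out2.values.to_numpy() - out1.values.to_numpy()).max() < 0.01


# ---------------------------------------------------------------------------
# precision weights
# ---------------------------------------------------------------------------

def test_precision_weights_homoskedastic_nearly_constant():
    rng = np.random.default_rng(4)
    samples = [m.SampleAnnotation(f"s{i}", "P2", "LII", f"a{i}", "rnaseq")
               for i in range(8)]
    vals = rng.normal(8.0, 1.0, size=(600, 1)) + rng.normal(0, 0.5, size=(600, 8))
    mat = _matrix(vals, samples)
    design = pd.DataFrame({"mu": np.ones(8)}, index=mat.sample_ids)
    w = normalize.precision_weights(mat, design)
    assert (w.to_numpy() > 0).all()
    cv = w.iloc[:, 0].std() / w.iloc[:, 0].mean()
    assert cv < 0.2


def test_precision_weights_follow_planted_trend():
    """Noise sd decreasing in mean -> weights increasing in mean."""
    rng = np.random.default_rng(5)
    samples = [m.SampleAnnotation(f"s{i}", "P2", "LII", f"a{i}", "rnaseq")
               for i in range(8)]
    means = np.linspace(2, 12, 400)
    sds = np.linspace(1.2, 0.2, 400)
    vals = means[:, None] + rng.normal(size=(400, 8)) * sds[:, None]
    mat = _matrix(vals, samples)
    design = pd.DataFrame({"mu": np.ones(8)}, index=mat.sample_ids)
    w = normalize.precision_weights(mat, design).iloc[:, 0].to_numpy()
    lo = w[means < 5].mean()
    hi = w[means > 9].mean()
    assert hi > lo


def test_precision_weights_single_feature_unit(small_samples):
    mat = _matrix([[1.0, 2.0, 3.0, 4.0]], small_samples)
    design = pd.DataFrame({"mu": np.ones(4)}, index=mat.sample_ids)
    w = normalize.precision_weights(mat, design)
    assert np.allclose(w.to_numpy(), 1.0)


# ---------------------------------------------------------------------------
# delta-Ct
# ---------------------------------------------------------------------------

def _ct_matrix(values, n=3):
    samples = [m.SampleAnnotation(f"q{i}", "P2", "NA", f"q{i}", "qpcr")
               for i in range(values.shape[1])]
    return _matrix(values, samples, "ct")


def test_delta_ct_hand_arithmetic():
    ct = _ct_matrix(np.array([[20.0], [22.0], [24.0]]))
    out = normalize.delta_ct_normalize(ct)
    assert np.allclose(out.values.iloc[:, 0].to_numpy(), [2.0, 0.0, -2.0])


def test_delta_ct_additive_shift_invariance():
    rng = np.random.default_rng(6)
    vals = rng.uniform(20, 30, size=(10, 4))
    ct = _ct_matrix(vals)
    out = normalize.delta_ct_normalize(ct)
    shifted = vals.copy()
    shifted[:, 2] += 3.7
    out2 = normalize.delta_ct_normalize(_ct_matrix(shifted))
    assert np.allclose(out.values.to_numpy(), out2.values.to_numpy(), atol=1e-12)


def test_delta_ct_drops_flagged_and_centers():
    vals = np.array([[20.0, 21.0], [22.0, 23.0], [24.0, 25.0]])
    mask = pd.DataFrame(False, index=["f0", "f1", "f2"], columns=["q0", "q1"])
    mask.loc["f1", "q0"] = True
    ct = _ct_matrix(vals)
    out = normalize.delta_ct_normalize(ct, mask)
    assert list(out.values.index) == ["f0", "f2"]
    assert np.allclose(out.values.mean(axis=0).to_numpy(), 0.0, atol=1e-12)
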