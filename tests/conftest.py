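import numpy as np
import pandas as pd
import pytest

import mecmir as m


@pytest.fixture
def small_samples():
    """Four samples: two animals x two layers at two ages."""
    return [
        m.SampleAnnotation("s1", "P2", "LII", "a1", "array"),
        m.SampleAnnotation("s2", "P2", "LDeep", "a1", "array"),
        m.SampleAnnotation("s3", "P23", "LII", "a2", "array"),
        m.SampleAnnotation("s4", "P23", "LDeep", "a2", "array"),
    ]


@pytest.fixture
def small_matrix(small_samples):
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [4.0, 3.0, 2.0, 1.0],
         [5.0, 5.0, 5.0, 5.0]],
        index=["f1", "f2", "f3"],
        columns=[s.sample_id for s in small_samples])
    return m.ExpressionMatrix(values, small_samples, "log2")


@pytest.fixture
def default_sim():
    """One realisation of the default synthetic study."""
    cfg = m.SimulationConfig(seed=1)
    mirna, mrna, truth = m.simulate_expression(cfg)
    return cfg, mirna, mrna, truth


def normalized_views(mirna, mrna):
    """Quantile-normalized miRNA matrix and TMM/log-CPM/quantile mRNA matrix."""
    from mecmir import normalize
    mn = normalize.quantile_normalize(mirna)
    counts = normalize.filter_features(mrna)
    lc = normalize.quantile_normalize(
        normalize.log_cpm(counts, normalize.tmm_factors(counts)))
    return mn, lc
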