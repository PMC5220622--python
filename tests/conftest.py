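import numpy as np
import pandas as pd
import pytest

from thyromics.preprocess import log10_transform, runday_normalize
from thyromics.synthetic import (
    make_design,
    metabolite_defaults,
    simulate_features,
    simulate_hormones,
)


@pytest.fixture(scope="session")
def cohort():
    """A default 16-subject, 5-visit cohort with hormones and annotations."""
    design, subjects = make_design(seed=101)
    samples = simulate_hormones(design, subjects, seed=202)
    return design, subjects, samples


@pytest.fixture(scope="session")
def clean_layer(cohort):
    """A 40-feature metabolite layer with strong planted effects, no noise
    sources beyond the residual: no missingness, no run-day scaling."""
    design, subjects, samples = cohort
    cfg = metabolite_defaults(
        n_features=40,
        effect_fraction=0.25,
        beta_range=(0.01, 0.03),
        missing_rate=0.0,
        runday_scaling=False,
        outlier_shift_sd=0.0,
    )
    matrix, catalog = simulate_features(design, subjects, samples, cfg, seed=303)
    return matrix, catalog


@pytest.fixture(scope="session")
def clean_log_layer(clean_layer):
    matrix, catalog = clean_layer
    return log10_transform(matrix), catalog


@pytest.fixture()
def tiny_matrix():
    """A hand-sized raw matrix with controlled missingness."""
    idx = [f"s{i}" for i in range(5)]
    return pd.DataFrame(
        {
            "f_full": [2.0, 4.0, 6.0, 8.0, 10.0],
            "f_hole": [1.0, np.nan, 3.0, np.nan, 5.0],
            "f_zero": [0.0, 1.0, 10.0, 100.0, 1000.0],
        },
        index=idx,
    )
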