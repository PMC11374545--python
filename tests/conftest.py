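import numpy as np
import pandas as pd
import pytest

from plantdex.survey_inference import SurveyDesign
from plantdex.synthetic_data import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One in-memory synthetic cohort reused across read-only tests."""
    return generate_cohort(GeneratorConfig(n=150, seed=42, rep_groups=12))


def make_design(n, seed=0, equal=False, R=8):
    """A survey design with lognormal weights and delete-a-group replicates;
    with equal=True the weights are constant (replicates still jackknife)."""
    rng = np.random.default_rng(seed)
    w = np.ones(n) if equal else np.exp(rng.normal(0, 0.4, n))
    groups = np.arange(n) % R
    rep = np.where(groups[:, None] == np.arange(R)[None, :], 0.0,
                   w[:, None] * R / (R - 1))
    return SurveyDesign(np.arange(n), w, rep)


def degenerate_design(n, equal_weights=True, seed=0, R=4):
    """Replicate sets all equal to the main weights: replicate variance 0."""
    rng = np.random.default_rng(seed)
    w = np.ones(n) if equal_weights else np.exp(rng.normal(0, 0.4, n))
    return SurveyDesign(np.arange(n), w, np.tile(w[:, None], (1, R)))


@pytest.fixture
def regression_frame():
    """20-row fixture with a continuous and a binary outcome."""
    rng = np.random.default_rng(7)
    n = 20
    x1 = rng.normal(0, 1, n)
    x2 = rng.normal(0, 1, n)
    y = 1.0 + 2.0 * x1 - 0.5 * x2 + rng.normal(0, 0.3, n)
    yb = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 0.8 * x1)))).astype(float)
    return pd.DataFrame({"x1": x1, "x2": x2, "y": y, "yb": yb})
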