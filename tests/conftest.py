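import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from mmsig.data import CohortDesign, FeatureMatrix
from mmsig.synthetic import EffectSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """42-subject cohort, 60 features, 3 planted effects — fast shared fixture."""
    return generate_cohort(
        p_by_block={"VBM": 20, "FC": 30, "SC": 10},
        effect=EffectSpec(n_planted=3, effect_size=2.0, rho=0.2),
        seed=11,
    )


@pytest.fixture(scope="session")
def null_cohort():
    """Zero-effect cohort with the default 500-feature layout."""
    return generate_cohort(
        p_by_block={"VBM": 30, "FC": 40, "SC": 10},
        effect=EffectSpec(n_planted=0, effect_size=0.0),
        seed=5,
    )


@pytest.fixture
def toy_feature_matrix():
    rng = np.random.default_rng(3)
    vals = rng.standard_normal((12, 8))
    names = [f"VBM:f{i}" for i in range(5)] + [f"FC:f{i}" for i in range(3)]
    mods = ["VBM"] * 5 + ["FC"] * 3
    return FeatureMatrix(vals, names, mods)


@pytest.fixture
def toy_design():
    rng = np.random.default_rng(4)
    labels = np.array([1] * 8 + [0] * 4)
    cov = pd.DataFrame({"age": rng.normal(65, 8, 12), "sex": rng.integers(0, 2, 12)})
    return CohortDesign(labels, cov)
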