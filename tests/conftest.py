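import numpy as np
import pytest

from painscale.pain_scale import fit_scale, score_trials
from painscale.synthetic_data import default_config, generate_cohort


@pytest.fixture(scope="session")
def baseline_cohort():
    """Synthetic scale-construction cohort (CS/DB/LP/HP, 10 subjects)."""
    config = default_config("baseline_scale", seed=7)
    trials, truth = generate_cohort(config)
    return trials, truth


@pytest.fixture(scope="session")
def fitted_model(baseline_cohort):
    trials, _ = baseline_cohort
    return fit_scale(trials, seed=7)


@pytest.fixture(scope="session")
def scored_baseline(baseline_cohort, fitted_model):
    trials, _ = baseline_cohort
    return score_trials(fitted_model, trials)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
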