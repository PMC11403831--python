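import numpy as np
import pytest

from woundcurve import (
    FitConfig,
    ModelSpec,
    ModelTemplate,
    TrialDesign,
    fit,
    generate_trial,
)
from woundcurve import experiments as ex


@pytest.fixture(scope="session")
def sqrt_truth() -> ModelSpec:
    """Square-root-family generating model used across the suite."""
    return ModelSpec(**ex.TRUTH_SQRT)


@pytest.fixture(scope="session")
def small_trial(sqrt_truth):
    """A 40-patient single-method trial with a 10-visit schedule."""
    design = TrialDesign(
        n_patients=40,
        visit_schedule=np.array([0, 7, 14, 21, 28, 35, 42, 49, 56, 63], float),
        methods={"ARANZ Automatic": None},
        truncate_baseline=False,
    )
    table, record = generate_trial(design, sqrt_truth, seed=42)
    return table, record


@pytest.fixture(scope="session")
def small_fit(small_trial, sqrt_truth):
    """Posterior fit of the generating family to the small trial."""
    table, _ = small_trial
    template = ModelTemplate(family=sqrt_truth.family)
    samples = fit(template, table,
                  FitConfig(chains=2, walkers=32, warmup=800, draws=400,
                            thin=6, seed=7))
    return template, table, samples


@pytest.fixture(scope="session")
def recovery_results():
    """Shared 20-replicate recovery/precision experiment (heavy)."""
    return ex.recovery_and_precision(n_rep=20, seed=20240916)


@pytest.fixture(scope="session")
def selection_results():
    """Shared 20-replicate model-selection experiment (heavy)."""
    return ex.model_selection(n_rep=20, seed=20240916)
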