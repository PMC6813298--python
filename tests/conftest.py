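"""Shared fixtures.

The expensive multi-seed simulation suites are session-scoped so the
end-to-end acceptance checks and the per-module invariants evaluate the
same runs.
"""
import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rsgica.gica import run_gica
from rsgica.phantom import generate_study
from rsgica.pipeline import evaluate_null_study, evaluate_phantom_study
from rsgica.preprocess import preprocess_study

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_study():
    """4-run, 24-volume study on a 16x16x8 grid — seconds-scale I/O tests."""
    return generate_study(
        n_subjects=2, runs_per_subject=2, n_volumes=24, seed=3,
        grid_shape=(16, 16, 8),
    )


@pytest.fixture(scope="session")
def small_study():
    """6 subjects x 2 runs x 60 volumes on the default grid."""
    return generate_study(n_subjects=6, runs_per_subject=2, n_volumes=60, seed=5)


@pytest.fixture(scope="session")
def small_decomposition(small_study):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pre = preprocess_study(small_study)
        decomp = run_gica(pre, 7, seed=5)
    return small_study, pre, decomp


@pytest.fixture(scope="session")
def recovery_suite():
    """Ten full-scale phantom pipeline evaluations (22 subjects x 2 runs,
    139 volumes, snr 1, model order n_networks + 3) with a model-order-10
    robustness probe."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [
            evaluate_phantom_study(seed=seed, probe_model_order=10)
            for seed in range(1, 11)
        ]


@pytest.fixture(scope="session")
def null_suite():
    """Twenty source-free phantom evaluations (type-I control probe)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [evaluate_null_study(seed=seed) for seed in range(1, 21)]
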