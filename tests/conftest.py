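"""Shared fixtures: reference parameter sets and small precomputed curves."""

import pytest

from nlrm2.datatypes import NoiseModel, default_drive
from nlrm2.physics import ensemble_m2
from nlrm2.reference import solution_params


@pytest.fixture(scope="session")
def solution():
    """Injection-solution ensemble parameters (the best-characterized row)."""
    return solution_params()


@pytest.fixture(scope="session")
def drive121():
    """Signed 121-point field grid over +-300 Oe at the standard drive."""
    return default_drive(121)


@pytest.fixture(scope="session")
def solution_model(solution, drive121):
    """Noiseless solution-row forward curve on the 121-point grid (complex)."""
    return ensemble_m2(solution, drive121).complex


@pytest.fixture(scope="session")
def noiseless_pair(solution, drive121, solution_model):
    """Noise-free (direct, reverse) branch pair of the solution specimen."""
    from nlrm2.synthetic import simulate_sweep

    return simulate_sweep(
        solution, drive121, 8.0, NoiseModel(seed=1), label="solution",
        model=solution_model,
    )


@pytest.fixture(scope="session")
def noiseless_curve(noiseless_pair):
    from nlrm2.signal_processing import preprocess

    return preprocess(*noiseless_pair)
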