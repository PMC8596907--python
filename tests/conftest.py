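"""Shared fixtures: model-generated curves and simulated plates."""

import numpy as np
import pytest

from cqman import (
    AmplificationCurve,
    AnalysisConfig,
    BIOMARKER_LEVELS,
    GompertzFit,
    SimulationConfig,
    analyze_plate,
    results_to_frame,
    simulate_dilution_plate,
)


def make_gompertz_curve(
    y0=0.05, ymax=1.05, b=1.5, x0=25.0, n_cycles=40,
    noise_sd=0.0, seed=0, well_id="W01", gene="G01",
    sample="S01", concentration=None,
):
    """Curve sampled exactly from the Gompertz model (+ optional noise)."""
    cycles = np.arange(1, n_cycles + 1)
    fluor = y0 + (ymax - y0) * np.exp(-np.exp(-(cycles - x0) / b))
    if noise_sd > 0:
        fluor = fluor + np.random.default_rng(seed).normal(0, noise_sd, n_cycles)
    return AmplificationCurve(
        well_id=well_id, gene=gene, sample=sample,
        known_concentration=concentration, cycles=cycles, fluorescence=fluor,
    )


@pytest.fixture
def gompertz_curve():
    return make_gompertz_curve()


@pytest.fixture
def standard_fit():
    """The worked reference fit used across closed-form tests."""
    return GompertzFit(y0=0.0, ymax=1.0, b=2.0, x0=20.0, converged=True)


@pytest.fixture(scope="session")
def noiseless_biomarker():
    """Noiseless 20-gene x 5-level x 3-replicate plate with truth + results."""
    cfg = SimulationConfig(noise_sd=0.0, seed=7)
    plate, truth = simulate_dilution_plate(BIOMARKER_LEVELS, 3, 20, cfg)
    results = analyze_plate(plate, AnalysisConfig())
    return plate, truth, results, results_to_frame(results)


@pytest.fixture(scope="session")
def small_noisy_plate():
    """5-gene noisy plate reused by indicator-level tests."""
    cfg = SimulationConfig(noise_sd=0.01, seed=11)
    plate, truth = simulate_dilution_plate(BIOMARKER_LEVELS, 3, 5, cfg)
    results = analyze_plate(plate)
    return plate, truth, results
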