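"""Mechanistic qPCR curve simulator with known ground truth.

Curves are generated from per-cycle amplification kinetics, *not* by
sampling the Gompertz model, so the analysis pipeline is always exercised
under model mismatch, as it is with real instrument data:

    N_n = N_{n-1} * E_n,   E_n = 1 + (E - 1) * max(0, 1 - (N_{n-1} / K)^h)

Early on (N << K) the product grows by the full per-cycle efficiency E; as
product accumulates toward the carrying capacity K the per-cycle gain is
suppressed by the factor 1 - (N/K)^h and the reaction stalls exactly at
N = K, giving a flat plateau.  The default exponent h = 2 encodes
product-product reannealing — a bimolecular process whose rate grows with
the square of product concentration and which is the classic driver of the
qPCR plateau — and yields the familiar baseline / exponential /
transitional / plateau shape.  Observed fluorescence adds baseline,
optional linear drift, a copies-to-fluorescence scale, and seeded additive
Gaussian noise:

    F_n = baseline + drift * n + scale * N_n + eps_n
"""

from __future__ import annotations

import dataclasses
from dataclasses import replace

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import AmplificationCurve, PlateData

#: Dilution designs matching the two benchmark datasets.
BIOMARKER_LEVELS = (150000.0, 15000.0, 1500.0, 150.0, 15.0)
REPLICATE_SET_LEVELS = (15000.0, 1500.0, 150.0, 15.0)


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of one simulated reaction.

    Defaults are a realistic SYBR-green-style reaction: efficiency 1.85
    (within the commonly observed 1.65-1.9 range), plateau around 1
    fluorescence unit over a 0.05 baseline, ~1% plateau-level noise, and a
    45-cycle program long enough for a 15-copy input to reach plateau.
    """

    n0: float = 15000.0
    efficiency: float = 1.85
    carrying_capacity: float = 1e9
    hill: float = 2.0
    fluorescence_scale: float = 5e-10
    baseline: float = 0.05
    baseline_drift: float = 0.0
    noise_sd: float = 0.01
    n_cycles: int = 45
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1.0 < self.efficiency <= 2.0:
            raise ParameterError(
                f"efficiency must be in (1, 2], got {self.efficiency}"
            )
        if self.n_cycles < 10:
            raise ParameterError("n_cycles must be >= 10")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.n0 <= 0 or self.carrying_capacity <= 0 or self.hill <= 0:
            raise ParameterError("n0, carrying_capacity and hill must be positive")
        if self.fluorescence_scale <= 0:
            raise ParameterError("fluorescence_scale must be positive")


def _copies_trajectory(cfg: SimulationConfig) -> np.ndarray:
    n = np.empty(cfg.n_cycles)
    current = cfg.n0
    for i in range(cfg.n_cycles):
        depletion = (current / cfg.carrying_capacity) ** cfg.hill
        e_n = 1.0 + (cfg.efficiency - 1.0) * max(0.0, 1.0 - depletion)
        current *= e_n
        n[i] = current
    return n


def simulate_curve(
    config: SimulationConfig,
    well_id: str = "W01",
    gene: str = "G01",
    sample: str = "S01",
    known_concentration: float | None = None,
) -> AmplificationCurve:
    """One seeded amplification curve from the kinetic recurrence.

    ``known_concentration`` defaults to the true input copy number, so the
    simulated well is directly usable in dilution-series indicator runs.
    """
    rng = np.random.default_rng(config.seed)
    cycles = np.arange(1, config.n_cycles + 1)
    copies = _copies_trajectory(config)
    fluor = (
        config.baseline
        + config.baseline_drift * cycles
        + config.fluorescence_scale * copies
    )
    if config.noise_sd > 0:
        fluor = fluor + rng.normal(0.0, config.noise_sd, size=config.n_cycles)
    if known_concentration is None:
        known_concentration = config.n0
    return AmplificationCurve(
        well_id=well_id,
        gene=gene,
        sample=sample,
        known_concentration=known_concentration,
        cycles=cycles,
        fluorescence=fluor,
    )


def simulate_dilution_plate(
    levels,
    replicates: int,
    genes: int,
    base_config: SimulationConfig | None = None,
    efficiency_jitter_sd: float = 0.02,
    baseline_jitter_sd: float = 0.005,
    scale_jitter_sd: float = 0.05,
) -> tuple[PlateData, pd.DataFrame]:
    """A dilution-series plate (genes x levels x replicates) plus ground truth.

    Per-gene amplification parameters (efficiency, baseline, fluorescence
    scale) are jittered deterministically from the base seed, emulating
    amplicon-to-amplicon variation; replicate wells of a gene share the
    gene's parameters and differ only in noise.  Returns the plate and a
    table of true inputs: columns well_id, gene, true_n0, true_e.
    """
    levels = [float(v) for v in levels]
    if any(a <= b for a, b in zip(levels, levels[1:])):
        raise ParameterError("levels must be strictly descending")
    if replicates < 1 or genes < 1:
        raise ParameterError("replicates and genes must be >= 1")
    cfg = base_config if base_config is not None else SimulationConfig()
    rng = np.random.default_rng(cfg.seed)

    curves = []
    truth_rows = []
    for g in range(genes):
        gene_name = f"G{g + 1:02d}"
        e_g = float(np.clip(rng.normal(cfg.efficiency, efficiency_jitter_sd), 1.60, 2.0))
        baseline_g = float(cfg.baseline + rng.normal(0.0, baseline_jitter_sd))
        scale_g = float(cfg.fluorescence_scale * np.exp(rng.normal(0.0, scale_jitter_sd)))
        for li, level in enumerate(levels):
            for rep in range(replicates):
                seed_c = int(rng.integers(0, 2**31 - 1))
                c = replace(
                    cfg,
                    n0=level,
                    efficiency=e_g,
                    baseline=baseline_g,
                    fluorescence_scale=scale_g,
                    seed=seed_c,
                )
                well_id = f"{gene_name}L{li + 1}R{rep + 1}"
                curves.append(
                    simulate_curve(
                        c,
                        well_id=well_id,
                        gene=gene_name,
                        sample=f"std_{level:g}",
                        known_concentration=level,
                    )
                )
                truth_rows.append(
                    {"well_id": well_id, "gene": gene_name, "true_n0": level, "true_e": e_g}
                )
    plate = PlateData(curves=tuple(curves), dataset_label="simulated dilution series")
    return plate, pd.DataFrame(truth_rows)


def simulate_ntc(base_config: SimulationConfig | None = None, n_wells: int = 3) -> PlateData:
    """No-template-control wells: baseline + drift + noise, no amplification."""
    if n_wells < 1:
        raise ParameterError("n_wells must be >= 1")
    cfg = base_config if base_config is not None else SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    cycles = np.arange(1, cfg.n_cycles + 1)
    curves = []
    for w in range(n_wells):
        fluor = cfg.baseline + cfg.baseline_drift * cycles.astype(float)
        if cfg.noise_sd > 0:
            fluor = fluor + rng.normal(0.0, cfg.noise_sd, size=cfg.n_cycles)
        curves.append(
            AmplificationCurve(
                well_id=f"NTC{w + 1:02d}",
                gene="NTC",
                sample="NTC",
                known_concentration=None,
                cycles=cycles,
                fluorescence=fluor,
            )
        )
    return PlateData(curves=tuple(curves), dataset_label="simulated NTC")
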