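"""Synthetic plate recordings with known ground truth.

Emulates multi-day 96-well bioluminescence assays: each well is the mean of
a population of stochastic single-cell oscillators sampled on the plate
reader's ~40-min cadence, distorted by a well-specific affine transform
(luminescence scale and baseline offset vary between wells) and additive
Gaussian measurement noise.  Ground truth (parameters, seeds, distortions)
is returned as a manifest so fitting stages can be validated end to end.

The reference "untreated culture" condition -- an oscillator with a 24.0-h
free-running period that entrains to symmetric LD cycles between T = 20 h
and T = 30 h, resets strongly (type-0 phase response to 12-h light pulses),
and shows population-level amplitude damping in darkness with sustained
single-cell rhythms -- is :data:`CONTROL_PARAMS`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .light import LightProtocol, concat, constant, ld_cycle
from .model import ClockParameters, burn_in_initial_state, simulate_population

__all__ = [
    "CONTROL_PARAMS",
    "FIG_PROTOCOL",
    "WellSpec",
    "PlateDesign",
    "generate_plate",
    "fig2a_fixture",
    "compound_series_fixture",
]

#: Reference untreated-culture parameter set (equal degradation rates).
CONTROL_PARAMS = ClockParameters.with_equal_degradation(A=3.5, d=0.1798, i=0.03, sigma=0.01)


def _fig_protocol() -> LightProtocol:
    """6 days darkness, three 12:12 LD cycles, 3 days constant light (288 h)."""
    return concat(constant(0, 144), concat(ld_cycle(12, 12, 3), constant(1, 72)))


FIG_PROTOCOL = _fig_protocol()


@dataclass(frozen=True)
class WellSpec:
    well_id: str
    treatment: str
    concentration: float
    params: ClockParameters


@dataclass
class PlateDesign:
    wells: list[WellSpec]
    protocol: LightProtocol
    duration_h: float
    sampling_interval_min: float = 40.0
    measurement_noise_rel: float = 0.05  # sd as a fraction of the trace sd
    scale_range: tuple[float, float] = (0.5, 2.0)
    offset_range: tuple[float, float] = (0.0, 1.0)
    n_cells: int = 1000
    dt: float = 0.02

    def __post_init__(self) -> None:
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise ValueError("well ids must be unique")
        if self.duration_h > self.protocol.total_duration + 1e-9:
            raise ValueError("duration exceeds the protocol span")

    @property
    def sample_times(self) -> np.ndarray:
        step = self.sampling_interval_min / 60.0
        n = int(np.floor(self.duration_h / step))
        return np.arange(n + 1) * step


def generate_plate(
    design: PlateDesign, rng_seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate every well of a plate design.

    Returns ``(plate, meta, manifest)``: a wide table (time_h + one column
    per well), the well metadata table, and a JSON-serializable manifest of
    all ground truths.  Regenerating from the same design and seed is
    bit-exact.
    """
    times = design.sample_times
    data: dict[str, np.ndarray] = {"time_h": times}
    manifest: dict = {"seed": rng_seed, "protocol": design.protocol.to_dict(), "wells": {}}
    burn_cache: dict[ClockParameters, tuple] = {}
    for w_idx, well in enumerate(design.wells):
        ss = np.random.SeedSequence(entropy=rng_seed, spawn_key=(w_idx,))
        sim_seed = int(ss.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(ss.spawn(1)[0])
        if well.params not in burn_cache:
            burn_cache[well.params] = burn_in_initial_state(well.params, dt=design.dt)
        x0 = burn_cache[well.params]
        pop = simulate_population(
            well.params,
            design.protocol,
            n=design.n_cells,
            x0=x0,
            t_end=design.protocol.total_duration,
            dt=design.dt,
            rng_seed=sim_seed,
        )
        values = np.interp(times, pop.times, pop.mean_luminescence)
        scale = rng.uniform(*design.scale_range)
        offset = rng.uniform(*design.offset_range)
        distorted = scale * values + offset
        noise_sd = design.measurement_noise_rel * np.std(distorted, ddof=1)
        distorted = distorted + rng.normal(0.0, noise_sd, len(distorted)) if noise_sd > 0 else distorted
        data[well.well_id] = distorted
        manifest["wells"][well.well_id] = {
            "treatment": well.treatment,
            "concentration": well.concentration,
            "params": well.params.to_dict(),
            "sim_seed": sim_seed,
            "scale": scale,
            "offset": offset,
            "noise_sd": noise_sd,
        }
    plate = pd.DataFrame(data)
    meta = pd.DataFrame(
        {
            "well": [w.well_id for w in design.wells],
            "treatment": [w.treatment for w in design.wells],
            "concentration": [w.concentration for w in design.wells],
        }
    )
    return plate, meta, manifest


def fig2a_fixture(
    params: ClockParameters = CONTROL_PARAMS,
    rng_seed: int = 0,
    n_wells: int = 16,
    n_cells: int = 1000,
    measurement_noise_rel: float = 0.05,
    dt: float = 0.02,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """The canonical fitting plate: 288 h of DD, 12:12 LD, then LL.

    Sixteen replicate wells of one condition under the 6-day-darkness /
    three-LD-cycle / 3-day-light schedule used for parameter estimation.
    """
    wells = [
        WellSpec(f"w{k:02d}", "control", 0.0, params) for k in range(n_wells)
    ]
    design = PlateDesign(
        wells,
        FIG_PROTOCOL,
        duration_h=FIG_PROTOCOL.total_duration,
        n_cells=n_cells,
        measurement_noise_rel=measurement_noise_rel,
        dt=dt,
    )
    return generate_plate(design, rng_seed)


def compound_series_fixture(
    control_params: ClockParameters,
    deltas: dict[str, float],
    n_concentrations: int = 3,
    treatment: str = "compound",
    rng_seed: int = 0,
    wells_per_group: int = 4,
    protocol: LightProtocol | None = None,
    n_cells: int = 500,
    measurement_noise_rel: float = 0.05,
    dt: float = 0.02,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """A control group plus a concentration series of parameter perturbations.

    ``deltas`` maps parameter names to the per-concentration-step additive
    change; concentration ``c`` (1-based) applies ``c * delta``.  Emulates
    dose-response plate sets: e.g. a progressive reduction of ``A`` mimics a
    transcription-activation inhibitor, a progressive increase of ``sigma``
    a desynchronizing treatment.
    """
    if not deltas:
        raise ValueError("need at least one parameter delta")
    if protocol is None:
        protocol = concat(ld_cycle(12, 12, 5), constant(0, 120))
    wells: list[WellSpec] = []
    for k in range(wells_per_group):
        wells.append(WellSpec(f"ctrl_{k:02d}", "control", 0.0, control_params))
    for c in range(1, n_concentrations + 1):
        p = control_params
        for name, dv in deltas.items():
            p = p.replace(**{name: getattr(p, name) + c * dv})
        for k in range(wells_per_group):
            wells.append(WellSpec(f"{treatment}_c{c}_{k:02d}", treatment, float(c), p))
    design = PlateDesign(
        wells,
        protocol,
        duration_h=protocol.total_duration,
        n_cells=n_cells,
        measurement_noise_rel=measurement_noise_rel,
        dt=dt,
    )
    return generate_plate(design, rng_seed)


def write_fixture(plate: pd.DataFrame, meta: pd.DataFrame, manifest: dict, stem) -> None:
    """Write plate CSV, metadata CSV and manifest JSON under a path stem."""
    plate.to_csv(f"{stem}.csv", index=False)
    meta.to_csv(f"{stem}_meta.csv", index=False)
    with open(f"{stem}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=float)
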