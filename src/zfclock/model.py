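"""Core clock model: parameters, states, and single-cell/population simulation.

The oscillator is a three-variable transcription--translation negative
feedback loop of the protein-sequestration (Kim--Forger) type, written in
nondimensionalized form with all production rates rescaled to 1::

    dM/dt = f(R, A) - d_M * M + i * I(t) + sigma * xi_M
    dP/dt = M       - d_P * P            + sigma * xi_P
    dR/dt = P       - d_R * R            + sigma * xi_R

``M`` is clock-gene mRNA, ``P`` cytoplasmic protein, ``R`` the nuclear
repressor.  ``f`` is the fraction of free activator (E-box activation):
the repressor stoichiometrically sequesters the activator ``A`` into an
inactive complex with dissociation constant ``K``; for ``K -> 0`` the
activation reduces to the piecewise-linear form ``max(0, 1 - R/A)``.
``I(t)`` is a binary light input acting through light-driven (D-box) clock
gene induction with sensitivity ``i``; ``xi_*`` are independent white
noises of intensity ``sigma`` modelling intrinsic single-cell fluctuations.

The bioluminescence reporter reads out E-box activation, so a cell's
luminescence is ``L_j = f(R, A)`` and a culture well is the arithmetic mean
of ``n`` independent cells (30,000 per well experimentally; 1,000 suffices
during fitting).

State variables are *not* clamped at zero: additive noise can push them
transiently negative, in which case the piecewise activation is evaluated
as written (values above 1 are then possible).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from . import _kernels
from .light import LightProtocol, ld_cycle

__all__ = [
    "ClockParameters",
    "ClockState",
    "Trajectory",
    "PopulationResult",
    "IntegrationError",
    "sequestration_activation",
    "piecewise_activation",
    "drift",
    "simulate_deterministic",
    "simulate_single_cell",
    "simulate_population",
    "burn_in_initial_state",
    "DEFAULT_DT",
    "DEFAULT_RECORD_DT",
]

DEFAULT_DT = 0.01  # integration step, hours
DEFAULT_RECORD_DT = 0.1  # output grid, hours

PARAM_NAMES = ("A", "d_M", "d_P", "d_R", "i", "sigma")


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""


@dataclass(frozen=True)
class ClockParameters:
    """The six free parameters of one cell's oscillator (plus optional K).

    A      activator concentration (dimensionless, > 0)
    d_M, d_P, d_R   degradation rates (1/h, > 0)
    i      light sensitivity (dimensionless, >= 0)
    sigma  noise intensity (dimensionless, >= 0)
    K      dissociation constant of the repressor-activator complex; ``None``
           selects the K -> 0 piecewise activation.
    """

    A: float
    d_M: float
    d_P: float
    d_R: float
    i: float = 0.0
    sigma: float = 0.0
    K: float | None = None

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ValueError(f"A must be > 0, got {self.A}")
        for name in ("d_M", "d_P", "d_R"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.i < 0:
            raise ValueError(f"i must be >= 0, got {self.i}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.K is not None and self.K < 0:
            raise ValueError(f"K must be >= 0, got {self.K}")

    @classmethod
    def with_equal_degradation(
        cls, A: float, d: float, i: float = 0.0, sigma: float = 0.0, K: float | None = None
    ) -> "ClockParameters":
        """All three degradation rates set to a common value ``d``."""
        return cls(A=A, d_M=d, d_P=d, d_R=d, i=i, sigma=sigma, K=K)

    @property
    def equal_degradation(self) -> bool:
        return self.d_M == self.d_P == self.d_R

    def replace(self, **kw) -> "ClockParameters":
        return replace(self, **kw)

    def as_array(self) -> np.ndarray:
        """The six free parameters in canonical order (A, d_M, d_P, d_R, i, sigma)."""
        return np.array([self.A, self.d_M, self.d_P, self.d_R, self.i, self.sigma])

    def to_dict(self) -> dict:
        d = {n: getattr(self, n) for n in PARAM_NAMES}
        if self.K is not None:
            d["K"] = self.K
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ClockParameters":
        return cls(**{k: v for k, v in d.items() if k in PARAM_NAMES + ("K",)})

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


class ClockState(NamedTuple):
    """Instantaneous model state (all dimensionless)."""

    M: float
    P: float
    R: float


@dataclass
class Trajectory:
    """A single simulated cell: states and luminescence on a regular time grid."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 3): columns M, P, R
    luminescence: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.states) == len(self.luminescence)):
            raise ValueError("times, states and luminescence must have equal length")

    @property
    def final_state(self) -> ClockState:
        return ClockState(*self.states[-1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_h": self.times,
                "M": self.states[:, 0],
                "P": self.states[:, 1],
                "R": self.states[:, 2],
                "luminescence": self.luminescence,
            }
        )


@dataclass
class PopulationResult:
    """Mean luminescence of ``n`` independent cells (a simulated culture well)."""

    times: np.ndarray
    mean_luminescence: np.ndarray
    n: int
    seed: int | None = None
    cells: np.ndarray | None = field(default=None, repr=False)  # (record_cells, n_t)


# ---------------------------------------------------------------------------
# activation functions and drift


def sequestration_activation(R: float, A: float, K: float):
    """Free-activator fraction under 1:1 stoichiometric repressor sequestration.

    ``f = (A - R - K + sqrt((A - R - K)^2 + 4AK)) / (2A)``; continuous in all
    arguments and bounded in (0, 1] for R >= 0, K > 0.
    """
    if np.any(np.asarray(A) <= 0):
        raise ValueError("A must be > 0")
    if np.any(np.asarray(K) < 0):
        raise ValueError("K must be >= 0")
    b = A - R - K
    return (b + np.sqrt(b * b + 4.0 * A * K)) / (2.0 * A)


def piecewise_activation(R: float, A: float):
    """K -> 0 limit of the sequestration function: ``max(0, 1 - R/A)``."""
    if np.any(np.asarray(A) <= 0):
        raise ValueError("A must be > 0")
    return np.maximum(0.0, 1.0 - np.asarray(R) / A)


def _f(R: float, params: ClockParameters) -> float:
    if params.K is None:
        return float(piecewise_activation(R, params.A))
    return float(sequestration_activation(R, params.A, params.K))


def drift(state: ClockState, params: ClockParameters, light: int) -> tuple[float, float, float]:
    """Deterministic rates (dM/dt, dP/dt, dR/dt); noise excluded."""
    if light not in (0, 1):
        raise ValueError(f"light must be 0 or 1, got {light}")
    M, P, R = state
    dM = _f(R, params) - params.d_M * M + params.i * light
    dP = M - params.d_P * P
    dR = P - params.d_R * R
    return (dM, dP, dR)


# ---------------------------------------------------------------------------
# simulation


def _grid(t_end: float, dt: float, record_dt: float) -> tuple[int, int]:
    stride = int(round(record_dt / dt))
    if stride < 1 or abs(stride * dt - record_dt) > 1e-9:
        raise ValueError(f"record_dt {record_dt} must be a multiple of dt {dt}")
    n_steps = int(round(t_end / dt))
    n_steps -= n_steps % stride
    if n_steps < stride:
        raise ValueError("t_end too short for the requested grids")
    return n_steps, stride


def _kernel_args(params: ClockParameters):
    use_K = params.K is not None
    K = params.K if use_K else 0.0
    return params.A, params.d_M, params.d_P, params.d_R, params.i, K, use_K


def simulate_deterministic(
    params: ClockParameters,
    protocol: LightProtocol,
    x0: ClockState = ClockState(0.0, 0.0, 0.0),
    t_end: float | None = None,
    dt: float = DEFAULT_DT,
    record_dt: float = DEFAULT_RECORD_DT,
) -> Trajectory:
    """Integrate the noise-free model (sigma forced to 0) with fixed-step RK4."""
    if t_end is None:
        t_end = protocol.total_duration
    n_steps, stride = _grid(t_end, dt, record_dt)
    A, dM, dP, dR, isens, K, use_K = _kernel_args(params)
    light = protocol.values_on_grid(n_steps, dt)
    states, lum, status = _kernels.integrate_deterministic(
        float(x0[0]), float(x0[1]), float(x0[2]), A, dM, dP, dR, isens, K, use_K, light, dt, stride
    )
    if status >= 0:
        raise IntegrationError(f"non-finite state at step {status} (t={status * dt:.3f} h)")
    times = np.arange(states.shape[0]) * dt * stride
    return Trajectory(times, states, lum)


def simulate_single_cell(
    params: ClockParameters,
    protocol: LightProtocol,
    x0: ClockState = ClockState(0.0, 0.0, 0.0),
    t_end: float | None = None,
    dt: float = DEFAULT_DT,
    rng_seed: int = 0,
    record_dt: float = DEFAULT_RECORD_DT,
    preroll_h: float = 0.0,
) -> Trajectory:
    """One Euler--Maruyama realization of the stochastic model.

    ``preroll_h`` hours of unrecorded dark simulation precede t = 0 (used to
    de-correlate phases when a desynchronized start is wanted).  Identical
    seed and inputs give a bit-identical trajectory.
    """
    if t_end is None:
        t_end = protocol.total_duration
    n_steps, stride = _grid(t_end, dt, record_dt)
    A, dM, dP, dR, isens, K, use_K = _kernel_args(params)
    light = protocol.values_on_grid(n_steps, dt)
    seed = int(np.random.SeedSequence(rng_seed).generate_state(1)[0])
    states, lum, status = _kernels.integrate_cell(
        float(x0[0]),
        float(x0[1]),
        float(x0[2]),
        A,
        dM,
        dP,
        dR,
        isens,
        params.sigma,
        K,
        use_K,
        light,
        dt,
        stride,
        seed,
        int(round(preroll_h / dt)),
    )
    if status >= 0:
        raise IntegrationError(f"non-finite state at step {status} (t={status * dt:.3f} h)")
    times = np.arange(states.shape[0]) * dt * stride
    return Trajectory(times, states, lum)


def _cell_seeds(rng_seed: int, n: int) -> np.ndarray:
    # Prefix-stable: cell j's seed does not depend on n.
    return np.random.SeedSequence(rng_seed).generate_state(n).astype(np.int64)


def simulate_population(
    params: ClockParameters,
    protocol: LightProtocol,
    n: int,
    x0: ClockState = ClockState(0.0, 0.0, 0.0),
    t_end: float | None = None,
    dt: float = DEFAULT_DT,
    rng_seed: int = 0,
    record_cells: int = 0,
    record_dt: float = DEFAULT_RECORD_DT,
    preroll_h: float = 0.0,
) -> PopulationResult:
    """Mean luminescence over ``n`` independent stochastic cells.

    All cells start from the same initial state; diversity arises from the
    noise (optionally seeded by a dark ``preroll_h``).  The first
    ``record_cells`` single-cell luminescence traces are retained.
    """
    if n < 1:
        raise ValueError(f"need n >= 1 cells, got {n}")
    if t_end is None:
        t_end = protocol.total_duration
    n_steps, stride = _grid(t_end, dt, record_dt)
    A, dM, dP, dR, isens, K, use_K = _kernel_args(params)
    light = protocol.values_on_grid(n_steps, dt)
    seeds = _cell_seeds(rng_seed, n)
    mean_lum, rec, status = _kernels.integrate_population(
        float(x0[0]),
        float(x0[1]),
        float(x0[2]),
        A,
        dM,
        dP,
        dR,
        isens,
        params.sigma,
        K,
        use_K,
        light,
        dt,
        stride,
        seeds,
        int(record_cells),
        int(round(preroll_h / dt)),
    )
    if status >= 0:
        raise IntegrationError(f"non-finite state at step {status} (t={status * dt:.3f} h)")
    times = np.arange(mean_lum.shape[0]) * dt * stride
    return PopulationResult(
        times, mean_lum, n, seed=rng_seed, cells=rec if record_cells else None
    )


def burn_in_initial_state(
    params: ClockParameters,
    days: float = 10.0,
    light_h: float = 12.0,
    dark_h: float = 12.0,
    dt: float = DEFAULT_DT,
) -> ClockState:
    """Deterministic state after ``days`` of LD cycling, used as initial condition.

    The cycle is dark-first, so the returned state sits exactly at a
    light-to-dark transition -- matching recordings that start at the
    beginning of the dark phase.
    """
    period = light_h + dark_h
    n_cycles = int(np.ceil(days * 24.0 / period))
    proto = ld_cycle(light_h, dark_h, n_cycles)
    traj = simulate_deterministic(params, proto, t_end=n_cycles * period, dt=dt, record_dt=dt)
    return traj.final_state
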