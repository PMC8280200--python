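"""Entrainment analyses on fitted parameter sets.

Phase response curve (PRC): a single light pulse is delivered at onset
phases spanning one circadian cycle of the free-running (constant-darkness)
deterministic oscillator; the shift is the displacement of a late
post-pulse peak relative to an unpulsed control, wrapped to (-12, 12] h.
The phase transition curve (new phase vs. old phase) classifies resetting
strength: average slope ~1 (the pulse barely moves the clock) is type 1,
average slope ~0 (the pulse sets the clock to a fixed phase regardless of
when it arrives) is type 0.

Phase angle of entrainment: for a symmetric LD cycle of period T, the
interval from lights-on to the next population-mean peak, normalized by
T/24 and negated -- negative values mean the peak trails the light onset.

Phase histograms quantify single-cell synchrony: each retained cell
contributes its luminescence peak positions (mod 24 h) within an analysis
window; a sharply peaked histogram means a synchronized population, a flat
one means noise has dispersed the phases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fitting import ParameterPopulation
from .light import concat, constant, ld_cycle, with_pulse
from .metrics import circular_variance, detect_peaks, smooth, wrap_phase
from .model import (
    ClockParameters,
    PopulationResult,
    burn_in_initial_state,
    simulate_deterministic,
    simulate_population,
)
from .trace import Trace

__all__ = [
    "PhaseResponseCurve",
    "PhaseAngleCurve",
    "PhaseHistogram",
    "phase_response_curve",
    "prc_type",
    "phase_angle_curve",
    "phase_histogram",
    "mean_activation_dd",
    "pca_parameter_populations",
    "PCAResult",
]

log = logging.getLogger(__name__)


@dataclass
class PhaseResponseCurve:
    pulse_phases: np.ndarray  # circadian time of pulse onset, [0, 24)
    phase_shifts: np.ndarray  # (-12, 12]
    new_phases: np.ndarray  # [0, 24)

    def __post_init__(self) -> None:
        if not (len(self.pulse_phases) == len(self.phase_shifts) == len(self.new_phases)):
            raise ValueError("PRC arrays must be aligned")


@dataclass
class PhaseAngleCurve:
    periods_T: np.ndarray
    phase_angles: np.ndarray  # NaN where the model failed to entrain


@dataclass
class PhaseHistogram:
    bin_edges: np.ndarray  # over [0, 24]
    densities: np.ndarray  # integrate to 1
    window: tuple[float, float]
    phases: np.ndarray  # raw peak phases contributing to the histogram


def phase_response_curve(
    params: ClockParameters,
    pulse_h: float = 12.0,
    n_phases: int = 12,
    measure_peak: int = 4,
    dt: float = 0.02,
) -> PhaseResponseCurve:
    """Simulated PRC of the deterministic model to single light pulses.

    The oscillator is entrained by 12:12 LD, released into darkness, and a
    pulse of ``pulse_h`` hours is applied at ``n_phases`` onset times
    spanning one free-running cycle (starting one full cycle into
    darkness).  Shifts are measured on the ``measure_peak``-th peak after
    pulse end, control minus pulsed, wrapped to (-12, 12].
    """
    x0 = burn_in_initial_state(params, dt=dt)
    t_end = 24.0 * 12
    dark = constant(0, t_end)
    ctrl = simulate_deterministic(params, dark, x0=x0, dt=dt)
    ctrl_tr = Trace(ctrl.times, ctrl.luminescence)
    ctrl_peaks, _ = detect_peaks(ctrl_tr)
    if len(ctrl_peaks) < measure_peak + 3:
        raise ValueError("parameter set is not oscillatory in constant darkness")

    onsets = 24.0 + np.arange(n_phases) * 24.0 / n_phases
    pulse_phases = []
    shifts = []
    new_phases = []
    for onset in onsets:
        pulsed = simulate_deterministic(
            params, with_pulse(dark, onset, pulse_h), x0=x0, dt=dt
        )
        p_peaks, _ = detect_peaks(Trace(pulsed.times, pulsed.luminescence))
        after_p = p_peaks[p_peaks > onset + pulse_h]
        after_c = ctrl_peaks[ctrl_peaks > onset + pulse_h]
        if len(after_p) < measure_peak or len(after_c) < measure_peak:
            raise ValueError(f"too few post-pulse peaks for onset {onset} h")
        shift = wrap_phase(after_c[measure_peak - 1] - after_p[measure_peak - 1])
        ref = ctrl_peaks[ctrl_peaks <= onset]
        old = (onset - ref[-1]) % 24.0 if len(ref) else onset % 24.0
        pulse_phases.append(old)
        shifts.append(shift)
        new_phases.append((old + shift) % 24.0)
    order = np.argsort(pulse_phases)
    return PhaseResponseCurve(
        np.asarray(pulse_phases)[order],
        np.asarray(shifts)[order],
        np.asarray(new_phases)[order],
    )


def prc_type(prc: PhaseResponseCurve) -> int:
    """0 or 1: winding number of the phase transition curve over one cycle.

    Computed as the closed-loop sum of minimally wrapped steps of the new
    phase as the old phase advances through 24 h; the sum is a multiple of
    24 h and its quotient is the average transition-curve slope.  Steps
    close to the wrapping ambiguity (>= 10.8 h) make the winding
    undecidable and raise an error.
    """
    if len(prc.pulse_phases) < 8:
        raise ValueError("need at least 8 phase samples to classify a PRC")
    new = prc.new_phases
    steps = wrap_phase(np.diff(np.concatenate([new, new[:1]])))
    if np.any(np.abs(steps) >= 0.45 * 24.0):
        raise ValueError(
            "phase transition curve has ambiguous jumps; sample more pulse phases "
            f"(max |step| = {np.max(np.abs(steps)):.2f} h)"
        )
    winding = int(np.round(np.sum(steps) / 24.0))
    if winding not in (0, 1):
        raise ValueError(f"transition-curve winding {winding} is neither 0 nor 1")
    return winding


def phase_angle_curve(
    params: ClockParameters,
    T_values,
    n_cells: int = 1000,
    n_cycles: int = 8,
    steady_cycles: int = 5,
    rng_seed: int = 0,
    dt: float = 0.02,
    entrain_tol: float = 0.05,
) -> PhaseAngleCurve:
    """Phase angle of entrainment versus LD cycle period T.

    For each T a symmetric (T/2 : T/2, dark-first) cycle drives the
    population for ``n_cycles``; entrainment is accepted when the
    steady-state inter-peak interval matches T within ``entrain_tol``
    (fractional).  The angle is -(t_peak - t_lights_on) * 24 / T for the
    first population-mean peak at or after a steady-state lights-on event;
    non-entrained periods yield NaN.
    """
    T_values = np.asarray(T_values, dtype=float)
    x0 = burn_in_initial_state(params, dt=dt)
    angles = np.full(len(T_values), np.nan)
    for k, T in enumerate(T_values):
        proto = ld_cycle(T / 2, T / 2, n_cycles)
        pop = simulate_population(
            params, proto, n=n_cells, x0=x0, dt=dt, rng_seed=rng_seed
        )
        tr = smooth(Trace(pop.times, pop.mean_luminescence), 2.0)
        peaks, _ = detect_peaks(tr, min_distance_h=T / 2)
        steady = peaks[peaks >= (steady_cycles - 1) * T]
        if len(steady) < 2:
            log.info("T=%g h: too few steady-state peaks; not entrained", T)
            continue
        if abs(np.mean(np.diff(steady)) - T) > entrain_tol * T:
            log.info("T=%g h: period %.2f h does not match; not entrained", T, np.mean(np.diff(steady)))
            continue
        t_on = steady_cycles * T + T / 2  # dark-first: lights-on at T/2 into the cycle
        after = peaks[peaks >= t_on]
        if len(after) == 0:
            continue
        angles[k] = -(after[0] - t_on) * 24.0 / T
    return PhaseAngleCurve(T_values, angles)


def phase_histogram(
    result: PopulationResult,
    window: tuple[float, float],
    n_bins: int = 24,
    smooth_h: float = 2.0,
    min_cells: int = 50,
) -> PhaseHistogram:
    """Distribution of single-cell peak phases (mod 24 h) within a window."""
    if result.cells is None or len(result.cells) < min_cells:
        raise ValueError(f"need >= {min_cells} retained single-cell trajectories")
    lo, hi = window
    if lo < result.times[0] or hi > result.times[-1] + 1e-9:
        raise ValueError(f"window {window} outside the simulated span")
    phases = []
    for cell in result.cells:
        tr = smooth(Trace(result.times, cell), smooth_h).window(lo, hi)
        if len(tr) < 3:
            continue
        times, _ = detect_peaks(tr, min_distance_h=12.0)
        phases.extend(times % 24.0)
    phases = np.asarray(phases)
    edges = np.linspace(0.0, 24.0, n_bins + 1)
    dens, _ = np.histogram(phases, bins=edges, density=len(phases) > 0)
    return PhaseHistogram(edges, dens, window, phases)


def synchrony(hist: PhaseHistogram) -> float:
    """Circular variance of the contributing phases (0 = perfect synchrony)."""
    return circular_variance(hist.phases)


def mean_activation_dd(
    params: ClockParameters,
    n_cells: int = 1000,
    dd_span_h: float = 120.0,
    entrain_days: int = 5,
    rng_seed: int = 0,
    dt: float = 0.02,
) -> float:
    """Mean transcription activation (population-mean luminescence) in darkness.

    The population is entrained by 12:12 LD, released into constant
    darkness, and the un-normalized population mean is averaged over the DD
    span -- the readout behind compound-induced changes in baseline E-box
    activation.
    """
    proto = concat(ld_cycle(12, 12, entrain_days), constant(0, dd_span_h))
    x0 = burn_in_initial_state(params, dt=dt)
    pop = simulate_population(params, proto, n=n_cells, x0=x0, dt=dt, rng_seed=rng_seed)
    dd = Trace(pop.times, pop.mean_luminescence).window(entrain_days * 24.0, np.inf)
    return float(np.mean(dd.values))


@dataclass
class PCAResult:
    projections: list[np.ndarray]  # one (n_members, n_components) array per population
    explained_variance_ratio: np.ndarray
    medians: np.ndarray  # (n_populations, n_components), median in PC space
    mads: np.ndarray  # (n_populations, n_components), median absolute deviation
    components: np.ndarray
    labels: list[str | None]


def pca_parameter_populations(populations: list[ParameterPopulation]) -> PCAResult:
    """Project parameter-set ensembles onto principal components.

    Members of all populations are pooled, each of the six parameters is
    z-standardized across the pool, and PCA is fit on the pooled matrix.
    Per-population spread is summarized as median +/- MAD in PC space.
    """
    from sklearn.decomposition import PCA

    if len(populations) < 2:
        raise ValueError("need at least two populations to compare")
    mats = [p.as_matrix() for p in populations]
    pooled = np.vstack(mats)
    mu = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    degenerate = sd == 0
    if np.any(degenerate):
        log.warning(
            "%d parameter(s) constant across the pool; dropped from the projection",
            int(degenerate.sum()),
        )
        sd = np.where(degenerate, 1.0, sd)
    std = (pooled - mu) / sd
    rank = np.linalg.matrix_rank(std - std.mean(axis=0))
    n_comp = int(min(rank, std.shape[1], std.shape[0]))
    pca = PCA(n_components=n_comp)
    pca.fit(std)
    projections = []
    medians = []
    mads = []
    for m in mats:
        proj = pca.transform((m - mu) / sd)
        projections.append(proj)
        med = np.median(proj, axis=0)
        medians.append(med)
        mads.append(np.median(np.abs(proj - med), axis=0))
    return PCAResult(
        projections,
        pca.explained_variance_ratio_,
        np.array(medians),
        np.array(mads),
        pca.components_,
        [p.treatment for p in populations],
    )
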