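"""Trace normalization, goodness of fit, damped-sine fitting, and rhythm metrics.

Normalizations
--------------
Untreated recordings are normalized per trace to Z-scores,
``z(x) = (x - mean) / sd``.  Compound-treated recordings keep their group
mean/variance relationship to control through the adjusted Z-score::

    z_d(x) = (x - mean)/sd * (S_d/S_c) + (mean_d - mean_c)/S_c

with (mean_d, S_d) the compound group's mean-of-means and mean-of-SDs and
(mean_c, S_c) the control group's.  For the control group the expression
reduces exactly to the plain Z-score.  Model output is centered and scaled
by the *control-parameter simulation's* statistics so that simulated and
measured traces live on the same scale.

Fit quality is the model efficiency coefficient
``E_f = 1 - SS_res / SS_data`` in (-inf, 1]; 1 is a perfect fit and values
<= 0 mean the data mean predicts better than the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .trace import GroupStats, Trace, TraceStats

__all__ = [
    "zscore",
    "adjusted_zscore",
    "model_zscore",
    "model_efficiency",
    "DampedSineFit",
    "damped_sine",
    "fit_damped_sine",
    "detect_peaks",
    "estimate_period",
    "sustained_oscillation_check",
    "smooth",
    "circular_variance",
    "wrap_phase",
]


def wrap_phase(x, period: float = 24.0):
    """Wrap a phase difference onto (-period/2, period/2]."""
    y = np.asarray(x, dtype=float) % period
    y = np.where(y > period / 2, y - period, y)
    return float(y) if np.isscalar(x) or np.ndim(x) == 0 else y


# ---------------------------------------------------------------------------
# normalization


def zscore(trace: Trace) -> Trace:
    s = trace.stats
    if s.is_constant:
        raise ValueError("undefined normalization: constant trace (sd = 0)")
    return trace.with_values((trace.values - s.mean) / s.sd)


def adjusted_zscore(trace: Trace, compound: GroupStats, control: GroupStats) -> Trace:
    s = trace.stats
    if s.is_constant:
        raise ValueError("undefined normalization: constant trace (sd = 0)")
    if control.mean_of_sds <= 0:
        raise ValueError("control group mean-of-SDs must be > 0")
    z = (trace.values - s.mean) / s.sd
    scaled = z * (compound.mean_of_sds / control.mean_of_sds)
    return trace.with_values(
        scaled + (compound.mean_of_means - control.mean_of_means) / control.mean_of_sds
    )


def model_zscore(model_trace: Trace, control_sim: TraceStats) -> Trace:
    """Center/scale model output by the control-parameter simulation's own stats."""
    if control_sim.sd <= 0:
        raise ValueError("control simulation sd must be > 0")
    return model_trace.with_values((model_trace.values - control_sim.mean) / control_sim.sd)


def model_efficiency(data: Trace | np.ndarray, model: Trace | np.ndarray) -> float:
    """E_f = 1 - sum((x - xhat)^2) / sum((x - xbar)^2)."""
    x = data.values if isinstance(data, Trace) else np.asarray(data, dtype=float)
    xh = model.values if isinstance(model, Trace) else np.asarray(model, dtype=float)
    if x.shape != xh.shape:
        raise ValueError(f"length mismatch: data {x.shape} vs model {xh.shape}")
    ss_data = float(np.sum((x - x.mean()) ** 2))
    if ss_data == 0.0:
        raise ValueError("data trace is constant; E_f undefined")
    return 1.0 - float(np.sum((x - xh) ** 2)) / ss_data


# ---------------------------------------------------------------------------
# damped sine


def damped_sine(t, amplitude, damping_ratio, period, phase):
    """f_ds(t) = A * exp(-d t) * sin(2 pi t / T + theta)."""
    return amplitude * np.exp(-damping_ratio * t) * np.sin(2.0 * np.pi * t / period + phase)


@dataclass(frozen=True)
class DampedSineFit:
    amplitude: float
    damping_ratio: float  # 1/h
    period: float  # h
    phase: float  # rad
    residual: float  # sum of squares

    def __call__(self, t):
        return damped_sine(t, self.amplitude, self.damping_ratio, self.period, self.phase)


def _envelope_damping_guess(t: np.ndarray, x: np.ndarray) -> float:
    """Initial damping from log-envelope regression on detected peaks."""
    idx, props = find_peaks(np.abs(x), prominence=0.05 * (np.max(np.abs(x)) + 1e-300))
    if len(idx) < 3:
        return 0.01
    h = np.abs(x[idx])
    keep = h > 0
    if keep.sum() < 3:
        return 0.01
    slope = np.polyfit(t[idx][keep], np.log(h[keep]), 1)[0]
    return float(np.clip(-slope, 0.0, 0.5))


def fit_damped_sine(
    trace: Trace,
    period_starts: tuple[float, ...] = (20.0, 24.0, 28.0),
    phase_starts: tuple[float, ...] = (0.0, np.pi / 2, np.pi, 3 * np.pi / 2),
) -> DampedSineFit:
    """Least-squares damped-sine fit with multi-start initialization.

    The trace is mean-centered before fitting (the damped sine carries no
    offset term).  Starts span a grid of phases and circadian-range periods;
    the damping initial guess comes from log-envelope regression on peaks.
    The lowest-residual converged start wins.
    """
    t = trace.times - trace.times[0]
    x = trace.values - np.mean(trace.values)
    if t[-1] < 2 * min(period_starts):
        raise ValueError("trace must span at least two expected periods")
    a0 = float(np.sqrt(2.0) * np.std(x))
    if a0 == 0:
        raise ValueError("constant trace")
    d0 = _envelope_damping_guess(t, x)
    best: DampedSineFit | None = None
    bounds = ([0.0, -0.1, 4.0, -2 * np.pi], [np.inf, 1.0, 100.0, 4 * np.pi])
    for T0 in period_starts:
        for th0 in phase_starts:
            try:
                popt, _ = curve_fit(
                    damped_sine, t, x, p0=[a0, d0, T0, th0], bounds=bounds, maxfev=4000
                )
            except RuntimeError:
                continue
            res = float(np.sum((damped_sine(t, *popt) - x) ** 2))
            if best is None or res < best.residual:
                amp, d, T, th = popt
                best = DampedSineFit(float(amp), float(d), float(T), float(th % (2 * np.pi)), res)
    if best is None:
        raise RuntimeError("damped-sine fit failed to converge from every start")
    return best


# ---------------------------------------------------------------------------
# peaks, period, oscillation screen


def smooth(trace: Trace, window_h: float) -> Trace:
    """Centered moving average over ``window_h`` hours (odd sample count)."""
    if window_h <= 0 or len(trace) < 3:
        return trace
    dt = float(np.median(np.diff(trace.times)))
    w = max(1, int(round(window_h / dt)))
    if w % 2 == 0:
        w += 1
    if w <= 1:
        return trace
    pad = w // 2
    padded = np.concatenate(
        [np.full(pad, trace.values[0]), trace.values, np.full(pad, trace.values[-1])]
    )
    return trace.with_values(np.convolve(padded, np.ones(w) / w, mode="valid"))


def _default_prominence(values: np.ndarray) -> float:
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    if iqr > 0:
        return 0.1 * iqr
    rng = float(values.max() - values.min())
    return 0.1 * rng if rng > 0 else np.inf


def detect_peaks(
    trace: Trace,
    prominence: float | None = None,
    min_distance_h: float | None = None,
    refine: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Local maxima exceeding a prominence threshold.

    Returns (times, heights).  The default prominence is 10% of the trace's
    interquartile range.  With ``refine`` a parabola through the three
    samples around each peak sharpens the time estimate below the sampling
    step.
    """
    if len(trace) < 3:
        raise ValueError("need at least 3 samples")
    if prominence is None:
        prominence = _default_prominence(trace.values)
    if not np.isfinite(prominence):
        return np.array([]), np.array([])
    dt = float(np.median(np.diff(trace.times)))
    distance = max(1, int(round(min_distance_h / dt))) if min_distance_h else None
    idx, _ = find_peaks(trace.values, prominence=prominence, distance=distance)
    times = trace.times[idx].astype(float)
    heights = trace.values[idx].astype(float)
    if refine:
        for k, j in enumerate(idx):
            if 0 < j < len(trace) - 1:
                y0, y1, y2 = trace.values[j - 1 : j + 2]
                denom = y0 - 2 * y1 + y2
                if denom < 0:
                    delta = 0.5 * (y0 - y2) / denom
                    if abs(delta) <= 1.0:
                        times[k] = trace.times[j] + delta * dt
                        heights[k] = y1 - 0.25 * (y0 - y2) * delta
    return times, heights


def peak_prominences_of(trace: Trace, prominence: float | None = None) -> np.ndarray:
    if prominence is None:
        prominence = _default_prominence(trace.values)
    if not np.isfinite(prominence):
        return np.array([])
    _, props = find_peaks(trace.values, prominence=prominence)
    return props["prominences"]


def estimate_period(
    trace: Trace,
    transient_h: float = 24.0,
    prominence: float | None = None,
    min_distance_h: float | None = None,
    smooth_h: float = 0.0,
) -> float:
    """Mean inter-peak interval after discarding an initial transient."""
    t0 = trace.times[0] + transient_h
    win = trace.window(t0, np.inf)
    if smooth_h > 0:
        win = smooth(win, smooth_h)
    times, _ = detect_peaks(win, prominence=prominence, min_distance_h=min_distance_h)
    if len(times) < 2:
        raise ValueError("aperiodic: fewer than 2 peaks after the transient")
    return float(np.mean(np.diff(times)))


def sustained_oscillation_check(
    trace: Trace,
    min_peaks: int = 4,
    min_rel_amplitude: float = 0.5,
    transient_h: float = 24.0,
) -> bool:
    """True iff the trace keeps oscillating with undiminished amplitude.

    Requires at least ``min_peaks`` post-transient peaks whose final
    prominence is at least ``min_rel_amplitude`` times the first one.  Used
    as the deterministic screen before stochastic cost evaluation: a stable
    fixed point (spiralling-in trajectory) fails, a limit cycle passes.
    """
    win = trace.window(trace.times[0] + transient_h, np.inf)
    if len(win) < 3:
        return False
    proms = peak_prominences_of(win)
    if len(proms) < min_peaks:
        return False
    return bool(proms[-1] >= min_rel_amplitude * proms[0])


def circular_variance(phases_h: np.ndarray, period: float = 24.0) -> float:
    """1 - |mean resultant| of phases mapped onto the circle; 0 = synchrony."""
    ang = 2.0 * np.pi * np.asarray(phases_h, dtype=float) / period
    if len(ang) == 0:
        raise ValueError("no phases")
    return float(1.0 - np.abs(np.mean(np.exp(1j * ang))))
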