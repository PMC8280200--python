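# Methods

## Model

Each cell is a three-variable negative feedback loop — mRNA `M`,
cytoplasmic protein `P`, nuclear repressor `R` — with protein-sequestration
repression: the repressor binds the activator (total concentration `A`)
into an inactive 1:1 complex with dissociation constant `K`, and the free
activator fraction

    f(R, A, K) = (A − R − K + sqrt((A − R − K)² + 4AK)) / (2A)

drives transcription.  For `K → 0` this becomes the piecewise-linear
`max(0, 1 − R/A)`, which is the default: oscillations require small `K`
anyway, and on a grid `R ∈ [0, 2A]` the two forms differ by less than 1e-2
already at `K = 1e-4` (the difference shrinks with `K`; the test suite
verifies both the pointwise bound and closeness of short deterministic
trajectories).  Production rates are nondimensionalized to 1 — both the
recordings and the model output are normalized before comparison, so
absolute amplitudes carry no information and keeping production rates free
would only create exactly compensating parameter directions.

Light enters additively in the `M` equation as `i·I(t)` with binary
`I(t)`, representing light-driven clock-gene induction, and each equation
receives independent additive white noise of intensity `σ`, representing
intrinsic cellular fluctuations.  Single-cell luminescence is `L = f(R,A)`
(the reporter reads out E-box activation) and a well is the mean over `n`
independent cells.  There is no intercellular coupling — the cultures are
modelled, and behave in this model, as independent oscillators: in
constant darkness the cells' phases diffuse apart and the population mean
loses amplitude while every retained single-cell trace keeps oscillating.

State variables are not clamped at zero.  Additive noise produces small
negative excursions; the piecewise activation is then evaluated as written
(`R < 0` gives `f > 1`).  Clamping would bias the noise and is not part of
the model definition.

## Parameters

| parameter | meaning | units | reference value |
| --- | --- | --- | --- |
| `A` | activator concentration | – | 3.5 |
| `d_M, d_P, d_R` | degradation rates | 1/h | 0.1798 |
| `i` | light sensitivity | – | 0.03 |
| `σ` | noise intensity | – | 0.01 |
| `K` | RA dissociation constant | – | 0 (piecewise limit) |

The reference set (`zfclock.synth.CONTROL_PARAMS`) defines the synthetic
"untreated culture" condition.  It was chosen, once, as the point found by
scanning the equal-degradation family that satisfies **all** the behaviors
the fitted cellular clock is supposed to show simultaneously: a 24.0-h
deterministic free-running period; entrainment to 12:12 LD with phase
tracking of a 12-h schedule displacement; entrainment of the population
mean to symmetric 15:15 and 10:10 cycles; a visible LD oscillation; a
type-0 (strong-resetting) phase response to 12-h light pulses; and
population-level amplitude damping in darkness with sustained single-cell
amplitude.  The constraint set is tight: a weak-light regime near
`A ≈ 1, i ≈ 0.01` reproduces everything except the resetting strength (its
PRC is type 1), and light sensitivities above `i ≈ 0.05` suppress the
luminescence rhythm outright, because the light-driven repressor
production pins `R` above `A`.  `σ = 0.01` makes successive dark-phase
population peaks decline monotonically at a damped-sine damping ratio of a
few 1e-3/h while single cells retain at least half their initial peak
amplitude — measurable desynchronization without drowning the single-cell
rhythm.

## Numerics

Deterministic runs use fixed-step classical RK4, stochastic runs
Euler–Maruyama with per-variable increments `σ·sqrt(dt)·N(0,1)`; both hold
the light level constant over a step.  The default step is `dt = 0.01 h`
(fitting stages use `dt = 0.02 h`; halving `dt` moves a 10-day
deterministic trajectory by less than 1e-3 in sup norm, and the additive
noise makes Euler–Maruyama strong order 1).  Output is recorded on a
regular grid (default 0.1 h) and interpolated linearly onto the 40-min
plate cadence where a data grid must be matched.  Integrators are
numba-compiled; a state that becomes non-finite aborts with the offending
step index.

Randomness is reproducible and prefix-stable: cell `j`'s generator seed is
word `j` of the `SeedSequence` stream of the population seed, so adding
cells or retaining traces never changes the draws of other cells, and
`n = 1` reproduces the single-cell simulator exactly.

Peak detection uses local maxima above a prominence threshold (default 10%
of the trace's interquartile range) with optional three-point parabolic
refinement of the peak time; periods are mean inter-peak intervals after a
transient (default 24 h).  Population means are smoothed with a 2-h moving
average before circadian peak extraction.  The sustained-oscillation
screen demands at least 4 post-transient peaks whose final prominence is
at least half the first — a limit cycle passes, a spiral into a stable
fixed point fails.

Damped-sine fits (`A·e^(−dt)·sin(2πt/T + θ)`) are nonlinear least squares
on the mean-centered trace (the model has no offset term) with multi-start
initialization: phases `{0, π/2, π, 3π/2}`, periods `{20, 24, 28} h`, and
the damping initialized from log-envelope regression on detected peaks;
the lowest-residual start wins.  Sample means and standard deviations use
the n−1 denominator throughout.

## Normalization

Untreated recordings: per-trace Z-score.  Compound-treated recordings: the
adjusted Z-score `z_d(x) = z(x)·S_d/S_c + (x̄_d − x̄_c)/S_c`, which removes
well-to-well scale and offset variation while preserving each group's mean
and variance relative to control; for the control group it reduces exactly
to the Z-score.  Model output is centered and scaled by the
control-parameter simulation's own statistics.  The synthetic generator
applies per-well affine distortions (scale in [0.5, 2], offset in [0, 1])
precisely so that these normalizations do real work in the tests.

## Fitting pipeline

All stages use differential evolution (scipy), `polish=False` (the costs
are piecewise-constant in the peak-detection outputs, so gradient polish
is useless), recombination 0.9, dithered mutation [0.5, 1].  Bounds:
`A ∈ (0.05, 5]`, each `d ∈ (0.01, 2]` 1/h, `i ∈ [0, 2]`, `σ ∈ [0, 0.5]`.
Failed evaluations (no peaks, non-circadian damped-sine fit, integration
failure) return a penalty of 1e6, which dominates any attainable cost.

**Stage 1 (C1).**  `C1 = (T_DD−24)² + (T_LD−24)² + wrap(P_LD−P_LDs+12)²`
with σ = 0 and equal degradation rates (the oscillation-probability-
maximizing constraint).  Operational conventions: periods are mean
inter-peak intervals of the deterministic luminescence after a 5-day
transient of a 10-day run; a phase is the last peak time modulo 24 h; the
phase difference is wrapped to (−12, 12] before squaring, since phases
live on the circle and the unwrapped form would make the exact optimum
unreachable.  The free-running trace must additionally pass the
sustained-oscillation screen — damped candidates still show light-driven
peaks under LD, so period estimates alone cannot reject them.  The DE
initial population samples `d` and `i` log-uniformly: entrainable light
sensitivities occupy a narrow low band of the admissible range that a
uniform draw would rarely seed (bounds are unchanged).  Runs stop early
once `C1 < 0.01`; a run ending above 0.5 is retried with a fresh seed.
The optimization is repeated independently (50 times at reporting scale)
to build a diverse population of oscillatory parameter sets.

**Stage 2 (C2).**  `C2 = (d_data − d_model)²`, optimizing σ only.
`d_data` comes from the recording's first six days (the dark portion of
the estimation plate); `d_model` from the simulated population mean in
darkness after three 12:12 LD cycles, both via the damped-sine fit.  A
model fit whose period leaves [16, 40] h is rejected with the penalty —
at large σ the population mean is noise-dominated and its fitted damping
is meaningless, which would otherwise create spurious minima.  Near the
reference noise level the damping–σ relation is shallow, so this stage
carries roughly ±40% spread at desk scale; it only seeds stage 3, which
sharpens σ against the full trace.

**Stage 3 (C3).**  Mean squared error between the Z-scored recording and
the Z-scored simulated population mean (1,000 cells at reporting scale),
over `(A, d, i, σ)` with equal degradation kept, DE-initialized from the
stage-2 population.  Initial conditions come from a 10-day deterministic
12:12 LD burn-in per candidate.  Before any stochastic evaluation the
deterministic model is screened for sustained dark-phase oscillations;
failures return the maximal cost immediately.

**Stage 4 (C4).**  Sum of LD-segment and DD-segment mean squared errors
against adjusted-Z-scored treated recordings; all six parameters free (no
equal-degradation tie, no oscillation screen — treated cells need not
oscillate in darkness).  The initial state is the untreated model's state
at a light-to-dark transition, fixed for the whole optimization; the
dark-first burn-in ends exactly at such a transition, matching recordings
that start at the beginning of the dark phase.  Concentrations are fitted
in order, each seeded with the previous final population; fits with
`E_f ≤ 0` are flagged excluded.

Stochastic costs use common random numbers — one fixed simulation seed per
stage — so DE ranks candidates on identical noise draws.  (Reseeding per
generation would serve the same purpose; scipy's optimizer exposes no
generation hook, and a single fixed seed already removes the ranking
noise.)  With fixed seeds the whole pipeline is bit-reproducible.

**Identifiability.**  From a single Z-normalized estimation-plate
recording, `d` is recovered to a few percent and `σ` to tens of percent,
and the refit model predicts fresh simulations from the true parameters
with `E_f > 0.9`.  `A` and `i` are well constrained in the strong-light
reference regime, but in weak-light regimes (`i ≲ 0.01`) they lie on a
nearly flat iso-period ridge that only resolves when the Monte-Carlo floor
of the cost drops (several thousand simulated cells per evaluation) —
single-parameter readouts of fits in that regime should be treated with
caution, consistent with treatment effects being multi-parameter.

## Analyses

**PRC.**  Deterministic model, entrained then released into darkness; one
pulse per run at onsets spanning one cycle (starting one full cycle into
darkness); the shift is the control-minus-pulsed displacement of the 4th
peak after pulse end, wrapped to (−12, 12] (measuring at the 6th peak
moves shifts by < 0.5 h).  The type is the winding number of the phase
transition curve: the closed-loop sum of minimally wrapped steps of new
phase over one cycle of old phase, an exact multiple of 24 h; steps near
the 12-h wrapping ambiguity raise an error instead of guessing, and the
caller can refine the phase grid.

**Phase angle of entrainment.**  For each symmetric dark-first cycle of
period T, the population is simulated for ≥ 8 cycles; steady state is
declared after 5 cycles, entrainment requires the steady inter-peak
interval to match T within 5%, and the angle is
`−(t_peak − t_lights_on)·24/T` for the first peak at or after a
steady-state lights-on.  Non-entrained periods are reported missing, not
substituted.

**Phase histograms.**  Retained single-cell traces are smoothed (2 h),
peaks at least 12 h apart are extracted inside the analysis window, and
peak times modulo 24 h are binned (24 × 1 h bins, density-normalized);
every peak a cell contributes in the window counts.  Synchrony is
summarized as circular variance.  Single-cell peak times jitter by a
couple of hours even under entrainment, so LD-versus-DD synchrony
contrasts are resolved at noise intensities around σ ≈ 0.04 and above for
windows placed within the first days of darkness; at the reference
σ = 0.01 the same contrast needs longer dark exposure.

**PCA of parameter populations.**  Members of all populations are pooled,
each of the six parameters is z-standardized across the pool, and PCA is
fit on the pooled matrix; populations are summarized as median ± median
absolute deviation in PC space.  A parameter constant across the pool is
dropped from the projection (logged); rank deficiency reduces the
component count.

## The synthetic-data generator

`zfclock.synth` emulates the recording setup end to end: wells simulated
as cell populations at their ground-truth parameters, sampled on a 40-min
grid, distorted per well by an affine transform drawn from the stated
ranges, plus additive Gaussian measurement noise (default sd 5% of the
trace sd; the biophysical model itself adds no measurement noise, but real
photon-counting traces are not clean, and the normalizations should be
exercised against it).  Fixtures: the 288-h estimation plate (6 d
darkness, three 12:12 LD cycles, 3 d light; 16 replicate wells at
reporting scale) and compound series (control plus concentrations with
progressively scaled parameter deltas — e.g. decreasing `A` for an
amplitude-suppressing treatment, increasing `σ` for a desynchronizing
one).  Everything is reproducible from (design, seed).

What the generator does not emulate: instrument artifacts (plate-movement
gaps, finite integration windows, cross-talk), slow baseline drift,
well-edge effects, or cell death.  Passing tests therefore demonstrate
that the pipeline recovers the model's own dynamics through realistic
scale/offset/noise distortions — not that the model is a complete
description of any particular cell line.

## Problem sizes

Reporting-scale population means use 30,000 cells in the model definition;
1,000 cells reproduce them within Monte-Carlo error and are the default
for fitting and analyses.  The test suite and the reproduction script run
the same pipeline at desk scale — hundreds of cells per evaluation, 4–8
stage-1 repeats, DE populations of 6–16 over ≤ 12 generations — which
leaves every qualitative property and every measured target intact.

## Known limitations

- Binary light only; no graded intensities, spectra, or twilight ramps.
- No intercellular coupling and no multi-loop clock architecture; strong
  transients after treatment administration are absorbed into parameter
  changes rather than modelled mechanistically.
- The C1 phase convention (last-peak time modulo the cycle) is one of
  several reasonable choices; any consistent convention yields the same
  optimum because only wrapped differences enter the cost.
- Conventional PRCs are not defined for parameter sets whose dark-phase
  oscillations collapse too quickly for peak-based analysis; such cases
  raise errors or report missing values rather than substitutes.
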