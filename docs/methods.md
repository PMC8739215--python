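# Methods

## Model

`tcnmm` implements a neural mass model of the thalamocortical loop with
six lumped populations: cortical pyramidal cells (PY), fast (GABA_A) and
slow (GABA_B) inhibitory interneurons (I1, I2), excitatory interneurons /
spiny stellate cells (EI), the thalamic relay nucleus (TC) and the
thalamic reticular nucleus (RE).  Each population's mean potential obeys
a first-order relaxation driven by the sigmoid-transformed activity of
its afferents:

    dX/dt = tau_X ( h_X - X + sum_S ± c_S_X f(S) ) [+ N_X]

with the transfer function f(x) = 1/(1 + eps^(-x)), eps = 2.5e5.
Excitatory (glutamatergic) terms enter with +, inhibitory (GABAergic)
with −.  The external drives N_py (cortical) and N_tc (sensory) are
biased sinusoids, `B + a sin(2 pi f t)`, added to the PY and TC equations
*outside* the tau multiplier; constant-input analysis sets both
amplitudes to zero (biases 0.7 and 0.1).  The model output is the mean
of the four cortical populations, (PY + I1 + I2 + EI)/4.

Because eps is large, f is nearly a step: the system behaves almost
piecewise-linear with thin switching layers.  Two consequences run
through everything below: Newton solvers need damping, and extra
"saturated-corner" equilibria exist far from the operating branch.

### Parameters

All coupling strengths, offsets and time scales default to the reference
parameterization of the extended circuit (`ModelParameters()`), with the
three EI couplings defaulting to c_py_ei = 0.8, c_i1_ei = 0.3,
c_tc_ei = 4.5.  Time is in seconds and the tau values in 1/s.  The two
input gains c_Npy_py and c_Ntc_tc multiply the whole external drive and
default to 1, leaving the printed equations unchanged.

The `ei_enabled=False` variant ablates the EI population: its state is
frozen at zero, every coupling with EI as source or target is dropped,
and the output becomes the mean of the remaining three cortical
populations.  This is the minimal ablation construction; nothing else is
re-tuned.

## Simulation

Classic fixed-step RK4 with dt = 0.0039 s over 60 s by default; the
drives are evaluated at the substep times.  The integrator is a compiled
(numba) kernel; the public `vector_field` is a plain numpy reference
implementation and the test suite checks the two against each other.
Runs are bit-deterministic.  A divergence guard aborts when any state
exceeds 1e6 (with the bounded sigmoid the intact model cannot diverge;
the guard protects against pathological inputs).  The default initial
condition is the zero state; sweep engines override it with attractor
inheritance.  Convergence is 4th order; the production step 0.0039 s
sits outside the asymptotic regime (the steep sigmoid's switching layers
dominate the local error there), which the convergence test accounts
for by measuring at dt = 0.001 s.

## Features of the steady-state window

Analysis uses the last 2 s of the output (512 samples at the default
step).  Features are

- **DF** — dominant frequency: the maximum-power bin of the mean-removed
  periodogram (f > 0), refined by parabolic interpolation of log-power
  over the three bins around the peak.  The raw bin width of a 2 s
  window is 0.5 Hz, too coarse for the 3.5 Hz and 4 Hz class boundaries
  below; the interpolated estimate matches a 32 s reference spectrum to
  ~0.03 Hz on this model's waveforms.
- **Pmax1/Pmax2, Pmin1/Pmin2** — the largest/smallest local maxima and
  minima (strict sign changes of the first difference, plateaus carried
  through).  Extremum values are clustered into levels with tolerance
  1e−3 to count distinct amplitudes (a period-doubled cycle has two
  maximum levels).
- **ptp** and the window **mean**.

A window with peak-to-peak below 1e−3 model units is a fixed-point
regime: DF is reported as 0 and extrema as absent.  Both thresholds are
set by the scale separation in the model (oscillation amplitudes
0.02–0.4 versus numerical jitter below 1e−4) and are not tuned per
analysis.

## Classification

Seven activity types are assigned by fixed-precedence rules on the
features (first match wins):

1. **tonic** — DF ≥ 14 Hz, single trough level (Pmin1−Pmin2 < 0.01);
2. flat window → **normal** if the resting level is above −0.1,
   **slow rhythmic** if it lies in (−0.8, −0.1) (the stable-focus branch
   at negative output);
3. **preictal** — DF < 3.5 Hz, Pmin1−Pmin2 < 0.2, Pmax1−Pmax2 < 0.12 and
   ptp < 0.15 (low-amplitude spikes);
4. **clonic** — 2 ≤ DF ≤ 4 Hz with a single trough level
   (Pmin1−Pmin2 < 0.004): the high-amplitude slow wave;
5. **typical absence** — 2 < DF < 4 Hz with trough spread > 0.004 (the
   spike-and-wave signature: two distinct minima levels per cycle);
6. **atypical absence** — DF > 4 or DF < 2 Hz with trough spread > 0.01;
7. otherwise **unclassified**.

Design notes.  The preictal/clonic separator is amplitude: the settled
clonic wave in this model has a *single* maximum level, so a
maximum-spread condition cannot distinguish it from anything; what
separates the two states phenomenologically is low versus high
amplitude, and the 0.15 bound sits between the observed preictal band
(ptp ≤ 0.12) and the clonic band (ptp ≥ 0.15).  The clonic/absence
separator is the trough spread, with the same 0.004 threshold on both
sides so the two classes are complementary on the shared 2–4 Hz band.
The classifier targets the model's autonomous regimes; driven responses
(frequency sweeps) are summarized by amplitude and DF instead.

## Equilibria and Hopf localization

With constant inputs the model is autonomous.  Equilibria are found by
damped Newton iteration (step halving up to 20 times, at most 200
iterations, residual below 1e−10) from a deterministic multi-start grid
(3 points per axis over [−4, 2]^6, plus the origin), deduplicated at
distance 1e−6.  Each record carries the eigenvalues of the analytic
Jacobian and a stability class (stable node/focus, saddle, unstable).

One-parameter continuation warm-starts Newton from the last tracked
state.  The operating (cortical) branch folds near the first oscillation
onset: past the fold the warm start fails, and the branch is re-acquired
by the multi-start search, selecting the equilibrium *closest in state
space* to the last tracked one.  Closest-state selection matters because
a saturated down-state node and saddle points coexist with the operating
branch and would otherwise capture the continuation.

`locate_hopf` bisects the parameter value where the real part of the
leading complex-conjugate eigenvalue pair of the tracked equilibrium
crosses zero, to a bracket width of 1e−4.  Whether a crossing is super-
or subcritical is read off simulations (amplitude growth just past the
crossing), not from normal-form coefficients.

## Sweeps and event detection

1D sweeps simulate 60 s per grid point with attractor inheritance (the
final state seeds the next point), then record the feature set of the
last 2 s.  Period-doubling events are placed at grid midpoints where the
count of distinct maximum levels doubles (1→2 or 2→4) — a waveform
criterion, not Floquet analysis.  Bistable windows are contiguous runs
where forward and backward sweeps settle onto attractors whose amplitude
envelopes (ptp, Pmax1, Pmin1) differ by more than 0.01 model units;
their edges approximate fold-limit-cycle and subcritical-Hopf
boundaries.  Default grid resolution is 0.002 in the cortical couplings
(printed event locations carry 2–3 significant digits) and 0.02 for the
thalamic coupling c_tc_re.

2D maps classify every cell of a (c_py_ei, c_i1_ei) grid at fixed
c_tc_ei, each cell cold-started from the zero state so the map reflects
the attractor reached from one common condition.

## Frequency response

Sweeps drive one channel with a 0.02-amplitude sinusoid (the reference
drive amplitude; the un-swept channel's amplitude is zero) across a
frequency grid, with attractor inheritance, and record steady-state
peak-to-peak amplitude and DF per frequency.  Caveat: below ~0.5 Hz the
2 s analysis window covers less than one drive cycle, so the measured
amplitude is clipped in a phase-dependent way and the curve is jagged;
the low-frequency "resonance" of the cortical channel lives in this
regime and is a property of the measurement procedure, which this
package reproduces deliberately.  The true full-cycle response of the
cortical channel is low-pass (monotone).

Resonance peaks are interior maxima of the edge-normalized smoothed
amplitude curve above a prominence threshold (5% of the curve range);
refinement re-sweeps ±0.15 Hz around the strongest peak at 0.01 Hz with
four lead-in grid points so inheritance settles before the scored
window.  Jumps (the non-linear amplitude-jump phenomenon) are
adjacent-point differences exceeding 5× the median difference of their
local neighbourhood (±5 points): a genuine discontinuity is a local
outlier, while the steep smooth flank of a resonance has comparable
neighbours — the local rule keeps the detector empty on any driven
linear second-order system.  A frequency band is flagged aperiodic
(chaos proxy) when the window's autocorrelation at one drive period
falls below 0.9; no Lyapunov exponents are computed.

The state-switch protocol simulates a piecewise-constant c_py_ei
schedule (default 0.76 → 0.748 → 0.76, 20 s epochs) with the state
carried continuously across epochs and a fixed 1 Hz drive, and reports
per-epoch features.

## Synthetic fixtures

`generate_fixtures(seed)` produces deterministic series for testing the
feature extractor and classifier without running the model: pure and
mixed sinusoids, an alternating two-amplitude spike train (the
period-doubled signature), a damped oscillation at negative offset (the
slow-rhythmic proxy), a spike-and-wave-like series with two trough
levels 0.05 apart, constant series, and seeded noise — plus canned
feature sets for each activity type.  These emulate isolated waveform
signatures only; they carry no circuit dynamics, so tests passing on
them validate the feature/classification pipeline, not the model.

## Problem sizes

Default analyses are desk-scale by choice: 60 s runs (~15 400 RK4
steps), 1D sweeps of 60–350 points, 40×40 maps, frequency grids of
100–200 points with 0.01 Hz refinement around detected features (the
uniform fine grid would change no detected location by more than one
coarse step, which the grid-refinement invariant checks).

## Known limitations

- Unstable limit-cycle branches are not continued; bistable windows are
  localized by forward/backward hysteresis only, so window edges carry
  one-grid-step resolution and fold-limit-cycle points between detected
  windows can be missed.
- The classifier is calibrated on the model's settled autonomous output;
  transient-modulated or driven signals can land in `unclassified` or in
  a neighbouring class near DF boundaries.
- Near class boundaries (DF ≈ 4 Hz) the sub-bin DF estimate decides the
  label; cells whose true frequency sits within the interpolation error
  of the boundary can flip class between grids.
- "Chaotic" flags are an autocorrelation proxy, not a Lyapunov
  computation.
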