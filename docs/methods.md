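# Methods

## The channel model

ASIC1a is described in Hodgkin–Huxley form with two independent gates: a
fast activation gate `a` (opening/closing) and a slow sensitization gate `s`
(desensitization/recovery).  The current density is

    I_ASIC1a = g_asic · a · s · (V_m − E_asic),

with g_asic = 10 mS cm⁻² and E_asic = +50 mV by default.  Each gate relaxes
first-order toward a pH-dependent steady state with a pH-dependent rate:

    dx/dt = r_x(pH) · (x∞(pH) − x),   x ∈ {a, s}.

Steady states are Hill-type functions of pH,

    x∞(pH) = 1 / (1 + K^F · 10^(F·H·(pH − 7 − δ))),

where K positions the curve along the pH axis, H is a slope factor (sign
encodes direction: H > 0 for the activation gate, which opens on
acidification), F ≥ 1 is a steepening factor and δ a pH offset.  The
midpoint pH is 7 + δ − log₁₀(K)/H and is independent of F.  The default
constants are K = 23.67, H = 2.797, F = 1.48, δ = 0 (gate a) and K = 11.18,
H = −9.448, F = 1, δ = 0.15 (gate s).

Rates are double sigmoids of pH,

    r(pH) = a₁/(1 + e^(b₁(pH − c₁))) + a₂/(1 + e^(b₂(pH − c₂))),

with (0.3487, 10.14, 6.392, 234.3, −5.553, 8.595) for r_a and (0.002531,
13.94, 6.769, 0.0008942, −18.39, 7.436) for r_s (ms⁻¹ amplitudes).  The
rates are evaluated in the linear domain; this is identical to
exponentiating a fit of ln r and avoids an exp/log round trip.  Both rates
are strictly positive and bounded by a₁ + a₂.

The small overlap of a∞ and s∞ (the *window current*, a∞·s∞ ≈ 2×10⁻⁴ at
pH 7.4) is what sustains steady currents at mildly acidic pH; the F = 1.48
steepening of a∞ exists precisely to keep this window small, and the
δ = 0.15 alkaline shift of s∞ compensates the finite 60-s conditioning of
the steady-state-desensitization (SSD) protocol (see *Fitting pipeline*).

## pH waveforms and protocols

pH versus time is represented as contiguous polynomial segments (degree ≤ 2
in local time), continuous at every join.  Three builders cover the
experimental repertoire:

- **Steps with finite solution exchange** — the pH moves linearly over the
  exchange time: 1 ms for excised outside-out patches, 200 ms for whole
  cells.
- **Linear ramps** — pH(t) = pH(0) − q·t, with q set by the end pH and ramp
  duration.
- **Sigmoid ramps** — quadratic ease-in over 0.5·rt, linear over rt,
  quadratic ease-out over 0.5·rt.  Requiring pH and dpH/dt continuous at
  the four junctions fixes all six coefficients in closed form; the
  mid-segment slope is (pH_f − pH_i)/(1.5·rt).  The 90–10% fall time (FT)
  — the field's measure of acidification speed — evaluates to
  (2 − 2√0.15)·rt ≈ 1.2254·rt, since both crossings land inside the
  quadratic ease segments (solve τ²/(1.5·rt²) = 0.1).  Protocols specified
  by FT use rt = FT/1.2254.  Whether an experimentally reported FT
  corresponds exactly to this analytic interval is a convention of this
  package; the constant is derived in code and unit-tested against dense
  numerical sampling.

The protocol library builds the six voltage-clamp protocols used to
characterise the channel (activation series, deactivation, steady-state
activation, SSD curve, SSD kinetics, recovery kinetics) as *single long
waveforms* spanning all sweeps, so gate state carries over between sweeps
with the experimental inter-sweep intervals — sweeps are annotated with
analysis windows rather than simulated independently.

## The neuron

The membrane equation is

    c_m dV_m/dt = −(g_Na m³h (V_m−E_Na) + g_K n⁴ (V_m−E_K)
                    + g_L (V_m−E_L) + I_ASIC1a + I_stim),

with c_m = 1 µF cm⁻², g_Na = 135, g_K = 45, g_L = 0.5 mS cm⁻², E_Na = +55,
E_K = −72, E_L = −49.387 mV, I_stim = 0.  The m, h, n rate functions are
the classic squid-axon forms translated so that rest sits at −60 mV, with
the h-gate rates running at one tenth of the classic speed; this is the
parameterisation consistent with the model's stated half-activation of the
Na⁺ conductance (m∞³ = 0.5 at −21.6 mV — note the cube: m∞ itself is 0.794
there), half-inactivation (h∞ = 0.5 at −57.3 mV) and total rates at 0 mV
(α+β = 3.8 ms⁻¹ for m, 0.1 ms⁻¹ for h).  The removable singularities of
α_m and α_n are evaluated by the analytic limit u/(e^u − 1) → 1 inside a
guard band of 10⁻⁶ mV.

**Na_v perturbations.**  A voltage shift s_x moves a gate's voltage
dependence (its V½) by exactly +s_x — the rate functions are evaluated at
V_m − s_x — so a negative s_m hyperpolarises activation and increases
excitability.  A scale factor f_x multiplies both rates, changing kinetics
without moving the steady-state curves.

**Resting state.**  Initial conditions are the gate equilibria at the
starting pH and V_m = −60 mV.  The exact fixed point of the default model
(zero net steady current at pH 7.4) is −59.20 mV; the initialisation
transient is a damped overshoot of < 2 mV that settles within ~2 s.  A
closed-form holding-current solver (`holding_current`) returns the I_stim
pinning rest at any target potential, for perturbation sweeps where rest
shifts.

**Spontaneous firing** is defined as ≥ 2 action potentials in 20 s at
constant pH 7.4 from equilibrium.  Under this criterion the resting model
is quiescent and becomes a spontaneous oscillator for m-gate shifts below
≈ −1.9 mV (bisection, robust to dt halving).

## Numerical integration

All state variables advance by explicit forward Euler with a constant time
step, the scheme the model was designed for: 0.01 ms in current clamp and
for outside-out voltage clamp, 0.1 ms for whole-cell voltage clamp (the
gate rates at whole-cell pH ranges keep dt·r < 0.04).  Two guards are
enforced per step: dt·r < 1 for both ASIC gates (explicit-Euler stability;
violations raise with the step index) and |V_m| < 200 mV (blow-up).  The
per-current decomposition satisfies c_m·ΔV/Δt + ΣI = 0 identically at every
step, and tests assert it to 10⁻⁹.

Convergence: halving dt from 0.01 to 0.005 ms leaves AP counts unchanged
and changes burst frequencies by < 3%.  Absolute spike times, however,
converge only first-order and shift by ~1.6 ms (fast ramp) to ~10 ms (slow
ramp) under dt halving: a threshold crossing against a slowly rising drive
amplifies the O(dt) voltage error.  Burst-internal inter-spike intervals on
fast ramps agree to < 0.5 ms.

## Trace analysis conventions

- **Spikes**: upward crossings of 0 mV, re-armed after V_m falls below
  −20 mV (0 mV cleanly separates full spikes from subthreshold
  oscillations in this model).  Firing time runs from the first spike's
  0-mV crossing to the downward −20-mV crossing after the last spike;
  frequency = count / firing time.
- **Charge**: trapezoidal integral of the current, reported in mC cm⁻²;
  the default window runs from stimulus onset until |I| returns below 1% of
  the peak, capped at the trace end.
- **Phase plane**: dV/dt by central differences.  The spike threshold is
  the intersection of a line fitted to the sub-threshold branch (|dV/dt|
  below max(1 mV/ms, 5% of the maximal upstroke) — the adaptive part is
  needed because mid-burst inter-spike trajectories never fall fully flat)
  and a line fitted to the ascending-limb points between 10% and 40% of the
  maximal dV/dt.  Descending-limb points near the spike peak are excluded;
  without that exclusion the "steep" tangent is contaminated and the
  intersection is meaningless.
- **Mono-exponential fits**: least squares of A·e^(−t/τ) + C with a
  deterministic multistart on τ (1/e crossing, span/5, span/20); fits whose
  amplitude is within 3 standard deviations of the residual noise are
  flagged rather than returned as rates.
- **Hill fits**: I = I_max/(1 + 10^(±n_H(pH − pH₅₀))), slope sign free,
  flagged when flat or when pH₅₀ leaves the sampled range.

## Synthetic recordings and the fitting pipeline

The generator produces voltage-clamp recordings as gain · (model current) +
white Gaussian noise, at 1-ms sampling for whole-cell protocols and 0.02-ms
sampling for outside-out protocols (fast protocols are assigned to
outside-out patches and slow ones to whole cells, as in the experiments
they emulate).  The default noise scale is 5 µA cm⁻² (~0.5% of a saturating
response) — a nominal choice; realistic magnitudes are not derivable from
the modelled experiments.  It deliberately omits 1/f noise, seal leak,
series-resistance error and capacitive transients, so passing
parameter-recovery tests demonstrates correctness of the estimators under
idealised noise, not robustness to real-rig artifacts.

Two generator choices extend the measured conditions for identifiability:
deactivation sweeps return not only to pH 7.4 but also to 7.0, 7.2, 7.6 and
7.8.  Without the near-neutral returns the fast rate's valley (pH 6.9–7.2)
is unconstrained by any measurable opening, and without the alkaline
returns its steep alkaline limb is pure extrapolation; both regions matter
for simulating neutral-pH recovery.  Conditioning durations for SSD
kinetics span 0.5–32 s so that both fast (τ ≈ 0.5 s at pH 6.7) and slow
(τ ≈ 40 s at pH 7.1) entry is sampled.

**Extraction.**  Opening and decay rates come from mono-exponential fits
within each test pulse.  Because the current is the *product* of the
exponential opening and the slow desensitization decay, a naive
single-exponential rise fit is biased fast by 15–30% at weak stimuli; the
extractor therefore divides the rise by e^(−r_decay·t), with r_decay
measured from the same sweep, before fitting (residual bias < 2%).
Deactivation rates are fitted on the tail after the return exchange, until
the tail collapses to 2% of its starting amplitude.  SSD and recovery rates
are fitted on normalised test/control amplitudes versus conditioning
duration.  Amplitudes are read off a lightly smoothed (≈ 20-sample boxcar)
copy of the trace, mimicking the low-pass filter of real recordings;
without it the max-statistic rides the noise and near-zero responses are
systematically overestimated.  Series with fewer than three usable points,
or amplitudes below 10× the noise floor, are dropped.

**Fits.**  Steady-state curves are fitted as f(pH) = 1/(1 + K·10^(H(pH−7)))
with a logit-linear regression providing the initial guess (exact on
noise-free data).  Rates are fitted on ln r with the double sigmoid,
log-parameterised amplitudes, grid-scan initial guesses and a deterministic
multistart over slope magnitudes {4, 8, 16}.  Rate-fit quality is assessed
by *function-value* recovery over pH 6–8, never by coefficient equality —
the six coefficients trade off against each other and only the function
enters downstream simulation.  Flat rate series are reported as degenerate.

**Refinements.**  `apply_refinements` sets F = 1.48 on the activation gate
(midpoint-preserving steepening; the published value, kept as the default)
and shifts the sensitization curve alkaline.  For the published model the
shift is the fixed 0.15; in the recovery loop the shift is instead
*estimated* by reconstruction — the SSD protocol is re-simulated with the
base-fit model and the shift is set to the bias between the fitted curve
midpoint and its reconstruction.  This is the same logic that motivates the
fixed value (60 s of conditioning is too short for complete desensitization
near neutral pH, so the measured SSD curve sits acidic of the underlying
s∞), but it adapts to the bias actually present in the data at hand; a
fixed 0.15 overshoots whenever the true protocol bias is smaller, as it is
for suites generated from the final published constants (bias ≈ 0.05).

With moderate noise the full loop recovers both steady-state midpoints to
< 0.01 pH units and both rate functions to < 7% everywhere on pH 6–8.

## Sweeps

Grid experiments run the forward model per cell and return long-format
pandas DataFrames.  Default grids: end pH 5.8–7.2 in 0.1 steps with FT ∈
{1, 2, 4, 8, 16, 32} s for the current/charge map; end pH 5.6–7.0 in 0.2
steps with FT 0.5–9 s in 0.5-s steps for the firing map (both
configurable; the published grids are unstated, so these are package
conventions recorded in the output).  Each cell simulates
hold (5 s) + 2·rt(FT_max) + 30 s plateau so slow ramps reach quasi-steady
behaviour, and all cells of a grid share one counting window.  The
sensitivity sweep records both FT and total ramp time (2·rt), since
conductance-sensitivity results are conventionally plotted against total
ramp time.  The "middle" AP is the one at index ⌈count/2⌉ in spike order.
Parameter sets that fire spontaneously at rest are flagged in a dedicated
column; their ramp-evoked counts are reported but should not be read as
acid-evoked signalling.

## Known limitations

- Single-compartment neuron with one Na_v/K_v pair; no BK channels, Ca²⁺
  dynamics, temperature effects or additional channel subtypes.
- pH acts as an instantaneous bulk value; solution exchange is modelled as
  short linear ramps, not perfusion hydrodynamics.
- The burst frequency of very fast ramps is sensitive to the AP-counting
  conventions (the burst ends in damped, near-threshold oscillations);
  frequencies for fast ramps carry a ~10–15% convention uncertainty, while
  intermediate-ramp frequencies are robust.
- Absolute spike times under slow ramps are first-order-sensitive to the
  Euler step (see *Numerical integration*); counts and frequencies are the
  stable observables.
- The noise model is additive white Gaussian only.
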