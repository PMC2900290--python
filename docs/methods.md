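# Methods

## Model and assumptions

`threshkit` treats spike initiation in a single-compartment membrane

    C dV/dt = g_L(E_L − V) + g_Na P_Na (E_Na − V) + Σ_i g_i (E_i − V) + I

with a transient sodium conductance whose open fraction factorizes into
independent activation and inactivation gates (P_Na = m³h by default).  Three
approximations produce the closed-form theory:

1. **Instantaneous activation.**  The activation time constant (a fraction of
   a millisecond) is far below every other time constant in play, so m is
   replaced by its equilibrium curve.  This is adequate for *initiation*, not
   for spike shape, and it is also why stochastic channel gating cannot be
   represented in this framework.
2. **Exponential tail.**  Spikes start well below the half-activation voltage
   V_a, where a Boltzmann activation curve reduces to exp((V − V_a)/k_a), and
   the Na driving force is approximated by its value at V_a.
3. **Quasi-static modulation.**  Inactivation h, voltage-gated gates and
   synaptic conductances are treated as frozen on the ~1 ms timescale of
   initiation; they enter the threshold as parameters, not dynamics.

Under 1–3 the membrane equation takes the exponential integrate-and-fire
form with threshold parameter

    θ = V_T − k_a ln h + k_a ln(g_tot/g_L),
    V_T = V_a − k_a ln[ g_Na (E_Na − V_a)/(g_L k_a) ],

where g_tot = Σ g_i (every non-Na conductance, leak included) and E* is the
conductance-weighted reversal of that effective channel.  θ is the
*slow-input* threshold: the voltage at the minimum of the excitability curve
F(V), i.e. the solution of F′(θ) = 0, which is what a DC ramp finds.  Two
other definitions are provided with exact conversions:

* **fast-input threshold** θ_fast — the unstable upper root of F(V) = 0,
  the voltage a brief charge injection must exceed.  Closed form via the
  secondary branch of the Lambert W function,
  θ_fast = E* − k_a·W₋₁(−e^{(E*−θ)/k_a}) (E* shifted by I/g_tot for a DC
  bias);
* **empirical (onset) threshold** θ_emp — the rising-branch solution of
  F(V) + I = C·k_th, the value reported by a first-derivative onset
  criterion k_th; same W₋₁ form with E* further shifted by −C·k_th/g_tot.

The numeric bracketing root-finders on F (bisection bracket [−120 mV, V_a],
tolerance 1e−9 mV) are public API and serve as the normative definitions;
the closed forms are the fast path and the test suite holds them to 1e−6 mV
agreement over a thousand random parameter sets.

Because h obeys dh/dt = (h∞(V) − h)/τ_h(V), the threshold inherits a
first-order dynamics dθ/dt ≈ (θ∞(V) − θ)/τ_h(V) with equilibrium
θ∞(V) = θ evaluated at h = h∞(V).  `integrate_threshold` offers the exact
mode (integrate the gates, map through the threshold equation pointwise —
the reference) and the first-order mode (valid while θ stays within ~k_a of
θ∞; the two agree to 0.1 mV there, and the relaxation time constant matches
τ_h(V) to 2%).  An action potential resets h multiplicatively
(h → h·e^{−δ/τ̄}, δ the spike duration, τ̄ the time-averaged τ_h over the
spike), raising θ by the same k_a·δ/τ̄ after every spike; a slow K gate
instead relaxes toward 1 during the spike, so its threshold effect
saturates rather than accumulates.

## Units

mV, ms, nS, pA, pF throughout (so nS·mV = pA); conductance densities in
parameter files are mS/cm² with the membrane area in µm²; Na surface density
in the AIS inversion is pS/µm²; cable constants use Ω·cm and Ω·cm².
Logarithms are natural.

## The synthetic-data generator

All validation inputs are generated by the package's own simulators; no
external recordings are used.

**Point-conductance model** (`destexhe2001.json`): a 34,636 µm² compartment
(C = 1 µF/cm²), leak 0.045 mS/cm² at −80 mV, Traub–Miles kinetics
(voltage origin −63 mV) for the Na channel (48 mS/cm², E_Na = 50 mV, m³h)
and the delayed rectifier (10 mS/cm², E_K = −90 mV, n⁴), plus a slow
non-inactivating K current (0.5 mS/cm², τ_max = 1 s).  This calibration is
pinned by four quantities the test suite recomputes: the windowed Boltzmann
fit of the conductance activation curve over −51..−38 mV gives
(V_a, k_a) = (−30.3 mV, 3.73 mV) while a whole-range fit gives k ≈ 6 mV;
the half-inactivation voltage is ≈ −41.6 mV; the derived V_T is −67.8 mV;
and the minimum of the model's actual excitability curve is −60.5 mV.

**Synaptic background**: excitatory and inhibitory conductances follow
Ornstein–Uhlenbeck processes (exact-discretization update, so stationary
mean and SD are exact at any dt) with means 12.1/57.3 nS, correlation times
2.728/10.49 ms and reversals 0/−75 mV.  The standard deviations are set to
the in-vivo-like operating point σ_e = 12, σ_i = 26.4 nS, which yields
subthreshold fluctuations of ≈ 4 mV SD and irregular firing at a few Hz —
the regime the validation protocols require.  (The often-quoted 4×-smaller
σ pair describes a much quieter state: it produces no spontaneous spikes
and essentially no threshold variability, leaving nothing to predict.)
Negative conductance excursions are clipped at zero inside the update (a
physical constraint); clip counts are logged, ~1–3% of samples at these σ.

What the generator does *not* emulate: multicompartment initiation and
backpropagation (the theory's compartment stands for soma + initial
segment below threshold, justified by the ~935 µm space constant),
channel-gating noise, synaptic-input correlations, and realistic somatic
spike shapes (single-compartment spikes are small and stereotyped when h is
depleted).  Passing tests therefore demonstrate the internal consistency of
theory, simulation and measurement on this model class — not quantitative
transfer to any particular real neuron.

**EIF model**: the reduction with h = 1 and leak only, used as an exactly
solvable reference: its onset voltages match the θ_emp closed form, its
phase-plot sharpness fit recovers k_a within 5%, and pulse-probing it
recovers θ_fast to one ladder step.

## Measurement protocols

**Onset detection.**  First-derivative method: the onset is the start of
the contiguous dV/dt > k_th run that ends in the upstroke (default
k_th = 10 mV/ms); derivatives are central differences on the raw grid
(optional boxcar smoothing, default off).  Curvature methods (d2/d3): the
maximum of the second/third derivative within 5 ms of the peak, searched
only where dV/dt < 50 mV/ms — on sharp conductance-based spikes the raw
curvature keeps growing far into the upstroke, which is not what the onset
concept targets.  On fluctuating-conductance traces the two curvature
methods rank-agree at ρ ≈ 0.98 (with light smoothing) while
first-derivative vs curvature pairs reach ρ ≈ 0.8: onset noise on this
surrogate is comparable to the threshold signal itself.

**Frozen-noise pulse probing.**  A base run is simulated once; at every
probe time outside spike windows, one trial per ladder level restarts the
integration from the recorded state with V set to that level and replays
the identical conductance paths; the measured instantaneous threshold is
the lowest level that fires within the response window.  Non-monotone
response patterns are resolved to the lowest firing level and flagged, as
are probes where every level fires or none does.  For the fluctuating-model
protocol (probes every 0.6 ms, 65 levels spanning −51..−38 mV over 200 ms)
the response window is one probe period, 0.6 ms: the window must be short
enough that the measured level ladder actually brackets the threshold — at
windows ≥ 1.5 ms the slow escape from just-suprathreshold levels pushes the
measurement below the ladder and most probes become unresolvable.  The
generic operation defaults to 5 ms (appropriate for quiescent or
well-separated-threshold settings); both are exposed.

The probe comparison statistics report variance explained as the squared
Pearson correlation (shift-invariant, because onset-style measures sit a
roughly constant offset above the slow threshold) alongside the
non-shift-invariant 1 − SSE/SST, and the mean shift.  Two shifts are
reported: against the slow prediction (≈ 13 mV on this model) and against
its fast-input conversion (≈ 8.5 mV).  The residual fast shift is the
exponential-approximation bias: with inactivation hyperpolarized by
12.5 mV the threshold sits near V_a where the activation curve is no
longer exponential, and anchoring V_T at the true excitability-curve
minimum (−60.5 mV instead of −67.8 mV) absorbs it.  Both anchorings are
available (`calibrate_threshold_params(..., v_t="excitability_min")`);
the excitability-minimum anchoring is also what makes the between-spike
guarantee hold: V(t) stays below the predicted θ(t) for ≥ 99.9% of
subthreshold samples.

A caveat this package measures rather than hides: the probe *measurement*
chain on this surrogate carries escape-margin noise of the same order as
the resolved threshold signal (τ_h here is only 4–6 ms, so post-spike
threshold elevation decays quickly and subthreshold h barely moves), so the
probe-based variance explained is low and seed-dependent (≈ 10–40%) even
though the threshold-equation prediction explains ≈ 80% of the variance of
the true instantaneous threshold (numeric F-root with frozen gates) on the
same segments.

**Simulated voltage clamp.**  The Na-only channel (`clamp_demo.json`)
holds at −70 mV and steps to −100..+50 mV in 1 mV increments (20 ms, dt
0.01 ms; spacing and duration are not critical and are exposed — the 1 mV
grid moves the fitted slope by < 0.5%).  Gate trajectories at fixed voltage
are integrated in closed form; the conductance is read at the current peak
(earliest global maximum of |I|), converted with the known E_Na, excluded
within 5 mV of E_Na, normalized, and fitted to a Boltzmann strictly below
−40 mV.  The steady conductance activation curve is the stated Boltzmann
(V_a = −30, k_a = 6 mV) realized with the HH m³h convention (gate
equilibrium = cube root of the curve), so the separation-of-timescales
limit recovers k = 6 exactly while overlap between τ_h and τ_m = 0.3 ms
inflates the fitted slope: ≈ 54% at τ_h = 0.3 ms, ≈ 12% at 1 ms, < 2% once
τ_h/τ_m ≳ 30.  A single-gate transient would show a far weaker bias
(≈ 16% at equal time constants); the m³ convention is the package's
standard for sodium channels and reproduces the magnitude of the effect
this protocol exists to demonstrate.

**Inactivation-slope regression.**  With half-inactivation hyperpolarized
to ≈ −62 mV (near experimental values), Na conductance tripled and synaptic
σ doubled, spike-onset voltages span ~9 mV and regressing them on ln h at
onset gives a slope magnitude of ≈ 3.8 mV on 30 s runs — close to the
windowed k_a of 3.73 mV, as the theory demands (θ carries the term
−k_a ln h).  The magnitude sits slightly *above* k_a because h keeps
depleting during the upstroke before the dV/dt criterion is crossed,
which covaries mechanically with the onset voltage.

## Numerical choices

* Gates: exponential Euler (exact for piecewise-constant V); membrane
  voltage: forward Euler at dt = 0.025 ms by default, Heun (RK2) available.
  Gate equilibria and time constants are pre-tabulated on a 0.01 mV grid.
  Halving dt leaves spike counts unchanged; with RK2 at dt = 0.005 ms the
  first spike time converges below 0.05 ms (later spike times drift
  linearly with the accumulated period error, ~0.1 ms over 1 s).
* Boltzmann/exponential fits: bounded nonlinear least squares with a
  deterministic scale-aware initialization (V_half at half of the in-window
  maximum, k from the 25–75% rise span / ln 9) plus a fixed multi-start
  grid over slope starts — windowed fits of non-Boltzmann curves sit on a
  shallow (V_half, k) ridge with genuine local minima.  Identical inputs
  give bit-identical results; k is bounded to (0.1, 50) mV.
* h is floored at 1e−6 before any logarithm (−k_a ln h diverges during the
  spike, where the quasi-static theory is explicitly invalid); floored
  samples are counted and logged.  Spike windows (onset to onset + 7 ms)
  are excluded from all prediction-vs-measurement statistics.
* Probe trials are integrated as a vectorized ensemble sharing the frozen
  background arrays, so the 22k-trial protocol costs seconds.
* Randomness: `numpy` Generators seeded from an explicit seed per run;
  identical seeds reproduce conductance paths bit-identically.

## Known limitations

* The exponential-approximation closed forms carry a systematic bias
  (≈ 7 mV on the packaged model) whenever the threshold approaches V_a;
  the excitability-minimum anchoring corrects the offset but not the
  curvature mismatch.
* The quasi-static assumption fails within the spike and for inputs faster
  than ~1 ms; predictions there are extrapolations.
* The first-order threshold ODE is undefined across discontinuous resets;
  exact mode is the reference around spikes.
* Probe-based threshold measurement is escape-time limited: the measured
  level equals the true instantaneous threshold plus a window-dependent
  margin, and the choice of response window trades ladder coverage against
  that margin.
* The AIS Na-density inversion is the exact inverse of the package's V_T
  formula; densities inferred from onset-style (fast) threshold
  measurements will be underestimated unless the measurement is first
  converted to a slow-input threshold.
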