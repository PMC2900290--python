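# threshkit

Spike-threshold theory, dynamics and measurement for single-compartment
neuron models.

The voltage at which a neuron fires is not one number: it depends on how the
cell is driven (DC ramp, brief charge pulse, or the experimenter's dV/dt
onset criterion), and it moves from moment to moment with sodium-channel
inactivation, voltage-gated potassium conductances and synaptic bombardment.
`threshkit` implements a closed-form *threshold equation* that makes those
dependencies explicit, together with the simulation and measurement
machinery needed to test it on conductance-based models.

## The model

Near spike initiation, with instantaneous Na activation and the exponential
approximation of the Boltzmann activation curve, the membrane equation
reduces to an exponential integrate-and-fire form

```
C dV/dt = g_tot (E* − V) + g_tot k_a exp((V − θ)/k_a) + I
```

whose slow-input threshold (the minimum of the excitability curve,
F′(θ) = 0) is

```
θ = V_T − k_a ln h + k_a ln(g_tot / g_L),
V_T = V_a − k_a ln[ g_Na (E_Na − V_a) / (g_L k_a) ].
```

Here (V_a, k_a) are the midpoint and slope factor of the Na activation
curve, h the fraction of non-inactivated Na channels, and g_tot/E* the
summed non-Na conductance and its effective reversal potential.  The
threshold rises by k_a per e-fold drop in Na availability and per e-fold
rise in total conductance, and depends on channel densities only through
ratios.  Closed forms for the fast-input (charge) threshold and for the
dV/dt-criterion onset follow from the Lambert W function; numeric
root-finders on F are part of the API and are the normative definitions the
closed forms are tested against.

Because h and the conductances obey first-order kinetics, the threshold is
itself a dynamical variable: it relaxes toward an equilibrium θ∞(V) with
the inactivation time constant, and every action potential resets h
partially, raising the threshold by a fixed increment k_a·δ/τ̄.

The package ships a point-conductance surrogate (Traub–Miles m³h sodium
channel, delayed-rectifier n⁴ and slow non-inactivating K currents,
Ornstein–Uhlenbeck excitatory/inhibitory conductances) used by all
validation protocols: frozen-noise pulse-probe threshold measurement,
spike-onset detection, onset-vs-ln h regression, phase-plot sharpness
fitting, and a simulated voltage clamp that quantifies how overlap between
activation and inactivation kinetics biases the measured activation slope.

## Worked example

```python
import threshkit as tk
from threshkit.cli_io import calibrate_threshold_params

model, background = tk.destexhe_2001()
p = calibrate_threshold_params(model)        # Boltzmann fit over −51..−38 mV
print(f"windowed activation fit: V_a = {p.V_a:.1f} mV, k_a = {p.k_a:.2f} mV")
print(f"base threshold V_T      = {tk.base_threshold(p):.1f} mV")

state = tk.ThresholdState(
    h=0.7,                                   # 30% of Na channels inactivated
    conductances=((p.g_L, p.E_L), (12.1, 0.0), (57.3, -75.0)),
)
print(f"threshold (h=0.7, in-vivo load) = {tk.threshold(p, state):.1f} mV")
print(f"fast-input threshold            = {tk.fast_threshold(p, state):.1f} mV")
print(f"onset (dV/dt = 10 mV/ms)        = {tk.empirical_threshold(p, 10.0, s=state):.1f} mV")

geom = tk.GeometryParams(d=1.5, R_i=150.0, R_m=35000.0)
print(f"AIS electrotonic length = {tk.electrotonic_length(geom):.0f} um")
```

prints

```
windowed activation fit: V_a = -30.3 mV, k_a = 3.73 mV
base threshold V_T      = -67.8 mV
threshold (h=0.7, in-vivo load) = -60.1 mV
fast-input threshold            = -57.3 mV
onset (dV/dt = 10 mV/ms)        = -50.0 mV
AIS electrotonic length = 935 um
```

The in-vitro slow threshold of this model is −67.8 mV.  Under an in-vivo
synaptic load (total conductance ≈ 5.4× leak) with 30% of Na channels
inactivated, the instantaneous threshold rises to −60.1 mV; a brief charge
pulse must reach −57.3 mV to trigger a spike, and a 10 mV/ms onset
criterion would report −50.0 mV — three answers to "what is the threshold",
all related in closed form.  The 935 µm space constant shows that soma and
axon initial segment are effectively one compartment below threshold.

The `threshkit` command exposes the same machinery from the shell
(`simulate`, `predict`, `threshold-series`, `detect`, `probe`, `clamp`,
`fit`, `reproduce`); see `threshkit --help`.

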