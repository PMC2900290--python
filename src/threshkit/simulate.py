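"""Synthetic-data engines: point-conductance and exponential integrate-and-fire.

The workhorse is a single-compartment conductance-based neuron (transient Na
current m^3 h, delayed-rectifier K current n^4, slow non-inactivating K
current p) bombarded by excitatory and inhibitory synaptic conductances
modelled as Ornstein-Uhlenbeck processes -- the classic point-conductance
surrogate for in-vivo-like cortical input.  The packaged parameter set
(``destexhe2001.json``) reproduces the Destexhe et al. (2001) model: membrane
area 34636 um^2, C = 1 uF/cm^2, leak 0.045 mS/cm^2 at -80 mV, Traub-Miles
kinetics, Na 48 mS/cm^2 (E_Na = 50 mV), delayed rectifier 10 mS/cm^2, slow K
0.5 mS/cm^2, and the canonical fluctuating-conductance statistics
(g_e0 = 12.1 nS, sigma_e = 3 nS, tau_e = 2.728 ms; g_i0 = 57.3 nS,
sigma_i = 6.6 nS, tau_i = 10.49 ms).

Integration uses exponential Euler for the gating variables (exact for
piecewise-constant voltage) and forward Euler for V, at dt = 0.025 ms by
default; a second-order Heun step is available.  Gate equilibria and time
constants are pre-tabulated on a 0.01 mV grid, which keeps the per-step cost
low without approximating the kinetics beyond the integration scheme itself.

Frozen noise: passing the same seed reproduces the synaptic conductance
paths bit-identically, which is what the repeated-trial threshold-probing
protocol requires.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .channels import GateModel, NaChannel, gate_tau, gate_value
from .errors import InstabilityError, ParameterError, SchemaError
from .theory import ThresholdParams, base_threshold

logger = logging.getLogger("threshkit")

__all__ = [
    "Trace",
    "Channel",
    "MembraneModel",
    "SynapticBackground",
    "ou_process",
    "simulate_membrane",
    "simulate_eif",
    "apply_modifications",
    "load_membrane_json",
    "destexhe_2001",
]

SPIKE_DETECT_MV = -20.0  # bookkeeping crossing; onset measurement is measure's job
SPIKE_LOCKOUT_MS = 2.0

_TABLE_VMIN, _TABLE_VMAX, _TABLE_DV = -150.0, 100.0, 0.01


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class Trace:
    """Uniformly sampled simulation record (units: ms, mV, nS, pA)."""

    dt: float
    V: np.ndarray
    m: Optional[np.ndarray] = None
    h: Optional[np.ndarray] = None
    n: Optional[np.ndarray] = None
    p: Optional[np.ndarray] = None
    g_e: Optional[np.ndarray] = None
    g_i: Optional[np.ndarray] = None
    I: Optional[np.ndarray] = None
    spikes: np.ndarray = field(default_factory=lambda: np.empty(0))  # onset times, ms
    extra: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")
        n = self.V.size
        for name in ("m", "h", "n", "p", "g_e", "g_i", "I"):
            arr = getattr(self, name)
            if arr is not None and np.asarray(arr).size != n:
                raise ParameterError(f"column {name} length mismatch")

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.V.size) * self.dt

    def to_frame(self) -> pd.DataFrame:
        cols = {"t_ms": self.t, "V_mV": self.V}
        for name, col in (
            ("m", "m"),
            ("h", "h"),
            ("n", "n"),
            ("p", "p"),
            ("g_e", "ge_nS"),
            ("g_i", "gi_nS"),
            ("I", "I_pA"),
        ):
            arr = getattr(self, name)
            if arr is not None:
                cols[col] = arr
        for k, v in self.extra.items():
            cols[k] = v
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class Channel:
    """One non-Na voltage-gated channel: g_max * gate^exponent * (E - V)."""

    g_max: float  # nS
    E_rev: float  # mV
    gate: GateModel

    def __post_init__(self):
        if self.g_max < 0:
            raise ParameterError("g_max must be >= 0")


@dataclass(frozen=True)
class MembraneModel:
    """Single-compartment conductance-based neuron."""

    C: float  # pF
    g_L: float  # nS
    E_L: float  # mV
    Na: NaChannel
    K_delayed: Optional[Channel] = None
    K_slow: Optional[Channel] = None
    area_um2: Optional[float] = None

    def __post_init__(self):
        if self.C <= 0 or self.g_L <= 0:
            raise ParameterError("C and g_L must be > 0")

    def threshold_params(self, V_a: float, k_a: float) -> ThresholdParams:
        """Bundle this model's densities with a fitted activation curve."""
        return ThresholdParams(
            V_a=V_a, k_a=k_a, g_Na=self.Na.g_max, g_L=self.g_L, E_Na=self.Na.E_rev,
            C=self.C, E_L=self.E_L,
        )


@dataclass(frozen=True)
class SynapticBackground:
    """Ornstein-Uhlenbeck excitatory/inhibitory conductance background."""

    g_e0: float  # nS
    sigma_e: float  # nS
    tau_e: float  # ms
    E_e: float  # mV
    g_i0: float  # nS
    sigma_i: float  # nS
    tau_i: float  # ms
    E_i: float  # mV

    def __post_init__(self):
        if self.sigma_e < 0 or self.sigma_i < 0:
            raise ParameterError("sigma must be >= 0")
        if self.tau_e <= 0 or self.tau_i <= 0:
            raise ParameterError("tau must be > 0")

    def sample(self, n_steps: int, dt: float, rng: np.random.Generator):
        """Draw (g_e, g_i) paths; negative excursions are clipped at 0.

        Returns (g_e, g_i, n_clip) where n_clip counts clipped samples (the
        inhibitory conductance cannot be negative, so clip frequency is
        monitored and logged).
        """
        ge, ne = _ou_clipped(self.g_e0, self.sigma_e, self.tau_e, dt, n_steps, rng, self.g_e0)
        gi, ni = _ou_clipped(self.g_i0, self.sigma_i, self.tau_i, dt, n_steps, rng, self.g_i0)
        n_clip = ne + ni
        if n_clip:
            logger.warning(
                "synaptic background: clipped %d negative conductance sample(s) (%.3g%%)",
                n_clip,
                100.0 * n_clip / (2 * n_steps),
            )
        return ge, gi, n_clip


def ou_process(
    mean: float,
    sigma: float,
    tau: float,
    dt: float,
    n_steps: int,
    rng: Union[int, np.random.Generator],
    x0: Optional[float] = None,
) -> np.ndarray:
    """Ornstein-Uhlenbeck path by exact discretization.

    x(t+dt) = mean + (x - mean) e^(-dt/tau) + sigma sqrt(1 - e^(-2 dt/tau)) xi,
    which has the process's exact transition density, so the stationary mean
    and standard deviation equal ``mean`` and ``sigma`` for any dt.
    """
    if tau <= 0 or dt <= 0:
        raise ParameterError("tau and dt must be > 0")
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    a = math.exp(-dt / tau)
    b = sigma * math.sqrt(1.0 - a * a)
    x = np.empty(n_steps)
    x[0] = mean if x0 is None else float(x0)
    if sigma == 0.0:
        for i in range(1, n_steps):
            x[i] = mean + (x[i - 1] - mean) * a
        return x
    xi = rng.standard_normal(n_steps - 1)
    # AR(1) recursion x_i = a x_{i-1} + c_i via a stable linear filter
    c = mean * (1.0 - a) + b * xi
    x[1:], _ = lfilter([1.0], [1.0, -a], c, zi=np.array([a * x[0]]))
    return x


def _ou_clipped(
    mean: float, sigma: float, tau: float, dt: float, n_steps: int,
    rng: np.random.Generator, x0: float,
) -> Tuple[np.ndarray, int]:
    """OU path with the nonnegativity clip applied after every step.

    The unclipped exact-discretization path is tried first; only when it
    actually goes negative is the recursion re-run sequentially with the
    same noise increments, clipping at 0 inside the loop (conductances are
    physically nonnegative, so the clipped value feeds the next step).
    """
    a = math.exp(-dt / tau)
    b = sigma * math.sqrt(1.0 - a * a)
    rng_state = rng.bit_generator.state
    x = ou_process(mean, sigma, tau, dt, n_steps, rng, x0=x0)
    if not np.any(x < 0.0):
        return x, 0
    rng.bit_generator.state = rng_state
    xi = rng.standard_normal(n_steps - 1)
    x = np.empty(n_steps)
    x[0] = max(x0, 0.0)
    n_clip = 0
    drift = mean * (1.0 - a)
    prev = x[0]
    for i in range(1, n_steps):
        v = drift + a * prev + b * xi[i - 1]
        if v < 0.0:
            v = 0.0
            n_clip += 1
        x[i] = v
        prev = v
    return x, n_clip


# --------------------------------------------------------------------------
# Gate lookup tables
# --------------------------------------------------------------------------

def _gate_tables(gate: GateModel):
    Vg = np.arange(_TABLE_VMIN, _TABLE_VMAX + _TABLE_DV, _TABLE_DV)
    return np.asarray(gate_value(gate, Vg), float), np.asarray(gate_tau(gate, Vg), float)


def _vidx(V: np.ndarray) -> np.ndarray:
    idx = np.rint((np.asarray(V) - _TABLE_VMIN) / _TABLE_DV).astype(np.int64)
    n = int((_TABLE_VMAX - _TABLE_VMIN) / _TABLE_DV) + 1
    return np.clip(idx, 0, n - 1)


class _ModelTables:
    """Pre-tabulated x_inf and exp(-dt/tau) for every gate of a model."""

    def __init__(self, model: MembraneModel, dt: float):
        self.gates = {}
        specs = {"m": model.Na.activation}
        if model.Na.inactivation is not None:
            specs["h"] = model.Na.inactivation
        if model.K_delayed is not None:
            specs["n"] = model.K_delayed.gate
        if model.K_slow is not None:
            specs["p"] = model.K_slow.gate
        for name, gate in specs.items():
            xinf, tau = _gate_tables(gate)
            self.gates[name] = (xinf, np.exp(-dt / tau), gate.exponent)

    def equilibrium(self, V0: float) -> Dict[str, float]:
        i = int(_vidx(np.array([V0]))[0])
        return {name: tabs[0][i] for name, tabs in self.gates.items()}


# --------------------------------------------------------------------------
# Conductance-based simulation
# --------------------------------------------------------------------------

def _current_input(I, n_steps: int) -> np.ndarray:
    if I is None:
        return np.zeros(n_steps)
    if np.ndim(I) == 0:
        return np.full(n_steps, float(I))
    I = np.asarray(I, dtype=float)
    if I.size < n_steps:
        raise ParameterError("injected current array shorter than the simulation")
    return I[:n_steps]


def simulate_membrane(
    model: MembraneModel,
    background: Optional[SynapticBackground] = None,
    I=None,
    duration: float = 1000.0,
    dt: float = 0.025,
    seed: Optional[int] = None,
    frozen: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    V0: Optional[float] = None,
    integrator: str = "euler",
) -> Trace:
    """Integrate the full conductance-based membrane equation.

    ``background`` draws fresh OU conductance paths from ``seed``;
    ``frozen=(g_e, g_i)`` replays stored paths instead (bit-identical across
    calls).  ``I`` is an injected current in pA (scalar or per-step array).
    Raises :class:`InstabilityError` on numerical blow-up (|V| > 200 mV).
    """
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    if integrator not in ("euler", "rk2"):
        raise ParameterError("integrator must be 'euler' or 'rk2'")
    n_steps = int(round(duration / dt))
    tabs = _ModelTables(model, dt)

    if frozen is not None:
        ge, gi = np.asarray(frozen[0], float), np.asarray(frozen[1], float)
        if ge.size < n_steps or gi.size < n_steps:
            raise ParameterError("frozen background shorter than the simulation")
        ge, gi = ge[:n_steps], gi[:n_steps]
        E_e = background.E_e if background is not None else 0.0
        E_i = background.E_i if background is not None else -75.0
    elif background is not None:
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        ge, gi, _ = background.sample(n_steps, dt, rng)
        E_e, E_i = background.E_e, background.E_i
    else:
        ge = gi = None
        E_e = E_i = 0.0

    I_arr = _current_input(I, n_steps)
    V = np.empty(n_steps)
    V[0] = model.E_L if V0 is None else float(V0)
    gate_names = list(tabs.gates)
    rec = {name: np.empty(n_steps) for name in gate_names}
    state = tabs.equilibrium(V[0])
    for name in gate_names:
        rec[name][0] = state[name]

    g_Na, E_Na = model.Na.g_max, model.Na.E_rev
    gKd = model.K_delayed.g_max if model.K_delayed else 0.0
    EKd = model.K_delayed.E_rev if model.K_delayed else 0.0
    gM = model.K_slow.g_max if model.K_slow else 0.0
    EM = model.K_slow.E_rev if model.K_slow else 0.0
    gL, EL, C = model.g_L, model.E_L, model.C
    p_m = tabs.gates["m"][2]
    has_h = "h" in tabs.gates
    p_n = tabs.gates["n"][2] if "n" in tabs.gates else 0
    p_p = tabs.gates["p"][2] if "p" in tabs.gates else 0

    spikes = []
    last_spike = -np.inf

    def dVdt(v, st, k):
        i_ion = gL * (EL - v)
        na_open = st["m"] ** p_m * (st["h"] if has_h else 1.0)
        i_ion += g_Na * na_open * (E_Na - v)
        if gKd:
            i_ion += gKd * st["n"] ** p_n * (EKd - v)
        if gM:
            i_ion += gM * st["p"] ** p_p * (EM - v)
        if ge is not None:
            i_ion += ge[k] * (E_e - v) + gi[k] * (E_i - v)
        return (i_ion + I_arr[k]) / C

    v = V[0]
    for k in range(1, n_steps):
        i = int(round((v - _TABLE_VMIN) / _TABLE_DV))
        i = 0 if i < 0 else (25000 if i > 25000 else i)
        for name in gate_names:
            xinf, decay, _ = tabs.gates[name]
            state[name] = xinf[i] + (state[name] - xinf[i]) * decay[i]
        if integrator == "euler":
            v_new = v + dt * dVdt(v, state, k - 1)
        else:  # Heun / RK2
            k1 = dVdt(v, state, k - 1)
            k2 = dVdt(v + dt * k1, state, k)
            v_new = v + 0.5 * dt * (k1 + k2)
        if abs(v_new) > 200.0:
            raise InstabilityError(
                f"|V| exceeded 200 mV at t = {k * dt:.3f} ms; reduce dt"
            )
        t_now = k * dt
        if v_new >= SPIKE_DETECT_MV > v and t_now - last_spike >= SPIKE_LOCKOUT_MS:
            spikes.append(t_now)
            last_spike = t_now
        v = v_new
        V[k] = v
        for name in gate_names:
            rec[name][k] = state[name]

    return Trace(
        dt=dt,
        V=V,
        m=rec.get("m"),
        h=rec.get("h"),
        n=rec.get("n"),
        p=rec.get("p"),
        g_e=ge,
        g_i=gi,
        I=I_arr,
        spikes=np.asarray(spikes),
    )


def integrate_ensemble(
    model: MembraneModel,
    V_init: np.ndarray,
    gate_init: Dict[str, np.ndarray],
    ge_path: Optional[np.ndarray],
    gi_path: Optional[np.ndarray],
    start_indices: np.ndarray,
    n_steps: int,
    dt: float,
    E_e: float = 0.0,
    E_i: float = -75.0,
    I=None,
    spike_mV: float = SPIKE_DETECT_MV,
) -> np.ndarray:
    """Integrate many trials of the same model in parallel; report who spiked.

    Trial ``i`` starts from (V_init[i], gate_init[*][i]) and is driven by the
    frozen background slice starting at ``start_indices[i]``.  Used by the
    pulse-probe protocol, where thousands of trials differ only in their
    initial depolarization and probe time.  Returns a boolean array marking
    trials whose V crossed ``spike_mV`` upward within the window.
    """
    tabs = _ModelTables(model, dt)
    V = np.array(V_init, dtype=float)
    state = {k: np.array(v, dtype=float) for k, v in gate_init.items()}
    start = np.asarray(start_indices, dtype=np.int64)
    g_Na, E_Na = model.Na.g_max, model.Na.E_rev
    gKd = model.K_delayed.g_max if model.K_delayed else 0.0
    EKd = model.K_delayed.E_rev if model.K_delayed else 0.0
    gM = model.K_slow.g_max if model.K_slow else 0.0
    EM = model.K_slow.E_rev if model.K_slow else 0.0
    p_m = tabs.gates["m"][2]
    has_h = "h" in tabs.gates
    I_scalar = 0.0 if I is None else float(I)
    spiked = V >= spike_mV
    below = ~spiked
    for k in range(1, n_steps):
        idx = _vidx(V)
        for name, (xinf, decay, _) in tabs.gates.items():
            xi = xinf[idx]
            state[name] = xi + (state[name] - xi) * decay[idx]
        i_ion = model.g_L * (model.E_L - V)
        na_open = state["m"] ** p_m * (state["h"] if has_h else 1.0)
        i_ion += g_Na * na_open * (E_Na - V)
        if gKd:
            i_ion += gKd * state["n"] ** tabs.gates["n"][2] * (EKd - V)
        if gM:
            i_ion += gM * state["p"] ** tabs.gates["p"][2] * (EM - V)
        if ge_path is not None:
            j = start + (k - 1)
            i_ion += ge_path[j] * (E_e - V) + gi_path[j] * (E_i - V)
        V = V + dt * (i_ion + I_scalar) / model.C
        crossed = below & (V >= spike_mV)
        spiked |= crossed
        below = V < spike_mV
    return spiked


# --------------------------------------------------------------------------
# Exponential integrate-and-fire
# --------------------------------------------------------------------------

def simulate_eif(
    p: ThresholdParams,
    I=None,
    duration: float = 1000.0,
    dt: float = 0.025,
    V0: Optional[float] = None,
    V_reset: float = -70.0,
    V_peak: float = 0.0,
    refractory: float = 0.0,
) -> Trace:
    """Exponential integrate-and-fire model with spike-and-reset bookkeeping.

    C dV/dt = g_L (E_L - V) + g_L k_a exp((V - V_T)/k_a) + I; when V reaches
    ``V_peak`` a spike time is recorded and V is reset.  V_T is the base
    threshold of ``p``, so the model is the reduction of the threshold
    theory's membrane equation with h = 1 and leak only.
    """
    n_steps = int(round(duration / dt))
    I_arr = _current_input(I, n_steps)
    VT = base_threshold(p)
    V = np.empty(n_steps)
    V[0] = p.E_L if V0 is None else float(V0)
    spikes = []
    hold_until = -np.inf
    v = V[0]
    for k in range(1, n_steps):
        t_now = k * dt
        if t_now < hold_until:
            V[k] = V_reset
            v = V_reset
            continue
        dv = (p.g_L * (p.E_L - v) + p.g_L * p.k_a * math.exp((v - VT) / p.k_a) + I_arr[k - 1]) / p.C
        v = v + dt * dv
        if v >= V_peak:
            spikes.append(t_now)
            V[k] = V_peak  # keep the spike sample visible in the record
            v = V_reset
            hold_until = t_now + refractory
            continue
        V[k] = v
    return Trace(dt=dt, V=V, I=I_arr, spikes=np.asarray(spikes))


# --------------------------------------------------------------------------
# Parameter modifications and model loading
# --------------------------------------------------------------------------

def apply_modifications(
    model: MembraneModel,
    shift_Vi: float = 0.0,
    scale_gNa: float = 1.0,
    scale_sigma: float = 1.0,
    background: Optional[SynapticBackground] = None,
):
    """Return modified copies of the model (and background, if given).

    ``shift_Vi`` displaces the Na inactivation curve (negative values
    hyperpolarize it, promoting inactivation and threshold variability),
    ``scale_gNa`` multiplies the maximal Na conductance, ``scale_sigma``
    multiplies both synaptic conductance standard deviations.  The originals
    are untouched.
    """
    if scale_gNa <= 0 or scale_sigma <= 0:
        raise ParameterError("scale factors must be > 0")
    na = model.Na
    if shift_Vi != 0.0:
        if na.inactivation is None:
            raise ParameterError("model has no Na inactivation gate to shift")
        na = replace(na, inactivation=na.inactivation.shifted(shift_Vi))
    na = replace(na, g_max=na.g_max * scale_gNa)
    new_model = replace(model, Na=na)
    if background is None:
        return new_model
    new_bg = replace(
        background,
        sigma_e=background.sigma_e * scale_sigma,
        sigma_i=background.sigma_i * scale_sigma,
    )
    return new_model, new_bg


def _gate_from_dict(d: dict, polarity: str) -> GateModel:
    known = {"rates", "exponent", "V_half_mV", "k_mV", "tau_ms", "curve", "V_shift_mV"}
    unknown = set(d) - known
    if unknown:
        raise SchemaError(f"unknown gate keys: {sorted(unknown)}")
    return GateModel(
        polarity=polarity,
        V_half=d.get("V_half_mV"),
        k=d.get("k_mV"),
        tau=d.get("tau_ms"),
        rates=d.get("rates"),
        exponent=int(d.get("exponent", 1)),
        curve=d.get("curve", "gate"),
        V_shift=float(d.get("V_shift_mV", 0.0)),
    )


def load_membrane_json(source) -> Tuple[MembraneModel, Optional[SynapticBackground]]:
    """Build a MembraneModel (+ background) from a JSON description.

    Densities are given per membrane area (mS/cm^2, uF/cm^2) together with
    the area in um^2; they are converted to total conductances (nS) and
    capacitance (pF) here.  ``source`` is a path, file object or dict.
    """
    if isinstance(source, dict):
        cfg = source
    elif hasattr(source, "read"):
        cfg = json.load(source)
    else:
        with open(source) as fh:
            cfg = json.load(fh)
    try:
        area_cm2 = cfg["area_um2"] * 1e-8
        C = cfg["C_uF_cm2"] * area_cm2 * 1e6  # uF -> pF
        gL = cfg["g_L_mS_cm2"] * area_cm2 * 1e6  # mS -> nS
        na_cfg = cfg["Na"]
        na = NaChannel(
            g_max=na_cfg["G_mS_cm2"] * area_cm2 * 1e6,
            E_rev=na_cfg["E_mV"],
            activation=_gate_from_dict(na_cfg["m"], "activation"),
            inactivation=_gate_from_dict(na_cfg["h"], "inactivation") if "h" in na_cfg else None,
        )
        kd = None
        if "Kd" in cfg:
            kd = Channel(
                g_max=cfg["Kd"]["G_mS_cm2"] * area_cm2 * 1e6,
                E_rev=cfg["Kd"]["E_mV"],
                gate=_gate_from_dict(cfg["Kd"]["n"], "activation"),
            )
        km = None
        if "M" in cfg:
            km = Channel(
                g_max=cfg["M"]["G_mS_cm2"] * area_cm2 * 1e6,
                E_rev=cfg["M"]["E_mV"],
                gate=_gate_from_dict(cfg["M"]["p"], "activation"),
            )
        model = MembraneModel(
            C=C, g_L=gL, E_L=cfg["E_L_mV"], Na=na, K_delayed=kd, K_slow=km,
            area_um2=cfg["area_um2"],
        )
        bg = None
        if "background" in cfg:
            b = cfg["background"]
            bg = SynapticBackground(
                g_e0=b["g_e0_nS"], sigma_e=b["sigma_e_nS"], tau_e=b["tau_e_ms"], E_e=b["E_e_mV"],
                g_i0=b["g_i0_nS"], sigma_i=b["sigma_i_nS"], tau_i=b["tau_i_ms"], E_i=b["E_i_mV"],
            )
    except KeyError as err:
        raise SchemaError(f"membrane JSON missing key: {err}") from err
    return model, bg


def destexhe_2001() -> Tuple[MembraneModel, SynapticBackground]:
    """The packaged point-conductance model with its synaptic background."""
    ref = resources.files("threshkit.data").joinpath("destexhe2001.json")
    with ref.open() as fh:
        model, bg = load_membrane_json(fh)
    assert bg is not None
    return model, bg
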