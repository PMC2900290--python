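"""Threshold dynamics along a membrane-potential trace.

The threshold equation gives an instantaneous threshold once the modulating
variables (Na inactivation h, K-channel gates, synaptic conductances) are
known.  Because those variables obey first-order kinetics driven by V(t), the
threshold itself becomes a dynamical variable: it relaxes toward an
equilibrium value theta_inf(V) with the inactivation time constant tau_h(V),
rises after every action potential (partial reset of h, or K-gate activation)
and decays back between spikes.

Two prediction modes are provided.  ``exact`` integrates the gating variables
along the trace and maps them through the threshold equation at every sample
-- this is the reference.  ``first_order`` integrates
d(theta)/dt = (theta_inf(V) - theta)/tau_h(V) directly; it is a good
approximation only while the threshold stays within ~k_a of its steady state,
and is provided for analysis, not as the reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .channels import GateModel, gate_tau, gate_value
from .errors import ParameterError, ResolutionError
from .theory import ThresholdParams, ThresholdState, base_threshold, threshold

logger = logging.getLogger("threshkit")

__all__ = [
    "ThresholdSeries",
    "integrate_gate",
    "theta_equilibrium",
    "integrate_threshold",
    "spike_reset_h",
    "spike_reset_n",
    "k_gate_threshold_ode",
    "H_FLOOR",
]

#: Na availability is clipped here before taking logarithms; during the spike
#: h collapses toward 0 and -k_a ln h would diverge, but the quasi-static
#: theory is explicitly invalid inside the spike anyway.
H_FLOOR = 1e-6


@dataclass
class ThresholdSeries:
    """Time-resolved threshold prediction with per-mechanism contributions.

    ``components`` maps mechanism names to additive contributions in mV:
    ``theta_act`` (the static V_T), ``theta_h`` (-k_a ln h), ``theta_K``
    (K-conductance term) and ``theta_syn`` (synaptic-conductance term);
    their sum equals ``theta`` in exact mode.  ``n_clipped`` counts samples
    where h hit the floor.
    """

    t: np.ndarray  # ms
    theta: np.ndarray  # mV
    components: Dict[str, np.ndarray]
    mode: str
    n_clipped: int = 0


def _as_arrays(V_trace) -> Tuple[np.ndarray, float]:
    """Accept a Trace-like object (``.V``, ``.dt``) or a (V, dt) tuple."""
    if hasattr(V_trace, "V") and hasattr(V_trace, "dt"):
        return np.asarray(V_trace.V, dtype=float), float(V_trace.dt)
    V, dt = V_trace
    return np.asarray(V, dtype=float), float(dt)


def integrate_gate(
    gate: GateModel,
    V_trace,
    x0: Optional[float] = None,
    check_dt: bool = True,
) -> np.ndarray:
    """Integrate dx/dt = (x_inf(V) - x)/tau(V) along a voltage trace.

    Uses the exponential-Euler update
    x <- x_inf + (x - x_inf) exp(-dt/tau), which is exact for piecewise
    constant V and keeps x inside (0, 1) unconditionally.  ``x0`` defaults to
    the equilibrium at the first sample.
    """
    V, dt = _as_arrays(V_trace)
    xinf = np.asarray(gate_value(gate, V), dtype=float)
    tau = np.asarray(gate_tau(gate, V), dtype=float)
    if check_dt:
        tau_min = float(np.min(tau))
        if dt >= tau_min / 5.0:
            raise ResolutionError(
                f"dt = {dt} ms too coarse: min tau over the trace is {tau_min:.4g} ms"
            )
    decay = np.exp(-dt / tau)
    x = np.empty_like(V)
    x[0] = xinf[0] if x0 is None else float(x0)
    for i in range(1, V.size):
        x[i] = xinf[i] + (x[i - 1] - xinf[i]) * decay[i]
    return x


def theta_equilibrium(
    p: ThresholdParams,
    gate_h: GateModel,
    V,
    extra_conductances: Sequence[Tuple[float, float]] = (),
):
    """Equilibrium threshold theta_inf(V): threshold at h = h_inf(V).

    As V rises, Na channels inactivate and theta_inf rises with it -- the
    threshold adapts to the membrane potential.  For strongly depolarized V,
    h_inf underflows and is clipped at :data:`H_FLOOR` (with a warning).
    ``extra_conductances`` are static (g, E) pairs added on top of the leak.
    """
    hinf = np.asarray(gate_value(gate_h, V), dtype=float)
    n_clip = int(np.sum(hinf < H_FLOOR))
    if n_clip:
        logger.warning("theta_equilibrium: h_inf clipped at %g for %d sample(s)", H_FLOOR, n_clip)
    hinf = np.clip(hinf, H_FLOOR, 1.0)
    g_tot = p.g_L + sum(g for g, _ in extra_conductances)
    VT = base_threshold(p)
    out = VT - p.k_a * np.log(hinf) + p.k_a * math.log(g_tot / p.g_L)
    return out if np.ndim(out) else float(out)


def integrate_threshold(
    p: ThresholdParams,
    gate_h: GateModel,
    V_trace,
    mode: str = "exact",
    k_channels: Sequence[Tuple[float, float, GateModel]] = (),
    syn_conductances: Optional[Sequence[Tuple[np.ndarray, float]]] = None,
    h0: Optional[float] = None,
) -> ThresholdSeries:
    """Time-varying threshold prediction along a voltage trace.

    Parameters
    ----------
    gate_h : Na inactivation gate (integrated along the trace).
    k_channels : (g_max nS, E mV, GateModel) triples for voltage-gated
        non-Na channels; their gates are integrated along the trace and their
        conductance g_max * x^exponent enters g_tot(t).
    syn_conductances : (g(t) array in nS, E mV) pairs of synaptic
        conductances sampled on the same grid, entering g_tot(t) directly.
    mode : ``"exact"`` maps integrated gate values through the threshold
        equation pointwise; ``"first_order"`` integrates
        d(theta)/dt = (theta_inf - theta)/tau_h instead (h-driven part only,
        conductance terms are added quasi-statically).
    """
    V, dt = _as_arrays(V_trace)
    t = np.arange(V.size) * dt
    VT = base_threshold(p)

    g_K = np.zeros_like(V)
    for g_max, _E, gate in k_channels:
        x = integrate_gate(gate, (V, dt))
        g_K = g_K + g_max * x**gate.exponent
    g_syn = np.zeros_like(V)
    if syn_conductances:
        for g_arr, _E in syn_conductances:
            g_arr = np.asarray(g_arr, dtype=float)
            if g_arr.shape != V.shape:
                raise ParameterError("synaptic conductance arrays must match the trace length")
            g_syn = g_syn + g_arr

    g_tot = p.g_L + g_K + g_syn
    comp_act = np.full_like(V, VT)
    comp_K = p.k_a * np.log((p.g_L + g_K) / p.g_L)
    comp_syn = p.k_a * np.log(g_tot / (p.g_L + g_K))

    if mode == "exact":
        h = integrate_gate(gate_h, (V, dt), x0=h0)
        n_clip = int(np.sum(h < H_FLOOR))
        h = np.clip(h, H_FLOOR, 1.0)
        comp_h = -p.k_a * np.log(h)
        theta_t = comp_act + comp_h + comp_K + comp_syn
    elif mode == "first_order":
        hinf = np.clip(np.asarray(gate_value(gate_h, V), dtype=float), H_FLOOR, 1.0)
        tau = np.asarray(gate_tau(gate_h, V), dtype=float)
        n_clip = int(np.sum(hinf <= H_FLOOR))
        theta_inf = comp_act - p.k_a * np.log(hinf)
        th = np.empty_like(V)
        th[0] = theta_inf[0] if h0 is None else VT - p.k_a * math.log(h0)
        decay = np.exp(-dt / tau)
        for i in range(1, V.size):
            th[i] = theta_inf[i] + (th[i - 1] - theta_inf[i]) * decay[i]
        comp_h = th - comp_act
        theta_t = th + comp_K + comp_syn
    else:
        raise ParameterError(f"unknown mode {mode!r}")

    if n_clip:
        logger.warning("integrate_threshold: h clipped at %g for %d sample(s)", H_FLOOR, n_clip)
    return ThresholdSeries(
        t=t,
        theta=theta_t,
        components={
            "theta_act": comp_act,
            "theta_h": comp_h,
            "theta_K": comp_K,
            "theta_syn": comp_syn,
        },
        mode=mode,
        n_clipped=n_clip,
    )


def spike_reset_h(h: float, delta_spike: float, tau_bar: float) -> float:
    """Partial reset of Na availability by one action potential.

    During the spike h relaxes toward 0 with mean time constant ``tau_bar``
    for a duration ``delta_spike``, hence h -> h exp(-delta_spike/tau_bar).
    The corresponding threshold shift +k_a delta_spike/tau_bar is the same
    for every spike, so consecutive spikes raise the threshold by equal
    increments.
    """
    if not (0.0 < h <= 1.0):
        raise ParameterError("h must lie in (0, 1]")
    if delta_spike < 0 or tau_bar <= 0:
        raise ParameterError("delta_spike must be >= 0 and tau_bar > 0")
    return h * math.exp(-delta_spike / tau_bar)


def spike_reset_n(n: float, delta_spike: float, tau_bar: float) -> float:
    """K-gate reset by one action potential: n relaxes toward 1 during the spike.

    n -> 1 - (1 - n) exp(-delta_spike/tau_bar).  The induced threshold
    increase saturates as n approaches 1, so unlike the Na-inactivation
    shift it is not additive across spikes.
    """
    if not (0.0 <= n <= 1.0):
        raise ParameterError("n must lie in [0, 1]")
    if delta_spike < 0 or tau_bar <= 0:
        raise ParameterError("delta_spike must be >= 0 and tau_bar > 0")
    return 1.0 - (1.0 - n) * math.exp(-delta_spike / tau_bar)


def k_gate_threshold_ode(
    p: ThresholdParams,
    k_gate: GateModel,
    g_K_max: float,
    V_trace,
    spike_onsets_ms: Sequence[float] = (),
    delta_spike: float = 7.0,
    tau_bar: Optional[float] = None,
) -> ThresholdSeries:
    """Threshold dynamics driven by a slow K conductance (Na inactivation neglected).

    Integrates the K activation gate n along the trace and maps it through the
    threshold equation with g_tot = g_L + g_K_max n^exponent.  If
    ``spike_onsets_ms`` are supplied (e.g. for a spike-stripped trace), the
    reset n -> 1 - (1-n) exp(-delta_spike/tau_bar) is applied at each onset,
    emulating the gate's relaxation toward 1 during the omitted spike.
    """
    if g_K_max < 0:
        raise ParameterError("g_K_max must be >= 0")
    V, dt = _as_arrays(V_trace)
    reset_at = {int(round(t_on / dt)) for t_on in spike_onsets_ms}
    tb = tau_bar if tau_bar is not None else float(np.min(gate_tau(k_gate, V)))
    xinf = np.asarray(gate_value(k_gate, V), dtype=float)
    tau = np.asarray(gate_tau(k_gate, V), dtype=float)
    decay = np.exp(-dt / tau)
    n = np.empty_like(V)
    n[0] = xinf[0]
    for i in range(1, V.size):
        n[i] = xinf[i] + (n[i - 1] - xinf[i]) * decay[i]
        if i in reset_at:
            n[i] = spike_reset_n(n[i], delta_spike, tb)
    g_K = g_K_max * n**k_gate.exponent
    VT = base_threshold(p)
    comp_K = p.k_a * np.log((p.g_L + g_K) / p.g_L)
    theta_t = VT + comp_K
    t = np.arange(V.size) * dt
    return ThresholdSeries(
        t=t,
        theta=theta_t,
        components={
            "theta_act": np.full_like(V, VT),
            "theta_h": np.zeros_like(V),
            "theta_K": comp_K,
            "theta_syn": np.zeros_like(V),
        },
        mode="exact",
    )
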