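"""Gating-variable models and activation-curve measurement.

Voltage-gated channels are described by independent gating variables x with
first-order kinetics dx/dt = (x_inf(V) - x)/tau(V).  The equilibrium curve
x_inf is either a Boltzmann function (midpoint ``V_half``, slope factor ``k``)
or derived from Hodgkin-Huxley forward/backward rate functions alpha, beta via
x_inf = alpha/(alpha+beta), tau = 1/(alpha+beta).  The open fraction of a
channel is the product of its gating variables raised to their exponents
(m^3 h for the standard Na channel, n^4 for the delayed rectifier).

The module also provides the measurement side: least-squares Boltzmann and
exponential fits of activation curves restricted to a voltage window, a
window-position sensitivity sweep, and a simulated voltage-clamp protocol that
quantifies how overlap between activation and inactivation kinetics biases the
fitted activation slope.

Units package-wide: mV, ms, nS, pA, pF.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    DegenerateDataError,
    FitError,
    ParameterError,
    ResolutionError,
)

logger = logging.getLogger("threshkit")

__all__ = [
    "GateModel",
    "NaChannel",
    "FitResult",
    "RATE_FUNCTIONS",
    "gate_value",
    "gate_tau",
    "boltzmann",
    "exp_activation",
    "fit_boltzmann",
    "fit_exponential",
    "window_sensitivity",
    "simulate_voltage_clamp",
    "ka_bias_curve",
]


# --------------------------------------------------------------------------
# Hodgkin-Huxley rate functions (registry)
# --------------------------------------------------------------------------

def _vtrap(x: np.ndarray, scale: float) -> np.ndarray:
    """x / (exp(x/scale) - 1) with the x -> 0 singularity removed."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        np.abs(x) < 1e-9, scale * np.ones_like(x), x / np.expm1(np.where(np.abs(x) < 1e-9, 1.0, x) / scale)
    )
    return out


def _traub_alpha_m(v, vtraub=-63.0):
    x = 13.0 - (np.asarray(v, float) - vtraub)
    return 0.32 * _vtrap(x, 4.0)


def _traub_beta_m(v, vtraub=-63.0):
    x = (np.asarray(v, float) - vtraub) - 40.0
    return 0.28 * _vtrap(x, 5.0)


def _traub_alpha_h(v, vtraub=-63.0):
    v2 = np.asarray(v, float) - vtraub
    return 0.128 * np.exp((17.0 - v2) / 18.0)


def _traub_beta_h(v, vtraub=-63.0):
    v2 = np.asarray(v, float) - vtraub
    return 4.0 / (1.0 + np.exp((40.0 - v2) / 5.0))


def _traub_alpha_n(v, vtraub=-63.0):
    x = 15.0 - (np.asarray(v, float) - vtraub)
    return 0.032 * _vtrap(x, 5.0)


def _traub_beta_n(v, vtraub=-63.0):
    v2 = np.asarray(v, float) - vtraub
    return 0.5 * np.exp((10.0 - v2) / 40.0)


def _im_p_inf(v):
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, float) + 35.0) / 10.0))


def _im_p_tau(v, tau_max=1000.0):
    v = np.asarray(v, float)
    return tau_max / (3.3 * np.exp((v + 35.0) / 20.0) + np.exp(-(v + 35.0) / 20.0))


#: name -> ("rates", alpha, beta) or ("inf_tau", x_inf, tau)
RATE_FUNCTIONS = {
    "traub_m": ("rates", _traub_alpha_m, _traub_beta_m),
    "traub_h": ("rates", _traub_alpha_h, _traub_beta_h),
    "traub_n": ("rates", _traub_alpha_n, _traub_beta_n),
    "im_p": ("inf_tau", _im_p_inf, _im_p_tau),
}


# --------------------------------------------------------------------------
# Gate and channel models
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GateModel:
    """One gating variable: equilibrium curve plus time constant.

    Either ``(V_half, k)`` describe a Boltzmann equilibrium, or ``rates`` names
    an entry of :data:`RATE_FUNCTIONS` from which both the equilibrium and the
    time constant are derived.  ``exponent`` is the power the gate contributes
    to the channel open fraction (3 for m^3, 4 for n^4, 1 for h); it is *not*
    applied by :func:`gate_value`.

    If ``curve`` is ``"conductance"`` the Boltzmann (V_half, k) describes the
    steady-state *conductance* activation curve x_inf^exponent, i.e. the gate
    equilibrium is the exponent-th root of the Boltzmann.  This is how a
    voltage-clamp-measured activation curve maps onto a multi-gate channel.

    ``V_shift`` displaces the voltage dependence (equilibrium and time
    constant): positive shifts move the curves toward depolarized potentials.
    """

    polarity: str = "activation"  # 'activation' | 'inactivation'
    V_half: Optional[float] = None  # mV
    k: Optional[float] = None  # mV, > 0
    tau: Optional[float] = None  # ms (constant); None for rate-based gates
    rates: Optional[str] = None  # key into RATE_FUNCTIONS
    exponent: int = 1
    curve: str = "gate"  # 'gate' | 'conductance'
    V_shift: float = 0.0  # mV

    def __post_init__(self):
        if self.polarity not in ("activation", "inactivation"):
            raise ParameterError(f"unknown polarity {self.polarity!r}")
        if self.exponent < 1:
            raise ParameterError("gate exponent must be a positive integer")
        if self.rates is None:
            if self.V_half is None or self.k is None:
                raise ParameterError("Boltzmann gate needs V_half and k")
            if self.k <= 0:
                raise ParameterError("slope factor k must be > 0")
            if self.tau is None:
                raise ParameterError("Boltzmann gate needs a time constant")
        else:
            if self.rates not in RATE_FUNCTIONS:
                raise ParameterError(f"unknown rate functions {self.rates!r}")
        if self.curve not in ("gate", "conductance"):
            raise ParameterError(f"unknown curve convention {self.curve!r}")

    def shifted(self, dV: float) -> "GateModel":
        """Return a copy with the voltage dependence displaced by ``dV`` mV."""
        return replace(self, V_shift=self.V_shift + dV)


def _check_voltage(V) -> np.ndarray:
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ParameterError("membrane potential must be finite")
    return V


def boltzmann(V, V_half: float, k: float):
    """Increasing Boltzmann function 1 / (1 + exp((V_half - V)/k))."""
    if k <= 0:
        raise ParameterError("slope factor k must be > 0")
    return 1.0 / (1.0 + np.exp((V_half - np.asarray(V, float)) / k))


def gate_value(gate: GateModel, V):
    """Equilibrium open fraction x_inf(V) of one gate (exponent not applied)."""
    V = _check_voltage(V) - gate.V_shift
    if gate.rates is not None:
        kind, f, g = RATE_FUNCTIONS[gate.rates]
        if kind == "rates":
            a, b = f(V), g(V)
            x = a / (a + b)
        else:
            x = f(V)
    else:
        x = boltzmann(V, gate.V_half, gate.k)
        if gate.polarity == "inactivation":
            x = 1.0 - x
        if gate.curve == "conductance" and gate.exponent != 1:
            x = x ** (1.0 / gate.exponent)
    return x


def gate_tau(gate: GateModel, V):
    """Time constant tau(V) of one gate, in ms."""
    V = _check_voltage(V) - gate.V_shift
    if gate.rates is not None:
        kind, f, g = RATE_FUNCTIONS[gate.rates]
        if kind == "rates":
            return 1.0 / (f(V) + g(V))
        return g(V)
    return gate.tau * np.ones_like(np.asarray(V, float))


@dataclass(frozen=True)
class NaChannel:
    """Transient sodium channel: open fraction = activation^exponent * h."""

    g_max: float  # nS
    E_rev: float  # mV
    activation: GateModel
    inactivation: Optional[GateModel] = None
    instantaneous_activation: bool = False

    def __post_init__(self):
        if self.g_max < 0:
            raise ParameterError("g_max must be >= 0")

    def open_fraction(self, V, h=None):
        a = gate_value(self.activation, V) ** self.activation.exponent
        if h is None:
            h = 1.0 if self.inactivation is None else gate_value(self.inactivation, V)
        return a * h


def exp_activation(V, V_a: float, k_a: float):
    """Exponential approximation exp((V - V_a)/k_a) of the activation curve.

    Valid only well below V_a, where the Boltzmann curve is in its
    exponential tail; near and above V_a it exceeds 1.
    """
    if k_a <= 0:
        raise ParameterError("k_a must be > 0")
    return np.exp((np.asarray(V, float) - V_a) / k_a)


# --------------------------------------------------------------------------
# Activation-curve fitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    V_half: float  # mV
    k: float  # mV
    window: Tuple[float, float]  # (V_lo, V_hi) mV
    rms_residual: float
    n_points: int


_K_BOUNDS = (0.1, 50.0)


def _window_mask(V: np.ndarray, window) -> np.ndarray:
    lo, hi = float(window[0]), float(window[1])
    if not lo < hi:
        raise ParameterError("fit window must satisfy V_lo < V_hi")
    return (V >= lo) & (V <= hi)


def _fit_init(V: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Deterministic, scale-aware initialization for both fit models.

    V_half starts at the voltage where y first reaches half of its in-window
    maximum; k starts from the 25%-75% rise span divided by ln 9 (exact for a
    Boltzmann).  Both are independent of the optimizer's behaviour.
    """
    ymax = float(np.max(y))
    order = np.argsort(V)
    Vs, ys = V[order], y[order]

    def v_at(frac: float) -> float:
        target = frac * ymax
        idx = int(np.argmax(ys >= target))
        return float(Vs[idx])

    v50 = v_at(0.5)
    span = v_at(0.75) - v_at(0.25)
    k0 = span / math.log(9.0) if span > 0 else 1.0
    k0 = min(max(k0, _K_BOUNDS[0] * 1.5), _K_BOUNDS[1] / 1.5)
    return v50, k0


def _run_fit(model: Callable, V, y, window) -> FitResult:
    V = np.asarray(V, dtype=float)
    y = np.asarray(y, dtype=float)
    if V.shape != y.shape:
        raise ParameterError("V_grid and y must have the same length")
    if np.any((y < -1e-12) | (y > 1.0 + 1e-9)):
        raise ParameterError("activation values must lie in [0, 1]")
    mask = _window_mask(V, window) & np.isfinite(y)
    if int(mask.sum()) < 4:
        raise FitError(
            f"need at least 4 samples inside window {tuple(window)}, got {int(mask.sum())}"
        )
    Vw, yw = V[mask], y[mask]
    if np.max(yw) <= 0.0:
        raise DegenerateDataError("all in-window activation values are zero")
    v0, k0 = _fit_init(Vw, yw)
    # deterministic multi-start: the scale-aware init plus a fixed grid of
    # slope starts, because windowed fits of non-Boltzmann curves sit on a
    # shallow (V_half, k) ridge with local minima
    v_mid = 0.5 * (float(window[0]) + float(window[1]))
    starts = [(v0, k0)]
    for ks in (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0):
        for vs in (v0, v_mid):
            starts.append((vs, ks))
    best = None
    for vs, ks in starts:
        ks = min(max(ks, _K_BOUNDS[0] * 1.5), _K_BOUNDS[1] / 1.5)
        res = least_squares(
            lambda p: model(Vw, p[0], p[1]) - yw,
            x0=np.array([vs, ks]),
            bounds=([-300.0, _K_BOUNDS[0]], [300.0, _K_BOUNDS[1]]),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if best is None or res.cost < best.cost - 1e-18:
            best = res
    res = best
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return FitResult(
        V_half=float(res.x[0]),
        k=float(res.x[1]),
        window=(float(window[0]), float(window[1])),
        rms_residual=rms,
        n_points=int(mask.sum()),
    )


def fit_boltzmann(V_grid, y, window) -> FitResult:
    """Least-squares Boltzmann fit 1/(1+exp((V_half-V)/k)) inside ``window``."""
    return _run_fit(lambda V, vh, k: boltzmann(V, vh, k), V_grid, y, window)


def fit_exponential(V_grid, y, window) -> FitResult:
    """Least-squares exponential fit exp((V - V_half)/k) inside ``window``.

    V_half and k are reported jointly: the fitted curve is
    exp((V - V_half)/k), so V_half is the voltage where it reaches 1.
    """
    return _run_fit(lambda V, vh, k: np.exp((np.asarray(V, float) - vh) / k), V_grid, y, window)


def window_sensitivity(V_grid, y, window_width: float, centers: Sequence[float]):
    """Boltzmann fit in a sliding window; one FitResult per window center."""
    V = np.asarray(V_grid, dtype=float)
    if window_width <= 0:
        raise ParameterError("window_width must be > 0")
    lo, hi = float(np.min(V)), float(np.max(V))
    out = []
    for c in centers:
        w = (c - window_width / 2.0, c + window_width / 2.0)
        if w[0] < lo - 1e-9 or w[1] > hi + 1e-9:
            raise ParameterError(f"window {w} extends beyond the data range ({lo}, {hi})")
        out.append(fit_boltzmann(V, y, w))
    return out


# --------------------------------------------------------------------------
# Simulated voltage clamp
# --------------------------------------------------------------------------

def simulate_voltage_clamp(
    channel: NaChannel,
    V0: float = -70.0,
    V_steps=None,
    duration: float = 20.0,
    dt: float = 0.01,
    exclusion_guard: float = 5.0,
):
    """Peak-conductance activation curve from a simulated clamp protocol.

    The membrane is held at ``V0`` until gates equilibrate, then stepped to
    each test voltage.  At fixed voltage the gate ODEs are linear, so the gate
    trajectories are integrated exactly on the time grid.  The channel current
    g_max * a(t)^p * h(t) * (V - E_rev) is monitored; the conductance is read
    at the current peak (global maximum of |I|, earliest sample on ties),
    converted with the known reversal potential and normalized by the maximum
    over all retained steps.  Steps within ``exclusion_guard`` mV of E_rev are
    excluded from normalization (the conversion is ill-conditioned there).

    Returns ``(V_kept, g_norm)`` as float arrays.
    """
    if channel.inactivation is None:
        raise ParameterError("voltage clamp protocol requires an inactivation gate")
    if V_steps is None:
        V_steps = np.arange(-100.0, 50.0 + 1e-9, 1.0)
    V_steps = _check_voltage(V_steps)
    tau_m_min = float(np.min(gate_tau(channel.activation, V_steps)))
    if dt >= tau_m_min / 5.0:
        raise ResolutionError(
            f"dt = {dt} ms too coarse for activation kinetics (tau_m_min = {tau_m_min} ms)"
        )
    t = np.arange(0.0, duration, dt)
    a0 = float(gate_value(channel.activation, V0))
    h0 = float(gate_value(channel.inactivation, V0))
    p = channel.activation.exponent

    keep = np.abs(V_steps - channel.E_rev) >= exclusion_guard
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning(
            "excluding %d clamp step(s) within %g mV of E_rev = %g mV",
            n_drop,
            exclusion_guard,
            channel.E_rev,
        )
    Vk = V_steps[keep]
    a_inf = gate_value(channel.activation, Vk)
    h_inf = gate_value(channel.inactivation, Vk)
    tau_a = gate_tau(channel.activation, Vk)
    tau_h = gate_tau(channel.inactivation, Vk)

    g_peak = np.empty_like(Vk)
    for i in range(Vk.size):
        at = a_inf[i] + (a0 - a_inf[i]) * np.exp(-t / tau_a[i])
        ht = h_inf[i] + (h0 - h_inf[i]) * np.exp(-t / tau_h[i])
        I = channel.g_max * (at**p) * ht * (Vk[i] - channel.E_rev)
        j = int(np.argmax(np.abs(I)))  # earliest on ties
        g_peak[i] = abs(I[j]) / abs(Vk[i] - channel.E_rev)
    g_norm = g_peak / np.max(g_peak)
    return Vk, g_norm


def ka_bias_curve(
    channel: NaChannel,
    tau_h_values: Sequence[float],
    fit_window=(-100.0, -40.0),
    **clamp_kwargs,
):
    """Relative error of the clamp-fitted slope factor versus tau_h.

    For each inactivation time constant the clamp protocol is simulated, the
    normalized peak-conductance curve is fitted to a Boltzmann inside
    ``fit_window`` (the subthreshold region, V < -40 mV by default), and the
    relative error (k_fit - k_true)/k_true is reported against the channel's
    true steady-state activation slope.

    Returns a list of ``(tau_h, k_fit, relative_error)`` tuples.
    """
    if channel.inactivation is None:
        raise ParameterError("ka_bias_curve requires an inactivation gate")
    k_true = channel.activation.k
    out = []
    for th in tau_h_values:
        if th <= 0:
            raise ParameterError("tau_h must be > 0")
        chan = replace(channel, inactivation=replace(channel.inactivation, tau=float(th)))
        V, g = simulate_voltage_clamp(chan, **clamp_kwargs)
        fit = fit_boltzmann(V, g, fit_window)
        out.append((float(th), fit.k, (fit.k - k_true) / k_true))
    return out
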