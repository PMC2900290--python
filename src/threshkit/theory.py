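"""Closed-form spike-threshold theory for single-compartment neurons.

Near spike initiation the membrane equation with instantaneous Na activation
and the exponential approximation of the activation curve reads

    C dV/dt = g_tot (E* - V) + g_Na h (E_Na - V_a) exp((V - V_a)/k_a) + I
            = g_tot (E* - V) + g_tot k_a exp((V - theta)/k_a) + I,

where g_tot is the summed non-Na conductance, E* its conductance-weighted
reversal potential, h the Na inactivation variable, and (V_a, k_a) the
midpoint and slope factor of the Na activation curve.  Three threshold
definitions follow from the current-voltage function F(V) (the right-hand
side at I = 0):

* slow-input threshold theta:  F'(theta) = 0 (minimum of the excitability
  curve; threshold for DC and ramp inputs),
* fast-input threshold theta_fast:  upper root of F(V) = 0 (threshold for
  brief charge injections),
* empirical threshold theta_emp:  rising-branch solution of
  F(V) + I = C k_th (first-derivative spike-onset measure).

Solving F'(theta) = 0 gives the threshold equation

    theta = V_T - k_a ln h + k_a ln(g_tot / g_L),
    V_T   = V_a - k_a ln( g_Na (E_Na - V_a) / (g_L k_a) ),

so the threshold moves by -k_a per e-fold of Na availability h and +k_a per
e-fold of total conductance, and depends on channel densities only through
ratios.  theta_fast and theta_emp have closed forms through the Lambert W
function; the numeric root finders on F are part of the public API and are
the normative definitions the closed forms are tested against.

Units: mV, ms, nS, pA, pF (so nS * mV = pA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import lambertw

from .errors import NoThresholdError, ParameterError

__all__ = [
    "ThresholdParams",
    "ThresholdState",
    "GeometryParams",
    "effective_channel",
    "base_threshold",
    "base_threshold_numeric",
    "threshold",
    "threshold_numeric",
    "threshold_decomposition",
    "fast_threshold",
    "fast_threshold_numeric",
    "rest_potential",
    "empirical_threshold",
    "empirical_threshold_numeric",
    "slow_to_fast",
    "F_exp",
    "invert_for_Na_density",
    "electrotonic_length",
    "channel_table_thresholds",
]

_BRACKET_LO = -120.0  # mV, lower end for all subthreshold root searches
_XTOL = 1e-9  # mV, bisection tolerance


@dataclass(frozen=True)
class ThresholdParams:
    """Static parameters of the threshold theory.

    V_a, k_a : midpoint and slope factor (mV) of the Na activation curve
        (for a multi-gate channel, of the *conductance* activation curve).
    g_Na : maximal Na conductance (nS).
    g_L, E_L : leak conductance (nS) and reversal (mV).
    E_Na : Na reversal potential (mV).
    C : membrane capacitance (pF).
    """

    V_a: float
    k_a: float
    g_Na: float
    g_L: float
    E_Na: float
    C: float = 250.0
    E_L: float = -80.0
    #: explicit base-threshold calibration.  When set, base_threshold returns
    #: this value instead of the exponential-approximation closed form --
    #: used to anchor the threshold equation at a model's actual
    #: excitability-curve minimum, absorbing the approximation's bias.
    V_T: Optional[float] = None

    def __post_init__(self):
        if self.k_a <= 0:
            raise ParameterError("k_a must be > 0")
        if self.g_Na <= 0 or self.g_L <= 0:
            raise ParameterError("g_Na and g_L must be > 0")
        if self.E_Na <= self.V_a:
            raise ParameterError("E_Na must exceed V_a")
        if self.C <= 0:
            raise ParameterError("C must be > 0")


def effective_channel(conductances: Iterable[Tuple[float, float]]) -> Tuple[float, float]:
    """Collapse non-Na channels into one: (g_tot, E*).

    g_tot is the sum of the conductances and E* their conductance-weighted
    mean reversal potential, so that sum_i g_i (E_i - V) = g_tot (E* - V).
    """
    pairs = list(conductances)
    if not pairs:
        raise ParameterError("at least one (g, E) pair is required")
    g = np.array([p[0] for p in pairs], dtype=float)
    E = np.array([p[1] for p in pairs], dtype=float)
    if np.any(g < 0):
        raise ParameterError("conductances must be >= 0")
    g_tot = float(g.sum())
    if g_tot <= 0:
        raise ParameterError("total conductance must be > 0")
    return g_tot, float((g * E).sum() / g_tot)


@dataclass(frozen=True)
class ThresholdState:
    """Instantaneous modulating state: Na availability and other channels.

    ``conductances`` lists every non-Na channel as (g in nS, E in mV) pairs,
    leak included.  ``h`` is the fraction of non-inactivated Na channels.
    """

    h: float = 1.0
    conductances: Tuple[Tuple[float, float], ...] = ()

    def __post_init__(self):
        if not (0.0 < self.h <= 1.0):
            raise ParameterError("h must lie in (0, 1]")
        effective_channel(self.conductances)  # validates

    @property
    def g_tot(self) -> float:
        return effective_channel(self.conductances)[0]

    @property
    def E_star(self) -> float:
        return effective_channel(self.conductances)[1]

    @classmethod
    def resting(cls, p: ThresholdParams, h: float = 1.0) -> "ThresholdState":
        """Leak-only state (the in-vitro baseline)."""
        return cls(h=h, conductances=((p.g_L, p.E_L),))


# --------------------------------------------------------------------------
# Current-voltage function and numeric oracles
# --------------------------------------------------------------------------

def _state_or_resting(p: ThresholdParams, s: Optional[ThresholdState]) -> ThresholdState:
    return s if s is not None else ThresholdState.resting(p)


def F_exp(p: ThresholdParams, V, s: Optional[ThresholdState] = None, I: float = 0.0):
    """Exponential-approximation current-voltage function F(V) + I, in pA."""
    s = _state_or_resting(p, s)
    g_tot, E_star = effective_channel(s.conductances)
    V = np.asarray(V, dtype=float)
    na = p.g_Na * s.h * (p.E_Na - p.V_a) * np.exp((V - p.V_a) / p.k_a)
    return g_tot * (E_star - V) + na + I


def _dF_exp(p: ThresholdParams, V, s: ThresholdState):
    g_tot, _ = effective_channel(s.conductances)
    na = p.g_Na * s.h * (p.E_Na - p.V_a) / p.k_a * np.exp((np.asarray(V, float) - p.V_a) / p.k_a)
    return -g_tot + na


def threshold_numeric(p: ThresholdParams, s: Optional[ThresholdState] = None) -> float:
    """Slow-input threshold located as the root of F'(V) = 0 by bracketing.

    This is the normative definition; :func:`threshold` is the closed-form
    fast path.
    """
    s = _state_or_resting(p, s)
    lo, hi = _BRACKET_LO, p.V_a
    flo, fhi = _dF_exp(p, lo, s), _dF_exp(p, hi, s)
    if not (flo < 0 < fhi):
        raise NoThresholdError(
            "F'(V) has no sign change on the subthreshold bracket; "
            "the Na conductance is too small (or too large) for a threshold"
        )
    return float(brentq(lambda v: _dF_exp(p, v, s), lo, hi, xtol=_XTOL))


def base_threshold_numeric(p: ThresholdParams) -> float:
    """Numeric V_T: critical point of F for the leak-only state, h = 1."""
    return threshold_numeric(p, ThresholdState.resting(p))


# --------------------------------------------------------------------------
# Closed forms
# --------------------------------------------------------------------------

def base_threshold(p: ThresholdParams) -> float:
    """Base (slow-input) threshold V_T = V_a - k_a ln(g_Na (E_Na-V_a)/(g_L k_a)).

    Doubling g_Na lowers V_T by k_a ln 2; scaling g_Na and g_L together
    leaves it unchanged.  Raises :class:`NoThresholdError` when the formula
    would place V_T at or above V_a, where the exponential approximation
    (and the spike threshold itself) ceases to exist.

    If ``p.V_T`` is set, that calibrated value is returned instead (the
    scaling contracts above apply only to the derived form).
    """
    if p.V_T is not None:
        if p.V_T >= p.V_a:
            raise NoThresholdError("calibrated V_T must lie below V_a")
        return p.V_T
    arg = p.g_Na * (p.E_Na - p.V_a) / (p.g_L * p.k_a)
    if arg <= 1.0:
        raise NoThresholdError("g_Na too small relative to g_L: no threshold below V_a")
    return p.V_a - p.k_a * math.log(arg)


def threshold(p: ThresholdParams, s: Optional[ThresholdState] = None) -> float:
    """The threshold equation: theta = V_T - k_a ln h + k_a ln(g_tot/g_L).

    g_tot sums every non-Na conductance (leak, voltage-gated, synaptic).
    Sensitivities are exactly d(theta)/d(ln h) = -k_a and
    d(theta)/d(ln g_tot) = +k_a; theta reduces to V_T for h = 1 and
    g_tot = g_L.
    """
    s = _state_or_resting(p, s)
    g_tot, _ = effective_channel(s.conductances)
    return base_threshold(p) - p.k_a * math.log(s.h) + p.k_a * math.log(g_tot / p.g_L)


def threshold_decomposition(
    p: ThresholdParams,
    h: float = 1.0,
    k_conductances: Sequence[Tuple[float, float]] = (),
    syn_conductances: Sequence[Tuple[float, float]] = (),
) -> Tuple[float, float, float, float]:
    """Cumulative threshold predictions of increasing mechanistic complexity.

    Returns (activation only, + Na inactivation, + K conductances,
    + synaptic conductances); the last element equals :func:`threshold`
    evaluated on the full state.
    """
    leak = ((p.g_L, p.E_L),)
    lvl0 = base_threshold(p)
    lvl1 = threshold(p, ThresholdState(h=h, conductances=leak))
    lvl2 = threshold(p, ThresholdState(h=h, conductances=leak + tuple(k_conductances)))
    lvl3 = threshold(
        p,
        ThresholdState(h=h, conductances=leak + tuple(k_conductances) + tuple(syn_conductances)),
    )
    return (lvl0, lvl1, lvl2, lvl3)


def _upper_root(p: ThresholdParams, theta_s: float, E_eff: float) -> float:
    """Upper solution of g(E_eff - V) + g k_a exp((V-theta_s)/k_a) = 0.

    Writing u = (V - E_eff)/k_a the equation becomes u = exp(u) * exp(a)
    with a = (E_eff - theta_s)/k_a, solved by the secondary branch of the
    Lambert W function: u = -W_{-1}(-exp(a)).
    """
    a = (E_eff - theta_s) / p.k_a
    z = -math.exp(a)
    if z < -1.0 / math.e:
        raise NoThresholdError("F(V) has no root: the neuron has no resting state")
    u = -float(np.real(lambertw(z, k=-1)))
    return E_eff + p.k_a * u


def fast_threshold(
    p: ThresholdParams, s: Optional[ThresholdState] = None, I: float = 0.0
) -> float:
    """Fast-input (charge) threshold: upper root of F(V) + I = 0.

    Always exceeds the slow threshold; a brief pulse that lands the membrane
    above it triggers a regenerative upstroke even though the slow threshold
    sits lower.
    """
    s = _state_or_resting(p, s)
    g_tot, E_star = effective_channel(s.conductances)
    theta_s = threshold(p, s)
    return _upper_root(p, theta_s, E_star + I / g_tot)


def rest_potential(
    p: ThresholdParams, s: Optional[ThresholdState] = None, I: float = 0.0
) -> float:
    """Stable fixed point (lower root of F(V) + I = 0)."""
    s = _state_or_resting(p, s)
    g_tot, E_star = effective_channel(s.conductances)
    theta_s = threshold(p, s)
    E_eff = E_star + I / g_tot
    a = (E_eff - theta_s) / p.k_a
    z = -math.exp(a)
    if z < -1.0 / math.e:
        raise NoThresholdError("F(V) has no root: the neuron has no resting state")
    u = -float(np.real(lambertw(z, k=0)))
    return E_eff + p.k_a * u


def slow_to_fast(
    p: ThresholdParams,
    theta_slow,
    g_tot,
    E_star,
    I: float = 0.0,
):
    """Convert slow-input threshold(s) to fast-input threshold(s), vectorized.

    Applies the F(V) = 0 upper-root relation elementwise; inputs may be
    scalars or arrays of matching shape.  Entries where no resting state
    exists come back as NaN.
    """
    theta_slow = np.asarray(theta_slow, dtype=float)
    g_tot = np.broadcast_to(np.asarray(g_tot, dtype=float), theta_slow.shape)
    E_star = np.broadcast_to(np.asarray(E_star, dtype=float), theta_slow.shape)
    E_eff = E_star + I / g_tot
    a = (E_eff - theta_slow) / p.k_a
    z = -np.exp(a)
    with np.errstate(invalid="ignore"):
        u = -np.real(lambertw(z, k=-1))
    out = E_eff + p.k_a * u
    out = np.where(z < -1.0 / math.e, np.nan, out)
    return out if out.ndim else float(out)


def fast_threshold_numeric(
    p: ThresholdParams, s: Optional[ThresholdState] = None, I: float = 0.0
) -> float:
    """Numeric fast threshold: bisection root of F(V) + I on [theta, V_a]."""
    s = _state_or_resting(p, s)
    theta_s = threshold_numeric(p, s)
    f = lambda v: F_exp(p, v, s, I)
    lo, hi = theta_s, p.V_a
    if f(lo) >= 0:
        raise NoThresholdError("F + I is non-negative at its minimum: no unstable root")
    if f(hi) <= 0:
        raise NoThresholdError("no sign change up to V_a")
    return float(brentq(f, lo, hi, xtol=_XTOL))


def empirical_threshold(
    p: ThresholdParams,
    k_th: float,
    I: float = 0.0,
    s: Optional[ThresholdState] = None,
) -> float:
    """First-derivative-criterion threshold: V where dV/dt first reaches k_th.

    Solves C k_th = F(V) + I on the rising branch (the crossing immediately
    before the upstroke).  k_th is in mV/ms; theta_emp increases with k_th
    and tends to the fast threshold as k_th -> 0+ at I = 0.
    """
    if k_th <= 0:
        raise ParameterError("k_th must be > 0")
    s = _state_or_resting(p, s)
    g_tot, E_star = effective_channel(s.conductances)
    theta_s = threshold(p, s)
    E_eff = E_star + (I - p.C * k_th) / g_tot
    try:
        return _upper_root(p, theta_s, E_eff)
    except NoThresholdError as err:
        raise NoThresholdError(f"no dV/dt = {k_th} mV/ms crossing below the spike") from err


def empirical_threshold_numeric(
    p: ThresholdParams,
    k_th: float,
    I: float = 0.0,
    s: Optional[ThresholdState] = None,
) -> float:
    """Numeric empirical threshold: root of F(V) + I - C k_th on the rising branch."""
    if k_th <= 0:
        raise ParameterError("k_th must be > 0")
    s = _state_or_resting(p, s)
    theta_s = threshold_numeric(p, s)
    f = lambda v: F_exp(p, v, s, I) - p.C * k_th
    lo, hi = theta_s, p.V_a
    if f(lo) >= 0:
        raise NoThresholdError("dV/dt exceeds k_th already at the excitability minimum")
    if f(hi) <= 0:
        raise NoThresholdError("no crossing below V_a")
    return float(brentq(f, lo, hi, xtol=_XTOL))


# --------------------------------------------------------------------------
# Morphology: electrotonic length and AIS Na density
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GeometryParams:
    """Axon initial segment geometry and passive cable constants.

    d : axon diameter (um).
    R_i : intracellular resistivity (Ohm cm).
    R_m : membrane specific resistance (Ohm cm^2).
    S_AIS : AIS membrane area (um^2).
    """

    d: float
    R_i: float
    R_m: float
    S_AIS: float = 1.0

    def __post_init__(self):
        if min(self.d, self.R_i, self.R_m, self.S_AIS) <= 0:
            raise ParameterError("all geometry parameters must be > 0")


def electrotonic_length(geom: GeometryParams) -> float:
    """Passive space constant lambda = sqrt(d R_m / (4 R_i)), in um.

    A lambda much larger than the soma-AIS distance justifies treating soma
    and initiation site as one electrotonic compartment below threshold.
    """
    d_cm = geom.d * 1e-4
    lam_cm = math.sqrt(d_cm * geom.R_m / (4.0 * geom.R_i))
    return lam_cm * 1e4


def invert_for_Na_density(
    theta_measured: float,
    g_tot: float,
    geom: GeometryParams,
    V_a: float,
    k_a: float,
    E_Na: float,
) -> float:
    """Na conductance density (pS/um^2) over the AIS from a measured threshold.

    Inverts the base-threshold formula for g_Na,

        g_Na = g_tot k_a / (E_Na - V_a) * exp((V_a - theta)/k_a),

    and divides by the AIS area.  The round trip through
    :func:`base_threshold` reproduces theta exactly; the recovered density is
    linear in g_tot.
    """
    if k_a <= 0:
        raise ParameterError("k_a must be > 0")
    if g_tot <= 0:
        raise ParameterError("g_tot must be > 0")
    if theta_measured >= V_a:
        raise ParameterError("threshold must lie below V_a for the inversion")
    if E_Na <= V_a:
        raise ParameterError("E_Na must exceed V_a")
    g_Na_nS = g_tot * k_a / (E_Na - V_a) * math.exp((V_a - theta_measured) / k_a)
    return g_Na_nS * 1e3 / geom.S_AIS  # nS -> pS


def channel_table_thresholds(
    table: pd.DataFrame, g_ratio_values: Sequence[float], E_Na: float = 55.0
) -> pd.DataFrame:
    """Base threshold for each channel type across Na/leak conductance ratios.

    ``table`` must have columns ``name, V_a_mV, k_a_mV``; the output is a long
    DataFrame with one row per (channel, g_Na/g_L) pair.  Because V_T depends
    on densities only through g_Na/g_L, the ratio fully determines each curve.
    """
    required = {"name", "V_a_mV", "k_a_mV"}
    if not required.issubset(table.columns):
        raise ParameterError(f"channel table needs columns {sorted(required)}")
    rows = []
    for _, r in table.iterrows():
        for ratio in g_ratio_values:
            if ratio <= 0:
                raise ParameterError("g_Na/g_L ratios must be > 0")
            p = ThresholdParams(
                V_a=float(r["V_a_mV"]),
                k_a=float(r["k_a_mV"]),
                g_Na=float(ratio),
                g_L=1.0,
                E_Na=E_Na,
            )
            rows.append({"name": r["name"], "g_ratio": float(ratio), "V_T_mV": base_threshold(p)})
    return pd.DataFrame(rows)
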