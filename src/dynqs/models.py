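"""Kinetic models of fed-batch microbial growth on a single carbon source.

Two plant models are defined over the state (X, S, qS, V) — total biomass
[g_DCW], total substrate [g], biomass-specific substrate uptake rate
[g g_DCW^-1 h^-1] and broth volume [L]:

* the standard Monod model, in which qS is an algebraic function of the
  broth substrate concentration, and
* the dynamic substrate-uptake model, in which qS is itself a state with
  an adaptability rate ``lambda`` [g g_DCW^-1 h^-2] driving it toward its
  saturation value.

Both share the growth-rate link mu(qS) and the stoichiometric output map
to the off-gas rates CER [cmmol/h] and OUR [mmol/h].

All kinetic laws consume *concentrations* (X/V, S/V in g/L) derived on the
fly; states are stored as total amounts.  OUR is emitted with the
consumption-negative sign convention used throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np

__all__ = [
    "ModelConstants",
    "KineticParameters",
    "PlantState",
    "InputSignal",
    "monod_qs",
    "growth_rate",
    "output_map",
    "gas_rates",
    "monod_rhs",
    "dynamic_qs_rhs",
    "steady_state_qs",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class ModelConstants:
    """Fixed physical constants of the E. coli / glycerol system.

    Defaults are the values used for all experiments in this package:
    carbon-mole based molar masses, the maintenance coefficient, degrees
    of reduction for the electron balance, the feed substrate
    concentration and the Monod saturation constant (k_S is treated as
    known and never estimated).
    """

    MW_X: float = 0.0236  # biomass molar mass [g_DCW / cmmol]
    MW_S: float = 0.0307  # substrate (glycerol) molar mass [g / cmmol]
    m_c: float = 1.1      # maintenance coefficient [cmmol g_DCW^-1 h^-1]
    gamma_X: float = 4.25   # biomass degree of reduction [-]
    gamma_O2: float = -4.0  # oxygen degree of reduction [-]
    gamma_S: float = 4.67   # substrate degree of reduction [-]
    S_in: float = 750.0   # feed substrate concentration [g/L]
    k_S: float = 0.004    # substrate saturation constant [g/L]

    def __post_init__(self) -> None:
        for name in ("MW_X", "MW_S", "m_c", "gamma_X", "gamma_O2",
                     "gamma_S", "S_in", "k_S"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        for name in ("MW_X", "MW_S", "k_S", "S_in"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.gamma_O2 >= 0:
            raise ValueError("gamma_O2 must be negative (electron acceptor)")


@dataclass(frozen=True)
class KineticParameters:
    """Estimable kinetic parameters.

    qS_max : maximum specific substrate uptake rate [g g_DCW^-1 h^-1]
    Y_XC   : biomass yield on carbon source [cmol/cmol, dimensionless]
    """

    qS_max: float
    Y_XC: float

    def __post_init__(self) -> None:
        if self.qS_max < 0:
            raise ValueError("qS_max must be >= 0")
        if not 0 <= self.Y_XC <= 1:
            raise ValueError("Y_XC must lie in [0, 1]")


@dataclass
class PlantState:
    """Continuous reactor state as total amounts.

    X  : total biomass [g_DCW]
    S  : total substrate [g]
    qS : specific substrate uptake rate [g g_DCW^-1 h^-1]
    V  : broth volume [L]
    """

    X: float
    S: float
    qS: float
    V: float

    def __post_init__(self) -> None:
        if min(self.X, self.S, self.qS, self.V) < 0:
            raise ValueError("PlantState components must be non-negative")

    @property
    def X_conc(self) -> float:
        return self.X / self.V

    @property
    def S_conc(self) -> float:
        return self.S / self.V


def _zero(t: float) -> float:
    return 0.0


@dataclass
class InputSignal:
    """Time-dependent reactor inputs: feed rate and outflow rate [L/h].

    Outflow removal is concentration-proportional (-F_out * X/V etc.);
    F_out defaults to zero, with physical samples treated as instantaneous
    discrete withdrawals outside the ODE.
    """

    u_in: Callable[[float], float] = _zero
    F_out: Callable[[float], float] = _zero


def monod_qs(S_conc: ArrayLike, params: KineticParameters,
             consts: ModelConstants) -> ArrayLike:
    """Algebraic Monod uptake rate qS(S/V) = qS_max * s / (k_S + s)."""
    s = np.asarray(S_conc, dtype=float)
    if np.any(s < 0):
        raise ValueError("substrate concentration must be >= 0")
    out = params.qS_max * s / (consts.k_S + s)
    return out if out.ndim else float(out)


def growth_rate(qS: ArrayLike, params: KineticParameters,
                consts: ModelConstants) -> ArrayLike:
    """Growth-rate link mu = (qS/MW_S * Y_XC - m_c) * MW_X  [h^-1].

    Negative when maintenance consumption exceeds uptake.
    """
    q = np.asarray(qS, dtype=float)
    out = (q / consts.MW_S * params.Y_XC - consts.m_c) * consts.MW_X
    return out if out.ndim else float(out)


def gas_rates(X: ArrayLike, qS: ArrayLike, params: KineticParameters,
              consts: ModelConstants) -> tuple[ArrayLike, ArrayLike]:
    """Stoichiometric off-gas rates from biomass X [g] and uptake qS.

    CER = X * (qS/MW_S * (1 - Y_XC) + m_c)          [cmmol/h, >= 0]
    OUR = -| X/gamma_O2 * qS/MW_S * (gamma_X*Y_XC - gamma_S) |  [mmol/h]

    OUR is emitted consumption-negative.
    """
    Xa = np.asarray(X, dtype=float)
    q = np.asarray(qS, dtype=float)
    cer = Xa * (q / consts.MW_S * (1.0 - params.Y_XC) + consts.m_c)
    our_raw = (Xa / consts.gamma_O2) * (q / consts.MW_S) * (
        consts.gamma_X * params.Y_XC - consts.gamma_S)
    our = -np.abs(our_raw)
    if cer.ndim == 0:
        return float(cer), float(our)
    return cer, our


def output_map(state: PlantState, params: KineticParameters,
               consts: ModelConstants) -> tuple[float, float]:
    """(CER, OUR) for a plant state; see :func:`gas_rates`."""
    return gas_rates(state.X, state.qS, params, consts)


def monod_rhs(t: float, y: np.ndarray, params: KineticParameters,
              consts: ModelConstants, inputs: InputSignal) -> np.ndarray:
    """Time derivatives of (X, S, V) under the standard Monod model.

    qS is algebraic; substrate is clamped at zero from below so the
    integrator cannot consume non-existent substrate.
    """
    X, S, V = float(y[0]), float(y[1]), float(y[2])
    if V <= 0:
        raise ValueError(f"degenerate state: V={V} at t={t}")
    u = inputs.u_in(t)
    f_out = inputs.F_out(t)
    s_conc = max(S, 0.0) / V
    qS = params.qS_max * s_conc / (consts.k_S + s_conc)
    mu = (qS / consts.MW_S * params.Y_XC - consts.m_c) * consts.MW_X
    Xp = max(X, 0.0)
    dX = mu * Xp - f_out * Xp / V
    dS = u * consts.S_in - qS * Xp - f_out * max(S, 0.0) / V
    dV = u - f_out
    return np.array([dX, dS, dV])


def dynamic_qs_rhs(t: float, y: np.ndarray, params: KineticParameters,
                   lam: Union[float, Callable[[float], float]],
                   consts: ModelConstants,
                   inputs: InputSignal) -> np.ndarray:
    """Time derivatives of (X, S, qS, V) under the dynamic-uptake model.

    dqS/dt = lam * (1 - qS/qS_max) * s/(k_S+s)
             - qS * qS_max * x * k_S/(k_S+s)^2

    with s = S/V, x = X/V.  The positive term raises qS toward qS_max at
    rate lam, damped near saturation; the negative term is the
    batch-mode time derivative of the Monod curve and reproduces the
    rapid decay of qS near substrate depletion.  States are clamped to
    their physical ranges inside the evaluation so that small solver
    overshoots cannot destabilise the dynamics.
    """
    X, S, qS, V = float(y[0]), float(y[1]), float(y[2]), float(y[3])
    if V <= 0:
        raise ValueError(f"degenerate state: V={V} at t={t}")
    lam_t = lam(t) if callable(lam) else float(lam)
    if lam_t < 0:
        raise ValueError("lambda must be >= 0")
    u = inputs.u_in(t)
    f_out = inputs.F_out(t)
    s_conc = max(S, 0.0) / V
    x_conc = max(X, 0.0) / V
    q = min(max(qS, 0.0), params.qS_max)
    mu = (q / consts.MW_S * params.Y_XC - consts.m_c) * consts.MW_X
    Xp = max(X, 0.0)
    sat = s_conc / (consts.k_S + s_conc)
    dq = (lam_t * (1.0 - q / params.qS_max) * sat
          - q * params.qS_max * x_conc * consts.k_S
          / (consts.k_S + s_conc) ** 2) if params.qS_max > 0 else 0.0
    dX = mu * Xp - f_out * Xp / V
    dS = u * consts.S_in - q * Xp - f_out * max(S, 0.0) / V
    dV = u - f_out
    return np.array([dX, dS, dq, dV])


def steady_state_qs(S_conc: ArrayLike, X_conc: ArrayLike,
                    params: KineticParameters, lam: float,
                    consts: ModelConstants) -> ArrayLike:
    """Stationary uptake rate of the dynamic model at fixed (S/V, X/V).

    Setting dqS/dt = 0 and solving gives

        qS = lam*s / ( qS_max * x * k_S/(k_S+s) + lam*s/qS_max )

    which is bounded by qS_max, decreasing in the biomass concentration
    and tends to qS_max as s -> infinity: the apparent uptake capacity
    decays with accumulating biomass even at identical substrate levels.
    """
    s = np.asarray(S_conc, dtype=float)
    x = np.asarray(X_conc, dtype=float)
    if np.any(s < 0) or np.any(x < 0):
        raise ValueError("concentrations must be >= 0")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    num = lam * s
    den = (params.qS_max * x * consts.k_S / (consts.k_S + s)
           + lam * s / params.qS_max)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    out = np.clip(out, 0.0, params.qS_max)
    return out if out.ndim else float(out)
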