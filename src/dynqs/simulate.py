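"""Synthetic plant generator for fed-batch E. coli runs.

Emulates the reference in-silico experiment used throughout the package:
a batch phase on 8 g/L glycerol, an exponential feed started at the
design time after substrate depletion, a sigmoidal activation of the
substrate-uptake adaptability rate lambda(t), optional Dirac-like feed
spikes (narrow Gaussians), and the analytical noise model of the offline
biomass/substrate assays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .models import (
    InputSignal,
    KineticParameters,
    ModelConstants,
    PlantState,
    dynamic_qs_rhs,
    gas_rates,
    monod_qs,
    monod_rhs,
)

__all__ = [
    "FeedProfile",
    "ActivationProfile",
    "SimulationTrajectory",
    "feed_rate",
    "design_feed_coefficient",
    "lambda_activation",
    "simulate_plant",
    "sample_offline",
    "reference_feed",
    "reference_activation",
    "reference_initial_state",
    "reference_parameters",
    "SPIKE_CENTERS",
    "SPIKE_SIGMA",
]

# Feed-spike design of the reference simulation experiment: narrow
# Gaussians at regular intervals in the carbon-limited phase, peak height
# twice the base feed signal at each center.
SPIKE_CENTERS = (18.0, 22.0, 26.0, 30.0)
SPIKE_SIGMA = 0.01  # [h]
SPIKE_FACTOR = 2.0


@dataclass(frozen=True)
class FeedProfile:
    """Exponential fed-batch feed law with optional Gaussian spikes.

    u(t) = u0 * exp(mu_set * (t - t_start))   for t > t_start, else 0,
    plus sum of amplitude_j * exp(-(t-tc_j)^2 / (2 sigma_j^2)).
    """

    u0: float
    mu_set: float
    t_start: float
    spikes: tuple[tuple[float, float, float], ...] = ()  # (center, sigma, amplitude)

    def __post_init__(self) -> None:
        if self.u0 < 0:
            raise ValueError("u0 must be >= 0")
        for c, s, a in self.spikes:
            if s <= 0:
                raise ValueError("spike sigma must be > 0")
            if a < 0:
                raise ValueError("spike amplitude must be >= 0")

    def base(self, t):
        t = np.asarray(t, dtype=float)
        out = np.where(t > self.t_start,
                       self.u0 * np.exp(self.mu_set * (t - self.t_start)), 0.0)
        return out if out.ndim else float(out)

    def __call__(self, t):
        return feed_rate(t, self)

    def with_spikes(self, centers: Sequence[float], sigma: float = SPIKE_SIGMA,
                    factor: float = SPIKE_FACTOR) -> "FeedProfile":
        """Attach Gaussian spikes with peak height factor*base(center)."""
        spikes = tuple((float(c), float(sigma), factor * self.base(c))
                       for c in centers)
        return FeedProfile(self.u0, self.mu_set, self.t_start, spikes)


def feed_rate(t, profile: FeedProfile):
    """Total feed rate [L/h]: exponential base plus Gaussian spikes."""
    ta = np.asarray(t, dtype=float)
    u = np.asarray(profile.base(ta), dtype=float).copy()
    for c, s, a in profile.spikes:
        u = u + a * np.exp(-0.5 * ((ta - c) / s) ** 2)
    return u if u.ndim else float(u)


def design_feed_coefficient(mu_set: float, X0_guess: float, V0: float,
                            Y_XS_guess: float, S_in: float) -> float:
    """Pre-exponential feed coefficient u0 = mu_set*X0*V0/(Y_XS*S_in) [L/h].

    X0_guess is the expected biomass concentration [g/L] at the end of
    the batch phase, Y_XS_guess a gravimetric yield guess [g_DCW/g].
    """
    if min(mu_set, X0_guess, V0, Y_XS_guess, S_in) <= 0:
        raise ValueError("all feed-design inputs must be > 0")
    return mu_set * X0_guess * V0 / (Y_XS_guess * S_in)


@dataclass(frozen=True)
class ActivationProfile:
    """Sigmoidal activation of the adaptability rate:
    lambda(t) = lambda_act / (1 + exp(-a*(t - t_act))).
    """

    lambda_act: float
    a: float
    t_act: float

    def __post_init__(self) -> None:
        if self.lambda_act < 0:
            raise ValueError("lambda_act must be >= 0")

    def __call__(self, t):
        return lambda_activation(t, self)


def lambda_activation(t, profile: ActivationProfile):
    """Evaluate the sigmoid; lambda(t_act) = lambda_act/2, limits 0 and lambda_act."""
    ta = np.asarray(t, dtype=float)
    # guard exp overflow for very negative arguments
    z = np.clip(profile.a * (ta - profile.t_act), -500.0, 500.0)
    out = profile.lambda_act / (1.0 + np.exp(-z))
    return out if out.ndim else float(out)


def reference_feed(with_spikes: bool = True) -> FeedProfile:
    """Feed law of the reference simulation experiment:
    u(t) = 0.0014*exp(0.12*(t-11.5)) for t > 11.5 h, with four Gaussian
    spikes (sigma 0.01 h, peak 2x base) at t = 18, 22, 26, 30 h."""
    profile = FeedProfile(u0=0.0014, mu_set=0.12, t_start=11.5)
    if with_spikes:
        profile = profile.with_spikes(SPIKE_CENTERS)
    return profile


def reference_activation() -> ActivationProfile:
    """lambda_act = 8 g/gDCW/h^2, steepness 0.8, midpoint 8 h."""
    return ActivationProfile(lambda_act=8.0, a=0.8, t_act=8.0)


def reference_initial_state() -> PlantState:
    """X0 = 0.05 g/L, S0 = 8 g/L, qS0 = 0.5, V0 = 1 L (totals in 1 L)."""
    return PlantState(X=0.05, S=8.0, qS=0.5, V=1.0)


def reference_parameters() -> KineticParameters:
    """True simulation parameters qS_max = 1.2, Y_XC = 0.62."""
    return KineticParameters(qS_max=1.2, Y_XC=0.62)


@dataclass
class SimulationTrajectory:
    """Dense simulated trajectory with states, lambda, outputs and feed."""

    t: np.ndarray
    X: np.ndarray
    S: np.ndarray
    qS: np.ndarray
    V: np.ndarray
    lam: np.ndarray
    CER: np.ndarray
    OUR: np.ndarray
    u_in: np.ndarray

    @property
    def X_conc(self) -> np.ndarray:
        return self.X / self.V

    @property
    def S_conc(self) -> np.ndarray:
        return self.S / self.V

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "X": self.X, "S": self.S, "qS": self.qS,
            "V": self.V, "lambda": self.lam, "CER": self.CER,
            "OUR": self.OUR, "u_in": self.u_in,
        })

    def observations(self, dt: float = 0.05) -> pd.DataFrame:
        """Subsample (t, CER, OUR, u_in) on a uniform grid for the observer."""
        t_obs = np.arange(self.t[0], self.t[-1] + 1e-9, dt)
        return pd.DataFrame({
            "t": t_obs,
            "CER": np.interp(t_obs, self.t, self.CER),
            "OUR": np.interp(t_obs, self.t, self.OUR),
            "u_in": np.interp(t_obs, self.t, self.u_in),
        })

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate_plant(init: PlantState, params: KineticParameters,
                   feed: FeedProfile,
                   act: Optional[ActivationProfile] = None,
                   t_end: float = 32.0,
                   consts: ModelConstants = ModelConstants(),
                   model: str = "dynamic",
                   dt_out: float = 0.01,
                   rtol: float = 1e-8, atol: float = 1e-10,
                   max_step: float = 5e-3,
                   method: str = "LSODA") -> SimulationTrajectory:
    """Integrate the plant from ``init`` to ``t_end`` hours.

    ``model`` selects the transition: "dynamic" integrates (X, S, qS, V)
    with lambda(t) from ``act``; "monod" integrates (X, S, V) with the
    algebraic Monod uptake law (``act`` ignored).  The step bound
    ``max_step`` guarantees the narrow feed spikes cannot be stepped
    over; the error control then resolves them.
    """
    inputs = InputSignal(u_in=feed)
    t_eval = np.arange(0.0, t_end + dt_out / 2, dt_out)

    if model == "dynamic":
        if act is None:
            raise ValueError("dynamic model requires an activation profile")
        y0 = [init.X, init.S, init.qS, init.V]

        def rhs(t, y):
            return dynamic_qs_rhs(t, y, params, act, consts, inputs)
    elif model == "monod":
        y0 = [init.X, init.S, init.V]

        def rhs(t, y):
            return monod_rhs(t, y, params, consts, inputs)
    else:
        raise ValueError(f"unknown model {model!r}")

    sol = solve_ivp(rhs, (0.0, t_end), y0, t_eval=t_eval, method=method,
                    rtol=rtol, atol=atol, max_step=max_step)
    if not sol.success:
        raise RuntimeError(
            f"plant integration failed at t={sol.t[-1] if len(sol.t) else 0}: "
            f"{sol.message}")

    t = sol.t
    if model == "dynamic":
        X, S, qS, V = sol.y
        lam = np.asarray(lambda_activation(t, act), dtype=float)
    else:
        X, S, V = sol.y
        qS = monod_qs(np.maximum(S, 0.0) / V, params, consts)
        lam = np.zeros_like(t)

    # clip solver overshoot to the physical ranges
    X = np.maximum(X, 0.0)
    S = np.maximum(S, 0.0)
    qS = np.clip(qS, 0.0, params.qS_max)
    cer, our = gas_rates(X, qS, params, consts)
    u = np.asarray(feed_rate(t, feed), dtype=float)
    return SimulationTrajectory(t=t, X=X, S=S, qS=qS, V=V, lam=lam,
                                CER=np.asarray(cer), OUR=np.asarray(our),
                                u_in=u)


def offline_dispersion(X_d, S_d) -> tuple[np.ndarray, np.ndarray]:
    """Analytical dispersion of the offline assays.

    Biomass: 5% multiplicative for X > 2.5 g/L, fixed 0.2 g/L below.
    Substrate (HPLC): fixed 0.05 g/L resolution.
    """
    X_d = np.asarray(X_d, dtype=float)
    sd_X = np.where(X_d > 2.5, 0.05 * X_d, 0.2)
    sd_S = np.full_like(np.asarray(S_d, dtype=float), 0.05)
    return sd_X, sd_S


def sample_offline(traj: SimulationTrajectory, times: Sequence[float],
                   rng: Optional[np.random.Generator] = None,
                   noise: bool = True) -> pd.DataFrame:
    """Draw offline samples (concentrations) from a trajectory.

    Returns a frame with columns t, X_d, S_d, sd_X, sd_S.  With
    ``noise=False`` (or rng None) the exact trajectory concentrations
    are returned; otherwise Gaussian noise with the assay dispersions is
    added and values are floored at zero.
    """
    times = np.asarray(times, dtype=float)
    if times.min() < traj.t[0] - 1e-9 or times.max() > traj.t[-1] + 1e-9:
        raise ValueError("offline sample times outside trajectory span")
    X_d = np.interp(times, traj.t, traj.X_conc)
    S_d = np.interp(times, traj.t, traj.S_conc)
    sd_X, sd_S = offline_dispersion(X_d, S_d)
    if noise and rng is not None:
        X_d = np.maximum(X_d + rng.normal(0.0, sd_X), 0.0)
        S_d = np.maximum(S_d + rng.normal(0.0, sd_S), 0.0)
        sd_X, sd_S = offline_dispersion(X_d, S_d)
    return pd.DataFrame({"t": times, "X_d": X_d, "S_d": S_d,
                         "sd_X": sd_X, "sd_S": sd_S})
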