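"""Bayesian observer: particle filter with augmented state-parameter ensemble.

Each particle carries the plant state (X, S, qS, V), the kinetic
parameters (qS_max, Y_XC), the current adaptability rate lambda, and a
dimensionless cell age phi.  The filter propagates the ensemble through
the dynamic substrate-uptake ODE (or the plain Monod ODE, for model
comparison), weights particles by a Gaussian likelihood on the CER
channel only, and performs sequential importance resampling whenever the
effective sample size drops below a configurable fraction.

lambda is a non-decreasing Gamma process clocked by cell age: on every
resampling event each particle receives an increment
``dlam ~ Gamma(shape=alpha*dphi, scale=beta)`` where dphi is the cell
age accumulated since the particle's lineage last drew an increment.
Shape values below 1 concentrate mass near zero, which sustains the
lag-phase population of particles with lambda ~ 0 until the data demand
activation.

qS_max carries no process noise: it is estimated purely by Bayesian
selection from the prior.  Y_XC receives a small Gaussian random walk,
activated only once the ensemble has located qS_max (weighted spread
below a threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, truncnorm

from .models import KineticParameters, ModelConstants, PlantState
from .simulate import FeedProfile

__all__ = [
    "PFConfig",
    "ParticleEnsemble",
    "FilterResult",
    "TruncatedNormalPrior",
    "default_prior",
    "init_particles",
    "propagate",
    "log_likelihood",
    "update_weights",
    "effective_sample_size",
    "resample_sir",
    "lambda_increment",
    "run_filter",
]

# PSO search box reused as the physical support of parameter priors
PRIOR_BOUNDS = {"qS_max": (0.2, 1.6), "Y_XC": (0.3, 0.8)}


@dataclass(frozen=True)
class PFConfig:
    """Particle-filter hyperparameters (defaults = reference configuration)."""

    n_particles: int = 1000
    dt: float = 0.05                 # observation sampling time [h]
    sigma2_cer: float = 0.2          # likelihood variance on CER [cmmol^2/h^2]
    neff_fraction: float = 0.5       # SIR trigger: N_eff < fraction * N
    alpha: float = 0.25              # Gamma-process shape rate [per unit phi]
    beta: float = 1.7                # Gamma-process scale
    yxc_walk_var_rate: float = 1e-5  # Y_XC random-walk variance per hour
    qsmax_spread_threshold: float = 1e-4  # weighted std of qS_max that flags "found"
    init_spread: float = 0.10        # uniform +-10% spread on initial X, S
    transition: str = "dynamic"      # "dynamic" | "monod"
    substeps: int = 5                # RK4 substeps per dt
    spike_substeps: int = 125        # RK4 substeps per dt inside spike windows
    lambda_updates: bool = True      # Gamma increments on resampling events
    yxc_walk: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.neff_fraction <= 1:
            raise ValueError("neff_fraction must be in (0, 1]")
        for name in ("n_particles", "dt", "sigma2_cer", "alpha", "beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.transition not in ("dynamic", "monod"):
            raise ValueError("transition must be 'dynamic' or 'monod'")


class TruncatedNormalPrior:
    """Independent truncated-normal prior over (qS_max, Y_XC).

    Synthetic stand-in for an experimentally built parameter density:
    centred on the dominant mode of the empirical distribution
    (qS_max ~ 1.06, Y_XC ~ 0.63) and truncated to the PSO search box.
    """

    def __init__(self, mean=(1.06, 0.63), sd=(0.15, 0.04),
                 bounds=(PRIOR_BOUNDS["qS_max"], PRIOR_BOUNDS["Y_XC"])):
        self.mean = np.asarray(mean, dtype=float)
        self.sd = np.asarray(sd, dtype=float)
        self.bounds = tuple((float(lo), float(hi)) for lo, hi in bounds)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        cols = []
        for m, s, (lo, hi) in zip(self.mean, self.sd, self.bounds):
            a, b = (lo - m) / s, (hi - m) / s
            cols.append(truncnorm.rvs(a, b, loc=m, scale=s, size=n,
                                      random_state=rng))
        return np.column_stack(cols)


def default_prior() -> TruncatedNormalPrior:
    return TruncatedNormalPrior()


class PointMassPrior:
    """Degenerate prior at a single (qS_max, Y_XC); used for collapse tests."""

    def __init__(self, qS_max: float, Y_XC: float):
        self.theta = np.array([qS_max, Y_XC], dtype=float)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.tile(self.theta, (n, 1))


@dataclass
class ParticleEnsemble:
    """Struct-of-arrays ensemble; all arrays have length n_particles."""

    X: np.ndarray
    S: np.ndarray
    qS: np.ndarray
    V: np.ndarray
    qS_max: np.ndarray
    Y_XC: np.ndarray
    lam: np.ndarray
    phi: np.ndarray
    phi_last_draw: np.ndarray
    weights: np.ndarray

    @property
    def n(self) -> int:
        return self.X.size

    def copy(self) -> "ParticleEnsemble":
        return ParticleEnsemble(**{k: v.copy() for k, v in self.__dict__.items()})

    def take(self, idx: np.ndarray) -> "ParticleEnsemble":
        out = ParticleEnsemble(**{k: v[idx].copy() for k, v in self.__dict__.items()})
        out.weights = np.full(idx.size, 1.0 / idx.size)
        return out


def init_particles(x0_nominal: PlantState, prior, config: PFConfig,
                   rng: np.random.Generator,
                   qs0: Optional[float] = None) -> ParticleEnsemble:
    """Initialise the ensemble around a nominal initial state.

    X and S are uniform within +-init_spread of nominal, (qS_max, Y_XC)
    are drawn from the parameter prior, qS0 is uniform on
    [0, qS_max_i] per particle (unknown initial uptake state) unless a
    fixed ``qs0`` is given, lambda starts at 0 and weights are uniform.
    """
    if min(x0_nominal.X, x0_nominal.S, x0_nominal.V) <= 0:
        raise ValueError("nominal initial state must be positive")
    n = config.n_particles
    spread = config.init_spread
    theta = prior.sample(n, rng)
    qS_max = theta[:, 0]
    Y_XC = theta[:, 1]
    X = x0_nominal.X * rng.uniform(1 - spread, 1 + spread, n)
    S = x0_nominal.S * rng.uniform(1 - spread, 1 + spread, n)
    if qs0 is None:
        qS = rng.uniform(0.0, qS_max)
    else:
        qS = np.minimum(np.full(n, float(qs0)), qS_max)
    return ParticleEnsemble(
        X=X, S=S, qS=qS, V=np.full(n, x0_nominal.V),
        qS_max=qS_max, Y_XC=Y_XC,
        lam=np.zeros(n), phi=np.zeros(n), phi_last_draw=np.zeros(n),
        weights=np.full(n, 1.0 / n))


def _ensemble_rhs(t: float, X, S, qS, V, qS_max, Y_XC, lam,
                  feed: Callable, consts: ModelConstants, dynamic: bool):
    """Vectorised RHS over the ensemble; returns (dX, dS, dqS, dV, aging).

    ``aging`` is the cell-age integrand mu + MW_X*m_c = qS/MW_S*Y_XC*MW_X,
    which is non-negative by construction.
    """
    u = feed(t) if callable(feed) else feed
    s_conc = np.maximum(S, 0.0) / V
    x_conc = np.maximum(X, 0.0) / V
    if dynamic:
        q = np.clip(qS, 0.0, qS_max)
        sat = s_conc / (consts.k_S + s_conc)
        dq = (lam * (1.0 - q / qS_max) * sat
              - q * qS_max * x_conc * consts.k_S / (consts.k_S + s_conc) ** 2)
    else:
        q = qS_max * s_conc / (consts.k_S + s_conc)
        dq = np.zeros_like(q)
    mu = (q / consts.MW_S * Y_XC - consts.m_c) * consts.MW_X
    Xp = np.maximum(X, 0.0)
    dX = mu * Xp
    dS = u * consts.S_in - q * Xp
    dV = np.full_like(V, u)
    aging = mu + consts.MW_X * consts.m_c
    return dX, dS, dq, dV, aging, q


def _particle_cer(ens: ParticleEnsemble, consts: ModelConstants,
                  dynamic: bool) -> np.ndarray:
    if dynamic:
        q = np.clip(ens.qS, 0.0, ens.qS_max)
    else:
        s_conc = np.maximum(ens.S, 0.0) / ens.V
        q = ens.qS_max * s_conc / (consts.k_S + s_conc)
    return np.maximum(ens.X, 0.0) * (q / consts.MW_S * (1.0 - ens.Y_XC)
                                     + consts.m_c)


def _in_spike_window(t0: float, t1: float, feed, halfwidth_sigmas: float = 5.0) -> bool:
    spikes = getattr(feed, "spikes", ())
    for c, s, _ in spikes:
        if t0 <= c + halfwidth_sigmas * s and t1 >= c - halfwidth_sigmas * s:
            return True
    return False


def propagate(ens: ParticleEnsemble, feed, t0: float, t1: float,
              config: PFConfig, consts: ModelConstants = ModelConstants(),
              yxc_active: bool = False,
              rng: Optional[np.random.Generator] = None) -> ParticleEnsemble:
    """Integrate every particle over [t0, t1] under its own parameters.

    Fixed-substep classical RK4, with a finer substep count inside feed
    spike windows; qS is clipped to [0, qS_max] and all amounts to >= 0
    after each substep.  Cell age phi accumulates the per-particle
    growth-plus-maintenance integrand.  When ``yxc_active`` the Y_XC
    random walk is applied once per call with variance
    ``yxc_walk_var_rate * (t1 - t0)``.
    """
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    dynamic = config.transition == "dynamic"
    n_sub = (config.spike_substeps if _in_spike_window(t0, t1, feed)
             else config.substeps)
    h = (t1 - t0) / n_sub
    out = ens.copy()
    X, S, qS, V = out.X, out.S, out.qS, out.V
    qmax, Y = out.qS_max, out.Y_XC
    lam = out.lam
    phi_inc = np.zeros_like(out.phi)
    t = t0
    for _ in range(n_sub):
        k1 = _ensemble_rhs(t, X, S, qS, V, qmax, Y, lam, feed, consts, dynamic)
        k2 = _ensemble_rhs(t + h / 2, X + h / 2 * k1[0], S + h / 2 * k1[1],
                           qS + h / 2 * k1[2], V + h / 2 * k1[3],
                           qmax, Y, lam, feed, consts, dynamic)
        k3 = _ensemble_rhs(t + h / 2, X + h / 2 * k2[0], S + h / 2 * k2[1],
                           qS + h / 2 * k2[2], V + h / 2 * k2[3],
                           qmax, Y, lam, feed, consts, dynamic)
        k4 = _ensemble_rhs(t + h, X + h * k3[0], S + h * k3[1],
                           qS + h * k3[2], V + h * k3[3],
                           qmax, Y, lam, feed, consts, dynamic)
        X = X + h / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        S = S + h / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        qS = qS + h / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        V = V + h / 6 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        phi_inc = phi_inc + h / 6 * (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4])
        # feasibility clipping after each substep
        X = np.maximum(X, 0.0)
        S = np.maximum(S, 0.0)
        qS = np.clip(qS, 0.0, qmax)
        t += h
    out.X, out.S, out.qS, out.V = X, S, qS, V
    out.phi = out.phi + np.maximum(phi_inc, 0.0)
    if yxc_active and config.yxc_walk:
        if rng is None:
            raise ValueError("rng required for the Y_XC random walk")
        sd = np.sqrt(config.yxc_walk_var_rate * (t1 - t0))
        lo, hi = PRIOR_BOUNDS["Y_XC"]
        out.Y_XC = np.clip(out.Y_XC + rng.normal(0.0, sd, out.n), lo, hi)
    return out


def log_likelihood(y_cer: float, cer_model: Union[float, np.ndarray],
                   config: PFConfig) -> Union[float, np.ndarray]:
    """Gaussian log-density of the CER residual (CER channel only)."""
    r = np.asarray(y_cer - np.asarray(cer_model, dtype=float))
    out = -0.5 * np.log(2 * np.pi * config.sigma2_cer) \
        - r ** 2 / (2 * config.sigma2_cer)
    return out if out.ndim else float(out)


def update_weights(ens: ParticleEnsemble, y_cer: float, config: PFConfig,
                   consts: ModelConstants = ModelConstants()) -> bool:
    """Multiply weights by the CER likelihood and renormalise (in place).

    Log-sum-exp stabilised.  Returns True if the update degenerated
    (all likelihoods underflowed) and weights were reset uniform.
    """
    cer = _particle_cer(ens, consts, config.transition == "dynamic")
    logw = np.log(np.maximum(ens.weights, 1e-300)) \
        + np.asarray(log_likelihood(y_cer, cer, config))
    m = logw.max()
    if not np.isfinite(m):
        ens.weights = np.full(ens.n, 1.0 / ens.n)
        return True
    w = np.exp(logw - m)
    ens.weights = w / w.sum()
    return False


def effective_sample_size(weights: np.ndarray) -> float:
    """N_eff = 1 / sum(w^2) for normalised weights."""
    w = np.asarray(weights, dtype=float)
    return float(1.0 / np.sum(w ** 2))


def systematic_indices(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Ancestor indices of systematic resampling (one uniform offset)."""
    w = np.asarray(weights, dtype=float)
    n = w.size
    positions = (rng.uniform() + np.arange(n)) / n
    cumw = np.cumsum(w)
    cumw[-1] = 1.0
    return np.searchsorted(cumw, positions)


def resample_sir(ens: ParticleEnsemble, rng: np.random.Generator) -> ParticleEnsemble:
    """Systematic resampling: N ancestors drawn proportional to weights."""
    return ens.take(systematic_indices(ens.weights, rng))


def lambda_increment(ens: ParticleEnsemble, config: PFConfig,
                     rng: np.random.Generator) -> None:
    """Gamma-process lambda update (in place), clocked by cell age.

    dlam_i ~ Gamma(shape=alpha*dphi_i, scale=beta) with
    dphi_i = phi_i - phi at the lineage's last draw; dphi = 0 yields a
    degenerate zero increment, so lambda is non-decreasing.
    """
    dphi = np.maximum(ens.phi - ens.phi_last_draw, 0.0)
    shape = config.alpha * dphi
    dlam = np.zeros(ens.n)
    pos = shape > 0
    if np.any(pos):
        dlam[pos] = rng.gamma(shape[pos], config.beta)
    ens.lam = ens.lam + dlam
    ens.phi_last_draw = ens.phi.copy()


_TRACE_COLS = ("X", "S", "qS", "V", "qS_max", "Y_XC", "lam", "phi")


def _weighted_moments(ens: ParticleEnsemble):
    w = ens.weights
    vals = {c: getattr(ens, "lam" if c == "lam" else c) for c in _TRACE_COLS}
    mean = {c: float(np.sum(w * v)) for c, v in vals.items()}
    std = {c: float(np.sqrt(max(np.sum(w * (v - mean[c]) ** 2), 0.0)))
           for c, v in vals.items()}
    return mean, std


def _weighted_hist_mode(values: np.ndarray, weights: np.ndarray,
                        bins: int = 50) -> float:
    lo, hi = float(values.min()), float(values.max())
    if hi - lo < 1e-12:
        return lo
    counts, edges = np.histogram(values, bins=bins, range=(lo, hi),
                                 weights=weights)
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def weighted_kde_mode(values: np.ndarray, weights: np.ndarray,
                      gridsize: int = 512) -> float:
    """MAP estimate: mode of a weighted Gaussian KDE over the ensemble."""
    v = np.asarray(values, dtype=float)
    if np.ptp(v) < 1e-9:
        return float(v[0])
    kde = gaussian_kde(v, weights=weights)
    grid = np.linspace(v.min(), v.max(), gridsize)
    return float(grid[np.argmax(kde(grid))])


@dataclass
class FilterResult:
    """Per-step traces and event log of a particle-filter run."""

    t: np.ndarray
    mmse: pd.DataFrame           # weighted means per _TRACE_COLS
    std: pd.DataFrame            # weighted standard deviations
    residual_mean: np.ndarray    # weighted mean of e = y - CER_i
    residual_var: np.ndarray     # weighted variance of the residual
    cer_obs: np.ndarray
    neff: np.ndarray
    resample_events: np.ndarray  # event times
    lam_map: np.ndarray          # per-step histogram-mode MAP of lambda
    degeneracy_events: np.ndarray
    final_lam_map_kde: float
    config: PFConfig

    def mmse_at(self, t_query: float) -> pd.Series:
        i = int(np.argmin(np.abs(self.t - t_query)))
        return self.mmse.iloc[i]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t": self.t})
        for c in self.mmse.columns:
            df[f"mmse_{c}"] = self.mmse[c].to_numpy()
            df[f"std_{c}"] = self.std[c].to_numpy()
        df["residual_mean"] = self.residual_mean
        df["residual_var"] = self.residual_var
        df["cer_obs"] = self.cer_obs
        df["neff"] = self.neff
        df["lam_map"] = self.lam_map
        df["resample_event"] = np.isin(self.t, self.resample_events).astype(int)
        return df

    def summary(self) -> dict:
        last = self.mmse.iloc[-1]
        return {
            "final": {c: float(last[c]) for c in self.mmse.columns},
            "final_lam_map_kde": self.final_lam_map_kde,
            "n_resample_events": int(self.resample_events.size),
            "n_degeneracy_events": int(self.degeneracy_events.size),
            "mean_residual": float(np.mean(self.residual_mean)),
        }


def run_filter(observations: pd.DataFrame, feed, x0_nominal: PlantState,
               prior=None, config: PFConfig = PFConfig(),
               consts: ModelConstants = ModelConstants(),
               rng: Optional[np.random.Generator] = None,
               seed: Optional[int] = None,
               qs0: Optional[float] = None) -> FilterResult:
    """Run the observer over a uniformly sampled CER record.

    ``observations`` must hold columns t (uniform grid, step config.dt)
    and CER.  ``feed`` is a FeedProfile or callable u_in(t).  The first
    row is the initialisation time; assimilation starts at the second.
    """
    if prior is None:
        prior = default_prior()
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)

    t = observations["t"].to_numpy(dtype=float)
    y = observations["CER"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("need at least two observation rows")
    steps = np.diff(t)
    if not np.allclose(steps, config.dt, rtol=0, atol=1e-6):
        raise ValueError("observations must lie on a uniform dt grid")

    ens = init_particles(x0_nominal, prior, config, rng, qs0=qs0)

    n_steps = t.size
    mmse_rows, std_rows = [], []
    res_mean = np.zeros(n_steps)
    res_var = np.zeros(n_steps)
    neff = np.zeros(n_steps)
    lam_map = np.zeros(n_steps)
    events, degen = [], []

    mean0, std0 = _weighted_moments(ens)
    mmse_rows.append(mean0)
    std_rows.append(std0)
    neff[0] = effective_sample_size(ens.weights)
    lam_map[0] = 0.0
    cer0 = _particle_cer(ens, consts, config.transition == "dynamic")
    res_mean[0] = float(np.sum(ens.weights * (y[0] - cer0)))
    res_var[0] = float(np.sum(ens.weights * (y[0] - cer0 - res_mean[0]) ** 2))

    yxc_active = False
    for k in range(1, n_steps):
        if not yxc_active:
            w = ens.weights
            qm_mean = np.sum(w * ens.qS_max)
            qm_sd = np.sqrt(max(np.sum(w * (ens.qS_max - qm_mean) ** 2), 0.0))
            yxc_active = qm_sd <= config.qsmax_spread_threshold
        ens = propagate(ens, feed, t[k - 1], t[k], config, consts,
                        yxc_active=yxc_active, rng=rng)
        degenerated = update_weights(ens, y[k], config, consts)
        if degenerated:
            degen.append(t[k])

        cer = _particle_cer(ens, consts, config.transition == "dynamic")
        e = y[k] - cer
        res_mean[k] = float(np.sum(ens.weights * e))
        res_var[k] = float(np.sum(ens.weights * (e - res_mean[k]) ** 2))
        neff[k] = effective_sample_size(ens.weights)

        mean_k, std_k = _weighted_moments(ens)
        mmse_rows.append(mean_k)
        std_rows.append(std_k)
        lam_map[k] = _weighted_hist_mode(ens.lam, ens.weights)

        if neff[k] < config.neff_fraction * ens.n:
            ens = resample_sir(ens, rng)
            if config.lambda_updates and config.transition == "dynamic":
                lambda_increment(ens, config, rng)
            events.append(t[k])

    final_map = weighted_kde_mode(ens.lam, ens.weights) \
        if config.transition == "dynamic" else 0.0
    return FilterResult(
        t=t,
        mmse=pd.DataFrame(mmse_rows),
        std=pd.DataFrame(std_rows),
        residual_mean=res_mean,
        residual_var=res_var,
        cer_obs=y,
        neff=neff,
        resample_events=np.asarray(events),
        lam_map=lam_map,
        degeneracy_events=np.asarray(degen),
        final_lam_map_kde=final_map,
        config=config,
    )
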