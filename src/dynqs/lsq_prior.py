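"""Least-squares parameter fitting and the Monte-Carlo empirical prior.

The Monod model's kinetic parameters theta = (qS_max, Y_XC) are fitted by
minimising a weighted sum of squares combining sparse offline samples
(biomass and substrate concentrations) and dense online off-gas records
(CER, OUR), each block weighted by the inverse of the maximum variance
recorded per channel, with the online block scaled by |K|/|T| to balance
the very different sample counts.

Because the objective is flat in qS_max on data windows that only cover
the carbon-limited phase, parameter confidence is approximated
empirically: many random mini-batches of the dataset are refitted with
particle swarm optimization (a swarm size that cannot collapse below a
minimum per-particle step keeps solutions spread out in insensitive
directions), and the aggregated solutions define a kernel-density
empirical prior p(theta) for the Bayesian observer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import minimize
from scipy.stats import gaussian_kde

from .models import InputSignal, KineticParameters, ModelConstants, monod_rhs
from .simulate import offline_dispersion

__all__ = [
    "Dataset",
    "LSQConfig",
    "PSOSettings",
    "EmpiricalPrior",
    "objective_F",
    "fit_nelder_mead",
    "draw_minibatch",
    "pso_minimize",
    "build_empirical_prior",
]

DEFAULT_BOUNDS = {"qS_max": (0.2, 1.6), "Y_XC": (0.3, 0.8)}


@dataclass
class Dataset:
    """One experiment (or mini-batch window) in the package's CSV schema.

    offline : frame with t, X_d, S_d, sd_X, sd_S (concentrations, g/L)
    online  : frame with t, CER, OUR, u_in
    V0      : broth volume [L] at the first online time
    """

    offline: pd.DataFrame
    online: pd.DataFrame
    V0: float

    def volume_at(self, t: float) -> float:
        """Volume from V0 plus the trapezoid integral of the feed rate."""
        tt = self.online["t"].to_numpy(dtype=float)
        u = self.online["u_in"].to_numpy(dtype=float)
        if t <= tt[0]:
            return self.V0
        mask = tt <= t
        t_sub = np.append(tt[mask], t)
        u_sub = np.append(u[mask], np.interp(t, tt, u))
        return self.V0 + float(np.trapezoid(u_sub, t_sub))


@dataclass
class LSQConfig:
    """Weights and numerics of the weighted least-squares objective.

    R, Q hold the diagonal inverse-variance weights for the offline
    states [X, S] and online outputs [CER, OUR].  When None they are
    derived from the dataset: R from the maximum squared analytical
    dispersion per state, Q from (2% of the maximum absolute value of
    each output channel)^2.
    """

    R: Optional[np.ndarray] = None
    Q: Optional[np.ndarray] = None
    q_frac: float = 0.02
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    rtol: float = 1e-6
    atol: float = 1e-8

    def weights_for(self, data: Dataset) -> tuple[np.ndarray, np.ndarray]:
        if self.R is not None:
            R = np.asarray(self.R, dtype=float)
        else:
            R = 1.0 / np.array([
                max(np.max(data.offline["sd_X"].to_numpy() ** 2), 1e-12),
                max(np.max(data.offline["sd_S"].to_numpy() ** 2), 1e-12),
            ])
        if self.Q is not None:
            Q = np.asarray(self.Q, dtype=float)
        else:
            sig = self.q_frac * np.array([
                max(np.max(np.abs(data.online["CER"].to_numpy())), 1e-12),
                max(np.max(np.abs(data.online["OUR"].to_numpy())), 1e-12),
            ])
            Q = 1.0 / sig ** 2
        return R, Q


def _integrate_monod(theta: np.ndarray, data: Dataset,
                     consts: ModelConstants, config: LSQConfig):
    """Forward-integrate the Monod plant over the data window.

    Initial state comes from the earliest offline record; returns
    (offline predictions [g/L], online CER/OUR predictions) or None on
    integration failure.
    """
    params = KineticParameters(qS_max=float(theta[0]),
                               Y_XC=float(min(theta[1], 1.0)))
    toff = data.offline["t"].to_numpy(dtype=float)
    ton = data.online["t"].to_numpy(dtype=float)
    t0 = toff[0]
    t_end = max(toff[-1], ton[-1])
    V_start = data.volume_at(t0)
    y0 = [data.offline["X_d"].iloc[0] * V_start,
          data.offline["S_d"].iloc[0] * V_start,
          V_start]
    tt = data.online["t"].to_numpy(dtype=float)
    uu = data.online["u_in"].to_numpy(dtype=float)
    inputs = InputSignal(u_in=lambda t: float(np.interp(t, tt, uu)))
    t_eval = np.unique(np.concatenate([toff, ton[(ton >= t0)]]))
    try:
        sol = solve_ivp(lambda t, y: monod_rhs(t, y, params, consts, inputs),
                        (t0, t_end), y0, t_eval=t_eval, method="LSODA",
                        rtol=config.rtol, atol=config.atol)
    except (ValueError, RuntimeError):
        return None
    if not sol.success:
        return None
    X, S, V = np.maximum(sol.y[0], 0.0), np.maximum(sol.y[1], 0.0), sol.y[2]
    qS = params.qS_max * (S / V) / (consts.k_S + S / V)
    cer = X * (qS / consts.MW_S * (1 - params.Y_XC) + consts.m_c)
    our = -np.abs((X / consts.gamma_O2) * (qS / consts.MW_S)
                  * (consts.gamma_X * params.Y_XC - consts.gamma_S))
    ix_off = np.searchsorted(sol.t, toff)
    ix_on = np.searchsorted(sol.t, ton[ton >= t0])
    x_pred = np.column_stack([(X / V)[ix_off], (S / V)[ix_off]])
    y_pred = np.column_stack([cer[ix_on], our[ix_on]])
    return x_pred, y_pred, ton[ton >= t0]


def objective_F(theta, data: Dataset, config: LSQConfig = LSQConfig(),
                consts: ModelConstants = ModelConstants()) -> float:
    """Weighted SSE cost F(theta) >= 0; +inf when integration fails.

    F = sum_k r_x^T R r_x  +  (|K|/|T|) * sum_t r_y^T Q r_y
    with both residual blocks computed from one forward integration.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        return float("inf")
    out = _integrate_monod(theta, data, consts, config)
    if out is None:
        return float("inf")
    x_pred, y_pred, t_on = out
    x_obs = data.offline[["X_d", "S_d"]].to_numpy(dtype=float)
    mask = data.online["t"].to_numpy(dtype=float) >= data.offline["t"].iloc[0]
    y_obs = data.online.loc[mask, ["CER", "OUR"]].to_numpy(dtype=float)
    R, Q = config.weights_for(data)
    rx = x_obs - x_pred
    ry = y_obs - y_pred
    K = x_obs.shape[0]
    T = max(y_obs.shape[0], 1)
    F_off = float(np.sum(rx ** 2 @ R))
    F_on = float(np.sum(ry ** 2 @ Q))
    return F_off + (K / T) * F_on


def fit_nelder_mead(data: Dataset, config: LSQConfig = LSQConfig(),
                    theta0: Sequence[float] = (0.8, 0.55),
                    consts: ModelConstants = ModelConstants(),
                    fatol: float = 1e-8, maxiter: int = 400):
    """Nelder-Mead minimisation of F; non-negativity via log-space simplex.

    Returns (theta_hat, cost, converged).  Non-convergence still returns
    the best point found.
    """

    def f_log(z):
        return objective_F(np.exp(z), data, config, consts)

    res = minimize(f_log, np.log(np.asarray(theta0, dtype=float)),
                   method="Nelder-Mead",
                   options={"fatol": fatol, "xatol": 1e-6, "maxiter": maxiter})
    return np.exp(res.x), float(res.fun), bool(res.success)


def draw_minibatch(data: Dataset, rng: np.random.Generator,
                   min_offline: int = 2) -> Dataset:
    """Random mini-batch: >=2 offline samples with injected analytical
    noise, plus all online records between the first and last of them.

    The earliest selected record supplies the initial condition of the
    forward integration (via the returned Dataset's offline frame).
    """
    n = len(data.offline)
    if n < min_offline:
        raise ValueError(f"dataset has {n} offline samples; need >= {min_offline}")
    k = int(rng.integers(min_offline, n + 1))
    idx = np.sort(rng.choice(n, size=k, replace=False))
    off = data.offline.iloc[idx].reset_index(drop=True).copy()
    X_d = np.maximum(off["X_d"] + rng.normal(0.0, off["sd_X"]), 0.0)
    S_d = np.maximum(off["S_d"] + rng.normal(0.0, off["sd_S"]), 0.0)
    sd_X, sd_S = offline_dispersion(X_d, S_d)
    off["X_d"], off["S_d"], off["sd_X"], off["sd_S"] = X_d, S_d, sd_X, sd_S
    t0, t1 = off["t"].iloc[0], off["t"].iloc[-1]
    on = data.online[(data.online["t"] >= t0) & (data.online["t"] <= t1)]
    on = on.reset_index(drop=True)
    return Dataset(offline=off, online=on, V0=data.volume_at(t0))


@dataclass(frozen=True)
class PSOSettings:
    """Global-best PSO settings; defaults are the reference configuration."""

    swarm_size: int = 100
    f_tol: float = 0.001
    max_iter: int = 20
    min_step: float = 0.001
    inertia: float = 0.7
    cognitive: float = 1.5
    social: float = 1.5


def pso_minimize(fun: Callable[[np.ndarray], float], bounds: Sequence[tuple],
                 settings: PSOSettings, rng: np.random.Generator):
    """Global-best particle swarm minimisation within box bounds.

    A per-particle velocity floor (min_step) prevents the swarm from
    collapsing in directions where the objective is insensitive, so flat
    regions keep their dispersion instead of overfitting to noise.
    Terminates when the best objective improves by less than f_tol
    between iterations, or after max_iter iterations.  Returns
    (x_best, f_best).
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    d = lo.size
    n = settings.swarm_size
    x = rng.uniform(lo, hi, size=(n, d))
    v = rng.uniform(-(hi - lo), hi - lo, size=(n, d)) * 0.1
    f = np.array([fun(xi) for xi in x])
    pbest, fpbest = x.copy(), f.copy()
    g = int(np.argmin(f))
    gbest, fgbest = x[g].copy(), float(f[g])
    for _ in range(settings.max_iter):
        r1 = rng.uniform(size=(n, d))
        r2 = rng.uniform(size=(n, d))
        v = (settings.inertia * v
             + settings.cognitive * r1 * (pbest - x)
             + settings.social * r2 * (gbest - x))
        speed = np.linalg.norm(v, axis=1)
        slow = speed < settings.min_step
        if np.any(slow):
            direction = rng.standard_normal((int(slow.sum()), d))
            direction /= np.linalg.norm(direction, axis=1, keepdims=True)
            v[slow] = np.where(speed[slow, None] > 1e-12,
                               v[slow] * (settings.min_step / speed[slow, None]),
                               settings.min_step * direction)
        x = np.clip(x + v, lo, hi)
        f = np.array([fun(xi) for xi in x])
        improved = f < fpbest
        pbest[improved], fpbest[improved] = x[improved], f[improved]
        g = int(np.argmin(fpbest))
        prev_best = fgbest
        if fpbest[g] < fgbest:
            gbest, fgbest = pbest[g].copy(), float(fpbest[g])
        if abs(prev_best - fgbest) < settings.f_tol:
            break
    return gbest, fgbest


class EmpiricalPrior:
    """Weighted-sample / KDE prior over (qS_max, Y_XC).

    Wraps the aggregated Monte-Carlo PSO solutions with a Gaussian KDE
    (Scott's rule, per-dimension bandwidth floor applied through sample
    jitter when the solutions are nearly degenerate).  Sampling rejects
    draws outside the search bounds.
    """

    BW_FLOOR = 1e-3

    def __init__(self, samples: np.ndarray,
                 bounds: dict = DEFAULT_BOUNDS,
                 batch_ids: Optional[np.ndarray] = None):
        samples = np.atleast_2d(np.asarray(samples, dtype=float))
        if samples.shape[1] != 2:
            raise ValueError("samples must be (n, 2): (qS_max, Y_XC)")
        self.samples = samples
        self.bounds = {k: tuple(v) for k, v in bounds.items()}
        self.batch_ids = (np.asarray(batch_ids) if batch_ids is not None
                          else np.zeros(len(samples), dtype=int))
        self._kde = None

    @property
    def kde(self) -> gaussian_kde:
        if self._kde is None:
            pts = self.samples.T.copy()
            if pts.shape[1] < 2:
                pts = np.repeat(pts, 16, axis=1)
            # bandwidth floor: jitter near-degenerate sample clouds so
            # Scott's factor cannot yield a singular kernel covariance
            cov = np.atleast_2d(np.cov(pts))
            if (not np.all(np.isfinite(cov))
                    or np.min(np.linalg.eigvalsh(cov)) < self.BW_FLOOR ** 2):
                rng = np.random.default_rng(0)
                pts = pts + rng.normal(0.0, self.BW_FLOOR, pts.shape)
            self._kde = gaussian_kde(pts)
        return self._kde

    def pdf(self, theta) -> np.ndarray:
        return self.kde(np.atleast_2d(np.asarray(theta, dtype=float)).T)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        lo = np.array([self.bounds["qS_max"][0], self.bounds["Y_XC"][0]])
        hi = np.array([self.bounds["qS_max"][1], self.bounds["Y_XC"][1]])
        out = np.empty((0, 2))
        while out.shape[0] < n:
            draw = self.kde.resample(2 * n, seed=rng).T
            ok = np.all((draw >= lo) & (draw <= hi), axis=1)
            out = np.vstack([out, draw[ok]])
        return out[:n]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"qS_max": self.samples[:, 0],
                             "Y_XC": self.samples[:, 1],
                             "source_batch_id": self.batch_ids})

    def to_json(self) -> str:
        return json.dumps({
            "kernel": "gaussian",
            "bandwidth": "scott+floor1e-3",
            "bounds": self.bounds,
            "samples": self.samples.tolist(),
            "batch_ids": self.batch_ids.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "EmpiricalPrior":
        obj = json.loads(text)
        return cls(np.asarray(obj["samples"]), obj["bounds"],
                   np.asarray(obj["batch_ids"]))


def build_empirical_prior(datasets: Sequence[Dataset], rng: np.random.Generator,
                          n_batches: int = 100,
                          settings: PSOSettings = PSOSettings(),
                          config: LSQConfig = LSQConfig(),
                          consts: ModelConstants = ModelConstants()) -> EmpiricalPrior:
    """Aggregate Monte-Carlo PSO fits over random mini-batches.

    Each dataset is resampled ``n_batches`` times; every mini-batch is
    refitted by PSO inside the search bounds, and the solutions form the
    empirical prior.  Raises if every fit fails.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    bounds = [config.bounds["qS_max"], config.bounds["Y_XC"]]
    thetas, ids = [], []
    for i, data in enumerate(datasets):
        for b in range(n_batches):
            mb = draw_minibatch(data, rng)
            theta, cost = pso_minimize(
                lambda th: objective_F(th, mb, config, consts),
                bounds, settings, rng)
            if np.isfinite(cost):
                thetas.append(theta)
                ids.append(i * n_batches + b)
    if not thetas:
        raise RuntimeError("all mini-batch fits failed")
    return EmpiricalPrior(np.asarray(thetas), config.bounds, np.asarray(ids))
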