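"""Hierarchical two-state switching state-space model for Argos tracks.

Process model: a first-difference correlated random walk (DCRW) on the
regular grid.  With ``d_t = x_t - x_{t-1}`` the displacement of an animal
between successive grid times (lon/lat degrees),

    d_t | d_{t-1}, b_t  ~  N2( gamma[b] * T(theta[b]) @ d_{t-1}, Sigma )

where ``T(theta)`` is the rotation matrix, ``gamma[b]`` the move-persistence
coefficient and ``b_t in {1, 2}`` a latent behavioural state (1 = transiting:
theta near 0, high gamma; 2 = area-restricted search: low gamma, frequent
reversals).  Behaviours follow a first-order Markov chain with switching
probabilities ``alpha = (P(1|1), P(1|2))``.  Movement parameters are shared
across all animals of a species (the hierarchical part); states and
behaviours are per-animal.

Observation model: each Argos fix ``y`` in grid interval ``(t, j)`` is the
linearly interpolated state ``(1-j) x_t + j x_{t+1}`` plus independent
scaled-t errors in lon and lat whose scale and degrees of freedom depend on
the fix's Argos location class.

Inference is MCMC (Metropolis-within-Gibbs): single-site random-walk
Metropolis updates of the states vectorised over a 3-colouring of the grid,
exact Gibbs updates of the behaviours over a 2-colouring, and adaptive
random-walk Metropolis for the shared movement parameters (adaptation frozen
after burn-in).  The default protocol is 2 chains x 50000 iterations with
45000 burn-in and thinning by 5.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import gammaln

from .exceptions import AnalysisError, ConfigurationError, ParameterError
from .track_io import LOCATION_CLASSES, RegularGrid, Track, build_time_grid

logger = logging.getLogger("whaletrack")

LOG2PI = math.log(2.0 * math.pi)

#: behaviour-mean cut-offs: b_mean < 1.25 -> transiting, > 1.75 -> ARS
B_TRANSIT_CUTOFF = 1.25
B_ARS_CUTOFF = 1.75

DEFAULT_MCMC = {"n_chains": 2, "n_iter": 50_000, "burn_in": 45_000, "thin": 5}

PARAM_NAMES = ("theta1", "theta2", "gamma1", "gamma2",
               "alpha1", "alpha2", "sigma_lon", "sigma_lat", "rho")


# ---------------------------------------------------------------------------
# Domain types

@dataclass
class MovementParams:
    """Shared DCRW movement parameters.

    theta : mean turn angle (radians) per behaviour, index 0 = transiting.
    gamma : move persistence in [0, 1] per behaviour; gamma[0] > gamma[1].
    Sigma : 2x2 positive-definite process covariance (degrees^2).
    alpha : (P(b_t=1 | b_{t-1}=1), P(b_t=1 | b_{t-1}=2)).
    """

    theta: np.ndarray
    gamma: np.ndarray
    Sigma: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.theta.shape != (2,) or self.gamma.shape != (2,) or self.alpha.shape != (2,):
            raise ParameterError("theta, gamma, alpha must each have 2 entries")
        if not (self.gamma[0] > self.gamma[1]):
            raise ParameterError(
                f"gamma ordering violated: transiting persistence {self.gamma[0]} "
                f"must exceed ARS persistence {self.gamma[1]}"
            )
        if np.any((self.gamma < 0) | (self.gamma > 1)):
            raise ParameterError("gamma components must lie in [0, 1]")
        if np.any((self.alpha <= 0) | (self.alpha >= 1)):
            raise ParameterError("alpha components must lie in (0, 1)")
        if self.Sigma.shape != (2, 2) or not np.allclose(self.Sigma, self.Sigma.T):
            raise ParameterError("Sigma must be symmetric 2x2")
        if np.linalg.eigvalsh(self.Sigma).min() <= 0:
            raise ParameterError("Sigma must be positive-definite")


def rotation_matrix(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


@dataclass
class ArgosErrorModel:
    """Per-location-class scaled-t error parameters (degrees).

    ``table`` maps each class in {3,2,1,0,A,B} to (nu, tau_lon, tau_lat).
    """

    table: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        for c in LOCATION_CLASSES:
            if c not in self.table:
                raise ConfigurationError(f"Argos error model missing class {c!r}")
            nu, tl, tb = self.table[c]
            if nu <= 0 or tl <= 0 or tb <= 0:
                raise ConfigurationError(f"class {c!r}: nu and scales must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "ArgosErrorModel":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        table = {
            str(c): (float(v["nu"]), float(v["tau_lon"]), float(v["tau_lat"]))
            for c, v in raw["classes"].items()
        }
        return cls(table)

    @classmethod
    def default(cls) -> "ArgosErrorModel":
        ref = importlib.resources.files("whaletrack") / "data" / "argos_error_model.yml"
        with importlib.resources.as_file(ref) as path:
            return cls.from_yaml(path)

    def params_for(self, loc_class: str) -> tuple[float, float, float]:
        try:
            return self.table[str(loc_class)]
        except KeyError:
            raise ConfigurationError(f"no error parameters for class {loc_class!r}")


@dataclass
class StateSeries:
    """Classified per-grid-time summary for one animal.

    ``frame`` columns: time, lon, lat, lon_lo, lon_hi, lat_lo, lat_hi,
    b_mean, behaviour in {"transiting", "ARS", "uncertain"}.
    """

    animal_id: str
    dt_hours: float
    frame: pd.DataFrame


@dataclass
class PosteriorFit:
    """Retained MCMC samples for a population of tracks.

    Arrays are indexed (chain, sample, ...); ``x_samples`` additionally by
    (animal, grid time, coord) and ``b_samples`` by (animal, grid time) with
    values in {1, 2} (entry t holds the behaviour of displacement t; entry 0
    mirrors entry 1).  Grid-time slots past an animal's ``n_states`` are
    padding.
    """

    animal_ids: list[str]
    t0: list[pd.Timestamp]
    dt_hours: float
    n_states: np.ndarray
    x_samples: np.ndarray        # (chains, keep, K, Tmax, 2) float32
    b_samples: np.ndarray        # (chains, keep, K, Tmax) uint8
    params: dict[str, np.ndarray]  # name -> (chains, keep)
    mcmc: dict

    @property
    def n_chains(self) -> int:
        return self.x_samples.shape[0]

    @property
    def n_keep(self) -> int:
        return self.x_samples.shape[1]

    def param_flat(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            animal_ids=np.array(self.animal_ids),
            t0=np.array([t.isoformat() for t in self.t0]),
            dt_hours=self.dt_hours,
            n_states=self.n_states,
            x_samples=self.x_samples,
            b_samples=self.b_samples,
            mcmc=np.array([repr(self.mcmc)]),
            **{f"param_{k}": v for k, v in self.params.items()},
        )

    @classmethod
    def load(cls, path) -> "PosteriorFit":
        import ast

        z = np.load(path, allow_pickle=False)
        params = {k[6:]: z[k] for k in z.files if k.startswith("param_")}
        return cls(
            animal_ids=[str(a) for a in z["animal_ids"]],
            t0=[pd.Timestamp(str(t)) for t in z["t0"]],
            dt_hours=float(z["dt_hours"]),
            n_states=z["n_states"],
            x_samples=z["x_samples"],
            b_samples=z["b_samples"],
            params=params,
            mcmc=ast.literal_eval(str(z["mcmc"][0])),
        )


# ---------------------------------------------------------------------------
# Elementary densities (also the public per-op contracts)

def _gauss2_ll(resid: np.ndarray, Sinv: np.ndarray, logdet: float) -> np.ndarray:
    """Log density of N2(0, Sigma) at residuals (..., 2), given the inverse."""
    quad = (Sinv[0, 0] * resid[..., 0] ** 2
            + 2.0 * Sinv[0, 1] * resid[..., 0] * resid[..., 1]
            + Sinv[1, 1] * resid[..., 1] ** 2)
    return -LOG2PI - 0.5 * logdet - 0.5 * quad


def _sigma_inv_logdet(Sigma: np.ndarray) -> tuple[np.ndarray, float]:
    det = Sigma[0, 0] * Sigma[1, 1] - Sigma[0, 1] ** 2
    if det <= 0 or not np.isfinite(det):
        raise np.linalg.LinAlgError("process covariance is singular")
    Sinv = np.array([[Sigma[1, 1], -Sigma[0, 1]], [-Sigma[0, 1], Sigma[0, 0]]]) / det
    return Sinv, math.log(det)


def process_loglik(d_prev, d_curr, b: int, params: MovementParams) -> float:
    """Log density of displacement ``d_curr`` given ``d_prev`` in behaviour ``b``.

    The mean is ``gamma[b] * T(theta[b]) @ d_prev`` and the covariance Sigma.
    """
    if b not in (1, 2):
        raise ParameterError(f"behaviour must be 1 or 2, got {b}")
    d_prev = np.asarray(d_prev, dtype=float)
    d_curr = np.asarray(d_curr, dtype=float)
    A = params.gamma[b - 1] * rotation_matrix(params.theta[b - 1])
    Sinv, logdet = _sigma_inv_logdet(params.Sigma)
    return float(_gauss2_ll(d_curr - A @ d_prev, Sinv, logdet))


def _t_logpdf(x: np.ndarray, nu, tau) -> np.ndarray:
    """Scaled Student-t log density (own closed form; scipy.stats.t agrees)."""
    const = (gammaln((nu + 1.0) / 2.0) - gammaln(nu / 2.0)
             - 0.5 * np.log(nu * np.pi) - np.log(tau))
    z = x / tau
    return const - (nu + 1.0) / 2.0 * np.log1p(z * z / nu)


def observation_loglik(x_t, x_next, j: float, y, em: ArgosErrorModel) -> float:
    """Log likelihood of one Argos fix given bracketing states.

    The predicted position is ``(1-j) x_t + j x_next``; lon and lat residuals
    get independent scaled-t densities with the fix's class parameters.
    """
    if not (0.0 <= j < 1.0):
        raise ParameterError(f"interpolation weight j must be in [0,1), got {j}")
    nu, tau_lon, tau_lat = em.params_for(y.loc_class)
    x_t = np.asarray(x_t, dtype=float)
    x_next = np.asarray(x_next, dtype=float)
    mu = (1.0 - j) * x_t + j * x_next
    return float(_t_logpdf(y.lon - mu[0], nu, tau_lon)
                 + _t_logpdf(y.lat - mu[1], nu, tau_lat))


# ---------------------------------------------------------------------------
# Sampler internals

class _Model:
    """Flattened multi-animal data plus the likelihood machinery."""

    def __init__(self, tracks: list[Track], dt_hours: float, em: ArgosErrorModel):
        self.K = len(tracks)
        self.dt_hours = dt_hours
        self.grids: list[RegularGrid] = [build_time_grid(tr, dt_hours) for tr in tracks]
        self.T = np.array([g.n_states for g in self.grids])
        self.Tmax = int(self.T.max())
        if self.Tmax < 4:
            raise ParameterError("tracks too short for the DCRW grid (need >=4 states)")

        obs_k, obs_t, obs_j, obs_y = [], [], [], []
        obs_nu, obs_tau = [], []
        for k, (tr, g) in enumerate(zip(tracks, self.grids)):
            n = len(tr.data)
            obs_k.append(np.full(n, k))
            obs_t.append(g.obs_interval)
            obs_j.append(g.obs_weight)
            obs_y.append(tr.lonlat)
            prm = np.array([em.params_for(c) for c in tr.loc_classes])
            obs_nu.append(prm[:, 0])
            obs_tau.append(prm[:, 1:3])
        self.obs_k = np.concatenate(obs_k)
        self.obs_t = np.concatenate(obs_t)
        self.obs_j = np.concatenate(obs_j)[:, None]          # (N,1)
        self.obs_y = np.concatenate(obs_y)                   # (N,2)
        self.obs_nu = np.concatenate(obs_nu)[:, None]        # (N,1)
        self.obs_tau = np.concatenate(obs_tau)               # (N,2)
        self.obs_tnext = np.minimum(self.obs_t + 1, self.T[self.obs_k] - 1)
        self.obs_const = (gammaln((self.obs_nu + 1) / 2) - gammaln(self.obs_nu / 2)
                          - 0.5 * np.log(self.obs_nu * np.pi) - np.log(self.obs_tau))

        # 3-colour site lists for state updates
        self.site_k, self.site_t, self.site_slot = [], [], []
        slot_of = np.full((self.K, self.Tmax), -1, dtype=np.int64)
        for c in range(3):
            ks, ts = [], []
            for k in range(self.K):
                t = np.arange(c, self.T[k], 3)
                ks.append(np.full(len(t), k))
                ts.append(t)
            ks = np.concatenate(ks)
            ts = np.concatenate(ts)
            slot_of[ks, ts] = np.arange(len(ks))
            self.site_k.append(ks)
            self.site_t.append(ts)
        # observation attachments per colour (left node t, right node t+1)
        self.att = []
        for c in range(3):
            idx_l = np.nonzero(self.obs_t % 3 == c)[0]
            idx_r = np.nonzero((self.obs_tnext % 3 == c) & (self.obs_tnext != self.obs_t))[0]
            idx = np.concatenate([idx_l, idx_r])
            role = np.concatenate([np.zeros(len(idx_l), bool), np.ones(len(idx_r), bool)])
            node_t = np.where(role, self.obs_tnext[idx], self.obs_t[idx])
            slot = slot_of[self.obs_k[idx], node_t]
            self.att.append((idx, slot, role))

        # 2-parity behaviour site lists (displacement index t = 1 .. T_k-1)
        self.bsite_k, self.bsite_t = [], []
        for p in range(2):
            ks, ts = [], []
            for k in range(self.K):
                t = np.arange(1, self.T[k])
                t = t[t % 2 == p]
                ks.append(np.full(len(t), k))
                ts.append(t)
            self.bsite_k.append(np.concatenate(ks))
            self.bsite_t.append(np.concatenate(ts))

        # masks for the full process / markov log-likelihood (term index 2..Tmax-1)
        tt = np.arange(2, self.Tmax)
        self.proc_mask = tt[None, :] <= (self.T[:, None] - 1)       # (K, Tmax-2)
        tm = np.arange(1, self.Tmax - 1)
        self.markov_mask = (tm[None, :] + 1) <= (self.T[:, None] - 1)

    # -- likelihood pieces ---------------------------------------------------

    def obs_ll_full(self, X: np.ndarray) -> float:
        j = self.obs_j
        mu = (1 - j) * X[self.obs_k, self.obs_t] + j * X[self.obs_k, self.obs_tnext]
        z = (self.obs_y - mu) / self.obs_tau
        ll = self.obs_const - (self.obs_nu + 1) / 2 * np.log1p(z * z / self.obs_nu)
        return float(ll.sum())

    def proc_ll_full(self, X, B, A1, A2, Sinv, logdet) -> float:
        D = X[:, 1:] - X[:, :-1]                  # D[:, t-1] = d_t
        Dp, Dc = D[:, :-1], D[:, 1:]              # d_{t-1}, d_t for t = 2..Tmax-1
        b = B[:, 2:]                              # behaviour of displacement t
        mean = np.where((b == 1)[..., None], Dp @ A1.T, Dp @ A2.T)
        ll = _gauss2_ll(Dc - mean, Sinv, logdet)
        return float(np.sum(ll, where=self.proc_mask))

    def markov_ll_full(self, B, logP) -> float:
        b_prev = B[:, 1:-1] - 1
        b_next = B[:, 2:] - 1
        ll = logP[b_prev, b_next]
        return float(np.sum(ll, where=self.markov_mask))

    def site_proc_ll(self, c, X, B, xt, A1, A2, Sinv, logdet) -> np.ndarray:
        """Summed process terms touching each colour-c site, with x_site = xt."""
        k, t = self.site_k[c], self.site_t[c]
        Tk = self.T[k]
        lim = self.Tmax - 1
        xm2 = X[k, np.clip(t - 2, 0, lim)]
        xm1 = X[k, np.clip(t - 1, 0, lim)]
        xp1 = X[k, np.clip(t + 1, 0, lim)]
        xp2 = X[k, np.clip(t + 2, 0, lim)]
        out = np.zeros(len(k))
        for off, (da, db_) in enumerate((((xm1, xm2), (xt, xm1)),
                                         ((xt, xm1), (xp1, xt)),
                                         ((xp1, xt), (xp2, xp1)))):
            tau = t + off
            act = (tau >= 2) & (tau <= Tk - 1)
            if not act.any():
                continue
            b = B[k, np.clip(tau, 0, lim)]
            d_prev = da[0] - da[1]
            d_curr = db_[0] - db_[1]
            mean = np.where((b == 1)[:, None], d_prev @ A1.T, d_prev @ A2.T)
            ll = _gauss2_ll(d_curr - mean, Sinv, logdet)
            out += np.where(act, ll, 0.0)
        return out

    def site_obs_ll(self, c, X, xt) -> np.ndarray:
        idx, slot, role = self.att[c]
        if len(idx) == 0:
            return np.zeros(len(self.site_k[c]))
        left = np.where(role[:, None], X[self.obs_k[idx], self.obs_t[idx]], xt[slot])
        right = np.where(role[:, None], xt[slot], X[self.obs_k[idx], self.obs_tnext[idx]])
        j = self.obs_j[idx]
        mu = (1 - j) * left + j * right
        z = (self.obs_y[idx] - mu) / self.obs_tau[idx]
        ll = (self.obs_const[idx]
              - (self.obs_nu[idx] + 1) / 2 * np.log1p(z * z / self.obs_nu[idx])).sum(axis=1)
        return np.bincount(slot, weights=ll, minlength=len(self.site_k[c]))

    def init_states(self, rng: np.random.Generator, jitter: float = 0.0) -> np.ndarray:
        """Linear interpolation of the observed fixes onto each animal's grid."""
        X = np.zeros((self.K, self.Tmax, 2))
        for k, g in enumerate(self.grids):
            sel = self.obs_k == k
            ot = self.obs_t[sel] + self.obs_j[sel, 0]
            order = np.argsort(ot, kind="mergesort")
            gt = np.arange(g.n_states, dtype=float)
            for c in range(2):
                y = self.obs_y[sel][:, c]
                X[k, : g.n_states, c] = np.interp(gt, ot[order], y[order])
                X[k, g.n_states:, c] = X[k, g.n_states - 1, c]
        if jitter > 0:
            X += rng.normal(0.0, jitter, size=X.shape)
        return X


def _halfnormal_lp(x: float, scale: float) -> float:
    return -0.5 * (x / scale) ** 2 if x > 0 else -np.inf


def _log_prior(name: str, v: float) -> float:
    """Priors: theta1 ~ U(-pi/4, pi/4); theta2 ~ U(-pi, pi]; gamma1 ~ Beta(2,1);
    gamma2 ~ Beta(1,2); alpha ~ Beta(1,1); sigma ~ HalfNormal(0.1 deg);
    rho ~ U(-1, 1).  (Ordering gamma1 > gamma2 is enforced separately.)"""
    if name == "theta1":
        return 0.0 if abs(v) < math.pi / 4 else -np.inf
    if name == "theta2":
        return 0.0
    if name == "gamma1":
        return math.log(2 * v) if 0 < v < 1 else -np.inf
    if name == "gamma2":
        return math.log(2 * (1 - v)) if 0 < v < 1 else -np.inf
    if name in ("alpha1", "alpha2"):
        return 0.0 if 0 < v < 1 else -np.inf
    if name in ("sigma_lon", "sigma_lat"):
        return _halfnormal_lp(v, 0.1)
    if name == "rho":
        return 0.0 if -1 < v < 1 else -np.inf
    raise KeyError(name)


def _params_from_dict(p: dict) -> tuple:
    """(A1, A2, Sinv, logdet, logP) from the scalar parameter dict."""
    A1 = p["gamma1"] * rotation_matrix(p["theta1"])
    A2 = p["gamma2"] * rotation_matrix(p["theta2"])
    sl, sb, rho = p["sigma_lon"], p["sigma_lat"], p["rho"]
    Sigma = np.array([[sl * sl, rho * sl * sb], [rho * sl * sb, sb * sb]])
    Sinv, logdet = _sigma_inv_logdet(Sigma)
    a1, a2 = p["alpha1"], p["alpha2"]
    logP = np.log(np.array([[a1, 1 - a1], [a2, 1 - a2]]))
    return A1, A2, Sinv, logdet, logP


def _init_params(rng: np.random.Generator) -> dict:
    """Overdispersed start drawn from the priors (ordering enforced)."""
    while True:
        g1, g2 = rng.beta(2, 1), rng.beta(1, 2)
        if g1 > g2 + 0.05:
            break
    return {
        "theta1": rng.uniform(-math.pi / 8, math.pi / 8),
        "theta2": rng.uniform(-math.pi, math.pi),
        "gamma1": g1,
        "gamma2": g2,
        "alpha1": rng.uniform(0.5, 0.95),
        "alpha2": rng.uniform(0.05, 0.5),
        "sigma_lon": rng.uniform(0.02, 0.1),
        "sigma_lat": rng.uniform(0.02, 0.1),
        "rho": rng.uniform(-0.3, 0.3),
    }


_TRANSFORMS = {
    # name -> (to_unconstrained, to_constrained, log|d constrained/d unconstrained|)
    "gamma1": "logit", "gamma2": "logit", "alpha1": "logit", "alpha2": "logit",
    "sigma_lon": "log", "sigma_lat": "log", "rho": "atanh",
    "theta1": "id", "theta2": "wrap",
}


def _propose(name: str, v: float, step: float, rng) -> tuple[float, float]:
    """Random-walk proposal on the transformed scale; returns (v', log Jacobian ratio)."""
    kind = _TRANSFORMS[name]
    e = rng.normal(0.0, step)
    if kind == "id":
        return v + e, 0.0
    if kind == "wrap":
        w = v + e
        w = math.pi - math.fmod(math.pi - w, 2 * math.pi)
        if w > math.pi:
            w -= 2 * math.pi
        return w, 0.0
    if kind == "logit":
        z = math.log(v / (1 - v)) + e
        w = 1.0 / (1.0 + math.exp(-z))
        ljr = (math.log(w) + math.log1p(-w)) - (math.log(v) + math.log1p(-v))
        return w, ljr
    if kind == "log":
        w = v * math.exp(e)
        return w, math.log(w) - math.log(v)
    if kind == "atanh":
        z = math.atanh(v) + e
        w = math.tanh(z)
        ljr = math.log1p(-w * w) - math.log1p(-v * v)
        return w, ljr
    raise KeyError(kind)


def _run_chain(model: _Model, mcmc: dict, seed_seq: np.random.SeedSequence,
               store_x: bool = True) -> dict:
    rng = np.random.default_rng(seed_seq)
    n_iter, burn_in, thin = mcmc["n_iter"], mcmc["burn_in"], mcmc["thin"]
    n_keep = (n_iter - burn_in) // thin

    for attempt in range(5):
        p = _init_params(rng)
        X = model.init_states(rng, jitter=0.002)
        B = rng.integers(1, 3, size=(model.K, model.Tmax)).astype(np.int8)
        A1, A2, Sinv, logdet, logP = _params_from_dict(p)
        ll0 = (model.proc_ll_full(X, B, A1, A2, Sinv, logdet)
               + model.obs_ll_full(X) + model.markov_ll_full(B, logP))
        if np.isfinite(ll0):
            break
    else:
        raise AnalysisError("non-finite likelihood at initialization after 5 retries")

    step_x = 0.01
    steps = {n: 0.1 for n in PARAM_NAMES}
    acc_x, try_x = 0, 0
    acc = {n: 0 for n in PARAM_NAMES}

    keep = {
        "x": np.zeros((n_keep, model.K, model.Tmax, 2), dtype=np.float32) if store_x else None,
        "b": np.zeros((n_keep, model.K, model.Tmax), dtype=np.uint8),
        "params": {n: np.zeros(n_keep) for n in PARAM_NAMES},
    }
    kidx = 0

    for it in range(n_iter):
        # --- states: 3-colour vectorised single-site Metropolis
        for c in rng.permutation(3):
            k, t = model.site_k[c], model.site_t[c]
            cur = X[k, t]
            prop = cur + rng.normal(0.0, step_x, size=cur.shape)
            d = (model.site_proc_ll(c, X, B, prop, A1, A2, Sinv, logdet)
                 - model.site_proc_ll(c, X, B, cur, A1, A2, Sinv, logdet)
                 + model.site_obs_ll(c, X, prop) - model.site_obs_ll(c, X, cur))
            ok = np.log(rng.uniform(size=len(d))) < d
            X[k[ok], t[ok]] = prop[ok]
            acc_x += int(ok.sum())
            try_x += len(ok)

        # --- behaviours: 2-parity Gibbs
        for pnum in rng.permutation(2):
            k, t = model.bsite_k[pnum], model.bsite_t[pnum]
            lim = model.Tmax - 1
            d_curr = X[k, t] - X[k, np.clip(t - 1, 0, lim)]
            d_prev = X[k, np.clip(t - 1, 0, lim)] - X[k, np.clip(t - 2, 0, lim)]
            has_proc = t >= 2
            lp = np.zeros((len(k), 2))
            for s, A in ((0, A1), (1, A2)):
                ll = _gauss2_ll(d_curr - d_prev @ A.T, Sinv, logdet)
                lp[:, s] = np.where(has_proc, ll, 0.0)
            left_ok = t >= 2
            bl = B[k, np.clip(t - 1, 0, lim)] - 1
            lp += np.where(left_ok[:, None], logP[bl], 0.0)
            right_ok = (t + 1) <= model.T[k] - 1
            br = B[k, np.clip(t + 1, 0, lim)] - 1
            lp += np.where(right_ok[:, None], logP[:, br].T, 0.0)
            p1 = 1.0 / (1.0 + np.exp(lp[:, 1] - lp[:, 0]))
            B[k, t] = np.where(rng.uniform(size=len(k)) < p1, 1, 2).astype(np.int8)
        B[:, 0] = B[:, 1]

        # --- shared movement parameters: component-wise adaptive RWM
        proc_cur = model.proc_ll_full(X, B, A1, A2, Sinv, logdet)
        markov_cur = model.markov_ll_full(B, logP)
        for name in PARAM_NAMES:
            v = p[name]
            w, ljr = _propose(name, v, steps[name], rng)
            lp_prior = _log_prior(name, w)
            if not np.isfinite(lp_prior):
                continue
            cand = dict(p)
            cand[name] = w
            if not (cand["gamma1"] > cand["gamma2"]):
                continue
            if name in ("alpha1", "alpha2"):
                _, _, _, _, logP_c = _params_from_dict(cand)
                markov_new = model.markov_ll_full(B, logP_c)
                d = markov_new - markov_cur + lp_prior - _log_prior(name, v) + ljr
                if math.log(rng.uniform()) < d:
                    p = cand
                    logP = logP_c
                    markov_cur = markov_new
                    acc[name] += 1
            else:
                A1_c, A2_c, Sinv_c, logdet_c, _ = _params_from_dict(cand)
                proc_new = model.proc_ll_full(X, B, A1_c, A2_c, Sinv_c, logdet_c)
                d = proc_new - proc_cur + lp_prior - _log_prior(name, v) + ljr
                if math.log(rng.uniform()) < d:
                    p = cand
                    A1, A2, Sinv, logdet = A1_c, A2_c, Sinv_c, logdet_c
                    proc_cur = proc_new
                    acc[name] += 1

        # --- adaptation (burn-in only, window of 100)
        if it < burn_in and (it + 1) % 100 == 0:
            rate = acc_x / max(try_x, 1)
            step_x = float(np.clip(step_x * math.exp(rate - 0.35), 1e-5, 1.0))
            acc_x = try_x = 0
            for name in PARAM_NAMES:
                r = acc[name] / 100.0
                steps[name] = float(np.clip(steps[name] * math.exp(r - 0.44), 1e-4, 3.0))
                acc[name] = 0

        if it >= burn_in and (it - burn_in) % thin == 0 and kidx < n_keep:
            if store_x:
                keep["x"][kidx] = X
            keep["b"][kidx] = B
            for name in PARAM_NAMES:
                keep["params"][name][kidx] = p[name]
            kidx += 1

        if (it + 1) % 5000 == 0:
            logger.debug("iter %d/%d step_x=%.4g gamma=(%.3f, %.3f)",
                         it + 1, n_iter, step_x, p["gamma1"], p["gamma2"])

    if not store_x:
        keep["x"] = np.zeros((0, model.K, model.Tmax, 2), dtype=np.float32)
    return keep


def fit_hssm(tracks: list[Track], dt_hours: float,
             error_model: ArgosErrorModel | None = None,
             mcmc: dict | None = None, seed: int = 0) -> PosteriorFit:
    """Fit the hierarchical switching state-space model to a set of tracks.

    All tracks must share a species/time step; movement parameters are pooled
    across animals while states and behaviours stay per-animal.  Deterministic
    given ``seed`` and inputs.
    """
    if not tracks:
        raise ParameterError("need at least one track")
    species = {tr.species for tr in tracks}
    if len(species) > 1:
        raise ParameterError(f"all tracks must share a species, got {sorted(species)}")
    if error_model is None:
        error_model = ArgosErrorModel.default()
    settings = dict(DEFAULT_MCMC)
    if mcmc:
        settings.update(mcmc)
    n_iter, burn_in = settings["n_iter"], settings["burn_in"]
    if min(settings["n_chains"], n_iter, burn_in, settings["thin"]) <= 0 or burn_in >= n_iter:
        raise ParameterError(f"invalid MCMC settings {settings}")

    model = _Model(tracks, dt_hours, error_model)
    logger.info("fitting hSSSM: %d animals, Tmax=%d states, %d obs, %d chains x %d iter",
                model.K, model.Tmax, len(model.obs_k),
                settings["n_chains"], n_iter)

    children = np.random.SeedSequence(seed).spawn(settings["n_chains"])
    chains = [_run_chain(model, settings, ss) for ss in children]

    return PosteriorFit(
        animal_ids=[tr.animal_id for tr in tracks],
        t0=[g.t0 for g in model.grids],
        dt_hours=dt_hours,
        n_states=model.T.copy(),
        x_samples=np.stack([ch["x"] for ch in chains]),
        b_samples=np.stack([ch["b"] for ch in chains]),
        params={n: np.stack([ch["params"][n] for ch in chains]) for n in PARAM_NAMES},
        mcmc={**settings, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Diagnostics and classification

def potential_scale_reduction(chains: np.ndarray) -> float:
    """Gelman–Rubin PSRF for one scalar parameter, chains shaped (m, n).

    Floored at 1.0 so that identical chains report exactly 1.0; when the
    within-chain variance is 0 and the chain means agree, returns 1.0.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ParameterError("need >=2 chains to compute the Gelman-Rubin diagnostic")
    m, n = chains.shape
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = means.var(ddof=1)
    if W == 0.0:
        return 1.0 if np.allclose(means, means[0]) else np.inf
    var_plus = (n - 1) / n * W + B_over_n
    return max(1.0, math.sqrt(var_plus / W))


def gelman_rubin(fit: PosteriorFit) -> dict[str, float]:
    """Per-parameter potential scale reduction factors for a fit."""
    if fit.n_chains < 2:
        raise ParameterError(
            "Gelman-Rubin diagnostic needs >=2 chains; re-run the fit with n_chains >= 2"
        )
    return {name: potential_scale_reduction(fit.params[name]) for name in PARAM_NAMES}


def classify_b_mean(b_mean: np.ndarray) -> np.ndarray:
    """Apply the 1.25/1.75 cut-offs to behaviour means."""
    out = np.full(b_mean.shape, "uncertain", dtype=object)
    out[b_mean < B_TRANSIT_CUTOFF] = "transiting"
    out[b_mean > B_ARS_CUTOFF] = "ARS"
    return out


def classify_behaviour(fit: PosteriorFit) -> list[StateSeries]:
    """Summarise a fit into per-animal classified state series.

    ``b_mean`` at each grid time is the mean of the retained MCMC behaviour
    samples; locations are posterior medians with central 95% intervals.
    """
    if fit.b_samples.size == 0:
        raise ParameterError("fit contains no behaviour samples")
    out = []
    b_all = fit.b_samples.reshape(-1, *fit.b_samples.shape[2:]).astype(float)
    has_x = fit.x_samples.size > 0
    if has_x:
        x_all = fit.x_samples.reshape(-1, *fit.x_samples.shape[2:]).astype(float)
    for k, animal_id in enumerate(fit.animal_ids):
        Tk = int(fit.n_states[k])
        times = fit.t0[k] + pd.to_timedelta(np.arange(Tk) * fit.dt_hours, unit="h")
        b_mean = b_all[:, k, :Tk].mean(axis=0)
        if has_x:
            xs = x_all[:, k, :Tk, :]
            med = np.median(xs, axis=0)
            lo = np.percentile(xs, 2.5, axis=0)
            hi = np.percentile(xs, 97.5, axis=0)
        else:
            med = lo = hi = np.full((Tk, 2), np.nan)
        frame = pd.DataFrame(
            {
                "time": times,
                "lon": med[:, 0], "lat": med[:, 1],
                "lon_lo": lo[:, 0], "lon_hi": hi[:, 0],
                "lat_lo": lo[:, 1], "lat_hi": hi[:, 1],
                "b_mean": b_mean,
                "behaviour": classify_b_mean(b_mean),
            }
        )
        out.append(StateSeries(animal_id=animal_id, dt_hours=fit.dt_hours, frame=frame))
    return out
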