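"""Likelihood-based calibration of the pathway model.

Observed relative periosteal bone formation rates are modeled as normal
around the simulator's per-protocol means mu_i(theta) with per-protocol
variances profiled out analytically (sigma_i^2 = mean squared residual).
The six-parameter MLE is located by simulated annealing with random
restarts inside the admissible box; parameter knock-outs, nested
likelihood-ratio tests (young vs aged), profile-likelihood confidence
intervals and restoration experiments are built on top of the same
machinery.

The user-facing surface is :class:`CaNFATCalibrator`, a scikit-learn style
estimator (``fit`` / ``predict`` / ``score``); the module-level functions
are the underlying primitives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .abm import simulate_bout
from .histomorphometry import protocol_rmar, tissue_outcomes
from .mechanics import LoadingProtocol
from .network import CellNetwork
from .params import (PARAM_NAMES, ParameterVector, SimConstants,
                     bounds_array)

OBS_COLUMNS = ["protocol_id", "animal_id", "peak_strain_ue", "rp_bfr"]

#: Variance floor preventing log-likelihood divergence at perfect fits.
VAR_FLOOR = 1e-8


class ObservationTable:
    """Per-animal rp.BFR observations, one row per (protocol, animal)."""

    def __init__(self, frame: pd.DataFrame):
        missing = set(OBS_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"observation table missing columns: {sorted(missing)}")
        if (frame["peak_strain_ue"] <= 0).any():
            raise ValueError("animal-specific peak strains must be > 0")
        self.frame = frame.reset_index(drop=True)
        pid = self.frame["protocol_id"].astype(str)
        self._values = {
            str(k): g["rp_bfr"].to_numpy(dtype=float)
            for k, g in self.frame.groupby(pid, sort=False)}
        self._mean_strain = {
            str(k): float(g["peak_strain_ue"].mean())
            for k, g in self.frame.groupby(pid, sort=False)}

    @property
    def protocol_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["protocol_id"].astype(str)))

    @property
    def n_total(self) -> int:
        return len(self.frame)

    def counts(self) -> dict[str, int]:
        return {str(k): int(v)
                for k, v in self.frame.groupby("protocol_id", sort=False).size().items()}

    def values_for(self, protocol_id) -> np.ndarray:
        return self._values[str(protocol_id)]

    def mean_strain(self, protocol_id) -> float:
        return self._mean_strain[str(protocol_id)]

    @classmethod
    def read_csv(cls, path) -> "ObservationTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


class MeanSimulator:
    """Computes per-protocol simulated means mu_i(theta), with caching.

    ``strain_mode`` selects whether each protocol is simulated once at its
    animals' mean peak strain (default; affordable under simulated
    annealing) or once per animal-specific strain with the results averaged.
    """

    def __init__(self, network: CellNetwork, protocols: list[LoadingProtocol],
                 constants: SimConstants = SimConstants(),
                 obs: ObservationTable | None = None,
                 strain_mode: str = "protocol_mean"):
        if strain_mode not in ("protocol_mean", "per_animal"):
            raise ValueError(f"unknown strain_mode {strain_mode!r}")
        self.network = network
        self.protocols = {p.id: p for p in protocols}
        self.constants = constants
        self.strain_mode = strain_mode
        self._mu_cache: dict = {}
        self._strains: dict[str, list[float]] = {}
        for pid, proto in self.protocols.items():
            if obs is not None and pid in set(obs.protocol_ids):
                sel = obs.frame["protocol_id"].astype(str) == str(pid)
                strains = obs.frame.loc[sel, "peak_strain_ue"].to_numpy(float)
            else:
                strains = np.array([proto.peak_strain])
            if strain_mode == "protocol_mean":
                self._strains[pid] = [float(strains.mean())]
            else:
                self._strains[pid] = [float(s) for s in strains]
        self.n_evals = 0
        # precomputed network structure and per-protocol timelines, so each
        # likelihood evaluation touches only the compiled kernel
        from .abm import _csr_adjacency
        from .mechanics import protocol_timeline, strain_field
        self._indptr, self._indices = _csr_adjacency(network)
        self._scale, _ = strain_field(network, 1.0)
        self._is_prec = np.array([c.kind == "precursor" for c in network.cells],
                                 dtype=np.bool_)
        self._is_peri = np.array(
            [c.kind == "precursor" and c.surface == "periosteal"
             for c in network.cells], dtype=np.bool_)[self._is_prec]
        self._timelines = {pid: protocol_timeline(p).astype(np.float64)
                           for pid, p in self.protocols.items()}

    def _mu_one(self, theta: ParameterVector, proto: LoadingProtocol,
                peak: float) -> float:
        from .abm import _run_bout, ca_drive_from_strain, rmar_from_nfat
        c = self.constants
        drive = np.asarray(ca_drive_from_strain(
            peak * self._scale, theta.strain_threshold), dtype=float)
        if not c.strain_on_precursors:
            drive = np.where(self._is_prec, 0.0, drive)
        dummy = np.zeros((1, 1))
        nfatn = _run_bout(
            self._timelines[proto.id], drive, self._indptr, self._indices,
            self._is_prec, float(theta.er_capacity),
            float(theta.er_recovery), float(theta.nfat_memory),
            float(c.gj_threshold), float(c.nfat_gain), float(c.nfatd_max),
            float(c.dt), int(c.ca_tail_s), int(c.nfat_tail_s),
            False, dummy, dummy, dummy, dummy)
        rmar = np.asarray(rmar_from_nfat(
            nfatn[self._is_prec], theta.nfat_capacity, theta.mar_max,
            c.sigmoidal_mar), dtype=float)
        peri = rmar[self._is_peri]
        if peri.size == 0:
            return 0.0
        active = peri > 1e-12
        if not active.any():
            return 0.0
        return float(active.mean() * peri[active].mean())

    def means(self, theta: ParameterVector) -> dict[str, float]:
        key = tuple(theta.to_array())
        if key in self._mu_cache:
            return self._mu_cache[key]
        mu = {}
        for pid, proto in self.protocols.items():
            vals = [self._mu_one(theta, proto, s) for s in self._strains[pid]]
            mu[pid] = float(np.mean(vals))
        self.n_evals += 1
        if len(self._mu_cache) > 4096:
            self._mu_cache.clear()
        self._mu_cache[key] = mu
        return mu


# ---------------------------------------------------------------------------
# likelihood

def profile_variances(obs: ObservationTable, mu: dict[str, float],
                      var_floor: float = VAR_FLOOR,
                      pooled: bool = False) -> dict[str, float]:
    """Per-protocol ML variances sigma_i^2 = mean((y_ij - mu_i)^2), floored.

    With ``pooled=True`` a single variance over all rows is used, which is
    the only option when some protocol has a single animal.
    """
    if pooled:
        resid = np.concatenate([
            obs.values_for(pid) - mu[str(pid)] for pid in obs.protocol_ids])
        v = max(float(np.mean(resid**2)), var_floor)
        return {pid: v for pid in obs.protocol_ids}
    out = {}
    for pid in obs.protocol_ids:
        y = obs.values_for(pid)
        if len(y) < 2:
            raise ValueError(
                f"protocol {pid!r} has a single animal; per-protocol variance "
                "profiling is degenerate — use pooled=True")
        out[pid] = max(float(np.mean((y - mu[str(pid)]) ** 2)), var_floor)
    return out


def log_likelihood_from_means(obs: ObservationTable, mu: dict[str, float],
                              var_floor: float = VAR_FLOOR,
                              pooled: bool = False) -> float:
    """Normal log-likelihood at the profiled variances."""
    sigma2 = profile_variances(obs, mu, var_floor, pooled)
    ll = 0.0
    for pid in obs.protocol_ids:
        y = obs.values_for(pid)
        v = sigma2[pid]
        ss = float(np.sum((y - mu[str(pid)]) ** 2))
        ll += -0.5 * len(y) * math.log(2 * math.pi * v) - ss / (2 * v)
    return ll


def log_likelihood(obs: ObservationTable, theta: ParameterVector,
                   simulator: MeanSimulator, **kwargs) -> float:
    return log_likelihood_from_means(obs, simulator.means(theta), **kwargs)


# ---------------------------------------------------------------------------
# simulated annealing

@dataclass(frozen=True)
class SAConfig:
    """Simulated-annealing schedule (geometric cooling, random restarts)."""

    n_restarts: int = 5
    steps_per_temp: int = 50
    cooling: float = 0.95
    t_initial: float = 10.0
    t_min: float = 1e-3
    step_scale: float = 0.1          # proposal sd as a fraction of range
    max_evals_per_restart: int | None = 2000
    polish_evals: int = 0            # Powell refinement budget (0 = off)
    polish_each_restart: bool = False  # refine every restart's best, not
    # just the overall winner (helps when restarts land in distinct basins)

    def __post_init__(self):
        if self.n_restarts < 1 or self.steps_per_temp < 1:
            raise ValueError("SA config requires at least one restart and one step")
        if not (0 < self.cooling < 1):
            raise ValueError("cooling factor must be in (0, 1)")


@dataclass
class SAResult:
    x: np.ndarray
    fun: float                        # maximized objective
    trace: pd.DataFrame               # restart, temperature, best, n_evals
    n_evals: int
    seed: int
    restart_bests: list = None        # (x, f) per restart, best first


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    rng_w = hi - lo
    out = x.copy()
    free = rng_w > 0
    over = free & (out > hi)
    out[over] = 2 * hi[over] - out[over]
    under = free & (out < lo)
    out[under] = 2 * lo[under] - out[under]
    return np.clip(out, lo, hi)


class _BoxTransform:
    """Search-space transform for box-constrained annealing.

    Parameters whose admissible range spans more than ``log_span`` are
    searched in log(x - lo + eps) coordinates, so proposals move them
    multiplicatively — essential when scale-like parameters (store
    capacity, DNA-binding capacity) trade off against each other along
    ridges spanning decades.  Narrow parameters stay linear.
    """

    def __init__(self, lo, hi, log_span: float = 30.0):
        self.lo, self.hi = lo, hi
        width = hi - lo
        self.eps = width * 1e-6
        self.is_log = (width > log_span)
        self.zlo = np.where(self.is_log,
                            np.log(np.maximum(self.eps, 1e-300)), lo)
        self.zhi = np.where(self.is_log,
                            np.log(np.maximum(width + self.eps, 1e-300)), hi)

    def to_z(self, x):
        z = np.asarray(x, dtype=float).copy()
        z[self.is_log] = np.log(x[self.is_log] - self.lo[self.is_log]
                                + self.eps[self.is_log])
        return z

    def from_z(self, z):
        x = np.asarray(z, dtype=float).copy()
        x[self.is_log] = (np.exp(z[self.is_log]) - self.eps[self.is_log]
                          + self.lo[self.is_log])
        return np.clip(x, self.lo, self.hi)


def anneal(objective, bounds, config: SAConfig = SAConfig(), seed: int = 0,
           x0_list: list[np.ndarray] | None = None) -> SAResult:
    """Maximize ``objective`` over a box by simulated annealing.

    Proposals are Gaussian, reflected at the bounds; parameters whose
    bounds collapse (lo == hi) stay fixed.  Warm starts in ``x0_list``
    seed the first restarts (and are always evaluated, so the result can
    never be worse than the best warm start).
    """
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    if np.any(lo > hi):
        raise ValueError("invalid bounds: lower > upper")
    rng = np.random.default_rng(seed)
    free = hi > lo
    tf = _BoxTransform(lo, hi)
    zspan = np.where(free, tf.zhi - tf.zlo, 0.0)
    best_x, best_f = None, -np.inf
    trace_rows = []
    n_evals = 0
    starts = [np.clip(np.asarray(s, dtype=float), lo, hi)
              for s in (x0_list or [])]
    warm_best, warm_best_f = None, -np.inf
    for s in starts:
        fs = objective(s)
        n_evals += 1
        if fs > warm_best_f:
            warm_best, warm_best_f = s, fs
        if fs > best_f:
            best_x, best_f = s.copy(), fs
    restart_bests: list = []
    for r in range(config.n_restarts):
        if r == 0 and warm_best is not None:
            x, f = warm_best.copy(), warm_best_f
        else:
            z0 = tf.zlo + (tf.zhi - tf.zlo) * rng.random(len(lo))
            x = np.where(free, tf.from_z(z0), lo)
            f = objective(x)
            n_evals += 1
        r_best_x, r_best_f = x.copy(), f
        if f > best_f:
            best_x, best_f = x.copy(), f
        z = tf.to_z(x)
        temp = config.t_initial
        evals_this = 1
        while temp > config.t_min:
            for _ in range(config.steps_per_temp):
                scale = config.step_scale * (0.1 + 0.9 * temp / config.t_initial)
                zp = z + np.where(free, rng.normal(0, 1, len(lo)) * scale * zspan, 0.0)
                zp = _reflect(zp, tf.zlo, tf.zhi)
                prop = np.where(free, tf.from_z(zp), lo)
                fp = objective(prop)
                n_evals += 1
                evals_this += 1
                if fp > r_best_f:
                    r_best_x, r_best_f = prop.copy(), fp
                if fp > best_f:
                    best_x, best_f = prop.copy(), fp
                delta = fp - f
                if delta >= 0 or rng.random() < math.exp(delta / temp):
                    x, z, f = prop, zp, fp
                if (config.max_evals_per_restart is not None
                        and evals_this >= config.max_evals_per_restart):
                    break
            trace_rows.append((r, temp, best_f, n_evals))
            if (config.max_evals_per_restart is not None
                    and evals_this >= config.max_evals_per_restart):
                break
            temp *= config.cooling
        if config.polish_each_restart and config.polish_evals > 0:
            px, pf, used = _polish(objective, r_best_x, r_best_f, tf, free,
                                   config.polish_evals)
            n_evals += used
            r_best_x, r_best_f = px, pf
            if pf > best_f:
                best_x, best_f = px, pf
            trace_rows.append((r, 0.0, best_f, n_evals))
        restart_bests.append((r_best_x.copy(), float(r_best_f)))
    if not config.polish_each_restart and config.polish_evals > 0:
        best_x, best_f, used = _polish(objective, best_x, best_f, tf, free,
                                       config.polish_evals)
        n_evals += used
        trace_rows.append((-1, 0.0, best_f, n_evals))
    trace = pd.DataFrame(trace_rows,
                         columns=["restart", "temperature", "best", "n_evals"])
    restart_bests.sort(key=lambda t: -t[1])
    return SAResult(best_x, best_f, trace, n_evals, seed, restart_bests)


def _polish(objective, x, f, tf: _BoxTransform, free, maxfev):
    """Deterministic Powell refinement over the free coordinates, run in
    the (log-aware) search coordinates; effective because the profiled
    likelihood is smooth in these coordinates."""
    from scipy.optimize import minimize

    idx = np.flatnonzero(free)
    if idx.size == 0:
        return x, f, 0
    z0 = tf.to_z(x)

    def neg(sub):
        z = z0.copy()
        z[idx] = np.clip(sub, tf.zlo[idx], tf.zhi[idx])
        full = np.where(free, tf.from_z(z), tf.lo)
        return -objective(full)

    res = minimize(neg, z0[idx], method="Powell",
                   bounds=list(zip(tf.zlo[idx], tf.zhi[idx])),
                   options={"maxfev": maxfev, "xtol": 1e-8,
                            "ftol": 1e-10})
    if -res.fun > f:
        z = z0.copy()
        z[idx] = np.clip(res.x, tf.zlo[idx], tf.zhi[idx])
        out = np.where(free, tf.from_z(z), tf.lo)
        return out, float(-res.fun), int(res.nfev)
    return x, f, int(res.nfev)


# ---------------------------------------------------------------------------
# model fitting

@dataclass
class FitResult:
    theta: ParameterVector
    sigma2: dict[str, float]
    loglik: float
    mu: dict[str, float]
    trace: pd.DataFrame
    n_evals: int
    seed: int
    constants: SimConstants = field(default_factory=SimConstants)
    elites: list = field(default_factory=list)   # distinct restart optima

    def to_dict(self) -> dict:
        return {
            "theta": self.theta.to_dict(),
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "mu": self.mu,
            "n_evals": self.n_evals,
            "seed": self.seed,
            "constants": self.constants.to_dict(),
        }


def _fit_bounds(fixed: dict[str, float] | None = None,
                bounds: np.ndarray | None = None) -> np.ndarray:
    b = bounds_array() if bounds is None else np.asarray(bounds, float).copy()
    for name, value in (fixed or {}).items():
        if name not in PARAM_NAMES:
            raise KeyError(f"unknown parameter {name!r}")
        i = PARAM_NAMES.index(name)
        b[i] = (value, value)
    return b


def fit_abm(obs: ObservationTable, network: CellNetwork,
            protocols: list[LoadingProtocol],
            constants: SimConstants = SimConstants(),
            sa_config: SAConfig = SAConfig(), seed: int = 0,
            fixed: dict[str, float] | None = None,
            bounds: np.ndarray | None = None,
            strain_mode: str = "protocol_mean",
            pooled_variance: bool = False,
            x0_list: list[np.ndarray] | None = None) -> FitResult:
    """Maximum-likelihood fit of the six pathway parameters."""
    sim = MeanSimulator(network, protocols, constants, obs, strain_mode)
    b = _fit_bounds(fixed, bounds)

    def objective(x):
        theta = ParameterVector.from_array(x)
        return log_likelihood_from_means(obs, sim.means(theta),
                                         pooled=pooled_variance)

    res = anneal(objective, b, sa_config, seed, x0_list)
    theta = ParameterVector.from_array(res.x)
    mu = sim.means(theta)
    sigma2 = profile_variances(obs, mu, pooled=pooled_variance)
    elites = [x for x, _ in (res.restart_bests or [])][:8]
    return FitResult(theta, sigma2, res.fun, mu, res.trace, res.n_evals,
                     seed, constants, elites)


def knockout_fit(obs: ObservationTable, network: CellNetwork,
                 protocols: list[LoadingProtocol], param_name: str,
                 **kwargs) -> FitResult:
    """Refit with one parameter constrained to zero (in-silico knock-out)."""
    if param_name not in PARAM_NAMES:
        raise KeyError(f"unknown parameter {param_name!r}; "
                       f"choose from {PARAM_NAMES}")
    return fit_abm(obs, network, protocols, fixed={param_name: 0.0}, **kwargs)


# ---------------------------------------------------------------------------
# hypothesis tests

@dataclass(frozen=True)
class HypothesisTest:
    constraint: str
    df: int
    statistic: float       # 2 * (logL_full - logL_constrained)
    p_value: float


def lrt(loglik_full: float, loglik_constrained: float, df: int,
        constraint: str = "", tol: float = 1e-6) -> HypothesisTest:
    """Likelihood-ratio test of a nested constraint against chi-square."""
    if df < 1:
        raise ValueError("df must be >= 1")
    lam = 2.0 * (loglik_full - loglik_constrained)
    if lam < -tol:
        raise ValueError(
            f"negative LR statistic ({lam:.4g}): models are not nested or "
            "the full model is under-optimized")
    lam = max(lam, 0.0)
    return HypothesisTest(constraint, df, lam,
                          float(stats.chi2.sf(lam, df)))


@dataclass
class JointFitResult:
    theta_young: ParameterVector
    theta_aged: ParameterVector
    loglik: float
    shared: tuple[str, ...]
    n_evals: int
    seed: int


def fit_joint(obs_young: ObservationTable, obs_aged: ObservationTable,
              network_young: CellNetwork, network_aged: CellNetwork,
              protocols_young: list[LoadingProtocol],
              protocols_aged: list[LoadingProtocol],
              shared: set[str] | None = None,
              constants: SimConstants = SimConstants(),
              sa_config: SAConfig = SAConfig(), seed: int = 0,
              strain_mode: str = "protocol_mean",
              x0_list: list[np.ndarray] | None = None) -> JointFitResult:
    """Fit young and aged tables jointly, sharing a subset of parameters.

    The free vector is (shared params once) + (young-specific) +
    (aged-specific); the objective is the sum of the two tables'
    profiled log-likelihoods.
    """
    shared = set(PARAM_NAMES) if shared is None else set(shared)
    unknown = shared - set(PARAM_NAMES)
    if unknown:
        raise KeyError(f"unknown parameter(s) {sorted(unknown)}")
    sep = [n for n in PARAM_NAMES if n not in shared]
    sh = [n for n in PARAM_NAMES if n in shared]
    base = dict(zip(PARAM_NAMES, bounds_array()))
    joint_bounds = np.array([base[n] for n in sh]
                            + [base[n] for n in sep] * 2)

    sim_y = MeanSimulator(network_young, protocols_young, constants,
                          obs_young, strain_mode)
    sim_a = MeanSimulator(network_aged, protocols_aged, constants,
                          obs_aged, strain_mode)

    def unpack(x):
        vals_sh = dict(zip(sh, x[:len(sh)]))
        vals_y = dict(zip(sep, x[len(sh):len(sh) + len(sep)]))
        vals_a = dict(zip(sep, x[len(sh) + len(sep):]))
        ty = ParameterVector(**{n: vals_sh.get(n, vals_y.get(n)) for n in PARAM_NAMES})
        ta = ParameterVector(**{n: vals_sh.get(n, vals_a.get(n)) for n in PARAM_NAMES})
        return ty, ta

    def objective(x):
        ty, ta = unpack(x)
        return (log_likelihood_from_means(obs_young, sim_y.means(ty))
                + log_likelihood_from_means(obs_aged, sim_a.means(ta)))

    res = anneal(objective, joint_bounds, sa_config, seed, x0_list)
    ty, ta = unpack(res.x)
    return JointFitResult(ty, ta, res.fun, tuple(sh), res.n_evals, seed)


def pack_joint(theta_young: ParameterVector, theta_aged: ParameterVector,
               shared: set[str]) -> np.ndarray:
    """Pack two parameter vectors into the joint free vector used by
    :func:`fit_joint` (shared values taken from the young vector)."""
    sep = [n for n in PARAM_NAMES if n not in shared]
    sh = [n for n in PARAM_NAMES if n in shared]
    return np.array([getattr(theta_young, n) for n in sh]
                    + [getattr(theta_young, n) for n in sep]
                    + [getattr(theta_aged, n) for n in sep])


def age_comparison_lrt(obs_young, obs_aged, network_young, network_aged,
                       protocols_young, protocols_aged,
                       free_with_age: set[str],
                       constants: SimConstants = SimConstants(),
                       sa_config: SAConfig = SAConfig(), seed: int = 0
                       ) -> tuple[HypothesisTest, JointFitResult, JointFitResult]:
    """LRT of "aging leaves ``free_with_age`` unchanged" vs letting them
    differ (all other parameters shared in both models).

    The constrained (all-shared over ``free_with_age``) model is fitted
    first and its solution warm-starts the full model, so the statistic is
    non-negative by construction.
    """
    if not free_with_age:
        raise ValueError("free_with_age must name at least one parameter")
    shared_full = set(PARAM_NAMES) - set(free_with_age)
    constrained = fit_joint(obs_young, obs_aged, network_young, network_aged,
                            protocols_young, protocols_aged,
                            shared=set(PARAM_NAMES), constants=constants,
                            sa_config=sa_config, seed=seed)
    warm = pack_joint(constrained.theta_young, constrained.theta_aged,
                      shared_full)
    full = fit_joint(obs_young, obs_aged, network_young, network_aged,
                     protocols_young, protocols_aged, shared=shared_full,
                     constants=constants, sa_config=sa_config,
                     seed=seed + 1, x0_list=[warm])
    # symmetric polish: project the full solution back into the shared
    # space (average the age-varying parameters) so an under-optimized
    # constrained fit does not inflate the statistic
    proj = ParameterVector.from_array(0.5 * (full.theta_young.to_array()
                                             + full.theta_aged.to_array()))
    re_cfg = dc_replace(sa_config, n_restarts=1, max_evals_per_restart=2,
                        polish_each_restart=False,
                        polish_evals=max(sa_config.polish_evals, 150))
    reshared = fit_joint(obs_young, obs_aged, network_young, network_aged,
                         protocols_young, protocols_aged,
                         shared=set(PARAM_NAMES), constants=constants,
                         sa_config=re_cfg, seed=seed + 2,
                         x0_list=[proj.to_array(),
                                  constrained.theta_young.to_array()])
    if reshared.loglik > constrained.loglik:
        constrained = reshared
    if constrained.loglik > full.loglik:
        refull = fit_joint(obs_young, obs_aged, network_young, network_aged,
                           protocols_young, protocols_aged,
                           shared=shared_full, constants=constants,
                           sa_config=re_cfg, seed=seed + 3,
                           x0_list=[pack_joint(constrained.theta_young,
                                               constrained.theta_aged,
                                               shared_full)])
        if refull.loglik > full.loglik:
            full = refull
    test = lrt(full.loglik, constrained.loglik, df=len(free_with_age),
               constraint=f"age leaves {sorted(free_with_age)} unchanged")
    return test, full, constrained


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals

@dataclass(frozen=True)
class ProfileGrid:
    n_side: int = 4              # grid points per direction
    #: Reduced-budget profile values are lower bounds on the true profile;
    #: grid points within this margin below the threshold still count as
    #: qualifying, resolving optimizer noise toward the wider interval.
    #: The default equals the typical spread observed between repeated
    #: reduced-budget optimizations of the same objective.
    noise_margin: float = 3.0
    sa_config: SAConfig = field(default_factory=lambda: SAConfig(
        n_restarts=1, steps_per_temp=10, cooling=0.6, t_initial=1.0,
        t_min=0.1, step_scale=0.15, max_evals_per_restart=30,
        polish_evals=130))


def profile_ci(objective, x_hat: np.ndarray, f_hat: float, param_index: int,
               bounds, level: float = 0.95,
               grid: ProfileGrid = ProfileGrid(), seed: int = 0,
               elites: list | None = None,
               _pool_hook=None) -> tuple[float, float]:
    """Profile-likelihood interval for one parameter.

    The profile is evaluated on a grid from the MLE toward each bound
    (geometric spacing for log-scale parameters), re-optimizing the other
    parameters at a reduced annealing budget warm-started from the MLE and
    from the previous grid point.  The reference maximum is the best value
    seen anywhere (so an under-optimized MLE cannot shrink the interval);
    the interval is the connected above-threshold region around the profile
    maximum, with endpoints linearly interpolated at the crossing and
    clipped to the admissible bounds.
    """
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[param_index]
    center = float(x_hat[param_index])
    if level <= 0:
        return (center, center)
    thr = stats.chi2.ppf(level, 1) / 2.0

    pool = [np.asarray(e, dtype=float) for e in (elites or [])][:8]
    esc_budget = [3]   # strong re-optimizations per profile, cost-capped

    def profile_at(v, warm_extra, sub_seed, quick_cut, allow_deep=True):
        b = bounds.copy()
        b[param_index] = (v, v)
        warm = ([x_hat.copy()] + [w.copy() for w in warm_extra]
                + [e.copy() for e in pool])
        for w in warm:
            w[param_index] = v
        # warm starts alone often prove the point is inside the interval
        # (any feasible value lower-bounds the profile); re-optimize only
        # when qualification is in doubt
        fw = [objective(w) for w in warm]
        k = int(np.argmax(fw))
        if quick_cut is not None and fw[k] >= quick_cut:
            return fw[k], warm[k]
        if quick_cut is not None and fw[k] < quick_cut - 60.0:
            # hopeless region: no reduced-budget re-optimization recovers
            # tens of log-likelihood units
            return fw[k], warm[k]
        res = anneal(objective, b, grid.sa_config, seed=sub_seed,
                     x0_list=[warm[k]])
        fun, x = res.fun, res.x
        if (quick_cut is not None and fun < quick_cut
                and (allow_deep or fun > quick_cut - 12.0)):
            # contested point: warm starts may all come from other basins,
            # so give one fresh random quench a chance before concluding
            # (suppressed deep below the cut right after a failed attempt
            # in the same direction — close calls always get the quench)
            esc = dc_replace(grid.sa_config, n_restarts=1,
                             max_evals_per_restart=80, t_initial=2.0,
                             polish_evals=300)
            res2 = anneal(objective, b, esc, seed=sub_seed + 7)
            if res2.fun > fun:
                fun, x = res2.fun, res2.x
        if (quick_cut is not None and esc_budget[0] > 0
                and quick_cut - 12.0 < fun < quick_cut):
            # crossing-adjacent and still short: spend real effort, a few
            # times per profile at most
            esc_budget[0] -= 1
            esc2 = dc_replace(grid.sa_config, n_restarts=2,
                              steps_per_temp=15, t_initial=2.0,
                              max_evals_per_restart=120, polish_evals=300,
                              polish_each_restart=True)
            res3 = anneal(objective, b, esc2, seed=sub_seed + 13,
                          x0_list=[x])
            if res3.fun > fun:
                fun, x = res3.fun, res3.x
        if _pool_hook is not None:
            _pool_hook(fun, x)
        return fun, x

    tf1 = _BoxTransform(np.array([lo]), np.array([hi]))

    def _z(v):
        return float(tf1.to_z(np.array([v]))[0])

    def _v(z):
        return float(tf1.from_z(np.array([z]))[0])

    def _grid_between(a, b, n):
        za, zb = _z(a), _z(b)
        if tf1.is_log[0]:
            # never step by more than ~4x per grid point, or structure
            # within a factor of the center is skipped entirely
            n = max(n, int(math.ceil(abs(zb - za) / math.log(4.0))))
        return [_v(z) for z in np.linspace(za, zb, n + 1)[1:]]

    # the reference maximum is the fitted log-likelihood: when the reduced
    # budget under-optimizes a profile point the interval errs on the wide
    # side, which is the honest direction for a desk-scale construction
    cut = f_hat - thr
    prof: dict[float, float] = {center: f_hat}
    xs: dict[float, np.ndarray] = {center: np.asarray(x_hat, float)}
    for direction, bound in ((-1, lo), (+1, hi)):
        if center == bound:
            continue
        warm_prev: list[np.ndarray] = []
        deep_lamp = True
        for j, v in enumerate(_grid_between(center, bound, grid.n_side)):
            f_v, x_v = profile_at(float(v), warm_prev,
                                  seed + 1000 * (direction + 2) + j,
                                  cut + 0.3, allow_deep=deep_lamp)
            prof[float(v)] = f_v
            xs[float(v)] = x_v
            warm_prev = [x_v]
            deep_lamp = f_v > cut - 12.0

    vs = np.array(sorted(prof))
    fs = np.array([prof[v] for v in vs])
    cut_soft = cut - grid.noise_margin
    qual = np.flatnonzero(fs >= cut_soft)
    # the likelihood region can be multimodal at a coarse grid; report its
    # interval hull, with the endpoints localized by bisection
    i0, i1 = int(qual[0]), int(qual[-1])

    def _bisect(v_in, v_out, sub_seed, n_bis=2):
        x_warm = [xs[v_in]]
        f_in = prof[v_in]
        f_out = prof[v_out]
        for k in range(n_bis):
            vm = _v(0.5 * (_z(v_in) + _z(v_out)))
            if vm in (v_in, v_out):
                break
            f_m, x_m = profile_at(vm, x_warm, sub_seed + k, cut + 0.3)
            if f_m >= cut_soft:
                v_in, f_in, x_warm = vm, f_m, [x_m]
            else:
                v_out, f_out = vm, f_m
        frac = (f_in - cut_soft) / (f_in - f_out) if f_in > f_out else 0.0
        return float(v_in + frac * (v_out - v_in))

    lo_end = lo if vs[i0] <= lo or i0 == 0 else \
        _bisect(float(vs[i0]), float(vs[i0 - 1]), seed + 50000)
    hi_end = hi if vs[i1] >= hi or i1 == len(vs) - 1 else \
        _bisect(float(vs[i1]), float(vs[i1 + 1]), seed + 60000)
    return (float(np.clip(lo_end, lo, hi)), float(np.clip(hi_end, lo, hi)))


def scan_elites(objective, bounds, n: int = 256, top: int = 3,
                polish_evals: int = 150, seed: int = 0) -> list[np.ndarray]:
    """Coarse global scan: evaluate a space-filling sample (uniform in the
    log-aware search coordinates) and Powell-polish the best few.  Used to
    seed profile computations with representatives of distinct likelihood
    basins that restart annealing may have missed."""
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    free = hi > lo
    tf = _BoxTransform(lo, hi)
    rng = np.random.default_rng(seed)
    zs = tf.zlo + (tf.zhi - tf.zlo) * rng.random((n, len(lo)))
    xs = [np.where(free, tf.from_z(z), lo) for z in zs]
    fs = np.array([objective(x) for x in xs])
    out = []
    for k in np.argsort(-fs)[:top]:
        x, f, _ = _polish(objective, xs[int(k)], float(fs[int(k)]), tf, free,
                          polish_evals)
        out.append(x)
    return out


def joint_profile_cis(objective, x_hat: np.ndarray, f_hat: float, bounds,
                      param_indices, level: float = 0.95,
                      grid: ProfileGrid = ProfileGrid(), seed: int = 0,
                      elites: list | None = None, n_passes: int = 1
                      ) -> dict[int, tuple[float, float]]:
    """Profile-likelihood intervals for several parameters at once.

    All profiles share a growing pool of elite solutions: every profile
    re-optimization feeds its optimum back into the pool, so the later
    profiles bridge likelihood basins the earlier ones discovered.  The
    reference maximum stays anchored at the fitted log-likelihood
    throughout (``n_passes > 1`` re-anchors on a much better solution and
    recomputes, but at reduced budgets a lucky deep optimization would
    tighten the threshold against points evaluated with ordinary luck, so
    the single-pass anchored construction is the default).
    """
    bounds = np.asarray(bounds, dtype=float)
    pool: list[tuple[float, np.ndarray]] = [(f_hat, np.asarray(x_hat, float))]
    for e in (elites or []):
        pool.append((-np.inf, np.asarray(e, dtype=float)))

    def add_pool(f, x):
        pool.append((f, x.copy()))
        pool.sort(key=lambda t: -t[0])
        del pool[12:]

    best_f, best_x = f_hat, np.asarray(x_hat, dtype=float)
    cis: dict[int, tuple[float, float]] = {}
    for pass_n in range(n_passes):
        for pi in param_indices:
            lo, hi = bounds[pi]
            ci = profile_ci(
                objective, best_x, best_f, pi, bounds, level, grid,
                seed=seed + 131 * pass_n,
                elites=[x for _, x in pool],
                _pool_hook=add_pool)
            cis[pi] = ci
        # a second pass is worthwhile only when the profiles uncovered a
        # solution better than the fit by more than optimizer noise
        if pool and pool[0][0] > best_f + grid.noise_margin:
            best_f, best_x = pool[0][0], pool[0][1].copy()
        else:
            break
    return cis


def profile_ci_abm(obs: ObservationTable, fit: FitResult,
                   network: CellNetwork, protocols: list[LoadingProtocol],
                   param_name: str, level: float = 0.95,
                   grid: ProfileGrid = ProfileGrid(), seed: int = 0,
                   strain_mode: str = "protocol_mean") -> tuple[float, float]:
    sim = MeanSimulator(network, protocols, fit.constants, obs, strain_mode)

    def objective(x):
        return log_likelihood_from_means(
            obs, sim.means(ParameterVector.from_array(x)))

    i = PARAM_NAMES.index(param_name)
    return profile_ci(objective, fit.theta.to_array(), fit.loglik, i,
                      bounds_array(), level, grid, seed,
                      elites=getattr(fit, "elites", None))


# ---------------------------------------------------------------------------
# restoration experiments

def restoration_experiment(theta_aged: ParameterVector,
                           theta_young: ParameterVector,
                           restore_set: set[str],
                           network_aged: CellNetwork,
                           protocols: list[LoadingProtocol],
                           constants: SimConstants = SimConstants()) -> dict:
    """Percent change in simulated rp.BFR when aged parameters in
    ``restore_set`` are overridden by their young optima."""
    unknown = set(restore_set) - set(PARAM_NAMES)
    if unknown:
        raise KeyError(f"unknown parameter(s) {sorted(unknown)}")
    restored = theta_aged.replace(
        **{n: getattr(theta_young, n) for n in restore_set})
    sim = MeanSimulator(network_aged, protocols, constants)
    mu_aged = sim.means(theta_aged)
    mu_rest = sim.means(restored)
    pct = {}
    for pid in mu_aged:
        if mu_aged[pid] > 0:
            pct[pid] = 100.0 * (mu_rest[pid] - mu_aged[pid]) / mu_aged[pid]
        else:
            pct[pid] = None   # undefined baseline
    defined = [v for v in pct.values() if v is not None]
    return {
        "percent_change": pct,
        "mean": float(np.mean(defined)) if defined else None,
        "range": (float(min(defined)), float(max(defined))) if defined else None,
        "mu_aged": mu_aged,
        "mu_restored": mu_rest,
        "restored_theta": restored,
    }


# ---------------------------------------------------------------------------
# scikit-learn style front end

class CaNFATCalibrator(BaseEstimator):
    """Maximum-likelihood calibrator for the Ca2+/NFAT pathway model.

    Parameters
    ----------
    network : CellNetwork
        The cell network to simulate on.
    protocols : list of LoadingProtocol
        The loading protocols referenced by the observation table.
    constants : SimConstants
        Fixed simulation constants.
    sa_config : SAConfig
        Annealing schedule.
    strain_mode : {"protocol_mean", "per_animal"}
        How animal-specific strains enter the simulated means.
    seed : int
        Seed for the annealer.

    Attributes (after ``fit``)
    --------------------------
    theta_ : ParameterVector          fitted parameters
    sigma2_ : dict                    profiled per-protocol variances
    loglik_ : float                   maximized log-likelihood
    mu_ : dict                        fitted per-protocol means
    result_ : FitResult               full fit record (trace, seed, ...)
    """

    def __init__(self, network=None, protocols=None,
                 constants=SimConstants(), sa_config=SAConfig(),
                 strain_mode="protocol_mean", pooled_variance=False,
                 seed=0):
        self.network = network
        self.protocols = protocols
        self.constants = constants
        self.sa_config = sa_config
        self.strain_mode = strain_mode
        self.pooled_variance = pooled_variance
        self.seed = seed

    def _obs(self, X) -> ObservationTable:
        return X if isinstance(X, ObservationTable) else ObservationTable(X)

    def fit(self, X, y=None, fixed: dict[str, float] | None = None):
        """Fit the six parameters to an observation table.

        ``X`` is an :class:`ObservationTable` or a DataFrame with columns
        protocol_id, animal_id, peak_strain_ue, rp_bfr; ``y`` is ignored
        (the targets live in the table)."""
        if self.network is None or self.protocols is None:
            raise ValueError("network and protocols must be set before fit")
        obs = self._obs(X)
        res = fit_abm(obs, self.network, self.protocols, self.constants,
                      self.sa_config, self.seed, fixed=fixed,
                      strain_mode=self.strain_mode,
                      pooled_variance=self.pooled_variance)
        self.result_ = res
        self.theta_ = res.theta
        self.sigma2_ = res.sigma2
        self.loglik_ = res.loglik
        self.mu_ = res.mu
        return self

    def predict(self, X=None) -> np.ndarray:
        """Simulated mean rp.BFR per protocol (order of ``self.protocols``
        or of the protocol list passed as ``X``)."""
        if not hasattr(self, "theta_"):
            raise AttributeError("estimator is not fitted")
        protocols = X if X is not None else self.protocols
        sim = MeanSimulator(self.network, protocols, self.constants)
        mu = sim.means(self.theta_)
        return np.array([mu[p.id] for p in protocols])

    def score(self, X, y=None) -> float:
        """Profiled log-likelihood of an observation table at ``theta_``."""
        if not hasattr(self, "theta_"):
            raise AttributeError("estimator is not fitted")
        obs = self._obs(X)
        sim = MeanSimulator(self.network, self.protocols, self.constants,
                            obs, self.strain_mode)
        return log_likelihood_from_means(obs, sim.means(self.theta_),
                                         pooled=self.pooled_variance)

    def knockout(self, X, param_name: str) -> FitResult:
        """Refit with ``param_name`` constrained to zero."""
        obs = self._obs(X)
        return knockout_fit(obs, self.network, self.protocols, param_name,
                            constants=self.constants,
                            sa_config=self.sa_config, seed=self.seed,
                            strain_mode=self.strain_mode,
                            pooled_variance=self.pooled_variance)

    def profile_ci(self, X, param_name: str, level: float = 0.95,
                   grid: ProfileGrid = ProfileGrid()) -> tuple[float, float]:
        if not hasattr(self, "result_"):
            raise AttributeError("estimator is not fitted")
        obs = self._obs(X)
        return profile_ci_abm(obs, self.result_, self.network,
                              self.protocols, param_name, level, grid,
                              seed=self.seed, strain_mode=self.strain_mode)
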