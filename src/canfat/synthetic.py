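"""Synthetic protocol suites and observation tables.

Emulates the statistical structure the calibration assumes — per-protocol
animal-specific peak strains and normally distributed rp.BFR around the
simulator's means — so fitting, testing and parameter-recovery studies
need no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import (FitResult, MeanSimulator, ObservationTable,
                          SAConfig, ProfileGrid, fit_abm,
                          joint_profile_cis, log_likelihood_from_means)
from .mechanics import LoadingProtocol
from .network import CellNetwork
from .params import PARAM_NAMES, ParameterVector, SimConstants, YOUNG_MLE


def make_protocol_suite(
    n_protocols: int = 10,
    strain_range: tuple[float, float] = (1000.0, 3000.0),
    cycle_counts: tuple[int, ...] = (50, 100, 250),
    rest_intervals: tuple[int, ...] = (0, 10),
    bouts_per_week: int = 3,
    n_weeks: int = 3,
    prefix: str = "p",
) -> list[LoadingProtocol]:
    """A deterministic suite mixing cyclic and rest-inserted protocols.

    Peak strains are spread evenly over ``strain_range``; cycle counts and
    rest intervals cycle through the given values so the suite spans both
    protocol families.  Defaults give a 10-protocol "young-like" study;
    ``n_protocols=7`` with the same ranges is the "aged-like" counterpart.
    """
    if n_protocols == 0:
        return []
    if n_protocols == 1:
        strains = [sum(strain_range) / 2]
    else:
        strains = np.linspace(*strain_range, n_protocols)
    return [
        LoadingProtocol(
            id=f"{prefix}{i + 1}",
            peak_strain=float(strains[i]),
            cycles_per_day=int(cycle_counts[i % len(cycle_counts)]),
            rest_interval=float(rest_intervals[i % len(rest_intervals)]),
            bouts_per_week=bouts_per_week,
            n_weeks=n_weeks,
        )
        for i in range(n_protocols)
    ]


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Ground truth and noise structure of a synthetic study.

    ``rel_noise_sd`` scales the residual SD with the simulated mean
    (sigma_i = rel_noise_sd * mu_i); ``abs_noise_floor`` (um/d) keeps the
    residual SD positive when a protocol's mean is zero.  ``strain_jitter``
    is the SD of animal-specific peak strains relative to the protocol's
    nominal strain.
    """

    theta_star: ParameterVector = YOUNG_MLE
    n_animals: int = 7
    rel_noise_sd: float = 0.25
    abs_noise_floor: float = 1e-3
    strain_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_animals < 2:
            raise ValueError("need at least two animals per protocol")
        if min(self.rel_noise_sd, self.abs_noise_floor, self.strain_jitter) < 0:
            raise ValueError("noise SDs must be >= 0")


def simulate_observations(
    theta_star: ParameterVector,
    protocols: list[LoadingProtocol],
    network: CellNetwork,
    config: SyntheticStudyConfig,
    seed: int | None = None,
    constants: SimConstants = SimConstants(),
) -> ObservationTable:
    """Draw a synthetic observation table around the simulated means."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    for proto in protocols:
        strains = [max(proto.peak_strain *
                       (1.0 + config.strain_jitter * rng.standard_normal()),
                       1e-6)
                   for _ in range(config.n_animals)]
        for j, strain in enumerate(strains):
            rows.append([proto.id, f"a{j + 1}", strain, np.nan])
    frame = pd.DataFrame(
        rows, columns=["protocol_id", "animal_id", "peak_strain_ue", "rp_bfr"])
    # the model mean is defined at the protocol's mean animal-specific
    # strain (the convention the calibration uses), so observations are
    # centered there
    frame["rp_bfr"] = 0.0
    obs_tmp = ObservationTable(frame)
    sim = MeanSimulator(network, protocols, constants, obs=obs_tmp)
    mu = sim.means(theta_star)
    y = []
    for proto in protocols:
        m = mu[proto.id]
        sd = max(config.rel_noise_sd * abs(m), config.abs_noise_floor)
        y.extend(m + sd * rng.standard_normal(config.n_animals))
    frame = frame.assign(rp_bfr=y)
    return ObservationTable(frame)


@dataclass
class RecoveryReport:
    per_replicate: pd.DataFrame      # replicate, parameter, truth, estimate, ci
    summary: pd.DataFrame            # parameter, bias, rmse, ci_coverage

    def coverage(self) -> dict[str, float]:
        return dict(zip(self.summary["parameter"], self.summary["ci_coverage"]))


def recovery_harness(
    network: CellNetwork,
    protocols: list[LoadingProtocol],
    config: SyntheticStudyConfig = SyntheticStudyConfig(),
    n_replicates: int = 5,
    sa_config: SAConfig = SAConfig(n_restarts=2, max_evals_per_restart=300),
    ci_grid: ProfileGrid = ProfileGrid(),
    ci_level: float = 0.95,
    constants: SimConstants = SimConstants(),
    seed: int = 0,
) -> RecoveryReport:
    """Simulate -> fit -> profile-CI loop; aggregates bias, RMSE, coverage.

    Each replicate draws a fresh observation table at ``theta_star``, fits
    by annealing (warm-started at nothing — starts are random), and builds
    a profile-likelihood CI per parameter.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    from .params import ParameterVector, bounds_array
    truth = config.theta_star
    rows = []
    for r in range(n_replicates):
        obs = simulate_observations(truth, protocols, network, config,
                                    seed=seed + 7919 * r, constants=constants)
        fit = fit_abm(obs, network, protocols, constants, sa_config,
                      seed=seed + 104729 * r + 1)
        sim = MeanSimulator(network, protocols, constants, obs)

        def objective(x):
            return log_likelihood_from_means(
                obs, sim.means(ParameterVector.from_array(x)))

        from .calibration import scan_elites
        extra = scan_elites(objective, bounds_array(),
                            seed=seed + 271 * r + 5)
        cis = joint_profile_cis(
            objective, fit.theta.to_array(), fit.loglik, bounds_array(),
            range(len(PARAM_NAMES)), level=ci_level, grid=ci_grid,
            seed=seed + 13 * r, elites=extra + list(fit.elites))
        for i, name in enumerate(PARAM_NAMES):
            ci = cis[i]
            t = getattr(truth, name)
            rows.append((r, name, t, getattr(fit.theta, name),
                         ci[0], ci[1], ci[0] <= t <= ci[1]))
    per_rep = pd.DataFrame(rows, columns=[
        "replicate", "parameter", "truth", "estimate", "ci_lo", "ci_hi",
        "covered"])
    summ = (per_rep.groupby("parameter", sort=False)
            .apply(lambda g: pd.Series({
                "bias": float((g["estimate"] - g["truth"]).mean()),
                "rmse": float(np.sqrt(((g["estimate"] - g["truth"]) ** 2).mean())),
                "ci_coverage": float(g["covered"].mean()),
            }), include_groups=False)
            .reset_index())
    return RecoveryReport(per_rep, summ)
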