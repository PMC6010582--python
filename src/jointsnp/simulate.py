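"""Synthetic-cohort generator for the joint longitudinal/survival model.

The generative model couples a linear random-intercept/random-slope biomarker
trajectory with an exponential (constant-baseline) proportional-hazards event
process through the subject-specific trajectory:

    Y_ij = theta0_i + theta1_i * t_ij + gamma * Z_i + eps_ij,   eps ~ N(0, sigma^2)
    lambda_i(t) = lambda0 * exp(beta * X_i(t) + alpha * Z_i),
    X_i(t) = theta0_i + theta1_i * t + gamma * Z_i

with (theta0_i, theta1_i) bivariate normal, Z_i ~ Binomial(2, f) under
Hardy-Weinberg sampling, administrative censoring at the horizon, and
event-driven dropout (no biomarker measurement after the observed follow-up
time).  Event times come from the closed-form inverse of the cumulative
hazard; the baseline rate is calibrated deterministically so the model-implied
event probability before the horizon matches a target incidence proportion.

Default parameter values correspond to an observational diabetes cohort
followed for nine years with four three-yearly fasting-glucose measurements
and a common TCF7L2 risk variant (``table1_defaults``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import CohortData

__all__ = [
    "GenerativeParams",
    "ScenarioSpec",
    "SimulatedCohort",
    "table1_defaults",
    "table1_scenario",
    "simulate_genotypes",
    "simulate_random_effects",
    "event_time_inverse",
    "cumulative_hazard",
    "event_probability",
    "calibrate_lambda",
    "simulate_cohort",
    "params_for_scenario",
    "scenario_grid",
]


@dataclass(frozen=True)
class GenerativeParams:
    """Full simulation truth for one generative setting.

    Attributes
    ----------
    mu : (2,) array — population mean intercept and slope of the trajectory.
    Sigma : (2, 2) array — covariance of the random intercept/slope.
    sigma_e : float — measurement-error SD (biomarker units).
    gamma : float — per-allele SNP effect on the biomarker.
    alpha : float — per-allele SNP log-hazard effect.
    beta : float — log-hazard per unit of the (true) trajectory.
    f : float — effect-allele frequency.
    lambda0 : float or None — constant baseline hazard per year; None until
        calibrated against a target incidence.
    horizon : float — administrative censoring time (years).
    m : int — number of scheduled, evenly spaced measurements on [0, horizon].
    """

    mu: np.ndarray
    Sigma: np.ndarray
    sigma_e: float
    gamma: float
    alpha: float
    beta: float
    f: float
    lambda0: Optional[float] = None
    horizon: float = 9.0
    m: int = 4

    def __post_init__(self):
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "Sigma", np.asarray(self.Sigma, dtype=float))
        if self.mu.shape != (2,) or self.Sigma.shape != (2, 2):
            raise ValueError("mu must be length-2 and Sigma 2x2")
        if not np.allclose(self.Sigma, self.Sigma.T):
            raise ValueError("Sigma must be symmetric")
        if np.linalg.eigvalsh(self.Sigma).min() < -1e-12:
            raise ValueError("Sigma must be positive semi-definite")
        if self.sigma_e < 0:
            raise ValueError("sigma_e must be >= 0")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("allele frequency f must lie in [0, 1]")
        if self.lambda0 is not None and self.lambda0 <= 0:
            raise ValueError("lambda0 must be > 0")
        if self.m < 2:
            raise ValueError("need at least 2 scheduled measurements")

    @property
    def schedule(self) -> np.ndarray:
        """Measurement times: m evenly spaced visits on [0, horizon]."""
        return np.linspace(0.0, self.horizon, self.m)

    def with_lambda(self, lambda0: float) -> "GenerativeParams":
        return replace(self, lambda0=lambda0)


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the simulation grid plus replication bookkeeping."""

    m: int
    n: int
    f: float
    d: float
    n_replicates: int = 1
    base_seed: int = 0
    index: int = 0

    def __post_init__(self):
        if self.n < 1 or self.m < 2:
            raise ValueError("need n >= 1 and m >= 2")
        if not 0.0 < self.d < 1.0:
            raise ValueError("target incidence d must lie in (0, 1)")

    def replicate_seed(self, replicate: int) -> np.random.SeedSequence:
        """Independent, reproducible stream for one replicate."""
        return np.random.SeedSequence((self.base_seed, self.index, replicate))


@dataclass
class SimulatedCohort:
    """A simulated cohort together with its latent truth.

    ``truth`` has one row per individual: theta0, theta1, the uniform draw u,
    the (possibly infinite) true event time, and the dosage z.
    """

    cohort: CohortData
    truth: pd.DataFrame
    params: GenerativeParams


# ----------------------------------------------------------------------
def table1_defaults() -> GenerativeParams:
    """Generative parameters of the reference diabetes-cohort setting.

    Intercept/slope law N2([4.55, 0.0108], [[0.143, -0.00109],
    [-0.00109, 6.8e-4]]), error SD 0.305 mmol/L, per-allele biomarker effect
    0.0229, per-allele log-hazard effect 0.265, trajectory-hazard link 3.17,
    effect-allele frequency 0.244, horizon 9 years, 4 scheduled visits.
    ``lambda0`` is left uncalibrated (use :func:`calibrate_lambda`).
    """
    return GenerativeParams(
        mu=np.array([4.55, 0.0108]),
        Sigma=np.array([[0.143, -0.00109], [-0.00109, 6.8e-4]]),
        sigma_e=0.305,
        gamma=0.0229,
        alpha=0.265,
        beta=3.17,
        f=0.244,
        horizon=9.0,
        m=4,
    )


def table1_scenario(n_replicates: int = 1, base_seed: int = 0) -> ScenarioSpec:
    """Scenario matching the reference cohort: n=4,352, m=4, f=0.244, d=0.0384."""
    return ScenarioSpec(m=4, n=4352, f=0.244, d=0.0384,
                        n_replicates=n_replicates, base_seed=base_seed)


# ----------------------------------------------------------------------
def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_genotypes(n: int, f: float, seed) -> np.ndarray:
    """i.i.d. Hardy-Weinberg dosages: Binomial(2, f) draws."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must lie in [0, 1]")
    return _rng(seed).binomial(2, f, size=n).astype(float)


def simulate_random_effects(n: int, mu, Sigma, seed) -> np.ndarray:
    """i.i.d. bivariate-normal intercept/slope pairs, shape (n, 2)."""
    mu = np.asarray(mu, float)
    Sigma = np.asarray(Sigma, float)
    if np.linalg.eigvalsh(Sigma).min() < -1e-12:
        raise ValueError("Sigma must be positive semi-definite")
    return _rng(seed).multivariate_normal(mu, Sigma, size=n, method="cholesky"
                                          if np.linalg.eigvalsh(Sigma).min() > 0
                                          else "svd")


# ----------------------------------------------------------------------
# Event-time machinery
# ----------------------------------------------------------------------
def _log_risk_const(theta0, z, params: GenerativeParams):
    """Time-constant part of the log hazard: beta*(theta0+gamma*z) + alpha*z."""
    return params.beta * (theta0 + params.gamma * z) + params.alpha * z


def cumulative_hazard(t, theta0, theta1, z, params: GenerativeParams):
    """H_i(t) for the linear-trajectory exponential-baseline hazard.

    H(t) = lambda0 * exp(beta*(theta0+gamma*z) + alpha*z)
                  * (exp(beta*theta1*t) - 1) / (beta*theta1)
    with the limit lambda0 * exp(...) * t when beta*theta1 = 0.
    """
    if params.lambda0 is None:
        raise ValueError("lambda0 not set; calibrate first")
    t = np.asarray(t, float)
    c = params.beta * np.asarray(theta1, float)
    amp = params.lambda0 * np.exp(_log_risk_const(np.asarray(theta0, float), z, params))
    small = np.abs(c) < 1e-10
    c_safe = np.where(small, 1.0, c)
    with np.errstate(over="ignore"):  # huge t probes saturate to inf, which
        growth = np.where(small, t, (np.exp(c_safe * t) - 1.0) / c_safe)
    return amp * growth  # is the correct limit for root bracketing


def event_time_inverse(theta0, theta1, z, params: GenerativeParams, u):
    """Invert F(T) = u for the event time; returns +inf when the cumulative
    hazard is bounded below -log(1-u) (the event never occurs).

    Closed form: T = log(1 - beta*theta1*log(1-u) / (lambda0*exp(beta*theta0
    + (beta*gamma+alpha)z))) / (beta*theta1), reducing to the plain
    exponential draw when beta*theta1 = 0.
    """
    if params.lambda0 is None:
        raise ValueError("lambda0 not set; calibrate first")
    u = np.asarray(u, float)
    if np.any((u <= 0.0) | (u >= 1.0)):
        raise ValueError("u must lie strictly in (0, 1)")
    theta0 = np.asarray(theta0, float)
    theta1 = np.asarray(theta1, float)
    target = -np.log1p(-u)  # -log(1-u) > 0
    amp = params.lambda0 * np.exp(_log_risk_const(theta0, z, params))
    c = params.beta * theta1
    small = np.abs(c) < 1e-10
    c_safe = np.where(small, 1.0, c)
    arg = 1.0 + c_safe * target / amp
    with np.errstate(invalid="ignore", divide="ignore"):
        t_general = np.where(arg > 0.0, np.log(np.maximum(arg, 1e-300)) / c_safe, np.inf)
    t_limit = target / amp
    return np.where(small, t_limit, t_general)


# ----------------------------------------------------------------------
# Baseline-rate calibration
# ----------------------------------------------------------------------
def _gh_nodes_2d(mu, Sigma, n_points: int = 40):
    """Gauss-Hermite nodes/weights for E over N(mu, Sigma) in 2-D."""
    x, w = np.polynomial.hermite.hermgauss(n_points)
    X0, X1 = np.meshgrid(x, x, indexing="ij")
    W = np.outer(w, w).ravel() / np.pi  # physicists' normalisation in 2-D
    E = np.column_stack([X0.ravel(), X1.ravel()])
    L = np.linalg.cholesky(np.asarray(Sigma, float) + 1e-14 * np.eye(2))
    nodes = np.asarray(mu, float) + np.sqrt(2.0) * E @ L.T
    return nodes, W


def event_probability(params: GenerativeParams, n_quad: int = 40) -> float:
    """Model-implied P(event before horizon), by deterministic integration.

    Gauss-Hermite quadrature over the random-effect law crossed with the
    exact Hardy-Weinberg distribution of the dosage.
    """
    nodes, W = _gh_nodes_2d(params.mu, params.Sigma, n_quad)
    f = params.f
    pz = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
    prob = 0.0
    for z, p_z in zip((0.0, 1.0, 2.0), pz):
        if p_z == 0.0:
            continue
        H = cumulative_hazard(params.horizon, nodes[:, 0], nodes[:, 1], z, params)
        prob += p_z * np.sum(W * -np.expm1(-H))
    return float(prob)


def calibrate_lambda(params: GenerativeParams, target_d: float,
                     tol: float = 1e-4, n_quad: int = 40) -> float:
    """Constant baseline rate achieving a target event proportion.

    Solves P(event <= horizon) = ``target_d`` by bisection-safe root finding
    on a deterministic quadrature of the event probability; the probability
    is strictly increasing in lambda0, so the root is unique.
    """
    if not 0.0 < target_d < 1.0:
        raise ValueError("target incidence must lie in (0, 1)")

    def gap(lam):
        return event_probability(params.with_lambda(lam), n_quad) - target_d

    lo, hi = 1e-12, 1.0
    while gap(hi) < 0:
        hi *= 10.0
        if hi > 1e12:
            attained = event_probability(params.with_lambda(1e12), n_quad)
            raise ValueError(
                f"target incidence {target_d} unattainable; bound ~{attained:.4g}"
            )
    lam = brentq(gap, lo, hi, xtol=1e-14, rtol=1e-12)
    if abs(gap(lam)) > tol:
        raise RuntimeError("calibration failed to reach tolerance")
    return float(lam)


# ----------------------------------------------------------------------
# Cohort simulation
# ----------------------------------------------------------------------
def simulate_cohort(spec: ScenarioSpec, params: GenerativeParams,
                    seed=None, replicate: int = 0) -> SimulatedCohort:
    """Draw one full cohort under the generative model.

    Genotypes, random effects and event times are drawn as documented above;
    biomarker records follow the even measurement schedule and are truncated
    at the observed follow-up time (event-driven dropout + administrative
    censoring at the horizon).  ``lambda0`` is calibrated on the fly from
    ``spec.d`` when the parameter set does not carry one.

    ``seed`` may be an int, a SeedSequence or a Generator; when omitted the
    scenario's per-replicate seed stream is used.
    """
    if params.m != spec.m:
        raise ValueError(f"scenario m={spec.m} inconsistent with params.m={params.m}")
    if spec.f != params.f:
        raise ValueError(f"scenario f={spec.f} inconsistent with params.f={params.f}")
    if params.lambda0 is None:
        params = params.with_lambda(calibrate_lambda(params, spec.d))
    rng = _rng(spec.replicate_seed(replicate) if seed is None else seed)

    n = spec.n
    z = rng.binomial(2, params.f, size=n).astype(float)
    theta = rng.multivariate_normal(params.mu, params.Sigma, size=n)
    u = rng.uniform(size=n)
    true_t = event_time_inverse(theta[:, 0], theta[:, 1], z, params, u)
    t_obs = np.minimum(true_t, params.horizon)
    delta = (true_t <= params.horizon).astype(int)

    sched = params.schedule
    keep = sched[None, :] <= t_obs[:, None]          # half-open: keep t <= t_obs
    n_rec = keep.sum(axis=1)
    ids = np.arange(1, n + 1)
    rid = np.repeat(ids, n_rec)
    times = np.broadcast_to(sched, (n, sched.size))[keep]
    theta_rep0 = np.repeat(theta[:, 0], n_rec)
    theta_rep1 = np.repeat(theta[:, 1], n_rec)
    z_rep = np.repeat(z, n_rec)
    eps = rng.normal(0.0, params.sigma_e, size=times.size)
    y = theta_rep0 + theta_rep1 * times + params.gamma * z_rep + eps

    longitudinal = pd.DataFrame({"id": rid, "time": times, "value": y})
    survival = pd.DataFrame({"id": ids, "time": t_obs, "status": delta})
    truth = pd.DataFrame(
        {"id": ids, "theta0": theta[:, 0], "theta1": theta[:, 1],
         "u": u, "true_time": true_t, "z": z}
    )
    cohort = CohortData(longitudinal, survival)
    return SimulatedCohort(cohort=cohort, truth=truth, params=params)


def params_for_scenario(params: GenerativeParams, spec: ScenarioSpec,
                        calibrate: bool = True) -> GenerativeParams:
    """Adapt a base parameter set to one scenario cell.

    Overrides (m, f), drops any stale baseline rate and, by default,
    recalibrates lambda0 to the scenario's target incidence.
    """
    out = replace(params, m=spec.m, f=spec.f, lambda0=None)
    if calibrate:
        out = out.with_lambda(calibrate_lambda(out, spec.d))
    return out


# ----------------------------------------------------------------------
DEFAULT_M_GRID = (2, 3, 4, 5)
DEFAULT_N_GRID = (500, 1000, 2500, 5000, 10000)
DEFAULT_F_GRID = (0.05, 0.1, 0.25, 0.5)
DEFAULT_D_GRID = (0.025, 0.05, 0.1)


def scenario_grid(
    m_grid: Sequence[int] = DEFAULT_M_GRID,
    n_grid: Sequence[int] = DEFAULT_N_GRID,
    f_grid: Sequence[float] = DEFAULT_F_GRID,
    d_grid: Sequence[float] = DEFAULT_D_GRID,
    n_replicates: int = 500,
    base_seed: int = 0,
) -> List[ScenarioSpec]:
    """Cartesian scenario grid (default 4 x 5 x 4 x 3 = 240 cells).

    Ordering is deterministic (m slowest, d fastest); each scenario carries
    its grid index, from which per-replicate seeds are derived.
    """
    if not (len(m_grid) and len(n_grid) and len(f_grid) and len(d_grid)):
        raise ValueError("empty scenario grid")
    specs = []
    idx = 0
    for m in m_grid:
        for n in n_grid:
            for f in f_grid:
                for d in d_grid:
                    specs.append(ScenarioSpec(m=m, n=n, f=f, d=d,
                                              n_replicates=n_replicates,
                                              base_seed=base_seed, index=idx))
                    idx += 1
    return specs
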