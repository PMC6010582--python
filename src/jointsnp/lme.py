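"""Linear mixed-effects model for the longitudinal sub-model.

Random intercept and slope per individual, fixed genotype (additive dosage)
and optional baseline-covariate effects:

    y_ij = mu0 + mu1 * t_ij + gamma * z_i + delta' w_i + b0_i + b1_i t_ij + eps_ij

with (b0, b1) ~ N(0, Sigma) and eps ~ N(0, sigma_e^2).  Estimation is
maximum likelihood (not REML): the fixed effects are profiled out by GLS at
each variance-parameter value and the closed-form Gaussian marginal
likelihood is maximised over (Sigma, sigma_e) on a log-Cholesky scale, so the
estimated Sigma is positive semi-definite by construction.

ML is used deliberately so the resulting log-likelihood is comparable with
the joint likelihood and valid in likelihood-ratio tests.  The model is fit
to the observed, dropout-truncated records as-is; under event-driven dropout
this is exactly the naive longitudinal analysis whose behaviour the
simulation study quantifies.

Individuals sharing a measurement-time pattern share one marginal covariance
matrix, so cohorts on a common visit schedule are fit in a handful of
vectorised pattern blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .cohort import CohortData

__all__ = [
    "LongitudinalParams",
    "LongitudinalMixedModel",
    "LongitudinalResults",
    "fit_lme",
    "lme_loglik",
]


@dataclass(frozen=True)
class LongitudinalParams:
    """Parameters of the longitudinal sub-model."""

    mu: np.ndarray          # (2,) mean intercept and slope
    Sigma: np.ndarray       # (2,2) random-effect covariance
    sigma_e: float          # residual SD
    gamma: float = 0.0      # per-allele genotype effect
    delta: np.ndarray = None  # covariate effects, may be empty

    def __post_init__(self):
        object.__setattr__(self, "mu", np.asarray(self.mu, float))
        object.__setattr__(self, "Sigma", np.asarray(self.Sigma, float))
        d = np.asarray([] if self.delta is None else self.delta, float).ravel()
        object.__setattr__(self, "delta", d)
        if np.linalg.eigvalsh(self.Sigma).min() < -1e-10:
            raise ValueError("Sigma must be positive semi-definite")
        if self.sigma_e <= 0:
            raise ValueError("sigma_e must be > 0")

    def fixed_vector(self) -> np.ndarray:
        return np.concatenate([self.mu, [self.gamma], self.delta])


class _PatternBlock:
    """Individuals sharing one measurement-time vector."""

    __slots__ = ("times", "B", "rows", "Y")

    def __init__(self, times: np.ndarray, rows: np.ndarray, Y: np.ndarray):
        self.times = times                    # (k,)
        self.B = np.column_stack([np.ones_like(times), times])  # (k, 2)
        self.rows = rows                      # indices into the cohort id order
        self.Y = Y                            # (n_p, k)


class _LmeData:
    """Pattern-grouped view of the longitudinal records."""

    def __init__(self, cohort: CohortData, genotype: Optional[np.ndarray],
                 covariates: Optional[np.ndarray], fe_names: List[str]):
        ids = cohort.ids
        pos = {i: k for k, i in enumerate(ids)}
        lon = cohort.longitudinal.sort_values(["id", "time"])
        n = len(ids)

        # per-individual time tuples -> pattern groups
        times_by: Dict[int, List[float]] = {}
        values_by: Dict[int, List[float]] = {}
        for i, t, v in zip(lon["id"].to_numpy(), lon["time"].to_numpy(),
                           lon["value"].to_numpy()):
            times_by.setdefault(i, []).append(t)
            values_by.setdefault(i, []).append(v)
        groups: Dict[tuple, List[int]] = {}
        for i in ids:
            key = tuple(np.round(times_by[i], 10))
            groups.setdefault(key, []).append(i)

        self.blocks: List[_PatternBlock] = []
        for key, members in groups.items():
            rows = np.array([pos[i] for i in members])
            Y = np.array([values_by[i] for i in members])
            self.blocks.append(_PatternBlock(np.asarray(key, float), rows, Y))
        self._suffstats = None

        # subject-level fixed design: constant part C (n, p), slope part D (n, p)
        cols_C = [np.ones(n), np.zeros(n)]
        cols_D = [np.zeros(n), np.ones(n)]
        if genotype is not None:
            cols_C.append(np.asarray(genotype, float))
            cols_D.append(np.zeros(n))
        if covariates is not None and covariates.shape[1]:
            for j in range(covariates.shape[1]):
                cols_C.append(covariates[:, j])
                cols_D.append(np.zeros(n))
        self.C = np.column_stack(cols_C)
        self.D = np.column_stack(cols_D)
        self.fe_names = fe_names
        self.n = n
        self.N = sum(b.Y.size for b in self.blocks)
        self.ids = ids

    # ------------------------------------------------------------------
    def _stats(self):
        """Per-block sufficient statistics; the data enter the likelihood
        only through these, so each evaluation is O(#patterns)."""
        if self._suffstats is None:
            out = []
            for b in self.blocks:
                M = np.stack([self.C[b.rows], self.D[b.rows]], axis=1)  # (n_p,2,p)
                T = np.einsum("iap,ibq->abpq", M, M)   # (2,2,p,p)
                U = np.einsum("iap,ik->apk", M, b.Y)   # (2,p,k)
                YtY = b.Y.T @ b.Y                      # (k,k)
                out.append((b, T, U, YtY))
            self._suffstats = out
        return self._suffstats

    def gls(self, Sigma: np.ndarray, sigma2: float):
        """Profile GLS at fixed variance parameters.

        Returns (fe, XtVX, profile_loglik, pieces); the pieces allow the
        log-likelihood at arbitrary fixed effects to be evaluated.
        """
        p = self.C.shape[1]
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        yty = 0.0
        logdet = 0.0
        for b, T, U, YtY in self._stats():
            k = b.times.size
            V = b.B @ Sigma @ b.B.T + sigma2 * np.eye(k)
            Vc = np.linalg.cholesky(V)
            Vinv = np.linalg.inv(V)
            logdet += 2.0 * np.log(np.diag(Vc)).sum() * len(b.rows)
            BtVinv = b.B.T @ Vinv                   # (2, k)
            G = BtVinv @ b.B                        # (2, 2)
            XtVX += np.einsum("ab,abpq->pq", G, T)
            XtVy += np.einsum("ak,apk->p", BtVinv, U)
            yty += float(np.einsum("kl,kl->", Vinv, YtY))
        try:
            fe = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            # rank-deficient profile (e.g. a single record): minimum-norm GLS
            fe, *_ = np.linalg.lstsq(XtVX, XtVy, rcond=None)
        quad = yty - 2.0 * fe @ XtVy + fe @ XtVX @ fe
        llf = -0.5 * (self.N * np.log(2.0 * np.pi) + logdet + quad)
        return fe, XtVX, llf, (logdet, yty, XtVy)

    def loglik_at(self, Sigma, sigma2, fe) -> float:
        """Marginal log-likelihood at arbitrary parameter values."""
        _, XtVX, _, (logdet, yty, XtVy) = self.gls(Sigma, sigma2)
        fe = np.asarray(fe, float)
        quad = yty - 2.0 * fe @ XtVy + fe @ XtVX @ fe
        return -0.5 * (self.N * np.log(2.0 * np.pi) + logdet + quad)


def _unpack_var(phi: np.ndarray) -> Tuple[np.ndarray, float]:
    L = np.array([[np.exp(phi[0]), 0.0], [phi[1], np.exp(phi[2])]])
    return L @ L.T, np.exp(2.0 * phi[3])


class LongitudinalMixedModel:
    """Random intercept/slope mixed model for a cohort biomarker.

    Parameters
    ----------
    cohort : CohortData
    genotype : array-like, optional
        Per-individual dosage aligned to ``cohort.ids``; adds an additive
        fixed genotype effect.
    covariate_columns : sequence of str, optional
        Baseline covariates (from ``cohort.covariates``) entering as fixed
        effects.
    """

    def __init__(self, cohort: CohortData, genotype=None,
                 covariate_columns: Optional[Sequence[str]] = None):
        self.cohort = cohort
        self.genotype = None if genotype is None else np.asarray(genotype, float)
        if self.genotype is not None and self.genotype.size != cohort.n_individuals:
            raise ValueError("genotype vector length must match the cohort")
        self.covariate_columns = list(covariate_columns or [])
        cov = (cohort.covariate_matrix(self.covariate_columns)
               if self.covariate_columns else None)
        names = ["mu0", "mu1"]
        if self.genotype is not None:
            names.append("gamma")
        names += [f"delta_{c}" for c in self.covariate_columns]
        self._data = _LmeData(cohort, self.genotype, cov, names)
        # record-level design is affine in t, so its span equals span{C, C+D}
        design_span = np.vstack([self._data.C, self._data.C + self._data.D])
        if np.linalg.matrix_rank(design_span) < self._data.C.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")

    # ------------------------------------------------------------------
    def _start(self) -> np.ndarray:
        lon = self.cohort.longitudinal
        v = lon.groupby("id")["value"]
        within = float(np.nanmean(v.var())) if len(lon) > len(v) else 1.0
        within = max(within, 1e-4)
        total = max(float(lon["value"].var()), within)
        s_int = max(total - within / 2.0, 1e-3)
        span = max(lon["time"].max(), 1.0)
        return np.array([0.5 * np.log(s_int), 0.0,
                         0.5 * np.log(max(s_int, 1e-3)) - np.log(span) - 1.0,
                         0.5 * np.log(within)])

    def fit(self, start: Optional[np.ndarray] = None,
            tol: float = 1e-10, max_iter: int = 500) -> "LongitudinalResults":
        data = self._data

        def neg(phi):
            Sigma, s2 = _unpack_var(phi)
            try:
                return -data.gls(Sigma, s2)[2]
            except np.linalg.LinAlgError:
                return 1e12

        phi0 = self._start() if start is None else np.asarray(start, float)
        res = minimize(neg, phi0, method="L-BFGS-B",
                       options={"ftol": tol, "gtol": 1e-9, "maxiter": max_iter})
        # polish with Nelder-Mead if L-BFGS stalled on the FD gradient
        res2 = minimize(neg, res.x, method="Nelder-Mead",
                        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        best = res2 if res2.fun < res.fun else res
        Sigma, s2 = _unpack_var(best.x)
        fe, XtVX, llf, _ = data.gls(Sigma, s2)
        fe_cov = np.linalg.inv(XtVX)
        converged = bool(res.success or res2.success)
        has_g = self.genotype is not None
        params = LongitudinalParams(
            mu=fe[:2], Sigma=Sigma, sigma_e=float(np.sqrt(s2)),
            gamma=float(fe[2]) if has_g else 0.0,
            delta=fe[3:] if has_g else fe[2:],
        )
        return LongitudinalResults(
            model=self, params=params, fe=fe, fe_names=data.fe_names,
            bse=np.sqrt(np.diag(fe_cov)), fe_cov=fe_cov, llf=float(llf),
            converged=converged, n_iter=int(res.nit + res2.nit),
        )

    # ------------------------------------------------------------------
    def loglik(self, params: LongitudinalParams) -> float:
        """Exact marginal Gaussian log-likelihood at given parameters."""
        fe = [params.mu]
        if self.genotype is not None:
            fe.append([params.gamma])
        fe.append(params.delta)
        return self._data.loglik_at(params.Sigma, params.sigma_e**2,
                                    np.concatenate(fe))

    def profile_fixed_effects(self, Sigma, sigma_e: float):
        """GLS fixed effects and log-likelihood at fixed variance parameters."""
        fe, XtVX, llf, _ = self._data.gls(np.asarray(Sigma, float), sigma_e**2)
        return fe, np.linalg.inv(XtVX), float(llf)


@dataclass
class LongitudinalResults:
    """ML fit of the longitudinal mixed model."""

    model: LongitudinalMixedModel
    params: LongitudinalParams
    fe: np.ndarray
    fe_names: List[str]
    bse: np.ndarray
    fe_cov: np.ndarray
    llf: float
    converged: bool
    n_iter: int

    # ------------------------------------------------------------------
    def predict_random_effects(self) -> pd.DataFrame:
        """Empirical-Bayes posterior means of each subject's intercept/slope.

        Returns one row per individual with columns ``id``, ``theta0``,
        ``theta1``: the posterior mean of the random intercept/slope pair
        (population mean plus the subject deviation), excluding the fixed
        genotype/covariate shifts, plus the posterior variances/covariance.
        """
        data = self.model._data
        Sigma = self.params.Sigma
        s2 = self.params.sigma_e**2
        fe = self.fe
        n = data.n
        theta = np.zeros((n, 2))
        post = np.zeros((n, 3))
        for b in data.blocks:
            k = b.times.size
            V = b.B @ Sigma @ b.B.T + s2 * np.eye(k)
            Vinv = np.linalg.inv(V)
            # subject fixed mean at this pattern: (C fe) + (D fe) * t
            const = data.C[b.rows] @ fe
            slope = data.D[b.rows] @ fe
            mean = const[:, None] + slope[:, None] * b.times[None, :]
            R = b.Y - mean                       # residuals about the fixed line
            K = Sigma @ (b.B.T @ Vinv)           # (2, k) gain
            dev = R @ K.T                        # (n_p, 2) posterior mean of b_i
            theta[b.rows, 0] = fe[0] + dev[:, 0]
            theta[b.rows, 1] = fe[1] + dev[:, 1]
            pc = Sigma - K @ b.B @ Sigma
            post[b.rows] = [pc[0, 0], pc[1, 1], pc[0, 1]]
        return pd.DataFrame({
            "id": data.ids, "theta0": theta[:, 0], "theta1": theta[:, 1],
            "var_theta0": post[:, 0], "var_theta1": post[:, 1],
            "cov_theta01": post[:, 2],
        })

    # ------------------------------------------------------------------
    def to_table(self) -> pd.DataFrame:
        rows = [(n, e, s) for n, e, s in zip(self.fe_names, self.fe, self.bse)]
        rows += [("sigma_e", self.params.sigma_e, np.nan),
                 ("Sigma_00", self.params.Sigma[0, 0], np.nan),
                 ("Sigma_01", self.params.Sigma[0, 1], np.nan),
                 ("Sigma_11", self.params.Sigma[1, 1], np.nan)]
        return pd.DataFrame(rows, columns=["parameter", "estimate", "se"])

    def summary(self) -> str:
        lines = ["Linear mixed model (ML), random intercept + slope",
                 f"individuals: {self.model.cohort.n_individuals}   "
                 f"records: {len(self.model.cohort.longitudinal)}   "
                 f"log-likelihood: {self.llf:.4f}   converged: {self.converged}",
                 f"{'parameter':<14}{'estimate':>12}{'se':>12}"]
        for _, r in self.to_table().iterrows():
            se = f"{r['se']:>12.5f}" if np.isfinite(r["se"]) else f"{'-':>12}"
            lines.append(f"{r['parameter']:<14}{r['estimate']:>12.5f}{se}")
        return "\n".join(lines)


# ----------------------------------------------------------------------
def fit_lme(cohort: CohortData, genotype=None,
            covariate_columns: Optional[Sequence[str]] = None,
            **fit_kw) -> LongitudinalResults:
    """Fit the random intercept/slope model; see LongitudinalMixedModel."""
    return LongitudinalMixedModel(cohort, genotype=genotype,
                                  covariate_columns=covariate_columns).fit(**fit_kw)


def lme_loglik(params: LongitudinalParams, cohort: CohortData, genotype=None,
               covariate_columns: Optional[Sequence[str]] = None) -> float:
    """Exact marginal log-likelihood of the mixed model at given parameters."""
    return LongitudinalMixedModel(cohort, genotype=genotype,
                                  covariate_columns=covariate_columns).loglik(params)
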