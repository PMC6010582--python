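"""Shared-parameter joint likelihood estimator.

The longitudinal biomarker and the event hazard share one pair of subject
random effects b_i = (theta0_i, theta1_i):

    y_ij | b_i ~ N(theta0_i + theta1_i t_ij + gamma z_i + delta'w_i, sigma^2)
    lambda_i(t) = lambda0(t) exp(beta X_i(t) + alpha z_i + eta'w_i),
    X_i(t) = theta0_i + theta1_i t + gamma z_i + delta'w_i
    b_i ~ N2(mu, Sigma)

with a piecewise-constant baseline hazard lambda0(t) on three intervals cut
by two interior knots.  The observed-data likelihood integrates the product
of the longitudinal density, the survival density and the random-effect law
over b_i; because X_i is affine in t and the baseline is piecewise constant,
the cumulative hazard is available in closed form on each piece and only the
2-D random-effect integral is numerical.

That integral is approximated by (adaptive) Gauss-Hermite quadrature: nodes
are recentred at each subject's posterior mode of b_i and rescaled by the
posterior curvature, both found by a vectorised 2-D Newton iteration (the
subject-level log-joint is strictly concave in b_i).  The integrated
log-likelihood is then maximised by quasi-Newton (L-BFGS) on an
unconstrained parameterisation (log-Cholesky covariance, log scales), with
node refreshes between optimisation sweeps.  Standard errors come from the
inverse of a central-difference observed-information matrix, mapped to the
natural scale by a numerical delta method.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import chi2, norm

from .cohort import CohortData
from .lme import LongitudinalParams
from .twostep import TwoStepModel

__all__ = [
    "BaselineSpec",
    "QuadratureSpec",
    "JointParams",
    "JointModel",
    "JointResults",
    "choose_knots",
    "joint_loglik",
    "fit_joint",
    "lrt_snp_effect",
]


@dataclass(frozen=True)
class BaselineSpec:
    """Piecewise-constant baseline hazard: two interior knots, three rates."""

    knots: Tuple[float, float]
    horizon: float = 9.0

    def __post_init__(self):
        k1, k2 = self.knots
        if not 0.0 < k1 < k2 < self.horizon:
            raise ValueError("knots must satisfy 0 < k1 < k2 < horizon")

    @property
    def edges(self) -> np.ndarray:
        return np.array([0.0, self.knots[0], self.knots[1], np.inf])

    @property
    def n_pieces(self) -> int:
        return 3


@dataclass(frozen=True)
class QuadratureSpec:
    """Gauss-Hermite rule: points per dimension; adaptive recentring flag."""

    n_points: int = 5
    adaptive: bool = True

    def __post_init__(self):
        if self.n_points < 3:
            raise ValueError("need at least 3 quadrature points per dimension")


@dataclass(frozen=True)
class JointParams:
    """Full joint-model parameter set (natural scale)."""

    mu: np.ndarray
    Sigma: np.ndarray
    sigma_e: float
    gamma: float
    beta: float
    alpha: float
    rates: np.ndarray
    delta: np.ndarray = field(default_factory=lambda: np.array([]))
    eta: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        object.__setattr__(self, "mu", np.asarray(self.mu, float))
        object.__setattr__(self, "Sigma", np.asarray(self.Sigma, float))
        object.__setattr__(self, "rates", np.asarray(self.rates, float))
        object.__setattr__(self, "delta", np.asarray(self.delta, float).ravel())
        object.__setattr__(self, "eta", np.asarray(self.eta, float).ravel())
        if (self.rates <= 0).any():
            raise ValueError("baseline rates must be positive")

    def longitudinal(self) -> LongitudinalParams:
        return LongitudinalParams(mu=self.mu, Sigma=self.Sigma,
                                  sigma_e=self.sigma_e, gamma=self.gamma,
                                  delta=self.delta)


# ----------------------------------------------------------------------
def choose_knots(survival: pd.DataFrame, horizon: float = 9.0
                 ) -> Tuple[float, float]:
    """Interior knots at the tertiles (33.3% / 66.7%) of observed event times.

    Degenerate event-time distributions (fewer than 3 events, or tied
    tertiles) fall back to evenly spaced knots at horizon/3 and 2*horizon/3.
    """
    events = survival.loc[survival["status"] == 1, "time"].to_numpy(float)
    if events.size < 3:
        raise ValueError("need at least 3 events to place baseline knots")
    k1, k2 = np.quantile(events, [1.0 / 3.0, 2.0 / 3.0])
    if not 0.0 < k1 < k2 < horizon:
        k1, k2 = horizon / 3.0, 2.0 * horizon / 3.0
    return float(k1), float(k2)


# ----------------------------------------------------------------------
# Closed-form piece integrals of exp(c*s), with series fallback near c=0
# ----------------------------------------------------------------------
def _int_exp(l, u, c):
    """Integral of exp(c s) over (l, u], elementwise; 0 when u <= l."""
    width = np.maximum(u - l, 0.0)
    small = np.abs(c) < 1e-7
    c_safe = np.where(small, 1.0, c)
    exact = (np.exp(c_safe * u) - np.exp(c_safe * l)) / c_safe
    series = width + c * np.maximum(u**2 - l**2, 0.0) / 2.0
    return np.where(width > 0, np.where(small, series, exact), 0.0)


def _int_s_exp(l, u, c):
    """Integral of s exp(c s) over (l, u]."""
    small = np.abs(c) < 1e-7
    c_safe = np.where(small, 1.0, c)
    f = lambda s: np.exp(c_safe * s) * (s / c_safe - 1.0 / c_safe**2)
    exact = f(u) - f(l)
    series = (u**2 - l**2) / 2.0 + c * (u**3 - l**3) / 3.0
    return np.where(u > l, np.where(small, series, exact), 0.0)


def _int_s2_exp(l, u, c):
    """Integral of s^2 exp(c s) over (l, u]."""
    small = np.abs(c) < 1e-7
    c_safe = np.where(small, 1.0, c)
    f = lambda s: np.exp(c_safe * s) * (s**2 / c_safe - 2.0 * s / c_safe**2
                                        + 2.0 / c_safe**3)
    exact = f(u) - f(l)
    series = (u**3 - l**3) / 3.0 + c * (u**4 - l**4) / 4.0
    return np.where(u > l, np.where(small, series, exact), 0.0)


# ----------------------------------------------------------------------
class JointModel:
    """Joint longitudinal/survival model for one cohort and dosage vector.

    Parameters
    ----------
    cohort : CohortData
    genotype : array-like, optional
        Dosage per individual (canonical id order).  When given, the SNP
        enters both sub-models (gamma in the trajectory, alpha in the
        hazard); ``include_alpha=False`` drops the direct survival effect,
        which is the reduced model of the SNP likelihood-ratio test.
    covariate_columns : sequence of str, optional
        Baseline covariates entering both sub-models (delta / eta).
    baseline : BaselineSpec, optional
        Defaults to knots at the event-time tertiles.
    quad : QuadratureSpec, optional
    """

    def __init__(self, cohort: CohortData, genotype=None,
                 covariate_columns: Optional[Sequence[str]] = None,
                 baseline: Optional[BaselineSpec] = None,
                 quad: QuadratureSpec = QuadratureSpec(),
                 horizon: Optional[float] = None):
        if cohort.n_events == 0:
            raise ValueError("no events: survival parameters unidentifiable")
        self.cohort = cohort
        self.genotype = None if genotype is None else np.asarray(genotype, float)
        self.covariate_columns = list(covariate_columns or [])
        self.include_alpha = genotype is not None
        self.quad = quad
        horizon = float(horizon if horizon is not None
                        else cohort.survival["time"].max())
        self.baseline = baseline or BaselineSpec(
            choose_knots(cohort.survival, horizon), horizon=horizon)

        self._prepare()

    # ------------------------------------------------------------------
    def _prepare(self):
        c = self.cohort
        ids = c.ids
        self.n = len(ids)
        self.tobs = c.survival["time"].to_numpy(float)
        self.delta_i = c.survival["status"].to_numpy(int)
        self.z = (self.genotype if self.genotype is not None
                  else np.zeros(self.n))
        self.W = (c.covariate_matrix(self.covariate_columns)
                  if self.covariate_columns else np.empty((self.n, 0)))

        # longitudinal sufficient statistics per individual
        pos = {i: k for k, i in enumerate(ids)}
        idx = np.array([pos[i] for i in c.longitudinal["id"]])
        t = c.longitudinal["time"].to_numpy(float)
        y = c.longitudinal["value"].to_numpy(float)
        self.m_i = np.bincount(idx, minlength=self.n).astype(float)
        self.S_t = np.bincount(idx, weights=t, minlength=self.n)
        self.S_tt = np.bincount(idx, weights=t * t, minlength=self.n)
        self.S_y = np.bincount(idx, weights=y, minlength=self.n)
        self.S_ty = np.bincount(idx, weights=t * y, minlength=self.n)
        self.S_yy = np.bincount(idx, weights=y * y, minlength=self.n)

        # piece boundaries clipped at each subject's observed time
        edges = self.baseline.edges
        K = self.baseline.n_pieces
        self.piece_l = np.minimum(edges[:-1][None, :], self.tobs[:, None])
        self.piece_u = np.minimum(
            np.minimum(edges[1:], np.inf)[None, :], self.tobs[:, None])
        self.piece_at_T = np.clip(
            np.searchsorted(edges[1:-1], self.tobs, side="left"), 0, K - 1)

        # quadrature skeleton
        x, w = np.polynomial.hermite.hermgauss(self.quad.n_points)
        X0, X1 = np.meshgrid(x, x, indexing="ij")
        self.e_nodes = np.column_stack([X0.ravel(), X1.ravel()])  # (Q, 2)
        self.logw = (np.log(np.outer(w, w).ravel())
                     + (self.e_nodes**2).sum(axis=1))
        self.Q = self.e_nodes.shape[0]
        self._nodes = None  # (b0, b1, logdetB) once placed

        # parameter layout
        names = ["mu0", "mu1", "chol00", "chol10", "chol11", "log_sigma"]
        if self.genotype is not None:
            names.append("gamma")
        names += [f"delta_{c_}" for c_ in self.covariate_columns]
        names.append("beta")
        if self.include_alpha:
            names.append("alpha")
        names += [f"eta_{c_}" for c_ in self.covariate_columns]
        names += [f"log_rate{k+1}" for k in range(K)]
        self.param_names = names

    # ------------------------------------------------------------------
    # packing
    # ------------------------------------------------------------------
    def pack(self, p: JointParams) -> np.ndarray:
        L = np.linalg.cholesky(p.Sigma + 1e-12 * np.eye(2))
        out = [p.mu[0], p.mu[1], np.log(L[0, 0]), L[1, 0], np.log(L[1, 1]),
               np.log(p.sigma_e)]
        if self.genotype is not None:
            out.append(p.gamma)
        out.extend(np.asarray(p.delta, float))
        out.append(p.beta)
        if self.include_alpha:
            out.append(p.alpha)
        out.extend(np.asarray(p.eta, float))
        out.extend(np.log(p.rates))
        return np.asarray(out, float)

    def unpack(self, x: np.ndarray) -> JointParams:
        x = np.asarray(x, float)
        i = 0
        mu = x[i:i + 2]; i += 2
        L = np.array([[np.exp(x[i]), 0.0], [x[i + 1], np.exp(x[i + 2])]])
        i += 3
        Sigma = L @ L.T
        sigma_e = np.exp(x[i]); i += 1
        gamma = 0.0
        if self.genotype is not None:
            gamma = x[i]; i += 1
        pw = len(self.covariate_columns)
        delta = x[i:i + pw]; i += pw
        beta = x[i]; i += 1
        alpha = 0.0
        if self.include_alpha:
            alpha = x[i]; i += 1
        eta = x[i:i + pw]; i += pw
        rates = np.exp(x[i:])
        return JointParams(mu=mu, Sigma=Sigma, sigma_e=sigma_e, gamma=gamma,
                           beta=beta, alpha=alpha, rates=rates,
                           delta=delta, eta=eta)

    # ------------------------------------------------------------------
    # subject-level log-joint pieces
    # ------------------------------------------------------------------
    def _shifts(self, p: JointParams):
        g = p.gamma * self.z + (self.W @ p.delta if p.delta.size else 0.0)
        s = p.alpha * self.z + (self.W @ p.eta if p.eta.size else 0.0)
        return np.asarray(g, float), np.asarray(s, float)

    def _long_quad(self, b0, b1, p: JointParams, g):
        """log p(y_i | b) at node arrays b0, b1 (n, Q)."""
        m = self.m_i[:, None]
        Sy = (self.S_y - self.m_i * g)[:, None]
        Sty = (self.S_ty - self.S_t * g)[:, None]
        Syy = (self.S_yy - 2.0 * g * self.S_y + self.m_i * g * g)[:, None]
        quad = (Syy - 2.0 * b0 * Sy - 2.0 * b1 * Sty + b0**2 * m
                + 2.0 * b0 * b1 * self.S_t[:, None] + b1**2 * self.S_tt[:, None])
        s2 = p.sigma_e**2
        return -0.5 * m * np.log(2.0 * np.pi * s2) - 0.5 * quad / s2

    def _surv_parts(self, b0, b1, p: JointParams, g, s):
        """(cumulative hazard, event log-hazard) at nodes (n, Q)."""
        c = p.beta * b1
        log_amp = p.beta * (b0 + g[:, None]) + s[:, None]
        growth = np.zeros_like(b0)
        for k in range(self.baseline.n_pieces):
            growth = growth + p.rates[k] * _int_exp(
                self.piece_l[:, k][:, None], self.piece_u[:, k][:, None], c)
        H = np.exp(log_amp) * growth
        log_rate_T = np.log(p.rates)[self.piece_at_T][:, None]
        log_haz_T = (log_rate_T + p.beta * (b0 + b1 * self.tobs[:, None]
                                            + g[:, None]) + s[:, None])
        return H, self.delta_i[:, None] * log_haz_T

    def _log_prior(self, b0, b1, p: JointParams):
        S = p.Sigma
        det = S[0, 0] * S[1, 1] - S[0, 1] ** 2
        if not det > 0:
            raise FloatingPointError("singular random-effect covariance")
        i00, i11, i01 = S[1, 1] / det, S[0, 0] / det, -S[0, 1] / det
        d0 = b0 - p.mu[0]
        d1 = b1 - p.mu[1]
        quad = i00 * d0**2 + 2.0 * i01 * d0 * d1 + i11 * d1**2
        return -np.log(2.0 * np.pi) - 0.5 * np.log(det) - 0.5 * quad

    def _log_joint(self, b0, b1, p: JointParams):
        g, s = self._shifts(p)
        H, log_haz = self._surv_parts(b0, b1, p, g, s)
        return self._long_quad(b0, b1, p, g) + log_haz - H \
            + self._log_prior(b0, b1, p)

    # ------------------------------------------------------------------
    # adaptive node placement
    # ------------------------------------------------------------------
    def _posterior_mode(self, p: JointParams, max_iter: int = 50):
        """Vectorised Newton for each subject's mode and curvature of the
        log-joint in b; the objective is strictly concave in b."""
        g, s = self._shifts(p)
        s2 = p.sigma_e**2
        S = p.Sigma
        det = S[0, 0] * S[1, 1] - S[0, 1] ** 2
        P = np.array([[S[1, 1], -S[0, 1]], [-S[0, 1], S[0, 0]]]) / det
        Sy = self.S_y - self.m_i * g
        Sty = self.S_ty - self.S_t * g
        amp_const = p.beta * g + s

        b = np.column_stack([
            np.where(self.m_i > 0, (self.S_y - self.m_i * g) / np.maximum(self.m_i, 1),
                     p.mu[0]),
            np.full(self.n, p.mu[1]),
        ])

        def value(bb):
            return self._log_joint(bb[:, :1], bb[:, 1:2], p)[:, 0]

        val = value(b)
        for _ in range(max_iter):
            b0, b1 = b[:, 0], b[:, 1]
            c = p.beta * b1
            amp = np.exp(p.beta * b0 + amp_const)
            I0 = np.zeros(self.n)
            I1 = np.zeros(self.n)
            I2 = np.zeros(self.n)
            for k in range(self.baseline.n_pieces):
                l, u = self.piece_l[:, k], self.piece_u[:, k]
                I0 += p.rates[k] * _int_exp(l, u, c)
                I1 += p.rates[k] * _int_s_exp(l, u, c)
                I2 += p.rates[k] * _int_s2_exp(l, u, c)
            H0, H1, H2 = amp * I0, amp * I1, amp * I2

            d0 = b0 - p.mu[0]
            d1 = b1 - p.mu[1]
            g0 = (Sy - b0 * self.m_i - b1 * self.S_t) / s2 \
                + self.delta_i * p.beta - p.beta * H0 \
                - (P[0, 0] * d0 + P[0, 1] * d1)
            g1 = (Sty - b0 * self.S_t - b1 * self.S_tt) / s2 \
                + self.delta_i * p.beta * self.tobs - p.beta * H1 \
                - (P[1, 0] * d0 + P[1, 1] * d1)
            h00 = -self.m_i / s2 - p.beta**2 * H0 - P[0, 0]
            h01 = -self.S_t / s2 - p.beta**2 * H1 - P[0, 1]
            h11 = -self.S_tt / s2 - p.beta**2 * H2 - P[1, 1]

            dete = h00 * h11 - h01**2
            step0 = -(h11 * g0 - h01 * g1) / dete
            step1 = -(-h01 * g0 + h00 * g1) / dete
            gnorm = np.hypot(g0, g1)
            if gnorm.max() < 1e-9:
                break
            scale = np.ones(self.n)
            for _ in range(20):
                cand = b + np.column_stack([scale * step0, scale * step1])
                new_val = value(cand)
                worse = new_val < val - 1e-12
                if not worse.any():
                    b, val = cand, new_val
                    break
                scale = np.where(worse, scale / 2.0, scale)
            else:
                improve = new_val >= val
                b[improve] = cand[improve]
                val[improve] = new_val[improve]
        # curvature at the mode -> scale matrices B_i = chol(inv(-Hess))
        cov00 = -h11 / dete
        cov11 = -h00 / dete
        cov01 = h01 / dete
        return b, (cov00, cov01, cov11)

    def _place_nodes(self, p: JointParams):
        if self.quad.adaptive:
            mode, (c00, c01, c11) = self._posterior_mode(p)
            l00 = np.sqrt(np.maximum(c00, 1e-12))
            l10 = c01 / l00
            l11 = np.sqrt(np.maximum(c11 - l10**2, 1e-12))
        else:
            L = np.linalg.cholesky(p.Sigma + 1e-12 * np.eye(2))
            mode = np.tile(p.mu, (self.n, 1))
            l00 = np.full(self.n, L[0, 0])
            l10 = np.full(self.n, L[1, 0])
            l11 = np.full(self.n, L[1, 1])
        e0, e1 = self.e_nodes[:, 0], self.e_nodes[:, 1]
        root2 = np.sqrt(2.0)
        b0 = mode[:, 0][:, None] + root2 * l00[:, None] * e0[None, :]
        b1 = (mode[:, 1][:, None] + root2 * (l10[:, None] * e0[None, :]
                                             + l11[:, None] * e1[None, :]))
        logdetB = np.log(l00) + np.log(l11)
        self._nodes = (b0, b1, logdetB)

    # ------------------------------------------------------------------
    def loglik(self, p: JointParams, refresh_nodes: bool = False) -> float:
        """Integrated joint log-likelihood at the given parameters."""
        if self._nodes is None or refresh_nodes:
            self._place_nodes(p)
        b0, b1, logdetB = self._nodes
        g = self._log_joint(b0, b1, p)
        per = logsumexp(self.logw[None, :] + g, axis=1)
        return float(np.sum(per + np.log(2.0) + logdetB))

    def loglik_grad(self, p: JointParams):
        """(loglik, gradient in packed space), nodes held fixed.

        The gradient of the integrated log-likelihood is the posterior
        expectation (under the quadrature weights) of the complete-data
        score, evaluated node-wise in closed form.
        """
        if self._nodes is None:
            self._place_nodes(p)
        b0, b1, logdetB = self._nodes
        g_shift, s_shift = self._shifts(p)
        s2 = p.sigma_e**2

        # --- longitudinal pieces ---------------------------------------
        m = self.m_i[:, None]
        Sy = (self.S_y - self.m_i * g_shift)[:, None]
        Sty = (self.S_ty - self.S_t * g_shift)[:, None]
        Syy = (self.S_yy - 2.0 * g_shift * self.S_y
               + self.m_i * g_shift**2)[:, None]
        R = (Syy - 2.0 * b0 * Sy - 2.0 * b1 * Sty + b0**2 * m
             + 2.0 * b0 * b1 * self.S_t[:, None] + b1**2 * self.S_tt[:, None])
        long_q = -0.5 * m * np.log(2.0 * np.pi * s2) - 0.5 * R / s2
        res_sum = (Sy - b0 * m - b1 * self.S_t[:, None])  # sum of residuals

        # --- survival pieces -------------------------------------------
        c = p.beta * b1
        log_amp = p.beta * (b0 + g_shift[:, None]) + s_shift[:, None]
        A = np.exp(log_amp)
        G0 = np.zeros_like(b0)
        G1 = np.zeros_like(b0)
        lamI = []
        for k in range(self.baseline.n_pieces):
            l = self.piece_l[:, k][:, None]
            u = self.piece_u[:, k][:, None]
            Ik = p.rates[k] * _int_exp(l, u, c)
            G0 = G0 + Ik
            G1 = G1 + p.rates[k] * _int_s_exp(l, u, c)
            lamI.append(Ik)
        H = A * G0
        dlt = self.delta_i[:, None]
        T = self.tobs[:, None]
        log_rate_T = np.log(p.rates)[self.piece_at_T][:, None]
        XT = b0 + b1 * T + g_shift[:, None]
        surv_q = dlt * (log_rate_T + p.beta * XT + s_shift[:, None]) - H

        # --- prior pieces ----------------------------------------------
        S = p.Sigma
        det = S[0, 0] * S[1, 1] - S[0, 1] ** 2
        if not det > 0:  # degenerate probe during line search
            raise FloatingPointError("singular random-effect covariance")
        P = np.array([[S[1, 1], -S[0, 1]], [-S[0, 1], S[0, 0]]]) / det
        d0 = b0 - p.mu[0]
        d1 = b1 - p.mu[1]
        quad = P[0, 0] * d0**2 + 2 * P[0, 1] * d0 * d1 + P[1, 1] * d1**2
        prior_q = -np.log(2.0 * np.pi) - 0.5 * np.log(det) - 0.5 * quad

        g_nq = long_q + surv_q + prior_q
        logint = self.logw[None, :] + g_nq
        per = logsumexp(logint, axis=1)
        ll = float(np.sum(per + np.log(2.0) + logdetB))
        omega = np.exp(logint - per[:, None])  # posterior node weights

        def avg(term):
            return float(np.sum(omega * term))

        grads = {}
        Pd0 = P[0, 0] * d0 + P[0, 1] * d1
        Pd1 = P[1, 0] * d0 + P[1, 1] * d1
        grads["mu0"] = avg(Pd0)
        grads["mu1"] = avg(Pd1)
        # dprior/dSigma = 0.5 * (Pd Pd' - P); chain to log-Cholesky scale
        M00 = 0.5 * (Pd0 * Pd0 - P[0, 0])
        M01 = 0.5 * (Pd0 * Pd1 - P[0, 1])
        M11 = 0.5 * (Pd1 * Pd1 - P[1, 1])
        L = np.linalg.cholesky(S + 1e-300 * np.eye(2))
        for name, dL in (("chol00", np.array([[L[0, 0], 0.0], [0.0, 0.0]])),
                         ("chol10", np.array([[0.0, 0.0], [1.0, 0.0]])),
                         ("chol11", np.array([[0.0, 0.0], [0.0, L[1, 1]]]))):
            dS = dL @ L.T + L @ dL.T
            grads[name] = avg(M00 * dS[0, 0] + 2 * M01 * dS[0, 1]
                              + M11 * dS[1, 1])
        grads["log_sigma"] = avg(-m + R / s2)
        z = self.z[:, None]
        d_g_long = res_sum / s2              # dlog p(y|b)/d(shift)
        d_g_surv = p.beta * (dlt - H)        # dlog p(T|b)/d(shift)
        if self.genotype is not None:
            grads["gamma"] = avg(z * (d_g_long + d_g_surv))
        for j, cname in enumerate(self.covariate_columns):
            wj = self.W[:, j][:, None]
            grads[f"delta_{cname}"] = avg(wj * (d_g_long + d_g_surv))
        grads["beta"] = avg(dlt * XT - (b0 + g_shift[:, None]) * H
                            - b1 * A * G1)
        if self.include_alpha:
            grads["alpha"] = avg(z * (dlt - H))
        for j, cname in enumerate(self.covariate_columns):
            wj = self.W[:, j][:, None]
            grads[f"eta_{cname}"] = avg(wj * (dlt - H))
        for k in range(self.baseline.n_pieces):
            event_in_k = (self.piece_at_T == k)[:, None] * dlt
            grads[f"log_rate{k+1}"] = avg(event_in_k - A * lamI[k])

        grad = np.array([grads[n] for n in self.param_names])
        return ll, grad

    def _neg(self, x: np.ndarray) -> float:
        try:
            val = self.loglik(self.unpack(x))
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1e12
        if not np.isfinite(val):
            return 1e12
        return -val

    def _neg_and_grad(self, x: np.ndarray):
        try:
            ll, grad = self.loglik_grad(self.unpack(x))
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1e12, np.zeros_like(x)
        if not np.isfinite(ll) or not np.all(np.isfinite(grad)):
            return 1e12, np.zeros_like(x)
        return -ll, -grad

    # ------------------------------------------------------------------
    def _default_init(self) -> JointParams:
        ts = TwoStepModel(self.cohort, genotype=self.genotype,
                          covariate_columns=self.covariate_columns).fit()
        lp = ts.lme.params
        beta0 = float(np.clip(ts.beta, -25.0, 25.0))
        alpha0 = float(ts.alpha) if self.include_alpha else 0.0
        # occurrence/exposure baseline rates, discounted by the mean risk score
        g, s = self._shifts(replace_like(lp, beta0, alpha0, self.baseline))
        edges = self.baseline.edges
        rates = []
        for k in range(self.baseline.n_pieces):
            exposure = np.maximum(self.piece_u[:, k] - self.piece_l[:, k], 0.0)
            mid = np.where(exposure > 0,
                           0.5 * (self.piece_l[:, k] + self.piece_u[:, k]), 0.0)
            events = np.sum((self.delta_i == 1) & (self.piece_at_T == k))
            score = np.exp(beta0 * (lp.mu[0] + lp.mu[1] * mid + g) + s)
            denom = float(np.sum(exposure * score))
            rates.append(max(events, 0.5) / max(denom, 1e-12))
        return JointParams(mu=lp.mu, Sigma=lp.Sigma, sigma_e=lp.sigma_e,
                           gamma=lp.gamma, beta=beta0, alpha=alpha0,
                           rates=np.asarray(rates), delta=lp.delta,
                           eta=np.zeros(len(self.covariate_columns)))

    def fit(self, init: Optional[JointParams] = None, tol: float = 1e-8,
            param_tol: float = 1e-6, max_iter: int = 500,
            n_refresh: int = 3) -> "JointResults":
        """Maximise the integrated likelihood.

        Quasi-Newton sweeps with the quadrature nodes held fixed, separated
        by node refreshes at the current estimate; declared converged when
        one sweep changes the log-likelihood by < ``tol`` (relative) or every
        parameter by < ``param_tol`` (relative).
        """
        p0 = init if init is not None else self._default_init()
        x = self.pack(p0)
        self._place_nodes(p0)
        prev_ll = -self._neg(x)
        converged = False
        n_iter = 0
        for sweep in range(n_refresh):
            res = minimize(self._neg_and_grad, x, method="L-BFGS-B", jac=True,
                           options={"maxiter": max_iter, "ftol": 1e-12,
                                    "gtol": 1e-8})
            n_iter += res.nit
            dx = np.max(np.abs(res.x - x) / (np.abs(x) + 1e-8))
            x = res.x
            self._place_nodes(self.unpack(x))
            ll = -self._neg(x)
            if (abs(ll - prev_ll) <= tol * (abs(prev_ll) + 1.0)
                    or dx <= param_tol):
                converged = True
                break
            prev_ll = ll
        params = self.unpack(x)
        llf = self.loglik(params)
        return JointResults(model=self, params=params, packed=x,
                            param_names=list(self.param_names), llf=llf,
                            converged=converged, n_iter=n_iter)

    # ------------------------------------------------------------------
    def observed_information(self, x: np.ndarray, step: float = 1e-4
                             ) -> np.ndarray:
        """Central-difference Hessian of -loglik in the packed space."""
        k = x.size
        H = np.zeros((k, k))
        h = step * np.maximum(np.abs(x), 1.0)
        f0 = self._neg(x)
        for i in range(k):
            for j in range(i, k):
                if i == j:
                    xp, xm = x.copy(), x.copy()
                    xp[i] += h[i]
                    xm[i] -= h[i]
                    H[i, i] = (self._neg(xp) - 2 * f0 + self._neg(xm)) / h[i]**2
                else:
                    xpp, xpm, xmp, xmm = (x.copy() for _ in range(4))
                    xpp[[i, j]] += [h[i], h[j]]
                    xpm[i] += h[i]; xpm[j] -= h[j]
                    xmp[i] -= h[i]; xmp[j] += h[j]
                    xmm[[i, j]] -= [h[i], h[j]]
                    H[i, j] = H[j, i] = (
                        self._neg(xpp) - self._neg(xpm) - self._neg(xmp)
                        + self._neg(xmm)) / (4.0 * h[i] * h[j])
        return H


def replace_like(lp: LongitudinalParams, beta: float, alpha: float,
                 baseline: BaselineSpec) -> JointParams:
    """Bundle longitudinal estimates with survival coefficients and unit
    baseline rates (a packing convenience for initialisation)."""
    return JointParams(mu=lp.mu, Sigma=lp.Sigma, sigma_e=lp.sigma_e,
                       gamma=lp.gamma, beta=beta, alpha=alpha,
                       rates=np.ones(baseline.n_pieces), delta=lp.delta,
                       eta=np.zeros(lp.delta.size))


# ----------------------------------------------------------------------
@dataclass
class JointResults:
    """Maximum-likelihood fit of the joint model."""

    model: JointModel
    params: JointParams
    packed: np.ndarray
    param_names: List[str]
    llf: float
    converged: bool
    n_iter: int
    _bse: Optional[pd.Series] = field(default=None, repr=False)

    # natural-scale reporting names
    NATURAL = ("mu0", "mu1", "Sigma_00", "Sigma_01", "Sigma_11", "sigma_e",
               "gamma", "beta", "alpha")

    def _natural_vector(self, x: np.ndarray) -> np.ndarray:
        p = self.model.unpack(x)
        out = [p.mu[0], p.mu[1], p.Sigma[0, 0], p.Sigma[0, 1], p.Sigma[1, 1],
               p.sigma_e]
        if self.model.genotype is not None:
            out.append(p.gamma)
        out.extend(p.delta)
        out.append(p.beta)
        if self.model.include_alpha:
            out.append(p.alpha)
        out.extend(p.eta)
        out.extend(p.rates)
        return np.asarray(out)

    def natural_names(self) -> List[str]:
        names = ["mu0", "mu1", "Sigma_00", "Sigma_01", "Sigma_11", "sigma_e"]
        if self.model.genotype is not None:
            names.append("gamma")
        names += [f"delta_{c}" for c in self.model.covariate_columns]
        names.append("beta")
        if self.model.include_alpha:
            names.append("alpha")
        names += [f"eta_{c}" for c in self.model.covariate_columns]
        names += [f"rate{k+1}" for k in range(self.model.baseline.n_pieces)]
        return names

    @property
    def estimates(self) -> pd.Series:
        return pd.Series(self._natural_vector(self.packed),
                         index=self.natural_names())

    def standard_errors(self, step: float = 1e-4) -> pd.Series:
        """SEs from the inverse central-difference observed information,
        delta-mapped to the natural scale.  Cached after the first call."""
        if self._bse is None:
            H = self.model.observed_information(self.packed, step=step)
            eig = np.linalg.eigvalsh(H)
            if eig.min() <= 0:
                cov = np.linalg.pinv(H)
                flagged = True
            else:
                cov = np.linalg.inv(H)
                flagged = False
            # numerical Jacobian of the natural-scale map
            x = self.packed
            k = x.size
            f0 = self._natural_vector(x)
            J = np.zeros((f0.size, k))
            for i in range(k):
                hh = 1e-6 * max(abs(x[i]), 1.0)
                xp, xm = x.copy(), x.copy()
                xp[i] += hh
                xm[i] -= hh
                J[:, i] = (self._natural_vector(xp)
                           - self._natural_vector(xm)) / (2 * hh)
            var = np.einsum("pi,ij,pj->p", J, cov, J)
            se = np.sqrt(np.maximum(var, 0.0))
            self._bse = pd.Series(se, index=self.natural_names())
            self._bse.attrs["information_flagged"] = flagged
        return self._bse

    @property
    def bse(self) -> pd.Series:
        return self.standard_errors()

    def wald_test(self, parameter: str) -> Tuple[float, float]:
        """Two-sided normal Wald test of one natural-scale parameter."""
        est = self.estimates[parameter]
        se = self.standard_errors()[parameter]
        if not np.isfinite(se) or se <= 0:
            raise ValueError(f"no standard error available for {parameter!r}")
        zval = est / se
        return float(zval), float(2.0 * norm.sf(abs(zval)))

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({"parameter": self.natural_names(),
                             "estimate": self.estimates.to_numpy(),
                             "se": self.standard_errors().to_numpy()})

    def summary(self) -> str:
        lines = ["Joint model (shared random effects, piecewise-constant "
                 "baseline, adaptive Gauss-Hermite)",
                 f"individuals: {self.model.n}   events: "
                 f"{int(self.model.delta_i.sum())}   log-likelihood: "
                 f"{self.llf:.4f}   converged: {self.converged}",
                 f"{'parameter':<14}{'estimate':>12}{'se':>12}"]
        for _, r in self.to_table().iterrows():
            lines.append(f"{r['parameter']:<14}{r['estimate']:>12.5f}"
                         f"{r['se']:>12.5f}")
        return "\n".join(lines)


# ----------------------------------------------------------------------
# functional wrappers
# ----------------------------------------------------------------------
def joint_loglik(params: JointParams, cohort: CohortData, genotype=None,
                 covariate_columns=None, baseline: Optional[BaselineSpec] = None,
                 quad: QuadratureSpec = QuadratureSpec()) -> float:
    """Integrated joint log-likelihood at given parameters (deterministic
    given the quadrature spec; nodes placed at the supplied parameters)."""
    model = JointModel(cohort, genotype=genotype,
                       covariate_columns=covariate_columns,
                       baseline=baseline, quad=quad)
    return model.loglik(params, refresh_nodes=True)


def fit_joint(cohort: CohortData, genotype=None, covariate_columns=None,
              baseline: Optional[BaselineSpec] = None,
              quad: QuadratureSpec = QuadratureSpec(), **kw) -> JointResults:
    """Fit the joint model; see JointModel."""
    return JointModel(cohort, genotype=genotype,
                      covariate_columns=covariate_columns,
                      baseline=baseline, quad=quad).fit(**kw)


def lrt_snp_effect(cohort: CohortData, genotype, covariate_columns=None,
                   baseline: Optional[BaselineSpec] = None,
                   quad: QuadratureSpec = QuadratureSpec(),
                   full: Optional[JointResults] = None
                   ) -> Tuple[float, int, float]:
    """Likelihood-ratio test of the direct SNP effect on the hazard.

    Compares the full joint model against the nested model with alpha = 0
    (the SNP removed from the survival sub-model, kept in the trajectory).
    Returns (statistic, df, p).
    """
    if full is None:
        full_model = JointModel(cohort, genotype=genotype,
                                covariate_columns=covariate_columns,
                                baseline=baseline, quad=quad)
        full = full_model.fit()
    reduced_model = JointModel(cohort, genotype=genotype,
                               covariate_columns=covariate_columns,
                               baseline=full.model.baseline, quad=quad)
    reduced_model.include_alpha = False
    reduced_model._prepare()
    init = replace(full.params, alpha=0.0)
    reduced = reduced_model.fit(init=init)
    stat = 2.0 * (full.llf - reduced.llf)
    if stat < -1e-6:
        # reduced beat full: re-polish the full fit from the reduced optimum
        refit = full.model.fit(init=replace(reduced.params, alpha=0.0))
        if refit.llf > full.llf:
            full = refit
        stat = 2.0 * (full.llf - reduced.llf)
    stat = max(stat, 0.0)
    return float(stat), 1, float(chi2.sf(stat, 1))
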