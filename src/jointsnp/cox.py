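"""Cox proportional-hazards estimation with time-varying covariates.

Two layouts are supported on top of one Breslow partial-likelihood engine:

* **Episode (counting-process) layout** — covariates piecewise constant on
  half-open intervals (start, stop]; an individual is at risk at time t iff
  start < t <= stop for one of its episodes.  `build_locf_episodes` produces
  the last-observation-carried-forward layout used by the extended-Cox
  comparator: the raw biomarker value measured at t_j is carried on
  (t_j, t_{j+1}].
* **Functional layout** — each subject's covariate is an affine function of
  time, a_i + b_i * t, evaluated *exactly* at every event time (no step
  approximation).  This is the layout the two-step estimator plugs its
  empirical-Bayes trajectories into, and the oracle fit on true trajectories.

Ties are handled with the Breslow approximation; simulated event times are
continuous so ties have measure zero there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortData

__all__ = [
    "CoxResults",
    "build_locf_episodes",
    "CoxTimeVaryingModel",
    "CoxFunctionalModel",
    "fit_cox",
    "fit_cox_functional",
]


@dataclass
class CoxResults:
    """Partial-likelihood fit: estimates, SEs from the inverse observed
    information, maximised partial log-likelihood and diagnostics."""

    params: np.ndarray
    bse: np.ndarray
    cov: np.ndarray
    names: List[str]
    llf: float
    llf_null: float
    converged: bool
    score_norm: float
    n_iter: int
    n_events: int
    degenerate: List[str] = field(default_factory=list)
    separation: bool = False  # monotone likelihood: estimate diverging

    def __getitem__(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def se(self, name: str) -> float:
        return float(self.bse[self.names.index(name)])

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parameter": self.names, "estimate": self.params, "se": self.bse}
        )

    def summary(self) -> str:
        lines = [
            "Cox proportional hazards (Breslow partial likelihood)",
            f"events: {self.n_events}   partial log-likelihood: {self.llf:.4f}   "
            f"converged: {self.converged}",
            f"{'parameter':<14}{'estimate':>12}{'se':>12}",
        ]
        for n, e, s in zip(self.names, self.params, self.bse):
            lines.append(f"{n:<14}{e:>12.5f}{s:>12.5f}")
        if self.degenerate:
            lines.append(f"no-information covariates: {', '.join(self.degenerate)}")
        return "\n".join(lines)


# ----------------------------------------------------------------------
# Breslow partial-likelihood engine
# ----------------------------------------------------------------------
def _partial_loglik_terms(beta, providers):
    """Log partial likelihood, score and information over event times.

    ``providers`` yields, per distinct event time, (V, W): the covariate
    rows of the risk set and of the failing individuals.
    """
    p = beta.size
    ll = 0.0
    g = np.zeros(p)
    H = np.zeros((p, p))
    for V, W in providers:
        d = W.shape[0]
        eta = V @ beta
        m = eta.max()
        w = np.exp(eta - m)
        s0 = w.sum()
        s1 = V.T @ w
        s2 = (V * w[:, None]).T @ V
        ll += W.sum(axis=0) @ beta - d * (np.log(s0) + m)
        g += W.sum(axis=0) - d * s1 / s0
        H += d * (s2 / s0 - np.outer(s1, s1) / s0**2)
    return ll, g, H


def _newton_cox(provider_factory: Callable[[], list], p: int, names: List[str],
                n_events: int, tol: float = 1e-9, max_iter: int = 50) -> CoxResults:
    providers = provider_factory()
    beta = np.zeros(p)
    ll0, g, H = _partial_loglik_terms(beta, providers)
    llf_null = ll0

    # covariates carrying no information at beta=0 (e.g. constant in every
    # risk set): freeze them at 0 with infinite SE rather than fail
    diag = np.diag(H)
    active = diag > 1e-12 * max(diag.max(), 1.0)
    degenerate = [n for n, a in zip(names, active) if not a]

    ll = ll0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Ha = H[np.ix_(active, active)]
        ga = g[active]
        if not active.any():
            converged = True
            break
        try:
            step = np.linalg.solve(Ha, ga)
        except np.linalg.LinAlgError:
            break
        if np.linalg.norm(ga) < tol:
            converged = True
            break
        # step-halving line search on the partial likelihood
        scale = 1.0
        for _ in range(30):
            cand = beta.copy()
            cand[active] += scale * step
            ll_new, g_new, H_new = _partial_loglik_terms(cand, providers)
            if ll_new >= ll - 1e-12:
                beta, ll, g, H = cand, ll_new, g_new, H_new
                break
            scale /= 2.0
        else:
            break
        if np.abs(beta).max() > 100.0:  # monotone likelihood / separation
            break
        if np.linalg.norm(g[active]) < tol:
            converged = True
            break

    cov = np.full((p, p), np.nan)
    bse = np.full(p, np.inf)
    if active.any():
        try:
            cov_a = np.linalg.inv(H[np.ix_(active, active)])
            cov[np.ix_(active, active)] = cov_a
            bse[active] = np.sqrt(np.diag(cov_a))
        except np.linalg.LinAlgError:
            converged = False
    separation = bool(np.abs(beta).max(initial=0.0) > 15.0)
    return CoxResults(
        params=beta, bse=bse, cov=cov, names=list(names), llf=float(ll),
        llf_null=float(llf_null), converged=converged and not separation,
        score_norm=float(np.linalg.norm(g[active]) if active.any() else 0.0),
        n_iter=it, n_events=n_events, degenerate=degenerate,
        separation=separation,
    )


# ----------------------------------------------------------------------
# Episode layout
# ----------------------------------------------------------------------
def build_locf_episodes(cohort: CohortData, genotype=None,
                        covariate_columns: Optional[Sequence[str]] = None
                        ) -> pd.DataFrame:
    """Counting-process episodes with the biomarker carried forward.

    The measurement taken at t_j is the covariate value on (t_j, t_{j+1}];
    the final episode extends to the observed follow-up time and carries the
    event indicator.  Optional genotype dosages / baseline covariates are
    replicated onto every episode as constant columns.
    """
    tobs = cohort.survival.set_index("id")["time"]
    status = cohort.survival.set_index("id")["status"]
    z = None if genotype is None else pd.Series(np.asarray(genotype, float),
                                                index=cohort.ids)
    cov = (cohort.covariates.set_index("id")[list(covariate_columns)]
           if covariate_columns else None)

    rows = []
    for i, grp in cohort.longitudinal.sort_values("time").groupby("id"):
        t_end = float(tobs.loc[i])
        times = grp["time"].to_numpy()
        values = grp["value"].to_numpy()
        if times[0] > 0:
            raise ValueError(f"individual {i!r} has no baseline measurement")
        bounds = np.append(times, t_end)
        for j in range(len(times)):
            start, stop = bounds[j], min(bounds[j + 1], t_end)
            if stop <= start:
                continue
            rows.append((i, start, stop, 0, values[j]))
        rows[-1] = rows[-1][:3] + (int(status.loc[i]), rows[-1][4])
    ep = pd.DataFrame(rows, columns=["id", "start", "stop", "status", "value"])
    if z is not None:
        ep["z"] = z.reindex(ep["id"]).to_numpy()
    if cov is not None:
        for c in cov.columns:
            ep[c] = cov[c].reindex(ep["id"]).to_numpy()
    return ep


class CoxTimeVaryingModel:
    """Cox model on a counting-process episode table.

    Parameters
    ----------
    episodes : DataFrame
        Columns ``id``, ``start``, ``stop``, ``status`` plus covariates;
        covariates are constant on each half-open episode (start, stop].
    covariate_columns : sequence of str
        Columns entering the linear predictor, in order.
    """

    def __init__(self, episodes: pd.DataFrame, covariate_columns: Sequence[str]):
        for col in ("id", "start", "stop", "status"):
            if col not in episodes.columns:
                raise ValueError(f"episode table missing column {col!r}")
        if (episodes["start"] >= episodes["stop"]).any():
            raise ValueError("episodes must satisfy start < stop")
        self.episodes = episodes.reset_index(drop=True)
        self.names = list(covariate_columns)
        self._start = episodes["start"].to_numpy(float)
        self._stop = episodes["stop"].to_numpy(float)
        self._status = episodes["status"].to_numpy(int)
        self._X = episodes[self.names].to_numpy(float)
        self.n_events = int(self._status.sum())
        if self.n_events == 0:
            raise ValueError("no events: partial likelihood undefined")

    def _providers(self) -> list:
        out = []
        event_times = np.unique(self._stop[self._status == 1])
        for t in event_times:
            at_risk = (self._start < t) & (t <= self._stop)
            failing = at_risk & (self._status == 1) & (self._stop == t)
            out.append((self._X[at_risk], self._X[failing]))
        return out

    def fit(self, tol: float = 1e-9, max_iter: int = 50) -> CoxResults:
        return _newton_cox(self._providers, len(self.names), self.names,
                           self.n_events, tol=tol, max_iter=max_iter)


# ----------------------------------------------------------------------
# Functional (affine-trajectory) layout
# ----------------------------------------------------------------------
class CoxFunctionalModel:
    """Cox model whose time-varying covariate is an affine path per subject.

    The first covariate is X_i(t) = intercept_i + slope_i * t, evaluated
    exactly at each event time; genotype dosage and baseline covariates
    enter as static columns.
    """

    def __init__(self, survival: pd.DataFrame, intercepts, slopes,
                 genotype=None, covariates: Optional[pd.DataFrame] = None,
                 names: Optional[List[str]] = None):
        self.tobs = survival["time"].to_numpy(float)
        self.delta = survival["status"].to_numpy(int)
        n = self.tobs.size
        self.a = np.asarray(intercepts, float)
        self.b = np.asarray(slopes, float)
        if self.a.size != n or self.b.size != n:
            raise ValueError("trajectory coefficients must match survival rows")
        static_cols = []
        self.names = ["beta"]
        if genotype is not None:
            static_cols.append(np.asarray(genotype, float))
            self.names.append("alpha")
        if covariates is not None:
            for c in covariates.columns:
                static_cols.append(covariates[c].to_numpy(float))
                self.names.append(f"eta_{c}")
        if names is not None:
            self.names = list(names)
        self.static = (np.column_stack(static_cols) if static_cols
                       else np.empty((n, 0)))
        self.n_events = int(self.delta.sum())
        if self.n_events == 0:
            raise ValueError("no events: partial likelihood undefined")

        # sort by t_obs descending: the risk set at any event time is a prefix
        order = np.argsort(-self.tobs, kind="stable")
        self._t_sorted = self.tobs[order]
        self._a_s, self._b_s = self.a[order], self.b[order]
        self._static_s = self.static[order]
        self._delta_s = self.delta[order]

    def _providers(self) -> list:
        out = []
        for t in np.unique(self.tobs[self.delta == 1]):
            r = np.searchsorted(-self._t_sorted, -t, side="right")
            traj = self._a_s[:r] + self._b_s[:r] * t
            V = np.column_stack([traj, self._static_s[:r]])
            fail = (self._t_sorted[:r] == t) & (self._delta_s[:r] == 1)
            out.append((V, V[fail]))
        return out

    def fit(self, tol: float = 1e-9, max_iter: int = 50) -> CoxResults:
        return _newton_cox(self._providers, len(self.names), self.names,
                           self.n_events, tol=tol, max_iter=max_iter)


# ----------------------------------------------------------------------
def fit_cox(episodes: pd.DataFrame, covariate_columns: Sequence[str],
            **kw) -> CoxResults:
    """Fit a Cox model on a counting-process episode table."""
    return CoxTimeVaryingModel(episodes, covariate_columns).fit(**kw)


def fit_cox_functional(survival: pd.DataFrame, intercepts, slopes,
                       genotype=None, covariates=None, **kw) -> CoxResults:
    """Fit a Cox model with exact affine time-varying trajectories."""
    return CoxFunctionalModel(survival, intercepts, slopes,
                              genotype=genotype, covariates=covariates).fit(**kw)
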