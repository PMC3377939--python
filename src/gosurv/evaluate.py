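"""Test-set model assessment.

Three criteria: (1) a logrank test comparing survival between high- and
low-risk groups split at the median prognostic index; (2) a likelihood-ratio
test of the prognostic index used as a single Cox covariate; (3) the IPCW
Brier score BS(t) — squared prediction error weighted by the inverse
Kaplan-Meier estimate of the censoring distribution — and its time average,
the integrated Brier score over [0, t*] (default t* = 10 years).
Survival predictions come from the Breslow estimator of the cumulative
baseline hazard.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from gosurv.cox import CoxFit, RiskModelInput, _breslow_parts, fit_penalized_cox, log_partial_likelihood
from gosurv.data import SurvivalResponse

logger = logging.getLogger(__name__)


@dataclass
class BaselineHazard:
    """Right-continuous step estimate of the cumulative baseline hazard."""

    event_times: np.ndarray
    cumulative_hazard: np.ndarray

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.cumulative_hazard = np.asarray(self.cumulative_hazard, dtype=float)
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(np.diff(self.cumulative_hazard) < 0) or np.any(self.cumulative_hazard < 0):
            raise ValueError("cumulative hazard must be nonnegative and nondecreasing")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        padded = np.concatenate([[0.0], self.cumulative_hazard])
        return padded[idx]


@dataclass
class CensoringDistribution:
    """Kaplan-Meier estimate of the censoring distribution G(t).

    Censorings play the role of events; observed deaths are censored
    observations for G.  ``times``/``values`` hold the step function after
    each censoring time; G(0) = 1.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("G must lie in [0, 1]")
        if np.any(np.diff(self.values) > 1e-12):
            raise ValueError("G must be nonincreasing")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        padded = np.concatenate([[1.0], self.values])
        return padded[idx]

    def left(self, t) -> np.ndarray:
        """Left limit G(t-)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="left")
        padded = np.concatenate([[1.0], self.values])
        return padded[idx]

    @property
    def support_limit(self) -> float:
        """Largest time with G(t) > 0 (inf when G never reaches zero)."""
        zero = self.values <= 0
        if not zero.any():
            return np.inf
        return float(self.times[np.argmax(zero)])


@dataclass
class PredictionErrorCurve:
    time: np.ndarray
    bs: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.bs = np.asarray(self.bs, dtype=float)
        if self.time.shape != self.bs.shape:
            raise ValueError("time grid and BS values must align")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(self.bs < -1e-12):
            raise ValueError("Brier scores must be nonnegative")

    def at(self, t) -> np.ndarray:
        """Step-function (previous-value) evaluation on arbitrary times."""
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(self.time, t, side="right") - 1, 0, len(self.time) - 1)
        return self.bs[idx]


def assign_risk_groups(pi: np.ndarray) -> np.ndarray:
    """High-risk (1) iff the prognostic index exceeds the test-set median."""
    pi = np.asarray(pi, dtype=float)
    if len(pi) < 2:
        raise ValueError("need at least 2 samples to form risk groups")
    med = np.median(pi)
    labels = (pi > med).astype(int)
    if labels.sum() == 0 and np.all(pi == pi[0]):
        warnings.warn("all prognostic indices identical; everyone assigned low-risk")
    return labels


def logrank_test(labels: np.ndarray, survival: SurvivalResponse) -> tuple[float, float]:
    """Two-group logrank test; returns (chi-square statistic, p-value)."""
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary")
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("both groups must be nonempty")
    time, event = survival.time, survival.event
    obs_minus_exp = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n_k = int(at_risk.sum())
        n1_k = int((at_risk & (labels == 1)).sum())
        d_k = int(((time == t) & (event == 1)).sum())
        d1_k = int(((time == t) & (event == 1) & (labels == 1)).sum())
        obs_minus_exp += d1_k - d_k * n1_k / n_k
        if n_k > 1:
            var += d_k * (n1_k / n_k) * (1 - n1_k / n_k) * (n_k - d_k) / (n_k - 1)
    if var <= 0:
        return 0.0, 1.0
    chi2 = obs_minus_exp**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def pi_lrt(pi: np.ndarray, survival: SurvivalResponse) -> float:
    """Likelihood-ratio p-value for the prognostic index as a single Cox covariate."""
    pi = np.asarray(pi, dtype=float)
    if np.all(pi == pi[0]):
        raise ValueError("prognostic index is constant; LRT undefined")
    inp = RiskModelInput(pi.reshape(-1, 1), np.empty((len(pi), 0)), survival)
    fit = fit_penalized_cox(inp, "none", 0.0)
    if not fit.converged:
        raise RuntimeError("univariate Cox fit for the prognostic index did not converge")
    l1 = log_partial_likelihood(fit.beta, fit.gamma, inp)
    l0 = log_partial_likelihood(np.zeros(1), np.zeros(0), inp)
    lrt = 2.0 * (l1 - l0)
    return float(stats.chi2.sf(max(lrt, 0.0), df=1))


def breslow_baseline(fit: CoxFit, inp: RiskModelInput) -> BaselineHazard:
    """Breslow estimator: H0(t) = sum over event times t_k <= t of d_k / sum_{R(t_k)} exp(eta)."""
    eta = inp.X @ fit.beta + inp.Z @ fit.gamma
    time, event = inp.survival.time, inp.survival.event
    r = np.exp(eta)
    ev_times = np.unique(time[event == 1])
    increments = []
    for t in ev_times:
        d_k = int(((time == t) & (event == 1)).sum())
        R_k = float(r[time >= t].sum())
        increments.append(d_k / R_k)
    return BaselineHazard(ev_times, np.cumsum(increments))


def predict_survival(fit: CoxFit, baseline: BaselineHazard, X, Z, t) -> np.ndarray:
    """S(t | x, z) = exp(-H0(t) * exp(beta'x + gamma'z)); rows = samples, cols = times."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    Z = np.asarray(Z, dtype=float).reshape(X.shape[0], -1)
    eta = X @ fit.beta + Z @ fit.gamma
    H = np.atleast_1d(baseline(t))
    S = np.exp(-np.outer(np.exp(eta), H))
    return S[:, 0] if np.isscalar(t) or np.ndim(t) == 0 else S


def km_censoring(survival: SurvivalResponse) -> CensoringDistribution:
    """Product-limit estimate of the censoring distribution (role-swapped KM)."""
    time = survival.time
    cens = 1 - survival.event
    uniq = np.unique(time)
    factors = []
    times = []
    for t in uniq:
        n_k = int((time >= t).sum())
        c_k = int(((time == t) & (cens == 1)).sum())
        if c_k > 0:
            times.append(t)
            factors.append(1.0 - c_k / n_k)
    values = np.cumprod(factors) if factors else np.asarray([])
    return CensoringDistribution(np.asarray(times, float), np.asarray(values, float))


def brier_score(
    t: float,
    survival: SurvivalResponse,
    s_hat: np.ndarray,
    G: CensoringDistribution,
) -> float:
    """IPCW Brier score at time t.

    Patients with an observed event before t contribute S(t)^2 weighted by
    1/G(t_i-); patients still at risk past t contribute (1 - S(t))^2
    weighted by 1/G(t); patients censored before t contribute nothing.
    The event-term weight uses the left limit G(t_i-) (Graf convention).
    """
    time, event = survival.time, survival.event
    s_hat = np.asarray(s_hat, dtype=float)
    if s_hat.shape != time.shape:
        raise ValueError("one predicted survival probability per patient required")
    n = len(time)
    died = (time <= t) & (event == 1)
    alive = time > t
    total = 0.0
    if died.any():
        g_left = G.left(time[died])
        if np.any(g_left <= 0):
            raise ValueError(f"G(t-) is zero for an event before t={t}; choose a smaller t*")
        total += float(np.sum(s_hat[died] ** 2 / g_left))
    if alive.any():
        g_t = float(G(t))
        if g_t <= 0:
            raise ValueError(f"G({t}) = 0; choose a smaller t*")
        total += float(np.sum((1.0 - s_hat[alive]) ** 2) / g_t)
    return total / n


def integrated_brier_score(curve: PredictionErrorCurve, t_star: float = 10.0) -> float:
    """IBS = (1/t*) * integral of BS over [0, t*] (trapezoid on the union grid)."""
    if t_star <= 0:
        raise ValueError("t_star must be positive")
    if curve.time[-1] < t_star - 1e-9:
        raise ValueError(
            f"curve ends at {curve.time[-1]:g} but t*={t_star:g}; "
            "extend the grid or reduce t*"
        )
    grid = np.unique(np.concatenate([curve.time, [0.0, t_star]]))
    grid = grid[(grid >= 0) & (grid <= t_star)]
    vals = np.interp(grid, curve.time, curve.bs)
    return float(np.trapezoid(vals, grid) / t_star)


def prediction_error_curve(curves: list[PredictionErrorCurve]) -> PredictionErrorCurve:
    """Pointwise mean of per-split BS curves on the union time grid (step interpolation)."""
    if not curves:
        raise ValueError("need at least one curve to average")
    grid = np.unique(np.concatenate([c.time for c in curves]))
    stacked = np.vstack([c.at(grid) for c in curves])
    return PredictionErrorCurve(grid, stacked.mean(axis=0))
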