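"""Cox partial likelihood and L1/L2-penalized estimation with unpenalized clinical block.

The log partial likelihood uses the Breslow convention for tied event times
(all tied events share one risk set).  Penalties apply to the genomic
coefficients beta only; clinical coefficients gamma are mandatory and
unpenalized.  L1 fits use iteratively reweighted least squares with cyclic
coordinate descent and soft-thresholding; L2 (and unpenalized) fits use
Newton-Raphson on the full Hessian with a ridge-augmented beta block.  The
penalty weight lambda is tuned by M-fold cross-validated partial likelihood
(CVPL): the out-of-fold likelihood contribution summed over folds,
maximized over a lambda grid with shared fold memberships.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gosurv.data import SurvivalResponse

logger = logging.getLogger(__name__)

PENALTIES = ("l1", "l2", "none")


def _cd_kernel_py(X, Z, w, resid, b, g, lam, sx, sz, tol, max_cycles):
    """Cyclic coordinate descent on the weighted-least-squares subproblem.

    Soft-threshold updates for b (penalized), plain updates for g.  Mutates
    resid, b, g in place.  Shared between the numba-compiled and pure-Python
    paths, so keep it nopython-compatible.
    """
    n, p = X.shape
    q = Z.shape[1]
    for _cycle in range(max_cycles):
        md = 0.0
        for j in range(p):
            old = b[j]
            num = sx[j] * old
            for i in range(n):
                num += w[i] * X[i, j] * resid[i]
            if num > lam:
                new = (num - lam) / sx[j]
            elif num < -lam:
                new = (num + lam) / sx[j]
            else:
                new = 0.0
            d = new - old
            if d != 0.0:
                for i in range(n):
                    resid[i] -= X[i, j] * d
                b[j] = new
                if abs(d) > md:
                    md = abs(d)
        for j in range(q):
            old = g[j]
            num = sz[j] * old
            for i in range(n):
                num += w[i] * Z[i, j] * resid[i]
            new = num / sz[j]
            d = new - old
            if d != 0.0:
                for i in range(n):
                    resid[i] -= Z[i, j] * d
                g[j] = new
                if abs(d) > md:
                    md = abs(d)
        if md < tol:
            break


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _cd_kernel = njit(cache=True)(_cd_kernel_py)
except ImportError:  # pragma: no cover
    _cd_kernel = _cd_kernel_py


class ConvergenceError(RuntimeError):
    pass


@dataclass
class RiskModelInput:
    """Genomic block X (penalized), clinical block Z (unpenalized), and outcome."""

    X: np.ndarray
    Z: np.ndarray
    survival: SurvivalResponse

    def __post_init__(self) -> None:
        n = len(self.survival)

        def shape2d(a):
            a = np.asarray(a, dtype=float)
            if a.ndim == 1:
                a = a.reshape(-1, 1) if a.size else a.reshape(n, 0)
            if a.shape[0] != n:
                raise ValueError(f"covariate block has {a.shape[0]} rows, expected {n}")
            return a

        self.X = shape2d(self.X)
        self.Z = shape2d(self.Z)
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.Z))):
            raise ValueError("covariate matrices contain non-finite values")
        if self.survival.n_events == 0:
            raise ValueError("no events: partial likelihood is identically zero")

    @property
    def n(self) -> int:
        return len(self.survival)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    def subset(self, idx: np.ndarray) -> "RiskModelInput":
        return RiskModelInput(self.X[idx], self.Z[idx], self.survival.subset(idx))


@dataclass
class CoxFit:
    beta: np.ndarray
    gamma: np.ndarray
    penalty: str
    lam: float
    converged: bool
    n_iter: int
    objective: float

    @property
    def n_selected(self) -> int:
        """Number of nonzero genomic coefficients (p itself for l2/none)."""
        if self.penalty == "l1":
            return int(np.sum(self.beta != 0))
        return len(self.beta)

    def write(self, coef_path, header_path, covariate_ids=None, clinical_ids=None, sep="\t") -> None:
        cov = covariate_ids or [f"x{j}" for j in range(len(self.beta))]
        cli = clinical_ids or [f"z{j}" for j in range(len(self.gamma))]
        rows = [(c, b, 1) for c, b in zip(cov, self.beta)] + [(c, g, 0) for c, g in zip(cli, self.gamma)]
        pd.DataFrame(rows, columns=["covariate_id", "coefficient", "penalized"]).to_csv(
            coef_path, sep=sep, index=False
        )
        with open(header_path, "w") as fh:
            json.dump(
                {
                    "penalty": self.penalty,
                    "lambda": self.lam,
                    "converged": self.converged,
                    "n_iter": self.n_iter,
                    "objective": self.objective,
                },
                fh,
                indent=2,
            )


# ---------------------------------------------------------------------------
# partial-likelihood machinery (Breslow ties)


def _breslow_parts(eta: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Log partial likelihood plus per-sample gradient and curvature pieces.

    Returns (loglik, grad_eta, c1, c2) where, with r_i = exp(eta_i),
    c1_i = sum over event times t_k <= t_i of d_k / R_k and c2_i the same
    sum of d_k / R_k^2; grad_eta_i = delta_i - r_i c1_i.  The diagonal of
    the negative Hessian w.r.t. eta is r c1 - r^2 c2.
    """
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    order = np.argsort(time, kind="stable")
    t_s, e_s = time[order], event[order].astype(bool)
    r_s = np.exp(eta[order] - eta.max())  # shift for overflow safety
    rev = np.cumsum(r_s[::-1])[::-1]      # rev[i] = sum_{j: sorted pos >= i} r_j
    first = np.searchsorted(t_s, t_s, side="left")
    risk_at = rev[first]                  # risk-set sum for each sample's own time

    ev_pos = np.flatnonzero(e_s)
    ev_times = t_s[ev_pos]
    uniq_times, start = np.unique(ev_times, return_index=True)
    d_k = np.diff(np.append(start, len(ev_times)))
    R_k = np.clip(risk_at[ev_pos[start]], 1e-300, None)  # guard exp underflow at extreme eta

    loglik = float(eta[event.astype(bool)].sum()) - float(
        np.sum(d_k * (np.log(R_k) + eta.max()))
    )
    h1 = np.cumsum(d_k / R_k)
    h2 = np.cumsum(d_k / R_k**2)
    pos = np.searchsorted(uniq_times, t_s, side="right") - 1
    c1_s = np.where(pos >= 0, h1[np.maximum(pos, 0)], 0.0)
    c2_s = np.where(pos >= 0, h2[np.maximum(pos, 0)], 0.0)

    c1 = np.empty_like(c1_s)
    c2 = np.empty_like(c2_s)
    r = np.empty_like(r_s)
    c1[order], c2[order], r[order] = c1_s, c2_s, r_s
    # note: c2 is on the shifted scale (r divided by e^max twice in R_k^2),
    # consistent with r^2 when both use the shifted r — products r*c1, r^2*c2
    # are shift-invariant.
    grad = event - r * c1
    return loglik, grad, r, c1, c2


def log_partial_likelihood(beta: np.ndarray, gamma: np.ndarray, inp: RiskModelInput) -> float:
    """Breslow log partial likelihood at (beta, gamma)."""
    eta = inp.X @ np.asarray(beta, float) + inp.Z @ np.asarray(gamma, float)
    loglik, *_ = _breslow_parts(eta, inp.survival.time, inp.survival.event)
    return loglik


def _plik_eta(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    return _breslow_parts(eta, time, event)[0]


def _full_neg_hessian_eta(r: np.ndarray, c1: np.ndarray, c2: np.ndarray) -> np.ndarray:
    """Dense negative Hessian of the log partial likelihood w.r.t. eta."""
    # A_ij = delta_ij * r_i c1_i - r_i r_j * min(c2_i, c2_j)
    B = np.outer(r, r) * np.minimum.outer(c2, c2)
    A = np.diag(r * c1) - B
    return A


def _newton_fit(
    inp: RiskModelInput,
    lam: float,
    penalty: str,
    beta0: np.ndarray,
    gamma0: np.ndarray,
    tol: float,
    max_iter: int,
) -> CoxFit:
    """Newton-Raphson with step halving; l2 penalty on the beta block only."""
    time, event = inp.survival.time, inp.survival.event
    M = np.hstack([inp.X, inp.Z])
    p, q = inp.p, inp.q
    theta = np.concatenate([beta0, gamma0])
    pen_mask = np.concatenate([np.ones(p), np.zeros(q)])
    lam2 = lam if penalty == "l2" else 0.0

    def pen_obj(th):
        try:
            ll = _plik_eta(M @ th, time, event)
        except ValueError:
            return -np.inf
        return ll - lam2 * float(np.sum((th * pen_mask) ** 2))

    obj = pen_obj(theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = M @ theta
        _, grad_eta, r, c1, c2 = _breslow_parts(eta, time, event)
        g = M.T @ grad_eta - 2.0 * lam2 * pen_mask * theta
        A = _full_neg_hessian_eta(r, c1, c2)
        H = M.T @ A @ M
        H[np.diag_indices_from(H)] += 2.0 * lam2 * pen_mask + 1e-9
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # halve until the penalized objective does not decrease
        scale = 1.0
        new_obj = obj
        for _ in range(30):
            cand = theta + scale * step
            cand_obj = pen_obj(cand)
            if np.isfinite(cand_obj) and cand_obj >= obj - 1e-12:
                theta, new_obj = cand, cand_obj
                break
            scale *= 0.5
        else:
            break
        if abs(new_obj - obj) <= tol * (abs(obj) + 1.0):
            obj = new_obj
            converged = True
            break
        obj = new_obj
    if not converged:
        logger.warning("Newton fit did not converge in %d iterations", max_iter)
    return CoxFit(
        beta=theta[:p].copy(),
        gamma=theta[p:].copy(),
        penalty=penalty,
        lam=lam,
        converged=converged,
        n_iter=it,
        objective=obj,
    )


def _cd_fit(
    inp: RiskModelInput,
    lam: float,
    beta0: np.ndarray,
    gamma0: np.ndarray,
    tol: float,
    max_iter: int,
) -> CoxFit:
    """IRLS + cyclic coordinate descent with soft-thresholding for the l1 penalty."""
    time, event = inp.survival.time, inp.survival.event
    X, Z = inp.X, inp.Z
    p, q = inp.p, inp.q
    beta, gamma = beta0.copy(), gamma0.copy()

    def pen_obj(b, g):
        try:
            ll = _plik_eta(X @ b + Z @ g, time, event)
        except ValueError:
            return -np.inf
        return ll - lam * float(np.abs(b).sum())

    obj = pen_obj(beta, gamma)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta + Z @ gamma
        _, grad_eta, r, c1, c2 = _breslow_parts(eta, time, event)
        w = np.clip(r * c1 - r**2 * c2, 1e-5, None)
        resid = grad_eta / w  # working residual z - eta at the expansion point
        sx = np.einsum("ij,ij->j", X * w[:, None], X)
        sz = np.einsum("ij,ij->j", Z * w[:, None], Z)
        b_new, g_new = beta.copy(), gamma.copy()
        _cd_kernel(X, Z, w, resid, b_new, g_new, lam, sx, sz, 1e-8, 100)
        # monotone safeguard: halve the step until the penalized objective
        # does not decrease (the quadratic model can overshoot badly when a
        # cold start is far from the optimum)
        db, dg = b_new - beta, g_new - gamma
        step = 1.0
        new_obj = obj
        while step >= 1e-10:
            cand_b, cand_g = beta + step * db, gamma + step * dg
            cand_obj = pen_obj(cand_b, cand_g)
            if np.isfinite(cand_obj) and cand_obj >= obj - 1e-12:
                beta, gamma, new_obj = cand_b, cand_g, cand_obj
                break
            step *= 0.5
        if new_obj - obj <= tol * (abs(obj) + 1.0):
            obj = new_obj
            converged = True
            break
        obj = new_obj
    if not converged:
        logger.warning("coordinate descent did not converge in %d IRLS iterations", max_iter)
    # snap numerically-dead coefficients to exact zero (partial steps can
    # leave residues on coordinates the full CD solution zeroed)
    beta[np.abs(beta) < 1e-10] = 0.0
    return CoxFit(
        beta=beta,
        gamma=gamma,
        penalty="l1",
        lam=lam,
        converged=converged,
        n_iter=it,
        objective=obj,
    )


def fit_penalized_cox(
    inp: RiskModelInput,
    penalty: str,
    lam: float = 0.0,
    tol: float = 1e-6,
    max_iter: int = 200,
    warm_start: CoxFit | None = None,
) -> CoxFit:
    """Maximize l(beta, gamma) - penalty(beta); gamma is never penalized."""
    if penalty not in PENALTIES:
        raise ValueError(f"unknown penalty {penalty!r}")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if warm_start is not None:
        beta0, gamma0 = warm_start.beta.copy(), warm_start.gamma.copy()
    else:
        beta0, gamma0 = np.zeros(inp.p), np.zeros(inp.q)
        if penalty == "l1" and inp.q > 0:
            # start gamma at its clinical-only optimum so beta = 0 satisfies
            # the soft-threshold KKT condition exactly at lambda >= lambda_max
            gamma0 = fit_clinical_only(inp, tol=tol).gamma
    if penalty == "l1":
        return _cd_fit(inp, lam, beta0, gamma0, tol, max_iter)
    return _newton_fit(inp, lam, penalty, beta0, gamma0, tol, max_iter)


def fit_clinical_only(inp: RiskModelInput, tol: float = 1e-6, max_iter: int = 200) -> CoxFit:
    """Unpenalized fit of the clinical block with all genomic coefficients at zero."""
    reduced = RiskModelInput(np.empty((inp.n, 0)), inp.Z, inp.survival)
    fit = _newton_fit(reduced, 0.0, "none", np.zeros(0), np.zeros(inp.q), tol, max_iter)
    return CoxFit(
        beta=np.zeros(inp.p),
        gamma=fit.gamma,
        penalty="none",
        lam=0.0,
        converged=fit.converged,
        n_iter=fit.n_iter,
        objective=fit.objective,
    )


def lambda_max(inp: RiskModelInput) -> float:
    """Smallest l1 lambda for which all genomic coefficients stay at zero.

    Computed from the score of the partial likelihood at beta = 0 with gamma
    at its clinical-only optimum (KKT condition for the soft-threshold).
    """
    if inp.q > 0:
        gamma = fit_clinical_only(inp).gamma
    else:
        gamma = np.zeros(0)
    eta = inp.Z @ gamma
    _, grad_eta, *_ = _breslow_parts(eta, inp.survival.time, inp.survival.event)
    return float(np.max(np.abs(inp.X.T @ grad_eta)))


def default_lambda_grid(inp: RiskModelInput, penalty: str, n_lambda: int = 50) -> np.ndarray:
    """Descending lambda grid: l1 from lambda_max to 0.01*lambda_max, l2 heuristic span."""
    if penalty == "l1":
        lmax = lambda_max(inp)
        if lmax <= 0:
            return np.full(1, 0.0)
        return np.geomspace(lmax, 0.01 * lmax, n_lambda)
    scale = inp.n / max(inp.p, 1)
    return np.geomspace(1e6 * scale, 1e-2 * scale, n_lambda)


def make_cv_folds(survival: SurvivalResponse, M: int, seed: int, max_attempts: int = 20) -> list[np.ndarray]:
    """Event-stratified random folds; every fold and its complement keep >= 1 event."""
    if M < 2:
        raise ValueError("M must be >= 2")
    n = len(survival)
    for attempt in range(max_attempts):
        rng = np.random.default_rng(seed + attempt)
        ev = rng.permutation(np.flatnonzero(survival.event == 1))
        ce = rng.permutation(np.flatnonzero(survival.event == 0))
        folds = [np.sort(np.concatenate([ev[m::M], ce[m::M]])).astype(int) for m in range(M)]
        ok = all(
            survival.event[f].sum() >= 1 and survival.event.sum() - survival.event[f].sum() >= 1
            for f in folds
        )
        if ok and all(len(f) > 0 for f in folds):
            return folds
    raise ValueError(f"could not build {M} folds with >= 1 event each from {n} samples")


def cvpl(
    inp: RiskModelInput,
    penalty: str,
    lam: float,
    M: int = 10,
    seed: int = 0,
    folds: list[np.ndarray] | None = None,
    warm_starts: list[CoxFit] | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[float, list[CoxFit]]:
    """M-fold cross-validated log partial likelihood at one lambda.

    Each fold's contribution is l(beta_-m, gamma_-m) evaluated on all
    patients minus the same likelihood evaluated without fold m, both at
    parameters estimated without fold m.  Returns (CVPL, per-fold fits) so
    callers can warm-start across a lambda path.
    """
    if folds is None:
        folds = make_cv_folds(inp.survival, M, seed)
    total = 0.0
    fits: list[CoxFit] = []
    all_idx = np.arange(inp.n)
    for m, fold in enumerate(folds):
        keep = np.setdiff1d(all_idx, fold)
        sub = inp.subset(keep)
        ws = warm_starts[m] if warm_starts is not None else None
        fit = fit_penalized_cox(sub, penalty, lam, tol=tol, max_iter=max_iter, warm_start=ws)
        l_all = log_partial_likelihood(fit.beta, fit.gamma, inp)
        l_minus = log_partial_likelihood(fit.beta, fit.gamma, sub)
        total += l_all - l_minus
        fits.append(fit)
    return total, fits


def tune_lambda(
    inp: RiskModelInput,
    penalty: str,
    M: int = 10,
    grid: np.ndarray | None = None,
    n_lambda: int = 50,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 75,
    df_max_frac: float = 0.85,
) -> tuple[float, pd.DataFrame]:
    """Maximize CVPL over a lambda grid with shared fold memberships.

    The grid is traversed from the largest lambda down, warm-starting each
    fold's fit from the previous grid point.  Ties break toward the larger
    lambda (more parsimony), which the descending traversal guarantees.
    CV fits use a looser tolerance than the final fit (the CVPL curve is
    flat at that scale) and the l1 path stops early once the average fold
    model saturates (nonzero count >= ``df_max_frac`` x event count): such
    models only get worse and are by far the slowest to fit.
    """
    if grid is None:
        grid = default_lambda_grid(inp, penalty, n_lambda)
    grid = np.sort(np.asarray(grid, dtype=float))[::-1]
    if len(grid) == 0:
        raise ValueError("empty lambda grid")
    folds = make_cv_folds(inp.survival, M, seed)
    df_cap = df_max_frac * inp.survival.n_events
    rows = []
    warm: list[CoxFit] | None = None
    best_lam, best_val = None, -np.inf
    for lam in grid:
        val, warm = cvpl(
            inp, penalty, lam, folds=folds, warm_starts=warm, tol=tol, max_iter=max_iter
        )
        rows.append({"lambda": lam, "cvpl": val})
        if val > best_val + 1e-12:
            best_val, best_lam = val, lam
        if penalty == "l1" and np.mean([f.n_selected for f in warm]) >= df_cap:
            logger.debug("l1 path stopped early at lambda=%g (saturated)", lam)
            break
    if best_lam is None:
        raise ConvergenceError("no lambda on the grid produced a usable CVPL")
    return float(best_lam), pd.DataFrame(rows)


def prognostic_index(fit: CoxFit, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Risk score beta'x_i + gamma'z_i per sample."""
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    n = X.shape[0]
    Z = Z.reshape(n, -1)
    return X @ fit.beta + Z @ fit.gamma
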