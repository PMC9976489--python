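"""Newton-Raphson Cox proportional-hazards engine (Breslow ties).

This is the workhorse behind the per-CpG mortality EWAS, the survival
association tests and the proportional-hazards diagnostics.  The partial
log-likelihood with Breslow tie handling is maximised by Newton-Raphson
with step-halving whenever a step would decrease the likelihood; convergence
is declared when the largest score component falls below ``tol``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError


@dataclass
class CoxFit:
    coef: np.ndarray
    cov: np.ndarray          # inverse observed information at the optimum
    loglik: float
    score: np.ndarray
    n_iter: int
    converged: bool
    n: int
    n_events: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def wald_p(self) -> np.ndarray:
        z = self.coef / self.se
        return 2.0 * stats.norm.sf(np.abs(z))


def _prepare(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.shape != event.shape:
        raise ValidationError("time and event must have equal length")
    if np.any(time <= 0):
        raise ValidationError("all survival times must be > 0")
    if event.sum() < 1:
        raise ValidationError("at least one event is required")
    order = np.argsort(time, kind="stable")
    return time, event, order


def _loglik_deriv(X, time, event, order, beta, want_deriv=True):
    """Breslow partial log-likelihood, score and information.

    Vectorized over risk sets: with samples sorted by ascending time, the
    risk-set sums S0 = sum(exp(eta)), S1 = sum(exp(eta) x) and
    S2 = sum(exp(eta) x x^T) at each unique time are reverse cumulative
    sums evaluated at block starts.  The overflow-guarding shift of eta
    cancels exactly between the event terms and log(S0).
    """
    n, p = X.shape
    eta = X @ beta
    etac = eta - eta.max()
    w = np.exp(etac)
    Xa, wa, ta, ea, etaa = X[order], w[order], time[order], event[order], etac[order]

    rc0 = np.cumsum(wa[::-1])[::-1]
    starts = np.flatnonzero(np.r_[True, ta[1:] != ta[:-1]])
    d = np.add.reduceat(ea.astype(float), starts)
    eeta = np.add.reduceat(ea * etaa, starts)
    S0 = rc0[starts]
    has = d > 0
    loglik = float(eeta[has].sum() - (d[has] * np.log(S0[has])).sum())
    if not want_deriv:
        return loglik, None, None

    rc1 = np.cumsum((wa[:, None] * Xa)[::-1], axis=0)[::-1]
    rc2 = np.cumsum((wa[:, None, None] * (Xa[:, :, None] * Xa[:, None, :]))[::-1],
                    axis=0)[::-1]
    ex = np.add.reduceat(ea[:, None] * Xa, starts, axis=0)
    S1 = rc1[starts]
    S2 = rc2[starts]
    mean = S1 / S0[:, None]
    score = ex[has].sum(axis=0) - (d[has, None] * mean[has]).sum(axis=0)
    info = (
        d[has, None, None]
        * (S2[has] / S0[has, None, None] - mean[has, :, None] * mean[has, None, :])
    ).sum(axis=0)
    return loglik, score, info


def cox_fit(X, time, event, max_iter: int = 50, tol: float = 1e-8) -> CoxFit:
    """Fit a Cox PH model by Newton-Raphson with step-halving."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time, event, order = _prepare(time, event)
    n, p = X.shape
    beta = np.zeros(p)
    loglik, score, info = _loglik_deriv(X, time, event, order, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        new_beta = beta + step
        new_ll, new_score, new_info = _loglik_deriv(X, time, event, order, new_beta)
        halvings = 0
        while new_ll < loglik and halvings < 30:  # step-halving: never decrease
            step *= 0.5
            new_beta = beta + step
            new_ll, new_score, new_info = _loglik_deriv(X, time, event, order, new_beta)
            halvings += 1
        beta, loglik, score, info = new_beta, new_ll, new_score, new_info
    else:
        converged = bool(np.max(np.abs(score)) < tol)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return CoxFit(
        coef=beta, cov=cov, loglik=loglik, score=score, n_iter=it,
        converged=converged, n=n, n_events=int(event.sum()),
    )


def cox_loglik(X, time, event, beta) -> float:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time, event, order = _prepare(time, event)
    ll, _, _ = _loglik_deriv(X, time, event, order, np.asarray(beta, float), want_deriv=False)
    return ll


def schoenfeld_residuals(X, time, event, beta):
    """Unscaled Schoenfeld residuals at each event, in event-time order.

    Returns ``(residuals, event_times)`` where residuals has one row per
    event: the covariates of the subject failing minus the risk-set
    weighted mean at that time.  At the optimum they sum to zero per
    covariate (the score equation).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time, event, order = _prepare(time, event)
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()
    w = np.exp(eta)
    desc = order[::-1]
    Xd, wd, td, ed = X[desc], w[desc], time[desc], event[desc]

    res = []
    times = []
    S0 = 0.0
    S1 = np.zeros(p)
    i = 0
    while i < n:
        t = td[i]
        j = i
        while j < n and td[j] == t:
            S0 += wd[j]
            S1 += wd[j] * Xd[j]
            j += 1
        mean = S1 / S0
        for k in range(i, j):
            if ed[k]:
                res.append(Xd[k] - mean)
                times.append(t)
        i = j
    res = np.asarray(res)
    times = np.asarray(times)
    asc = np.argsort(times, kind="stable")
    return res[asc], times[asc]


def cumulative_hazard_terms(X, time, event, beta):
    """Per-sample exp(eta), cumulative baseline hazard and derivatives.

    Used by the Cox elastic net's iteratively reweighted quadratic
    approximation: returns ``(mu, wdiag, delta)`` where ``mu`` is each
    sample's expected event count (Breslow), ``wdiag`` the diagonal of the
    Hessian of the partial log-likelihood w.r.t. the linear predictor, and
    ``delta`` the event indicator — so gradient(eta) = delta - mu.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time, event, order = _prepare(time, event)
    n = X.shape[0]
    eta = X @ np.asarray(beta, float) if X.shape[1] else np.zeros(n)
    return _eta_derivs(eta, time, event)


def _eta_derivs(eta, time, event):
    """Breslow mu_i, Hessian diagonal and event indicator from eta.

    mu_i = exp(eta_i) * H1(t_i) with H1 the Breslow cumulative baseline
    hazard; the Hessian diagonal is mu_i - exp(2 eta_i) * H2(t_i) where H2
    accumulates d_k / S0_k^2.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    eta = np.asarray(eta, dtype=float)
    etac = eta - eta.max()
    w = np.exp(etac)
    asc = np.argsort(time, kind="stable")
    wa, ta, ea = w[asc], time[asc], event[asc]

    rc0 = np.cumsum(wa[::-1])[::-1]
    new_block = np.r_[True, ta[1:] != ta[:-1]]
    starts = np.flatnonzero(new_block)
    d = np.add.reduceat(ea.astype(float), starts)
    S0 = rc0[starts]
    c1 = np.cumsum(d / S0)
    c2 = np.cumsum(d / S0 ** 2)
    block_id = np.cumsum(new_block) - 1
    H1a, H2a = c1[block_id], c2[block_id]
    mu = np.empty_like(w)
    wdiag = np.empty_like(w)
    mu[asc] = wa * H1a
    wdiag[asc] = mu[asc] - wa ** 2 * H2a
    return mu, np.maximum(wdiag, 0.0), event.astype(float)
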