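"""Cox proportional-hazards engine.

Fits the semiparametric proportional-hazards model by Newton–Raphson
maximization of the partial likelihood, with the Efron approximation for
tied event times (Breslow available as an option), and tests the
proportional-hazards assumption through scaled Schoenfeld residuals.

The model is ``h(t | x) = h0(t) exp(x' beta)``; the baseline hazard ``h0``
is never estimated.  Standard errors come from the inverse of the observed
information at the maximum; confidence intervals for hazard ratios are
Wald intervals on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CoxFit",
    "PHTestResult",
    "ConvergenceError",
    "fit_cox",
    "schoenfeld_test",
]

Z95 = stats.norm.ppf(0.975)


class ConvergenceError(RuntimeError):
    """Partial-likelihood maximization failed (e.g. monotone likelihood)."""


@dataclass
class CoxFit:
    """Result of a proportional-hazards fit.

    ``coefficients`` are log-hazard ratios per unit of each design column;
    ``hr`` is their exponential.  ``partial_loglik`` is the Efron (or
    Breslow) partial log-likelihood at the maximum.
    """

    terms: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    hr: np.ndarray
    hr_ci95: np.ndarray  # (p, 2)
    p_values: np.ndarray
    partial_loglik: float
    null_loglik: float
    n_events: int
    n_used: int
    converged: bool
    iterations: int
    ties: str = "efron"
    covariance: np.ndarray = field(default=None, repr=False)

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def se(self, term: str) -> float:
        return float(self.standard_errors[self.terms.index(term)])

    def hazard_ratio(self, term: str) -> float:
        return float(self.hr[self.terms.index(term)])


@dataclass
class PHTestResult:
    """Scaled-Schoenfeld proportional-hazards diagnostics.

    ``rho`` is the Pearson correlation of each term's scaled Schoenfeld
    residuals with the rank of the event times; ``p`` the per-term
    1-df chi-square p-value; ``global_p`` the joint p-value over all terms.
    ``residuals``/``event_times`` carry the plot data.
    """

    terms: list[str]
    rho: np.ndarray
    p: np.ndarray
    global_stat: float
    global_p: float
    residuals: np.ndarray  # (n_events, p) scaled Schoenfeld residuals
    event_times: np.ndarray


def _validate(time, event, X, terms):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != time.shape[0]:
        X = X.T
    n, p = X.shape
    if time.shape[0] != n or event.shape[0] != n:
        raise ValueError("time, event and design must have equal length")
    if np.any(time <= 0):
        raise ValueError("all follow-up times must be positive")
    if not np.all(np.isin(event, (0.0, 1.0))):
        raise ValueError("event indicators must be 0/1")
    if event.sum() < 1:
        raise ValueError("at least one event is required")
    if terms is None:
        terms = [f"x{j}" for j in range(p)]
    if len(terms) != p:
        raise ValueError("terms must name every design column")
    # full-rank check on the raw design (centered: constant columns are
    # degenerate in a partial likelihood)
    Xc = X - X.mean(axis=0)
    if np.linalg.matrix_rank(Xc) < p:
        raise ValueError("design is rank deficient (constant or collinear column)")
    return time, event, X, list(terms)


def _group_structure(time, event):
    """Sort descending by time; return sorted order plus per-event-time groups.

    With a descending sort the risk set of an event at time t is a prefix
    of the array, so risk-set sums are prefix cumulative sums.
    Returns (order, groups, singles) where each group is
    (end_index_inclusive, event_positions) for one unique event time and
    ``singles = (ends, ev_pos)`` holds the untied groups as flat arrays for
    the vectorized path.
    """
    order = np.lexsort((-event, -time))  # primary key: time descending
    t_s = time[order]
    e_s = event[order]
    groups = []
    single_ends = []
    single_ev = []
    uniq_event_times = np.unique(t_s[e_s == 1])[::-1]  # descending
    # searchsorted on the ascending view to find each time's span
    asc = t_s[::-1]
    n = len(t_s)
    for ut in uniq_event_times:
        lo = n - np.searchsorted(asc, ut, side="right")
        hi = n - np.searchsorted(asc, ut, side="left")  # exclusive
        idx = np.arange(lo, hi)
        end = hi - 1
        ev_pos = idx[e_s[lo:hi] == 1]
        groups.append((end, ev_pos))
        if len(ev_pos) == 1:
            single_ends.append(end)
            single_ev.append(ev_pos[0])
    singles = (np.asarray(single_ends, dtype=int), np.asarray(single_ev, dtype=int))
    return order, groups, singles


def _loglik_grad_hess(beta, Xs, groups, singles, ties):
    n, p = Xs.shape
    eta = Xs @ beta
    eta = eta - eta.max()  # guard overflow; shifts cancel in the partial likelihood
    w = np.exp(eta)
    wX = w[:, None] * Xs
    cw = np.cumsum(w)
    cwX = np.cumsum(wX, axis=0)
    cwXX = np.cumsum(wX[:, :, None] * Xs[:, None, :], axis=0)

    loglik = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))

    # vectorized path for untied event times (Efron == Breslow there)
    ends1, ev1 = singles
    if len(ends1):
        S0 = cw[ends1]
        mu = cwX[ends1] / S0[:, None]
        loglik += float(eta[ev1].sum() - np.log(S0).sum())
        grad += Xs[ev1].sum(axis=0) - mu.sum(axis=0)
        hess += (cwXX[ends1] / S0[:, None, None]).sum(axis=0) - np.einsum(
            "ij,ik->jk", mu, mu
        )

    for end, ev_pos in groups:
        d = len(ev_pos)
        if d == 1:
            continue  # handled above
        S0 = cw[end]
        S1 = cwX[end]
        S2 = cwXX[end]
        loglik += eta[ev_pos].sum()
        grad += Xs[ev_pos].sum(axis=0)
        if ties == "efron":
            s0 = w[ev_pos].sum()
            s1 = wX[ev_pos].sum(axis=0)
            s2 = (wX[ev_pos][:, :, None] * Xs[ev_pos][:, None, :]).sum(axis=0)
            for l in range(d):
                f = l / d
                D0 = S0 - f * s0
                D1 = S1 - f * s1
                D2 = S2 - f * s2
                mu = D1 / D0
                loglik -= np.log(D0)
                grad -= mu
                hess += D2 / D0 - np.outer(mu, mu)
        else:  # breslow
            mu = S1 / S0
            loglik -= d * np.log(S0)
            grad -= d * mu
            hess += d * (S2 / S0 - np.outer(mu, mu))
    return loglik, grad, hess


def fit_cox(
    time,
    event,
    design,
    terms: list[str] | None = None,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxFit:
    """Fit a Cox model by Newton–Raphson on the partial likelihood.

    Parameters
    ----------
    time, event
        Follow-up in years (strictly positive) and 0/1 event indicators.
    design
        (n, p) covariate matrix.  Do not include an intercept: the partial
        likelihood is invariant to location shifts and a constant column
        is rank deficient.
    ties
        ``"efron"`` (default) or ``"breslow"`` tie handling.
    tol
        Convergence when the max absolute coefficient update < tol.

    Raises
    ------
    ConvergenceError
        On monotone likelihood (a coefficient diverging, as under complete
        separation) or failure to converge within ``max_iter``.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    time, event, X, terms = _validate(time, event, design, terms)
    order, groups, singles = _group_structure(time, event)
    Xs = X[order]
    # center columns for conditioning; coefficients are shift-invariant
    means = Xs.mean(axis=0)
    Xs = Xs - means
    p = X.shape[1]

    beta = np.zeros(p)
    ll, grad, hess = _loglik_grad_hess(beta, Xs, groups, singles, ties)
    null_ll = ll
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        # step-halving: never accept a decrease in the partial log-likelihood
        scale = 1.0
        for _ in range(30):
            beta_new = beta + scale * step
            ll_new, grad_new, hess_new = _loglik_grad_hess(beta_new, Xs, groups, singles, ties)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        delta = np.max(np.abs(beta_new - beta))
        beta, ll, grad, hess = beta_new, ll_new, grad_new, hess_new
        if np.any(np.abs(beta) > 50):
            worst = terms[int(np.argmax(np.abs(beta)))]
            raise ConvergenceError(
                f"monotone partial likelihood: coefficient for {worst!r} diverges "
                "(complete separation?)"
            )
        if delta < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"no convergence in {max_iter} iterations")

    cov = np.linalg.inv(hess)
    se = np.sqrt(np.diag(cov))
    hr = np.exp(beta)
    ci = np.column_stack([np.exp(beta - Z95 * se), np.exp(beta + Z95 * se)])
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    return CoxFit(
        terms=terms,
        coefficients=beta,
        standard_errors=se,
        hr=hr,
        hr_ci95=ci,
        p_values=pvals,
        partial_loglik=float(ll),
        null_loglik=float(null_ll),
        n_events=int(event.sum()),
        n_used=len(time),
        converged=converged,
        iterations=n_iter,
        ties=ties,
        covariance=cov,
    )


def schoenfeld_test(fit: CoxFit, time, event, design) -> PHTestResult:
    """Grambsch–Therneau test of proportional hazards.

    Computes per-event Schoenfeld residuals r_k = x_k - xbar(t_k) (risk-set
    weighted mean at the event time), scales them by the average risk-set
    covariance, and correlates with the rank of the event time.  The 1-df
    score chi-square per term uses the rank transform g(t); the global test
    is the joint quadratic form over all terms.
    """
    if not fit.converged:
        raise ValueError("PH test requires a converged fit")
    time, event, X, terms = _validate(time, event, design, fit.terms)
    if event.sum() < 3:
        raise ValueError("PH test undefined with fewer than 3 events")
    order, groups, _singles = _group_structure(time, event)
    Xs = X[order] - X.mean(axis=0)
    t_s = time[order]
    beta = fit.coefficients
    p = Xs.shape[1]

    eta = Xs @ beta
    eta = eta - eta.max()
    w = np.exp(eta)
    wX = w[:, None] * Xs
    cw = np.cumsum(w)
    cwX = np.cumsum(wX, axis=0)
    cwXX = np.cumsum(wX[:, :, None] * Xs[:, None, :], axis=0)

    resid = []
    Vsum = np.zeros((p, p))
    ev_times = []
    d_total = 0
    for end, ev_pos in groups:
        S0 = cw[end]
        mu = cwX[end] / S0
        V = cwXX[end] / S0 - np.outer(mu, mu)
        for k in ev_pos:
            resid.append(Xs[k] - mu)
            Vsum += V
            ev_times.append(t_s[k])
            d_total += 1
    resid = np.asarray(resid)
    ev_times = np.asarray(ev_times)
    Vbar = Vsum / d_total

    # scaled residuals for rho and the plot
    Vbar_inv = np.linalg.inv(Vbar)
    scaled = d_total * resid @ Vbar_inv.T + beta

    g = stats.rankdata(ev_times)
    gc = g - g.mean()
    ssg = float(gc @ gc)

    rho = np.array(
        [stats.pearsonr(scaled[:, j], g)[0] if np.std(scaled[:, j]) > 0 else 0.0 for j in range(p)]
    )
    z = gc @ resid  # per-term score
    per_stat = z**2 / (ssg * np.diag(Vbar))
    per_p = stats.chi2.sf(per_stat, df=1)
    global_stat = float(z @ np.linalg.solve(ssg * Vbar, z))
    global_p = float(stats.chi2.sf(global_stat, df=p))

    return PHTestResult(
        terms=terms,
        rho=rho,
        p=per_p,
        global_stat=global_stat,
        global_p=global_p,
        residuals=scaled,
        event_times=ev_times,
    )
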