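"""Survival-analysis primitives used throughout the pipeline.

Implements, from first principles:

* Cox proportional-hazards fitting by Newton–Raphson on the Efron (or
  Breslow) partial likelihood, returning the three overall tests —
  likelihood-ratio, Wald, and score (log-rank) — whose conjunction gates
  the multivariate stage of the biomarker screen;
* Harrell's concordance index over comparable subject pairs;
* the Kaplan–Meier product-limit estimator;
* the two-sample log-rank test.

The model is ``h(t | x) = h0(t) · exp(beta' x)``: each coefficient is a
log hazard ratio per unit of its covariate (z-units downstream, since
layers are z-scored before modelling).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .datatypes import CoxFit, KMCurve

__all__ = [
    "fit_cox",
    "concordance_index",
    "km_estimate",
    "logrank_test",
    "cox_partial_loglik",
]


def _efron_quantities(X, time, event, beta, ties, want_derivs=True):
    """Log partial likelihood at ``beta``, optionally with gradient and
    observed information.

    For each death rank l = 0..d_k−1 at a tied death time k, Efron's
    correction replaces the risk-set sums S by ``phi = S − (l/d_k)·D``
    where D sums over the tied deaths (Breslow uses l/d_k = 0). The
    information matrix is accumulated as a per-subject weighted Gram
    matrix ``X' diag(w) X − R1' R1``, avoiding any n×p×p temporaries:
    subject i's weight collects 1/phi0 over every death rank whose risk
    set contains i, minus its own tie-group correction if it died.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.mean()  # shift-invariant; guards exp overflow
    theta = np.exp(eta)

    order = np.argsort(time, kind="stable")
    t_s, e_s, X_s, th_s, eta_s = time[order], event[order], X[order], theta[order], eta[order]
    ev = e_s.astype(bool)

    uniq, group_starts = np.unique(t_s, return_index=True)
    d_counts = np.add.reduceat(e_s, group_starts)          # deaths per unique time
    has_death = d_counts > 0

    # risk-set sums at each unique time (reverse cumulative sums)
    S0 = np.cumsum(th_s[::-1])[::-1][group_starts][has_death]
    D0 = np.add.reduceat(np.where(ev, th_s, 0.0), group_starts)[has_death]
    d = d_counts[has_death]
    tau = uniq[has_death]

    # expand over death ranks l = 0..d_k-1 with Efron fractions l/d_k
    reps = np.repeat(np.arange(len(d)), d)
    if ties == "efron":
        offsets = np.arange(d.sum()) - np.repeat(np.cumsum(d) - d, d)
        frac = offsets / np.repeat(d, d)
    elif ties == "breslow":
        frac = np.zeros(int(d.sum()))
    else:
        raise ValueError(f"ties must be 'efron' or 'breslow', got {ties!r}")

    phi0 = S0[reps] - frac * D0[reps]
    loglik = float(eta_s[ev].sum() - np.log(phi0).sum())
    if not want_derivs:
        return loglik, None, None

    tx = th_s[:, None] * X_s                                # (n, p)
    S1 = np.cumsum(tx[::-1], axis=0)[::-1][group_starts][has_death]
    D1 = np.add.reduceat(np.where(ev[:, None], tx, 0.0), group_starts, axis=0)[has_death]
    r1 = (S1[reps] - frac[:, None] * D1[reps]) / phi0[:, None]   # (ranks, p)
    grad = X_s[ev].sum(axis=0) - r1.sum(axis=0)

    # per-group sums of 1/phi0 and frac/phi0 over that group's death ranks
    inv0 = 1.0 / phi0
    rank_starts = np.concatenate([[0], np.cumsum(d)[:-1]])
    a = np.add.reduceat(inv0, rank_starts)                  # per death group
    b = np.add.reduceat(frac * inv0, rank_starts)
    cum_a = np.cumsum(a)
    # subject i is in the risk set of every death group with tau <= t_i
    pos = np.searchsorted(tau, t_s, side="right")
    w = np.where(pos > 0, cum_a[np.clip(pos - 1, 0, None)], 0.0)
    # a dying subject's own-group correction: subtract frac/phi0 there
    grp_of = np.searchsorted(tau, t_s)                      # exact for event rows
    u = np.where(ev, b[np.clip(grp_of, 0, len(b) - 1)], 0.0)
    weight = th_s * (w - u)
    info = (X_s * weight[:, None]).T @ X_s - r1.T @ r1
    return loglik, grad, info


def cox_partial_loglik(X, time, event, beta, ties: str = "efron") -> float:
    """Efron/Breslow log partial likelihood at ``beta`` (for oracles and tests)."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(time):
        X = X.T
    ll, _, _ = _efron_quantities(
        X, np.asarray(time, float), np.asarray(event, int), np.asarray(beta, float), ties
    )
    return ll


def fit_cox(
    covariates,
    time,
    event,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-8,
    ridge: float = 0.0,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton–Raphson.

    Parameters
    ----------
    covariates : (n, p) array
        Covariate matrix; columns must be non-constant.
    time, event : (n,) arrays
        Observed follow-up (days) and death indicator (1 = event).
    ties : {"efron", "breslow"}
        Tied-event handling in the partial likelihood.
    max_iter, tol
        Newton iteration cap and gradient max-norm tolerance. Hitting
        ``max_iter`` or a singular information matrix yields
        ``converged=False`` rather than an exception, so genome-wide
        screens never abort; callers treat such fits as non-significant.
    ridge : float
        Optional L2 penalty (0.5·ridge·|beta|²) subtracted from the log
        partial likelihood, used to stabilize large collinear panels.

    Returns
    -------
    CoxFit
        Coefficients, standard errors, log-likelihoods and the three
        overall-test p-values (likelihood ratio, Wald, score/log-rank),
        each referred to a chi-square with p degrees of freedom.
    """
    X = np.asarray(covariates, float)
    if X.ndim == 1:
        X = X[:, None]
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    n, p = X.shape
    if len(time) != n or len(event) != n:
        raise ValueError("covariates, time and event must have equal length")
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events: a Cox model needs at least one death")
    const = np.ptp(X, axis=0) == 0
    if const.any():
        raise ValueError(f"constant covariate column(s): {np.where(const)[0].tolist()}")

    # center columns: partial likelihood is shift-invariant, conditioning improves
    Xc = X - X.mean(axis=0)

    eye = np.eye(p)
    beta = np.zeros(p)
    ll, grad, info = _efron_quantities(Xc, time, event, beta, ties)
    ll0 = ll
    # score test uses gradient/information at beta = 0
    try:
        stat_score = float(grad @ np.linalg.solve(info + ridge * eye, grad))
    except np.linalg.LinAlgError:
        stat_score = np.nan
    if ridge:
        ll -= 0.5 * ridge * float(beta @ beta)
        grad = grad - ridge * beta

    converged = False
    for _ in range(max_iter):
        pen_info = info + ridge * eye
        try:
            step = np.linalg.solve(pen_info, grad)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        # step-halving: insist the penalized log-likelihood does not decrease
        accepted = None
        scale = 1.0
        for _half in range(30):
            cand = beta + scale * step
            # full-step candidates almost always accept: compute derivatives
            # straight away; halved steps probe with the likelihood only
            derivs = _half == 0
            c_ll, c_grad, c_info = _efron_quantities(
                Xc, time, event, cand, ties, want_derivs=derivs
            )
            if ridge:
                c_ll -= 0.5 * ridge * float(cand @ cand)
            if np.isfinite(c_ll) and c_ll >= ll - 1e-12:
                accepted = (cand, c_ll, c_grad, c_info)
                break
            scale /= 2.0
        if accepted is None:
            break
        beta, ll, grad, info = accepted
        if grad is None:
            _, grad, info = _efron_quantities(Xc, time, event, beta, ties)
        if ridge:
            grad = grad - ridge * beta
        if np.max(np.abs(grad)) < tol:
            converged = True
            break

    pen_info = info + ridge * eye
    try:
        cov = np.linalg.inv(pen_info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        stat_wald = float(beta @ pen_info @ beta)
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        stat_wald = np.nan
        converged = False

    ll_fit_unpen = ll + (0.5 * ridge * float(beta @ beta) if ridge else 0.0)
    stat_lrt = max(2.0 * (ll_fit_unpen - ll0), 0.0)

    def _p(stat):
        if not np.isfinite(stat):
            return 1.0
        return float(max(stats.chi2.sf(stat, p), np.finfo(float).tiny))

    return CoxFit(
        beta=beta,
        se=se,
        loglik_null=ll0,
        loglik_fit=ll_fit_unpen,
        p_lrt=_p(stat_lrt),
        p_wald=_p(stat_wald),
        p_score=_p(stat_score),
        converged=converged,
        n_events=n_events,
    )


def concordance_index(risk, time, event) -> float:
    """Harrell's concordance index.

    A pair (i, j) is comparable iff the subject with the smaller
    observed time had the event (their failure order is then known).
    The pair is concordant iff the shorter-lived subject carries the
    higher risk score; ties in risk contribute 1/2.

    Returns the concordant-weight fraction in [0, 1]: 0.5 is a random
    score, 1 perfect concordance.
    """
    risk = np.asarray(risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if not (len(risk) == len(time) == len(event)):
        raise ValueError("risk, time and event must have equal length")

    earlier = time[:, None] < time[None, :]
    comparable = earlier & (event[:, None] == 1)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs (all censored or all times tied)")
    conc = comparable & (risk[:, None] > risk[None, :])
    tied = comparable & (risk[:, None] == risk[None, :])
    return float((conc.sum() + 0.5 * tied.sum()) / n_comp)


def km_estimate(time, event) -> KMCurve:
    """Kaplan–Meier product-limit survival estimate.

    The curve starts at S(0) = 1 and drops only at event times;
    censored subjects leave the risk set without a drop.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if len(time) == 0:
        raise ValueError("need at least one subject")
    n = len(time)
    order = np.argsort(time, kind="stable")
    t_s, e_s = time[order], event[order]
    uniq, starts, counts = np.unique(t_s, return_index=True, return_counts=True)
    at_risk = n - starts                       # subjects with t >= uniq[k]
    deaths = np.add.reduceat(e_s, starts)
    keep = deaths > 0
    surv = np.cumprod(1.0 - deaths[keep] / at_risk[keep])
    return KMCurve(
        times=np.concatenate([[0.0], uniq[keep]]),
        survival=np.concatenate([[1.0], surv]),
        at_risk=np.concatenate([[n], at_risk[keep]]),
    )


def logrank_test(group, time, event) -> float:
    """Two-sample log-rank test p-value (chi-square, 1 df).

    ``group`` is any two-level labelling (e.g. high/low risk). At each
    distinct event time the observed deaths in group 1 are compared with
    their hypergeometric expectation given the pooled risk set.
    """
    group = np.asarray(group)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {len(levels)}")
    if event.sum() == 0:
        raise ValueError("no events in either group")
    g1 = group == levels[0]

    order = np.argsort(time, kind="stable")
    t_s, e_s, g_s = time[order], event[order], g1[order]
    n = len(t_s)
    uniq, starts = np.unique(t_s, return_index=True)
    at_risk = n - starts
    # group-1 members still at risk at each unique time
    n1_rev = np.cumsum(g_s[::-1])[::-1]
    n1 = n1_rev[starts]
    d = np.add.reduceat(e_s, starts)
    d1 = np.add.reduceat(e_s * g_s, starts)

    keep = d > 0
    at_risk, n1, d, d1 = at_risk[keep], n1[keep], d[keep], d1[keep]
    expect = d * n1 / at_risk
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d * (n1 / at_risk) * (1 - n1 / at_risk) * (at_risk - d) / (at_risk - 1)
    var = np.where(at_risk > 1, var, 0.0)
    v = var.sum()
    if v <= 0:
        return 1.0
    chi2 = float((d1 - expect).sum() ** 2 / v)
    return float(max(stats.chi2.sf(chi2, 1), np.finfo(float).tiny))
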