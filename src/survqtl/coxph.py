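"""Cox proportional-hazards regression by Newton-Raphson on the partial
likelihood, with Efron's correction for tied event times.

This is the workhorse behind the gene- and variant-level survival screens.
It deliberately reimplements the semiparametric fit (rather than delegating
to a survival library) so the screening layer controls convergence,
monotone-likelihood flagging and Wald inference; established fitters are
used in the test suite as independent oracles.

Degenerate designs are handled explicitly: a covariate that perfectly
separates outcomes drives the coefficient to infinity (monotone partial
likelihood); the fit is flagged rather than reported at an arbitrary
stopping point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

__all__ = ["CoxFit", "cox_fit"]


@dataclass
class CoxFit:
    """Result of one Cox partial-likelihood fit.

    coef/se/p are per-column of the design matrix.  ``monotone`` marks
    likely monotone-likelihood degeneracy (diverging coefficient or
    non-convergence); hazard ratios from such fits are not trustworthy.
    """

    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    n_events: int
    converged: bool
    monotone: bool
    n_iter: int
    names: list = field(default_factory=list)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def zscores(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.coef / self.se

    @property
    def wald_p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zscores))

    def confidence_interval(self, level: float = 0.95) -> tuple:
        z = stats.norm.ppf(0.5 + level / 2.0)
        return np.exp(self.coef - z * self.se), np.exp(self.coef + z * self.se)


def _efron_loglik_grad_hess(
    beta: np.ndarray,
    x: np.ndarray,
    event_blocks: list,
    risk_starts: np.ndarray,
) -> tuple:
    """Partial log-likelihood, gradient and information under Efron ties.

    ``x`` is sorted by descending time so that the risk set at the i-th
    unique time is a prefix; ``event_blocks`` lists, per unique event time,
    the row indices of the deaths; ``risk_starts`` gives the prefix length
    (risk-set size) for each block.
    """
    n, p = x.shape
    eta = x @ beta
    # cap to keep exp() and its squares finite while a diverging
    # coefficient is still detectable by the coef bound
    w = np.exp(np.clip(eta, -200, 200))
    wx = w[:, None] * x
    wxx = np.einsum("i,ij,ik->ijk", w, x, x)

    cw = np.cumsum(w)
    cwx = np.cumsum(wx, axis=0)
    cwxx = np.cumsum(wxx, axis=0)

    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for block, r in zip(event_blocks, risk_starts):
        d = len(block)
        s0_r = cw[r - 1]
        s1_r = cwx[r - 1]
        s2_r = cwxx[r - 1]
        s0_d = w[block].sum()
        s1_d = wx[block].sum(axis=0)
        s2_d = wxx[block].sum(axis=0)
        loglik += eta[block].sum()
        grad += x[block].sum(axis=0)
        for ell in range(d):
            frac = ell / d
            phi = s0_r - frac * s0_d
            s1 = s1_r - frac * s1_d
            s2 = s2_r - frac * s2_d
            loglik -= np.log(phi)
            grad -= s1 / phi
            info += s2 / phi - np.outer(s1, s1) / phi**2
    return loglik, grad, info


def cox_fit(
    time: np.ndarray,
    event: np.ndarray,
    covariates: np.ndarray,
    names: Optional[list] = None,
    max_iter: int = 100,
    tol: float = 1e-9,
    coef_bound: float = 10.0,
) -> CoxFit:
    """Fit a Cox proportional-hazards model.

    Parameters
    ----------
    time, event : arrays of length n; event is 1 for an observed death.
    covariates : (n, p) design matrix (no intercept — the baseline hazard
        absorbs it).
    coef_bound : |coef| beyond which the likelihood is treated as monotone
        (perfect separation) and the fit flagged.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    if t.shape[0] != n or e.shape[0] != n:
        raise ValueError("time/event/covariates length mismatch")
    if e.sum() == 0:
        raise ValueError("no events observed: Cox model undefined")
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = np.where(sd == 0)[0].tolist()
        raise ValueError(f"constant covariate column(s): {bad}")

    # sort by descending time; ties put events in one contiguous block
    order = np.argsort(-t, kind="stable")
    t_s, e_s, x_s = t[order], e[order], x[order]

    event_blocks = []
    risk_starts = []
    i = 0
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        deaths = [k for k in range(i, j) if e_s[k] == 1]
        if deaths:
            event_blocks.append(np.array(deaths))
            risk_starts.append(j)  # risk set = all with time >= t_s[i]
        i = j
    risk_starts = np.array(risk_starts)

    beta = np.zeros(p)
    loglik, grad, info = _efron_loglik_grad_hess(beta, x_s, event_blocks, risk_starts)
    converged = False
    monotone = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            monotone = True
            break
        # step-halving line search
        scale = 1.0
        for _ in range(30):
            beta_new = beta + scale * step
            ll_new, grad_new, info_new = _efron_loglik_grad_hess(
                beta_new, x_s, event_blocks, risk_starts
            )
            if np.isfinite(ll_new) and ll_new >= loglik - 1e-12:
                break
            scale *= 0.5
        delta = np.abs(ll_new - loglik)
        beta, loglik, grad, info = beta_new, ll_new, grad_new, info_new
        if np.abs(beta).max() > coef_bound:
            monotone = True
            break
        if delta < tol and np.abs(grad).max() < 1e-9:
            converged = True
            break
    if not converged and not monotone:
        monotone = True  # non-convergence treated as degeneracy

    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return CoxFit(
        coef=beta,
        se=se,
        loglik=float(loglik),
        n=n,
        n_events=int(e.sum()),
        converged=converged,
        monotone=monotone,
        n_iter=it,
        names=list(names) if names is not None else [f"x{i}" for i in range(p)],
    )
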