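"""Kaplan-Meier estimation, the k-group log-rank test, and the
optimal-cutoff scan used to dichotomize expression for survival display.

The cutoff scan tests every distinct observed TPM value between the 20th
and 80th percentiles as a high/low split and keeps the cutoff with the
smallest log-rank p-value.  The selected p-value is an optimized statistic
and is reported as descriptive only — it is never pooled with the Cox
p-values for multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .qc import hard_call

__all__ = [
    "KmCurve",
    "CutoffScanResult",
    "km_estimate",
    "logrank_test",
    "optimal_cutoff_scan",
    "genotype_km",
]


@dataclass
class KmCurve:
    """Product-limit survival estimate for one group."""

    group: object
    times: np.ndarray       # distinct event/censor times, ascending
    survival: np.ndarray    # S(t) just after each time
    at_risk: np.ndarray     # number at risk just before each time
    n_events: np.ndarray    # deaths at each time


@dataclass
class CutoffScanResult:
    cutoffs: np.ndarray
    pvalues: np.ndarray
    selected_cutoff: float
    selected_p: float


def km_estimate(time, event, group=None) -> dict:
    """Kaplan-Meier curves per group (single pseudo-group when ``group`` is
    None).  Returns {label: KmCurve}."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if group is None:
        group = np.zeros(t.shape[0], dtype=int)
    g = np.asarray(group)
    curves = {}
    for label in np.unique(g):
        sel = g == label
        if not sel.any():
            raise ValueError(f"empty group {label}")
        ts, es = t[sel], e[sel]
        order = np.argsort(ts, kind="stable")
        ts, es = ts[order], es[order]
        utimes = np.unique(ts)
        surv = []
        at_risk = []
        n_ev = []
        s = 1.0
        for ut in utimes:
            n_risk = int((ts >= ut).sum())
            d = int(es[ts == ut].sum())
            if n_risk > 0:
                s *= 1.0 - d / n_risk
            at_risk.append(n_risk)
            n_ev.append(d)
            surv.append(s)
        curves[label] = KmCurve(
            group=label,
            times=utimes,
            survival=np.array(surv),
            at_risk=np.array(at_risk),
            n_events=np.array(n_ev),
        )
    return curves


def logrank_test(time, event, group) -> tuple:
    """Unweighted k-group log-rank test.

    Returns ``(chi_square, p_value)`` with k-1 degrees of freedom.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(group)
    labels = np.unique(g)
    k = labels.shape[0]
    if k < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    for label in labels:
        if not (g == label).any():
            raise ValueError(f"empty group {label}")

    event_times = np.unique(t[e == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    var = np.zeros((k, k))
    for ut in event_times:
        at_risk = t >= ut
        n_j = at_risk.sum()
        d_j = int(e[(t == ut)].sum())
        if n_j == 0 or d_j == 0:
            continue
        n_ij = np.array([(at_risk & (g == label)).sum() for label in labels], dtype=float)
        d_ij = np.array(
            [int(e[(t == ut) & (g == label)].sum()) for label in labels], dtype=float
        )
        observed += d_ij
        expected += d_j * n_ij / n_j
        if n_j > 1:
            factor = d_j * (n_j - d_j) / (n_j - 1.0)
            for a in range(k):
                for b in range(k):
                    delta = 1.0 if a == b else 0.0
                    var[a, b] += factor * n_ij[a] * (delta * n_j - n_ij[b]) / n_j**2
    z = (observed - expected)[:-1]
    v = var[:-1, :-1]
    try:
        chi2 = float(z @ np.linalg.solve(v, z))
    except np.linalg.LinAlgError:
        chi2 = float(z @ np.linalg.pinv(v) @ z)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return chi2, p


def optimal_cutoff_scan(
    tpm, time, event, min_group: int = 3,
    lower_pct: float = 20.0, upper_pct: float = 80.0,
) -> CutoffScanResult:
    """Scan observed TPM values in [P20, P80] for the split minimizing the
    two-group log-rank p-value.

    High group is TPM > cutoff, low group TPM <= cutoff; both strata must
    hold at least ``min_group`` subjects.  Ties in p resolve to the
    smallest cutoff.  Percentiles use linear interpolation.
    """
    x = np.asarray(tpm, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if x.shape[0] < 10:
        raise ValueError("cutoff scan needs >= 10 subjects")
    if np.all(x == x[0]):
        raise ValueError("constant TPM: no cutoff exists")
    lo, hi = np.percentile(x, [lower_pct, upper_pct])
    candidates = np.unique(x[(x >= lo) & (x <= hi)])
    cutoffs, pvals = [], []
    for c in candidates:
        high = x > c
        if high.sum() < min_group or (~high).sum() < min_group:
            continue
        _, p = logrank_test(t, e, high.astype(int))
        cutoffs.append(c)
        pvals.append(p)
    if not cutoffs:
        raise ValueError("no candidate cutoff leaves both strata non-empty")
    cutoffs = np.array(cutoffs)
    pvals = np.array(pvals)
    best = int(np.argmin(pvals))  # argmin takes the first (smallest cutoff) tie
    return CutoffScanResult(
        cutoffs=cutoffs,
        pvalues=pvals,
        selected_cutoff=float(cutoffs[best]),
        selected_p=float(pvals[best]),
    )


def genotype_km(dosages, time, event) -> tuple:
    """Genotype-stratified KM curves (ref/het/homalt) with a log-rank test.

    Dosages are hard-called; absent genotype categories are dropped.
    Returns ``(curves, chi_square, p)``.
    """
    d = hard_call(np.asarray(dosages, dtype=float))
    ok = ~np.isnan(d)
    d = d[ok]
    t = np.asarray(time, dtype=float)[ok]
    e = np.asarray(event, dtype=int)[ok]
    present = np.unique(d)
    if present.shape[0] < 2:
        raise ValueError("only one genotype category present")
    labels = {0.0: "ref", 1.0: "het", 2.0: "homalt"}
    g = np.array([labels[v] for v in d])
    curves = km_estimate(t, e, g)
    chi2, p = logrank_test(t, e, g)
    return curves, chi2, p
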