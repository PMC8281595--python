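"""Survival-analysis kernel: univariate Cox-PH, log-rank test, C-index.

The pipeline fits a univariate Cox proportional-hazards model to every
latent feature of every boosting member, i.e. tens of thousands of
one-covariate fits per run. A dedicated Newton solver on the Efron partial
likelihood keeps this fast: the tie structure of a survival table is
prepared once (:class:`CoxPrep`) and reused across all covariates, and each
likelihood evaluation is a handful of O(n) numpy operations. The solver is
cross-checked against lifelines' ``CoxPHFitter`` in the test suite.

The multi-group log-rank test delegates to lifelines. The concordance index
is computed directly from its definition over all comparable pairs
(shorter observed time with an event), with risk ties counted 1/2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import chi2

from .data_model import SurvivalTable
from .errors import MetricUnavailableError

logger = logging.getLogger(__name__)

_BETA_CAP = 50.0


@dataclass
class CoxResult:
    coefficient: float  # log hazard ratio per unit covariate
    standard_error: float
    p_value: float  # likelihood-ratio test
    converged: bool
    log_likelihood: float = np.nan


@dataclass
class LogrankResult:
    statistic: float
    degrees_of_freedom: int
    p_value: float


class CoxPrep:
    """Sorted order and tie structure of one survival table, shared by all
    univariate fits against it."""

    def __init__(self, survival: SurvivalTable):
        time = survival.time
        event = survival.event
        if event.sum() == 0:
            raise MetricUnavailableError("Cox model requires at least one event")
        self.order = np.argsort(-time, kind="stable")  # descending time
        t_s = time[self.order]
        e_s = event[self.order]
        self.n = len(t_s)
        # one group per distinct event time; risk set = prefix of the
        # descending array up to the last sample with time >= t
        event_times = np.unique(t_s[e_s == 1])[::-1]
        group_end, death_pos, offsets, d = [], [], [], []
        for t in event_times:
            members = np.nonzero(t_s == t)[0]
            deaths = members[e_s[members] == 1]
            group_end.append(members[-1])
            offsets.append(len(death_pos))
            death_pos.extend(deaths.tolist())
            d.append(len(deaths))
        self.group_end = np.asarray(group_end)
        self.death_pos = np.asarray(death_pos)
        self.death_offsets = np.asarray(offsets)
        self.d = np.asarray(d, dtype=float)
        self.max_d = int(self.d.max())

    def _segment_sums(self, values: np.ndarray) -> np.ndarray:
        return np.add.reduceat(values, self.death_offsets)

    def loglik(self, beta: float, x: np.ndarray) -> tuple[float, float, float]:
        """Efron partial log-likelihood, gradient and negative Hessian."""
        x_s = x[self.order]
        w = np.exp(np.clip(beta * x_s, -500, 500))
        xw = x_s * w
        x2w = x_s * xw
        cw = np.cumsum(w)
        cxw = np.cumsum(xw)
        cx2w = np.cumsum(x2w)
        S_R = cw[self.group_end]
        Sx_R = cxw[self.group_end]
        Sx2_R = cx2w[self.group_end]
        wD = self._segment_sums(w[self.death_pos])
        xwD = self._segment_sums(xw[self.death_pos])
        x2wD = self._segment_sums(x2w[self.death_pos])
        sum_xD = self._segment_sums(x_s[self.death_pos])

        ll = float(beta * sum_xD.sum())
        grad = float(sum_xD.sum())
        hess = 0.0
        for ell in range(self.max_d):
            mask = self.d > ell
            frac = ell / self.d[mask]
            denom = S_R[mask] - frac * wD[mask]
            num1 = Sx_R[mask] - frac * xwD[mask]
            num2 = Sx2_R[mask] - frac * x2wD[mask]
            mean = num1 / denom
            ll -= float(np.log(denom).sum())
            grad -= float(mean.sum())
            hess += float((num2 / denom - mean**2).sum())
        return ll, grad, hess


def fit_univariate_coxph(
    covariate: np.ndarray,
    survival: SurvivalTable,
    prep: CoxPrep | None = None,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxResult:
    """Newton maximization of the one-covariate Efron partial likelihood.

    The p-value is the likelihood-ratio test against beta = 0 (chi-square,
    1 df). A constant covariate carries no information and is returned as a
    non-converged null result (coefficient 0, p = 1). A monotone likelihood
    (perfectly separating covariate) is capped at |beta| = 50 and flagged
    as non-converged; its likelihood-ratio p-value remains usable.
    """
    x = np.asarray(covariate, dtype=float)
    if len(x) != len(survival):
        raise ValueError("covariate length does not match survival table")
    if prep is None:
        prep = CoxPrep(survival)
    if np.ptp(x) == 0:
        return CoxResult(0.0, np.inf, 1.0, converged=False, log_likelihood=np.nan)
    # standardize for numerical stability; rescale the estimate afterwards
    scale = x.std()
    xs = (x - x.mean()) / scale

    ll0, _, _ = prep.loglik(0.0, xs)
    beta, ll = 0.0, ll0
    converged = False
    for _ in range(max_iter):
        ll, grad, hess = prep.loglik(beta, xs)
        if abs(grad) < tol:
            converged = True
            break
        if hess <= 0:
            break
        step = grad / hess
        new_beta = float(np.clip(beta + step, -_BETA_CAP, _BETA_CAP))
        # step-halving keeps the likelihood non-decreasing
        for _ in range(30):
            new_ll, _, _ = prep.loglik(new_beta, xs)
            if new_ll >= ll - 1e-12:
                break
            new_beta = beta + (new_beta - beta) / 2.0
        if abs(new_beta - beta) < tol:
            beta = new_beta
            converged = True
            break
        beta = new_beta
    if abs(beta) >= _BETA_CAP:
        converged = False
    ll, _, hess = prep.loglik(beta, xs)
    se = 1.0 / np.sqrt(hess) if hess > 0 else np.inf
    lr_stat = max(2.0 * (ll - ll0), 0.0)
    p = float(chi2.sf(lr_stat, df=1))
    return CoxResult(
        coefficient=beta / scale,
        standard_error=se / scale,
        p_value=p,
        converged=converged,
        log_likelihood=ll,
    )


def logrank_test(labels, survival: SurvivalTable) -> LogrankResult:
    """K-group log-rank test on cluster labels; df = (non-empty groups) - 1."""
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise MetricUnavailableError("log-rank test requires >= 2 non-empty groups")
    if survival.n_events == 0:
        raise MetricUnavailableError("log-rank test requires >= 1 event")
    res = multivariate_logrank_test(survival.time, labels, survival.event)
    return LogrankResult(
        statistic=float(res.test_statistic),
        degrees_of_freedom=len(groups) - 1,
        p_value=float(res.p_value),
    )


def concordance_index(
    risk: np.ndarray, survival: SurvivalTable, chunk: int = 2048
) -> float:
    """Harrell's C: over pairs where the strictly shorter observed time had an
    event, the fraction in which that sample also has the higher risk
    (risk ties count 1/2). Raises when no pair is comparable."""
    risk = np.asarray(risk, dtype=float)
    if len(risk) != len(survival):
        raise ValueError("risk length does not match survival table")
    time, event = survival.time, survival.event
    n = len(risk)
    num = 0.0
    den = 0
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        comparable = (time[sl, None] < time[None, :]) & (event[sl, None] == 1)
        den += int(comparable.sum())
        diff = risk[sl, None] - risk[None, :]
        num += float((comparable & (diff > 0)).sum())
        num += 0.5 * float((comparable & (diff == 0)).sum())
    if den == 0:
        raise MetricUnavailableError("no comparable pairs (all censored or tied times)")
    return num / den
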