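"""Core statistical procedures for prognostic-score evaluation.

Everything here is implemented directly on top of numpy/scipy primitives:
Mann-Whitney U, Pearson chi-square, 2x2 odds ratios with Wald intervals,
logistic regression (IRLS), Cox proportional hazards (Efron ties),
the Kaplan-Meier product-limit estimator and the log-rank test.
scipy is used only for distribution tail functions and ranking.

Conventions
-----------
* All confidence intervals are Wald intervals on the log scale with
  z = 1.959964 (two-sided 95%).
* All p-values are two-sided.
* A 2x2 table is laid out exposure x outcome::

      a = exposed,   event        b = exposed,   no event
      c = unexposed, event        d = unexposed, no event
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as _chi2
from scipy.stats import norm as _norm
from scipy.stats import rankdata

Z95 = 1.959964


class ConvergenceError(RuntimeError):
    """A likelihood maximisation failed to converge (e.g. separation)."""


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    """2x2 integer counts, exposure (rows) by outcome (columns)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_diagnostic(cls, tp: int, fn: int, fp: int, tn: int) -> "ContingencyTable":
        """Build a table from diagnostic counts (test-positive = exposed)."""
        return cls(a=tp, b=fp, c=fn, d=tn)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: int | None = None


@dataclass(frozen=True)
class EffectEstimate:
    """A ratio-scale effect (odds or hazard ratio) with Wald CI and p."""

    point: float
    ci_low: float
    ci_high: float
    p_value: float
    kind: str = "odds-ratio"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError("confidence interval must bracket the point estimate")


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def probability_at(self, t: float) -> float:
        """S(t); right-continuous step function, S(t)=1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class RegressionFit:
    """Fitted coefficients and ratio-scale effect estimates per covariate."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    estimates: dict[str, EffectEstimate]
    loglik: float
    n_iter: int
    n: int
    score_chi2: float | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# rank / contingency tests
# ---------------------------------------------------------------------------

def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test, tie-corrected normal approximation.

    The statistic is U for the first sample (number of (x, y) pairs with
    x > y, counting ties as 1/2). A continuity correction of 0.5 is applied
    toward the null before computing the z score.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    mu = n1 * n2 / 2.0
    if var <= 0:  # all observations identical
        return TestResult(statistic=u1, p_value=1.0)
    z = max(abs(u1 - mu) - 0.5, 0.0) / math.sqrt(var)
    return TestResult(statistic=u1, p_value=min(1.0, 2.0 * _norm.sf(z)))


def pearson_chi_square(table) -> TestResult:
    """Pearson chi-square on an r x c count table, no continuity correction."""
    if isinstance(table, ContingencyTable):
        obs = table.as_array()
    else:
        obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal in contingency table")
    expected = np.outer(row, col) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return TestResult(statistic=stat, p_value=float(_chi2.sf(stat, df)), df=df)


def odds_ratio_2x2(table: ContingencyTable, haldane: bool = False) -> EffectEstimate:
    """Cross-product odds ratio ad/bc with Wald 95% CI and p-value.

    Zero cells are rejected unless ``haldane=True``, which adds 0.5 to every
    cell (Haldane-Anscombe correction).
    """
    a, b, c, d = (float(v) for v in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0:
        if not haldane:
            raise ValueError(
                "zero cell in 2x2 table; pass haldane=True for the "
                "Haldane-Anscombe +0.5 correction"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    p = 2.0 * _norm.sf(abs(log_or) / se)
    return EffectEstimate(
        point=math.exp(log_or),
        ci_low=math.exp(log_or - Z95 * se),
        ci_high=math.exp(log_or + Z95 * se),
        p_value=min(1.0, p),
        kind="odds-ratio",
    )


# ---------------------------------------------------------------------------
# logistic regression (IRLS)
# ---------------------------------------------------------------------------

def _as_design(predictors, names):
    if predictors is None:
        X = np.empty((0, 0))
        return X, []
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    if len(names) != X.shape[1]:
        raise ValueError("names must match the number of predictor columns")
    return X, list(names)


def fit_logistic(outcome, predictors=None, names=None,
                 tol: float = 1e-8, max_iter: int = 100) -> RegressionFit:
    """Maximum-likelihood logistic regression via Newton/IRLS.

    An intercept is always included. Per-covariate odds ratios with Wald
    95% CIs and p-values are returned in ``fit.estimates``. Convergence is
    declared when the log-likelihood changes by less than ``tol``.
    """
    y = np.asarray(outcome, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    X, names = _as_design(predictors, names)
    n = y.size
    if X.size and X.shape[0] != n:
        raise ValueError("outcome and predictors have different lengths")
    design = np.column_stack([np.ones(n)] + ([X] if X.size else []))
    p_cols = design.shape[1]
    if n <= p_cols - 1:
        raise ValueError("need more observations than predictors")
    if np.linalg.matrix_rank(design) < p_cols:
        raise ValueError("rank-deficient design matrix")

    beta = np.zeros(p_cols)
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        ll = float(y @ np.log(mu) + (1 - y) @ np.log(1 - mu))
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
        w = mu * (1 - mu)
        grad = design.T @ (y - mu)
        info = design.T @ (design * w[:, None])
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        beta = beta + step
        if np.abs(beta).max() > 30:
            raise ConvergenceError(
                "coefficients diverging; outcome is likely perfectly separated"
            )
    else:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")

    eta = design @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    info = design.T @ (design * w[:, None])
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))

    estimates = {}
    for j, name in enumerate(names, start=1):
        z = beta[j] / se[j]
        estimates[name] = EffectEstimate(
            point=math.exp(beta[j]),
            ci_low=math.exp(beta[j] - Z95 * se[j]),
            ci_high=math.exp(beta[j] + Z95 * se[j]),
            p_value=min(1.0, 2.0 * _norm.sf(abs(z))),
            kind="odds-ratio",
        )
    return RegressionFit(
        names=names, coef=beta, se=se, estimates=estimates,
        loglik=ll, n_iter=it, n=n,
        extra={"fitted_mean": float(mu.mean()), "intercept": float(beta[0])},
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)
# ---------------------------------------------------------------------------

def _cox_quantities(times, events, X, beta):
    """Efron partial log-likelihood, gradient and information at beta.

    Assumes times ascending. Risk set for an event time t is {i : t_i >= t};
    suffix cumulative sums over the sorted arrays give the risk-set sums.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # stabilise exp; cancels in all ratios
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = np.einsum("i,ij,ik->ijk", w, X, X)

    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        t = times[i]
        j = i
        while j < n and times[j] == t:
            j += 1
        ev = np.arange(i, j)[events[i:j] > 0]
        d = ev.size
        if d:
            tw0 = float(w[ev].sum())
            tw1 = wx[ev].sum(axis=0)
            tw2 = wxx[ev].sum(axis=0)
            ll += float(eta[ev].sum())
            grad += X[ev].sum(axis=0)
            for l in range(d):
                frac = l / d
                den0 = float(s0[i]) - frac * tw0
                den1 = s1[i] - frac * tw1
                den2 = s2[i] - frac * tw2
                xbar = den1 / den0
                ll -= math.log(den0)
                grad -= xbar
                info += den2 / den0 - np.outer(xbar, xbar)
        i = j
    return ll, grad, info


def fit_cox(time, event, predictors, names=None,
            tol: float = 1e-8, max_iter: int = 100) -> RegressionFit:
    """Cox proportional-hazards fit by Newton-Raphson with Efron ties.

    Returns per-covariate hazard ratios with Wald 95% CIs and p-values, plus
    the score chi-square at beta = 0 (equal to the log-rank statistic for a
    single binary covariate with no tied event times).
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    X, names = _as_design(predictors, names)
    if X.size == 0:
        raise ValueError("at least one covariate is required")
    if t.size != e.size or t.size != X.shape[0]:
        raise ValueError("time, event and predictors must have equal length")
    if (t <= 0).any():
        raise ValueError("times must be positive")
    if e.sum() == 0:
        raise ValueError("no events observed")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant covariate carries no information")

    order = np.argsort(t, kind="stable")
    t, e, X = t[order], e[order], X[order]
    Xc = X - X.mean(axis=0)  # centering improves conditioning, HRs unchanged

    p = Xc.shape[1]
    beta = np.zeros(p)
    ll0, grad0, info0 = _cox_quantities(t, e, Xc, beta)
    try:
        score_chi2 = float(grad0 @ np.linalg.solve(info0, grad0))
    except np.linalg.LinAlgError:
        score_chi2 = float("nan")

    ll_old = ll0
    for it in range(1, max_iter + 1):
        ll, grad, info = _cox_quantities(t, e, Xc, beta)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        # step-halving keeps the likelihood monotone
        new_beta = beta + step
        new_ll, _, _ = _cox_quantities(t, e, Xc, new_beta)
        halvings = 0
        while new_ll < ll and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new_ll, _, _ = _cox_quantities(t, e, Xc, new_beta)
            halvings += 1
        beta = new_beta
        if np.abs(beta).max() > 30:
            raise ConvergenceError(
                "coefficients diverging; the partial likelihood is monotone "
                "(all events at one covariate extreme)"
            )
        if abs(new_ll - ll_old) < tol:
            ll = new_ll
            break
        ll_old = new_ll
    else:
        raise ConvergenceError(f"Cox Newton-Raphson did not converge in {max_iter} iterations")

    _, _, info = _cox_quantities(t, e, Xc, beta)
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    estimates = {}
    for j, name in enumerate(names):
        z = beta[j] / se[j]
        estimates[name] = EffectEstimate(
            point=math.exp(beta[j]),
            ci_low=math.exp(beta[j] - Z95 * se[j]),
            ci_high=math.exp(beta[j] + Z95 * se[j]),
            p_value=min(1.0, 2.0 * _norm.sf(abs(z))),
            kind="hazard-ratio",
        )
    return RegressionFit(
        names=names, coef=beta, se=se, estimates=estimates,
        loglik=ll, n_iter=it, n=t.size, score_chi2=score_chi2,
        extra={"n_events": int(e.sum())},
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def kaplan_meier(time, event) -> SurvivalCurve:
    """Product-limit survival estimate.

    Subjects censored exactly at an event time remain in the risk set for
    that time (events before censorings, the standard convention).
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise ValueError("empty input")
    if (t <= 0).any():
        raise ValueError("times must be positive")

    event_times = np.unique(t[e > 0])
    n_at_risk = np.array([(t >= u).sum() for u in event_times], dtype=int)
    n_events = np.array([((t == u) & (e > 0)).sum() for u in event_times], dtype=int)
    if event_times.size == 0:
        return SurvivalCurve(
            event_times=np.empty(0), survival=np.empty(0), at_risk=np.empty(0, dtype=int)
        )
    surv = np.cumprod(1.0 - n_events / n_at_risk)
    return SurvivalCurve(event_times=event_times, survival=surv, at_risk=n_at_risk)


def log_rank(groups) -> TestResult:
    """Log-rank test across >= 2 groups of (time, event) samples.

    Observed-minus-expected event counts with the hypergeometric variance;
    the chi-square statistic uses the first k-1 groups and df = k-1.
    """
    parsed = []
    for g in groups:
        gt = np.asarray(g[0], dtype=float)
        ge = np.asarray(g[1], dtype=int)
        if gt.size == 0:
            raise ValueError("empty group")
        parsed.append((gt, ge))
    k = len(parsed)
    if k < 2:
        raise ValueError("need at least two groups")
    if sum(int(ge.sum()) for _, ge in parsed) == 0:
        raise ValueError("no events in any group")

    all_t = np.concatenate([gt for gt, _ in parsed])
    all_e = np.concatenate([ge for _, ge in parsed])
    times = np.unique(all_t[all_e > 0])

    o_minus_e = np.zeros(k)
    V = np.zeros((k, k))
    for u in times:
        n_j = np.array([(gt >= u).sum() for gt, _ in parsed], dtype=float)
        d_j = np.array([((gt == u) & (ge > 0)).sum() for gt, ge in parsed], dtype=float)
        n = n_j.sum()
        d = d_j.sum()
        if d == 0 or n <= 1:
            continue
        e_j = d * n_j / n
        o_minus_e += d_j - e_j
        # hypergeometric: Var_j = d (n-d)/(n-1) * (n_j/n)(1 - n_j/n)
        mult = d * (n - d) / (n - 1)
        V += mult * (np.diag(n_j / n) - np.outer(n_j / n, n_j / n))

    v = o_minus_e[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    try:
        stat = float(v @ np.linalg.solve(Vsub, v))
    except np.linalg.LinAlgError:
        warnings.warn("singular log-rank covariance; using pseudo-inverse")
        stat = float(v @ np.linalg.pinv(Vsub) @ v)
    df = k - 1
    return TestResult(statistic=stat, p_value=float(_chi2.sf(stat, df)), df=df)
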