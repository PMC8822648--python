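"""Rank correlations, sequential-Bonferroni correction, bootstrap effect
sizes and forward stepwise regression.

This is the statistical layer used by the satellitome comparison
report: Spearman rank correlations with a t-approximate test and a
Holm step-down ("sequential Bonferroni") family-wise correction;
Gardner--Altman-style bootstrap mean-difference effect sizes with BCa
intervals; and forward stepwise multiple regression with F-to-enter,
partial correlations and variance inflation factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    r_s: float
    t: float
    p: float
    n: int
    p_adj: float | None = None
    defined: bool = True


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with the t(n-2) significance test.

    Ranks use midranks for ties; ``t = r_s * sqrt((n-2) / (1-r_s^2))``
    and the two-sided p comes from the t distribution with n-2 df.  Zero
    variance in either vector yields a flagged-undefined result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal lengths")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), float("nan"), n, defined=False)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    r_s = float(np.corrcoef(rx, ry)[0, 1])
    if abs(r_s) >= 1.0:
        return CorrelationResult(r_s, float("inf") * np.sign(r_s), 0.0, n)
    t = r_s * np.sqrt((n - 2) / (1.0 - r_s**2))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return CorrelationResult(r_s, float(t), float(p), n)


def holm(pvals) -> np.ndarray:
    """Holm step-down adjustment (the sequential Bonferroni correction).

    Sorted ascending, ``p_(i)`` is multiplied by ``m - i + 1``; running
    maxima enforce monotonicity and values cap at 1.  The output is
    returned in the original input order.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = p[idx] * (m - rank)
        running = max(running, val)
        adj[idx] = min(1.0, running)
    return adj


# ---------------------------------------------------------------------------
# bootstrap effect sizes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSize:
    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    includes_zero: bool
    paired: bool
    method: str  # "bca" or "percentile"


def bootstrap_mean_diff(
    a,
    b,
    paired: bool = False,
    n_boot: int = 5000,
    seed: int | None = None,
    ci: float = 0.95,
    method: str = "bca",
) -> EffectSize:
    """Bootstrap mean-difference effect size with a BCa 95% interval.

    The point estimate is ``mean(a) - mean(b)`` (or the mean paired
    difference); the interval is bias-corrected and accelerated over
    `n_boot` resamples, falling back to the percentile interval (logged)
    when the BCa correction degenerates (e.g. zero-variance resamples).
    Seed-reproducible.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    if paired and len(a) != len(b):
        raise ValueError("paired samples must have equal lengths")
    rng = np.random.default_rng(seed)
    alpha = 1.0 - ci
    if paired:
        d = a - b
        point = float(d.mean())
        idx = rng.integers(0, len(d), size=(n_boot, len(d)))
        thetas = d[idx].mean(axis=1)
        jack = _jackknife_means(d)
    else:
        point = float(a.mean() - b.mean())
        ia = rng.integers(0, len(a), size=(n_boot, len(a)))
        ib = rng.integers(0, len(b), size=(n_boot, len(b)))
        thetas = a[ia].mean(axis=1) - b[ib].mean(axis=1)
        jack = np.concatenate([
            _jackknife_means(a) - b.mean(),
            a.mean() - _jackknife_means(b),
        ])
    thetas.sort()
    used = method
    lo_q, hi_q = alpha / 2.0, 1.0 - alpha / 2.0
    if method == "bca":
        qs = _bca_quantiles(thetas, point, jack, lo_q, hi_q)
        if qs is None:
            log.info("BCa correction degenerate; falling back to percentile interval")
            used = "percentile"
        else:
            lo_q, hi_q = qs
    elif method != "percentile":
        raise ValueError(f"unknown interval method: {method!r}")
    ci_low = float(np.quantile(thetas, lo_q))
    ci_high = float(np.quantile(thetas, hi_q))
    return EffectSize(
        point=point, ci_low=ci_low, ci_high=ci_high, n_boot=n_boot,
        includes_zero=ci_low <= 0.0 <= ci_high, paired=paired, method=used,
    )


def _jackknife_means(x: np.ndarray) -> np.ndarray:
    n = len(x)
    return (x.sum() - x) / (n - 1)


def _bca_quantiles(thetas, point, jack, lo_q, hi_q):
    prop = np.mean(thetas < point)
    if prop <= 0.0 or prop >= 1.0:
        return None
    z0 = sps.norm.ppf(prop)
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = np.sum((jm - jack) ** 2) ** 1.5
    if den == 0:
        return None
    acc = num / (6.0 * den)
    out = []
    for q in (lo_q, hi_q):
        z = sps.norm.ppf(q)
        denom = 1.0 - acc * (z0 + z)
        if denom <= 0:
            return None
        out.append(float(sps.norm.cdf(z0 + (z0 + z) / denom)))
    if not out[0] < out[1]:
        return None
    return tuple(out)


# ---------------------------------------------------------------------------
# forward stepwise regression
# ---------------------------------------------------------------------------

@dataclass
class StepwiseModel:
    entered: list[str]
    r2_steps: list[float]
    f_enter: list[float]
    p_enter: list[float]
    partial_r: dict[str, float]
    vif: dict[str, float]
    coef: dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    singular: bool = False
    residual_normality_p: float = float("nan")


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def forward_stepwise(X, y, names=None, p_enter: float = 0.05) -> StepwiseModel:
    """Forward stepwise OLS with F-to-enter selection.

    At each step the candidate with the largest F-to-enter joins the
    model if its p-value is below `p_enter`.  The result reports
    cumulative R-squared per step, partial correlations of the entered
    predictors (given the other entered ones), VIF of each entered
    predictor computed from its redundancy R-squared against *all other
    candidates* (entered or not), and a Shapiro-Wilk normality p-value
    for the standardized residuals.  A singular design stops the
    procedure with the set entered so far, flagged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if names is None:
        names = [f"x{j+1}" for j in range(m)]
    if len(names) != m:
        raise ValueError("names must match the number of predictors")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant predictor in the design")
    entered: list[int] = []
    r2_steps: list[float] = []
    f_steps: list[float] = []
    p_steps: list[float] = []
    tss = float(np.sum((y - y.mean()) ** 2))
    ones = np.ones((n, 1))
    _, rss_cur = _ols_rss(ones, y)
    singular = False
    while len(entered) < m and n > len(entered) + 2:
        best = None
        for j in range(m):
            if j in entered:
                continue
            design = np.hstack([ones, X[:, entered + [j]]])
            if np.linalg.matrix_rank(design) < design.shape[1]:
                continue
            _, rss_new = _ols_rss(design, y)
            df_resid = n - design.shape[1]
            if df_resid <= 0 or rss_new <= 0:
                f = np.inf
                p = 0.0
            else:
                f = (rss_cur - rss_new) / (rss_new / df_resid)
                p = float(sps.f.sf(f, 1, df_resid))
            if best is None or f > best[1]:
                best = (j, f, p, rss_new)
        if best is None:
            singular = True
            break
        j, f, p, rss_new = best
        if p >= p_enter:
            break
        entered.append(j)
        rss_cur = rss_new
        r2_steps.append(1.0 - rss_cur / tss if tss > 0 else float("nan"))
        f_steps.append(float(f))
        p_steps.append(p)
        if rss_cur <= 1e-12 * tss:
            break
    names_entered = [names[j] for j in entered]
    partial = {}
    for j in entered:
        others = [k for k in entered if k != j]
        partial[names[j]] = _partial_corr(X[:, j], y, X[:, others] if others else None)
    vif = {}
    for j in entered:
        others = [k for k in range(m) if k != j]
        design = np.hstack([ones, X[:, others]])
        _, rss_j = _ols_rss(design, X[:, j])
        tss_j = float(np.sum((X[:, j] - X[:, j].mean()) ** 2))
        r2_j = 1.0 - rss_j / tss_j if tss_j > 0 else 0.0
        vif[names[j]] = 1.0 / (1.0 - r2_j) if r2_j < 1.0 else float("inf")
    model = StepwiseModel(
        entered=names_entered, r2_steps=r2_steps, f_enter=f_steps,
        p_enter=p_steps, partial_r=partial, vif=vif, singular=singular,
    )
    if entered:
        design = np.hstack([ones, X[:, entered]])
        beta, rss = _ols_rss(design, y)
        model.intercept = float(beta[0])
        model.coef = {names[j]: float(b) for j, b in zip(entered, beta[1:])}
        resid = y - design @ beta
        if n >= 3 and np.ptp(resid) > 0 and rss > 1e-12 * max(tss, 1.0):
            model.residual_normality_p = float(sps.shapiro(resid).pvalue)
    return model


def _partial_corr(x: np.ndarray, y: np.ndarray, Z: np.ndarray | None) -> float:
    if Z is None or Z.size == 0:
        return float(np.corrcoef(x, y)[0, 1])
    ones = np.ones((len(x), 1))
    design = np.hstack([ones, Z])
    bx, _ = _ols_rss(design, x)
    by, _ = _ols_rss(design, y)
    rx = x - design @ bx
    ry = y - design @ by
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])
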