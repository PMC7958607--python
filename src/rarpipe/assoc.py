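"""Fatigability scoring and association statistics.

Scores the 10-item 0-5 perceived physical fatigability scale (sum 0-50,
cut point >= 15), and estimates associations of rhythm features with the
score: median (quantile) regression solved as a linear program with
seeded case-resampling bootstrap inference, a check-loss ratio test for
nested quantile models, Kruskal-Wallis and pairwise rank-sum group
comparisons, logistic odds ratios, and Cohen's d effect sizes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import linprog

from .errors import CollinearityError, ConfigError, DataError, UndefinedEffectError

logger = logging.getLogger(__name__)

PFS_N_ITEMS = 10
PFS_MAX_ITEM = 5
PFS_CUTPOINT = 15

__all__ = [
    "score_pfs",
    "classify_fatigability",
    "QuantRegResult",
    "median_regression",
    "check_loss",
    "LRTResult",
    "qr_likelihood_ratio_test",
    "group_comparison_tests",
    "LogisticORResult",
    "logistic_fatigability_or",
    "cohens_d",
]


# ---------------------------------------------------------------------------
# scale scoring


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def score_pfs(items, max_missing: int = 3) -> tuple[int | None, bool]:
    """Sum the 10 item responses into a 0-50 score.

    With 1..``max_missing`` missing items, each missing response is imputed
    with the mean of the respondent's completed items and the sum rounded to
    the nearest integer (person-mean imputation). More missing than
    ``max_missing`` yields a missing score. Returns ``(score, imputed)``.
    """
    items = list(items)
    if len(items) != PFS_N_ITEMS:
        raise DataError(f"expected {PFS_N_ITEMS} item responses, got {len(items)}")
    complete = []
    n_missing = 0
    for v in items:
        if _is_missing(v):
            n_missing += 1
            continue
        v = float(v)
        if not v.is_integer() or not 0 <= v <= PFS_MAX_ITEM:
            raise DataError(f"item response outside 0-{PFS_MAX_ITEM}: {v}")
        complete.append(int(v))
    if n_missing == 0:
        return sum(complete), False
    if n_missing > max_missing or not complete:
        return None, False
    person_mean = sum(complete) / len(complete)
    total = sum(complete) + n_missing * person_mean
    return int(math.floor(total + 0.5)), True


def classify_fatigability(score, cutpoint: int = PFS_CUTPOINT):
    """True iff score >= cutpoint (boundary inclusive); missing score -> None."""
    if _is_missing(score):
        return None
    if not 0 <= score <= PFS_N_ITEMS * PFS_MAX_ITEM:
        raise DataError(f"score outside 0-50: {score}")
    return bool(score >= cutpoint)


# ---------------------------------------------------------------------------
# quantile regression


@dataclass(frozen=True)
class QuantRegResult:
    tau: float
    names: tuple[str, ...]
    estimates: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    pvalues: np.ndarray
    check_loss: float
    n: int
    seed: int | None
    residuals: np.ndarray

    def coef(self, name: str) -> float:
        return float(self.estimates[self.names.index(name)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.estimates,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p_value": self.pvalues,
            }
        )


def check_loss(residuals: np.ndarray, tau: float) -> float:
    """Sum of the asymmetric absolute (check) loss rho_tau over residuals."""
    r = np.asarray(residuals, dtype=float)
    return float(np.sum(r * (tau - (r < 0))))


def _qr_fit(y: np.ndarray, X: np.ndarray, tau: float) -> np.ndarray:
    """Solve min_b sum rho_tau(y - Xb) as a linear program (HiGHS).

    Variables are (b, u+, u-) with y - Xb = u+ - u-, u+/- >= 0.
    """
    n, p = X.shape
    c = np.concatenate([np.zeros(p), np.full(n, tau), np.full(n, 1.0 - tau)])
    A_eq = np.hstack([X, np.eye(n), -np.eye(n)])
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:  # pragma: no cover - HiGHS is robust on feasible LPs
        raise DataError(f"quantile-regression LP failed: {res.message}")
    return res.x[:p]


def median_regression(
    y,
    X,
    names: list[str] | None = None,
    tau: float = 0.5,
    bootstrap_B: int = 1000,
    seed: int = 0,
) -> QuantRegResult:
    """Quantile regression of ``y`` on design ``X`` at quantile ``tau``.

    Rows with any missing value are dropped (logged). Point estimates come
    from the exact linear-programming solution of the check-loss problem;
    confidence intervals are seeded nonparametric case-resampling bootstrap
    percentiles with normal-approximation p-values. ``bootstrap_B=0`` skips
    inference (CIs and p-values are NaN).
    """
    if not 0.0 < tau < 1.0:
        raise ConfigError(f"tau must be in (0, 1), got {tau}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    keep = ~(np.isnan(y) | np.isnan(X).any(axis=1))
    dropped = int((~keep).sum())
    if dropped:
        logger.info("median_regression: dropped %d incomplete case(s)", dropped)
    y, X = y[keep], X[keep]
    n, p = X.shape
    if n <= p:
        raise DataError(f"need n > p, got n={n}, p={p}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        _, R = np.linalg.qr(X)
        dep = [names[j] for j in range(p) if abs(R[j, j] if j < R.shape[0] else 0) < 1e-10]
        raise CollinearityError(
            f"design matrix rank {rank} < {p}; dependent column(s): {dep or names}"
        )

    beta = _qr_fit(y, X, tau)
    resid = y - X @ beta

    ci_lo = np.full(p, np.nan)
    ci_hi = np.full(p, np.nan)
    pvals = np.full(p, np.nan)
    if bootstrap_B > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty((bootstrap_B, p))
        for b in range(bootstrap_B):
            ix = rng.integers(0, n, size=n)
            try:
                boot[b] = _qr_fit(y[ix], X[ix], tau)
            except (DataError, np.linalg.LinAlgError):
                boot[b] = np.nan
        ok = ~np.isnan(boot).any(axis=1)
        boot = boot[ok]
        ci_lo = np.percentile(boot, 2.5, axis=0)
        ci_hi = np.percentile(boot, 97.5, axis=0)
        se = boot.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        pvals = 2.0 * stats.norm.sf(np.abs(z))

    return QuantRegResult(
        tau=tau,
        names=tuple(names),
        estimates=beta,
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        pvalues=pvals,
        check_loss=check_loss(resid, tau),
        n=n,
        seed=seed if bootstrap_B > 0 else None,
        residuals=resid,
    )


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float
    sparsity: float


def _hall_sheather_bandwidth(n: int, tau: float, alpha: float = 0.05) -> float:
    z = stats.norm.ppf(1 - alpha / 2)
    q = stats.norm.ppf(tau)
    num = 1.5 * stats.norm.pdf(q) ** 2
    den = 2 * q**2 + 1
    return n ** (-1 / 3) * z ** (2 / 3) * (num / den) ** (1 / 3)


def qr_likelihood_ratio_test(full: QuantRegResult, reduced: QuantRegResult) -> LRTResult:
    """Check-loss ratio test for nested quantile-regression models.

    Statistic ``2*(L_reduced - L_full) / (tau*(1-tau)*s)`` referred to a
    chi-square with df = difference in parameter counts; the sparsity ``s``
    is a difference quotient of the full-model residual quantile function at
    the Hall-Sheather bandwidth.
    """
    if not set(reduced.names) <= set(full.names):
        raise ConfigError("reduced model terms are not a subset of the full model")
    if reduced.n != full.n or reduced.tau != full.tau:
        raise ConfigError("models must share rows and tau")
    df = len(full.names) - len(reduced.names)
    if df == 0:
        return LRTResult(statistic=0.0, df=0, p_value=1.0, sparsity=float("nan"))
    tau, n = full.tau, full.n
    h = _hall_sheather_bandwidth(n, tau)
    h = min(h, tau - 1e-6, 1 - tau - 1e-6)
    r = np.sort(full.residuals)
    s = (np.quantile(r, tau + h) - np.quantile(r, tau - h)) / (2 * h)
    s = max(s, 1e-12)
    statistic = max(0.0, 2.0 * (reduced.check_loss - full.check_loss) / (tau * (1 - tau) * s))
    return LRTResult(
        statistic=statistic,
        df=df,
        p_value=float(stats.chi2.sf(statistic, df)),
        sparsity=float(s),
    )


# ---------------------------------------------------------------------------
# rank tests, odds ratios, effect sizes


def group_comparison_tests(groups: dict[str, np.ndarray]) -> dict:
    """Kruskal-Wallis across all groups plus all pairwise rank-sum tests.

    Pairwise tests use the normal approximation with tie correction and are
    reported unadjusted; a Holm-corrected column is included as an optional
    extra but the primary p-values are raw.
    """
    if len(groups) < 2:
        raise ConfigError("need at least 2 groups")
    clean = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, vals in clean.items():
        if vals.size == 0:
            raise ConfigError(f"group {name!r} is empty")
    H, p = stats.kruskal(*clean.values())
    keys = sorted(clean)
    pairwise = {}
    raw_ps = []
    pairs = []
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            u, pw = stats.mannwhitneyu(
                clean[a], clean[b], alternative="two-sided", method="asymptotic"
            )
            pairwise[(a, b)] = {"statistic": float(u), "p_value": float(pw)}
            raw_ps.append(pw)
            pairs.append((a, b))
    order = np.argsort(raw_ps)
    m = len(raw_ps)
    holm = np.empty(m)
    running = 0.0
    for rank, ix in enumerate(order):
        running = max(running, (m - rank) * raw_ps[ix])
        holm[ix] = min(1.0, running)
    for pair, hp in zip(pairs, holm):
        pairwise[pair]["p_holm"] = float(hp)
    return {
        "kruskal": {"statistic": float(H), "p_value": float(p)},
        "pairwise": pairwise,
    }


@dataclass(frozen=True)
class LogisticORResult:
    names: tuple[str, ...]
    odds_ratios: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    pvalues: np.ndarray
    n: int
    separation: bool


def logistic_fatigability_or(y, X, names: list[str] | None = None) -> LogisticORResult:
    """Logistic regression odds ratios (per unit) with Wald CIs.

    Complete separation is flagged and estimates suppressed (NaN).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    keep = ~(np.isnan(y) | np.isnan(X).any(axis=1))
    y, X = y[keep], X[keep]
    n, p = X.shape
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        separated = (not fit.mle_retvals.get("converged", True)) or bool(
            np.any(np.abs(fit.params) > 20)
        )
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        separated = True
        fit = None
    if separated:
        logger.warning("logistic fit flagged for (quasi-)separation; estimates suppressed")
        nanvec = np.full(p, np.nan)
        return LogisticORResult(tuple(names), nanvec, nanvec.copy(), nanvec.copy(),
                                nanvec.copy(), n, True)
    se = fit.bse
    zcrit = stats.norm.ppf(0.975)
    return LogisticORResult(
        names=tuple(names),
        odds_ratios=np.exp(fit.params),
        ci_lower=np.exp(fit.params - zcrit * se),
        ci_upper=np.exp(fit.params + zcrit * se),
        pvalues=np.asarray(fit.pvalues),
        n=n,
        separation=False,
    )


def cohens_d(group_a, group_b) -> float:
    """Standardized mean difference with (n-1)-weighted pooled SD."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("each group needs at least 2 values")
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled_var == 0:
        raise UndefinedEffectError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))
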