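"""Antilogistic extended cosine modeling of 24-h rest-activity rhythms.

The mean curve on the log-count scale is

    f(t) = m + amp * expit(beta * (cos((t - phi) * 2*pi/24) - alpha))

with ``m`` the minimum level, ``amp`` the amplitude, ``alpha`` in (-1, 1)
controlling the width of the active period, ``beta`` > 0 the steepness of
the rest/active transition and ``phi`` the acrophase in hours. Derived
quantities: mesor level ``m + amp/2``, the ascending ("up mesor" / rise
time) and descending ("down mesor") crossings of that level at
``phi -/+ (24/2pi) * arccos(alpha)``, and a pseudo-F statistic comparing the
fitted curve with a constant-mean fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit

from .epoch_io import EpochSeries, SECONDS_PER_DAY
from .errors import DataError, InsufficientDataError

logger = logging.getLogger(__name__)

_OMEGA = 2.0 * np.pi / 24.0
_HOURS_PER_RADIAN = 24.0 / (2.0 * np.pi)

#: number of mean-model parameters (m, amp, alpha, beta, phi)
N_PARAMS = 5

FIT_TABLE_COLUMNS = [
    "participant_id",
    "m",
    "amp",
    "alpha",
    "beta",
    "phi",
    "mesor_log",
    "mesor_exp",
    "up_mesor",
    "down_mesor",
    "pseudo_f",
    "n_epochs",
    "n_days_observed",
    "converged",
]


@dataclass(frozen=True)
class CosineParams:
    m: float
    amp: float
    alpha: float
    beta: float
    phi: float

    def __post_init__(self) -> None:
        if not -1.0 < self.alpha < 1.0:
            raise DataError(f"alpha must be in (-1, 1), got {self.alpha}")
        if self.beta <= 0:
            raise DataError(f"beta must be positive, got {self.beta}")
        if self.amp < 0:
            raise DataError(f"amp must be non-negative, got {self.amp}")
        object.__setattr__(self, "phi", float(self.phi) % 24.0)

    def as_array(self) -> np.ndarray:
        return np.array([self.m, self.amp, self.alpha, self.beta, self.phi])


@dataclass(frozen=True)
class CosineFitResult:
    params: CosineParams
    mesor_log: float
    mesor_exp: float
    up_mesor: float
    down_mesor: float
    pseudo_f: float
    rss_model: float
    rss_null: float
    n_epochs: int
    n_days_observed: float
    converged: bool


def antilogistic_mean(t, params: CosineParams) -> np.ndarray | float:
    """Evaluate the mean curve at hour(s)-of-day ``t`` (any real; period 24)."""
    t = np.asarray(t, dtype=float)
    val = params.m + params.amp * expit(
        params.beta * (np.cos((t - params.phi) * _OMEGA) - params.alpha)
    )
    return val if val.ndim else float(val)


def cosinor_init(series: EpochSeries) -> CosineParams:
    """Standard-cosinor warm start via the linear cos/sin parameterization.

    Fits ``y = M + A*cos((t - phi) * 2pi/24)`` by least squares on wear epochs
    and maps to extended-model starting values ``m0 = M - A``, ``amp0 = 2A``,
    ``alpha0 = 0``, ``beta0 = 2``.
    """
    t, y = _wear_observations(series)
    X = np.column_stack([np.ones_like(t), np.cos(t * _OMEGA), np.sin(t * _OMEGA)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    M, b1, b2 = coef
    A = float(np.hypot(b1, b2))
    phi0 = float(np.arctan2(b2, b1) * _HOURS_PER_RADIAN) % 24.0
    return CosineParams(m=float(M - A), amp=2.0 * A, alpha=0.0, beta=2.0, phi=phi0)


def _wear_observations(series: EpochSeries) -> tuple[np.ndarray, np.ndarray]:
    if series.log_counts is None:
        raise DataError("log_counts not populated; run log_transform first")
    t = series.hours_of_day()
    if series.wear is not None:
        keep = series.wear
        t, y = t[keep], series.log_counts[keep]
    else:
        y = series.log_counts
    if t.size == 0:
        raise InsufficientDataError(
            f"participant {series.participant_id}: no wear epochs"
        )
    return t, y


def _residuals_and_jac(t: np.ndarray, y: np.ndarray):
    # optimizer parameterization: x = (m, amp, alpha, ln_beta, phi)
    def resid(x):
        m, amp, alpha, lnb, phi = x
        beta = np.exp(lnb)
        c = np.cos((t - phi) * _OMEGA)
        return m + amp * expit(beta * (c - alpha)) - y

    def jac(x):
        m, amp, alpha, lnb, phi = x
        beta = np.exp(lnb)
        c = np.cos((t - phi) * _OMEGA)
        s = expit(beta * (c - alpha))
        sp = s * (1.0 - s)
        J = np.empty((t.size, 5))
        J[:, 0] = 1.0
        J[:, 1] = s
        J[:, 2] = -amp * sp * beta
        J[:, 3] = amp * sp * (c - alpha) * beta  # d/d ln(beta)
        J[:, 4] = amp * sp * beta * np.sin((t - phi) * _OMEGA) * _OMEGA
        return J

    return resid, jac


def fit_extended_cosine(
    series: EpochSeries,
    init: CosineParams | None = None,
    min_epochs: int | None = None,
    ftol: float = 1e-10,
) -> CosineFitResult:
    """Fit the extended cosine model to a participant's wear epochs.

    Bounded nonlinear least squares on log counts with ``alpha`` in
    [-0.999, 0.999], ``beta`` optimized on the ln scale in (0, 1000],
    ``amp >= 0`` and ``phi`` unbounded (reduced mod 24 afterwards). If the
    first start does not converge, the acrophase start is shifted by -3 and
    +3 hours; the best attempt is returned with ``converged=False`` if all
    starts fail.
    """
    t, y = _wear_observations(series)
    if min_epochs is None:
        min_epochs = SECONDS_PER_DAY // series.epoch_seconds
    if t.size < min_epochs:
        raise InsufficientDataError(
            f"participant {series.participant_id}: {t.size} wear epochs "
            f"< required {min_epochs}"
        )
    if init is None:
        init = cosinor_init(series)

    resid, jac = _residuals_and_jac(t, y)
    lower = [-np.inf, 0.0, -0.999, np.log(1e-2), -np.inf]
    upper = [np.inf, np.inf, 0.999, np.log(1e3), np.inf]

    def clip_x0(x0):
        return np.clip(x0, lower, upper)

    best = None
    converged = False
    for dphi in (0.0, -3.0, 3.0):
        x0 = clip_x0(
            np.array(
                [
                    init.m,
                    max(init.amp, 1e-6),
                    init.alpha,
                    np.log(init.beta),
                    init.phi + dphi,
                ]
            )
        )
        sol = least_squares(
            resid,
            x0,
            jac=jac,
            bounds=(lower, upper),
            method="trf",
            ftol=ftol,
            xtol=1e-12,
            gtol=1e-12,
            max_nfev=400,
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success:
            converged = True
            if dphi == 0.0:
                best = sol
            break
    if not converged:
        logger.warning(
            "participant %s: extended-cosine fit did not converge", series.participant_id
        )

    m, amp, alpha, lnb, phi = best.x
    params = CosineParams(m=float(m), amp=float(amp), alpha=float(alpha),
                          beta=float(np.exp(lnb)), phi=float(phi) % 24.0)
    rss_model = float(np.sum(resid(best.x) ** 2))
    rss_null = float(np.sum((y - y.mean()) ** 2))
    n_days = t.size * series.epoch_seconds / SECONDS_PER_DAY
    return derive_parameters(
        params,
        rss_model=rss_model,
        rss_null=rss_null,
        n_epochs=int(t.size),
        n_days_observed=float(n_days),
        converged=converged,
    )


def derive_parameters(
    params: CosineParams,
    rss_model: float,
    rss_null: float,
    n_epochs: int,
    n_days_observed: float = float("nan"),
    converged: bool = True,
) -> CosineFitResult:
    """Derive mesor level and crossing times from fitted parameters.

    The curve crosses its mesor level ``m + amp/2`` at
    ``phi -/+ (24/2pi)*arccos(alpha)`` (ascending / descending).
    """
    if not -1.0 < params.alpha < 1.0:
        raise DataError("alpha outside (-1, 1)")
    half_width = _HOURS_PER_RADIAN * float(np.arccos(params.alpha))
    mesor_log = params.m + params.amp / 2.0
    return CosineFitResult(
        params=params,
        mesor_log=mesor_log,
        mesor_exp=float(np.exp(mesor_log)),
        up_mesor=(params.phi - half_width) % 24.0,
        down_mesor=(params.phi + half_width) % 24.0,
        pseudo_f=pseudo_f_statistic(rss_null, rss_model, n_epochs),
        rss_model=rss_model,
        rss_null=rss_null,
        n_epochs=n_epochs,
        n_days_observed=n_days_observed,
        converged=converged,
    )


def pseudo_f_statistic(
    rss_null: float, rss_model: float, n_epochs: int, p: int = N_PARAMS
) -> float:
    """F-ratio of the extended-cosine fit against a constant-mean fit."""
    if n_epochs <= p:
        raise InsufficientDataError(f"need more than {p} epochs, got {n_epochs}")
    if rss_model == 0.0:
        warnings.warn("perfect fit: pseudo-F is infinite", stacklevel=2)
        return float("inf")
    return ((rss_null - rss_model) / (p - 1)) / (rss_model / (n_epochs - p))


def fit_results_to_frame(results: dict[str, CosineFitResult]) -> pd.DataFrame:
    """Per-participant parameter table (one row per fitted participant)."""
    rows = []
    for pid in sorted(results):
        r = results[pid]
        rows.append(
            {
                "participant_id": pid,
                "m": r.params.m,
                "amp": r.params.amp,
                "alpha": r.params.alpha,
                "beta": r.params.beta,
                "phi": r.params.phi,
                "mesor_log": r.mesor_log,
                "mesor_exp": r.mesor_exp,
                "up_mesor": r.up_mesor,
                "down_mesor": r.down_mesor,
                "pseudo_f": r.pseudo_f,
                "n_epochs": r.n_epochs,
                "n_days_observed": r.n_days_observed,
                "converged": r.converged,
            }
        )
    return pd.DataFrame(rows, columns=FIT_TABLE_COLUMNS)
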