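"""Zero-intercept (through-origin) log-log regression.

Two detection counts measured on the same population should sit on the 1:1
line if the methods are equally sensitive, so the comparison is fit as
``y = b * x`` on natural-log counts with no intercept. With a single free
parameter the residual degrees of freedom are n - 1, the fit measure is the
uncentered R^2 = 1 - RSS / sum(y^2), and the overall F statistic compares the
slope model to the zero model on (1, n - 1) degrees of freedom.

Residuals may be reported raw, internally studentized (divided by
sigma_hat * sqrt(1 - h_ii), with leverage h_ii = x_i^2 / sum(x^2)), or simply
scaled by the residual standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    DegenerateDesignError,
    DegenerateResidualsError,
    DomainError,
    InsufficientDataError,
)


def log_counts(counts, population_ids=None, base: float = math.e) -> np.ndarray:
    """Element-wise logarithm of detection counts.

    Natural log by default; pass ``base=10`` for common logs (slope and R^2
    are invariant to the base, residual magnitudes are not).

    Raises
    ------
    DomainError
        If any count is nonpositive; the message names the offending
        population when ``population_ids`` is given.
    """
    arr = np.asarray(counts, dtype=float)
    bad = np.nonzero(~(arr > 0))[0]
    if bad.size:
        i = int(bad[0])
        who = f"population {population_ids[i]!r}" if population_ids is not None else f"index {i}"
        raise DomainError(f"count must be positive to take logs; {who} has {arr[i]!r}")
    out = np.log(arr)
    if base != math.e:
        out = out / math.log(base)
    return out


@dataclass(frozen=True)
class OriginFit:
    """Result of a through-origin least-squares fit."""

    slope: float
    slope_se: float
    r2_uncentered: float
    f_stat: float
    df_resid: int
    p_value: float
    sigma: float                      # residual scale, sqrt(RSS / (n - 1))
    residuals: np.ndarray             # y - slope * x, log-count units
    studentized_residuals: np.ndarray  # r / (sigma * sqrt(1 - h)), unitless
    leverages: np.ndarray
    population_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n(self) -> int:
        return len(self.residuals)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "slope_se": self.slope_se,
            "r2_uncentered": self.r2_uncentered,
            "f_stat": self.f_stat,
            "df_resid": self.df_resid,
            "p_value": self.p_value,
            "sigma": self.sigma,
            "n": self.n,
            "residuals": self.residuals.tolist(),
            "studentized_residuals": self.studentized_residuals.tolist(),
            "population_ids": list(self.population_ids),
        }


def fit_through_origin(x, y, population_ids=None) -> OriginFit:
    """Least-squares line through the origin.

    slope = sum(x*y) / sum(x^2); residual variance uses n - 1 degrees of
    freedom (one estimated parameter); the p-value is the upper tail of the
    F(1, n - 1) distribution.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 observations.
    DegenerateDesignError
        All predictor values zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"through-origin fit needs n >= 3, got n = {n}")
    sxx = float(x @ x)
    if sxx == 0.0:
        raise DegenerateDesignError("all predictor values are zero")

    slope = float(x @ y) / sxx
    resid = y - slope * x
    rss = float(resid @ resid)
    syy = float(y @ y)
    df = n - 1
    sigma2 = rss / df
    sigma = math.sqrt(sigma2)
    slope_se = math.sqrt(sigma2 / sxx)
    r2 = 1.0 - rss / syy if syy > 0 else 0.0
    f_stat = (syy - rss) / sigma2 if sigma2 > 0 else math.inf
    p = float(stats.f.sf(f_stat, 1, df)) if math.isfinite(f_stat) else 0.0

    leverage = x * x / sxx
    with np.errstate(divide="ignore", invalid="ignore"):
        stud = resid / (sigma * np.sqrt(1.0 - leverage)) if sigma > 0 else np.full(n, np.nan)

    ids = tuple(population_ids) if population_ids is not None else tuple()
    return OriginFit(
        slope=slope,
        slope_se=slope_se,
        r2_uncentered=r2,
        f_stat=f_stat,
        df_resid=df,
        p_value=p,
        sigma=sigma,
        residuals=resid,
        studentized_residuals=stud,
        leverages=leverage,
        population_ids=ids,
    )


def standardize_residuals(fit: OriginFit, kind: str = "studentized") -> np.ndarray:
    """Residuals on a common unitless scale.

    ``kind="studentized"`` (default) returns the internally studentized
    residuals r_i / (sigma_hat * sqrt(1 - h_ii)) -- the standard meaning of
    "standardized residuals" in regression software. ``kind="plain"`` returns
    r_i / sd(r) for sensitivity analysis. Neither forces mean 0 / scale 1.
    """
    if fit.df_resid < 1 or not fit.sigma > 0:
        raise DegenerateResidualsError(
            "residual scale is zero (perfect fit); standardized residuals undefined"
        )
    if kind == "studentized":
        return fit.studentized_residuals.copy()
    if kind == "plain":
        sd = float(np.std(fit.residuals, ddof=1))
        if sd == 0:
            raise DegenerateResidualsError("residuals have zero spread")
        return fit.residuals / sd
    raise DomainError(f"unknown residual kind {kind!r} (expected 'studentized' or 'plain')")
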