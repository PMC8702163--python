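"""Regressions of standardized residuals on study- and species-level drivers.

After the through-origin comparison of two counting methods, the standardized
residuals measure how much each population deviates from the common trend.
This module regresses those residuals on candidate explanations: how camera
data were analyzed (spatial vs random movement), the genetic tissue source
(hair vs scat), log study-site area, log body mass, and biogeographic realm.

Continuous and binary drivers use ordinary least squares with an intercept
(binary drivers coded 0/1: random = 0, spatial = 1; hair = 0, scat = 1) and an
F(1, n - 2) slope test. Multi-level categorical drivers (realm) use a
cell-means model: one mean per category, with the overall F comparing the
category model to the grand mean on (k - 1, n - k) degrees of freedom.

Two R^2 flavours are kept: the raw coefficient of determination and the
adjusted version truncated at zero, which is what the summary report prints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateDesignError, DomainError, InsufficientDataError
from .mean_difference import BootstrapCI, bootstrap_ci, paired_differences
from .study_table import ComparisonTable

#: 0/1 codings for the two binary study covariates.
BINARY_CODINGS = {
    "camera_analysis": {"random": 0.0, "spatial": 1.0},
    "tissue": {"hair": 0.0, "scat": 1.0},
}


@dataclass(frozen=True)
class DriverFit:
    """One row of the residual-driver table."""

    predictor_name: str
    coding: str                      # "continuous" | "binary" | "cell_means"
    n_used: int
    df: int                          # residual degrees of freedom
    r2_raw: float
    r2_adjusted: float               # adjusted R^2 truncated at 0
    f_stat: float
    p_value: float
    slope: float | None = None
    slope_se: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    group_means: dict = field(default_factory=dict)
    group_ses: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor_name,
            "coding": self.coding,
            "n_used": self.n_used,
            "df": self.df,
            "r2_raw": self.r2_raw,
            "r2_adjusted": self.r2_adjusted,
            "f_stat": self.f_stat,
            "p_value": self.p_value,
            "slope": self.slope,
            "slope_se": self.slope_se,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "group_means": dict(self.group_means),
            "group_ses": dict(self.group_ses),
        }


def _adjusted_r2(r2: float, n: int, n_params: int) -> float:
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_params)
    return max(adj, 0.0)


def fit_driver(residuals, covariate, coding: str, predictor_name: str = "covariate") -> DriverFit:
    """Regress standardized residuals on one study covariate.

    Parameters
    ----------
    residuals
        Standardized residuals, already restricted to populations with a
        non-missing covariate (listwise deletion happens upstream).
    covariate
        Numeric values for ``coding`` "continuous"/"binary" (binary must be
        0/1 with both levels present); category labels for "cell_means".
    """
    r = np.asarray(residuals, dtype=float)
    n = r.size
    if coding in ("continuous", "binary"):
        x = np.asarray(covariate, dtype=float)
        if x.size != n:
            raise DomainError("residuals and covariate lengths differ")
        if n < 3:
            raise InsufficientDataError(
                f"driver regression needs n >= 3, got n = {n} for {predictor_name!r}"
            )
        if coding == "binary":
            levels = np.unique(x)
            if levels.size < 2:
                raise DegenerateDesignError(
                    f"binary covariate {predictor_name!r} has a single level ({levels.tolist()})"
                )
        if np.ptp(x) == 0:
            raise DegenerateDesignError(f"covariate {predictor_name!r} is constant")
        return _ols_line(r, x, coding, predictor_name)
    if coding == "cell_means":
        labels = [str(v) for v in covariate]
        if len(labels) != n:
            raise DomainError("residuals and covariate lengths differ")
        return _cell_means(r, labels, predictor_name)
    raise DomainError(f"unknown coding {coding!r}")


def _ols_line(r: np.ndarray, x: np.ndarray, coding: str, name: str) -> DriverFit:
    n = r.size
    X = np.column_stack([np.ones(n), x])
    beta, _, _, _ = np.linalg.lstsq(X, r, rcond=None)
    fitted = X @ beta
    resid = r - fitted
    rss = float(resid @ resid)
    tss = float(((r - r.mean()) ** 2).sum())
    df = n - 2
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    f = ((tss - rss) / 1.0) / sigma2 if sigma2 > 0 else math.inf
    p = float(stats.f.sf(f, 1, df)) if math.isfinite(f) else 0.0
    return DriverFit(
        predictor_name=name,
        coding=coding,
        n_used=n,
        df=df,
        r2_raw=r2,
        r2_adjusted=_adjusted_r2(r2, n, 2),
        f_stat=f,
        p_value=p,
        slope=float(beta[1]),
        slope_se=float(se[1]),
        intercept=float(beta[0]),
        intercept_se=float(se[0]),
    )


def _cell_means(r: np.ndarray, labels: list[str], name: str) -> DriverFit:
    n = r.size
    cats = sorted(set(labels))
    k = len(cats)
    if k < 2:
        raise DegenerateDesignError(f"cell-means covariate {name!r} has a single category")
    if n - k < 1:
        raise InsufficientDataError(
            f"cell-means model for {name!r} leaves no residual degrees of freedom"
        )
    lab = np.asarray(labels)
    means = {c: float(r[lab == c].mean()) for c in cats}
    counts = {c: int((lab == c).sum()) for c in cats}
    ssw = float(sum(((r[lab == c] - means[c]) ** 2).sum() for c in cats))
    tss = float(((r - r.mean()) ** 2).sum())
    df = n - k
    sigma2 = ssw / df
    ses = {c: math.sqrt(sigma2 / counts[c]) for c in cats}
    r2 = 1.0 - ssw / tss if tss > 0 else 0.0
    f = ((tss - ssw) / (k - 1)) / sigma2 if sigma2 > 0 else math.inf
    p = float(stats.f.sf(f, k - 1, df)) if math.isfinite(f) else 0.0
    return DriverFit(
        predictor_name=name,
        coding="cell_means",
        n_used=n,
        df=df,
        r2_raw=r2,
        r2_adjusted=_adjusted_r2(r2, n, k),
        f_stat=f,
        p_value=p,
        group_means=means,
        group_ses=ses,
    )


def subgroup_mean_difference(
    table: ComparisonTable,
    group: str,
    n_boot: int = 1000,
    fraction: float = 0.8,
    seed: int = 0,
) -> BootstrapCI:
    """Camera-minus-trapping mean difference within one camera-analysis group.

    Restricts the camera vs live-trap pairs to populations whose camera
    record used the given analysis (``"spatial"`` or ``"random"``), then
    bootstraps the mean difference exactly as for the full comparisons.
    """
    if group not in ("spatial", "random"):
        raise DomainError(f"camera-analysis group must be 'spatial' or 'random', got {group!r}")
    ids, diffs = paired_differences(table, "camera", "live_trap")
    keep = [
        i for i, pid in enumerate(ids)
        if table.record(pid, "camera").camera_analysis == group
    ]
    if len(keep) < 2:
        raise InsufficientDataError(
            f"camera-analysis subgroup {group!r} has only {len(keep)} paired population(s);"
            " need at least 2"
        )
    return bootstrap_ci(
        diffs[keep],
        n_boot=n_boot,
        fraction=fraction,
        seed=seed,
        label=f"camera({group}) - live_trap",
    )
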