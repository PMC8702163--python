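"""Paired mean differences between methods, with m-out-of-n bootstrap CIs.

The headline effect size is the mean, over paired populations, of
(count by method A) - (count by method B), in individuals. Its uncertainty
is assessed by resampling 80% of the paired differences with replacement
1000 times, recording the mean of each resample, and taking the 2.5th and
97.5th percentiles of the replicate means. The reported point estimate is
always the full-data mean, not the mean of bootstrap means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InsufficientDataError
from .study_table import ComparisonTable, less_invasive_counts


@dataclass(frozen=True)
class BootstrapCI:
    """Mean difference with a percentile bootstrap confidence interval.

    Positive values mean the first-named method detected more individuals;
    ``label`` records the convention explicitly (e.g. "camera - live_trap").
    """

    mean_diff: float
    ci_low: float
    ci_high: float
    n_pairs: int
    n_boot: int
    resample_fraction: float
    seed: int
    label: str = ""

    @property
    def excludes_zero(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "mean_diff": self.mean_diff,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_pairs": self.n_pairs,
            "n_boot": self.n_boot,
            "resample_fraction": self.resample_fraction,
            "seed": self.seed,
            "excludes_zero": self.excludes_zero,
        }


def paired_differences(
    table: ComparisonTable,
    method_a: str,
    method_b: str,
    precedence: str = "genetic",
) -> tuple[list[str], np.ndarray]:
    """Per-population count difference ``method_a - method_b``.

    Either method may be the pseudo-method ``"less_invasive"``, which
    resolves, per population, to the camera or genetic count -- whichever that
    study used (``precedence`` breaks ties when a population has all three
    methods).

    Returns the paired population ids and the vector of differences.
    """
    counts: dict[str, dict[str, float]] = {}

    def _method_counts(method: str) -> dict[str, float]:
        if method == "less_invasive":
            ids, vals, _ = less_invasive_counts(table, precedence=precedence)
            return dict(zip(ids, vals))
        return {
            r.population_id: r.n_individuals
            for r in table.records
            if r.method == method
        }

    a = _method_counts(method_a)
    b = _method_counts(method_b)
    ids = [pid for pid in table.population_ids if pid in a and pid in b]
    if not ids:
        raise InsufficientDataError(
            f"no population has both {method_a!r} and {method_b!r} records"
        )
    diffs = np.array([a[pid] - b[pid] for pid in ids], dtype=float)
    return ids, diffs


def bootstrap_ci(
    diffs,
    n_boot: int = 1000,
    fraction: float = 0.8,
    seed: int = 0,
    label: str = "",
) -> BootstrapCI:
    """Percentile CI for a mean from an m-out-of-n bootstrap.

    Each replicate draws ``m = round(fraction * n)`` values (minimum 2) with
    replacement and records their mean; the CI is the [2.5, 97.5] percentile
    band of the replicate means, with linear interpolation between order
    statistics. Deterministic given ``seed``.
    """
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.size
    if n < 2:
        raise InsufficientDataError(f"bootstrap needs at least 2 differences, got {n}")
    if not (0 < fraction <= 1):
        raise DomainError(f"resample fraction must be in (0, 1], got {fraction!r}")
    if n_boot < 1:
        raise DomainError(f"n_boot must be positive, got {n_boot!r}")
    m = max(2, round(fraction * n))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, m))
    replicate_means = diffs[idx].mean(axis=1)
    lo, hi = np.percentile(replicate_means, [2.5, 97.5])
    return BootstrapCI(
        mean_diff=float(diffs.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_pairs=n,
        n_boot=n_boot,
        resample_fraction=fraction,
        seed=seed,
        label=label,
    )
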