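"""Full analysis: both method comparisons, bootstraps, drivers, and PGLS.

``run_analysis`` reproduces the whole meta-analysis on one study table:

1. through-origin regression of log live-trap counts on log less-invasive
   counts (and of log genetic on log camera counts);
2. standardized residuals from each fit;
3. bootstrap confidence intervals for the paired mean differences
   (less-invasive - trapping; genetic - camera) and for the spatial and
   random camera-analysis subgroups (camera - trapping);
4. regressions of each residual set on camera-analysis method, tissue
   source, log site area, log body mass, and biogeographic realm;
5. an intercept-only phylogenetic least squares fit of each residual set
   under the Brownian covariance of the taxonomy tree.

All randomness (the bootstraps) derives from a single seed, split into
independent per-stage streams, so adding a stage never perturbs another
stage's draws. The JSON report is byte-identical for identical inputs.
"""

from __future__ import annotations

import json
import logging
import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .errors import DetectCompError, InsufficientDataError
from .mean_difference import bootstrap_ci, paired_differences
from .origin_regression import fit_through_origin, log_counts, standardize_residuals
from .residual_drivers import BINARY_CODINGS, fit_driver, subgroup_mean_difference
from .study_table import ComparisonTable, less_invasive_counts
from .taxonomy_pgls import brownian_vcv, build_taxonomy_tree, pgls_intercept

logger = logging.getLogger("detectcomp")


@dataclass(frozen=True)
class AnalysisOptions:
    swap_axes: bool = False
    log_base: float = math.e
    resid_kind: str = "studentized"       # "studentized" | "plain"
    n_boot: int = 1000
    resample_fraction: float = 0.8
    trap_precedence: str = "genetic"      # less-invasive method used when all three exist
    species_epsilon: float = 1e-6         # within-species VCV jitter


def stage_seed(seed: int, stage: str) -> int:
    """Independent, stable sub-seed for one named pipeline stage."""
    return int(
        np.random.SeedSequence([seed, zlib.crc32(stage.encode())]).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class AnalysisReport:
    comparisons: dict = field(default_factory=dict)
    mean_differences: dict = field(default_factory=dict)
    drivers: list = field(default_factory=list)
    pgls: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "comparisons": self.comparisons,
            "mean_differences": self.mean_differences,
            "drivers": self.drivers,
            "pgls": self.pgls,
            "provenance": self.provenance,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def _comparison_inputs(table: ComparisonTable, options: AnalysisOptions):
    """(name, ids, x_counts, y_counts, extra) for each feasible comparison."""
    out = []
    try:
        ids, less, used = less_invasive_counts(table, precedence=options.trap_precedence)
        trap = [table.record(pid, "live_trap").n_individuals for pid in ids]
        out.append(
            (
                "trap_vs_lessinvasive",
                ids,
                less,          # predictor: less-invasive count
                trap,          # response: live-trap count
                {"lessinvasive_method": dict(zip(ids, used))},
            )
        )
    except InsufficientDataError:
        pass
    cg_ids = table.pairs("camera", "genetic")
    if cg_ids:
        cam = [table.record(pid, "camera").n_individuals for pid in cg_ids]
        gen = [table.record(pid, "genetic").n_individuals for pid in cg_ids]
        out.append(("genetic_vs_camera", cg_ids, cam, gen, {}))
    return out


def _driver_covariates(table, comp_name, ids, extra):
    """Per-driver (covariate values, coding, kept indices) for one residual set.

    Populations with a missing covariate are dropped listwise per driver.
    """
    def camera_analysis_of(pid):
        rec = table.record(pid, "camera")
        if comp_name == "trap_vs_lessinvasive":
            if extra["lessinvasive_method"].get(pid) != "camera":
                return None
        return rec.camera_analysis if rec is not None else None

    def tissue_of(pid):
        rec = table.record(pid, "genetic")
        if comp_name == "trap_vs_lessinvasive":
            if extra["lessinvasive_method"].get(pid) != "genetic":
                return None
        return rec.tissue if rec is not None else None

    def any_record(pid):
        for m in ("live_trap", "camera", "genetic"):
            rec = table.record(pid, m)
            if rec is not None:
                return rec
        return None

    drivers = {}
    cam = [camera_analysis_of(pid) for pid in ids]
    drivers["camera_analysis"] = (
        [None if v is None else BINARY_CODINGS["camera_analysis"].get(v) for v in cam],
        "binary",
    )
    tis = [tissue_of(pid) for pid in ids]
    drivers["tissue"] = (
        [None if v is None else BINARY_CODINGS["tissue"].get(v) for v in tis],
        "binary",
    )
    area = [any_record(pid).site_area_km2 for pid in ids]
    drivers["log_site_area_km2"] = (
        [None if v is None else math.log(v) for v in area],
        "continuous",
    )
    mass = [any_record(pid).body_mass_kg for pid in ids]
    drivers["log_body_mass_kg"] = (
        [None if v is None else math.log(v) for v in mass],
        "continuous",
    )
    drivers["realm"] = ([any_record(pid).realm for pid in ids], "cell_means")
    return drivers


def run_analysis(
    table: ComparisonTable,
    seed: int,
    options: AnalysisOptions | None = None,
) -> AnalysisReport:
    """Run the complete comparison analysis on a validated study table."""
    options = options or AnalysisOptions()
    report = AnalysisReport()
    report.provenance = {
        "version": __version__,
        "seed": seed,
        "log_base": "e" if options.log_base == math.e else str(options.log_base),
        "axis_convention": (
            "response = log less-invasive, predictor = log live-trap"
            if options.swap_axes
            else "response = log live-trap (or genetic), predictor = log"
            " less-invasive (or camera)"
        ),
        "residual_kind": options.resid_kind,
        "trap_precedence": options.trap_precedence,
        "n_boot": options.n_boot,
        "resample_fraction": options.resample_fraction,
        "n_records": len(table),
    }

    comparisons = _comparison_inputs(table, options)
    if not comparisons:
        raise InsufficientDataError(
            "table contains no comparable method pair: need live_trap plus a"
            " less-invasive method, or camera plus genetic"
        )

    residual_sets = {}
    for name, ids, x_counts, y_counts, extra in comparisons:
        lx = log_counts(x_counts, ids, base=options.log_base)
        ly = log_counts(y_counts, ids, base=options.log_base)
        if options.swap_axes:
            lx, ly = ly, lx
        if len(ids) < 3:
            logger.warning("skipping comparison %s: only %d pairs", name, len(ids))
            continue
        fit = fit_through_origin(lx, ly, population_ids=ids)
        resid = standardize_residuals(fit, kind=options.resid_kind)
        residual_sets[name] = (ids, resid, extra)
        report.comparisons[name] = fit.to_dict()

    # -- paired mean differences ------------------------------------------
    def _bootstrap(key, a, b, label):
        try:
            _, diffs = paired_differences(table, a, b, precedence=options.trap_precedence)
        except InsufficientDataError as exc:
            logger.warning("skipping mean difference %s: %s", key, exc)
            return
        if diffs.size < 2:
            logger.warning("skipping mean difference %s: fewer than 2 pairs", key)
            return
        ci = bootstrap_ci(
            diffs,
            n_boot=options.n_boot,
            fraction=options.resample_fraction,
            seed=stage_seed(seed, f"mean_diff:{key}"),
            label=label,
        )
        report.mean_differences[key] = ci.to_dict()

    _bootstrap("lessinvasive_minus_trap", "less_invasive", "live_trap",
               "less_invasive - live_trap")
    _bootstrap("genetic_minus_camera", "genetic", "camera", "genetic - camera")

    for group in ("spatial", "random"):
        try:
            ci = subgroup_mean_difference(
                table,
                group,
                n_boot=options.n_boot,
                fraction=options.resample_fraction,
                seed=stage_seed(seed, f"subgroup:{group}"),
            )
        except (InsufficientDataError, DetectCompError) as exc:
            logger.warning("skipping %s camera subgroup: %s", group, exc)
            continue
        report.mean_differences[f"camera_{group}_minus_trap"] = ci.to_dict()

    # -- residual-driver regressions --------------------------------------
    for comp_name, (ids, resid, extra) in residual_sets.items():
        for drv_name, (values, coding) in _driver_covariates(
            table, comp_name, ids, extra
        ).items():
            keep = [i for i, v in enumerate(values) if v is not None]
            if not keep:
                logger.warning(
                    "skipping driver %s for %s: covariate entirely missing",
                    drv_name, comp_name,
                )
                continue
            r = resid[keep]
            vals = [values[i] for i in keep]
            try:
                dfit = fit_driver(r, vals, coding, predictor_name=drv_name)
            except DetectCompError as exc:
                logger.warning("skipping driver %s for %s: %s", drv_name, comp_name, exc)
                continue
            row = dfit.to_dict()
            row["response"] = f"{comp_name} residuals"
            report.drivers.append(row)

        # -- PGLS on the same residual set --------------------------------
        recs = [next(r for r in table.records if r.population_id == pid) for pid in ids]
        tree = build_taxonomy_tree(recs)
        V = brownian_vcv(
            tree, [rec.species for rec in recs], epsilon=options.species_epsilon
        )
        pg = pgls_intercept(resid, V)
        row = pg.to_dict()
        row["response"] = f"{comp_name} residuals"
        row["newick"] = tree.newick()
        report.pgls[comp_name] = row

    return report


def report_table(report: AnalysisReport):
    """Flatten a report into the familiar summary-table layout.

    One row per fitted model: response, predictor, slope (SE), intercept or
    group means (SE), adjusted R^2 (truncated at 0), F, residual DF, p.
    Returns a pandas DataFrame.
    """
    import pandas as pd

    rows = []
    for name, fit in report.comparisons.items():
        resp, pred = {
            "trap_vs_lessinvasive": ("live trapping estimates",
                                     "camera and genetic data estimates"),
            "genetic_vs_camera": ("genetic data estimate",
                                  "camera trapping data estimate"),
        }.get(name, (name, "log counts"))
        rows.append({
            "response": resp,
            "predictor": pred,
            "slope": fit["slope"],
            "slope_se": fit["slope_se"],
            "intercept": None,
            "intercept_se": None,
            "r2": fit["r2_uncentered"],
            "f_stat": fit["f_stat"],
            "df": fit["df_resid"],
            "p_value": fit["p_value"],
        })
    for name, pg in report.pgls.items():
        rows.append({
            "response": f"{name} residuals",
            "predictor": "phylogenetic tree",
            "slope": None,
            "slope_se": None,
            "intercept": pg["intercept"],
            "intercept_se": pg["se"],
            "r2": None,
            "f_stat": None,
            "df": pg["df"],
            "p_value": pg["p_value"],
        })
    for drv in report.drivers:
        if drv["coding"] == "cell_means":
            means = "; ".join(
                f"{k}: {v:.3f} ({drv['group_ses'][k]:.3f})"
                for k, v in sorted(drv["group_means"].items())
            )
            rows.append({
                "response": drv["response"],
                "predictor": drv["predictor"],
                "slope": None,
                "slope_se": None,
                "intercept": means,
                "intercept_se": None,
                "r2": drv["r2_adjusted"],
                "f_stat": drv["f_stat"],
                "df": drv["df"],
                "p_value": drv["p_value"],
            })
        else:
            rows.append({
                "response": drv["response"],
                "predictor": drv["predictor"],
                "slope": drv["slope"],
                "slope_se": drv["slope_se"],
                "intercept": drv["intercept"],
                "intercept_se": drv["intercept_se"],
                "r2": drv["r2_adjusted"],
                "f_stat": drv["f_stat"],
                "df": drv["df"],
                "p_value": drv["p_value"],
            })
    return pd.DataFrame(rows)
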