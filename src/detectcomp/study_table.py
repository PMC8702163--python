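"""Study-comparison table: data model, CSV I/O, and count derivation.

The table is the sole input of the analysis pipeline. Each row records how
many distinct individuals one monitoring method detected in one population:
live trapping (physical capture-mark-release), camera trapping, or genetic
identification of individuals from noninvasively collected tissue. Rows also
carry the study covariates later used to explain residual disagreement
between methods: species taxonomy (order/family/genus/species), biogeographic
realm, study-site area, and species body mass.

Counts are stored as positive reals rather than integers because some source
studies report a density estimate instead of a raw count; the count is then
derived as density x area (:func:`count_from_density`) and is not rounded --
all downstream regressions operate on logs, where rounding is immaterial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import DomainError, InsufficientDataError, SchemaError, ValidationError

METHODS = ("live_trap", "camera", "genetic")
REALMS = ("australian", "nearctic", "neotropical", "palearctic")
CAMERA_ANALYSES = ("spatial", "random", "none")
TISSUES = ("hair", "scat", "none")

#: Column order of the CSV schema; a documented template ships in examples/.
CSV_COLUMNS = (
    "population_id",
    "order",
    "family",
    "genus",
    "species",
    "realm",
    "site_area_km2",
    "body_mass_kg",
    "method",
    "camera_analysis",
    "tissue",
    "n_individuals",
)

_MANDATORY_STRING_FIELDS = ("population_id", "order", "family", "genus", "species")


def count_from_density(density: float, area: float) -> float:
    """Number of individuals implied by a density estimate over a study site.

    Parameters
    ----------
    density
        Individuals per km^2; must be positive.
    area
        Study-site area in km^2; must be positive.

    Returns
    -------
    float
        ``density * area``, not rounded.
    """
    if not (density > 0):
        raise DomainError(f"density must be positive, got {density!r}")
    if not (area > 0):
        raise DomainError(f"area must be positive, got {area!r}")
    return density * area


@dataclass(frozen=True)
class MethodCount:
    """One population observed by one monitoring method.

    ``camera_analysis`` is meaningful only for camera records (whether the
    abundance estimate used camera locations -- ``spatial`` -- or assumed
    random movement -- ``random``); ``tissue`` only for genetic records
    (``hair`` or ``scat``). Both must be ``"none"`` otherwise.
    """

    population_id: str
    order: str
    family: str
    genus: str
    species: str
    realm: str
    method: str
    n_individuals: float
    site_area_km2: float | None = None
    body_mass_kg: float | None = None
    camera_analysis: str = "none"
    tissue: str = "none"

    def problems(self) -> list[str]:
        """All invariant violations of this record (empty list if valid)."""
        msgs: list[str] = []
        for name in _MANDATORY_STRING_FIELDS:
            if not str(getattr(self, name)).strip():
                msgs.append(f"empty {name}")
        if self.realm not in REALMS:
            msgs.append(f"unknown realm {self.realm!r} (expected one of {REALMS})")
        if self.method not in METHODS:
            msgs.append(f"unknown method {self.method!r} (expected one of {METHODS})")
        if not (isinstance(self.n_individuals, (int, float))
                and math.isfinite(self.n_individuals) and self.n_individuals > 0):
            msgs.append(f"n_individuals must be a positive real, got {self.n_individuals!r}")
        if self.camera_analysis not in CAMERA_ANALYSES:
            msgs.append(f"unknown camera_analysis {self.camera_analysis!r}")
        if self.tissue not in TISSUES:
            msgs.append(f"unknown tissue {self.tissue!r}")
        if self.method == "camera" and self.camera_analysis == "none":
            msgs.append("camera record must state camera_analysis (spatial|random)")
        if self.method != "camera" and self.camera_analysis != "none":
            msgs.append("camera_analysis only applies to camera records")
        if self.method == "genetic" and self.tissue == "none":
            msgs.append("genetic record must state tissue (hair|scat)")
        if self.method != "genetic" and self.tissue != "none":
            msgs.append("tissue only applies to genetic records")
        if self.site_area_km2 is not None and not self.site_area_km2 > 0:
            msgs.append(f"site_area_km2 must be positive when present, got {self.site_area_km2!r}")
        if self.body_mass_kg is not None and not self.body_mass_kg > 0:
            msgs.append(f"body_mass_kg must be positive when present, got {self.body_mass_kg!r}")
        return msgs


@dataclass(frozen=True)
class ComparisonTable:
    """Validated collection of :class:`MethodCount` records.

    At most one record exists per (population, method); populations holding
    records for two methods form the "pairs" the analysis compares.
    """

    records: tuple[MethodCount, ...] = field(default_factory=tuple)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[MethodCount]) -> "ComparisonTable":
        recs = tuple(records)
        problems: list[str] = []
        seen: set[tuple[str, str]] = set()
        for i, rec in enumerate(recs):
            for msg in rec.problems():
                problems.append(f"row {i} (population {rec.population_id!r}): {msg}")
            key = (rec.population_id, rec.method)
            if key in seen:
                problems.append(
                    f"row {i}: duplicate record for population {rec.population_id!r},"
                    f" method {rec.method!r}"
                )
            seen.add(key)
        if problems:
            raise ValidationError("invalid study table:\n  " + "\n  ".join(problems))
        return cls(records=recs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ComparisonTable":
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        records = []
        for _, row in df.iterrows():
            records.append(
                MethodCount(
                    population_id=str(row["population_id"]),
                    order=str(row["order"]),
                    family=str(row["family"]),
                    genus=str(row["genus"]),
                    species=str(row["species"]),
                    realm=str(row["realm"]),
                    method=str(row["method"]),
                    n_individuals=float(row["n_individuals"]),
                    site_area_km2=_opt_float(row["site_area_km2"]),
                    body_mass_kg=_opt_float(row["body_mass_kg"]),
                    camera_analysis=_opt_label(row["camera_analysis"]),
                    tissue=_opt_label(row["tissue"]),
                )
            )
        return cls.from_records(records)

    # -- queries ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    @property
    def population_ids(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.population_id not in out:
                out.append(rec.population_id)
        return out

    def record(self, population_id: str, method: str) -> MethodCount | None:
        for rec in self.records:
            if rec.population_id == population_id and rec.method == method:
                return rec
        return None

    def methods_of(self, population_id: str) -> set[str]:
        return {r.method for r in self.records if r.population_id == population_id}

    def pairs(self, method_a: str, method_b: str) -> list[str]:
        """Populations observed by both methods, in first-appearance order.

        Membership is symmetric: ``pairs(a, b)`` and ``pairs(b, a)`` list the
        same populations.
        """
        return [
            pid for pid in self.population_ids
            if {method_a, method_b} <= self.methods_of(pid)
        ]

    def subset(self, population_ids: Sequence[str]) -> "ComparisonTable":
        keep = set(population_ids)
        return ComparisonTable(
            records=tuple(r for r in self.records if r.population_id in keep)
        )

    # -- I/O ---------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "population_id": r.population_id,
                "order": r.order,
                "family": r.family,
                "genus": r.genus,
                "species": r.species,
                "realm": r.realm,
                "site_area_km2": r.site_area_km2,
                "body_mass_kg": r.body_mass_kg,
                "method": r.method,
                "camera_analysis": r.camera_analysis,
                "tissue": r.tissue,
                "n_individuals": r.n_individuals,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        # repr-exact floats so that write -> read round-trips bit-identically
        def _fmt(v):
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return ""
            return repr(float(v))

        for col in ("site_area_km2", "body_mass_kg", "n_individuals"):
            df[col] = df[col].map(_fmt)
        df.to_csv(path, index=False)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _opt_label(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)) or str(value).strip() == "":
        return "none"
    return str(value).strip()


def read_comparisons(path) -> ComparisonTable:
    """Read and validate a study-comparison table from CSV.

    Raises
    ------
    SchemaError
        If a mandatory column is absent.
    ValidationError
        If any row violates the record invariants (nonpositive count, missing
        method metadata, duplicate population/method, unknown realm, ...);
        the message indexes every offending row.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"could not parse {path}: {exc}") from exc
    return ComparisonTable.from_dataframe(df)


def less_invasive_counts(
    table: ComparisonTable, precedence: str = "genetic"
) -> tuple[list[str], list[float], list[str]]:
    """Per-population less-invasive count for the trapping comparison.

    For each population holding a live-trap record and at least one
    less-invasive record, returns the camera or genetic count -- whichever the
    study used. Populations monitored by all three methods contribute the
    method named by ``precedence`` ("genetic" by default).

    Returns
    -------
    (population_ids, counts, methods_used)
    """
    if precedence not in ("genetic", "camera"):
        raise DomainError(f"precedence must be 'genetic' or 'camera', got {precedence!r}")
    other = "camera" if precedence == "genetic" else "genetic"
    ids: list[str] = []
    counts: list[float] = []
    used: list[str] = []
    for pid in table.population_ids:
        methods = table.methods_of(pid)
        if "live_trap" not in methods:
            continue
        if precedence in methods:
            chosen = precedence
        elif other in methods:
            chosen = other
        else:
            continue
        rec = table.record(pid, chosen)
        assert rec is not None
        ids.append(pid)
        counts.append(rec.n_individuals)
        used.append(chosen)
    if not ids:
        raise InsufficientDataError(
            "no population has both a live_trap record and a less-invasive record"
        )
    return ids, counts, used
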