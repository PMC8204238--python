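"""Assembly of analysis datasets from CDM tables.

Two families of flat datasets feed the risk metrics:

* **per-PHI limited data sets** — one per PHI, each holding the PHI column
  plus the five common demographic attributes (Year_of_birth,
  Gender_concept_id, Race_concept_id, Ethnicity_concept_id, State), i.e.
  six columns;
* **scenario data sets** — seven multi-variable datasets modelling common
  clinical study extracts (diagnosis, procedure, drug treatment, lab
  test, device treatment, death, medical history), each combining eleven
  common variables (the five demographics plus six common PHIs) with the
  scenario's own date PHIs and order-code QI.

Surrogate keys (person_id, visit_occurrence_id, ...) are used only as
join keys and never appear among analysis columns — with them every
record would be trivially unique and the equivalence-class structure
meaningless. Rows carrying a null in any selected column are dropped and
counted, matching an analysis restricted to complete-case tables; tables
declared ``outer`` in a scenario (the death table in the death scenario)
instead keep their missing values as an explicit "(none)" token, since an
absent death is information shared by every living person rather than a
data defect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError
from .schema import MaskRule, Role, SchemaRegistry, ValueKind, VariableSpec, load_registry

__all__ = [
    "MISSING_TOKEN",
    "AnalysisDataset",
    "ScenarioSpec",
    "build_phi_dataset",
    "build_scenario_dataset",
    "default_scenarios",
    "SCENARIO_NAMES",
]

#: token standing for a retained missing value in an outer-joined column
MISSING_TOKEN = "(none)"

_SURROGATE_SUFFIXES = ("_id",)
_SURROGATE_ALLOWED = {
    "gender_concept_id",
    "race_concept_id",
    "ethnicity_concept_id",
    "condition_concept_id",
    "procedure_concept_id",
    "drug_concept_id",
    "device_concept_id",
    "measurement_concept_id",
    "observation_concept_id",
    "place_of_service_concept_id",
    "visit_concept_id",
}

_DEMOGRAPHIC_ORDER = (
    ("person", "year_of_birth"),
    ("person", "gender_concept_id"),
    ("person", "race_concept_id"),
    ("person", "ethnicity_concept_id"),
    ("location", "state"),
)

_COMMON_PHI_ORDER = (
    ("person", "month_of_birth"),
    ("person", "day_of_birth"),
    ("location", "county"),
    ("provider", "npi"),
    ("visit_occurrence", "visit_start_date"),
    ("visit_occurrence", "visit_end_date"),
)

SCENARIO_NAMES = (
    "diagnosis",
    "procedure",
    "drug_treatment",
    "lab_test",
    "device_treatment",
    "death",
    "medical_history",
)


def _is_surrogate(column: str) -> bool:
    return column.endswith(_SURROGATE_SUFFIXES) and column not in _SURROGATE_ALLOWED


@dataclass
class AnalysisDataset:
    """A named flat table of analysis values with per-column privacy roles."""

    name: str
    columns: tuple[VariableSpec, ...]
    frame: pd.DataFrame
    dropped_nulls: int = 0

    def __post_init__(self) -> None:
        self.columns = tuple(self.columns)
        names = [c.column_name for c in self.columns]
        if len(set(names)) != len(names):
            raise ValidationError(f"dataset {self.name!r}: duplicate column names")
        for c in self.columns:
            if _is_surrogate(c.column_name) or c.role is Role.OTHER:
                raise ValidationError(
                    f"dataset {self.name!r}: {c.column_name!r} is not an "
                    f"analysis variable (surrogate key or unclassified)"
                )
        if list(self.frame.columns) != names:
            raise ValidationError(
                f"dataset {self.name!r}: frame columns {list(self.frame.columns)} "
                f"do not match declared columns {names}"
            )

    @property
    def n_records(self) -> int:
        return len(self.frame)

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(c.column_name for c in self.columns)

    def manifest(self) -> dict:
        return {
            "name": self.name,
            "n_records": int(self.n_records),
            "dropped_nulls": int(self.dropped_nulls),
            "columns": [
                {"table": c.table_name, "column": c.column_name, "role": c.role.value}
                for c in self.columns
            ],
        }


@dataclass(frozen=True)
class ScenarioSpec:
    """Composition of one scenario data set."""

    name: str
    driving_table: str
    scenario_phis: tuple[VariableSpec, ...]
    scenario_qis: tuple[VariableSpec, ...]
    common_phis: tuple[VariableSpec, ...]
    common_demographics: tuple[VariableSpec, ...]
    outer_tables: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        demo_keys = tuple(v.key for v in self.common_demographics)
        if demo_keys != _DEMOGRAPHIC_ORDER:
            raise ValidationError(
                f"scenario {self.name!r}: common demographics must be the five "
                f"standard attributes {_DEMOGRAPHIC_ORDER}"
            )
        if len(self.common_phis) != 6:
            raise ValidationError(
                f"scenario {self.name!r}: exactly 6 common PHIs required, "
                f"got {len(self.common_phis)}"
            )

    @property
    def all_columns(self) -> tuple[VariableSpec, ...]:
        return (
            self.common_demographics
            + self.common_phis
            + self.scenario_phis
            + self.scenario_qis
        )


# ---------------------------------------------------------------------------
# join machinery
# ---------------------------------------------------------------------------

def _require_table(cdm, table: str) -> pd.DataFrame:
    if table not in cdm:
        raise InputError(f"required CDM table {table!r} is missing from the input")
    return cdm[table]


def _require_column(df: pd.DataFrame, table: str, column: str) -> None:
    if column not in df.columns:
        raise InputError(f"join key or column {table}.{column} absent from input CDM")


def _driving_table_for(phi: VariableSpec) -> str:
    """Tables without a person reference are reached through their natural
    event table: person-level attributes (location) through person, and
    provider attributes through the visit table that records the provider."""
    if phi.table_name == "location":
        return "person"
    if phi.table_name in ("provider", "care_site"):
        return "visit_occurrence"
    return phi.table_name


def _assemble(
    cdm,
    name: str,
    driving_table: str,
    specs: Sequence[VariableSpec],
    outer_tables: frozenset[str] = frozenset(),
) -> AnalysisDataset:
    """Left-join the columns in ``specs`` onto the driving table's rows."""
    driving = _require_table(cdm, driving_table)
    work = driving.copy()

    needed_tables = {s.table_name for s in specs}

    def join(right_table: str, left_key: str, right_key: str) -> None:
        nonlocal work
        right = _require_table(cdm, right_table)
        _require_column(work, driving_table, left_key)
        _require_column(right, right_table, right_key)
        if right[right_key].duplicated().any():
            raise ValidationError(
                f"join key {right_table}.{right_key} is not unique; a join "
                f"would duplicate rows"
            )
        renamed = right.rename(columns={right_key: left_key}) if right_key != left_key else right
        work = work.merge(renamed, on=left_key, how="left", suffixes=("", f"__{right_table}"))

    # person-level attributes
    if needed_tables & {"person", "location", "death"} and driving_table != "person":
        join("person", "person_id", "person_id")
    if "location" in needed_tables:
        join("location", "location_id", "location_id")
    if "death" in needed_tables and driving_table != "death":
        join("death", "person_id", "person_id")
    # visit-level attributes
    visit_needed = "visit_occurrence" in needed_tables or needed_tables & {
        "provider",
        "care_site",
    }
    if visit_needed and driving_table != "visit_occurrence":
        join("visit_occurrence", "visit_occurrence_id", "visit_occurrence_id")
    if "provider" in needed_tables:
        join("provider", "provider_id", "provider_id")
    if "care_site" in needed_tables:
        join("care_site", "care_site_id", "care_site_id")

    missing = [s for s in specs if s.column_name not in work.columns]
    if missing:
        raise InputError(
            f"dataset {name!r}: columns not reachable from {driving_table!r}: "
            + ", ".join(f"{s.table_name}.{s.column_name}" for s in missing)
        )

    out = work[[s.column_name for s in specs]].copy()

    # null handling: outer-table columns keep a shared missing token,
    # everything else is complete-case
    outer_cols = [s.column_name for s in specs if s.table_name in outer_tables]
    strict_cols = [c for c in out.columns if c not in outer_cols]
    before = len(out)
    if strict_cols:
        out = out.dropna(subset=strict_cols)
    dropped = before - len(out)
    for col in outer_cols:
        if out[col].isna().any():
            if pd.api.types.is_datetime64_any_dtype(out[col]):
                out[col] = out[col].dt.strftime("%Y-%m-%d")
            out[col] = out[col].fillna(MISSING_TOKEN)
    out = out.reset_index(drop=True)
    return AnalysisDataset(name=name, columns=tuple(specs), frame=out, dropped_nulls=dropped)


# ---------------------------------------------------------------------------
# public builders
# ---------------------------------------------------------------------------

def _registry_or_default(registry: SchemaRegistry | None) -> SchemaRegistry:
    return registry if registry is not None else load_registry("synpuf5pct")


def _specs_by_key(registry: SchemaRegistry, keys: Iterable[tuple[str, str]]):
    return tuple(registry.get(t, c) for t, c in keys)


def build_phi_dataset(
    cdm,
    phi: VariableSpec,
    registry: SchemaRegistry | None = None,
) -> AnalysisDataset:
    """Build the six-column limited data set for one PHI: the PHI column
    plus the five common demographic attributes, one output row per row of
    the PHI's (driving) table after complete-case filtering."""
    if phi.role is not Role.PHI:
        raise ValidationError(f"{phi.table_name}.{phi.column_name} is not a PHI")
    registry = _registry_or_default(registry)
    demographics = _specs_by_key(registry, _DEMOGRAPHIC_ORDER)
    driving = _driving_table_for(phi)
    return _assemble(cdm, phi.column_name, driving, (phi,) + demographics)


def build_scenario_dataset(
    cdm,
    scenario: ScenarioSpec,
) -> AnalysisDataset:
    """Build one scenario data set, driven by the scenario's event table
    and left-joined to the tables owning the common variables."""
    return _assemble(
        cdm,
        scenario.name,
        scenario.driving_table,
        scenario.all_columns,
        outer_tables=scenario.outer_tables,
    )


# scenario -> (driving table, scenario PHI keys, scenario QI keys, outer tables)
_SCENARIO_PLAN: dict[str, tuple[str, tuple, tuple, frozenset]] = {
    "diagnosis": (
        "condition_occurrence",
        (("condition_occurrence", "condition_start_date"),
         ("condition_occurrence", "condition_end_date")),
        (("condition_occurrence", "condition_concept_id"),),
        frozenset(),
    ),
    "procedure": (
        "procedure_occurrence",
        (("procedure_occurrence", "procedure_date"),),
        (("procedure_occurrence", "procedure_concept_id"),),
        frozenset(),
    ),
    "drug_treatment": (
        "drug_exposure",
        (("drug_exposure", "drug_exposure_start_date"),
         ("drug_exposure", "drug_exposure_end_date")),
        (("drug_exposure", "drug_concept_id"),),
        frozenset(),
    ),
    "lab_test": (
        "measurement",
        (("measurement", "measurement_date"),),
        (("measurement", "measurement_concept_id"),),
        frozenset(),
    ),
    "device_treatment": (
        "device_exposure",
        (("device_exposure", "device_exposure_start_date"),
         ("device_exposure", "device_exposure_end_date")),
        (("device_exposure", "device_concept_id"),),
        frozenset(),
    ),
    # the death scenario is visit-driven (a mortality extract keeps the
    # full visit history) with the one-row-per-person death table joined
    # outer; living persons share the "(none)" death-date token
    "death": (
        "visit_occurrence",
        (("death", "death_date"),),
        (("care_site", "place_of_service_concept_id"),),
        frozenset({"death"}),
    ),
    "medical_history": (
        "observation",
        (("observation", "observation_date"),),
        (("observation", "observation_concept_id"),),
        frozenset(),
    ),
}


def default_scenarios(registry: SchemaRegistry | None = None) -> dict[str, ScenarioSpec]:
    """The seven default scenario compositions.

    Each scenario contributes its own table's date PHIs and order-code QI;
    the six common PHIs are Month_of_birth, Day_of_birth, County, NPI and
    the two visit dates, shared across scenarios. All compositions are
    plain data and can be overridden by constructing ScenarioSpec directly
    or through YAML config.
    """
    registry = _registry_or_default(registry)
    demographics = _specs_by_key(registry, _DEMOGRAPHIC_ORDER)
    common_phis = _specs_by_key(registry, _COMMON_PHI_ORDER)
    out: dict[str, ScenarioSpec] = {}
    for name in SCENARIO_NAMES:
        driving, phi_keys, qi_keys, outer = _SCENARIO_PLAN[name]
        out[name] = ScenarioSpec(
            name=name,
            driving_table=driving,
            scenario_phis=_specs_by_key(registry, phi_keys),
            scenario_qis=_specs_by_key(registry, qi_keys),
            common_phis=common_phis,
            common_demographics=demographics,
            outer_tables=outer,
        )
    return out
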