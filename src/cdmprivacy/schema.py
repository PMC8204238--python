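"""Registry of OMOP CDM columns and their privacy roles.

Columns are classified against the 18 HIPAA identifier categories into
personal health identifiers (PHIs: dates, geographic subdivisions below
state, provider numbers, device identifiers, ...) and quasi-identifiers
(QIs: demographic attributes and clinical order codes whose combination
can single out a person). Dates and sub-state geography are fixed as PHIs
even though they behave like QIs, because HIPAA lists them among the 18
identifier categories; the safe-harbor masking rules follow directly from
the classification (dates are generalised to year, everything else among
the PHIs is suppressed).

Two profiles ship with the package:

``synpuf5pct``
    The 16 PHIs and 12 QIs present with complete values in the public
    SynPUF 5% OMOP CDM v5.2.2 release (12 clinical tables). Hard-coded.

``omop_full``
    A 45-PHI / 17-QI classification of the full CDM v5.2 table set,
    shipped as an editable YAML document (``profiles/omop_full.yaml``).
    The exact membership is a best-effort reconstruction and is meant to
    be reviewed/edited for a concrete deployment; the 45/17 totals are
    enforced by validation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .errors import ConfigurationError, ValidationError

__all__ = [
    "Role",
    "ValueKind",
    "MaskRule",
    "VariableSpec",
    "SchemaRegistry",
    "load_registry",
    "classify_variable",
    "hipaa_map_report",
    "BUILTIN_PROFILES",
]


class Role(str, enum.Enum):
    PHI = "phi"
    QI_DEMOGRAPHIC = "qi_demographic"
    QI_CLINICAL = "qi_clinical"
    OTHER = "other"

    @property
    def is_qi(self) -> bool:
        return self in (Role.QI_DEMOGRAPHIC, Role.QI_CLINICAL)


class ValueKind(str, enum.Enum):
    DATE = "date"
    CODE = "code"
    GEOGRAPHY = "geography"
    IDENTIFIER = "identifier"
    YEAR = "year"


class MaskRule(str, enum.Enum):
    YEAR_ONLY = "year_only"
    SUPPRESS = "suppress"
    NONE = "none"


def _norm(name: str) -> str:
    """Normalise a table/column name to lower snake_case for matching."""
    return name.strip().replace("-", "_").replace(" ", "_").lower()


@dataclass(frozen=True)
class VariableSpec:
    """One CDM column together with its privacy role and masking rule."""

    table_name: str
    column_name: str
    role: Role
    value_kind: ValueKind
    mask_rule: MaskRule

    def __post_init__(self) -> None:
        object.__setattr__(self, "table_name", _norm(self.table_name))
        object.__setattr__(self, "column_name", _norm(self.column_name))
        if self.role is Role.PHI:
            if self.mask_rule not in (MaskRule.YEAR_ONLY, MaskRule.SUPPRESS):
                raise ValidationError(
                    f"PHI {self.key} must be masked (year_only or suppress), "
                    f"got {self.mask_rule.value}"
                )
            if (self.value_kind is ValueKind.DATE) != (
                self.mask_rule is MaskRule.YEAR_ONLY
            ):
                raise ValidationError(
                    f"PHI {self.key}: date-kind variables take year_only and "
                    f"non-date variables take suppress"
                )
        elif self.role.is_qi and self.mask_rule is not MaskRule.NONE:
            raise ValidationError(f"QI {self.key} must have mask_rule=none")

    @property
    def key(self) -> tuple[str, str]:
        return (self.table_name, self.column_name)


def _phi(table: str, column: str, kind: ValueKind) -> VariableSpec:
    rule = MaskRule.YEAR_ONLY if kind is ValueKind.DATE else MaskRule.SUPPRESS
    return VariableSpec(table, column, Role.PHI, kind, rule)


def _qi(table: str, column: str, kind: ValueKind, demographic: bool) -> VariableSpec:
    role = Role.QI_DEMOGRAPHIC if demographic else Role.QI_CLINICAL
    return VariableSpec(table, column, role, kind, MaskRule.NONE)


@dataclass
class SchemaRegistry:
    """An immutable-by-convention collection of classified CDM variables."""

    profile_name: str
    cdm_version: str
    variables: tuple[VariableSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        seen: set[tuple[str, str]] = set()
        for v in self.variables:
            if v.key in seen:
                raise ValidationError(
                    f"duplicate column entry {v.table_name}.{v.column_name} "
                    f"in profile {self.profile_name!r}"
                )
            seen.add(v.key)

    # -- queries ---------------------------------------------------------

    def phis(self) -> tuple[VariableSpec, ...]:
        return tuple(v for v in self.variables if v.role is Role.PHI)

    def qis(self) -> tuple[VariableSpec, ...]:
        return tuple(v for v in self.variables if v.role.is_qi)

    def demographics(self) -> tuple[VariableSpec, ...]:
        return tuple(v for v in self.variables if v.role is Role.QI_DEMOGRAPHIC)

    def lookup(self, table: str, column: str) -> VariableSpec | None:
        key = (_norm(table), _norm(column))
        for v in self.variables:
            if v.key == key:
                return v
        return None

    def get(self, table: str, column: str) -> VariableSpec:
        spec = self.lookup(table, column)
        if spec is None:
            raise ConfigurationError(
                f"{table}.{column} is not a registered variable of profile "
                f"{self.profile_name!r}"
            )
        return spec

    # -- (de)serialisation ----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "profile_name": self.profile_name,
            "cdm_version": self.cdm_version,
            "variables": [
                {
                    "table": v.table_name,
                    "column": v.column_name,
                    "role": v.role.value,
                    "value_kind": v.value_kind.value,
                    "mask_rule": v.mask_rule.value,
                }
                for v in self.variables
            ],
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, doc: Mapping) -> "SchemaRegistry":
        try:
            raw: Iterable[Mapping] = doc.get("variables") or ()
            variables = tuple(
                VariableSpec(
                    table_name=entry["table"],
                    column_name=entry["column"],
                    role=Role(entry["role"]),
                    value_kind=ValueKind(entry["value_kind"]),
                    mask_rule=MaskRule(entry["mask_rule"]),
                )
                for entry in raw
            )
            return cls(
                profile_name=str(doc["profile_name"]),
                cdm_version=str(doc.get("cdm_version", "5.x")),
                variables=variables,
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ConfigurationError(f"malformed registry config: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SchemaRegistry":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, Mapping):
            raise ConfigurationError(f"{path}: not a mapping document")
        return cls.from_dict(doc)


# ---------------------------------------------------------------------------
# Built-in profiles
# ---------------------------------------------------------------------------

def _synpuf5pct_registry() -> SchemaRegistry:
    D, C, G, I, Y = (
        ValueKind.DATE,
        ValueKind.CODE,
        ValueKind.GEOGRAPHY,
        ValueKind.IDENTIFIER,
        ValueKind.YEAR,
    )
    variables = (
        # person
        _phi("person", "month_of_birth", C),
        _phi("person", "day_of_birth", C),
        _qi("person", "year_of_birth", Y, demographic=True),
        _qi("person", "gender_concept_id", C, demographic=True),
        _qi("person", "race_concept_id", C, demographic=True),
        _qi("person", "ethnicity_concept_id", C, demographic=True),
        # death
        _phi("death", "death_date", D),
        # device_exposure
        _phi("device_exposure", "device_exposure_start_date", D),
        _phi("device_exposure", "device_exposure_end_date", D),
        _qi("device_exposure", "device_concept_id", C, demographic=False),
        # drug_exposure
        _phi("drug_exposure", "drug_exposure_start_date", D),
        _phi("drug_exposure", "drug_exposure_end_date", D),
        _qi("drug_exposure", "drug_concept_id", C, demographic=False),
        # location
        _phi("location", "county", G),
        _qi("location", "state", G, demographic=True),
        # measurement
        _phi("measurement", "measurement_date", D),
        _qi("measurement", "measurement_concept_id", C, demographic=False),
        # observation
        _phi("observation", "observation_date", D),
        _qi("observation", "observation_concept_id", C, demographic=False),
        # procedure_occurrence
        _phi("procedure_occurrence", "procedure_date", D),
        _qi("procedure_occurrence", "procedure_concept_id", C, demographic=False),
        # visit_occurrence
        _phi("visit_occurrence", "visit_start_date", D),
        _phi("visit_occurrence", "visit_end_date", D),
        # condition_occurrence
        _phi("condition_occurrence", "condition_start_date", D),
        _phi("condition_occurrence", "condition_end_date", D),
        _qi("condition_occurrence", "condition_concept_id", C, demographic=False),
        # provider
        _phi("provider", "npi", I),
        # care_site
        _qi("care_site", "place_of_service_concept_id", C, demographic=False),
    )
    return SchemaRegistry("synpuf5pct", "5.2.2", variables)


_EXPECTED_COUNTS = {"synpuf5pct": (16, 12), "omop_full": (45, 17)}


def _omop_full_registry() -> SchemaRegistry:
    ref = resources.files("cdmprivacy").joinpath("profiles/omop_full.yaml")
    with resources.as_file(ref) as path:
        return SchemaRegistry.from_yaml(path)


BUILTIN_PROFILES = ("synpuf5pct", "omop_full")


def load_registry(profile: str | Path = "synpuf5pct") -> SchemaRegistry:
    """Load a built-in profile by name, or a registry config from a path.

    Raises ConfigurationError for an unknown profile name and
    ValidationError when a built-in profile fails its PHI/QI count check
    or a config document contains duplicate columns.
    """
    name = str(profile)
    if name == "synpuf5pct":
        registry = _synpuf5pct_registry()
    elif name == "omop_full":
        registry = _omop_full_registry()
    elif Path(name).exists():
        return SchemaRegistry.from_yaml(name)
    else:
        raise ConfigurationError(
            f"unknown registry profile {name!r}; built-ins are "
            f"{', '.join(BUILTIN_PROFILES)} (or pass a path to a YAML config)"
        )
    n_phi, n_qi = len(registry.phis()), len(registry.qis())
    expected = _EXPECTED_COUNTS[name]
    if (n_phi, n_qi) != expected:
        raise ValidationError(
            f"profile {name!r} declares {n_phi} PHIs / {n_qi} QIs, "
            f"expected {expected[0]}/{expected[1]}"
        )
    return registry


def classify_variable(registry: SchemaRegistry, table: str, column: str) -> VariableSpec:
    """Resolve one column to its privacy role.

    Unlisted columns (surrogate keys, source values, anything outside the
    profile) come back with role=other and no masking rule; they are never
    analysis variables.
    """
    spec = registry.lookup(table, column)
    if spec is not None:
        return spec
    return VariableSpec(table, column, Role.OTHER, ValueKind.CODE, MaskRule.NONE)


def hipaa_map_report(registry: SchemaRegistry) -> pd.DataFrame:
    """Tabular rendering of the HIPAA-to-CDM mapping, one row per variable,
    grouped by table (the package's analogue of the classification table a
    privacy audit would publish)."""
    rows = [
        {
            "table": v.table_name,
            "column": v.column_name,
            "role": v.role.value,
            "value_kind": v.value_kind.value,
            "mask_rule": v.mask_rule.value,
        }
        for v in registry.variables
    ]
    df = pd.DataFrame(rows, columns=["table", "column", "role", "value_kind", "mask_rule"])
    if len(df):
        df = df.sort_values(["table", "role", "column"], kind="stable").reset_index(drop=True)
    return df
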