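"""Synthetic OMOP-CDM table generator.

Emulates the *statistical structure* that drives re-identification risk in
claims-derived CDM releases such as the public SynPUF 5% sample: a short
(2008-2010) event window, per-person event multiplicity that differs
sharply by table (exactly one death date per deceased person versus tens
to hundreds of visits/conditions per person), a Day_of_birth column
already flattened to the constant "1", small-cardinality demographic
codes, and skewed clinical code usage. Clinical plausibility (diagnosis-
drug coherence, disease trajectories) is explicitly out of scope: only
the joint-frequency structure of the privacy-relevant columns matters
here.

Determinism: one master seed; each table draws from an independent
substream derived from the seed and a stable hash of the table name, so
adding or removing a table never perturbs the others.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

__all__ = [
    "EventModel",
    "SyntheticConfig",
    "CdmTableSet",
    "generate_cdm",
    "presets",
]

EVENT_TABLES = (
    "visit_occurrence",
    "condition_occurrence",
    "procedure_occurrence",
    "drug_exposure",
    "device_exposure",
    "measurement",
    "observation",
)

# event table -> (date column stem, concept column)
_EVENT_COLUMNS = {
    "visit_occurrence": (("visit_start_date", "visit_end_date"), None),
    "condition_occurrence": (
        ("condition_start_date", "condition_end_date"),
        "condition_concept_id",
    ),
    "procedure_occurrence": (("procedure_date",), "procedure_concept_id"),
    "drug_exposure": (
        ("drug_exposure_start_date", "drug_exposure_end_date"),
        "drug_concept_id",
    ),
    "device_exposure": (
        ("device_exposure_start_date", "device_exposure_end_date"),
        "device_concept_id",
    ),
    "measurement": (("measurement_date",), "measurement_concept_id"),
    "observation": (("observation_date",), "observation_concept_id"),
}


@dataclass(frozen=True)
class EventModel:
    """Per-person event-count distribution for one table.

    kind: "fixed" (exactly ``value`` events), "poisson" (Poisson(value)),
    or "zero_inflated" (with probability ``zero_prob`` no events at all,
    otherwise Poisson(value)).
    """

    kind: str = "poisson"
    value: float = 1.0
    zero_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "poisson", "zero_inflated"):
            raise ConfigurationError(f"unknown event-count model {self.kind!r}")
        if self.value < 0 or not (0.0 <= self.zero_prob <= 1.0):
            raise ConfigurationError("event-count parameters out of range")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, int(self.value), dtype=np.int64)
        counts = rng.poisson(self.value, n)
        if self.kind == "zero_inflated" and self.zero_prob > 0:
            counts = np.where(rng.random(n) < self.zero_prob, 0, counts)
        return counts.astype(np.int64)


def _default_vocab() -> dict[str, int]:
    # demographic cardinalities chosen for US-claims realism; clinical code
    # cardinalities mirror the order of magnitude seen in claims extracts
    return {
        "gender_concept_id": 2,
        "race_concept_id": 5,
        "ethnicity_concept_id": 2,
        "state": 50,
        "county": 300,
        "condition_concept_id": 4000,
        "procedure_concept_id": 4000,
        "drug_concept_id": 4000,
        "device_concept_id": 1000,
        "measurement_concept_id": 1000,
        "observation_concept_id": 1000,
        "place_of_service_concept_id": 5,
    }


def _default_events() -> dict[str, EventModel]:
    return {
        "visit_occurrence": EventModel("poisson", 12.0),
        "condition_occurrence": EventModel("poisson", 20.0),
        "procedure_occurrence": EventModel("poisson", 15.0),
        "drug_exposure": EventModel("poisson", 6.0),
        "device_exposure": EventModel("poisson", 2.0),
        "measurement": EventModel("poisson", 10.0),
        "observation": EventModel("poisson", 8.0),
    }


def _default_end_offsets() -> dict[str, tuple[int, int]]:
    # start/end pairs correlate: end = start + offset (days)
    return {
        "visit_occurrence": (0, 7),
        "condition_occurrence": (0, 14),
        "drug_exposure": (0, 0),  # dispense lines close same day
        "device_exposure": (0, 14),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic CDM draw."""

    n_persons: int = 1000
    date_range: tuple[dt.date, dt.date] = (dt.date(2008, 1, 1), dt.date(2010, 12, 31))
    events: Mapping[str, EventModel] = field(default_factory=_default_events)
    vocab_sizes: Mapping[str, int] = field(default_factory=_default_vocab)
    death_fraction: float = 0.05
    day_of_birth_constant: bool = True
    year_of_birth_range: tuple[int, int] = (1909, 1943)
    end_offset_days: Mapping[str, tuple[int, int]] = field(
        default_factory=_default_end_offsets
    )
    code_skew: float = 1.0
    providers_per_person: float = 20.0
    n_care_sites: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ConfigurationError("n_persons must be >= 1")
        if not (0.0 <= self.death_fraction <= 1.0):
            raise ConfigurationError("death_fraction must lie in [0, 1]")
        start, end = self.date_range
        if start > end:
            raise ConfigurationError(f"inverted date_range {start}..{end}")
        for col, size in self.vocab_sizes.items():
            if size < 1:
                raise ConfigurationError(f"vocab size for {col!r} must be >= 1")
        if self.year_of_birth_range[0] > self.year_of_birth_range[1]:
            raise ConfigurationError("inverted year_of_birth_range")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=int(seed))


class CdmTableSet:
    """A set of flat CDM tables keyed by lower-snake-case table name."""

    def __init__(self, tables: Mapping[str, pd.DataFrame]):
        self._tables: dict[str, pd.DataFrame] = dict(tables)

    def __getitem__(self, name: str) -> pd.DataFrame:
        try:
            return self._tables[name]
        except KeyError:
            raise KeyError(f"CDM table {name!r} not present") from None

    def __contains__(self, name: str) -> bool:
        return name in self._tables

    def __iter__(self) -> Iterator[str]:
        return iter(self._tables)

    @property
    def table_names(self) -> tuple[str, ...]:
        return tuple(self._tables)

    def row_counts(self) -> dict[str, int]:
        return {name: len(df) for name, df in self._tables.items()}

    def to_csv(self, directory: str | Path) -> None:
        """Write one CSV per table; dates serialise as ISO-8601 strings."""
        out = Path(directory)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self._tables.items():
            df.to_csv(out / f"{name}.csv", index=False)

    @classmethod
    def from_csv(cls, directory: str | Path) -> "CdmTableSet":
        """Load every ``*.csv`` in a directory as one CDM table (the entry
        point for a real CDM export such as SynPUF5PCT CSVs)."""
        directory = Path(directory)
        paths = sorted(directory.glob("*.csv"))
        if not paths:
            raise ConfigurationError(f"no CSV tables found under {directory}")
        tables = {}
        for path in paths:
            df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
            df.columns = [c.strip().lower() for c in df.columns]
            tables[path.stem.lower()] = df
        return cls(tables)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _table_rng(seed: int, table: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(table.encode())])


def _zipf_probs(size: int, skew: float) -> np.ndarray:
    ranks = np.arange(1, size + 1, dtype=float)
    weights = ranks ** (-skew)
    return weights / weights.sum()


def _draw_codes(
    rng: np.random.Generator, size: int, vocab: int, skew: float, offset: int = 0
) -> np.ndarray:
    """Skewed (Zipf-like) draw of integer codes from a vocabulary."""
    if vocab == 1:
        return np.full(size, offset + 1, dtype=np.int64)
    codes = rng.choice(vocab, size=size, p=_zipf_probs(vocab, skew))
    return (codes + offset + 1).astype(np.int64)


def _draw_dates(
    rng: np.random.Generator, size: int, date_range: tuple[dt.date, dt.date]
) -> np.ndarray:
    start, end = date_range
    span = (end - start).days + 1
    offsets = rng.integers(0, span, size)
    base = np.datetime64(start.isoformat(), "D")
    return base + offsets.astype("timedelta64[D]")


def generate_cdm(config: SyntheticConfig) -> CdmTableSet:
    """Draw one synthetic CDM table set.

    Deterministic for a fixed config (including its seed). Generated
    analysis columns never contain nulls, mirroring the complete-case
    table subset the risk analysis assumes.
    """
    n = config.n_persons
    skew = config.code_skew
    vocab = dict(_default_vocab())
    vocab.update(config.vocab_sizes)
    tables: dict[str, pd.DataFrame] = {}

    # location: one row per county; counties nest within states
    n_loc = vocab["county"]
    n_state = vocab["state"]
    location = pd.DataFrame(
        {
            "location_id": np.arange(1, n_loc + 1),
            "state": [f"S{(i % n_state) + 1:02d}" for i in range(n_loc)],
            "county": [f"C{i + 1:04d}" for i in range(n_loc)],
        }
    )
    tables["location"] = location

    # person
    rng = _table_rng(config.seed, "person")
    y0, y1 = config.year_of_birth_range
    person = pd.DataFrame(
        {
            "person_id": np.arange(1, n + 1),
            "year_of_birth": rng.integers(y0, y1 + 1, n),
            "month_of_birth": rng.integers(1, 13, n),
            "day_of_birth": (
                np.ones(n, dtype=np.int64)
                if config.day_of_birth_constant
                else rng.integers(1, 29, n)
            ),
            "gender_concept_id": _draw_codes(rng, n, vocab["gender_concept_id"], 0.3),
            "race_concept_id": _draw_codes(rng, n, vocab["race_concept_id"], skew),
            "ethnicity_concept_id": _draw_codes(
                rng, n, vocab["ethnicity_concept_id"], 0.3
            ),
            "location_id": _draw_codes(rng, n, n_loc, skew),
        }
    )
    tables["person"] = person

    # provider / care_site
    rng = _table_rng(config.seed, "provider")
    n_prov = vocab.get("npi") or max(1, int(round(config.providers_per_person * n)))
    tables["provider"] = pd.DataFrame(
        {
            "provider_id": np.arange(1, n_prov + 1),
            "npi": np.arange(1, n_prov + 1) + 10_0000_0000,
            "care_site_id": (np.arange(n_prov) % config.n_care_sites) + 1,
        }
    )
    rng = _table_rng(config.seed, "care_site")
    tables["care_site"] = pd.DataFrame(
        {
            "care_site_id": np.arange(1, config.n_care_sites + 1),
            "place_of_service_concept_id": _draw_codes(
                rng, config.n_care_sites, vocab["place_of_service_concept_id"], 0.5
            ),
        }
    )

    # death: at most one row per person, uniform date in range
    rng = _table_rng(config.seed, "death")
    n_dead = int(round(config.death_fraction * n))
    dead_ids = np.sort(rng.choice(person["person_id"].to_numpy(), n_dead, replace=False))
    tables["death"] = pd.DataFrame(
        {
            "person_id": dead_ids,
            "death_date": _draw_dates(rng, n_dead, config.date_range),
        }
    )

    # visits first (events reference them for provider/care-site joins)
    events = dict(_default_events())
    events.update(config.events)
    rng = _table_rng(config.seed, "visit_occurrence")
    visit_counts = np.maximum(events["visit_occurrence"].draw(rng, n), 1)
    n_visits = int(visit_counts.sum())
    visit_person = np.repeat(person["person_id"].to_numpy(), visit_counts)
    visit_provider = _draw_codes(rng, n_visits, n_prov, skew)
    starts = _draw_dates(rng, n_visits, config.date_range)
    lo, hi = dict(_default_end_offsets()).get("visit_occurrence", (0, 0))
    lo, hi = dict(config.end_offset_days).get("visit_occurrence", (lo, hi))
    ends = starts + rng.integers(lo, hi + 1, n_visits).astype("timedelta64[D]")
    provider_cs = tables["provider"]["care_site_id"].to_numpy()
    tables["visit_occurrence"] = pd.DataFrame(
        {
            "visit_occurrence_id": np.arange(1, n_visits + 1),
            "person_id": visit_person,
            "visit_start_date": starts,
            "visit_end_date": ends,
            "provider_id": visit_provider,
            "care_site_id": provider_cs[visit_provider - 1],
        }
    )
    # offsets for sampling a visit of the owning person
    visit_offsets = np.concatenate([[0], np.cumsum(visit_counts)])

    for table in EVENT_TABLES:
        if table == "visit_occurrence":
            continue
        rng = _table_rng(config.seed, table)
        counts = events[table].draw(rng, n)
        total = int(counts.sum())
        person_ids = np.repeat(person["person_id"].to_numpy(), counts)
        # attach each event to one of the owning person's visits
        per_person_visits = np.repeat(visit_counts, counts)
        pick = np.floor(rng.random(total) * per_person_visits).astype(np.int64)
        visit_ids = np.repeat(visit_offsets[:-1], counts) + pick + 1
        date_cols, concept_col = _EVENT_COLUMNS[table]
        frame: dict[str, np.ndarray] = {
            "person_id": person_ids,
            "visit_occurrence_id": visit_ids,
        }
        starts = _draw_dates(rng, total, config.date_range)
        frame[date_cols[0]] = starts
        if len(date_cols) == 2:
            lo, hi = dict(_default_end_offsets()).get(table, (0, 0))
            lo, hi = dict(config.end_offset_days).get(table, (lo, hi))
            frame[date_cols[1]] = starts + rng.integers(
                lo, hi + 1, total
            ).astype("timedelta64[D]")
        if concept_col is not None:
            frame[concept_col] = _draw_codes(rng, total, vocab[concept_col], skew)
        tables[table] = pd.DataFrame(frame)

    result = CdmTableSet(tables)
    _check_invariants(result, config)
    return result


def _check_invariants(cdm: CdmTableSet, config: SyntheticConfig) -> None:
    person = cdm["person"]
    if person["person_id"].duplicated().any():
        raise ValidationError("person table must have exactly one row per person")
    death = cdm["death"]
    if death["person_id"].duplicated().any():
        raise ValidationError("death table must have at most one row per person")
    if config.day_of_birth_constant and person["day_of_birth"].nunique() > 1:
        raise ValidationError("day_of_birth must be constant under this config")
    start = np.datetime64(config.date_range[0].isoformat())
    end = np.datetime64(config.date_range[1].isoformat())
    for table, (date_cols, _) in _EVENT_COLUMNS.items():
        col = cdm[table][date_cols[0]]
        if len(col) and (col.min() < start or col.max() > end):
            raise ValidationError(f"{table}.{date_cols[0]} falls outside date_range")


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _synpuf_like(n_persons: int) -> SyntheticConfig:
    # per-person event rates mirror the per-table record volumes of the
    # public SynPUF 5% OMOP release (~25.2k persons; visits ~48/person,
    # conditions ~128, procedures ~120, measurements ~29, observations
    # ~17, drug exposures ~6.3, device exposures ~1.9; deaths ~4.6%)
    return SyntheticConfig(
        n_persons=n_persons,
        death_fraction=1155 / 25200,
        events={
            "visit_occurrence": EventModel("poisson", 48.4),
            "condition_occurrence": EventModel("poisson", 128.2),
            "procedure_occurrence": EventModel("poisson", 120.0),
            "drug_exposure": EventModel("zero_inflated", 9.0, zero_prob=0.3),
            "device_exposure": EventModel("zero_inflated", 3.8, zero_prob=0.5),
            "measurement": EventModel("poisson", 29.4),
            "observation": EventModel("poisson", 16.7),
        },
    )


def presets() -> dict[str, SyntheticConfig]:
    """Named generator configurations.

    "synpuf_like" reproduces the structural scale of the SynPUF 5% OMOP
    release; "synpuf_like_small" keeps the same per-person multiplicities
    at a 2,000-person population for tractable end-to-end runs; "toy" is
    a <=50-person fixture for unit tests.
    """
    toy = SyntheticConfig(
        n_persons=40,
        death_fraction=0.2,
        events={
            "visit_occurrence": EventModel("poisson", 3.0),
            "condition_occurrence": EventModel("poisson", 4.0),
            "procedure_occurrence": EventModel("poisson", 3.0),
            "drug_exposure": EventModel("poisson", 2.0),
            "device_exposure": EventModel("poisson", 1.0),
            "measurement": EventModel("poisson", 2.0),
            "observation": EventModel("poisson", 2.0),
        },
        vocab_sizes={
            "condition_concept_id": 30,
            "procedure_concept_id": 30,
            "drug_concept_id": 20,
            "device_concept_id": 10,
            "measurement_concept_id": 15,
            "observation_concept_id": 15,
            "county": 20,
            "state": 8,
        },
        providers_per_person=2.0,
        n_care_sites=5,
    )
    return {
        "synpuf_like": _synpuf_like(25_200),
        "synpuf_like_small": _synpuf_like(2_000),
        "toy": toy,
    }
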