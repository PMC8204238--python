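"""Equivalence-class risk metrics.

An equivalence class (EC) is a maximal set of records identical on all
selected analysis columns; its size is the number of records in it. The
whole disclosure-risk analysis reduces to the histogram of EC sizes:

* ``c_k`` — number of classes of size exactly k, with the conservation
  law sum_k k*c_k = N (every record lives in exactly one class);
* *minimum cell size of k* — the percentage of records sitting in classes
  of size exactly k, ``100 * k * c_k / N``; at k = 1 this is the percent
  of unique, maximally re-identifiable records;
* *maximum EC size* — the largest class size, a measure of attained
  indistinguishability;
* *trust differential gap* — the difference in these percentages between
  two deidentification levels of the same data (limited minus safe
  harbor), quantifying how much risk the stricter policy removes.

Because a masked dataset's partition is a coarsening of the original's,
the unique-record percent can only fall and the maximum EC size can only
grow under masking; the gap at k = 1 is therefore non-negative whenever
the two inputs really are two levels of one dataset.

Percentages are carried at full floating precision; rounding to the
3-decimal presentation convention happens only in report rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .datasets import AnalysisDataset
from .errors import ValidationError

__all__ = [
    "ECProfile",
    "RiskSummary",
    "GapResult",
    "equivalence_profile",
    "percent_at_size",
    "unique_record_percent",
    "max_ec_size",
    "risk_summary",
    "trust_gap",
]


@dataclass(frozen=True)
class ECProfile:
    """Histogram of equivalence-class sizes: {class size k: class count c_k}."""

    histogram: Mapping[int, int]
    n_records: int
    columns: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        hist = {int(k): int(c) for k, c in self.histogram.items()}
        object.__setattr__(self, "histogram", hist)
        if any(k < 1 for k in hist) or any(c < 1 for c in hist.values()):
            raise ValidationError("EC histogram keys and counts must be >= 1")
        total = sum(k * c for k, c in hist.items())
        if total != self.n_records:
            raise ValidationError(
                f"EC histogram mass {total} does not equal n_records {self.n_records}"
            )

    @property
    def n_classes(self) -> int:
        return sum(self.histogram.values())

    def class_count(self, k: int) -> int:
        return self.histogram.get(int(k), 0)

    def record_count(self, k: int) -> int:
        """Number of records sitting in classes of size exactly k."""
        return self.class_count(k) * int(k)

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "histogram": dict(sorted(self.histogram.items())),
            "columns": list(self.columns) if self.columns else None,
        }


def equivalence_profile(
    dataset: AnalysisDataset | pd.DataFrame,
    columns: Sequence[str] | None = None,
) -> ECProfile:
    """Profile the equivalence-class structure of a dataset.

    One hash-grouping pass over the selected columns (default: all
    analysis columns); values are grouped as raw tokens, missing values
    form their own class key. Runs in O(N) — never pairwise.
    """
    frame = dataset.frame if isinstance(dataset, AnalysisDataset) else dataset
    cols = list(columns) if columns is not None else list(frame.columns)
    if not cols:
        raise ValidationError("equivalence_profile needs at least one column")
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValidationError(f"columns not in dataset: {missing}")
    n = len(frame)
    if n == 0:
        return ECProfile({}, 0, tuple(cols))
    sizes = frame.groupby(cols, dropna=False, sort=False, observed=True).size()
    hist = sizes.value_counts().to_dict()
    return ECProfile(hist, n, tuple(cols))


def percent_at_size(profile: ECProfile, k: int, cumulative: bool = False) -> float:
    """Percent of records in classes of size exactly k (the convention used
    throughout reporting), or of size <= k with ``cumulative=True``."""
    if k < 1:
        raise ValidationError("class size k must be >= 1")
    if profile.n_records == 0:
        raise ValidationError("cannot compute percentages on an empty profile")
    if cumulative:
        records = sum(profile.record_count(j) for j in profile.histogram if j <= k)
    else:
        records = profile.record_count(k)
    return 100.0 * records / profile.n_records


def unique_record_percent(profile: ECProfile) -> float:
    """Percent of records that are unique on the analysis columns
    (minimum cell size of one): 100 * c_1 / N."""
    return percent_at_size(profile, 1)


def max_ec_size(profile: ECProfile) -> int:
    """The largest equivalence-class size present."""
    if not profile.histogram:
        raise ValidationError("empty profile has no maximum EC size")
    return max(profile.histogram)


@dataclass(frozen=True)
class RiskSummary:
    """Per-dataset risk summary: percent of records at each class size
    1..k_max, the unique-record percent, and the maximum EC size."""

    percent_at_size: Mapping[int, float]
    unique_percent: float
    max_ec_size: int
    n_records: int
    unique_records: int = 0
    columns: tuple[str, ...] | None = None
    label: str = ""

    def gap_to(self, other: "RiskSummary") -> "GapResult":
        return trust_gap(self, other)


def risk_summary(profile: ECProfile, k_max: int = 20, label: str = "") -> RiskSummary:
    """Summarise a profile for reporting (class sizes 1..k_max)."""
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    percents = {k: percent_at_size(profile, k) for k in range(1, k_max + 1)}
    return RiskSummary(
        percent_at_size=percents,
        unique_percent=unique_record_percent(profile),
        max_ec_size=max_ec_size(profile),
        n_records=profile.n_records,
        unique_records=profile.class_count(1),
        columns=profile.columns,
        label=label,
    )


@dataclass(frozen=True)
class GapResult:
    """Trust differential between two deidentification levels of one
    dataset. ``gap_percent_at_size[k]`` is limited minus safe-harbor
    percent at class size k; ``gap_max_ec`` is safe-harbor minus limited
    maximum EC size (both non-negative under a genuine coarsening)."""

    limited: RiskSummary
    safe_harbor: RiskSummary
    gap_percent_at_size: Mapping[int, float] = field(default_factory=dict)
    gap_max_ec: int = 0

    @property
    def gap_unique_percent(self) -> float:
        return self.gap_percent_at_size[1]


def trust_gap(limited: RiskSummary, safe: RiskSummary) -> GapResult:
    """Element-wise trust differential between the limited summary and its
    safe-harbor image; both inputs are retained in the result."""
    if (
        limited.columns is not None
        and safe.columns is not None
        and set(limited.columns) != set(safe.columns)
    ):
        raise ValidationError(
            f"summaries cover different column sets: "
            f"{limited.columns} vs {safe.columns}"
        )
    ks = sorted(set(limited.percent_at_size) | set(safe.percent_at_size))
    gaps = {
        k: limited.percent_at_size.get(k, 0.0) - safe.percent_at_size.get(k, 0.0)
        for k in ks
    }
    return GapResult(
        limited=limited,
        safe_harbor=safe,
        gap_percent_at_size=gaps,
        gap_max_ec=safe.max_ec_size - limited.max_ec_size,
    )
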