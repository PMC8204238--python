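"""Row-wise deidentification policies.

Two policies matter in practice:

* ``limited`` — the identity transform: the data as released under a
  HIPAA limited-data-set agreement, dates and sub-state geography intact;
* ``safe_harbor`` — the HIPAA safe-harbor level: every date-kind PHI is
  generalised from "YYYY-MM-DD" to the literal token "YYYY-**-**" (only
  the year survives) and every non-date PHI (birth-date parts, county,
  NPI, ...) is replaced by the single shared token "*". QIs pass through
  untouched.

Suppressed values all collapse to one token rather than per-row nulls, so
a fully suppressed column contributes nothing to record
distinguishability. Both transforms are coarsenings: records equal before
masking remain equal after, which is what makes the limited-vs-safe-harbor
gap metrics well defined (unique records can only disappear, the largest
equivalence class can only grow).
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .datasets import MISSING_TOKEN, AnalysisDataset
from .errors import ConfigurationError, DataError
from .schema import MaskRule, Role, VariableSpec

__all__ = ["SUPPRESSED_TOKEN", "MaskPolicy", "mask_value", "apply_policy"]

SUPPRESSED_TOKEN = "*"

_ISO_DATE = re.compile(r"^(\d{4})-(\d{2})-(\d{2})$")


def mask_value(value, rule: MaskRule | str):
    """Apply one masking rule to one scalar.

    year_only keeps the year of an ISO date ("2008-03-14" -> "2008-**-**"),
    suppress returns the shared "*" token, none is the identity. The
    "(none)" missing token passes through year_only unchanged (an absent
    event stays absent). Raises DataError when year_only meets a value
    that does not parse as a date.
    """
    rule = MaskRule(rule)
    if rule is MaskRule.NONE:
        return value
    if rule is MaskRule.SUPPRESS:
        return SUPPRESSED_TOKEN
    # year_only
    if value == MISSING_TOKEN:
        return value
    if isinstance(value, (dt.date, dt.datetime)):
        return f"{value.year:04d}-**-**"
    if isinstance(value, np.datetime64):
        if np.isnat(value):
            return MISSING_TOKEN
        return f"{value.astype('datetime64[Y]').astype(int) + 1970:04d}-**-**"
    text = str(value).strip()
    if re.match(r"^\d{4}-\*\*-\*\*$", text):
        return text  # already generalised; idempotent
    match = _ISO_DATE.match(text)
    if match is None:
        raise DataError(f"cannot apply year_only masking to non-date value {value!r}")
    return f"{match.group(1)}-**-**"


@dataclass(frozen=True)
class MaskPolicy:
    """A named assignment of masking rules to variables.

    By default each variable receives its registry rule under
    ``safe_harbor`` and the identity under ``limited``; per-column
    overrides allow custom regimes.
    """

    name: str
    overrides: Mapping[tuple[str, str], MaskRule] = field(default_factory=dict)

    @classmethod
    def limited(cls) -> "MaskPolicy":
        return cls("limited")

    @classmethod
    def safe_harbor(cls) -> "MaskPolicy":
        return cls("safe_harbor")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MaskPolicy":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, Mapping) or "name" not in doc:
            raise ConfigurationError(f"{path}: policy config must map at least 'name'")
        overrides = {}
        for entry in doc.get("overrides") or ():
            try:
                overrides[(entry["table"], entry["column"])] = MaskRule(entry["rule"])
            except (KeyError, ValueError) as exc:
                raise ConfigurationError(f"{path}: bad override entry {entry!r}") from exc
        name = str(doc["name"])
        if name not in ("limited", "safe_harbor") and not overrides:
            name_ok = doc.get("base") in ("limited", "safe_harbor")
            if not name_ok:
                raise ConfigurationError(
                    f"{path}: custom policy needs overrides or a recognised base"
                )
        return cls(name, overrides)

    def rule_for(self, spec: VariableSpec) -> MaskRule:
        override = dict(self.overrides).get(spec.key)
        if override is not None:
            return override
        if self.name == "limited":
            return MaskRule.NONE
        # safe_harbor and customs based on it: PHIs masked per registry,
        # QIs untouched
        if spec.role is Role.PHI:
            return spec.mask_rule
        return MaskRule.NONE


def _mask_series(series: pd.Series, rule: MaskRule, column: str) -> pd.Series:
    if rule is MaskRule.NONE:
        return series
    if rule is MaskRule.SUPPRESS:
        return pd.Series(SUPPRESSED_TOKEN, index=series.index, name=series.name)
    # year_only, vectorised
    if pd.api.types.is_datetime64_any_dtype(series):
        years = series.dt.year
        out = years.map(lambda y: f"{int(y):04d}-**-**", na_action="ignore")
        return out.fillna(MISSING_TOKEN)
    values = series.astype(str).str.strip()
    already = values.str.match(r"^\d{4}-\*\*-\*\*$")  # idempotence
    is_missing = values == MISSING_TOKEN
    parsed = values.str.extract(_ISO_DATE, expand=True)[0]
    bad = parsed.isna() & ~already & ~is_missing
    if bad.any():
        row = int(bad.idxmax())
        raise DataError(
            f"column {column!r}, row {row}: value "
            f"{series.loc[row]!r} does not parse as an ISO date"
        )
    out = parsed + "-**-**"
    out = out.where(~already, values)
    return out.where(~is_missing, MISSING_TOKEN)


def apply_policy(dataset: AnalysisDataset, policy: MaskPolicy) -> AnalysisDataset:
    """Return the row-aligned masked image of a dataset.

    Row count and row order are preserved exactly (row i of the output is
    the masked image of row i of the input) so that paired sampling can
    share index sets between the two deidentification levels. The
    transform is idempotent.
    """
    frame = dataset.frame.copy()
    for spec in dataset.columns:
        rule = policy.rule_for(spec)
        if rule is not MaskRule.NONE:
            frame[spec.column_name] = _mask_series(frame[spec.column_name], rule, spec.column_name)
    return AnalysisDataset(
        name=f"{dataset.name}[{policy.name}]",
        columns=dataset.columns,
        frame=frame,
        dropped_nulls=dataset.dropped_nulls,
    )
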