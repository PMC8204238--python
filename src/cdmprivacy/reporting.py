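"""End-to-end pipeline driver and report tables.

Produces the four report families of a full risk audit:

* per-PHI full-data comparison (one row per PHI: N, unique records and
  percent under each policy, max EC size, gaps, plus an average row);
* per-scenario QI comparison (percent of records at class sizes 1/2/5
  under each policy with record counts, gaps, average row);
* class-size distribution export (dataset x policy x k = 1..20 percent),
  the long-format table behind a minimum-cell-size distribution figure;
* the equal-n sampling grid (sample sizes x datasets, mean (SD) unique
  count, percents, gap, per-size average row; cells with n > N marked
  not-applicable).

Every number in a report is recomputed from the emitted dataset profiles;
floats are rounded half-even to 3 decimals at the presentation layer
only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import (
    AnalysisDataset,
    ScenarioSpec,
    build_phi_dataset,
    build_scenario_dataset,
    default_scenarios,
)
from .errors import CdmPrivacyError, ConfigurationError
from .masking import MaskPolicy, apply_policy
from .metrics import equivalence_profile, risk_summary, trust_gap
from .sampling import aggregate_over_experiments, paired_sample_experiment
from .schema import SchemaRegistry, load_registry
from .synthetic import CdmTableSet, SyntheticConfig, generate_cdm, presets

logger = logging.getLogger("cdmprivacy")

__all__ = [
    "RunConfig",
    "build_policy_pair",
    "run_phi_experiment",
    "run_qi_experiment",
    "run_sampling_experiment",
    "run_all",
]

DEFAULT_SAMPLE_SIZES = (1_000, 10_000, 100_000, 1_000_000)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run. Exactly one input mode:
    a synthetic generator config or a directory of CDM CSV tables."""

    out_dir: Path
    profile: str = "synpuf5pct"
    synthetic: SyntheticConfig | None = None
    input_cdm: Path | None = None
    scenarios: Mapping[str, ScenarioSpec] | None = None
    k_max: int = 20
    sample_sizes: Sequence[int] = DEFAULT_SAMPLE_SIZES
    iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_cdm is None):
            raise ConfigurationError(
                "exactly one input mode required: synthetic config or --input-cdm"
            )
        self.out_dir = Path(self.out_dir)

    def load_cdm(self) -> CdmTableSet:
        if self.input_cdm is not None:
            return CdmTableSet.from_csv(self.input_cdm)
        return generate_cdm(self.synthetic.with_seed(self.seed))


def _round(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(3)  # numpy half-even
    return out


def build_policy_pair(
    dataset: AnalysisDataset,
) -> tuple[AnalysisDataset, AnalysisDataset]:
    """A dataset under both deidentification levels: (limited image,
    safe-harbor image), row-aligned."""
    return (
        apply_policy(dataset, MaskPolicy.limited()),
        apply_policy(dataset, MaskPolicy.safe_harbor()),
    )


def _profile_pair(limited: AnalysisDataset, safe: AnalysisDataset, k_max: int):
    prof_l = equivalence_profile(limited)
    prof_s = equivalence_profile(safe)
    sum_l = risk_summary(prof_l, k_max=k_max, label=limited.name)
    sum_s = risk_summary(prof_s, k_max=k_max, label=safe.name)
    return prof_l, prof_s, sum_l, sum_s


# ---------------------------------------------------------------------------
# per-PHI experiment
# ---------------------------------------------------------------------------

def build_all_phi_datasets(
    cdm: CdmTableSet, registry: SchemaRegistry
) -> dict[str, AnalysisDataset]:
    """One limited data set per registry PHI; failures are logged and the
    remaining variables still build."""
    out: dict[str, AnalysisDataset] = {}
    for phi in registry.phis():
        try:
            ds = build_phi_dataset(cdm, phi, registry)
        except CdmPrivacyError as exc:
            logger.warning("skipping PHI %s.%s: %s", phi.table_name, phi.column_name, exc)
            continue
        logger.info(
            "built %s: %d records (%d null rows dropped)",
            ds.name, ds.n_records, ds.dropped_nulls,
        )
        out[ds.name] = ds
    return out


def run_phi_experiment(
    cdm: CdmTableSet,
    registry: SchemaRegistry | None = None,
    k_max: int = 20,
    datasets: Mapping[str, AnalysisDataset] | None = None,
) -> pd.DataFrame:
    """Full-data comparison of every PHI under both policies.

    One row per PHI (variable, N, unique count/percent and max EC size
    per policy, gaps) plus an 'average' footer row of column means.
    """
    registry = registry if registry is not None else load_registry()
    rows = []
    if datasets is None:
        datasets = build_all_phi_datasets(cdm, registry)
    if not datasets:
        raise CdmPrivacyError("no PHI dataset could be built from the input CDM")
    for name, ds in datasets.items():
        limited, safe = build_policy_pair(ds)
        _, _, sum_l, sum_s = _profile_pair(limited, safe, k_max)
        gap = trust_gap(sum_l, sum_s)
        rows.append(
            {
                "variable": name,
                "n_records": ds.n_records,
                "unique_limited": sum_l.unique_records,
                "pct_unique_limited": sum_l.unique_percent,
                "max_ec_limited": sum_l.max_ec_size,
                "unique_safe_harbor": sum_s.unique_records,
                "pct_unique_safe_harbor": sum_s.unique_percent,
                "max_ec_safe_harbor": sum_s.max_ec_size,
                "gap_pct_unique": gap.gap_unique_percent,
                "gap_max_ec": gap.gap_max_ec,
            }
        )
    report = pd.DataFrame(rows)
    avg = {
        "variable": "average",
        "n_records": np.nan,
        "unique_limited": np.nan,
        "pct_unique_limited": report["pct_unique_limited"].mean(),
        "max_ec_limited": report["max_ec_limited"].mean(),
        "unique_safe_harbor": np.nan,
        "pct_unique_safe_harbor": report["pct_unique_safe_harbor"].mean(),
        "max_ec_safe_harbor": report["max_ec_safe_harbor"].mean(),
        "gap_pct_unique": aggregate_over_experiments(report["gap_pct_unique"]),
        "gap_max_ec": report["gap_max_ec"].mean(),
    }
    return pd.concat([report, pd.DataFrame([avg])], ignore_index=True)


# ---------------------------------------------------------------------------
# scenario (QI) experiment
# ---------------------------------------------------------------------------

def build_all_scenario_datasets(
    cdm: CdmTableSet,
    registry: SchemaRegistry,
    scenarios: Mapping[str, ScenarioSpec] | None = None,
) -> dict[str, AnalysisDataset]:
    scenarios = scenarios if scenarios is not None else default_scenarios(registry)
    out: dict[str, AnalysisDataset] = {}
    for name, spec in scenarios.items():
        try:
            ds = build_scenario_dataset(cdm, spec)
        except CdmPrivacyError as exc:
            logger.warning("skipping scenario %s: %s", name, exc)
            continue
        logger.info(
            "built scenario %s: %d records, %d columns (%d null rows dropped)",
            name, ds.n_records, len(ds.columns), ds.dropped_nulls,
        )
        out[name] = ds
    return out


def run_qi_experiment(
    cdm: CdmTableSet,
    registry: SchemaRegistry | None = None,
    scenarios: Mapping[str, ScenarioSpec] | None = None,
    k_max: int = 20,
    datasets: Mapping[str, AnalysisDataset] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scenario comparison under both policies.

    Returns (summary, distribution): the summary has one row per scenario
    with percent/record count at class sizes 1, 2 and 5 per policy and
    the three gaps, plus an average row; the distribution is the long
    k = 1..k_max percent table per dataset x policy.
    """
    registry = registry if registry is not None else load_registry()
    if datasets is None:
        datasets = build_all_scenario_datasets(cdm, registry, scenarios)
    if not datasets:
        raise CdmPrivacyError("no scenario dataset could be built from the input CDM")
    rows, dist_rows = [], []
    for name, ds in datasets.items():
        limited, safe = build_policy_pair(ds)
        prof_l, prof_s, sum_l, sum_s = _profile_pair(limited, safe, k_max)
        gap = trust_gap(sum_l, sum_s)
        row: dict = {"scenario": name, "n_records": ds.n_records}
        for k in (1, 2, 5):
            row[f"pct_k{k}_limited"] = sum_l.percent_at_size[k]
            row[f"records_k{k}_limited"] = prof_l.record_count(k)
            row[f"pct_k{k}_safe_harbor"] = sum_s.percent_at_size[k]
            row[f"records_k{k}_safe_harbor"] = prof_s.record_count(k)
            row[f"gap_k{k}"] = gap.gap_percent_at_size[k]
        rows.append(row)
        for policy, summ in (("limited", sum_l), ("safe_harbor", sum_s)):
            for k in range(1, k_max + 1):
                dist_rows.append(
                    {
                        "dataset": name,
                        "policy": policy,
                        "k": k,
                        "percent": summ.percent_at_size[k],
                    }
                )
    summary = pd.DataFrame(rows)
    avg: dict = {"scenario": "average", "n_records": np.nan}
    for k in (1, 2, 5):
        for col in (f"pct_k{k}_limited", f"records_k{k}_limited",
                    f"pct_k{k}_safe_harbor", f"records_k{k}_safe_harbor"):
            avg[col] = np.nan
        avg[f"gap_k{k}"] = aggregate_over_experiments(summary[f"gap_k{k}"])
    summary = pd.concat([summary, pd.DataFrame([avg])], ignore_index=True)
    return summary, pd.DataFrame(dist_rows)


# ---------------------------------------------------------------------------
# sampling experiment
# ---------------------------------------------------------------------------

def run_sampling_experiment(
    datasets: Mapping[str, AnalysisDataset],
    sample_sizes: Sequence[int] = DEFAULT_SAMPLE_SIZES,
    iterations: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Equal-n paired sampling grid over datasets x sample sizes.

    One row per cell (mean (SD) unique count and percent per policy,
    gap); cells with n > N are marked not-applicable; each sample size
    gets an average row over its applicable cells.
    """
    rows = []
    for n in sample_sizes:
        gaps = []
        for name, ds in datasets.items():
            limited, safe = build_policy_pair(ds)
            res = paired_sample_experiment(
                limited, safe, n=n, iterations=iterations, seed=seed, name=name
            )
            if res.skipped:
                logger.info("sampling %s at n=%d skipped (N=%d)", name, n, ds.n_records)
                rows.append(
                    {
                        "dataset": name,
                        "n": n,
                        "applicable": False,
                        "mean_limited": np.nan,
                        "sd_limited": np.nan,
                        "pct_limited": np.nan,
                        "mean_safe_harbor": np.nan,
                        "sd_safe_harbor": np.nan,
                        "pct_safe_harbor": np.nan,
                        "gap": np.nan,
                    }
                )
                continue
            rows.append(
                {
                    "dataset": name,
                    "n": n,
                    "applicable": True,
                    "mean_limited": res.limited.mean_unique,
                    "sd_limited": res.limited.sd_unique,
                    "pct_limited": res.limited.percent,
                    "mean_safe_harbor": res.safe_harbor.mean_unique,
                    "sd_safe_harbor": res.safe_harbor.sd_unique,
                    "pct_safe_harbor": res.safe_harbor.percent,
                    "gap": res.gap_percent,
                }
            )
            gaps.append(res.gap_percent)
        avg_row = {
            "dataset": "average",
            "n": n,
            "applicable": bool(gaps),
            "mean_limited": np.nan,
            "sd_limited": np.nan,
            "pct_limited": np.nanmean([r["pct_limited"] for r in rows if r["n"] == n and r["applicable"]]) if gaps else np.nan,
            "mean_safe_harbor": np.nan,
            "sd_safe_harbor": np.nan,
            "pct_safe_harbor": np.nanmean([r["pct_safe_harbor"] for r in rows if r["n"] == n and r["applicable"]]) if gaps else np.nan,
            "gap": aggregate_over_experiments(gaps) if gaps else np.nan,
        }
        rows.append(avg_row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def _render_text(df: pd.DataFrame) -> str:
    return df.to_string(index=False, na_rep="NA") + "\n"


def run_all(config: RunConfig) -> dict[str, Path]:
    """Execute every stage and write CSV reports (plus human-readable text
    renderings and dataset manifests) under ``config.out_dir``."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    registry = load_registry(config.profile)
    cdm = config.load_cdm()
    logger.info("input CDM row counts: %s", cdm.row_counts())

    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        rounded = _round(df)
        path = out / f"{name}.csv"
        rounded.to_csv(path, index=False)
        (out / f"{name}.txt").write_text(_render_text(rounded))
        written[name] = path

    phi_datasets = build_all_phi_datasets(cdm, registry)
    scenario_datasets = build_all_scenario_datasets(cdm, registry, config.scenarios)

    phi_report = run_phi_experiment(cdm, registry, k_max=config.k_max, datasets=phi_datasets)
    emit("phi_report", phi_report)

    qi_report, distribution = run_qi_experiment(
        cdm, registry, config.scenarios, k_max=config.k_max, datasets=scenario_datasets
    )
    emit("qi_report", qi_report)
    emit("qi_distribution", distribution)
    emit(
        "sampling_phi",
        run_sampling_experiment(
            phi_datasets, config.sample_sizes, config.iterations, config.seed
        ),
    )
    emit(
        "sampling_qi",
        run_sampling_experiment(
            scenario_datasets, config.sample_sizes, config.iterations, config.seed
        ),
    )

    manifest = {
        "seed": config.seed,
        "profile": config.profile,
        "sample_sizes": list(config.sample_sizes),
        "iterations": config.iterations,
        "cdm_row_counts": cdm.row_counts(),
        "datasets": [ds.manifest() for ds in (*phi_datasets.values(), *scenario_datasets.values())],
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    written["manifest"] = manifest_path
    return written
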