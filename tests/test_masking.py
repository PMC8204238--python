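import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdmprivacy import (
    DataError,
    MISSING_TOKEN,
    MaskPolicy,
    MaskRule,
    SUPPRESSED_TOKEN,
    apply_policy,
    build_phi_dataset,
    equivalence_profile,
    mask_value,
    max_ec_size,
    unique_record_percent,
)


class TestMaskValue:
    @pytest.mark.parametrize(
        "value,rule,expected",
        [
            ("2008-03-14", MaskRule.YEAR_ONLY, "2008-**-**"),
            (dt.date(2010, 12, 31), MaskRule.YEAR_ONLY, "2010-**-**"),
            (np.datetime64("2009-06-01"), MaskRule.YEAR_ONLY, "2009-**-**"),
            ("2008-**-**", MaskRule.YEAR_ONLY, "2008-**-**"),  # idempotent
            (MISSING_TOKEN, MaskRule.YEAR_ONLY, MISSING_TOKEN),
            ("1234567890", MaskRule.SUPPRESS, SUPPRESSED_TOKEN),
            (42, MaskRule.SUPPRESS, SUPPRESSED_TOKEN),
            ("anything", MaskRule.NONE, "anything"),
            (42, MaskRule.NONE, 42),
        ],
    )
    def test_rules(self, value, rule, expected):
        assert mask_value(value, rule) == expected

    def test_unparseable_date_raises(self):
        with pytest.raises(DataError):
            mask_value("not-a-date", MaskRule.YEAR_ONLY)

    def test_unparseable_date_in_frame_names_row_and_column(self, micro_cdm, registry):
        ds = build_phi_dataset(micro_cdm, registry.get("death", "death_date"), registry)
        ds.frame["death_date"] = ["garbage"]
        with pytest.raises(DataError, match="death_date.*row 0"):
            apply_policy(ds, MaskPolicy.safe_harbor())


class TestApplyPolicy:
    def test_limited_is_identity(self, toy_cdm, registry):
        ds = build_phi_dataset(toy_cdm, registry.get("provider", "npi"), registry)
        out = apply_policy(ds, MaskPolicy.limited())
        pd.testing.assert_frame_equal(out.frame, ds.frame)

    def test_safe_harbor_masks_only_phi_columns(self, toy_cdm, registry):
        ds = build_phi_dataset(
            toy_cdm, registry.get("visit_occurrence", "visit_start_date"), registry
        )
        out = apply_policy(ds, MaskPolicy.safe_harbor())
        assert out.frame["visit_start_date"].str.match(r"^\d{4}-\*\*-\*\*$").all()
        for col in ("year_of_birth", "gender_concept_id", "state"):
            pd.testing.assert_series_equal(out.frame[col], ds.frame[col])

    def test_row_alignment_preserved(self, toy_cdm, registry):
        ds = build_phi_dataset(
            toy_cdm, registry.get("condition_occurrence", "condition_end_date"), registry
        )
        out = apply_policy(ds, MaskPolicy.safe_harbor())
        assert len(out.frame) == len(ds.frame)
        years = pd.to_datetime(ds.frame["condition_end_date"]).dt.year
        masked_years = out.frame["condition_end_date"].str[:4].astype(int)
        assert (years.to_numpy() == masked_years.to_numpy()).all()

    def test_suppression_collapses_to_one_token(self, toy_cdm, registry):
        ds = build_phi_dataset(toy_cdm, registry.get("provider", "npi"), registry)
        out = apply_policy(ds, MaskPolicy.safe_harbor())
        assert (out.frame["npi"] == SUPPRESSED_TOKEN).all()

    def test_idempotence(self, toy_cdm, registry):
        ds = build_phi_dataset(toy_cdm, registry.get("death", "death_date"), registry)
        once = apply_policy(ds, MaskPolicy.safe_harbor())
        twice = apply_policy(once, MaskPolicy.safe_harbor())
        pd.testing.assert_frame_equal(twice.frame, once.frame)

    def test_constant_column_mask_preserves_ec_structure(self, registry):
        """Masking a PHI that is already constant (Day_of_birth == 1)
        cannot change the equivalence-class partition."""
        frame = pd.DataFrame(
            {
                "day_of_birth": [1] * 6,
                "year_of_birth": [1930, 1930, 1940, 1940, 1950, 1950],
                "gender_concept_id": [1, 1, 2, 2, 1, 2],
                "race_concept_id": [1] * 6,
                "ethnicity_concept_id": [1] * 6,
                "state": ["S1"] * 6,
            }
        )
        from cdmprivacy import AnalysisDataset

        cols = tuple(
            registry.get(t, c)
            for t, c in [
                ("person", "day_of_birth"),
                ("person", "year_of_birth"),
                ("person", "gender_concept_id"),
                ("person", "race_concept_id"),
                ("person", "ethnicity_concept_id"),
                ("location", "state"),
            ]
        )
        ds = AnalysisDataset("day_of_birth", cols, frame)
        before = equivalence_profile(ds).histogram
        after = equivalence_profile(apply_policy(ds, MaskPolicy.safe_harbor())).histogram
        assert before == after

    def test_policy_override_from_yaml(self, toy_cdm, registry, tmp_path):
        cfg = tmp_path / "policy.yaml"
        cfg.write_text(
            "name: custom\nbase: safe_harbor\noverrides:\n"
            "  - {table: visit_occurrence, column: visit_start_date, rule: suppress}\n"
        )
        policy = MaskPolicy.from_yaml(cfg)
        ds = build_phi_dataset(
            toy_cdm, registry.get("visit_occurrence", "visit_start_date"), registry
        )
        out = apply_policy(ds, policy)
        assert (out.frame["visit_start_date"] == SUPPRESSED_TOKEN).all()


@st.composite
def _masked_frames(draw):
    """Random mixed date/code frame; returned with its column specs."""
    n = draw(st.integers(1, 60))
    seed = draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(seed)
    years = rng.integers(2008, 2011, n)
    doy = rng.integers(0, 360, n)
    dates = (
        pd.to_datetime([f"{y}-01-01" for y in years])
        + pd.to_timedelta(doy, unit="D")
    ).strftime("%Y-%m-%d")
    frame = pd.DataFrame(
        {
            "death_date": dates,
            "county": [f"C{v}" for v in rng.integers(0, draw(st.integers(1, 8)), n)],
            "year_of_birth": rng.integers(1930, 1935, n),
            "state": [f"S{v}" for v in rng.integers(0, draw(st.integers(1, 5)), n)],
        }
    )
    return frame


@settings(max_examples=100, deadline=None, derandomize=True)
@given(frame=_masked_frames())
def test_masking_is_a_coarsening(registry, frame):
    """Safe harbor can only merge equivalence classes: the unique-record
    percent never rises and the maximum class size never shrinks."""
    from cdmprivacy import AnalysisDataset

    cols = tuple(
        registry.get(t, c)
        for t, c in [
            ("death", "death_date"),
            ("location", "county"),
            ("person", "year_of_birth"),
            ("location", "state"),
        ]
    )
    ds = AnalysisDataset("prop", cols, frame)
    masked = apply_policy(ds, MaskPolicy.safe_harbor())
    prof, mprof = equivalence_profile(ds), equivalence_profile(masked)
    assert unique_record_percent(mprof) <= unique_record_percent(prof)
    assert max_ec_size(mprof) >= max_ec_size(prof)
    # records equal before masking remain equal: class count cannot grow
    assert mprof.n_classes <= prof.n_classes
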