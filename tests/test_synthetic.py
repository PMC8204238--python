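import datetime as dt

import numpy as np
import pandas as pd
import pytest

from cdmprivacy import (
    ConfigurationError,
    EventModel,
    SyntheticConfig,
    build_phi_dataset,
    build_policy_pair,
    equivalence_profile,
    generate_cdm,
    presets,
    unique_record_percent,
)


class TestConfigValidation:
    def test_inverted_date_range_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(date_range=(dt.date(2010, 1, 1), dt.date(2008, 1, 1)))

    def test_bad_death_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(death_fraction=1.5)

    def test_zero_vocab_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(vocab_sizes={"state": 0})

    def test_unknown_event_model_rejected(self):
        with pytest.raises(ConfigurationError):
            EventModel("negative_binomial", 3.0)


class TestGeneration:
    def test_seed_determinism(self):
        cfg = presets()["toy"].with_seed(7)
        a, b = generate_cdm(cfg), generate_cdm(cfg)
        for name in a.table_names:
            pd.testing.assert_frame_equal(a[name], b[name])

    def test_different_seeds_differ(self):
        cfg = presets()["toy"]
        a = generate_cdm(cfg.with_seed(1))
        b = generate_cdm(cfg.with_seed(2))
        assert not a["visit_occurrence"].equals(b["visit_occurrence"])

    def test_death_bounded_and_unique(self):
        cdm = generate_cdm(SyntheticConfig(n_persons=100, death_fraction=0.1, seed=7))
        death = cdm["death"]
        assert len(death) == 10
        assert not death["person_id"].duplicated().any()

    def test_day_of_birth_constant(self, toy_cdm):
        assert toy_cdm["person"]["day_of_birth"].nunique() == 1
        assert toy_cdm["person"]["day_of_birth"].iloc[0] == 1

    def test_day_of_birth_varies_when_disabled(self):
        cdm = generate_cdm(SyntheticConfig(n_persons=200, day_of_birth_constant=False, seed=3))
        assert cdm["person"]["day_of_birth"].nunique() > 1

    def test_dates_within_range(self, toy_cdm):
        lo, hi = np.datetime64("2008-01-01"), np.datetime64("2010-12-31")
        for table, col in [
            ("visit_occurrence", "visit_start_date"),
            ("condition_occurrence", "condition_start_date"),
            ("death", "death_date"),
        ]:
            dates = toy_cdm[table][col]
            assert dates.min() >= lo and dates.max() <= hi

    def test_poisson_total_within_four_sd(self):
        cfg = SyntheticConfig(
            n_persons=1000,
            events={"visit_occurrence": EventModel("poisson", 12.0)},
            seed=1,
        )
        total = len(generate_cdm(cfg)["visit_occurrence"])
        sd = np.sqrt(12.0 * 1000)
        assert abs(total - 12_000) < 4 * sd

    def test_fixed_event_count(self):
        cfg = SyntheticConfig(
            n_persons=50, events={"measurement": EventModel("fixed", 3)}, seed=5
        )
        meas = generate_cdm(cfg)["measurement"]
        assert len(meas) == 150
        assert (meas.groupby("person_id").size() == 3).all()

    def test_no_nulls_in_generated_columns(self, toy_cdm):
        for name in toy_cdm.table_names:
            assert not toy_cdm[name].isna().any().any(), name

    def test_csv_roundtrip_preserves_shape(self, toy_cdm, tmp_path):
        toy_cdm.to_csv(tmp_path)
        from cdmprivacy import CdmTableSet

        back = CdmTableSet.from_csv(tmp_path)
        assert set(back.table_names) == set(toy_cdm.table_names)
        assert back.row_counts() == toy_cdm.row_counts()
        # ISO-8601 date serialisation
        assert back["death"]["death_date"].str.match(r"^\d{4}-\d{2}-\d{2}$").all()


class TestPresets:
    def test_required_presets_present(self):
        p = presets()
        assert {"synpuf_like", "toy"} <= set(p)

    def test_synpuf_like_window_is_three_years(self):
        cfg = presets()["synpuf_like"]
        assert cfg.date_range == (dt.date(2008, 1, 1), dt.date(2010, 12, 31))
        assert cfg.day_of_birth_constant

    def test_toy_is_small(self):
        assert presets()["toy"].n_persons <= 50

    def test_all_presets_validate(self):
        # construction runs validation; reaching here means all passed
        for name, cfg in presets().items():
            assert cfg.n_persons >= 1, name


def _masked_unique_percent(cdm, registry, table, column):
    ds = build_phi_dataset(cdm, registry.get(table, column), registry)
    _, safe = build_policy_pair(ds)
    return unique_record_percent(equivalence_profile(safe))


class TestStructuralEmulation:
    def test_single_occurrence_dates_stay_riskier_after_masking(self, registry):
        """A once-per-person date (death) keeps far more unique records
        after year-only masking than a many-per-person date (visit),
        because each deceased person contributes a single row against the
        full demographic cross-classification. Asserted over 5 seeds."""
        cfg = SyntheticConfig(
            n_persons=300,
            death_fraction=0.05,
            events={"visit_occurrence": EventModel("poisson", 20.0)},
        )
        for seed in range(5):
            cdm = generate_cdm(cfg.with_seed(seed))
            death = _masked_unique_percent(cdm, registry, "death", "death_date")
            visit = _masked_unique_percent(cdm, registry, "visit_occurrence", "visit_start_date")
            assert death > visit, f"seed {seed}: death {death} <= visit {visit}"

    def test_unique_fraction_monotone_in_vocab_size(self, registry):
        """Balls-and-bins: with row counts held fixed, widening a code
        vocabulary cannot lower the expected unique-record percentage
        (more bins, more single-ball bins). Asserted as a mean over 5
        seeds."""
        base = dict(n_persons=150, events={"condition_occurrence": EventModel("poisson", 6.0)})
        means = []
        for vocab in (5, 50, 500):
            vals = []
            for seed in range(5):
                cfg = SyntheticConfig(
                    **base, vocab_sizes={"condition_concept_id": vocab}, seed=seed
                )
                cond = generate_cdm(cfg)["condition_occurrence"]
                prof = equivalence_profile(
                    cond, ["condition_start_date", "condition_concept_id"]
                )
                vals.append(unique_record_percent(prof))
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]
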