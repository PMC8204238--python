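"""Full-data re-identification risk of one PHI under two policies.

Builds the six-column limited data set for the death date (the PHI plus
the five common demographics), applies the safe-harbor mask
("YYYY-MM-DD" -> "YYYY-**-**"), profiles the equivalence classes of
both versions and prints the trust differential gap: how many
percentage points of unique (singled-out) records the stricter policy
removes. A once-per-person date keeps almost all of its uniqueness even
after masking — the core finding this package quantifies.
"""

from cdmprivacy import (
    build_phi_dataset,
    build_policy_pair,
    equivalence_profile,
    generate_cdm,
    load_registry,
    max_ec_size,
    presets,
    risk_summary,
    trust_gap,
)

registry = load_registry("synpuf5pct")
cdm = generate_cdm(presets()["synpuf_like_small"].with_seed(1))

dataset = build_phi_dataset(cdm, registry.get("death", "death_date"), registry)
limited, safe = build_policy_pair(dataset)

sum_l = risk_summary(equivalence_profile(limited))
sum_s = risk_summary(equivalence_profile(safe))
gap = trust_gap(sum_l, sum_s)

print(f"dataset {dataset.name!r}: N = {dataset.n_records} records, "
      f"columns = {dataset.column_names}")
print(f"limited      unique {sum_l.unique_percent:7.3f}%  max EC size {sum_l.max_ec_size}")
print(f"safe harbor  unique {sum_s.unique_percent:7.3f}%  max EC size {sum_s.max_ec_size}")
print(f"trust differential gap (k=1): {gap.gap_unique_percent:.3f} percentage points")
print("A small gap with high residual uniqueness means safe harbor alone "
      "does not protect a once-per-person date.")
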