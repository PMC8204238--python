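"""Generate a synthetic OMOP CDM with claims-like structure.

The "synpuf_like_small" preset keeps the per-person event multiplicities
of a 5% Medicare claims extract (one death date per deceased person,
~48 visits and ~128 condition rows per person, a 2008-2010 event window,
Day_of_birth flattened to "1") at a 2,000-person population. Every table
is reproducible from the seed.
"""

from cdmprivacy import generate_cdm, presets

config = presets()["synpuf_like_small"].with_seed(1)
cdm = generate_cdm(config)

print(f"{config.n_persons} persons, window {config.date_range[0]}..{config.date_range[1]}")
for name, rows in sorted(cdm.row_counts().items()):
    print(f"  {name:24s} {rows:>8,} rows")
print("person.day_of_birth distinct values:", cdm["person"]["day_of_birth"].nunique())
print("deaths per person <= 1:", not cdm["death"]["person_id"].duplicated().any())
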