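"""Which CDM columns threaten privacy, and how are they masked?

Loads the built-in SynPUF-subset registry (16 PHIs / 12 QIs) and prints
the HIPAA-to-CDM classification: each row is one column with its privacy
role (phi / qi_demographic / qi_clinical) and the safe-harbor masking
rule it receives (year_only for dates, suppress for everything else
among the PHIs, none for QIs).
"""

from cdmprivacy import hipaa_map_report, load_registry

registry = load_registry("synpuf5pct")
print(hipaa_map_report(registry).to_string(index=False))
print(
    f"\n{len(registry.phis())} personal health identifiers, "
    f"{len(registry.qis())} quasi-identifiers "
    f"({len(registry.demographics())} demographic)."
)

full = load_registry("omop_full")
print(
    f"Full-CDM profile: {len(full.phis())} PHIs / {len(full.qis())} QIs "
    f"(editable YAML shipped with the package)."
)
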