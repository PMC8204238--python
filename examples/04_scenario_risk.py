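"""Quasi-identifier risk across the seven clinical study scenarios.

Each scenario data set mimics a real study extract (diagnosis,
procedure, drug treatment, lab test, device treatment, death, medical
history): eleven common variables plus the scenario's own dates and
order code. The report gives the percent of records at minimum cell
size 1, 2 and 5 under each policy and the gaps between policies; the
long-format distribution (k = 1..20) is what a minimum-cell-size figure
would plot.
"""

from cdmprivacy import generate_cdm, load_registry, presets, run_qi_experiment

registry = load_registry("synpuf5pct")
cdm = generate_cdm(presets()["synpuf_like_small"].with_seed(1))

summary, distribution = run_qi_experiment(cdm, registry)
cols = ["scenario", "n_records", "pct_k1_limited", "pct_k1_safe_harbor", "gap_k1"]
print(summary[cols].round(3).to_string(index=False))
print(f"\ndistribution export: {len(distribution)} rows "
      f"({distribution['dataset'].nunique()} scenarios x 2 policies x k=1..20)")
print("Records concentrated at k=1 under the limited policy are the "
      "re-identifiable ones; the gap column is the risk removed by safe harbor.")
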