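"""Full pipeline on the packaged synthetic three-supply scenario.

Generates 254 samples (98 private tapwater, 126 public tapwater, 30
bottled), runs ∑TQ, ∑EAR and ∑EAR-MED screening plus PERMANOVA, and
prints the group summaries and top mixture drivers.
"""

from dwscreen import run_default

result = run_default(seed=1)

print(f"samples: {result.manifest['n_samples']} "
      f"{result.manifest['group_sizes']}")

tq = result.tq_per_sample
for sup, sub in tq.groupby("supply_class"):
    frac = 100 * (sub["sum_tq"] > 1).mean()
    print(f"  {sup:10s}: {frac:5.1f}% of samples with ∑TQ > 1")

print("\nPERMANOVA across supplies (9999 permutations):")
print(result.permanova_results[["metric", "f_stat", "p_value"]].to_string(index=False))

print("\ntop ∑TQ drivers per supply:")
drv = result.driver_reports
print(drv.loc[drv["metric"] == "sum_tq"].groupby("supply_class").head(3).to_string(index=False))

print("\nHigh ∑TQ exceedance in every supply chain with distinct drivers —")
print("geogenic metals in private wells, disinfection byproducts in public")
print("tapwater — mirrors the qualitative structure the scenario encodes.")
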