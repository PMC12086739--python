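"""Bioactivity (∑EAR) screening with endpoint exclusion.

One public-tapwater sample with two organics, each carrying several
assay endpoints (one flagged baseline and therefore excluded).  Prints
the per-endpoint exposure-activity ratios and the per-sample ∑EAR.
"""

import pandas as pd

from dwscreen import compute_ear, filter_endpoints, summarize_sample_ear

detections = pd.DataFrame({
    "sample_id": ["tap-07", "tap-07"],
    "analyte_id": ["67-66-3", "1912-24-9"],
    "analyte_class": ["DBP", "pesticide"],
    "concentration": [30.0, 0.4],   # μg/L
    "detected": [True, True],
})

acc = pd.DataFrame({
    "analyte_id": ["67-66-3", "67-66-3", "1912-24-9", "1912-24-9"],
    "endpoint_id": ["ep_a", "ep_b", "ep_c", "ep_d"],
    "acc_ugL": [4776.0, 14325.0, 431.0, 1941.0],
    "flag_nonspecific": [False, False, False, False],
    "flag_baseline": [False, True, False, False],   # ep_b excluded
    "flag_unreliable": [False, False, False, False],
})

kept, removals = filter_endpoints(acc)
print(f"retained {len(kept)} of {len(acc)} endpoints "
      f"(removed per flag: {removals.to_dict()})")

ear = compute_ear(detections, kept)
print("\nper-endpoint EAR:")
print(ear.to_string(index=False))

samples = pd.DataFrame({"sample_id": ["tap-07"], "supply_class": ["public_tw"]})
summary, contributions = summarize_sample_ear(ear, samples)
print("\nper-sample summary (max endpoint per chemical, then summed):")
print(summary.to_string(index=False))
print("\n∑EAR above the 0.001 screening level flags the sample for further")
print("characterization of potential molecular-level effects.")
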