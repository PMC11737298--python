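"""Classify light-chain escape from serial clinical labs.

Simulates 200 patients' M-spike / free-light-chain trajectories (30% with
the escape pattern) and applies the three-criterion rule: (i) a visit with
dFLC > 10 mg/dL while M-spike < 1 g/dL, (ii) diagnosis M-spike > 1 g/dL,
(iii) exclusion when light-chain rises track M-spike rises.
"""
import pandas as pd

from mmlce.cohort import classify_lce, classify_lce_many
from mmlce.simulate import LabsSimSpec, simulate_clinical_series

series, truth = simulate_clinical_series(
    LabsSimSpec(seed=3, n_patients=200, fraction_lce=0.3))
calls = classify_lce_many(series)

merged = calls.join(truth, rsuffix="_truth")
tp = (merged["lce"] & merged["lce_truth"]).sum()
fn = (~merged["lce"] & merged["lce_truth"]).sum()
fp = (merged["lce"] & ~merged["lce_truth"]).sum()
tn = (~merged["lce"] & ~merged["lce_truth"]).sum()
print(f"{len(calls)} patients, {int(calls['lce'].sum())} called LCE")
print(f"sensitivity {tp/(tp+fn):.3f}, specificity {tn/(tn+fp):.3f}")
print("\ncalls by planted pattern:")
print(pd.crosstab(merged["pattern"], merged["lce"]).to_string())

# one escaped patient in detail
pid = merged.index[merged["lce"] & merged["lce_truth"]][0]
call = classify_lce(next(s for s in series if s.patient_id == pid))
print(f"\npatient {pid}: c1={call.c1} (dFLC high while M-spike low), "
      f"c2={call.c2} (secretory at diagnosis), "
      f"c3_exclusion={call.c3_exclusion} -> LCE={call.lce}")
print("dFLC trajectory (mg/dL by day):")
print(call.dflc.round(1).to_string())
# The escape signature: dFLC collapses with induction, then climbs at
# relapse while the M-spike stays suppressed below 1 g/dL.
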