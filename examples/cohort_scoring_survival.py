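"""Score a bulk cohort with a gene signature and associate the strata with
osteolysis and overall survival.

Simulates a 400-sample cohort in which a latent quarter of samples carry
the signature (log2 shift 1.5 on 50 genes), more 3+ lesion categories and
shorter survival; then recovers that structure with the summed z-score.
"""
import pandas as pd

from mmlce.cohort import compare_survival, geneset_score, lesion_association, \
    stratify
from mmlce.simulate import CohortSimSpec, simulate_bulk_cohort
from mmlce.types import GeneSet

spec = CohortSimSpec(seed=3, n_samples=400)
cohort, truth = simulate_bulk_cohort(spec)
sig = GeneSet(name="LCE_MM", up_genes=spec.signature_genes)

st = stratify(geneset_score(cohort, sig), m=1.0)  # cuts at mean +/- 1 SD
counts = st.strata.value_counts().to_dict()
print(f"strata (score > mean+1SD high, < mean-1SD low): {counts}")

called = st.strata[st.strata.isin(["high", "low"])]
acc = ((called == "high") == truth.loc[called.index, "latent_high"]).mean()
print(f"latent group recovered among called samples: accuracy {acc:.2f}")

res = compare_survival(cohort, called, endpoint="os")
print(f"OS, high vs low stratum: HR {res.hr:.2f} "
      f"[{res.ci_low:.2f}, {res.ci_high:.2f}], log-rank p {res.logrank_p:.2g}, "
      f"median OS high {res.medians['high']:.1f} vs low "
      f"{res.medians['low'] if res.medians['low'] != float('inf') else '>8'} years")

lyt = compare_survival(cohort, called, endpoint="lytic")
print(f"time to diffuse lytic lesions: HR {lyt.hr:.2f} "
      f"[{lyt.ci_low:.2f}, {lyt.ci_high:.2f}]")

assoc = lesion_association(st, cohort)
print("high/low x lesion-burden table (rows high, low; cols >=3, <3):")
print(assoc.table.to_string())
print(f"Fisher exact p = {assoc.fisher_p:.3g}; "
      f"Welch t on lesion counts p = {assoc.t_p:.3g} "
      f"(means {assoc.group_means['high']:.1f} vs {assoc.group_means['low']:.1f})")
# An HR well above 1 with a small p says the signature-high stratum fares
# worse, mirroring the planted hazard ratios (2.73 OS, 2.99 lytic).
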