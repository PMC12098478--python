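"""Simulate a clinical cohort from the exponential/volume-based model.

Each patient carries a latent trajectory (tumour volume, metastasis jump
times, death time) read out at monthly visits with 10% proportional size
noise; death is recorded at its exact time.  Note that the deceased show
a *lower* final metastasis count than the censored: their follow-up is
shorter, so they had less time to accumulate jumps -- a reminder that
visit-level summaries of coupled processes need the joint likelihood, not
naive group means.
"""

import numpy as np

from oncotraj import StudyDesign, get_model, mask_missing, simulate_cohort
from oncotraj.io import write_cohort

model = get_model("m1")
cohort = simulate_cohort(model, 500, StudyDesign(), seed=1)

deaths = [r for r in cohort if r.died]
alive = [r for r in cohort if not r.died]
count = lambda rs: np.mean([np.nanmax(r.n_metastases) for r in rs])
print(f"patients: {len(cohort)}, deaths within 30 months: {len(deaths)}")
print(f"mean final metastasis count  died: {count(deaths):.2f}   censored: {count(alive):.2f}")
print(f"median survival of the deceased: {np.median([r.times[-1] for r in deaths]):.1f} months")

# registry-style missingness: 30% of visits dropped, 20% of fields masked
sparse = mask_missing(cohort, 0.3, 0.2, 0.2, seed=2)
n_rows = sum(r.times.size for r in cohort)
n_sparse = sum(r.times.size for r in sparse)
print(f"rows before/after visit dropping: {n_rows} -> {n_sparse}")

write_cohort(sparse, "scratch_cohort.csv")
print("wrote scratch_cohort.csv (+ .meta.json provenance sidecar)")
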