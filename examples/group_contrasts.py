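"""Group-level selected-vs-other contrasts on a small synthetic batch.

Simulates a batch of hemispheres, runs the localization pipeline on each,
and contrasts the selected track against the mean of the other tracks with
paired Wilcoxon tests: beta and HFO band power per border-relative region,
and beta-HFO coupling strength (slow HFO dorsally, fast HFO ventrally).
Also simulates paired OFF/ON clinical scores and summarizes improvement.

Eight STNs keep this example quick; the full analysis uses 19.
"""

import numpy as np

from stnmer import improvement_pct, simulate_clinical_scores
from stnmer.cohort import cohort_tables, simulate_cohort
from stnmer.stats import contrast_selected_vs_other

cohort = simulate_cohort(n_stn=8, base_seed=7)
power, coupling = cohort_tables(cohort)

print("band-power contrasts (selected vs mean of other tracks):")
print(contrast_selected_vs_other(power).to_string(index=False))
print("\ncoupling contrasts:")
print(contrast_selected_vs_other(coupling).to_string(index=False))

pairs = simulate_clinical_scores(n_hemispheres=8, effect=0.518,
                                 dispersion=0.15, seed=7)
imp = [improvement_pct(off, on) for off, on in pairs]
print(f"\nsimulated OFF/ON scores: {pairs}")
print(f"mean contralateral motor improvement: {np.mean(imp):.1f}%")
# Small p-values mean the pipeline's selected track carries systematically
# higher in-STN band power and coupling than its neighbours, as built into
# the generator; the improvement percentage tracks the generator's effect.
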