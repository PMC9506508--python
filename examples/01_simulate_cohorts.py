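"""Generate a synthetic two-cohort ancestry/metabolomics study.

Builds reference panels at 84 ancestry-informative markers, two admixed
hypertensive cohorts with a bimodal West African ancestry (GWAA)
distribution, and metabolite matrices with planted differential clusters,
then prints the headline properties of the generated data.
"""

import numpy as np

from admixmet import simulate_study

study = simulate_study(seed=1)

q = study.discovery.q_true
low, high = q[q < 0.45], q[q >= 0.45]
print(f"discovery cohort: n={len(q)} "
      f"({len(low)} low-GWAA, {len(high)} high-GWAA)")
print(f"true GWAA medians: low {low.median():.1%}, high {high.median():.1%}")
# low ~1.6% and high ~85% mirror the bimodal ancestry mix of a US
# hypertensive cohort

diffs = (study.markers["p_AFR"] - study.markers["p_EUR"]).abs()
print(f"AIM frequency differentials: min {diffs.min():.2f} (all >= 0.30)")

raw = study.discovery.metabolome
print(f"metabolome: {raw.shape[0]} samples x {raw.shape[1]} metabolites, "
      f"{raw.isna().to_numpy().mean():.1%} missing")
meta = study.truth.metabolites
print("planted differential clusters:",
      {lab: int((meta['cluster'] == lab).sum())
       for lab in study.truth.differential_labels})

cov = study.discovery.covariates
hi = q.to_numpy() >= 0.45
print(f"baseline PRA medians: low {np.median(cov['pra'][~hi]):.2f}, "
      f"high {np.median(cov['pra'][hi]):.2f} ng/mL/h")
# PRA is systematically lower in the high-GWAA group, as in hypertensive
# cohorts
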