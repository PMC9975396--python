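"""The full pipeline: localize which network pairs drive the deviation.

Runs simulation, feature extraction, normative-model training and the
deviation statistics in one call, then shows that the edges flagged as
characteristic of the synthetic patient group are the edges that were
actually perturbed.
"""

import numpy as np

from fcnorm import RunConfig, run_pipeline
from fcnorm.atlas import DEFAULT_ATLAS
from fcnorm.simulate import default_config

config = RunConfig(cohort=default_config(seed=0), seed=0)
report = run_pipeline(config)

print("group comparisons (Mann-Whitney on MSE_s, raw p-values):")
for c in report.comparisons:
    print(f"  {c.group_a:11s} vs {c.group_b:11s}  "
          f"medians {c.median_a:.3f}/{c.median_b:.3f}  p = {c.p_value:.2g}")

print(f"\nmerged deviation threshold (z-units): {report.threshold:.3f}")
print("median node degree, healthy vs SCZ:")
print(" ", dict(zip(DEFAULT_ATLAS.labels, report.degree_medians["H-Test-U"])))
print(" ", dict(zip(DEFAULT_ATLAS.labels, report.degree_medians["SCZ-Test-U"])))

for group in ("SCZ-Test-U", "BD-Test-U", "ADHD-Test-U"):
    truth = {tuple(sorted(p, key=DEFAULT_ATLAS.index))
             for (p, _) in config.cohort.perturbations[group]}
    char = report.characterizations[group].characteristic
    print(f"\n{group}: injected {sorted(truth)}")
    print(f"  characteristic pairs found: {sorted(char)}")
    print(f"  injected pairs recovered: {len(truth & set(char))}/{len(truth)}")

mat, ids, flags = report.individual["SCZ-Test-U"]
print(f"\nindividual-level matrix: {mat.shape[0]} subjects x "
      f"{mat.shape[1]} characteristic pairs")
print(f"subjects above the healthy median on >= half the pairs: "
      f"{int(flags.sum())}/{len(ids)}")
print("group-level abnormality does not hold uniformly at the individual "
      "level: deviation profiles vary within the patient group.")
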