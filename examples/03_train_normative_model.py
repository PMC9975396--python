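"""Train the normative autoencoder on healthy controls and score deviation.

The model learns to reconstruct healthy connectivity vectors through a
13-unit bottleneck. Held-out healthy subjects reconstruct well; subjects
with injected abnormal edges reconstruct worse, which is the per-subject
deviation score MSE_s.
"""

import numpy as np

from fcnorm import (
    AutoencoderSpec,
    apply_standardizer,
    correlation_matrix,
    cross_validate,
    fit_standardizer,
    normalize_selection_metrics,
    reconstruct,
    train_autoencoder,
    vectorize_cohort,
)
from fcnorm.simulate import default_config, generate_cohort

cohort = generate_cohort(default_config(seed=0, include_replication=False))


def features(group):
    ids = cohort.subjects(group)
    return vectorize_cohort(
        [correlation_matrix(cohort.timeseries[s]) for s in ids], ids
    ).to_numpy()


train = features("H-Train")
std = fit_standardizer(train)  # mean/SD from the 200 training subjects only
spec = AutoencoderSpec(epochs=300, seed=0)
model = train_autoencoder(spec, apply_standardizer(std, train), std)
print(f"training loss: first epoch {model.history[0]:.3f}, "
      f"last epoch {model.history[-1]:.3f}")

for group in ("H-Test-U", "SCZ-Test-U", "BD-Test-U", "ADHD-Test-U"):
    res = reconstruct(model, apply_standardizer(std, features(group)))
    print(f"median MSE_s {group}: {np.median(res.mse_s):.3f}")
print("patients deviate more from the healthy norm than held-out healthy "
      "subjects: their median reconstruction error is higher.")

# cross-validation and the two normalized model-selection metrics
report = cross_validate(
    spec.with_(epochs=150), apply_standardizer(std, train), fold_count=10
)
print(f"\n10-fold CV: performance {report.performance:.3f}, "
      f"generalization gap {report.generalization_gap:+.3f}")
candidates = [
    (report.performance, report.generalization_gap),
    (report.performance * 1.2, report.generalization_gap * 0.5),
    (report.performance * 0.9, report.generalization_gap * 2.0),
]
norm, best = normalize_selection_metrics(candidates)
print(f"normalized candidate metrics:\n{norm.round(3)}\nselected candidate: {best}")
print("the selected architecture minimizes the sum of min-max-normalized "
      "reconstruction performance and generalization gap.")
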