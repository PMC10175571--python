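"""Train the one-hot CNN on a planted-motif benchmark and evaluate it.

Generates a separable synthetic benchmark (crosstalk-like compositional bias
vs uniform background), trains CNN_OH on the cross-validation pool with early
stopping, calibrates the decision threshold to the target specificity 0.694,
and reports SN/SP/ACC/MCC/AUC on the independent test group.

Takes a couple of minutes on one CPU.
"""

import numpy as np

from psadpr import (
    ModelConfig, calibrate_threshold, encode, evaluate,
    generate_crosstalk_benchmark, predict, train,
)

windows, labels, plan = generate_crosstalk_benchmark(
    1000, 1000, effect_size=1.0, seed=7)
X = encode(windows, "OH")

cv = plan.cv_indices
val_mask = np.isin(cv, plan.groups[plan.cv_group_ids[-1]])
tr, va = cv[~val_mask], cv[val_mask]

config = ModelConfig(encoding="OH", max_epochs=10, patience=3, seed=7)
model = train(config, X[tr], labels[tr], X[va], labels[va])
print("epochs trained:", len(model.history),
      "best val AUC:", round(max(h["val_auc"] for h in model.history), 4))

# threshold: smallest score cutting off 69.4% of validation negatives
va_scores = predict(model, X[va])
model.threshold = calibrate_threshold(va_scores[labels[va] == 0],
                                      target_specificity=0.694)
print("calibrated threshold:", round(model.threshold, 4))

test = plan.test_indices
report = evaluate(labels[test], predict(model, X[test]), model.threshold)
print(f"independent test (n={report.n}): "
      f"SN={report.SN:.3f} SP={report.SP:.3f} ACC={report.ACC:.3f} "
      f"MCC={report.MCC:.3f} AUC={report.AUC:.3f}")
# AUC near 1 reflects the planted motif's strength; SP sits near the 0.694
# calibration target by construction
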