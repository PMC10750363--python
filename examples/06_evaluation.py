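"""Patient-level folds, the metric suite, and rater reproduction."""

import numpy as np

from gaitpipe.evaluation import (RaterRatios, aggregate_cv, auroc, confusion,
                                 accuracy, f1, report_from_ratios,
                                 stratified_group_kfold)

# --- stratified group folds: 54 ASD + 27 non-ASD patients, k = 5
labels = {f"A{i}": "ASD" for i in range(54)}
labels.update({f"B{i}": "non-ASD" for i in range(27)})
fa = stratified_group_kfold(labels, k=5, seed=0)
sizes = [len(f) for f in fa]
balance = [sum(labels[p] == "ASD" for p in f) for f in fa]
print(f"validation fold sizes {sizes}, ASD per fold {balance}")
# Folds partition the 81 patients into {17,16,16,16,16} with the global
# 2:1 class ratio preserved within one patient per fold.

# --- clip-level metrics on toy predictions
y_true = ["ASD"] * 6 + ["non-ASD"] * 4
y_pred = ["ASD"] * 5 + ["non-ASD"] * 5
scores = [0.9, 0.8, 0.85, 0.7, 0.6, 0.4, 0.3, 0.35, 0.2, 0.1]
cm = confusion(y_true, y_pred)
print(f"accuracy {accuracy(cm):.3f}  F1(ASD) {f1(cm, 'ASD'):.3f}  "
      f"AUROC {auroc(y_true, scores):.3f}")

# --- published clinician rows, reconstructed from printed ratios
for name, ratios in (
    ("doctor 1", RaterRatios(0.4074, 0.5926, 0.3704, 0.6296, 54, 27)),
    ("doctor 2", RaterRatios(0.4815, 0.5185, 0.3889, 0.6111, 54, 27)),
):
    r = report_from_ratios(ratios, positive_label="non-ASD")
    print(f"{name}: accuracy {r.accuracy:.4f}  F1 {r.f1:.4f}  "
          f"AUROC {r.auroc:.4f}")
# doctor 1: 0.4815 / 0.4474 / 0.5185 — near-chance on 1-second videos.

print(f"CV mean of (0.7495, 0.7600, 0.7582): "
      f"{aggregate_cv([0.7495, 0.7600, 0.7582]):.4f}")
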