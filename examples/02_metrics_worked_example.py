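"""Five evaluation metrics on a near-perfect 6-class test set.

Constructs the classic single-error scenario: 72 test samples, 12 per class,
with exactly one class-1 sample predicted as class 5.  Prints overall
accuracy, macro precision/recall, macro F1 and Cohen's kappa.  One error in
72 balanced samples costs about 1.4 accuracy points and 1.7 kappa points —
kappa penalises harder because it discounts chance agreement.
"""

import numpy as np

from enoseda import compute_metrics

y_true = np.repeat(np.arange(6), 12)
y_pred = y_true.copy()
y_pred[np.flatnonzero(y_true == 1)[0]] = 5  # the single cross-class error

report = compute_metrics(y_true, y_pred, n_classes=6)
print("confusion diagonal:", np.diag(report.confusion))
print(f"overall accuracy : {report.overall_accuracy:.4f}")
print(f"precision (macro): {report.macro_precision:.4f}")
print(f"recall    (macro): {report.macro_recall:.4f}")
print(f"F1        (macro): {report.f1_macro:.4f}")
print(f"Cohen's kappa    : {report.kappa:.4f}")
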