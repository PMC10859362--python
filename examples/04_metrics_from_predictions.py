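"""Evaluation metrics from raw label sequences.

Shows the confusion-matrix reduction and the four metrics (precision,
recall, F1, accuracy) with macro and micro summaries, including how
undefined per-class ratios are excluded from the macro mean.
"""

import json

from fruitnet import confusion_matrix, metric_report, one_vs_rest_counts

y_true = [0, 0, 0, 1, 1, 2, 2, 2, 2, 3]
y_pred = [0, 0, 1, 1, 1, 2, 2, 0, 2, 2]

cm = confusion_matrix(y_true, y_pred, n_classes=4)
print("confusion matrix (rows = true, cols = predicted):")
print(cm.counts)
for k in range(4):
    print(f"class {k}: TP/FP/FN/TN = {one_vs_rest_counts(cm, k)}")

report = metric_report(cm)
print(json.dumps(report.to_dict(), indent=2))
# class 3 is never predicted -> its precision is undefined (null) and it is
# excluded from the macro averages; accuracy = trace/total = 7/10.
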