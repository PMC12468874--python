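"""Per-class metrics from a confusion matrix.

Uses the reference confusion counts of the full-corpus evaluation (2695
healthy and 802 unhealthy correct, 30 and 14 misclassified) and prints the
four per-class metrics as percentages rounded half-up to two decimals.
Note sensitivity of one class equals specificity of the other — a binary
identity, useful as a sanity check on any reported table.
"""

import numpy as np

from heartpcg.classify_eval import ConfusionMatrix, confusion_metrics

cm = ConfusionMatrix(np.array([[2695, 30], [14, 802]]))
print(f"N = {cm.total}, accuracy = {100 * cm.accuracy:.2f}%")
print(f"{'Class':<12}{'Sens':>8}{'Spec':>8}{'Prec':>8}{'F1':>8}")
for cls in ("healthy", "unhealthy"):
    m = confusion_metrics(cm, cls)
    print(f"{cls:<12}{m['sensitivity']:>8.2f}{m['specificity']:>8.2f}"
          f"{m['precision']:>8.2f}{m['f1']:>8.2f}")
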