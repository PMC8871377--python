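"""Reproduce the benchmark evaluation tables from their confusion counts.

The two public OCT test sets' results are fully determined by four
integers each: TP / FN / FP / TN with AMD positive.  This script rebuilds
the per-class and support-weighted metric rows from those counts alone.
"""

from octanomaly.metrics import ConfusionMatrix, class_metrics, round_half_up, weighted_metrics

for name, cm in [
    ("UCSD test set (500 AMD / 250 normal)", ConfusionMatrix(tp=500, fn=0, fp=1, tn=249)),
    ("Duke test set (723 AMD / 1407 normal)", ConfusionMatrix(tp=687, fn=36, fp=16, tn=1391)),
]:
    print(f"\n{name}: TP={cm.tp} FN={cm.fn} FP={cm.fp} TN={cm.tn}")
    print(f"{'class':<18}{'acc%':>8}{'sens%':>8}{'prec%':>8}{'F1%':>8}")
    per = class_metrics(cm)
    for cls in ("AMD", "NORMAL"):
        r = [round_half_up(per[cls][m], 2)
             for m in ("accuracy", "sensitivity", "precision", "f1")]
        print(f"{cls:<18}{r[0]:>8}{r[1]:>8}{r[2]:>8}{r[3]:>8}")
    w = weighted_metrics(cm)
    r = [round_half_up(w[m], 2) for m in ("accuracy", "sensitivity", "precision", "f1")]
    print(f"{'weighted avg':<18}{r[0]:>8}{r[1]:>8}{r[2]:>8}{r[3]:>8}")
# Per-class 'accuracy' is that class's recall; the weighted row averages the
# per-class values by class support, which for recall equals global accuracy.
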