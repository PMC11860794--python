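"""Train the common-matrix classifier and classify held-out beats.

Four synthetic beat classes, 20 training and 50 test beats per class.
Prints the confusion matrix and per-class metrics; the common-matrix
scores W(i) of one test beat show how the minimum-distance assignment
works.
"""

import numpy as np

import fdmcma as f

specs = f.beat_class_library()[:4]
ds = f.generate_dataset(specs, n_train=20, n_test=50, seed=3)

train_pool, test_pool = {}, {}
for sig in ds.train:
    train_pool.setdefault(sig.label, []).append(f.process_signal(sig))
for sig in ds.test:
    test_pool.setdefault(sig.label, []).append(f.process_signal(sig))

clf = f.train(train_pool, d=20)

y_true, y_pred = [], []
for lab in sorted(test_pool):
    for mat in test_pool[lab]:
        y_true.append(lab)
        y_pred.append(f.classify(mat, clf).label)

cm = f.confusion_matrix(y_true, y_pred)
rep = f.compute_metrics(cm)
print("confusion matrix (rows = truth):", *cm.labels)
print(cm.counts)
for i, lab in enumerate(rep.labels):
    print(f"  {lab}: Sen {rep.sen[i]:6.2f}%  Spe {rep.spe[i]:6.2f}%  "
          f"Ppr {rep.ppr[i]:6.2f}%  F1 {rep.f1[i]:6.2f}%")
print(f"overall accuracy: {rep.oa:.2f}%")

probe = test_pool[sorted(test_pool)[0]][0]
pred = f.classify(probe, clf)
print(f"\none test beat, true class {y_true[0]!r} -> predicted {pred.label!r}")
for lab, w in sorted(pred.scores.items(), key=lambda kv: kv[1]):
    print(f"  W[{lab}] = {w:10.4f}   (squared Frobenius distance of common matrices)")
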