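"""Monte-Carlo cross-validation on the synthetic beat benchmark.

Pools 100 beats per class, draws 30 of each for training in every run and
tests on the remaining 70; repeats 5 times and reports mean +/- sd of the
overall accuracy and per-class sensitivity.
"""

import fdmcma as f

specs = f.beat_class_library()[:4]
ds = f.generate_dataset(specs, n_train=50, n_test=50, seed=11)

pool = {}
for sig in ds.train + ds.test:
    pool.setdefault(sig.label, []).append(f.process_signal(sig))

report = f.run_mccv(pool, n_runs=5, n_train_per_class=30, d=20, seed=11)
print(f"MCCV over {len(report.runs)} runs, 30 train / 70 test per class:")
print(f"  OA = {report.mean['OA']:.2f}% +/- {report.sd['OA']:.2f}%")
for lab in report.labels:
    key = f"Sen[{lab}]"
    print(f"  Sen {lab}: {report.mean[key]:6.2f}% +/- {report.sd[key]:.2f}%")
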