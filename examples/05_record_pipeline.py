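"""Whole-record processing (10-second, 500 Hz rhythm-class records).

Beat-level work segments around R peaks; rhythm classes are instead
processed as whole 5000-sample records, where heart rate and regularity
show up directly in the time-frequency map.  This example decomposes one
record from each of two rhythm classes (bradycardia vs. tachycardia
analogues) and compares their T-F signatures; record decomposition is the
slow step (seconds per record), so the example keeps to two records.

Note: classifying rhythms from whole records uses exactly the same
train/classify calls as example 03, but needs substantially more training
records per class than beats do — within-class variability (RR jitter
shifting every beat) must be spanned by the difference subspace.
"""

import numpy as np

import fdmcma as f

specs = {s.name: s for s in f.record_class_library()}
for name in ("SB", "GSVT"):
    rec = f.generate_record(specs[name], seed=21)
    sig = f.normalize_signal(rec)
    dec = f.decompose(sig)
    tf = f.build_tf_map(dec)
    mat = f.build_data_matrix(sig, dec, variant="D")

    # the signal row of the data matrix carries the rhythm: count R peaks
    s_row = mat.grid[61]
    peaks = np.nonzero((s_row[1:-1] > 0.5)
                       & (s_row[1:-1] >= s_row[:-2])
                       & (s_row[1:-1] >= s_row[2:]))[0]
    bpm = len(peaks) * 60.0 / (rec.n / rec.fs)
    print(f"{name}: {rec.n} samples at {rec.fs:.0f} Hz, "
          f"rr_mean {specs[name].rr_mean:.0f} ms")
    print(f"  bands M = {dec.m}, data matrix {mat.grid.shape}")
    print(f"  R peaks in signal row: {len(peaks)} -> {bpm:.0f} bpm")
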