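"""From beats to 62 x d feature images.

Builds data matrices (60-row time-frequency map + spectrum row + signal
row) for a small class of beats, learns the class's 2DPCA projection, and
prints the shapes plus the fraction of scatter the leading d eigenvectors
capture.
"""

import numpy as np

import fdmcma as f
from fdmcma.features import class_covariance, projection_matrix

spec = f.beat_class_library()[0]
mats = [f.process_signal(f.generate_beat(spec, seed=s)) for s in range(10)]
print(f"data matrices: {len(mats)} x {mats[0].grid.shape} (variant D)")

cov = class_covariance(mats)
for d in (5, 20, 30):
    proj = projection_matrix(cov, d)
    captured = proj.eigenvalues.sum() / np.trace(cov.values)
    feat = f.extract_features(mats[0], proj)
    print(f"d = {d:2d}: feature image {feat.values.shape}, "
          f"captured scatter {captured * 100:5.1f}%")
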