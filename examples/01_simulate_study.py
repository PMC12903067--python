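"""Generate a synthetic multi-slide MSI study with planted batch effects.

Every batch (slide) carries one homogeneous QC section and one heterogeneous
QC section; each ion gets its own per-batch location and spread shift plus
within-batch drift, all recorded as ground truth.
"""

import numpy as np

from msibatchqc import SynthConfig, simulate_study
from msibatchqc.evaluate import between_batch_variance

cfg = SynthConfig(n_batches=5, grid_width=16, grid_height=16, n_features=40)
cube, truth = simulate_study(cfg, seed=7)

qc = cube.select(cube.tissue_mask("qc_homogeneous"))
print(f"cube: {cube.n_pixels} pixels x {cube.n_features} ions, "
      f"{len(np.unique(cube.batch))} batches, {len(cube.sections)} sections")
print(f"planted location factors a_bg: min {truth.a_bg.min():.2f}, max {truth.a_bg.max():.2f}")
print(f"median between-batch variance of homogeneous QC (raw): "
      f"{np.median(between_batch_variance(qc)):.1f}")
# a_bg far from 1 means that ion's whole image shifts in that batch; the
# between-batch variance quantifies the same effect per ion on QC pixels.
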