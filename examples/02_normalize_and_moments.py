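"""Classic normalizations and the per-batch moment table behind violin plots."""

import numpy as np

from msibatchqc import SynthConfig, simulate_study, tic_normalize, glog_transform
from msibatchqc.evaluate import batch_moments, violin_data

cube, _ = simulate_study(SynthConfig(n_batches=3, grid_width=10, grid_height=10,
                                     n_features=20), seed=1)

tic = tic_normalize(cube)
print(f"TIC row sums: {tic.intensities.sum(axis=1).min():.6f}..{tic.intensities.sum(axis=1).max():.6f}")

logged = glog_transform(cube, lam=1e6)
print(f"g-log range: {logged.intensities.min():.2f}..{logged.intensities.max():.2f} "
      f"(ln(500) = {np.log(500):.2f} is the value at zero intensity)")

moments = batch_moments(cube)
v = violin_data(moments, feature=0)
print("\nper-batch moments of ion 0 (median / IQR shift = the batch effect):")
print(v[["batch", "median", "iqr", "count"]].to_string(index=False))
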