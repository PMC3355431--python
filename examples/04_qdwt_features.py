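"""Local features: one-scale quaternion wavelet coefficients → block σ.

The 64×64 quaternion image is filtered with the cross-channel mixing
formulas, decimated to 32×32, and summarized as per-block quaternion
standard deviations on a 6×6 grid of 5×5 blocks (36 quaternions).
"""

import numpy as np

from quatpalm import QDWTConfig, SynthConfig, generate_dataset, qdwt_feature
from quatpalm.pipeline import PipelineConfig, preprocess_sample

cfg = SynthConfig(n_classes=3, instances_per_class=2, seed=2)
gallery, _ = generate_dataset(cfg)
Q = preprocess_sample(gallery[0], PipelineConfig())  # 64×64 quaternion image

qcfg = QDWTConfig()  # default filters, z = 5, dyadic decimation on
feat = qdwt_feature(Q, qcfg)
print(f"input {Q.shape} → coefficient image "
      f"{tuple(s // 2 for s in Q.shape)} → block grid {feat.grid}, "
      f"h = {feat.n_blocks} quaternion standard deviations")
print("\nfirst three σ blocks (rows are a, b, c, d channel σ):")
print(np.round(feat.sigmas.channels()[:, :3], 4))
print("\nEvery component is ≥ 0: a σ quaternion stores the four per-channel "
      "texture energies of one block.")
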