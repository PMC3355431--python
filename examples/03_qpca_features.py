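"""Global features: quaternion PCA on vectorized 64×64 quaternion images.

Fits the QPCA model at the default 90% energy ratio and shows the eigenvalue
spectrum, the retained component count, and a projected feature vector.
"""

import numpy as np

from quatpalm import SynthConfig, fit_qpca, generate_dataset, project, vectorize
from quatpalm.pipeline import PipelineConfig, preprocess_sample

cfg = SynthConfig(n_classes=10, instances_per_class=4, seed=11)
gallery, probe = generate_dataset(cfg)
pcfg = PipelineConfig()

vectors = [vectorize(preprocess_sample(s, pcfg)) for s in gallery]
model = fit_qpca(vectors, ratio=pcfg.energy_ratio)

D = model.eigenvalues
print(f"training samples n = {len(vectors)}, vector length m = {vectors[0].size}")
print(f"leading eigenvalues: {np.round(D[:5], 6)}")
print(f"energy ratio {model.energy_ratio:.0%} retains p = {model.n_components} "
      f"of {len(D)} components "
      f"({D[:model.n_components].sum() / D.sum():.1%} of the spectrum mass)")

f = project(model, vectorize(preprocess_sample(probe[0], pcfg)))
print(f"\na probe feature is a quaternion vector of length {f.size}; "
      f"first entry (a, b, c, d) = {np.round(f[0].channels(), 4)}")
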