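# quatpalm

Multispectral palmprint identification with a quaternion image model.

Multispectral palmprint sensors capture four co-registered images of one
palm under NIR, red, green and blue illumination.  Treating the four bands
as separate biometrics and fusing them at the image level (averaging) or at
the matching-score level discards cross-band structure.  `quatpalm` instead
represents one acquisition as a single quaternion-valued image

```
Q(x, y) = I(x, y) + R(x, y)·i + G(x, y)·j + B(x, y)·k
```

(NIR in the real channel; a missing illumination is a zero channel) and
extracts two complementary features directly from the quaternion matrix:

* **QPCA** — global appearance.  The vectorized training samples form
  `S (m×n)`; the small n×n quaternion Hermitian covariance
  `C = Eᴴ E / (n−1)` is reduced by quaternion Householder reflections to a
  real symmetric tridiagonal matrix `B` (`C = Pᴴ B P`), the real
  eigenproblem is solved, and eigenvectors are lifted back to pixel space
  (`V = E Pᴴ V_B`).  The projection keeps the leading components holding
  90 % of the eigenvalue mass.
* **QDWT** — local texture.  One-scale quaternion wavelet approximation
  coefficients (separable filtering with a cross-channel mixing of the
  (I, G) and (R, B) pairs), summarized as per-block quaternion standard
  deviations on non-overlapping 5×5 blocks.

Matching normalizes each feature's Euclidean distance by its standard
deviation over all training pairs and fuses them,
`d = 0.6·d̄_QPCA + 0.4·d̄_QDWT`; a probe takes the label of the nearest
gallery entry (rank-1 identification).

Because real multispectral palm databases are not redistributable, the
package ships a first-class synthetic generator: per-palm ridge/line
textures shared across bands, band mixing targeting a realistic
inter-spectrum correlation matrix (Blue–Green ≈ 0.74, Blue–NIR ≈ 0.45),
common per-acquisition shifts, band gain/offset jitter, and additive noise.

This package is aimed at biometrics and image-analysis researchers who want
a complete, testable reference implementation of quaternion-domain feature
extraction — including the quaternion Hermitian eigensolver, which is
verified against an independent complex-adjoint oracle.

## Worked example

`examples/05_identification.py` enrolls 12 synthetic palms (3 gallery + 3
probe acquisitions each) under substantial noise (σ = 0.35) and shift
(±6 px) and compares recognition schemes:

```
12 palms, 36 enrolled, 36 probes, noise σ = 0.35

single:nir     rank-1 accuracy = 97.22%
single:red     rank-1 accuracy = 91.67%
single:green   rank-1 accuracy = 75.00%
single:blue    rank-1 accuracy = 75.00%
image_fusion   rank-1 accuracy = 97.22%
score_fusion   rank-1 accuracy = 97.22%
quaternion     rank-1 accuracy = 97.22%
nir+blue only  rank-1 accuracy = 97.22% (two weakly correlated bands already fuse well)
```

Individual bands degrade unevenly (green and blue carry the least contrast
here), while every multiband scheme — including the quaternion model with
only the two least-correlated bands — recovers nearly all identities.  The
other examples walk through the quaternion algebra and the two feature
extractors step by step.

A thin CLI mirrors the library for shell use:

```bash
quatpalm synth --out ds --classes 8 --seed 7
quatpalm fit --data ds/gallery --out model.npz
quatpalm evaluate --gallery ds/gallery --probe ds/probe --scheme quaternion
quatpalm match --model model.npz --probe ds/probe/0
```

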