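# Methods

## The model

One multispectral palm acquisition is four co-registered 8-bit grayscale
ROI images, nominally 128×128, captured under NIR, red, green and blue
illumination.  The package represents the acquisition as a quaternion
matrix `Q = I + R·i + G·j + B·k`, with the NIR band in the real channel
and each unavailable band replaced by a zero matrix.  All downstream
algebra uses Hamilton's product (`i² = j² = k² = ijk = −1`); quaternion
arrays are stored struct-of-arrays as four parallel float64 channels in
the documented (a, b, c, d) = (NIR, R, G, B) order.

Preprocessing per band: 256-bin cumulative-histogram equalization
(removing global intensity differences between illuminations), then
block-mean downsampling by 2 (128 → 64).  Both the global and the local
feature extractor consume the same 64×64 quaternion image; the block-mean
(rather than naive decimation) choice is recorded in the configuration so
either behaviour is reproducible.  A constant image passes through
equalization unchanged (degenerate-histogram guard).  ROI localization
itself is out of scope: inputs are assumed pre-cropped, with a center-crop
utility for larger frames.

## QPCA: the quaternion Hermitian eigenproblem

Vectorized (row-major) training images form the columns of `S (m×n)`,
m = 4096, n the training count.  With `E = S − S̄` (per-pixel mean
removed), the small-covariance trick works on the n×n quaternion Hermitian
matrix `C = Eᴴ E/(n−1)` instead of the intractable m×m covariance.

`C` is reduced to a **real** symmetric tridiagonal matrix `B` with
`C = Pᴴ B P` in two stages:

1. **Quaternion Householder reflections.**  At step k the reflector
   `H = I − 2vvᴴ/‖v‖²` with `v = x + u·‖x‖·e₁`, where `x` is the
   sub-column below the first subdiagonal and `u = x₁/|x₁|` its left unit
   phase, annihilates everything below the subdiagonal.  Because `vᴴx` is
   real by this construction, `H` is Hermitian, unitary, and exactly
   analogous to the complex case.
2. **Phase rotations.**  The surviving subdiagonal entries are quaternions;
   a diagonal matrix of unit quaternions, built recursively so that
   `u_{k+1}·t_k·ū_k = |t_k|`, rotates them onto the nonnegative real axis.

The real tridiagonal eigenproblem is then solved with LAPACK
(`scipy.linalg.eigh_tridiagonal`); eigenvectors lift back through
`V_C = Pᴴ V_B` and `V = E V_C`.  Columns of `V` are explicitly unit-
normalized (otherwise projection magnitudes scale with the eigenvalues),
eigenvalues are rescaled by `(n−1)/(m−1)` and sorted descending (stable
sort; ties keep original order).  The `(n−1)/(m−1)` factor is a uniform
rescaling kept for fidelity to the method's published form; it cancels in
the energy ratio and therefore never changes component selection.

Component selection keeps the smallest p with cumulative eigenvalue mass
≥ the energy ratio (default **0.90**).  Eigenvalues below 1e-10 of the
largest are treated as zero, so a ratio of 1.0 keeps exactly the positive
spectrum and numerically junk null-space directions are excluded; an
all-zero spectrum (zero-variance training set) raises rather than
returning p = 0.

Projection computes `f = P̂ᴴ(s − mean)`.  Subtracting the training mean is
standard PCA practice and is consistent with the training-time centering;
a `center=False` switch projects the raw sample instead.  For
nearest-neighbor matching the two are equivalent, since the common offset
cancels in feature differences.

**Verification.**  The complex-adjoint embedding (per-entry 2×2 blocks
`[[a+bi, c+di], [−(c−di), a−bi]]`, a ring homomorphism) provides an
independent eigensolver oracle: eigenvalues of the adjoint of a Hermitian
quaternion matrix are real with multiplicity 2, and the test suite checks
the Householder path against them (and `C = PᴴBP` reconstruction) to 1e-8
over hundreds of random matrices.

## QDWT: local texture

One-scale quaternion wavelet approximation coefficients are computed by
separable filtering (rows first, then columns; symmetric padding) with a
signed cross-channel mixing that couples the (I, G) and (R, B) channel
pairs — see `quatpalm.qdwt` for the four channel formulas.  Structural
consequences used as tests: a zero image yields zero coefficients; if
R = B = 0 then coef_R = coef_B = 0 identically; and the transform is
real-linear.  Dyadic decimation (every second row/column, phase 0) is on
by default, giving 32×32 coefficients from a 64×64 image.  Detail
coefficients are deliberately not used (noise-sensitive); multi-scale
decomposition is out of scope.

The filter pair (g1, g2) is fully configurable.  The defaults are a short
low-pass / antisymmetric band-pass pair,
`g1 = [1/(4√2), 0, 3/(4√2), 1/2]/2` and `g2 = [−3/(4√2), 0, 3/(4√2)]/2`;
every module test is filter-agnostic, so swapping in another pair
preserves all guarantees except the literal coefficient values.

The coefficient image is partitioned into non-overlapping z×z blocks
(z = **5** by default, balancing stability against feature dimension),
row-major, discarding incomplete edge blocks (avoids biased small-sample
statistics at borders).  Each block contributes one quaternion whose
components are the per-channel **population** standard deviations (ddof 0,
stated so worked examples are deterministic).  For the default geometry:
64×64 → 32×32 coefficients → a 6×6 grid, h = 36 quaternions.

## Matching and fusion

Feature dissimilarity is the quaternion Euclidean distance
`d(p, q) = √Σ|p_l − q_l|²`, identical to the 4L-dimensional real
Euclidean distance — which lets pairwise computations use ordinary
`pdist`/`cdist` on channel-concatenated real matrices.

Each distance type is normalized by its population standard deviation over
**all unordered pairs** of training samples (genuine and impostor pairs
pooled; the method does not separate them), floored at 1e-12 with a
warning for degenerate galleries.  The fused score is
`d = w_QPCA·d̄_QPCA + w_QDWT·d̄_QDWT` with default weights **0.6/0.4**; it
is a pseudometric (weighted sum of scaled Euclidean metrics).  Rank-1
identification takes the minimal fused distance over the gallery, ties
broken by lowest gallery index (deterministic).  Verification-mode metrics
(EER/ROC) are not computed.

Baselines, for comparison under a shared protocol:

* `single:<band>` — the pipeline on a one-band quaternion image,
* `image_fusion` — the available bands averaged into one real image before
  feature extraction,
* `score_fusion` — per-band features extracted separately, each band's
  distances normalized by that band's own training σ and averaged with
  equal weights (weight learning is out of scope),
* band subsets — the quaternion pipeline with chosen channels zero-filled,
  emulating fewer than four illuminations.

Each scheme refits QPCA and the normalizer on its own representation of
the gallery.

## Synthetic data

The generator replaces a private palm database with a controllable
surrogate.  Per class, four independent textures (sums of 14 randomly
phased oriented sinusoids, 2–8 cycles across the template) are mixed into
the four bands through the Cholesky factor of a target 4×4 correlation
matrix; a few dark principal-line strokes with Gaussian cross-profiles
ride on the first (shared) component, so palm lines appear in every band.
The default target is a realistic inter-spectrum correlation structure in
which neighbouring wavelengths correlate strongly (Blue–Green 0.7421) and
distant ones weakly (Blue–NIR 0.4487).  Correlation targeting is
approximate (±0.05): linear mixing controls expectations exactly only for
unstructured textures, and pixel clipping plus additive noise attenuate
the realized coefficients slightly.

An acquisition applies one integer shift common to all four bands (the
physical sensor captures all bands in one hand placement), drawn uniformly
in [−max_shift, max_shift]², per-band gain/offset jitter
(σ = 0.05 / 0.02), and additive Gaussian noise, then clips to [0, 1].
Defaults: 20 classes × 12 instances (the first 6 enroll, the last 6
probe — mirroring a two-session protocol), 128×128 bands, noise σ = 0.02,
max shift 2 px.  Every output is a pure function of (config, seed);
written datasets are quantized to 8-bit PNG and round-trip through the
standard readers.

What the generator does **not** emulate: photorealistic skin texture,
nonlinear inter-band intensity relations, ROI-localization failures beyond
the shift parameter, rotation or per-band misregistration, and session
effects such as illumination drift.  Passing tests therefore show that the
pipeline recovers identity under the stated geometric/noise perturbations
with realistic band correlations — not that it attains any particular
accuracy on real palm databases.

## Numerical choices and limitations

* Double precision throughout; Householder tolerance for the Hermitian
  check is 1e-8 relative to the matrix norm.
* Quaternion eigenvalues are right eigenvalues; for Hermitian matrices
  they are real, so descending order is unambiguous.
* Feature distances are invariant to right-multiplication of any
  projection column by a unit quaternion (phase indeterminacy of
  quaternion eigenvectors), which the tests assert.
* The tridiagonalization materializes full reflector matrices
  (O(n³) quaternion work per fit with small constants); n is the training
  count, typically ≤ a few hundred, so this costs well under a second.
* Problem sizes in the test and reproduction scripts (20 palms × 12
  acquisitions; 200 oracle matrices of order ≤ 16; 30-vector isometry
  checks) are the package's standard study configuration; the generator
  scales to larger galleries linearly.
* The identification protocol is closed-set; open-set identification and
  verification metrics are out of scope.
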