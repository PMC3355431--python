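"""Synthetic multi-band palm-like galleries with controllable structure.

The generator emulates the statistical skeleton of a multispectral palmprint
database: each palm (class) owns an oriented line/ridge texture — sums of
randomly phased oriented sinusoids plus a few dark principal-line strokes —
that is shared across the four illumination bands, while each band mixes in
band-private texture.  The mixing coefficients come from a Cholesky factor of
a target 4×4 band-correlation matrix, so the expected pairwise Pearson
correlations between bands approximate the target (the default target is the
empirical inter-spectrum correlation structure of real multispectral palm
images, e.g. Blue–Green ≈ 0.74, Blue–NIR ≈ 0.45).

Acquisition instances of one palm differ by a small common integer shift
(the four bands are captured in one hand placement, so they shift together),
per-band gain/offset jitter, and additive Gaussian noise.  Session-1
instances form the gallery and session-2 instances the probes.  Everything
is a pure function of (config, seeds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import BANDS, MultispectralSample

__all__ = [
    "TABLE_BAND_CORRELATION",
    "SynthConfig",
    "make_class_template",
    "sample_instance",
    "generate_dataset",
    "band_correlation",
]

#: default inter-band correlation target, (nir, red, green, blue) order
TABLE_BAND_CORRELATION = np.array(
    [
        [1.0000, 0.7470, 0.3690, 0.4487],
        [0.7470, 1.0000, 0.5060, 0.6829],
        [0.3690, 0.5060, 1.0000, 0.7421],
        [0.4487, 0.6829, 0.7421, 1.0000],
    ]
)


@dataclass
class SynthConfig:
    """Generator settings.

    ``instances_per_class`` is split evenly into two sessions: the first half
    enrolls as gallery, the second half probes.  ``max_shift`` is the largest
    per-instance translation in pixels (common to all bands); ``noise_sd`` is
    the additive Gaussian noise level on unit-interval pixel values.
    """

    n_classes: int = 20
    instances_per_class: int = 12
    image_size: int = 128
    target_band_correlation: np.ndarray = field(
        default_factory=lambda: TABLE_BAND_CORRELATION.copy()
    )
    noise_sd: float = 0.02
    max_shift: int = 2
    gain_jitter: float = 0.05
    offset_jitter: float = 0.02
    n_sinusoids: int = 14
    n_lines: int = 4
    texture_scale: float = 0.12
    band_contrast: tuple = (1.0, 0.95, 0.9, 0.85)
    seed: int = 0

    def __post_init__(self):
        T = np.asarray(self.target_band_correlation, dtype=float)
        if T.shape != (4, 4) or not np.allclose(T, T.T) or \
           not np.allclose(np.diag(T), 1.0) or np.any(np.abs(T) > 1 + 1e-12):
            raise ValueError("target correlation must be symmetric, unit-diagonal, "
                             "with entries in [-1, 1]")
        self.target_band_correlation = T
        if self.n_classes < 2 or self.instances_per_class < 2:
            raise ValueError("need n_classes >= 2 and instances_per_class >= 2")


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    s = x.std()
    return x / s if s > 0 else x


def _base_texture(rng: np.random.Generator, size: int, n_sinusoids: int) -> np.ndarray:
    """Sum of randomly phased oriented sinusoids (ridge-like texture)."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    tex = np.zeros((size, size))
    for _ in range(n_sinusoids):
        theta = rng.uniform(0, np.pi)
        cycles = rng.uniform(2.0, 8.0)          # cycles across the template
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        proj = (xx * np.cos(theta) + yy * np.sin(theta)) / size
        tex += amp * np.sin(2 * np.pi * cycles * proj + phase)
    return tex


def _line_strokes(rng: np.random.Generator, size: int, n_lines: int) -> np.ndarray:
    """A few dark principal-line strokes with Gaussian cross-profiles."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    strokes = np.zeros((size, size))
    for _ in range(n_lines):
        theta = rng.uniform(0, np.pi)
        offset = rng.uniform(0.2, 0.8) * size
        width = rng.uniform(1.5, 3.0)
        depth = rng.uniform(2.0, 4.0)
        dist = xx * np.cos(theta) + yy * np.sin(theta) - offset
        strokes -= depth * np.exp(-(dist**2) / (2 * width**2))
    return strokes


def make_class_template(class_id: int, cfg: SynthConfig) -> dict[str, np.ndarray]:
    """Deterministic per-class band templates with the target correlation.

    Four independent class-specific textures are mixed through the Cholesky
    factor of the target correlation matrix; the shared principal-line
    strokes ride on the first (common) component.  Templates are padded by
    ``max_shift`` on every side so instances can be shifted without wrap.
    """
    try:
        L = np.linalg.cholesky(cfg.target_band_correlation)
    except np.linalg.LinAlgError as e:
        raise ValueError("target correlation matrix is not positive definite") from e
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7, class_id]))
    size = cfg.image_size + 2 * cfg.max_shift
    U = []
    for a in range(4):
        u = _base_texture(rng, size, cfg.n_sinusoids)
        if a == 0:  # palm lines are visible in every band via the shared component
            u = _standardize(u) + _line_strokes(rng, size, cfg.n_lines)
        U.append(_standardize(u))
    bands = {}
    for b, name in enumerate(BANDS):
        mix = sum(L[b, a] * U[a] for a in range(4))
        img = 0.5 + cfg.band_contrast[b] * cfg.texture_scale * mix
        bands[name] = np.clip(img, 0.0, 1.0)
    return bands


def sample_instance(
    template: dict[str, np.ndarray],
    cfg: SynthConfig,
    instance_seed,
    label=0,
    instance_id: int = 0,
    band_mask=(True, True, True, True),
) -> MultispectralSample:
    """One acquisition: common shift, per-band gain/offset jitter, noise."""
    rng = np.random.default_rng(instance_seed)
    if cfg.max_shift > 0:
        sx, sy = rng.integers(-cfg.max_shift, cfg.max_shift + 1, size=2)
    else:
        sx, sy = 0, 0
    r0, c0 = cfg.max_shift + int(sx), cfg.max_shift + int(sy)
    bands = {}
    for b, name in enumerate(BANDS):
        img = template[name][r0 : r0 + cfg.image_size, c0 : c0 + cfg.image_size]
        gain = 1.0 + rng.normal(0.0, cfg.gain_jitter)
        offset = rng.normal(0.0, cfg.offset_jitter)
        noisy = gain * (img - 0.5) + 0.5 + offset
        if cfg.noise_sd > 0:
            noisy = noisy + rng.normal(0.0, cfg.noise_sd, img.shape)
        if band_mask[b]:
            bands[name] = np.clip(noisy, 0.0, 1.0)
    return MultispectralSample(bands, label=label, instance_id=instance_id)


def generate_dataset(cfg: SynthConfig):
    """(gallery, probe) sample lists: session 1 enrolls, session 2 probes."""
    n_gal = cfg.instances_per_class // 2
    gallery, probe = [], []
    for cid in range(cfg.n_classes):
        template = make_class_template(cid, cfg)
        for inst in range(cfg.instances_per_class):
            s = sample_instance(
                template,
                cfg,
                instance_seed=np.random.SeedSequence([cfg.seed, 11, cid, inst]),
                label=cid,
                instance_id=inst,
            )
            (gallery if inst < n_gal else probe).append(s)
    return gallery, probe


def band_correlation(samples) -> np.ndarray:
    """Mean over samples of pairwise Pearson correlations between flattened
    band images; requires all four bands present."""
    samples = list(samples)
    if not samples:
        raise ValueError("no samples")
    acc = np.zeros((4, 4))
    for s in samples:
        if not all(s.availability):
            raise ValueError("band_correlation requires all four bands")
        X = np.stack([s.bands[b].ravel() for b in BANDS])
        acc += np.corrcoef(X)
    out = acc / len(samples)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2
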