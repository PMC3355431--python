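"""One-scale quaternion wavelet approximation coefficients and block-σ features.

The quaternion image Q = I + R·i + G·j + B·k is filtered with a pair of real
1-D filters (g1, g2) applied separably (first along rows, then along
columns) with a signed cross-channel mixing that couples the (I, G) and
(R, B) channel pairs:

    coef_I =  (I⊗g1)⊗g1 + (G⊗g2)⊗g1 + (G⊗g1)⊗g2 − (I⊗g2)⊗g2
    coef_R =  (R⊗g1)⊗g1 + (B⊗g2)⊗g1 + (B⊗g1)⊗g2 − (R⊗g2)⊗g2
    coef_G = −(I⊗g1)⊗g2 − (G⊗g2)⊗g2 − (G⊗g2)⊗g1 + (I⊗g1)⊗g1
    coef_B = −(R⊗g1)⊗g2 − (B⊗g2)⊗g2 − (B⊗g2)⊗g1 + (R⊗g1)⊗g1

Only the approximation coefficients are kept (detail coefficients are noise
sensitive).  The coefficient image is then cut into non-overlapping z×z
blocks (z = 5 by default); each block contributes one quaternion whose four
components are the per-channel population standard deviations, and the
feature vector concatenates the blocks row-major.

The filter pair is configurable.  The defaults are a short low-pass /
antisymmetric band-pass pair,

    g1 = [1/(4√2), 0, 3/(4√2), 1/2] / 2,      g2 = [−3/(4√2), 0, 3/(4√2)] / 2,

but every structural property of the transform (linearity, channel-vanishing
patterns, block bookkeeping) holds for any finite filter pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve1d

from .quaternion import QuaternionArray

__all__ = ["QDWTConfig", "QDWTFeature", "qdwt_approx", "block_std_features",
           "qdwt_feature", "DEFAULT_G1", "DEFAULT_G2"]

_SQ2 = np.sqrt(2.0)
DEFAULT_G1 = np.array([1 / (4 * _SQ2), 0.0, 3 / (4 * _SQ2), 0.5]) / 2.0
DEFAULT_G2 = np.array([-3 / (4 * _SQ2), 0.0, 3 / (4 * _SQ2)]) / 2.0

#: scipy.ndimage names for the supported padding modes
_BOUNDARY_MODES = {"symmetric": "reflect", "reflect": "mirror", "wrap": "wrap",
                   "nearest": "nearest", "constant": "constant"}


@dataclass
class QDWTConfig:
    """Filters, block size, boundary handling, and decimation toggle."""

    g1: np.ndarray = field(default_factory=lambda: DEFAULT_G1.copy())
    g2: np.ndarray = field(default_factory=lambda: DEFAULT_G2.copy())
    block_size: int = 5
    boundary: str = "symmetric"
    decimate: bool = True

    def __post_init__(self):
        self.g1 = np.asarray(self.g1, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        for name, g in (("g1", self.g1), ("g2", self.g2)):
            if g.ndim != 1 or g.size == 0 or not np.all(np.isfinite(g)):
                raise ValueError(f"{name} must be a nonempty finite 1-D vector")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.boundary not in _BOUNDARY_MODES:
            raise ValueError(f"unknown boundary mode {self.boundary!r}")

    def to_dict(self) -> dict:
        return {"g1": self.g1.tolist(), "g2": self.g2.tolist(),
                "z": self.block_size, "decimate": self.decimate,
                "boundary": self.boundary}

    @classmethod
    def from_dict(cls, d: dict) -> "QDWTConfig":
        return cls(g1=np.asarray(d.get("g1", DEFAULT_G1)),
                   g2=np.asarray(d.get("g2", DEFAULT_G2)),
                   block_size=int(d.get("z", 5)),
                   boundary=d.get("boundary", "symmetric"),
                   decimate=bool(d.get("decimate", True)))


@dataclass
class QDWTFeature:
    """Per-block quaternion standard deviations plus the block-grid shape."""

    sigmas: QuaternionArray
    grid: tuple[int, int]

    @property
    def n_blocks(self) -> int:
        return self.sigmas.size


def _sep(img: np.ndarray, frow: np.ndarray, fcol: np.ndarray, mode: str) -> np.ndarray:
    """(X ⊗ frow) ⊗ fcol: filter each row, then each column."""
    out = convolve1d(img, frow, axis=1, mode=mode)
    return convolve1d(out, fcol, axis=0, mode=mode)


def qdwt_approx(Q: QuaternionArray, cfg: QDWTConfig | None = None) -> QuaternionArray:
    """Approximation coefficients of the one-scale quaternion decomposition."""
    cfg = cfg or QDWTConfig()
    if Q.ndim != 2:
        raise ValueError("expected a 2-D quaternion image")
    support = max(cfg.g1.size, cfg.g2.size)
    if min(Q.shape) < support:
        raise ValueError(
            f"image {Q.shape} smaller than the filter support ({support})"
        )
    mode = _BOUNDARY_MODES[cfg.boundary]
    I, R, G, B = Q.a, Q.b, Q.c, Q.d
    g1, g2 = cfg.g1, cfg.g2

    coef_I = (_sep(I, g1, g1, mode) + _sep(G, g2, g1, mode)
              + _sep(G, g1, g2, mode) - _sep(I, g2, g2, mode))
    coef_R = (_sep(R, g1, g1, mode) + _sep(B, g2, g1, mode)
              + _sep(B, g1, g2, mode) - _sep(R, g2, g2, mode))
    coef_G = (-_sep(I, g1, g2, mode) - _sep(G, g2, g2, mode)
              - _sep(G, g2, g1, mode) + _sep(I, g1, g1, mode))
    coef_B = (-_sep(R, g1, g2, mode) - _sep(B, g2, g2, mode)
              - _sep(B, g2, g1, mode) + _sep(R, g1, g1, mode))

    if cfg.decimate:
        coef_I, coef_R, coef_G, coef_B = (
            c[::2, ::2] for c in (coef_I, coef_R, coef_G, coef_B)
        )
    return QuaternionArray(coef_I, coef_R, coef_G, coef_B)


def block_std_features(coef: QuaternionArray, z: int) -> QDWTFeature:
    """Row-major non-overlapping z×z block partition; per-block, per-channel
    population standard deviation.  Incomplete edge blocks are discarded."""
    if coef.ndim != 2:
        raise ValueError("expected a 2-D coefficient image")
    h, w = coef.shape
    gh, gw = h // z, w // z
    if gh == 0 or gw == 0:
        raise ValueError(f"coefficient image {coef.shape} smaller than one {z}×{z} block")
    sig = []
    for ch in (coef.a, coef.b, coef.c, coef.d):
        trimmed = ch[: gh * z, : gw * z]
        blocks = trimmed.reshape(gh, z, gw, z)
        sig.append(blocks.std(axis=(1, 3)).ravel())  # population std (ddof=0)
    return QDWTFeature(sigmas=QuaternionArray(*sig), grid=(gh, gw))


def qdwt_feature(Q: QuaternionArray, cfg: QDWTConfig | None = None) -> QDWTFeature:
    """Full local-texture feature: approximation coefficients → block σ."""
    cfg = cfg or QDWTConfig()
    return block_std_features(qdwt_approx(Q, cfg), cfg.block_size)
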