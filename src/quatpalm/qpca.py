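"""Quaternion principal component analysis (QPCA).

Training samples are vectorized quaternion images stacked as columns of
``S (m×n)``, with m the pixel count (4096 for 64×64 ROIs) and n the number of
training samples, typically n ≪ m.  The small-covariance trick works on the
n×n quaternion Hermitian matrix

    C = Eᴴ·E / (n−1),        E = S − S̄ (per-pixel mean removed),

reduces it to a real symmetric tridiagonal matrix B by quaternion Householder
reflections plus unit-quaternion phase rotations (C = Pᴴ·B·P with P unitary),
solves the real tridiagonal eigenproblem, and lifts eigenvectors back to
pixel space via V_C = Pᴴ·V_B and V = E·V_C.  Columns of V are explicitly
unit-normalized; eigenvalues are rescaled by (n−1)/(m−1) and sorted
descending.  The projection matrix keeps the leading components whose
eigenvalue mass reaches the configured energy ratio (default 90%).

The complex-adjoint eigensolver (``quatpalm.quaternion.complex_adjoint``)
serves as an independent oracle for this path in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh_tridiagonal

from .quaternion import (
    QuaternionArray,
    conj_transpose,
    hamilton_product,
    qeye,
    qmat_mul,
)

__all__ = [
    "TrainingMatrix",
    "QPCAModel",
    "center_training",
    "small_covariance",
    "householder_tridiagonalize",
    "eig_from_tridiagonal",
    "select_components",
    "fit_qpca",
    "project",
    "stack_columns",
]

#: relative threshold below which an eigenvalue counts as zero
_EIG_ZERO_RTOL = 1e-10


@dataclass
class TrainingMatrix:
    """Centered training data: S (m×n), per-pixel mean (m,), E = S − S̄."""

    S: QuaternionArray
    mean: QuaternionArray
    E: QuaternionArray


@dataclass
class QPCAModel:
    """Fitted QPCA model.

    ``projection`` is m×p with unit-norm quaternion columns; ``eigenvalues``
    holds the full descending spectrum (length n); ``center`` records whether
    projection subtracts the training mean.
    """

    mean: QuaternionArray
    projection: QuaternionArray
    eigenvalues: np.ndarray
    n_components: int
    energy_ratio: float
    center: bool = True

    def save(self, path, **extra) -> None:
        np.savez(
            path,
            mean=self.mean.channels(),
            projection=self.projection.channels(),
            eigenvalues=self.eigenvalues,
            n_components=self.n_components,
            energy_ratio=self.energy_ratio,
            center=self.center,
            **extra,
        )

    @classmethod
    def load(cls, path) -> "QPCAModel":
        with np.load(path) as f:
            return cls(
                mean=QuaternionArray.from_channels(f["mean"]),
                projection=QuaternionArray.from_channels(f["projection"]),
                eigenvalues=f["eigenvalues"],
                n_components=int(f["n_components"]),
                energy_ratio=float(f["energy_ratio"]),
                center=bool(f["center"]),
            )


def stack_columns(samples) -> QuaternionArray:
    """Stack quaternion vectors as the columns of an m×n matrix."""
    samples = list(samples)
    if not samples:
        raise ValueError("no samples")
    lengths = {s.size for s in samples}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent sample lengths: {sorted(lengths)}")
    chans = np.stack([s.channels().reshape(4, -1) for s in samples], axis=2)
    return QuaternionArray.from_channels(chans)


def center_training(S: QuaternionArray) -> TrainingMatrix:
    """Remove the per-pixel (per-row) mean over the n training columns."""
    if S.ndim != 2:
        raise ValueError("training matrix must be 2-D (m×n)")
    n = S.shape[1]
    if n < 2:
        raise ValueError(f"need at least 2 training samples, got {n}")
    mean = QuaternionArray(*(ch.mean(axis=1) for ch in (S.a, S.b, S.c, S.d)))
    E = QuaternionArray(*(ch - mu[:, None] for ch, mu in
                          zip((S.a, S.b, S.c, S.d), (mean.a, mean.b, mean.c, mean.d))))
    return TrainingMatrix(S=S, mean=mean, E=E)


def small_covariance(E: QuaternionArray) -> QuaternionArray:
    """C = Eᴴ·E / (n−1); quaternion Hermitian by construction."""
    n = E.shape[1]
    return qmat_mul(conj_transpose(E), E) / (n - 1)


def _hermitian_defect(C: QuaternionArray) -> float:
    return (C - conj_transpose(C)).norm()


def householder_tridiagonalize(
    C: QuaternionArray, tol: float = 1e-8
) -> tuple[np.ndarray, QuaternionArray]:
    """Reduce a quaternion Hermitian matrix to a real symmetric tridiagonal B.

    Returns ``(B, P)`` with B real tridiagonal (off-diagonals nonnegative) and
    P unitary such that ``C = Pᴴ·B·P``.  Each elimination step applies a
    quaternion Householder reflector annihilating the sub-column below the
    first subdiagonal; a final diagonal of unit-quaternion phases rotates the
    surviving subdiagonal entries onto the real axis.
    """
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {C.shape}")
    n = C.shape[0]
    scale = max(C.norm(), 1.0)
    if _hermitian_defect(C) > tol * scale:
        raise ValueError("input is not Hermitian within tolerance")

    A = C.copy()
    P = qeye(n)
    for k in range(n - 2):
        x = A[k + 1 :, k]
        alpha = float(np.sqrt(np.sum(x.abs() ** 2)))
        if alpha <= 1e-300:
            continue
        # left phase of the pivot entry: u = x0/|x0| (1 when x0 vanishes)
        x0 = x[0]
        x0n = float(x0.abs())
        u = x0 / x0n if x0n > 0 else QuaternionArray(np.float64(1.0))
        v = x.copy()
        v[0] = v[0] + u * alpha  # then Hx = −u·α·e1, since vᴴx is real
        vnorm2 = float(np.sum(v.abs() ** 2))
        if vnorm2 <= 1e-300:
            continue
        # full-size reflector H = I − 2 v vᴴ / |v|², embedded at rows/cols k+1:
        Hfull = qeye(n)
        vcol = v.reshape(-1, 1)
        outer = qmat_mul(vcol, conj_transpose(vcol)) * (2.0 / vnorm2)
        Hfull[k + 1 :, k + 1 :] = Hfull[k + 1 :, k + 1 :] - outer
        A = qmat_mul(qmat_mul(Hfull, A), Hfull)  # H is Hermitian and unitary
        P = qmat_mul(Hfull, P)

    # phase rotation: D·A·Dᴴ with unit quaternions making subdiagonals real ≥ 0
    phases = QuaternionArray.from_channels(np.zeros((4, n)))
    phases[0] = QuaternionArray(np.float64(1.0))
    for k in range(n - 1):
        t = A[k + 1, k]
        w = hamilton_product(t, phases[k].conj())
        wn = float(w.abs())
        if wn > 1e-300:
            phases[k + 1] = w.conj() / wn
        else:
            phases[k + 1] = QuaternionArray(np.float64(1.0))

    diag = A.a[np.arange(n), np.arange(n)].copy()
    off = np.empty(max(n - 1, 0))
    for k in range(n - 1):
        rotated = hamilton_product(
            hamilton_product(phases[k + 1], A[k + 1, k]), phases[k].conj()
        )
        off[k] = float(rotated.a)

    B = np.diag(diag)
    if n > 1:
        B[np.arange(n - 1) + 1, np.arange(n - 1)] = off
        B[np.arange(n - 1), np.arange(n - 1) + 1] = off

    # fold the phases into P:  P ← D·P
    Dphase = QuaternionArray.from_channels(np.zeros((4, n, n)))
    idx = np.arange(n)
    for ch_out, ch_in in zip((Dphase.a, Dphase.b, Dphase.c, Dphase.d),
                             (phases.a, phases.b, phases.c, phases.d)):
        ch_out[idx, idx] = ch_in
    P = qmat_mul(Dphase, P)
    return B, P


def eig_from_tridiagonal(
    B: np.ndarray,
    P: QuaternionArray,
    E: QuaternionArray,
) -> tuple[QuaternionArray, np.ndarray]:
    """Lift the real tridiagonal eigenproblem back to pixel space.

    Solves B·V_B = V_B·diag(D_C), forms V_C = Pᴴ·V_B and V = E·V_C, unit-
    normalizes the columns of V, rescales eigenvalues by (n−1)/(m−1), and
    sorts everything descending (stable; ties keep original order).
    """
    m, n = E.shape
    if n == 1:
        w = np.array([float(B[0, 0])])
        VB = np.eye(1)
    else:
        w, VB = eigh_tridiagonal(np.diag(B).copy(), np.diag(B, 1).copy())
    VC = qmat_mul(conj_transpose(P), QuaternionArray.from_real(VB))
    V = qmat_mul(E, VC)
    norms = np.sqrt(np.sum(V.abs() ** 2, axis=0))
    safe = np.where(norms > 1e-300, norms, 1.0)
    V = QuaternionArray(*(ch / safe[None, :] for ch in (V.a, V.b, V.c, V.d)))
    D = w * (n - 1) / max(m - 1, 1)
    order = np.argsort(-D, kind="stable")
    D = D[order]
    V = V[:, order]
    return V, D


def select_components(D: np.ndarray, ratio: float) -> int:
    """Smallest p with Σ_{x≤p} D_x / Σ_x D_x ≥ ratio (D sorted descending).

    Eigenvalues below 1e-10 of the largest are treated as zero, so a ratio of
    1.0 returns the count of positive eigenvalues.
    """
    if not 0 < ratio <= 1:
        raise ValueError(f"ratio must lie in (0, 1], got {ratio}")
    D = np.asarray(D, dtype=float)
    if np.any(np.diff(D) > 1e-12 * max(abs(D).max(initial=0.0), 1.0)):
        raise ValueError("eigenvalues must be sorted descending")
    Dc = np.where(D > _EIG_ZERO_RTOL * max(D.max(initial=0.0), 0.0), D, 0.0)
    total = Dc.sum()
    if total <= 0:
        raise ValueError("all-zero eigenvalue spectrum: no variance to keep")
    cum = np.cumsum(Dc) / total
    return int(np.searchsorted(cum, ratio - 1e-12) + 1)


def fit_qpca(samples, ratio: float = 0.9, center: bool = True) -> QPCAModel:
    """Fit a QPCA model from a list of quaternion vectors (energy ratio 0.90
    by default)."""
    S = stack_columns(samples)
    if S.shape[1] < 2:
        raise ValueError("need at least 2 training samples")
    tm = center_training(S)
    C = small_covariance(tm.E)
    B, P = householder_tridiagonalize(C)
    V, D = eig_from_tridiagonal(B, P, tm.E)
    p = select_components(D, ratio)
    model = QPCAModel(
        mean=tm.mean,
        projection=V[:, :p],
        eigenvalues=D,
        n_components=p,
        energy_ratio=ratio,
        center=center,
    )
    return model


def project(model: QPCAModel, s: QuaternionArray) -> QuaternionArray:
    """QPCA feature f = P̂ᴴ·(s − mean); accepts one vector or an m×k batch.

    With ``model.center`` false the raw sample is projected instead; for
    nearest-neighbor matching the two are equivalent because the common
    offset cancels in feature differences.
    """
    batch = s.ndim == 2
    mat = s if batch else s.reshape(-1, 1)
    if mat.shape[0] != model.mean.size:
        raise ValueError(
            f"sample length {mat.shape[0]} does not match model ({model.mean.size})"
        )
    if model.center:
        mu = model.mean.reshape(-1, 1)
        mat = mat - QuaternionArray(*(np.broadcast_to(ch, mat.shape)
                                      for ch in (mu.a, mu.b, mu.c, mu.d)))
    f = qmat_mul(conj_transpose(model.projection), mat)
    return f if batch else f[:, 0]
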