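"""Quaternion scalars, vectors, and matrices with Hamilton algebra.

A quaternion is ``q = a + b·i + c·j + d·k`` with the noncommutative
multiplication rules ``i² = j² = k² = ijk = −1``.  Arrays of quaternions are
stored struct-of-arrays: four parallel ``float64`` channels ``(a, b, c, d)``
of identical shape, so channel arithmetic vectorizes and serialization is a
plain four-channel container.  A quaternion scalar is simply the 0-d case.

The module also provides the complex-adjoint embedding: an ``n×n`` quaternion
matrix maps to a ``2n×2n`` complex matrix through per-entry 2×2 blocks

    a+bi+cj+dk  →  [[ a+bi,        c+di ],
                    [ −(c−di),     a−bi ]]

which is a ring homomorphism and serves as an independent oracle for the
quaternion Hermitian eigenproblem: eigenvalues of the adjoint of a Hermitian
quaternion matrix are real and come in pairs of multiplicity 2.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

__all__ = [
    "QuaternionArray",
    "quaternion",
    "hamilton_product",
    "qnorm",
    "conj_transpose",
    "qmat_mul",
    "complex_adjoint",
    "qvec_distance",
    "qeye",
    "save_quaternion_npz",
    "load_quaternion_npz",
]

CHANNEL_ORDER = ("a", "b", "c", "d")


class QuaternionArray:
    """N-dimensional array of quaternions (four parallel real channels).

    Parameters
    ----------
    a, b, c, d
        Real channel arrays of a common shape: the scalar part and the
        coefficients of i, j, k.  Missing channels default to zero.
    """

    __slots__ = ("a", "b", "c", "d")

    def __init__(self, a, b=None, c=None, d=None):
        a = np.asarray(a, dtype=float)
        self.a = a
        for name, ch in (("b", b), ("c", c), ("d", d)):
            arr = np.zeros_like(a) if ch is None else np.asarray(ch, dtype=float)
            if arr.shape != a.shape:
                raise ValueError(
                    f"channel {name!r} has shape {arr.shape}, expected {a.shape}"
                )
            setattr(self, name, arr)

    # ------------------------------------------------------------------ basic
    @property
    def shape(self) -> tuple:
        return self.a.shape

    @property
    def ndim(self) -> int:
        return self.a.ndim

    @property
    def size(self) -> int:
        return self.a.size

    def channels(self) -> np.ndarray:
        """Stacked ``(4,) + shape`` real array in (a, b, c, d) order."""
        return np.stack([self.a, self.b, self.c, self.d])

    @classmethod
    def from_channels(cls, arr) -> "QuaternionArray":
        arr = np.asarray(arr, dtype=float)
        if arr.shape[0] != 4:
            raise ValueError("expected leading axis of length 4 (a, b, c, d)")
        return cls(arr[0], arr[1], arr[2], arr[3])

    @classmethod
    def zeros(cls, shape) -> "QuaternionArray":
        return cls(np.zeros(shape))

    @classmethod
    def from_real(cls, arr) -> "QuaternionArray":
        """Purely real quaternion array (b = c = d = 0)."""
        return cls(np.asarray(arr, dtype=float))

    def copy(self) -> "QuaternionArray":
        return QuaternionArray(self.a.copy(), self.b.copy(), self.c.copy(), self.d.copy())

    def reshape(self, *shape) -> "QuaternionArray":
        return QuaternionArray(*(ch.reshape(*shape) for ch in self._chs()))

    def ravel(self) -> "QuaternionArray":
        return QuaternionArray(*(ch.ravel() for ch in self._chs()))

    def _chs(self):
        return (self.a, self.b, self.c, self.d)

    def __getitem__(self, idx) -> "QuaternionArray":
        return QuaternionArray(*(ch[idx] for ch in self._chs()))

    def __setitem__(self, idx, value: "QuaternionArray") -> None:
        if not isinstance(value, QuaternionArray):
            raise TypeError("can only assign a QuaternionArray")
        self.a[idx], self.b[idx] = value.a, value.b
        self.c[idx], self.d[idx] = value.c, value.d

    def __len__(self) -> int:
        return len(self.a)

    def __iter__(self) -> Iterator["QuaternionArray"]:
        for i in range(len(self)):
            yield self[i]

    def __repr__(self) -> str:
        return f"QuaternionArray(shape={self.shape})"

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other) -> "QuaternionArray":
        o = _as_qa(other)
        return QuaternionArray(self.a + o.a, self.b + o.b, self.c + o.c, self.d + o.d)

    __radd__ = __add__

    def __sub__(self, other) -> "QuaternionArray":
        o = _as_qa(other)
        return QuaternionArray(self.a - o.a, self.b - o.b, self.c - o.c, self.d - o.d)

    def __rsub__(self, other) -> "QuaternionArray":
        return _as_qa(other) - self

    def __neg__(self) -> "QuaternionArray":
        return QuaternionArray(-self.a, -self.b, -self.c, -self.d)

    def __mul__(self, other) -> "QuaternionArray":
        if isinstance(other, QuaternionArray):
            return hamilton_product(self, other)
        return QuaternionArray(*(ch * other for ch in self._chs()))

    def __rmul__(self, other) -> "QuaternionArray":
        # real scalars commute with quaternions
        if isinstance(other, QuaternionArray):  # pragma: no cover - dispatch
            return hamilton_product(other, self)
        return QuaternionArray(*(other * ch for ch in self._chs()))

    def __truediv__(self, other) -> "QuaternionArray":
        return QuaternionArray(*(ch / other for ch in self._chs()))

    def __matmul__(self, other) -> "QuaternionArray":
        return qmat_mul(self, other)

    def conj(self) -> "QuaternionArray":
        return QuaternionArray(self.a, -self.b, -self.c, -self.d)

    def abs(self) -> np.ndarray:
        """Elementwise quaternion norm √(a²+b²+c²+d²) as a real array."""
        return np.sqrt(self.a**2 + self.b**2 + self.c**2 + self.d**2)

    def __abs__(self):
        return self.abs()

    @property
    def H(self) -> "QuaternionArray":
        """Conjugate transpose (2-D arrays only)."""
        return conj_transpose(self)

    def norm(self) -> float:
        """Frobenius-style norm of the whole array viewed as real coordinates."""
        return float(np.sqrt(sum(float(np.sum(ch**2)) for ch in self._chs())))

    def as_real_vector(self) -> np.ndarray:
        """Flatten to a 4L real vector (channel-major: all a's, b's, c's, d's)."""
        return np.concatenate([ch.ravel() for ch in self._chs()])

    def allclose(self, other, atol: float = 1e-12, rtol: float = 1e-9) -> bool:
        o = _as_qa(other)
        return all(
            np.allclose(s, t, atol=atol, rtol=rtol)
            for s, t in zip(self._chs(), o._chs())
        )


def _as_qa(x) -> QuaternionArray:
    if isinstance(x, QuaternionArray):
        return x
    return QuaternionArray.from_real(np.asarray(x, dtype=float))


def quaternion(a=0.0, b=0.0, c=0.0, d=0.0) -> QuaternionArray:
    """A single quaternion scalar (the 0-d array case)."""
    return QuaternionArray(np.float64(a), np.float64(b), np.float64(c), np.float64(d))


def hamilton_product(p: QuaternionArray, q: QuaternionArray) -> QuaternionArray:
    """Elementwise noncommutative Hamilton product; broadcasts like numpy."""
    p, q = _as_qa(p), _as_qa(q)
    a1, b1, c1, d1 = p._chs()
    a2, b2, c2, d2 = q._chs()
    return QuaternionArray(
        a1 * a2 - b1 * b2 - c1 * c2 - d1 * d2,
        a1 * b2 + b1 * a2 + c1 * d2 - d1 * c2,
        a1 * c2 - b1 * d2 + c1 * a2 + d1 * b2,
        a1 * d2 + b1 * c2 - c1 * b2 + d1 * a2,
    )


def qnorm(q: QuaternionArray) -> np.ndarray | float:
    """Quaternion norm √(a²+b²+c²+d²), elementwise; a float for 0-d input."""
    q = _as_qa(q)
    out = q.abs()
    return float(out) if out.ndim == 0 else out


def conj_transpose(M: QuaternionArray) -> QuaternionArray:
    """Conjugate transpose of a 2-D quaternion matrix; an involution."""
    if M.ndim != 2:
        raise ValueError(f"conj_transpose expects a 2-D array, got ndim={M.ndim}")
    return QuaternionArray(M.a.T, -M.b.T, -M.c.T, -M.d.T)


def qmat_mul(A: QuaternionArray, B: QuaternionArray) -> QuaternionArray:
    """Quaternion matrix product; entry (u,v) = Σ_w A_uw · B_wv, order preserved.

    Implemented as 16 real matrix products on the channels, which is exactly
    the Hamilton product expanded and summed.
    """
    A, B = _as_qa(A), _as_qa(B)
    if A.ndim != 2 or B.ndim != 2:
        raise ValueError("qmat_mul expects 2-D operands")
    if A.shape[1] != B.shape[0]:
        raise ValueError(f"inner dimensions disagree: {A.shape} @ {B.shape}")
    a1, b1, c1, d1 = A._chs()
    a2, b2, c2, d2 = B._chs()
    return QuaternionArray(
        a1 @ a2 - b1 @ b2 - c1 @ c2 - d1 @ d2,
        a1 @ b2 + b1 @ a2 + c1 @ d2 - d1 @ c2,
        a1 @ c2 - b1 @ d2 + c1 @ a2 + d1 @ b2,
        a1 @ d2 + b1 @ c2 - c1 @ b2 + d1 @ a2,
    )


def complex_adjoint(M: QuaternionArray) -> np.ndarray:
    """2n×2n complex adjoint of a square quaternion matrix.

    Writing each entry as the complex pair (z1, z2) = (a+bi, c+di), the entry
    maps to the 2×2 block [[z1, z2], [−conj(z2), conj(z1)]].  The map is a
    ring homomorphism, so eigen-structure is faithfully represented (each
    quaternion eigenvalue appears with doubled multiplicity).
    """
    M = _as_qa(M)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"complex_adjoint expects a square matrix, got {M.shape}")
    n = M.shape[0]
    z1 = M.a + 1j * M.b
    z2 = M.c + 1j * M.d
    out = np.empty((2 * n, 2 * n), dtype=complex)
    out[0::2, 0::2] = z1
    out[0::2, 1::2] = z2
    out[1::2, 0::2] = -np.conj(z2)
    out[1::2, 1::2] = np.conj(z1)
    return out


def qvec_distance(p: QuaternionArray, q: QuaternionArray) -> float:
    """Euclidean distance √(Σ_l |p_l − q_l|²) between two quaternion vectors.

    Identical to the Euclidean distance of the two vectors viewed as 4L real
    coordinates.
    """
    p, q = _as_qa(p), _as_qa(q)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    diff = p - q
    return float(np.sqrt(np.sum(diff.abs() ** 2)))


def qeye(n: int) -> QuaternionArray:
    """The n×n quaternion identity matrix."""
    return QuaternionArray.from_real(np.eye(n))


def save_quaternion_npz(path, **arrays: QuaternionArray) -> None:
    """Serialize named quaternion arrays as four-channel containers.

    Each array ``name`` is stored under key ``name`` as a ``(4,)+shape`` real
    array in the documented (a, b, c, d) channel order; round-trips bit-exact.
    """
    np.savez(path, **{k: v.channels() for k, v in arrays.items()})


def load_quaternion_npz(path) -> dict[str, QuaternionArray]:
    with np.load(path) as data:
        return {k: QuaternionArray.from_channels(data[k]) for k in data.files}
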