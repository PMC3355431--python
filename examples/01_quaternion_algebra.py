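"""Quaternion algebra basics and the complex-adjoint oracle.

Builds a few quaternions, checks the defining relations of Hamilton's
product, and shows that the complex-adjoint embedding reproduces the
eigenvalues of a quaternion Hermitian matrix (each with multiplicity 2).
"""

import numpy as np

from quatpalm import (
    QuaternionArray,
    complex_adjoint,
    conj_transpose,
    hamilton_product,
    qnorm,
    quaternion,
)

i, j, k = quaternion(0, 1), quaternion(0, 0, 1), quaternion(0, 0, 0, 1)
ij = hamilton_product(i, j)
print("i·j  =", ij.channels(), " (equals k: multiplication is noncommutative)")
print("j·i  =", hamilton_product(j, i).channels(), " (the negative of k)")

q = quaternion(3, 4, 0, 0)
print("|3+4i| =", qnorm(q), " (the 4-D Euclidean norm of the coefficients)")

rng = np.random.default_rng(0)
A = QuaternionArray(*rng.normal(size=(4, 5, 5)))
H = (A + conj_transpose(A)) * 0.5  # Hermitian: H equals its conjugate transpose
w = np.linalg.eigvalsh(complex_adjoint(H))
print("\nEigenvalues of the 10×10 complex adjoint of a 5×5 Hermitian H:")
print(np.round(w, 6))
print("They are real and come in pairs — each quaternion eigenvalue doubled.")
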