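"""Distance normalization, weighted score fusion, and nearest-neighbor
identification.

Each sample yields two feature vectors: a global QPCA projection and a local
QDWT block-σ vector.  Dissimilarity per feature type is the quaternion
Euclidean distance.  Before fusion each distance is divided by the
population standard deviation of that distance type over all unordered pairs
of the training (gallery) set, then the two normalized distances are
combined as

    d = w_QPCA · d̄_QPCA + w_QDWT · d̄_QDWT        (defaults 0.6 / 0.4)

and the probe is assigned the label of the gallery entry with the smallest
fused distance (rank-1 identification; ties go to the lowest gallery index).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from .quaternion import QuaternionArray, qvec_distance

__all__ = [
    "FeaturePair",
    "DistanceNormalizer",
    "FusionWeights",
    "Gallery",
    "feature_distances",
    "fit_normalizer",
    "fused_distance",
    "identify",
    "evaluate_accuracy",
]

logger = logging.getLogger(__name__)

_SIGMA_FLOOR = 1e-12


@dataclass
class FeaturePair:
    """The two per-sample feature vectors (QPCA global, QDWT local)."""

    qpca: QuaternionArray
    qdwt: QuaternionArray

    def as_real(self) -> tuple[np.ndarray, np.ndarray]:
        return self.qpca.as_real_vector(), self.qdwt.as_real_vector()


@dataclass
class DistanceNormalizer:
    """Training-set distance standard deviations (strictly positive)."""

    sigma_qpca: float
    sigma_qdwt: float

    def __post_init__(self):
        if self.sigma_qpca <= 0 or self.sigma_qdwt <= 0:
            raise ValueError("distance standard deviations must be positive")


@dataclass
class FusionWeights:
    """Convex weights for the two normalized distances; must sum to 1."""

    w_qpca: float = 0.6
    w_qdwt: float = 0.4

    def __post_init__(self):
        if not (0 <= self.w_qpca <= 1 and 0 <= self.w_qdwt <= 1):
            raise ValueError("weights must lie in [0, 1]")
        if abs(self.w_qpca + self.w_qdwt - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


@dataclass
class Gallery:
    """Enrolled samples: labels plus stacked real feature matrices.

    ``qpca_mat`` and ``qdwt_mat`` are N×4p / N×4h real design matrices (one
    row per entry, quaternion channels concatenated), which makes pairwise
    quaternion Euclidean distances ordinary Euclidean row distances.
    """

    labels: list
    qpca_mat: np.ndarray
    qdwt_mat: np.ndarray
    normalizer: DistanceNormalizer | None = None
    weights: FusionWeights = field(default_factory=FusionWeights)

    def __post_init__(self):
        if len(self.labels) == 0:
            raise ValueError("gallery must be nonempty")
        if self.qpca_mat.shape[0] != len(self.labels) or \
           self.qdwt_mat.shape[0] != len(self.labels):
            raise ValueError("feature matrix rows must match label count")

    @classmethod
    def from_pairs(cls, labels, pairs, **kw) -> "Gallery":
        qp = np.stack([p.qpca.as_real_vector() for p in pairs])
        qd = np.stack([p.qdwt.as_real_vector() for p in pairs])
        return cls(list(labels), qp, qd, **kw)

    def __len__(self) -> int:
        return len(self.labels)


def feature_distances(u: FeaturePair, v: FeaturePair) -> tuple[float, float]:
    """(QPCA distance, QDWT distance) between two samples' features."""
    return (qvec_distance(u.qpca, v.qpca), qvec_distance(u.qdwt, v.qdwt))


def _pop_std(x: np.ndarray) -> float:
    return float(np.std(x))  # population (ddof=0)


def fit_normalizer(gallery: Gallery) -> DistanceNormalizer:
    """Population σ of each distance type over all unordered training pairs.

    Degenerate galleries (identical features throughout) are floored at
    1e-12 with a warning so downstream fusion never divides by zero.
    """
    if len(gallery) < 3:
        raise ValueError("need at least 3 gallery entries to fit a normalizer")
    sig_qpca = _pop_std(pdist(gallery.qpca_mat))
    sig_qdwt = _pop_std(pdist(gallery.qdwt_mat))
    if sig_qpca < _SIGMA_FLOOR or sig_qdwt < _SIGMA_FLOOR:
        logger.warning(
            "degenerate training distances (σ_QPCA=%.3g, σ_QDWT=%.3g); flooring",
            sig_qpca, sig_qdwt,
        )
    return DistanceNormalizer(
        sigma_qpca=max(sig_qpca, _SIGMA_FLOOR),
        sigma_qdwt=max(sig_qdwt, _SIGMA_FLOOR),
    )


def fused_distance(
    u: FeaturePair,
    v: FeaturePair,
    norm: DistanceNormalizer,
    w: FusionWeights | None = None,
) -> float:
    """Weighted sum of the σ-normalized QPCA and QDWT distances."""
    w = w or FusionWeights()
    d_qpca, d_qdwt = feature_distances(u, v)
    return w.w_qpca * d_qpca / norm.sigma_qpca + w.w_qdwt * d_qdwt / norm.sigma_qdwt


def _fused_matrix(gallery: Gallery, qp_rows: np.ndarray, qd_rows: np.ndarray) -> np.ndarray:
    """Fused distances between probe feature rows and every gallery entry."""
    norm = gallery.normalizer
    if norm is None:
        raise ValueError("gallery has no fitted normalizer")
    w = gallery.weights
    d1 = cdist(qp_rows, gallery.qpca_mat)
    d2 = cdist(qd_rows, gallery.qdwt_mat)
    return w.w_qpca * d1 / norm.sigma_qpca + w.w_qdwt * d2 / norm.sigma_qdwt


def identify(probe: FeaturePair, gallery: Gallery):
    """Label of the nearest gallery entry under the fused distance, plus the
    distance itself; ties break to the lowest gallery index."""
    qp, qd = probe.as_real()
    dists = _fused_matrix(gallery, qp[None, :], qd[None, :])[0]
    j = int(np.argmin(dists))  # argmin returns the first minimizer
    return gallery.labels[j], float(dists[j])


def evaluate_accuracy(gallery: Gallery, probes, return_report: bool = False):
    """Rank-1 identification rate of labeled probes against the gallery.

    ``probes`` is a sequence of (label, FeaturePair).  With ``return_report``
    a per-probe DataFrame (true/predicted labels and distances) accompanies
    the accuracy.
    """
    probes = list(probes)
    if not probes:
        raise ValueError("empty probe set")
    labels = [l for l, _ in probes]
    qp = np.stack([p.qpca.as_real_vector() for _, p in probes])
    qd = np.stack([p.qdwt.as_real_vector() for _, p in probes])
    fused = _fused_matrix(gallery, qp, qd)
    nearest = np.argmin(fused, axis=1)
    predicted = [gallery.labels[j] for j in nearest]
    hits = [t == p for t, p in zip(labels, predicted)]
    accuracy = float(np.mean(hits))
    if not return_report:
        return accuracy
    d1 = cdist(qp, gallery.qpca_mat)
    d2 = cdist(qd, gallery.qdwt_mat)
    rows = []
    for i, (t, p, j) in enumerate(zip(labels, predicted, nearest)):
        rows.append({
            "probe": i, "true_label": t, "predicted_label": p,
            "fused_distance": fused[i, j],
            "d_qpca": d1[i, j],
            "d_qdwt": d2[i, j],
            "correct": bool(t == p),
        })
    return accuracy, pd.DataFrame(rows)
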