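"""Per-band ROI preprocessing and quaternion image construction.

A multispectral palmprint sample is up to four co-registered grayscale ROI
images captured under NIR, red, green and blue illumination.  Preprocessing
is: histogram equalization per band (removes global intensity differences
between illuminations), block-mean downsampling (nominally 128×128 → 64×64),
then assembly into a single quaternion image

    Q(x, y) = I(x, y) + R(x, y)·i + G(x, y)·j + B(x, y)·k

with the NIR band in the real channel.  A missing band contributes a zero
channel, so galleries captured with fewer than four illuminations still fit
the same representation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import exposure

from .quaternion import QuaternionArray

__all__ = [
    "BANDS",
    "MultispectralSample",
    "hist_equalize",
    "downsample",
    "center_crop",
    "build_quaternion_image",
    "vectorize",
    "write_dataset",
    "read_dataset",
]

#: canonical band order; matches the quaternion channel order (a, b, c, d)
BANDS = ("nir", "red", "green", "blue")


@dataclass
class MultispectralSample:
    """Up to four aligned band images plus identity metadata.

    ``bands`` maps band name → H×W float image in [0, 1]; absent keys (or
    ``None`` values) are unavailable bands.  All present bands must share one
    shape and at least one band must be available.
    """

    bands: dict[str, np.ndarray]
    label: int | str
    instance_id: int = 0

    def __post_init__(self):
        self.bands = {
            k: np.asarray(v, dtype=float)
            for k, v in self.bands.items()
            if v is not None
        }
        unknown = set(self.bands) - set(BANDS)
        if unknown:
            raise ValueError(f"unknown band keys: {sorted(unknown)}")
        if not self.bands:
            raise ValueError("a sample needs at least one available band")
        shapes = {v.shape for v in self.bands.values()}
        if len(shapes) != 1:
            raise ValueError(f"band shapes disagree: {shapes}")

    @property
    def availability(self) -> tuple[bool, bool, bool, bool]:
        return tuple(b in self.bands for b in BANDS)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    def with_band_mask(self, mask) -> "MultispectralSample":
        """Keep only the bands flagged in ``mask`` (length-4, BANDS order)."""
        kept = {b: img for b, (keep, img) in
                zip(BANDS, ((m, self.bands.get(b)) for m, b in zip(mask, BANDS)))
                if keep and img is not None}
        return MultispectralSample(kept, self.label, self.instance_id)


def hist_equalize(band: np.ndarray) -> np.ndarray:
    """256-bin cumulative-histogram equalization, output in [0, 1].

    8-bit input is rescaled to the unit interval first.  A constant image is
    returned unchanged (degenerate histogram: there is no contrast to spread).
    """
    band = np.asarray(band, dtype=float)
    if band.size == 0:
        raise ValueError("empty image")
    if band.max() > 1.0:
        band = band / 255.0
    if np.ptp(band) == 0:
        return np.clip(band, 0.0, 1.0)
    return exposure.equalize_hist(band, nbins=256)


def downsample(band: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean decimation by an integer factor (anti-aliased)."""
    band = np.asarray(band, dtype=float)
    if factor == 1:
        return band.copy()
    h, w = band.shape
    if h % factor or w % factor:
        raise ValueError(f"image shape {band.shape} not divisible by {factor}")
    return band.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))


def center_crop(band: np.ndarray, size: int) -> np.ndarray:
    """Central size×size crop; stands in for full coordinate-system ROI
    localization when inputs are larger than the ROI."""
    h, w = band.shape
    if h < size or w < size:
        raise ValueError(f"image {band.shape} smaller than crop size {size}")
    r0, c0 = (h - size) // 2, (w - size) // 2
    return band[r0 : r0 + size, c0 : c0 + size]


def build_quaternion_image(sample: MultispectralSample) -> QuaternionArray:
    """Assemble Q = I + R·i + G·j + B·k; unavailable bands become zero channels."""
    h, w = sample.shape
    chans = [
        np.asarray(sample.bands[b], dtype=float) if b in sample.bands
        else np.zeros((h, w))
        for b in BANDS
    ]
    return QuaternionArray(*chans)


def vectorize(Q: QuaternionArray) -> QuaternionArray:
    """Row-major flattening of a quaternion image: (x, y) ↦ x·W + y."""
    return Q.ravel()


# --------------------------------------------------------------------- I/O

def _band_path(root: Path, label, instance_id: int, band: str) -> Path:
    return root / str(label) / f"{instance_id}_{band}.png"


def write_dataset(samples, root, manifest: str | None = "manifest.csv") -> pd.DataFrame:
    """Write samples as ``<root>/<subject>/<instance>_<band>.png`` plus a
    CSV manifest (subject, instance, band, path).  Images are quantized to
    8 bits; values are assumed to lie in [0, 1]."""
    root = Path(root)
    rows = []
    for s in samples:
        for band, img in s.bands.items():
            p = _band_path(root, s.label, s.instance_id, band)
            p.parent.mkdir(parents=True, exist_ok=True)
            u8 = np.clip(np.rint(np.asarray(img) * 255.0), 0, 255).astype(np.uint8)
            iio.imwrite(p, u8)
            rows.append(
                {"subject": s.label, "instance": s.instance_id, "band": band,
                 "path": os.path.relpath(p, root)}
            )
    df = pd.DataFrame(rows, columns=["subject", "instance", "band", "path"])
    if manifest:
        df.to_csv(root / manifest, index=False)
    return df


def read_dataset(source) -> list[MultispectralSample]:
    """Read a dataset from a directory layout or a CSV manifest.

    ``source`` is either a directory written by :func:`write_dataset` (a
    ``manifest.csv`` inside it is used when present, else the layout is
    globbed) or a manifest CSV path with columns subject, instance, band,
    path (paths relative to the manifest's directory).
    """
    source = Path(source)
    if source.is_dir():
        manifest = source / "manifest.csv"
        if manifest.exists():
            return _read_manifest(manifest)
        return _read_layout(source)
    return _read_manifest(source)


def _read_manifest(manifest: Path) -> list[MultispectralSample]:
    root = manifest.parent
    df = pd.read_csv(manifest)
    samples = []
    for (subject, instance), grp in df.groupby(["subject", "instance"], sort=True):
        bands = {}
        for _, row in grp.iterrows():
            band = str(row["band"]).lower()
            if band not in BANDS:
                raise ValueError(f"manifest row has unknown band {band!r}")
            img = iio.imread(root / row["path"])
            bands[band] = np.asarray(img, dtype=float) / 255.0
        samples.append(MultispectralSample(bands, label=subject, instance_id=int(instance)))
    return samples


def _read_layout(root: Path) -> list[MultispectralSample]:
    samples = []
    for subj_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        by_instance: dict[int, dict[str, np.ndarray]] = {}
        for f in sorted(subj_dir.glob("*_*.png")):
            inst_str, band = f.stem.rsplit("_", 1)
            if band not in BANDS:
                continue
            img = np.asarray(iio.imread(f), dtype=float) / 255.0
            by_instance.setdefault(int(inst_str), {})[band] = img
        for inst in sorted(by_instance):
            samples.append(
                MultispectralSample(by_instance[inst], label=subj_dir.name, instance_id=inst)
            )
    if not samples:
        raise ValueError(f"no samples found under {root}")
    return samples
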