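"""Volume-to-bag preprocessing: DICOM series to ordered slices, center cropping.

Mirrors the standard preparation for slice-bag models: each 3D volume is read
as a single-series DICOM set, slices are ordered by their spatial position
along the slice normal (instance number as fallback), intensities are min-max
scaled to [0, 1] per volume, and a centered 224×224 patch is cropped from
each slice.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

CROP_SIZE = 224


def dicom_to_slices(series_dir: str | Path) -> np.ndarray:
    """Read one single-series DICOM directory into an ordered (K, H, W) array.

    Slices are sorted by the projection of ImagePositionPatient onto the
    slice normal (the cross product of the two ImageOrientationPatient row
    vectors); if position tags are missing, InstanceNumber order is used.
    Intensities are min-max scaled to [0, 1] over the whole volume; a
    constant volume maps to all zeros.

    Raises a descriptive error for an empty directory or mixed series UIDs.
    """
    import pydicom

    series_dir = Path(series_dir)
    files = sorted(p for p in series_dir.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(p))
        except Exception:  # not a DICOM file (e.g. stray text) — skip
            continue
    if not datasets:
        raise ValueError(f"no readable DICOM files in {series_dir}")

    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(uids) > 1:
        raise ValueError(
            f"directory {series_dir} mixes {len(uids)} series (SeriesInstanceUID values: {sorted(uids)})"
        )

    def sort_key(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        ori = getattr(ds, "ImageOrientationPatient", None)
        if pos is not None and ori is not None:
            row = np.asarray(ori[:3], dtype=float)
            col = np.asarray(ori[3:], dtype=float)
            normal = np.cross(row, col)
            return float(np.dot(np.asarray(pos, dtype=float), normal))
        inst = getattr(ds, "InstanceNumber", None)
        if inst is None:
            raise ValueError(
                "DICOM slice lacks both ImagePositionPatient and InstanceNumber; cannot order slices"
            )
        return float(inst)

    datasets.sort(key=sort_key)
    volume = np.stack([ds.pixel_array.astype(float) for ds in datasets])
    vmin, vmax = volume.min(), volume.max()
    if vmax > vmin:
        volume = (volume - vmin) / (vmax - vmin)
    else:
        # degenerate constant volume: map everything to 0
        volume = np.zeros_like(volume)
    return volume


def center_crop(image: np.ndarray, size: int = CROP_SIZE) -> np.ndarray:
    """Crop a centered ``size``×``size`` patch; floor convention for odd remainders.

    An input smaller than ``size`` in either dimension is zero-padded
    symmetrically to ``size`` first (with a logged warning), then cropped.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("center_crop expects a 2D array")
    H, W = image.shape
    if H < size or W < size:
        logger.warning(
            "input %dx%d smaller than crop size %d; zero-padding before crop", H, W, size
        )
        ph, pw = max(size - H, 0), max(size - W, 0)
        image = np.pad(
            image,
            ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)),
        )
        H, W = image.shape
    r0 = (H - size) // 2
    c0 = (W - size) // 2
    return image[r0 : r0 + size, c0 : c0 + size]


def crop_bag(slices: np.ndarray, size: int = CROP_SIZE) -> np.ndarray:
    """Apply :func:`center_crop` to every slice of a (K, H, W) stack."""
    return np.stack([center_crop(s, size) for s in slices])


def preprocess_series(series_dir: str | Path, size: int = CROP_SIZE) -> np.ndarray:
    """DICOM series directory -> ordered, scaled, center-cropped (K, size, size) stack."""
    return crop_bag(dicom_to_slices(series_dir), size)
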