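"""Reading CT input (DICOM series, NIfTI volumes, PNG slices) and writing masks.

DICOM intensities are converted with RescaleSlope/RescaleIntercept when
present; 16-bit PNG fixtures are taken as raw calibrated units.  NIfTI
volumes are split slice-by-slice along the last axis with spacing taken
from the header zooms.
"""

from __future__ import annotations

from pathlib import Path
from typing import List

import numpy as np

from .core import BinaryMask, CtSlice, InvalidInputError

__all__ = [
    "read_slices",
    "write_mask_png",
    "write_slice_png16",
    "write_labels_nifti",
]


def _read_nifti(path: Path) -> List[CtSlice]:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    zooms = img.header.get_zooms()
    spacing = (float(zooms[0]), float(zooms[1]))
    if data.ndim == 2:
        data = data[..., None]
    if data.ndim != 3:
        raise InvalidInputError(f"{path}: expected 2-D or 3-D NIfTI, got ndim={data.ndim}")
    return [
        CtSlice(data[..., k], spacing_mm=spacing, id=f"{path.stem}_s{k:03d}")
        for k in range(data.shape[-1])
    ]


def _read_png(path: Path, spacing_mm=(0.6, 0.6)) -> CtSlice:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path)).astype(np.float64)
    if arr.ndim == 3:  # collapse any color axis; CT fixtures are grayscale
        arr = arr.mean(axis=-1)
    return CtSlice(arr, spacing_mm=spacing_mm, id=path.stem)


def _read_dicom_dir(path: Path) -> List[CtSlice]:
    import pydicom

    files = sorted(path.glob("*.dcm")) or sorted(
        p for p in path.iterdir() if p.is_file()
    )
    out: List[CtSlice] = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception as exc:  # unreadable file: report, continue
            import warnings

            warnings.warn(f"skipping unreadable DICOM {f}: {exc}", stacklevel=2)
            continue
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        sp = getattr(ds, "PixelSpacing", [0.6, 0.6])
        out.append(
            CtSlice(arr, spacing_mm=(float(sp[0]), float(sp[1])), id=f.stem)
        )
    return out


def read_slices(path: str | Path, spacing_mm=(0.6, 0.6)) -> List[CtSlice]:
    """Read a slice stack from a NIfTI file, a PNG file/dir, or a DICOM dir."""
    p = Path(path)
    if p.is_dir():
        pngs = sorted(p.glob("*.png"))
        if pngs:
            return [_read_png(f, spacing_mm) for f in pngs]
        return _read_dicom_dir(p)
    suffixes = "".join(p.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        return _read_nifti(p)
    if p.suffix == ".png":
        return [_read_png(p, spacing_mm)]
    raise InvalidInputError(f"unsupported input {p}")


def write_mask_png(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as 8-bit PNG (0/255)."""
    import imageio.v3 as iio

    iio.imwrite(str(path), (mask.pixels.astype(np.uint8) * 255))


def write_slice_png16(slice_: CtSlice, path: str | Path) -> None:
    """Write a slice as 16-bit grayscale PNG (clipped to [0, 65535])."""
    import imageio.v3 as iio

    arr = np.clip(np.round(slice_.pixels), 0, 65535).astype(np.uint16)
    iio.imwrite(str(path), arr)


def write_labels_nifti(labels: np.ndarray, path: str | Path, spacing_mm=(0.6, 0.6)) -> None:
    """Write a 2-D label image (or stack) as an int16 NIfTI label map."""
    import nibabel as nib

    arr = np.asarray(labels)
    if arr.ndim == 2:
        arr = arr[..., None]
    aff = np.diag([spacing_mm[0], spacing_mm[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(arr.astype(np.int16), aff), str(path))
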