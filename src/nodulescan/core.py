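"""Core containers shared by every pipeline stage.

A CT scan is processed one 2-D slice at a time.  :class:`CtSlice` carries
the calibrated intensity array plus the pixel spacing needed to convert
component areas to millimetres; :class:`BinaryMask` is a boolean image
aligned to a slice and tagged with the role it plays in the pipeline
(lung field, intermediate threshold band, final candidate mask, or
retained nodule mask).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = ["CtSlice", "BinaryMask", "MaskRole", "InvalidInputError"]


class InvalidInputError(ValueError):
    """Raised when an input violates a stage's preconditions."""


#: Allowed roles for a BinaryMask.
MaskRole = ("lung", "intermediate", "final", "nodule")


@dataclass
class CtSlice:
    """One 2-D grayscale CT slice.

    Parameters
    ----------
    pixels
        2-D array of calibrated intensities (typically a 12-bit range).
        Stored as float64; means and PDE updates are not integral.
    spacing_mm
        (row, col) pixel size in millimetres.
    id
        Slice identifier used in logs and CSV output.
    """

    pixels: np.ndarray
    spacing_mm: Tuple[float, float] = (0.6, 0.6)
    id: str = "slice"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise InvalidInputError(
                f"slice {self.id!r}: pixels must be 2-D with >=2 rows and cols, "
                f"got shape {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise InvalidInputError(f"slice {self.id!r}: non-finite intensities")
        r, c = self.spacing_mm
        if r <= 0 or c <= 0:
            raise InvalidInputError(f"slice {self.id!r}: non-positive spacing {self.spacing_mm}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, suffix: str = "") -> "CtSlice":
        """A copy of this slice with new pixel data and the same geometry."""
        return CtSlice(pixels=pixels, spacing_mm=self.spacing_mm, id=self.id + suffix)


@dataclass
class BinaryMask:
    """A boolean image aligned to a :class:`CtSlice`.

    The ``role`` tag records which pipeline product the mask is: the
    segmented lung field, one of the four intermediate threshold-band
    masks, the summed final candidate mask, or the post-filter nodule
    mask.
    """

    pixels: np.ndarray
    role: str = "intermediate"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise InvalidInputError(f"mask must be 2-D, got shape {self.pixels.shape}")
        if self.role not in MaskRole:
            raise InvalidInputError(f"unknown mask role {self.role!r}; expected one of {MaskRole}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    def area(self) -> int:
        """Number of true pixels."""
        return int(self.pixels.sum())

    def with_pixels(self, pixels: np.ndarray, role: str | None = None) -> "BinaryMask":
        return BinaryMask(pixels=pixels, role=role if role is not None else self.role)


def check_aligned(a, b, what: str = "inputs") -> None:
    """Raise InvalidInputError unless the two images share a shape."""
    if a.shape != b.shape:
        raise InvalidInputError(f"{what}: shape mismatch {a.shape} vs {b.shape}")
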