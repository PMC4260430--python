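"""Variable multistep threshold candidate generation.

Nodules sit in a band of intensities around the slice's density
threshold.  Five ordered thresholds are derived from the base density
threshold T and a step of one tenth of the slice's maximum lung
intensity:

    Th1 = T + 2*step  >  Th2 = T + step  >  Th3 = T
                      >  Th4 = T - step  >  Th5 = T - 2*step

The four half-open bands (Th2,Th1], (Th3,Th2], (Th4,Th3], (Th5,Th4]
partition (Th5, Th1]; each is binarized, cleaned by morphological
opening with a disk of radius 2 (which deletes specks and thin
structures), and the four intermediate masks are summed into the final
candidate mask.  Candidates are then cut out of the slice by array
multiplication and labeled with 8-connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import morphology

from .core import BinaryMask, CtSlice, InvalidInputError, check_aligned

__all__ = [
    "ThresholdSet",
    "CandidateSet",
    "compute_threshold_set",
    "band_mask",
    "intermediate_mask",
    "final_mask",
    "segment_candidates",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ThresholdSet:
    """Base threshold, step, and the five ordered thresholds Th1..Th5."""

    base: float
    step: float
    th: Tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise InvalidInputError(f"step must be > 0, got {self.step}")
        if not all(a > b for a, b in zip(self.th, self.th[1:])):
            raise InvalidInputError(f"thresholds must be strictly decreasing, got {self.th}")

    @property
    def bands(self) -> List[Tuple[float, float]]:
        """The four (hi, lo) band bounds, highest band first."""
        return [(self.th[k], self.th[k + 1]) for k in range(4)]


@dataclass
class CandidateSet:
    """Final candidate mask, its component labeling, and the cut-out slice."""

    final_mask: BinaryMask
    labels: np.ndarray
    n_components: int
    segmented: CtSlice


def compute_threshold_set(
    slice_: CtSlice,
    base: float,
    max_intensity: float | None = None,
) -> ThresholdSet:
    """Build the five-threshold set around the base density threshold.

    ``step`` is one tenth of the slice's maximum intensity.  When the
    bands are applied to the lung-masked image, pass the maximum over
    the lung region as ``max_intensity`` so exterior fill values cannot
    distort the step; by default the maximum of the whole slice is used.
    """
    m = float(slice_.pixels.max() if max_intensity is None else max_intensity)
    if m <= 0:
        raise InvalidInputError(f"maximum intensity must be > 0 to form a step, got {m}")
    step = m / 10.0
    th = (base + 2 * step, base + step, base, base - step, base - 2 * step)
    return ThresholdSet(base=base, step=step, th=th)


def band_mask(slice_: CtSlice, hi: float, lo: float) -> BinaryMask:
    """True exactly where ``lo < pixel <= hi`` (half-open band)."""
    if hi <= lo:
        raise InvalidInputError(f"band requires hi > lo, got hi={hi}, lo={lo}")
    px = slice_.pixels
    return BinaryMask((px > lo) & (px <= hi), role="intermediate")


def intermediate_mask(
    slice_: CtSlice, hi: float, lo: float, open_radius: int = 2
) -> BinaryMask:
    """Band mask cleaned by opening with a disk of radius ``open_radius``."""
    band = band_mask(slice_, hi, lo)
    if open_radius < 1:
        return band
    opened = morphology.opening(band.pixels, morphology.disk(open_radius))
    return band.with_pixels(opened)


def final_mask(ims: Sequence[BinaryMask]) -> BinaryMask:
    """Sum the four intermediate masks and binarize.

    The raw bands are disjoint, so the pixelwise sum is already 0/1;
    after opening the dilation can re-overlap bands, and binarizing
    (sum >= 1) keeps the result a binary mask.
    """
    if len(ims) != 4:
        raise InvalidInputError(f"expected exactly 4 intermediate masks, got {len(ims)}")
    shape = ims[0].shape
    for m in ims[1:]:
        check_aligned(ims[0].pixels, m.pixels, "intermediate masks")
    total = np.zeros(shape, dtype=np.int64)
    for m in ims:
        total += m.pixels.astype(np.int64)
    return BinaryMask(total >= 1, role="final")


def segment_candidates(slice_: CtSlice, mask: BinaryMask) -> CandidateSet:
    """Cut candidates out of the slice and label them.

    ``segmented`` is the elementwise product of slice and mask (zero
    outside the candidate mask); components are labeled with
    8-connectivity.
    """
    check_aligned(slice_.pixels, mask.pixels, "slice vs candidate mask")
    labels, n = ndimage.label(mask.pixels, structure=_STRUCT8)
    segmented = slice_.with_pixels(slice_.pixels * mask.pixels, suffix="")
    return CandidateSet(
        final_mask=mask if mask.role == "final" else mask.with_pixels(mask.pixels, "final"),
        labels=labels,
        n_components=int(n),
        segmented=segmented,
    )
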