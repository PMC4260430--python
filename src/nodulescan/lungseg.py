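"""Lung-field segmentation from a single CT slice.

The lung fields are dark (low attenuation) against the bright chest
wall, so they are approximated by keeping pixels at or below the
density threshold, then cleaned up in four steps:

1. drop every connected component touching the image border (exterior
   air, couch and reconstruction artifacts);
2. fill closed gaps inside the lungs (bright vessels and nodules punch
   holes in the binarized field);
3. remove the trachea, which is dark like the lungs but much smaller
   than either lung field;
4. smooth the lung boundary by morphological closing with a disk of
   radius 2, then refill holes the closing sealed, which recovers the
   indentations left by nodules attached to the pleural wall.

Component labeling uses 8-connectivity; hole filling uses the dual
4-connected background, the standard pairing that avoids topological
paradoxes on the digital grid.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage import morphology

from .core import BinaryMask, CtSlice, InvalidInputError, check_aligned

__all__ = [
    "binarize_lung_candidates",
    "remove_border_connected",
    "fill_holes",
    "remove_trachea",
    "smooth_boundary",
    "segment_lungs",
]

# 8-connectivity for foreground components, 4-connectivity for the
# background of the hole fill (grid duality).
_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


def binarize_lung_candidates(slice_: CtSlice, t: float) -> BinaryMask:
    """Mask of pixels at or below the density threshold ``t``.

    Lungs (and exterior air) are low-density, so the dark side of the
    threshold — pixel <= t — is kept.
    """
    return BinaryMask(slice_.pixels <= t, role="lung")


def remove_border_connected(mask: BinaryMask, connectivity: int = 8) -> BinaryMask:
    """Remove every connected component that touches the image border."""
    if connectivity not in (4, 8):
        raise InvalidInputError(f"connectivity must be 4 or 8, got {connectivity}")
    struct = _STRUCT8 if connectivity == 8 else _STRUCT4
    labels, _ = ndimage.label(mask.pixels, structure=struct)
    border = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    border = border[border != 0]
    out = mask.pixels & ~np.isin(labels, border)
    return mask.with_pixels(out)


def fill_holes(mask: BinaryMask) -> BinaryMask:
    """Fill every false region not connected to the image border.

    True pixels never flip; the output is a superset of the input.
    """
    filled = ndimage.binary_fill_holes(mask.pixels, structure=_STRUCT4)
    return mask.with_pixels(filled)


def remove_trachea(mask: BinaryMask) -> BinaryMask:
    """Keep the two largest components; drop smaller dark regions.

    The trachea is dark like the lungs but anatomically smaller than
    either lung field, so relative size alone identifies it.  With two
    or fewer components the mask is returned unchanged (near the carina
    the lungs can merge into one region; forcing two would split real
    anatomy).
    """
    labels, n = ndimage.label(mask.pixels, structure=_STRUCT8)
    if n <= 2:
        return mask.with_pixels(mask.pixels.copy())
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.argsort(areas)[-2:] + 1
    return mask.with_pixels(np.isin(labels, keep))


def smooth_boundary(mask: BinaryMask, radius: int = 2) -> BinaryMask:
    """Morphological closing with a disk structuring element.

    Radius 2 smooths the demarcation along the lung boundary without
    pulling in chest-wall tissue (radius 1 leaves parts of the lung
    uncovered, radius 3 annexes chest body).
    """
    if radius < 1:
        raise InvalidInputError(f"radius must be >= 1, got {radius}")
    closed = morphology.closing(mask.pixels, morphology.disk(radius))
    return mask.with_pixels(closed)


def segment_lungs(
    slice_: CtSlice,
    t: float,
    close_radius: int = 2,
    refill: bool = True,
) -> BinaryMask:
    """Full lung-field segmentation at density threshold ``t``.

    Pipeline: binarize -> remove border-connected objects -> fill holes
    -> remove trachea -> close boundary (disk radius ``close_radius``)
    -> refill holes sealed by the closing.  The final refill matters for
    juxtapleural nodules: a pleura-attached nodule is bright, so it
    leaves a notch in the binarized lung open to the chest wall; the
    closing seals the narrow opening and the refill then restores the
    nodule area to the lung field, keeping it visible downstream.

    Returns an empty mask with a warning when nothing survives (the
    slice is likely outside the lung range).
    """
    m = binarize_lung_candidates(slice_, t)
    m = remove_border_connected(m)
    m = fill_holes(m)
    m = remove_trachea(m)
    m = smooth_boundary(m, radius=close_radius)
    if refill:
        m = fill_holes(m)
    if not m.pixels.any():
        warnings.warn(
            f"slice {slice_.id!r}: no lung component survived segmentation "
            f"at threshold {t:.1f}; slice may be outside the lung range",
            stacklevel=2,
        )
    m.role = "lung"
    return m
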