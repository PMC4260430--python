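"""Shape-index false-positive reduction.

The shape index classifies the local geometry of the intensity graph
surface z = I(x, y) from its principal curvatures k1 >= k2:

    SI = 1/2 - (1/pi) * arctan( (k1 + k2) / (k1 - k2) )

With the sign convention that a concave-up bowl has positive
curvatures, the five canonical classes score

    cup 0.00, rut 0.25, saddle 0.50, ridge 0.75, cap 1.00.

A bright nodule is a cap of the intensity surface (both curvatures
negative) and scores near 1; a bright vessel is a ridge (one curvature
near zero) and scores near 0.75.  Candidate components whose mean shape
index does not exceed the 0.76 threshold are removed: vessels, airway
walls and other elongated or saddle-like structures, leaving the
blob-like nodule candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy import ndimage

from .candidates import CandidateSet
from .core import CtSlice, InvalidInputError, check_aligned

__all__ = [
    "ShapeIndexMap",
    "ScoredCandidate",
    "principal_curvatures",
    "shape_index_at",
    "shape_index_map",
    "filter_by_shape_index",
]


@dataclass
class ShapeIndexMap:
    """Per-pixel principal curvatures and shape index.

    ``si`` is NaN where the shape index is undefined (k1 = k2 = 0,
    a perfectly flat locus); ``defined`` flags the valid pixels.
    """

    k1: np.ndarray
    k2: np.ndarray
    si: np.ndarray
    sigma: float

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.si)


@dataclass
class ScoredCandidate:
    """One candidate component scored by its mean shape index."""

    label: int
    mean_si: float
    area_px: int
    centroid: Tuple[float, float]
    equiv_diameter_mm: float
    is_nodule: bool


def principal_curvatures(
    slice_: CtSlice, sigma: float = 1.5, metric: str = "hessian"
) -> Tuple[np.ndarray, np.ndarray]:
    """Principal curvatures of the intensity surface z = I(x, y).

    Derivatives are Gaussian derivatives at scale ``sigma`` pixels.
    With ``metric="hessian"`` (default) the curvatures are the
    eigenvalues of the smoothed Hessian — the graph-surface curvatures
    in the low-slope limit.  This is the scale-free choice: the shape
    index then depends only on the eigenvalue *ratio*, not on the
    intensity units, which is what lets one threshold serve a 12-bit
    intensity range.  With ``metric="graph"`` the full first-fundamental
    form is kept (second fundamental form over first); on calibrated CT
    amplitudes the steep flanks of any structure then degenerate
    towards cylinder-like geometry, so this mode is mainly useful for
    analytic low-amplitude surfaces.

    Sign convention: a concave-up quadratic bowl I = (x^2 + y^2) / 2
    has k1 = k2 = +1 at the apex, so bright blobs — intensity maxima —
    carry negative curvatures and land in the cap class.  Returned
    ordered k1 >= k2.
    """
    if sigma <= 0.5:
        raise InvalidInputError(f"sigma must exceed 0.5 px, got {sigma}")
    if metric not in ("hessian", "graph"):
        raise InvalidInputError(f"metric must be 'hessian' or 'graph', got {metric!r}")
    # Centring removes the truncation residue of the discrete derivative
    # kernels, which is proportional to the absolute intensity level
    # (a constant image must have exactly zero derivatives).
    I = slice_.pixels - slice_.pixels.mean()
    _g = dict(mode="nearest", truncate=8.0)
    # axis 0 = rows = y, axis 1 = cols = x; the labels are interchangeable
    # for curvature purposes as long as they are used consistently.
    r = ndimage.gaussian_filter(I, sigma, order=(0, 2), **_g)  # Ixx
    t = ndimage.gaussian_filter(I, sigma, order=(2, 0), **_g)  # Iyy
    s = ndimage.gaussian_filter(I, sigma, order=(1, 1), **_g)  # Ixy

    if metric == "hessian":
        H = (r + t) / 2.0
        K = r * t - s * s
    else:
        p = ndimage.gaussian_filter(I, sigma, order=(0, 1), **_g)  # Ix
        q = ndimage.gaussian_filter(I, sigma, order=(1, 0), **_g)  # Iy
        w = np.sqrt(1.0 + p * p + q * q)
        E = 1.0 + p * p
        F = p * q
        G = 1.0 + q * q
        L, M, N = r / w, s / w, t / w
        denom = E * G - F * F  # = w^2 >= 1
        K = (L * N - M * M) / denom
        H = (E * N - 2.0 * F * M + G * L) / (2.0 * denom)
    disc = np.sqrt(np.maximum(H * H - K, 0.0))
    return H + disc, H - disc


def shape_index_at(k1, k2):
    """Shape index from ordered principal curvatures (scalar or array).

    Evaluates ``1/2 - (1/pi) arctan((k1 + k2)/(k1 - k2))``.  The
    symmetric limits are taken explicitly: k1 = k2 < 0 (cap) gives 1,
    k1 = k2 > 0 (cup) gives 0, and k1 = k2 = 0 is undefined (NaN).
    Inputs are expected ordered k1 >= k2; unordered pairs are sorted.
    """
    k1 = np.asarray(k1, dtype=np.float64)
    k2 = np.asarray(k2, dtype=np.float64)
    hi = np.maximum(k1, k2)
    lo = np.minimum(k1, k2)
    diff = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        si = 0.5 - np.arctan((hi + lo) / diff) / np.pi
    equal = diff == 0
    si = np.where(equal & (hi < 0), 1.0, si)
    si = np.where(equal & (hi > 0), 0.0, si)
    si = np.where(equal & (hi == 0), np.nan, si)
    if si.ndim == 0:
        return float(si)
    return si


def shape_index_map(
    slice_: CtSlice, sigma: float = 1.5, flat_eps: float = 1e-8
) -> ShapeIndexMap:
    """Per-pixel shape index of the slice at smoothing scale ``sigma``.

    Pixels where both curvature magnitudes fall below ``flat_eps`` are
    flagged undefined: the formula is indeterminate on flat loci, and
    the discrete Gaussian kernels leave float-level residue (~1e-15 of
    the intensity scale) even on exactly constant images.
    """
    k1, k2 = principal_curvatures(slice_, sigma=sigma)
    si = np.asarray(shape_index_at(k1, k2))
    flat = np.maximum(np.abs(k1), np.abs(k2)) < flat_eps
    si = np.where(flat, np.nan, si)
    return ShapeIndexMap(k1=k1, k2=k2, si=si, sigma=sigma)


def filter_by_shape_index(
    cands: CandidateSet,
    si_map: ShapeIndexMap,
    si_threshold: float = 0.76,
    min_component_px: int = 3,
    spacing_mm: Tuple[float, float] | None = None,
) -> List[ScoredCandidate]:
    """Score candidate components by mean shape index and flag nodules.

    For each labeled component of at least ``min_component_px`` pixels
    (curvature means on 1–2 px specks are noise), the mean of the
    defined shape-index values over its pixels is computed; the
    component is kept as a nodule iff that mean strictly exceeds
    ``si_threshold`` (default 0.76, so a mean of exactly 0.76 is
    removed).  A component with no defined shape index anywhere scores
    0 and is removed with a warning.
    """
    check_aligned(cands.labels, si_map.si, "candidate labels vs shape-index map")
    if not 0 < si_threshold < 1:
        raise InvalidInputError(f"si_threshold must be in (0, 1), got {si_threshold}")
    if spacing_mm is None:
        spacing_mm = cands.segmented.spacing_mm
    px_area_mm2 = spacing_mm[0] * spacing_mm[1]

    scored: List[ScoredCandidate] = []
    labels = cands.labels
    for lab in range(1, cands.n_components + 1):
        comp = labels == lab
        area = int(comp.sum())
        if area < min_component_px:
            continue
        vals = si_map.si[comp]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            warnings.warn(
                f"component {lab}: shape index undefined on every pixel; removed",
                stacklevel=2,
            )
            mean_si = 0.0
        else:
            mean_si = float(vals.mean())
        rows, cols = np.nonzero(comp)
        centroid = (float(rows.mean()), float(cols.mean()))
        equiv_d = 2.0 * np.sqrt(area * px_area_mm2 / np.pi)
        scored.append(
            ScoredCandidate(
                label=lab,
                mean_si=mean_si,
                area_px=area,
                centroid=centroid,
                equiv_diameter_mm=float(equiv_d),
                is_nodule=bool(mean_si > si_threshold),
            )
        )
    return scored
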