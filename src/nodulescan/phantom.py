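"""Synthetic thoracic CT phantom with ground-truth nodule annotations.

The phantom emulates the slice-level appearance that drives the
detection pipeline, on a 12-bit-like intensity scale:

* an elliptical thorax (bright chest body) surrounded by exterior air
  that touches the image border;
* two dark elliptical lung fields and a small dark tracheal ring
  between them (smaller than either lung, so size-based removal
  applies);
* bright tubular vessels inside the lungs, rendered as random-walk
  tubes with a cylinder-projection cross-section so they present
  ridge-class geometry to the shape-index filter;
* bright nodules of 3–30 mm equivalent diameter rendered as
  hemispheric domes — the chord-length projection of a sphere through
  the slice — so even large nodules keep cap-class curvature rather
  than a flat plateau;
* additive Gaussian noise (truth masks are rendered noise-free).

Nodule attachment classes: ``isolated`` (well inside the parenchyma,
away from vessels), ``juxtapleural`` (crossing the lung boundary into
the chest wall), ``juxtavascular`` (centred on a vessel), ``diaphragm``
(crossing the inferior lung boundary).  All rendering is deterministic
given the spec's seed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core import BinaryMask, CtSlice, InvalidInputError

__all__ = [
    "NoduleSpec",
    "PhantomSpec",
    "PhantomTruth",
    "Scan",
    "generate_slice",
    "generate_scan",
    "write_scan",
    "default_suite",
    "PlacementError",
]

ATTACHMENTS = ("isolated", "juxtapleural", "juxtavascular", "diaphragm")

#: intensity ceiling of the 12-bit scale
INTENSITY_MAX = 4095.0


class PlacementError(InvalidInputError):
    """Raised when a nodule cannot be placed under its attachment constraints."""


@dataclass
class NoduleSpec:
    """One planted nodule.

    ``center`` may be None, in which case a feasible position for the
    requested attachment class is sampled (deterministically, from the
    phantom seed) during rendering; the resolved center is written back
    into the truth's spec list.  ``contrast`` offsets the peak
    intensity relative to the phantom's nominal nodule intensity.
    """

    diameter_mm: float
    attachment: str = "isolated"
    center: Optional[Tuple[float, float]] = None
    contrast: float = 0.0

    def __post_init__(self) -> None:
        if not 3.0 <= self.diameter_mm <= 30.0:
            raise InvalidInputError(
                f"nodule diameter must be in [3, 30] mm, got {self.diameter_mm}"
            )
        if self.attachment not in ATTACHMENTS:
            raise InvalidInputError(
                f"unknown attachment {self.attachment!r}; expected one of {ATTACHMENTS}"
            )


@dataclass
class PhantomSpec:
    """Full description of one synthetic slice."""

    size_px: Tuple[int, int] = (256, 256)
    spacing_mm: Tuple[float, float] = (0.6, 0.6)
    lung_intensity: float = 500.0
    body_intensity: float = 3000.0
    vessel_intensity: float = 1900.0
    nodule_intensity: float = 1700.0
    trachea_intensity: float = 200.0
    nodules: List[NoduleSpec] = field(default_factory=list)
    vessels: int = 3
    vessel_width_px: Tuple[float, float] = (6.0, 8.0)
    vessel_waviness: float = 0.08
    noise_sigma: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        ok = (
            self.body_intensity > self.vessel_intensity >= self.nodule_intensity
            and self.nodule_intensity > self.lung_intensity
        )
        if not ok:
            raise InvalidInputError(
                "intensity ordering must satisfy body > vessel >= nodule > lung, got "
                f"body={self.body_intensity}, vessel={self.vessel_intensity}, "
                f"nodule={self.nodule_intensity}, lung={self.lung_intensity}"
            )
        if self.vessels < 0 or self.noise_sigma < 0:
            raise InvalidInputError("vessels and noise_sigma must be non-negative")


@dataclass
class PhantomTruth:
    """Noise-free ground truth paired with a generated slice."""

    nodule_mask: np.ndarray  # int labels, one per nodule, 0 = background
    lung_mask: BinaryMask
    vessel_mask: np.ndarray  # boolean
    specs: List[NoduleSpec]


@dataclass
class Scan:
    """An ordered stack of phantom slices with their truths."""

    scan_id: str
    slices: List[CtSlice]
    truths: List[PhantomTruth]
    specs: List[PhantomSpec]

    @property
    def n_truth_nodules(self) -> int:
        return sum(len(t.specs) for t in self.truths)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _ellipse_coverage(shape, center, semi, softness: float = 1.0) -> np.ndarray:
    """Approximate area coverage of an ellipse with a ~1 px soft edge."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    rho = np.sqrt(((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2)
    scale = min(semi)  # approximate signed distance: (rho - 1) * min(semi)
    return np.clip(0.5 - (rho - 1.0) * scale / softness, 0.0, 1.0)


def _anatomy(spec: PhantomSpec):
    """Body/lung/trachea geometry derived from the image size."""
    nr, nc = spec.size_px
    body_c = (nr * 0.5, nc * 0.5)
    body_s = (nr * 0.40, nc * 0.46)
    lung_s = (nr * 0.27, nc * 0.145)
    left_c = (nr * 0.52, nc * 0.32)
    right_c = (nr * 0.52, nc * 0.68)
    trachea_c = (nr * 0.30, nc * 0.50)
    trachea_r = max(3.0, nr * 0.025)
    return body_c, body_s, left_c, right_c, lung_s, trachea_c, trachea_r


def _lung_interior_mask(shape, left_c, right_c, lung_s) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    m = np.zeros(shape, dtype=bool)
    for c0 in (left_c, right_c):
        rho = np.sqrt(((rr - c0[0]) / lung_s[0]) ** 2 + ((cc - c0[1]) / lung_s[1]) ** 2)
        m |= rho <= 1.0
    return m


def _walk_vessel(rng, lung_mask, start, width, waviness, max_len=55):
    """Random-walk centerline inside the lung, 1 px steps."""
    pts = [start]
    ang = rng.uniform(0, 2 * math.pi)
    r, c = start
    nr, nc = lung_mask.shape
    for _ in range(max_len):
        ang += rng.normal(0.0, waviness)
        r += math.sin(ang)
        c += math.cos(ang)
        ir, ic = int(round(r)), int(round(c))
        if not (0 <= ir < nr and 0 <= ic < nc) or not lung_mask[ir, ic]:
            break
        pts.append((r, c))
    return pts


def _tube_image(shape, centerline, width, amplitude, base, taper_len=10):
    """Cylinder-projection tube: intensity = base + amp * chord(d).

    The tube tapers linearly to ~2 px over its last ``taper_len``
    centerline points at both ends, as real vessels do; a bluntly
    truncated tube would end in an artificial cap-class stump.
    """
    n = len(centerline)
    if n < 2:
        return np.zeros(shape)
    # per-pixel local half-width from the nearest centerline point
    path = np.zeros(shape, dtype=bool)
    half_at = np.zeros(shape)
    for i, (r, c) in enumerate(centerline):
        end_dist = min(i, n - 1 - i)
        w = width if end_dist >= taper_len else 2.0 + (width - 2.0) * end_dist / taper_len
        ir, ic = int(round(r)), int(round(c))
        path[ir, ic] = True
        half_at[ir, ic] = max(half_at[ir, ic], w / 2.0)
    d, (inds_r, inds_c) = ndimage.distance_transform_edt(~path, return_indices=True)
    half = half_at[inds_r, inds_c]
    with np.errstate(invalid="ignore", divide="ignore"):
        chord = np.sqrt(np.clip(1.0 - (d / np.maximum(half, 1e-9)) ** 2, 0.0, None))
    return np.where(d <= half, base + amplitude * chord, 0.0)


#: radial profile exponent for nodules: (1 - (r/R)^2) ** ALPHA.
#: 0.5 is the chord-length projection of a homogeneous sphere; 0.35 is
#: slightly flatter-topped, emulating a solid nodule whose core is more
#: homogeneous than a pure sphere projection while keeping nonzero
#: convex curvature everywhere (no plateau).
DOME_EXPONENT = 0.35


def _dome_image(shape, center, radius_px, amplitude, base, alpha=DOME_EXPONENT):
    """Dome-profiled nodule: intensity = base + amplitude * (1-rho^2)^alpha."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
    prof = np.clip(1.0 - (d / radius_px) ** 2, 0.0, None) ** alpha
    return np.where(d <= radius_px, base + amplitude * prof, 0.0)


# ---------------------------------------------------------------------------
# nodule placement
# ---------------------------------------------------------------------------


def _resolve_center(
    spec: NoduleSpec,
    rng: np.random.Generator,
    lung_mask: np.ndarray,
    vessel_paths: List[Tuple[List[Tuple[float, float]], float]],
    radius_px: float,
    placed: List[Tuple[Tuple[float, float], float]],
    overlap_px: float = 2.0,
    max_tries: int = 400,
) -> Tuple[float, float]:
    """Sample a center satisfying the attachment constraint."""
    if spec.center is not None:
        return spec.center

    dist_in = ndimage.distance_transform_edt(lung_mask)
    vessel_pts = [p for path, _w in vessel_paths for p in path]

    def clear_of_others(pt) -> bool:
        return all(
            math.hypot(pt[0] - q[0], pt[1] - q[1]) > radius_px + rq + 3
            for q, rq in placed
        )

    def vessel_distance(pt) -> float:
        if not vessel_pts:
            return math.inf
        return min(math.hypot(pt[0] - p[0], pt[1] - p[1]) for p in vessel_pts)

    if spec.attachment == "juxtavascular":
        if not vessel_pts:
            raise PlacementError(
                "juxtavascular nodule requested but the phantom has no vessels"
            )
        # a feeding vessel terminates at the nodule rim: the dome is
        # planted just beyond one end of a tube, overlapping its end
        # cap.  A tube crossing the dome would either be swallowed by
        # the brighter vessel or carve the dome apart.  The offset is
        # shrunk in steps when the lung leaves no room; the largest
        # vessel-fed nodules may then also graze the pleura.
        order = list(rng.permutation(len(vessel_paths)))
        for frac in (0.55, 0.4, 0.25):
            for j in order:
                path, width = vessel_paths[j]
                if len(path) < 2:
                    continue
                ends = [(path[-1], path[-2]), (path[0], path[1])]
                if rng.integers(2):
                    ends.reverse()
                for end, prev in ends:
                    dr, dc = end[0] - prev[0], end[1] - prev[1]
                    norm = math.hypot(dr, dc) or 1.0
                    off = width / 2.0 + frac * radius_px
                    pt = (end[0] + dr / norm * off, end[1] + dc / norm * off)
                    ir, ic = int(round(pt[0])), int(round(pt[1]))
                    if not (0 <= ir < lung_mask.shape[0] and 0 <= ic < lung_mask.shape[1]):
                        continue
                    if dist_in[ir, ic] >= 0.7 * radius_px + 2 and clear_of_others(pt):
                        return (float(pt[0]), float(pt[1]))
        # fallback for the largest nodules in a crowded lung: tangent to
        # the deepest reachable point of any tube, accepting that the
        # nodule may also graze the pleura
        best, best_d = None, -1.0
        for path, width in vessel_paths:
            for a, b in zip(path, path[1:]):
                dr, dc = b[0] - a[0], b[1] - a[1]
                norm = math.hypot(dr, dc) or 1.0
                for sgn in (1.0, -1.0):
                    off = width / 2.0 + 0.55 * radius_px
                    pt = (a[0] - sgn * dc / norm * off, a[1] + sgn * dr / norm * off)
                    ir, ic = int(round(pt[0])), int(round(pt[1]))
                    if not (0 <= ir < lung_mask.shape[0] and 0 <= ic < lung_mask.shape[1]):
                        continue
                    if lung_mask[ir, ic] and clear_of_others(pt) and dist_in[ir, ic] > best_d:
                        best, best_d = (float(pt[0]), float(pt[1])), dist_in[ir, ic]
        if best is not None:
            return best
        raise PlacementError(
            f"could not place juxtavascular nodule of {spec.diameter_mm} mm"
        )

    if spec.attachment == "isolated":
        region = dist_in >= radius_px + 4
    else:  # juxtapleural / diaphragm: boundary band, center radius-overlap inside
        target = max(radius_px - overlap_px, 1.0)
        region = (dist_in > target - 1.0) & (dist_in <= target + 1.0)
        if spec.attachment == "diaphragm":
            rows = np.arange(lung_mask.shape[0])[:, None]
            region = region & (rows > int(lung_mask.shape[0] * 0.62))  # inferior
    cand_rows, cand_cols = np.nonzero(region)
    if cand_rows.size == 0:
        raise PlacementError(
            f"no feasible region for {spec.attachment} nodule of {spec.diameter_mm} mm"
        )
    # among feasible candidates pick the one farthest from the vessel
    # tree, so nodules overlap vessels only when geometry forces it
    best, best_d = None, -1.0
    for _ in range(min(max_tries, 120)):
        k = rng.integers(cand_rows.size)
        pt = (float(cand_rows[k]), float(cand_cols[k]))
        if not clear_of_others(pt):
            continue
        d = vessel_distance(pt)
        if d > best_d:
            best, best_d = pt, d
        if d > radius_px + 4:  # fully clear; no need to keep searching
            break
    if best is None:
        raise PlacementError(
            f"could not place {spec.attachment} nodule of {spec.diameter_mm} mm "
            f"after {max_tries} attempts"
        )
    return best


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_slice(spec: PhantomSpec, slice_id: str = "phantom") -> Tuple[CtSlice, PhantomTruth]:
    """Render one phantom slice and its noise-free ground truth.

    Deterministic given ``spec.seed``: the same spec always yields a
    bit-identical slice and truth.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.size_px)
    body_c, body_s, left_c, right_c, lung_s, trachea_c, trachea_r = _anatomy(spec)

    img = np.zeros(shape, dtype=np.float64)  # exterior air
    cov_body = _ellipse_coverage(shape, body_c, body_s)
    img = img * (1 - cov_body) + spec.body_intensity * cov_body
    for c0 in (left_c, right_c):
        cov = _ellipse_coverage(shape, c0, lung_s)
        img = img * (1 - cov) + spec.lung_intensity * cov
    cov_tr = _ellipse_coverage(shape, trachea_c, (trachea_r, trachea_r))
    img = img * (1 - cov_tr) + spec.trachea_intensity * cov_tr

    lung_true = _lung_interior_mask(shape, left_c, right_c, lung_s)

    # vessels: random-walk tubes strictly interior to the lung, so that
    # after binarization they are closed holes the flood fill restores
    # to the lung field (a tube open to the lung boundary would cut a
    # channel through the mask instead)
    vessel_paths: List[Tuple[List[Tuple[float, float]], float]] = []
    vessel_mask = np.zeros(shape, dtype=bool)
    for _ in range(spec.vessels):
        width = rng.uniform(*spec.vessel_width_px)
        margin = int(math.ceil(width / 2.0)) + 3
        corridor = ndimage.binary_erosion(lung_true, iterations=margin)
        inner = ndimage.binary_erosion(corridor, iterations=6)
        rows, cols = np.nonzero(inner if inner.any() else corridor)
        if rows.size == 0:
            break
        k = rng.integers(rows.size)
        path = _walk_vessel(
            rng, corridor, (float(rows[k]), float(cols[k])), width, spec.vessel_waviness
        )
        if len(path) < 10:
            continue
        tube = _tube_image(
            shape, path, width, spec.vessel_intensity - spec.lung_intensity,
            spec.lung_intensity,
        )
        tube = np.where(lung_true, tube, 0.0)
        vessel_mask |= tube > spec.lung_intensity
        img = np.maximum(img, tube)
        vessel_paths.append((path, width))

    # nodules
    sp_r, sp_c = spec.spacing_mm
    px_mm = (sp_r + sp_c) / 2.0
    nodule_mask = np.zeros(shape, dtype=np.int32)
    resolved: List[NoduleSpec] = []
    placed: List[Tuple[Tuple[float, float], float]] = []
    for i, nod in enumerate(spec.nodules, start=1):
        radius_px = (nod.diameter_mm / 2.0) / px_mm
        center = _resolve_center(nod, rng, lung_true, vessel_paths, radius_px, placed)
        peak = spec.nodule_intensity + nod.contrast
        dome = _dome_image(
            shape, center, radius_px, peak - spec.lung_intensity, spec.lung_intensity
        )
        img = np.maximum(img, dome)
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        disk = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2
        nodule_mask[disk & (nodule_mask == 0)] = i
        resolved.append(
            NoduleSpec(
                diameter_mm=nod.diameter_mm,
                attachment=nod.attachment,
                center=(float(center[0]), float(center[1])),
                contrast=nod.contrast,
            )
        )
        placed.append((center, radius_px))

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=shape)
    img = np.clip(img, 0.0, INTENSITY_MAX)

    truth = PhantomTruth(
        nodule_mask=nodule_mask,
        lung_mask=BinaryMask(lung_true, role="lung"),
        vessel_mask=vessel_mask,
        specs=resolved,
    )
    return CtSlice(pixels=img, spacing_mm=spec.spacing_mm, id=slice_id), truth


def generate_scan(
    spec_list: Sequence[PhantomSpec],
    scan_id: str = "scan",
    out_dir: str | Path | None = None,
) -> Scan:
    """Render an ordered slice stack; optionally write it to ``out_dir``."""
    if len(spec_list) == 0:
        raise InvalidInputError("a scan needs at least one slice spec")
    slices, truths = [], []
    for k, sp in enumerate(spec_list):
        s, t = generate_slice(sp, slice_id=f"{scan_id}_s{k:03d}")
        slices.append(s)
        truths.append(t)
    scan = Scan(scan_id=scan_id, slices=slices, truths=truths, specs=list(spec_list))
    if out_dir is not None:
        write_scan(scan, out_dir)
    return scan


def write_scan(scan: Scan, out_dir: str | Path) -> Path:
    """Write NIfTI volume + truth labels + JSON manifest for a scan."""
    import nibabel as nib

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        vol = np.stack([s.pixels for s in scan.slices], axis=-1)
        truth = np.stack([t.nodule_mask for t in scan.truths], axis=-1)
        lung = np.stack([t.lung_mask.pixels for t in scan.truths], axis=-1).astype(np.uint8)
        sp = scan.specs[0].spacing_mm
        aff = np.diag([sp[0], sp[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(vol.astype(np.float32), aff), out / "volume.nii")
        nib.save(nib.Nifti1Image(truth.astype(np.int16), aff), out / "truth_nodules.nii")
        nib.save(nib.Nifti1Image(lung, aff), out / "truth_lungs.nii")
        manifest = {
            "scan_id": scan.scan_id,
            "n_slices": len(scan.slices),
            "n_nodules": scan.n_truth_nodules,
            "volume_sha256": hashlib.sha256(
                np.ascontiguousarray(vol.astype(np.float32)).tobytes()
            ).hexdigest(),
            "specs": [
                {**asdict(sp_), "nodules": [asdict(n) for n in t.specs]}
                for sp_, t in zip(scan.specs, scan.truths)
            ],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except OSError as exc:
        raise OSError(f"failed writing scan to {out}: {exc}") from exc
    return out


def default_suite(
    n_scans: int = 20,
    slices_per_scan: int = 3,
    seed: int = 0,
    attachment_probs: Tuple[float, float, float, float] = (0.5, 0.2, 0.2, 0.1),
    nodules_per_slice: Tuple[int, int] = (1, 2),
) -> List[List[PhantomSpec]]:
    """Seeded multi-scan study suite with mixed nodule sizes and attachments.

    Diameters are uniform over the 3–30 mm range; attachments are drawn
    as (isolated, juxtapleural, juxtavascular, diaphragm) with the given
    probabilities.  Returns one spec list per scan.
    """
    rng = np.random.default_rng(seed)
    suite: List[List[PhantomSpec]] = []
    for i in range(n_scans):
        specs: List[PhantomSpec] = []
        for j in range(slices_per_scan):
            n_nod = int(rng.integers(nodules_per_slice[0], nodules_per_slice[1] + 1))
            nods = [
                NoduleSpec(
                    diameter_mm=float(rng.uniform(3.0, 30.0)),
                    attachment=str(rng.choice(ATTACHMENTS, p=attachment_probs)),
                )
                for _ in range(n_nod)
            ]
            specs.append(PhantomSpec(nodules=nods, seed=int(rng.integers(2**31 - 1))))
        suite.append(specs)
    return suite
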