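"""Recognition of individual GUVs in the lipid channel.

GUVs image as bright annuli.  The default detector is deterministic: Canny
edges feed a circular Hough transform over the configured radius range, the
candidate circles are refined against the local radial intensity profile, and
near-duplicate circles are suppressed.  :func:`import_detections` accepts
boxes produced by any external detector (e.g. a trained network) and subjects
them to the same validation, edge policy and ordering, so the two sources are
interchangeable downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from .errors import ParameterError
from .io_formats import DetectionRecord

__all__ = ["GUVRegion", "DetectParams", "detect_guvs", "import_detections", "circle_bbox"]


def circle_bbox(center: tuple[float, float], radius: float) -> tuple[int, int, int, int]:
    """Half-open pixel bbox of the disc ``|x - center| <= radius``."""
    r0 = int(np.floor(center[0] - radius))
    r1 = int(np.ceil(center[0] + radius)) + 1
    c0 = int(np.floor(center[1] - radius))
    c1 = int(np.ceil(center[1] + radius)) + 1
    return r0, r1, c0, c1


@dataclass(frozen=True)
class GUVRegion:
    """A detected vesicle: center/radius in pixels plus its half-open bbox."""

    center: tuple[float, float]
    radius: float
    bbox: tuple[int, int, int, int]
    score: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ParameterError("radius must be positive")
        if not 0.0 <= self.score <= 1.0:
            raise ParameterError("score must lie in [0, 1]")
        r0, r1, c0, c1 = self.bbox
        if not (r0 <= self.center[0] - self.radius and self.center[0] + self.radius < r1
                and c0 <= self.center[1] - self.radius and self.center[1] + self.radius < c1):
            raise ParameterError("bbox must contain center +/- radius")


@dataclass
class DetectParams:
    """Detector configuration.

    ``min_score`` is the fraction of circle perimeter that must be supported
    by edge votes; ``edge_policy='exclude'`` drops circles whose bbox exits
    the frame.
    """

    r_min: int
    r_max: int
    min_score: float = 0.35
    edge_policy: str = "exclude"
    canny_sigma: float = 2.0
    max_candidates: int = 200

    def __post_init__(self) -> None:
        if not 0 < self.r_min < self.r_max:
            raise ParameterError("need 0 < r_min < r_max")
        if self.edge_policy not in ("exclude", "include"):
            raise ParameterError("edge_policy must be 'exclude' or 'include'")


def _refine_circle(
    image: np.ndarray,
    center: tuple[float, float],
    r_min: float,
    r_max: float,
    n_iter: int = 3,
) -> tuple[tuple[float, float], float]:
    """Refine a circle candidate against the ring's radial intensity profile.

    The Hough peak pins the center to about a pixel but its radius sits on a
    Canny edge of the annulus, one ring-width off the intensity crest.  The
    crest is recovered from the radial profile around the candidate center
    (argmax of per-integer-distance mean intensity within ``r_max + 2``),
    then center and radius are polished as intensity-weighted moments of the
    crest annulus.
    """
    bg = float(np.median(image))
    weights_img = np.clip(image - bg, 0.0, None)
    h, w = image.shape
    cr, cc = float(center[0]), float(center[1])
    r = None
    for it in range(n_iter):
        lim = r_max + 2.0
        r0, r1 = max(0, int(cr - lim)), min(h, int(cr + lim) + 1)
        c0, c1 = max(0, int(cc - lim)), min(w, int(cc + lim) + 1)
        rows, cols = np.mgrid[r0:r1, c0:c1]
        wts = weights_img[r0:r1, c0:c1].copy()
        # noise floor: keep only pixels that plausibly belong to the ring
        wts[wts < 0.2 * wts.max()] = 0.0
        d = np.hypot(rows - cr, cols - cc)
        if it == 0 and wts[d <= lim].sum() > 0:
            # coarse centering on the whole window; the Hough center can sit
            # several pixels off on noisy rings
            sel = d <= lim
            cr = float(np.average(rows[sel], weights=wts[sel]))
            cc = float(np.average(cols[sel], weights=wts[sel]))
            d = np.hypot(rows - cr, cols - cc)
        bins = np.rint(d).astype(int)
        inside = bins <= int(lim)
        sums = np.bincount(bins[inside], weights=wts[inside], minlength=int(lim) + 1)
        counts = np.bincount(bins[inside], minlength=int(lim) + 1)
        profile = sums / np.maximum(counts, 1)
        r = float(np.argmax(profile))
        # wide band: the whole ring must fall inside even with an offset center
        band = np.abs(d - r) <= max(5.0, 0.4 * r)
        if wts[band].sum() <= 0:
            break
        cr = float(np.average(rows[band], weights=wts[band]))
        cc = float(np.average(cols[band], weights=wts[band]))
        # tight band around the crest for the radius estimate
        d = np.hypot(rows - cr, cols - cc)
        bins = np.rint(d).astype(int)
        inside = bins <= int(lim)
        sums = np.bincount(bins[inside], weights=wts[inside], minlength=int(lim) + 1)
        counts = np.bincount(bins[inside], minlength=int(lim) + 1)
        r = float(np.argmax(sums / np.maximum(counts, 1)))
        band = np.abs(d - r) <= 3.0
        if wts[band].sum() <= 0:
            break
        r = float(np.average(d[band], weights=wts[band]))
    r = float(np.clip(r if r else 0.5 * (r_min + r_max), r_min, r_max))
    return (cr, cc), r


def detect_guvs(lipid_channel: np.ndarray, params: DetectParams) -> list[GUVRegion]:
    """Detect ring-shaped GUVs in a single-channel image.

    Returns regions sorted by (row, col).  A constant image yields an empty
    list.  Overlapping detections (center distance < 0.5*(r1+r2)) are treated
    as duplicates and the higher-scoring one is kept.
    """
    img = np.asarray(lipid_channel, dtype=float)
    if img.ndim != 2:
        raise ParameterError("detect_guvs expects a single-channel image")
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return []
    norm = (img - lo) / (hi - lo)

    edges = canny(norm, sigma=params.canny_sigma)
    if not edges.any():
        return []
    radii = np.arange(params.r_min, params.r_max + 1)
    accumulator = hough_circle(edges, radii)
    accums, cx, cy, rad = hough_circle_peaks(
        accumulator,
        radii,
        min_xdistance=params.r_min,
        min_ydistance=params.r_min,
        total_num_peaks=params.max_candidates,
        normalize=True,
    )

    h, w = img.shape
    candidates = []
    for score, x, y, r in zip(accums, cx, cy, rad):
        if score < params.min_score:
            continue
        if params.edge_policy == "exclude" and (
            y - r < 0 or x - r < 0 or y + r >= h or x + r >= w
        ):
            # a partial rim at the frame edge must not be refined into a
            # spurious interior circle
            continue
        center, radius = _refine_circle(
            img, (float(y), float(x)), params.r_min, params.r_max
        )
        candidates.append((min(float(score), 1.0), center, radius))

    # non-maximum suppression: non-concentric GUVs never sit this close
    candidates.sort(key=lambda t: -t[0])
    kept: list[tuple[float, tuple[float, float], float]] = []
    for score, center, radius in candidates:
        dup = any(
            np.hypot(center[0] - kc[0], center[1] - kc[1]) < 0.5 * (radius + kr)
            for _, kc, kr in kept
        )
        if not dup:
            kept.append((score, center, radius))

    regions = []
    for score, center, radius in kept:
        bbox = circle_bbox(center, radius)
        if params.edge_policy == "exclude" and (
            bbox[0] < 0 or bbox[2] < 0 or bbox[1] > h or bbox[3] > w
        ):
            continue
        regions.append(GUVRegion(center, radius, bbox, score))
    regions.sort(key=lambda g: g.center)
    return regions


def import_detections(
    record: DetectionRecord,
    image_shape: tuple[int, int],
    edge_policy: str = "exclude",
) -> list[GUVRegion]:
    """Build GUV regions from externally produced detections.

    Boxes fully outside the image are dropped with a warning; boxes that
    merely exit the frame are dropped under ``edge_policy='exclude'`` and
    clipped under ``'include'``.  Output ordering matches :func:`detect_guvs`.
    """
    h, w = image_shape
    regions = []
    for reg in record.regions:
        r0, r1, c0, c1 = (int(v) for v in reg["bbox"])
        if r1 <= 0 or c1 <= 0 or r0 >= h or c0 >= w:
            warnings.warn(
                f"{record.image_id}: detection bbox {reg['bbox']} outside image; dropped"
            )
            continue
        exits = r0 < 0 or c0 < 0 or r1 > h or c1 > w
        if exits and edge_policy == "exclude":
            continue
        bbox = (max(r0, 0), min(r1, h), max(c0, 0), min(c1, w))
        center = (float(reg["center"][0]), float(reg["center"][1]))
        radius = float(reg["radius"])
        # clipping may shave the nominal disc; shrink radius to fit the box
        radius = min(
            radius,
            center[0] - bbox[0], bbox[1] - 1 - center[0],
            center[1] - bbox[2], bbox[3] - 1 - center[1],
        )
        if radius <= 0:
            warnings.warn(
                f"{record.image_id}: detection at {center} has no in-frame extent; dropped"
            )
            continue
        regions.append(GUVRegion(center, radius, bbox, 1.0))
    regions.sort(key=lambda g: g.center)
    return regions
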