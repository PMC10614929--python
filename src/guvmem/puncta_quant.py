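"""Per-GUV puncta calling, the headline proportions, and the cell-image
particle-area measure.

For each recognized GUV the protein-channel crop passes through a fixed
chain: background estimation by minimum cross-entropy (Li) thresholding and
subtraction, non-local-means denoising, Gaussian blur, rescale to 8-bit with
global histogram equalization, Otsu foreground masking, and connected-
component labelling keeping components larger than ``min_component_px``
pixels (strictly: area >= min_component_px + 1).  Two puncta from different
channels are colocalized when their bounding boxes overlap.

Both thresholds are computed as exhaustive discrete minimizers over all
candidate levels (vectorized through cumulative histogram moments), so they
agree exactly with a brute-force per-level search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.restoration import denoise_nl_means, estimate_sigma

from .errors import NoForegroundError, ParameterError
from .guv_detection import GUVRegion

__all__ = [
    "PipelineParams",
    "Punctum",
    "ColocResult",
    "PunctaSummary",
    "compute_li_threshold",
    "preprocess_crop",
    "compute_otsu_threshold",
    "equalize_hist_8bit",
    "label_puncta",
    "detect_puncta_in_guv",
    "proportion_guvs_with_puncta",
    "colocalize",
    "particle_area_above_threshold",
    "subtract_local_background",
]


@dataclass
class PipelineParams:
    """Tunables of the per-crop chain.

    ``min_component_px`` follows the 'larger than 5 pixels' rule: a punctum
    must have area strictly greater than this value.  The denoise/blur
    defaults are package choices (the underlying procedure does not pin
    them); downstream results are required to be stable under +/-50% changes.
    """

    nl_h: float = 10.0
    nl_patch: int = 7
    nl_search: int = 21
    blur_sigma: float = 1.0
    min_component_px: int = 5
    connectivity: int = 8
    crop_pad: int = 5
    detection_limit_k: float = 3.0
    noise_floor_k: float = 1.0

    def __post_init__(self) -> None:
        if min(self.nl_h, self.nl_patch, self.nl_search, self.blur_sigma) <= 0:
            raise ParameterError("filter parameters must be positive")
        if self.connectivity not in (4, 8):
            raise ParameterError("connectivity must be 4 or 8")
        if self.crop_pad < 0 or int(self.min_component_px) != self.min_component_px:
            raise ParameterError("crop_pad >= 0 and integer min_component_px required")


@dataclass(frozen=True)
class Punctum:
    """A connected foreground component: pixel set, area and tight bbox."""

    channel_role: str
    pixels: frozenset  # of (row, col)
    area: int
    bbox: tuple[int, int, int, int]  # half-open
    centroid: tuple[float, float]


@dataclass(frozen=True)
class ColocResult:
    n_puncta: dict
    n_colocalized: int
    proportion: float


@dataclass(frozen=True)
class PunctaSummary:
    n_guvs: int
    n_with_puncta: int
    proportion: float


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def _integer_levels(crop: np.ndarray) -> tuple[np.ndarray, int]:
    values = np.asarray(crop)
    if values.size == 0:
        raise ParameterError("empty crop")
    iv = np.rint(values).astype(np.int64)
    if np.any(iv < 0):
        raise ParameterError("intensities must be nonnegative")
    n_levels = max(int(iv.max()) + 1, 2)
    return iv, n_levels


def compute_li_threshold(crop: np.ndarray) -> float:
    """Minimum cross-entropy (Li-Lee) threshold of an integer-valued crop.

    Returns the level ``t`` minimizing the cross entropy between the image
    and its two-level reconstruction with means taken over the classes
    ``< t`` and ``>= t``; ties go to the smallest level, which places the
    threshold strictly above the background mode of a well-separated crop.
    A constant crop returns that constant.
    """
    iv, n_levels = _integer_levels(crop)
    if iv.min() == iv.max():
        return float(iv.flat[0])
    hist = np.bincount(iv.ravel(), minlength=n_levels).astype(np.int64)
    levels = np.arange(n_levels, dtype=np.int64)
    # class split at candidate t: low = {g < t}, high = {g >= t}
    n0 = np.concatenate(([0], np.cumsum(hist)[:-1]))
    a0 = np.concatenate(([0], np.cumsum(hist * levels)[:-1]))
    n1 = hist.sum() - n0
    a1 = (hist * levels).sum() - a0
    with np.errstate(divide="ignore", invalid="ignore"):
        term0 = np.where(a0 > 0, a0 * np.log(a0 / np.maximum(n0, 1)), 0.0)
        term1 = np.where(a1 > 0, a1 * np.log(a1 / np.maximum(n1, 1)), 0.0)
    eta = -(term0 + term1)
    return float(np.argmin(eta))


def compute_otsu_threshold(crop8: np.ndarray) -> int:
    """Otsu threshold: level minimizing within-class intensity variance.

    Ties go to the smallest minimizing level.  The foreground mask is
    ``crop8 > threshold``.  A constant crop raises
    :class:`~guvmem.errors.NoForegroundError`.
    """
    iv, n_levels = _integer_levels(crop8)
    if iv.min() == iv.max():
        raise NoForegroundError("constant crop: no foreground/background split")
    hist = np.bincount(iv.ravel(), minlength=n_levels).astype(np.int64)
    levels = np.arange(n_levels, dtype=np.int64)
    n_total = hist.sum()
    n0 = np.cumsum(hist)
    s0 = np.cumsum(hist * levels)
    q0 = np.cumsum(hist * levels * levels)
    n1 = n_total - n0
    s1 = s0[-1] - s0
    q1 = q0[-1] - q0
    with np.errstate(divide="ignore", invalid="ignore"):
        var0 = np.where(n0 > 0, q0 / np.maximum(n0, 1) - (s0 / np.maximum(n0, 1)) ** 2, 0.0)
        var1 = np.where(n1 > 0, q1 / np.maximum(n1, 1) - (s1 / np.maximum(n1, 1)) ** 2, 0.0)
    sigma_w = (n0 / n_total) * var0 + (n1 / n_total) * var1
    # a threshold must leave both classes nonempty
    valid = (n0 > 0) & (n1 > 0)
    sigma_w = np.where(valid, sigma_w, np.inf)
    return int(np.argmin(sigma_w))


def equalize_hist_8bit(img8: np.ndarray) -> np.ndarray:
    """Global 8-bit histogram equalization via the standard CDF lookup table.

    A constant image maps to all zeros.
    """
    img8 = np.asarray(img8, dtype=np.uint8)
    hist = np.bincount(img8.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    nonzero = cdf[hist > 0]
    cdf_min = int(nonzero[0]) if nonzero.size else 0
    denom = img8.size - cdf_min
    if denom <= 0:
        return np.zeros_like(img8)
    lut = np.rint((cdf - cdf_min) / denom * 255.0).clip(0, 255).astype(np.uint8)
    return lut[img8]


def preprocess_crop(
    crop: np.ndarray, background_threshold: float, params: PipelineParams
) -> np.ndarray:
    """Background subtraction, NL-means, Gaussian blur, 8-bit equalization.

    Stage order is fixed; output is an 8-bit crop.  A crop entirely at or
    below the background threshold comes out all-zero.

    Two numerical guards keep the chain meaningful on real (noisy) crops,
    both anchored to the crop's raw shot-noise level (wavelet-estimated
    before any smoothing, so they do not drift with the denoiser settings):

    * Detection limit: after denoising, a crop must rise at least
      ``detection_limit_k`` raw noise SDs above its median to count as
      containing structure; below that it is all residual noise from the
      unbound protein pool and comes out all-zero.
    * Offset removal: the flat unbound-protein level that background
      subtraction leaves behind, plus ``noise_floor_k`` raw noise SDs, is
      floored to zero before quantization, so rank-based equalization cannot
      promote sub-limit residual noise to foreground.
    """
    raw = np.asarray(crop, dtype=float)
    work = np.clip(raw - background_threshold, 0.0, None)
    if work.max() > 0:
        sigma_raw = float(estimate_sigma(raw))
        work = denoise_nl_means(
            work,
            patch_size=params.nl_patch,
            patch_distance=max(1, (params.nl_search - 1) // 2),
            h=params.nl_h,
            fast_mode=True,
            preserve_range=True,
        )
        work = ndimage.gaussian_filter(work, params.blur_sigma)
        med = float(np.median(work))
        rise = float(work.max()) - med
        if rise <= params.detection_limit_k * sigma_raw + 1e-12:
            return np.zeros(work.shape, dtype=np.uint8)
        work = np.clip(work - (med + params.noise_floor_k * sigma_raw), 0.0, None)
    hi = float(work.max())
    if hi <= 0:
        return np.zeros(work.shape, dtype=np.uint8)
    scaled = np.rint(work / hi * 255.0).astype(np.uint8)
    return equalize_hist_8bit(scaled)


# ---------------------------------------------------------------------------
# components and puncta
# ---------------------------------------------------------------------------

def label_puncta(
    mask: np.ndarray, params: PipelineParams, channel_role: str = ""
) -> list[Punctum]:
    """Connected components larger than ``min_component_px`` pixels.

    Components are sorted by the top-left corner of their bounding boxes.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = cc_label(mask, connectivity=1 if params.connectivity == 4 else 2)
    puncta = []
    for prop in regionprops(labels):
        if prop.area <= params.min_component_px:
            continue
        r0, c0, r1, c1 = prop.bbox
        pixels = frozenset((int(r), int(c)) for r, c in prop.coords)
        puncta.append(
            Punctum(
                channel_role=channel_role,
                pixels=pixels,
                area=int(prop.area),
                bbox=(r0, r1, c0, c1),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
            )
        )
    puncta.sort(key=lambda p: (p.bbox[0], p.bbox[2]))
    return puncta


def detect_puncta_in_guv(
    image,
    region: GUVRegion,
    channel_role: str,
    params: PipelineParams | None = None,
) -> list[Punctum]:
    """Run the full per-GUV chain on one protein channel.

    The crop is the region bbox padded by ``crop_pad`` (clipped to the
    frame); punctum coordinates are reported in the whole-image frame.  A
    crop with no foreground yields zero puncta.
    """
    if params is None:
        params = PipelineParams()
    channel = image.channel(channel_role)
    h, w = channel.shape
    r0 = max(region.bbox[0] - params.crop_pad, 0)
    r1 = min(region.bbox[1] + params.crop_pad, h)
    c0 = max(region.bbox[2] - params.crop_pad, 0)
    c1 = min(region.bbox[3] + params.crop_pad, w)
    if r0 >= r1 or c0 >= c1:
        raise ParameterError("region lies outside the image")
    crop = channel[r0:r1, c0:c1]

    background = compute_li_threshold(crop)
    processed = preprocess_crop(crop, background, params)
    try:
        level = compute_otsu_threshold(processed)
    except NoForegroundError:
        return []
    mask = processed > level
    puncta = label_puncta(mask, params, channel_role)
    shifted = [
        Punctum(
            channel_role=p.channel_role,
            pixels=frozenset((r + r0, c + c0) for r, c in p.pixels),
            area=p.area,
            bbox=(p.bbox[0] + r0, p.bbox[1] + r0, p.bbox[2] + c0, p.bbox[3] + c0),
            centroid=(p.centroid[0] + r0, p.centroid[1] + c0),
        )
        for p in puncta
    ]
    return shifted


def proportion_guvs_with_puncta(per_guv_puncta: list) -> PunctaSummary:
    """Fraction of GUVs carrying at least one punctum.

    ``per_guv_puncta`` holds, per GUV, either the list of puncta or the
    punctum count.
    """
    if not per_guv_puncta:
        raise ParameterError("need at least one GUV")
    counts = [
        entry if isinstance(entry, (int, np.integer)) else len(entry)
        for entry in per_guv_puncta
    ]
    n_pos = sum(1 for c in counts if c > 0)
    return PunctaSummary(len(counts), n_pos, n_pos / len(counts))


def _boxes_overlap(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1] and a[2] < b[3] and b[2] < a[3]


def colocalize(puncta_a: list[Punctum], puncta_b: list[Punctum]) -> ColocResult:
    """Bounding-box colocalization between two channels of the same GUV.

    A punctum is colocalized iff its bbox intersects at least one bbox of the
    other channel.  The colocalized count is taken in the channel with the
    higher punctum count (ties: the larger of the two counts, which keeps the
    proportion symmetric under channel swap), and the proportion divides by
    that channel's total.  Two empty channels give proportion 0.
    """
    na, nb = len(puncta_a), len(puncta_b)
    co_a = sum(
        1 for p in puncta_a if any(_boxes_overlap(p.bbox, q.bbox) for q in puncta_b)
    )
    co_b = sum(
        1 for q in puncta_b if any(_boxes_overlap(q.bbox, p.bbox) for p in puncta_a)
    )
    roles = (
        puncta_a[0].channel_role if puncta_a else "A",
        puncta_b[0].channel_role if puncta_b else "B",
    )
    if na > nb:
        n_co = co_a
    elif nb > na:
        n_co = co_b
    else:
        n_co = max(co_a, co_b)
    denom = max(na, nb)
    return ColocResult(
        n_puncta={roles[0]: na, roles[1]: nb},
        n_colocalized=n_co,
        proportion=n_co / denom if denom else 0.0,
    )


def quantify_guvs(
    image,
    regions: list[GUVRegion],
    protein_roles: list[str],
    params: PipelineParams | None = None,
) -> dict:
    """Run the per-GUV pipeline over all regions and channels of one image.

    Returns ``{"puncta": {role: [puncta per GUV]}, "summary": {role:
    PunctaSummary}, "coloc": {(roleA, roleB): [ColocResult per GUV]}}``.
    """
    if params is None:
        params = PipelineParams()
    per_role = {
        role: [detect_puncta_in_guv(image, reg, role, params) for reg in regions]
        for role in protein_roles
    }
    summary = {
        role: proportion_guvs_with_puncta(per_role[role]) for role in protein_roles
    }
    coloc = {}
    for i, ra in enumerate(protein_roles):
        for rb in protein_roles[i + 1:]:
            coloc[(ra, rb)] = [
                colocalize(per_role[ra][g], per_role[rb][g])
                for g in range(len(regions))
            ]
    return {"puncta": per_role, "summary": summary, "coloc": coloc}


def particle_area_above_threshold(
    cell_image: np.ndarray, threshold: float, min_area: int = 1
) -> int:
    """Total area (px) of connected components above an empirical threshold.

    Mirrors the per-cell 'above-threshold particle area' readout: binarize at
    ``> threshold``, label 8-connected components, and sum the areas of
    components of at least ``min_area`` pixels.
    """
    mask = np.asarray(cell_image) > threshold
    labels = cc_label(mask, connectivity=2)
    if labels.max() == 0:
        return 0
    areas = np.bincount(labels.ravel())[1:]
    return int(areas[areas >= min_area].sum())


def subtract_local_background(
    channel: np.ndarray, box_center: tuple[int, int], box_size: int = 10
) -> np.ndarray:
    """Display-only helper: subtract the mean of a small square sampled
    outside the GUV from the whole channel (clipped at zero).  Used for
    representative images; plays no part in quantification."""
    r, c = box_center
    half = box_size // 2
    patch = np.asarray(channel, dtype=float)[
        max(r - half, 0): r + half, max(c - half, 0): c + half
    ]
    if patch.size == 0:
        raise ParameterError("background box lies outside the image")
    return np.clip(np.asarray(channel, dtype=float) - patch.mean(), 0.0, None)
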