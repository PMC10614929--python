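import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from guvmem import (
    PipelineParams,
    colocalize,
    compute_li_threshold,
    compute_otsu_threshold,
    detect_puncta_in_guv,
    generate_guv_scene,
    label_puncta,
    particle_area_above_threshold,
    preprocess_crop,
    proportion_guvs_with_puncta,
)
from guvmem.errors import NoForegroundError, ParameterError
from guvmem.puncta_quant import Punctum, equalize_hist_8bit
from guvmem.synthetic_data import GUVSpec, PunctumSpec, SceneSpec

from conftest import spot_crop


# ---------------------------------------------------------------------------
# brute-force oracles (kept deliberately naive)
# ---------------------------------------------------------------------------

def li_cross_entropy_bruteforce(crop):
    iv = np.rint(np.asarray(crop)).astype(np.int64)
    if iv.min() == iv.max():
        return float(iv.flat[0])
    flat = iv.ravel()
    best_t, best_eta = None, None
    for t in range(int(iv.max()) + 1):
        low = flat[flat < t]
        high = flat[flat >= t]
        a0, n0 = int(low.sum()), len(low)
        a1, n1 = int(high.sum()), len(high)
        term0 = a0 * math.log(a0 / max(n0, 1)) if a0 > 0 else 0.0
        term1 = a1 * math.log(a1 / max(n1, 1)) if a1 > 0 else 0.0
        eta = -(term0 + term1)
        if best_eta is None or eta < best_eta:
            best_eta, best_t = eta, t
    return float(best_t)


def otsu_bruteforce(crop):
    iv = np.rint(np.asarray(crop)).astype(np.int64)
    flat = iv.ravel()
    n_total = len(flat)
    best_t, best_sw = None, None
    for t in range(int(iv.max()) + 1):
        low = flat[flat <= t]
        high = flat[flat > t]
        n0, n1 = len(low), len(high)
        if n0 == 0 or n1 == 0:
            continue
        q0, s0 = int((low * low).sum()), int(low.sum())
        q1, s1 = int((high * high).sum()), int(high.sum())
        var0 = q0 / max(n0, 1) - (s0 / max(n0, 1)) ** 2
        var1 = q1 / max(n1, 1) - (s1 / max(n1, 1)) ** 2
        sw = (n0 / n_total) * var0 + (n1 / n_total) * var1
        if best_sw is None or sw < best_sw:
            best_sw, best_t = sw, t
    return best_t


def flood_fill_components(mask, connectivity):
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    comps = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                stack, pix = [(r, c)], []
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    pix.append((rr, cc))
                    for dr, dc in offsets:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                rs = [p[0] for p in pix]
                cs = [p[1] for p in pix]
                comps.append(
                    {
                        "pixels": frozenset(pix),
                        "area": len(pix),
                        "bbox": (min(rs), max(rs) + 1, min(cs), max(cs) + 1),
                    }
                )
    comps.sort(key=lambda comp: (comp["bbox"][0], comp["bbox"][2]))
    return comps


def box_punctum(bbox, role="A"):
    r0, r1, c0, c1 = bbox
    pixels = frozenset((r, c) for r in range(r0, r1) for c in range(c0, c1))
    return Punctum(role, pixels, len(pixels), bbox,
                   ((r0 + r1 - 1) / 2, (c0 + c1 - 1) / 2))


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

class TestLiThreshold:
    def test_constant_crop_returns_constant(self):
        assert compute_li_threshold(np.full((5, 5), 7.0)) == 7.0

    def test_two_level_crop_threshold_strictly_between(self):
        crop = np.concatenate([np.full(100, 10.0), np.full(100, 200.0)])
        t = compute_li_threshold(crop.reshape(10, 20))
        assert 10 < t < 200

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        crop = rng.integers(0, 256, size=(20, 20)).astype(float)
        assert compute_li_threshold(crop) == li_cross_entropy_bruteforce(crop)

    def test_empty_crop_rejected(self):
        with pytest.raises(ParameterError):
            compute_li_threshold(np.empty((0, 0)))


class TestOtsuThreshold:
    def test_symmetric_bimodal_smallest_minimizer(self):
        crop = np.array([[0, 255]] * 8, dtype=float)
        # every level in [0, 254] gives zero within-class variance; smallest wins
        assert compute_otsu_threshold(crop) == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(100 + seed)
        crop = rng.integers(0, 256, size=(20, 20))
        assert compute_otsu_threshold(crop) == otsu_bruteforce(crop)

    def test_matches_skimage_between_class_maximizer(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(7)
        crop = rng.integers(0, 256, size=(30, 30))
        ours = compute_otsu_threshold(crop)
        # skimage maximizes between-class variance: same criterion, and for a
        # generic crop the optimum is unique
        assert ours == threshold_otsu(crop.astype(np.uint8))

    def test_constant_crop_signals_no_foreground(self):
        with pytest.raises(NoForegroundError):
            compute_otsu_threshold(np.full((6, 6), 3))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

class TestPreprocess:
    def test_all_zero_crop_stays_zero(self, pipeline_params):
        out = preprocess_crop(np.zeros((20, 20)), 0.0, pipeline_params)
        assert out.dtype == np.uint8
        assert not out.any()

    def test_crop_below_background_becomes_zero(self, pipeline_params):
        crop = np.full((20, 20), 40.0)
        assert not preprocess_crop(crop, 50.0, pipeline_params).any()

    def test_noiseless_spot_argmax_preserved(self, pipeline_params):
        crop = spot_crop(background=0.0)
        before = np.unravel_index(np.argmax(crop), crop.shape)
        out = preprocess_crop(crop, 0.0, pipeline_params)
        after = np.unravel_index(np.argmax(out), out.shape)
        # equalization is monotone and the smoothing kernels are symmetric
        assert math.hypot(after[0] - before[0], after[1] - before[1]) <= 1.0

    def test_equalizer_maps_constant_to_zero(self):
        assert not equalize_hist_8bit(np.full((8, 8), 100, np.uint8)).any()


# ---------------------------------------------------------------------------
# components
# ---------------------------------------------------------------------------

class TestLabelPuncta:
    def test_area_rule_strictly_larger_than_five(self, pipeline_params):
        mask = np.zeros((12, 24), bool)
        mask[2, 2:7] = True     # area 5: rejected
        mask[8, 10:16] = True   # area 6: kept
        puncta = label_puncta(mask, pipeline_params)
        assert len(puncta) == 1
        assert puncta[0].area == 6

    def test_empty_mask(self, pipeline_params):
        assert label_puncta(np.zeros((5, 5), bool), pipeline_params) == []

    @pytest.mark.parametrize("connectivity", [4, 8])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_flood_fill_oracle(self, connectivity, seed):
        rng = np.random.default_rng(seed)
        mask = rng.uniform(size=(24, 24)) < 0.45
        params = PipelineParams(connectivity=connectivity)
        got = label_puncta(mask, params)
        want = [c for c in flood_fill_components(mask, connectivity) if c["area"] > 5]
        assert len(got) == len(want)
        for g, w in zip(got, want):
            assert g.pixels == w["pixels"]
            assert g.area == w["area"]
            assert g.bbox == w["bbox"]

    def test_min_component_size_monotonicity(self, rng):
        mask = rng.uniform(size=(30, 30)) < 0.5
        counts = [
            len(label_puncta(mask, PipelineParams(min_component_px=m)))
            for m in range(0, 12)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


# ---------------------------------------------------------------------------
# per-GUV pipeline
# ---------------------------------------------------------------------------

def single_guv_scene(angles, noise=2.0, amplitude=200.0, seed=3):
    spec = SceneSpec(
        height=96, width=96,
        guvs=[GUVSpec((48.0, 48.0), 14.0)],
        puncta={"proteinA": [PunctumSpec(0, a, amplitude=amplitude) for a in angles]},
        noise_sigma=noise, background_offset=100.0, seed=seed,
    )
    return generate_guv_scene(spec)


class TestDetectPunctaInGuv:
    def test_single_high_snr_punctum_found(self, pipeline_params):
        img, truth = single_guv_scene([0.6], noise=20.0)
        region = truth.regions[0]
        puncta = detect_puncta_in_guv(img, region, "proteinA", pipeline_params)
        assert len(puncta) == 1
        planted = truth.puncta["proteinA"][0][0]
        r0, r1, c0, c1 = puncta[0].bbox
        assert r0 <= planted.center[0] < r1 and c0 <= planted.center[1] < c1

    def test_no_planted_puncta_noiseless_gives_zero(self, pipeline_params):
        img, truth = single_guv_scene([], noise=0.0)
        assert detect_puncta_in_guv(img, truth.regions[0], "proteinA", pipeline_params) == []

    def test_two_separated_puncta_resolved(self, pipeline_params):
        # separation along the ring far exceeds 4 spot sigmas
        img, truth = single_guv_scene([0.0, math.pi], noise=10.0)
        puncta = detect_puncta_in_guv(img, truth.regions[0], "proteinA", pipeline_params)
        assert len(puncta) == 2


class TestProportions:
    def test_counts_listing(self):
        s = proportion_guvs_with_puncta([1, 0, 0, 2])
        assert s.proportion == pytest.approx(0.5)
        assert (s.n_guvs, s.n_with_puncta) == (4, 2)

    def test_all_empty(self):
        assert proportion_guvs_with_puncta([[], [], []]).proportion == 0.0

    def test_zero_guvs_rejected(self):
        with pytest.raises(ParameterError):
            proportion_guvs_with_puncta([])


class TestColocalize:
    def test_identical_sets_fully_colocalized(self):
        pts = [box_punctum((0, 3, 0, 3)), box_punctum((10, 13, 10, 13)),
               box_punctum((20, 23, 20, 23))]
        res = colocalize(pts, [box_punctum(p.bbox, "B") for p in pts])
        assert res.proportion == pytest.approx(1.0)

    def test_partial_overlap_hand_case(self):
        a = [box_punctum((0, 4, 0, 4)), box_punctum((10, 14, 10, 14)),
             box_punctum((30, 34, 30, 34))]
        b = [box_punctum((2, 6, 2, 6), "B"), box_punctum((12, 16, 12, 16), "B")]
        res = colocalize(a, b)
        # A has 3 puncta (majority channel), exactly 2 overlap B
        assert res.n_colocalized == 2
        assert res.proportion == pytest.approx(2 / 3)

    def test_disjoint_sets(self):
        res = colocalize([box_punctum((0, 3, 0, 3))], [box_punctum((10, 13, 10, 13), "B")])
        assert res.proportion == 0.0

    def test_both_empty(self):
        assert colocalize([], []).proportion == 0.0

    @given(st.lists(st.tuples(st.integers(0, 40), st.integers(1, 6),
                              st.integers(0, 40), st.integers(1, 6)),
                    max_size=6),
           st.lists(st.tuples(st.integers(0, 40), st.integers(1, 6),
                              st.integers(0, 40), st.integers(1, 6)),
                    max_size=6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_swap_invariance(self, boxes_a, boxes_b):
        a = [box_punctum((r, r + h, c, c + w)) for r, h, c, w in boxes_a]
        b = [box_punctum((r, r + h, c, c + w), "B") for r, h, c, w in boxes_b]
        assert colocalize(a, b).proportion == pytest.approx(colocalize(b, a).proportion)


class TestParticleArea:
    def test_all_below_threshold(self):
        assert particle_area_above_threshold(np.full((10, 10), 5.0), 10.0) == 0

    def test_single_block(self):
        img = np.zeros((12, 12))
        img[4:8, 4:8] = 50.0
        assert particle_area_above_threshold(img, 10.0) == 16

    def test_two_blocks_min_area(self):
        img = np.zeros((20, 20))
        img[2:5, 2:5] = 50.0   # 9 px
        img[10:12, 10:12] = 50.0  # 4 px
        assert particle_area_above_threshold(img, 10.0, min_area=1) == 13
        assert particle_area_above_threshold(img, 10.0, min_area=5) == 9
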