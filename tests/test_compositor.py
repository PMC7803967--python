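import json

import numpy as np
import pytest
from scipy import stats

from egretwatch import compositor as comp
from egretwatch import synthetic
from egretwatch.compositor import (
    CompositorConfig,
    PlacementSample,
    Sprite,
    compose_scene,
    direct_paste,
    gaussian_paste,
    generate_dataset,
    opaque_box_in_frame,
    poisson_blend_region,
    poisson_paste,
    sample_placement,
)


def square_sprite(side=20, color=(255, 255, 255), alpha=255, species="great_egret"):
    rgba = np.zeros((side, side, 4), dtype=np.uint8)
    rgba[..., :3] = color
    rgba[..., 3] = alpha
    if alpha == 0:
        rgba[side // 2, side // 2, 3] = 1  # keep the opaque box non-empty
    return Sprite(rgba, species)


def identity_placement(center, area_fraction, light=1.0):
    return PlacementSample(center=center, area_fraction=area_fraction,
                           light_factor=light, rotation_deg=0.0, flip=False, shear=0.0)


def frac_for_side(side, frame_w, frame_h):
    """area_fraction that keeps a square sprite at its native pixel size."""
    return side * side / (frame_w * frame_h)


class TestSamplePlacement:
    def test_marginals_within_ranges(self, rng):
        samples = [sample_placement(rng, (640, 480)) for _ in range(10_000)]
        af = np.array([s.area_fraction for s in samples])
        lf = np.array([s.light_factor for s in samples])
        assert af.min() >= 0.0004 and af.max() <= 0.0056
        assert lf.min() >= 0.6 and lf.max() <= 1.0

    def test_light_factor_mean(self, rng):
        lf = np.array(
            [sample_placement(rng, (640, 480)).light_factor for _ in range(10_000)]
        )
        assert abs(lf.mean() - 0.8) < 0.01

    def test_ks_uniformity(self, rng):
        samples = [sample_placement(rng, (640, 480)) for _ in range(10_000)]
        af = np.array([s.area_fraction for s in samples])
        lf = np.array([s.light_factor for s in samples])
        p_af = stats.kstest(af, "uniform", args=(0.0004, 0.0056 - 0.0004)).pvalue
        p_lf = stats.kstest(lf, "uniform", args=(0.6, 0.4)).pvalue
        assert p_af > 0.01
        assert p_lf > 0.01

    def test_fixed_state_reproducible(self):
        a = sample_placement(np.random.default_rng(3), (640, 480))
        b = sample_placement(np.random.default_rng(3), (640, 480))
        assert a == b

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(comp.PlacementError):
            sample_placement(rng, (64, 64), allowed_mask=np.zeros((64, 64), bool))


class TestDirectPaste:
    def test_opaque_sprite_replaces_pixels(self, background):
        h, w = background.shape[:2]
        side = 16
        p = identity_placement((w / 2, h / 2), frac_for_side(side, w, h))
        out = direct_paste(background, square_sprite(side), p)
        x0, y0, x1, y1 = opaque_box_in_frame(background, square_sprite(side), p)
        assert (out[y0:y1, x0:x1] == 255).all()

    def test_transparent_sprite_is_identity(self, background):
        h, w = background.shape[:2]
        p = identity_placement((w / 2, h / 2), frac_for_side(16, w, h))
        out = direct_paste(background, square_sprite(16, alpha=0), p)
        # the lone seed pixel keeps the box non-empty; everything else untouched
        assert (out != background).sum() <= 3

    def test_light_factor_scales_white_to_153(self, background):
        h, w = background.shape[:2]
        p = identity_placement((w / 2, h / 2), frac_for_side(16, w, h), light=0.6)
        out = direct_paste(background, square_sprite(16), p)
        x0, y0, x1, y1 = opaque_box_in_frame(background, square_sprite(16), p)
        assert (out[y0:y1, x0:x1] == 153).all()

    def test_pixels_outside_sprite_unchanged(self, background):
        h, w = background.shape[:2]
        p = identity_placement((w / 2, h / 2), frac_for_side(16, w, h))
        out = direct_paste(background, square_sprite(16), p)
        x0, y0, x1, y1 = opaque_box_in_frame(background, square_sprite(16), p)
        mask = np.zeros(background.shape[:2], bool)
        mask[y0:y1, x0:x1] = True
        assert np.array_equal(out[~mask], background[~mask])


class TestGaussianPaste:
    def test_sigma_zero_equals_direct(self, background, sprite_pool):
        h, w = background.shape[:2]
        p = PlacementSample((w / 2, h / 2), 0.003, 0.8, rotation_deg=7.0, shear=0.05)
        a = gaussian_paste(background, sprite_pool[0], p, sigma=0.0)
        b = direct_paste(background, sprite_pool[0], p)
        assert np.array_equal(a, b)

    def test_blurred_mask_profile(self, background):
        h, w = background.shape[:2]
        side = 24
        p = identity_placement((w / 2, h / 2), frac_for_side(side, w, h))
        out = gaussian_paste(background, square_sprite(side), p, sigma=2.0)
        cy, cx = h // 2, w // 2
        # centre of the mask is fully sprite, far away fully background
        assert (out[cy, cx] == 255).all()
        assert np.array_equal(out[10, 10], background[10, 10])

    def test_convex_combination(self, background):
        h, w = background.shape[:2]
        color = np.array([40, 180, 220])
        sprite = square_sprite(20, color=tuple(color))
        p = identity_placement((w / 2, h / 2), frac_for_side(20, w, h))
        out = gaussian_paste(background, sprite, p, sigma=3.0).astype(int)
        bg = background.astype(int)
        lo = np.minimum(bg, color[None, None, :])
        hi = np.maximum(bg, color[None, None, :])
        # rounding of the convex blend can move a value at most 1 outside the hull
        assert (out >= lo - 1).all()
        assert (out <= hi + 1).all()

    def test_negative_sigma_rejected(self, background, sprite_pool):
        p = identity_placement((200, 150), 0.003)
        with pytest.raises(ValueError):
            gaussian_paste(background, sprite_pool[0], p, sigma=-1.0)


def dense_poisson_oracle(background, guide, mask):
    """Direct dense solve of the gradient-domain system (per channel)."""
    h, w = mask.shape
    ys, xs = np.nonzero(mask)
    idx = {(y, x): k for k, (y, x) in enumerate(zip(ys, xs))}
    n = len(ys)
    bg = background.astype(float)
    gd = guide.astype(float)
    out = bg.copy()
    for c in range(bg.shape[2]):
        A = np.zeros((n, n))
        b = np.zeros(n)
        for k, (y, x) in enumerate(zip(ys, xs)):
            A[k, k] = 4.0
            for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ny, nx = y + dy, x + dx
                if 0 <= ny < h and 0 <= nx < w:
                    b[k] += gd[y, x, c] - gd[ny, nx, c]
                    if (ny, nx) in idx:
                        A[k, idx[(ny, nx)]] = -1.0
                    else:
                        b[k] += bg[ny, nx, c]
        out[ys, xs, c] = np.linalg.solve(A, b)
    return out


class TestPoissonPaste:
    def test_constant_into_constant_is_background(self):
        bg = np.full((40, 40, 3), 90, dtype=np.uint8)
        sprite = square_sprite(12, color=(30, 200, 120))
        p = identity_placement((20.0, 20.0), frac_for_side(12, 40, 40))
        out = poisson_paste(bg, sprite, p)
        assert np.array_equal(out, bg)

    @pytest.mark.parametrize("method", ["cg", "direct"])
    def test_matches_dense_oracle(self, method, rng):
        bg = rng.integers(0, 255, (30, 30, 3)).astype(np.uint8)
        guide = rng.integers(0, 255, (30, 30, 3)).astype(np.uint8)
        mask = np.zeros((30, 30), bool)
        mask[8:24, 6:27] = True
        mask[10:14, 3:10] = True
        ours = poisson_blend_region(bg, guide, mask, method=method)
        oracle = dense_poisson_oracle(bg, guide, mask)
        assert np.abs(ours - oracle).max() <= 1e-6

    def test_boundary_pixels_keep_background(self, background):
        h, w = background.shape[:2]
        sprite = square_sprite(14, color=(10, 10, 10))
        p = identity_placement((w / 2, h / 2), frac_for_side(14, w, h))
        out = poisson_paste(background, sprite, p)
        x0, y0, x1, y1 = opaque_box_in_frame(background, sprite, p)
        ring = np.ones(background.shape[:2], bool)
        ring[y0:y1, x0:x1] = False
        assert np.array_equal(out[ring], background[ring])

    def test_region_on_frame_edge_rejected(self, background):
        sprite = square_sprite(14)
        h, w = background.shape[:2]
        p = identity_placement((4.0, 4.0), frac_for_side(14, w, h))
        with pytest.raises(comp.PlacementError):
            poisson_paste(background, sprite, p)


class TestMirrorCommutation:
    @pytest.mark.parametrize("mode", ["direct", "gaussian", "poisson"])
    def test_paste_commutes_with_mirror(self, background, sprite_pool, mode):
        h, w = background.shape[:2]
        p = PlacementSample((w / 2 + 21, h / 2 - 8), 0.004, 0.85,
                            rotation_deg=9.0, flip=False, shear=0.08)
        pm = p.mirrored(w)
        sprite = sprite_pool[0]
        mirrored_bg = background[:, ::-1].copy()
        if mode == "direct":
            a = direct_paste(background, sprite, p)
            b = direct_paste(mirrored_bg, sprite, pm)
        elif mode == "gaussian":
            a = gaussian_paste(background, sprite, p, sigma=2.0)
            b = gaussian_paste(mirrored_bg, sprite, pm, sigma=2.0)
        else:
            a = poisson_paste(background, sprite, p, method="direct")
            b = poisson_paste(mirrored_bg, sprite, pm, method="direct")
        assert np.abs(a[:, ::-1].astype(int) - b.astype(int)).max() <= 1


class TestComposeScene:
    def test_zero_birds_identity(self, background, sprite_pool, rng):
        img, ann = compose_scene(background, sprite_pool, 0, rng)
        assert np.array_equal(img, background)
        assert ann == []

    def test_five_birds_boxes_inside(self, background, sprite_pool, rng):
        img, ann = compose_scene(background, sprite_pool, 5, rng, "direct")
        assert len(ann) == 5
        for a in ann:
            x0, y0, x1, y1 = a["bbox"]
            assert 0 <= x0 < x1 <= background.shape[1]
            assert 0 <= y0 < y1 <= background.shape[0]

    def test_annotation_pixel_consistency(self, background, sprite_pool, rng):
        img, ann = compose_scene(background, sprite_pool, 4, rng, "direct")
        for a in ann:
            x0, y0, x1, y1 = a["bbox"]
            assert (img[y0:y1, x0:x1] != background[y0:y1, x0:x1]).any()

    def test_species_mix_balanced(self, sprite_pool, rng):
        bg = synthetic.generate_background(320, 200, seed=2)
        tally = {"great_egret": 0, "little_egret": 0}
        for _ in range(150):
            _, ann = compose_scene(bg, sprite_pool, 4, rng, "direct")
            for a in ann:
                tally[a["species"]] += 1
        total = sum(tally.values())
        ratio = tally["great_egret"] / total
        assert abs(ratio - 0.5) < 0.05


class TestGenerateDataset:
    def test_small_dataset_shape(self, tmp_path, sprite_pool):
        bgs = [synthetic.generate_background(256, 160, seed=s) for s in range(2)]
        manifest = generate_dataset(tmp_path / "d", sprite_pool, bgs,
                                    n_images=3, seed=1, paste_mode="direct")
        assert manifest["n_images"] == 3
        files = sorted((tmp_path / "d" / "images").glob("*.png"))
        assert len(files) == 3
        coco = json.loads((tmp_path / "d" / "annotations.json").read_text())
        assert len(coco["images"]) == 3
        assert {a["image_id"] for a in coco["annotations"]} <= {1, 2, 3}

    def test_rerun_identical_annotations(self, tmp_path, sprite_pool):
        bgs = [synthetic.generate_background(256, 160, seed=3)]
        generate_dataset(tmp_path / "a", sprite_pool, bgs, n_images=2, seed=5,
                         paste_mode="direct", write_images=False)
        generate_dataset(tmp_path / "b", sprite_pool, bgs, n_images=2, seed=5,
                         paste_mode="direct", write_images=False)
        assert (tmp_path / "a" / "annotations.json").read_text() == (
            tmp_path / "b" / "annotations.json"
        ).read_text()
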