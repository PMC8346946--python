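import numpy as np
import pytest
from scipy import ndimage

from glyphcomplexity.imaging import (
    BlankGlyphError,
    CANVAS,
    GlyphImage,
    Stage,
    load_image,
    prune_skeleton,
    render_glyph,
    render_script,
    resize_and_center,
    save_image,
    script_resize_ratio,
    skeleton_standardize,
    trim,
)


def _glyph(mask, stage=Stage.RAW):
    return GlyphImage(pixels=mask, stage=stage)


class TestTrim:
    def test_crops_to_bounding_box(self):
        mask = np.zeros((500, 500), bool)
        mask[100:140, 50:150] = True  # 40 rows × 100 cols block
        out = trim(_glyph(mask))
        assert out.pixels.shape == (40, 100)
        assert out.pixels.all()
        assert out.stage is Stage.TRIMMED

    def test_idempotent_on_tight_image(self):
        mask = np.ones((30, 60), bool)
        once = trim(_glyph(mask))
        twice = trim(once)
        assert np.array_equal(once.pixels, twice.pixels)

    def test_blank_image_errors(self):
        with pytest.raises(BlankGlyphError):
            trim(_glyph(np.zeros((10, 10), bool)))


class TestResize:
    def test_ratio_from_largest_dimension(self):
        imgs = [_glyph(np.ones((300, 700), bool), Stage.TRIMMED)]
        assert script_resize_ratio(imgs) == pytest.approx(0.7)

    def test_ratio_identity_at_490(self):
        imgs = [_glyph(np.ones((490, 100), bool), Stage.TRIMMED)]
        assert script_resize_ratio(imgs) == pytest.approx(1.0)

    def test_ratio_over_several_images(self):
        dims = [(100, 40), (980, 20), (200, 200)]
        imgs = [_glyph(np.ones(d, bool), Stage.TRIMMED) for d in dims]
        assert script_resize_ratio(imgs) == pytest.approx(0.5)

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            script_resize_ratio([])

    def test_resize_and_center_geometry(self):
        g = _glyph(np.ones((300, 700), bool), Stage.TRIMMED)
        out = resize_and_center(g, 0.7)
        assert out.pixels.shape == (CANVAS, CANVAS)
        rows = np.flatnonzero(out.pixels.any(axis=1))
        cols = np.flatnonzero(out.pixels.any(axis=0))
        assert cols[-1] - cols[0] + 1 == 490
        assert rows[-1] - rows[0] + 1 == 210
        # centered within 1 px
        assert abs((rows[0] + rows[-1]) / 2 - (CANVAS - 1) / 2) <= 1
        assert abs((cols[0] + cols[-1]) / 2 - (CANVAS - 1) / 2) <= 1

    def test_ratio_one_is_identity_up_to_centering(self):
        g = _glyph(np.ones((490, 490), bool), Stage.TRIMMED)
        out = resize_and_center(g, 1.0)
        assert out.pixels.sum() == 490 * 490

    def test_shared_ratio_preserves_relative_sizes(self):
        big = _glyph(np.ones((400, 400), bool), Stage.TRIMMED)
        small = _glyph(np.ones((100, 100), bool), Stage.TRIMMED)
        ratio = script_resize_ratio([big, small])
        out_big = resize_and_center(big, ratio)
        out_small = resize_and_center(small, ratio)
        got = out_big.pixels.sum() / out_small.pixels.sum()
        assert got == pytest.approx(16.0, rel=0.05)

    def test_overflow_ratio_errors(self):
        g = _glyph(np.ones((700, 100), bool), Stage.TRIMMED)
        with pytest.raises(ValueError):
            resize_and_center(g, 0.9)


def _resized(mask):
    return GlyphImage(pixels=mask, stage=Stage.RESIZED)


class TestSkeletonStandardize:
    def test_thick_bar_becomes_5px_bar(self):
        mask = np.zeros((CANVAS, CANVAS), bool)
        mask[246:255, 100:400] = True  # 9 px thick horizontal bar
        out = skeleton_standardize(_resized(mask))
        rows = np.flatnonzero(out.pixels.any(axis=1))
        cols = np.flatnonzero(out.pixels.any(axis=0))
        assert rows[-1] - rows[0] + 1 == 5  # uniform 2·2+1 thickness
        # length preserved up to end effects of the medial axis
        assert cols[-1] - cols[0] + 1 == pytest.approx(300, abs=12)

    def test_short_spur_is_pruned_but_l_shape_kept(self):
        mask = np.zeros((CANVAS, CANVAS), bool)
        mask[200:207, 100:300] = True   # horizontal arm of the L
        mask[200:320, 100:107] = True   # vertical arm
        spur = np.zeros_like(mask)
        spur[193:200, 200:205] = True   # 7–10 px artifact off the arm
        out_clean = skeleton_standardize(_resized(mask))
        out_spur = skeleton_standardize(_resized(mask | spur))
        # spur is gone: same foreground up to a small tolerance
        diff = np.logical_xor(out_clean.pixels, out_spur.pixels).sum()
        assert diff <= 0.02 * out_clean.pixels.sum()
        # both arms survive
        assert out_spur.pixels[:, 110:290].any()
        assert out_spur.pixels[250:310, :].any()

    def test_output_thickness_uniform_by_distance_transform(self):
        # dilation of a 1-px skeleton: 95% of foreground within radius+1
        mask = np.zeros((CANVAS, CANVAS), bool)
        mask[200:215, 100:350] = True   # L-shape with uneven arm thickness
        mask[200:330, 100:112] = True
        out = skeleton_standardize(_resized(mask))
        dist = ndimage.distance_transform_edt(out.pixels)
        frac = (dist[out.pixels] <= 2 + 1).mean()
        assert frac >= 0.95

    def test_deterministic(self):
        mask = np.zeros((CANVAS, CANVAS), bool)
        mask[240:260, 100:400] = True
        a = skeleton_standardize(_resized(mask))
        b = skeleton_standardize(_resized(mask))
        assert np.array_equal(a.pixels, b.pixels)

    def test_cross_with_short_arms_collapses_to_junction(self):
        # every arm is an endpoint-to-junction branch below the threshold,
        # so only the junction neighborhood survives pruning
        mask = np.zeros((CANVAS, CANVAS), bool)
        mask[248:253, 230:270] = True
        mask[230:270, 248:253] = True
        out = skeleton_standardize(_resized(mask), prune_len=60)
        assert 0 < out.pixels.sum() < 100

    def test_small_blob_without_junction_is_kept(self):
        mask = np.zeros((CANVAS, CANVAS), bool)
        mask[250:255, 250:265] = True  # 15 px mark: no junction, never pruned
        out = skeleton_standardize(_resized(mask), prune_len=500)
        assert out.pixels.any()


class TestPruneSkeleton:
    def test_whole_short_component_is_kept(self):
        skel = np.zeros((50, 50), bool)
        skel[10, 10:20] = True  # 10 px isolated path, no junction
        assert np.array_equal(prune_skeleton(skel, 35), skel)

    def test_short_branch_off_junction_removed(self):
        skel = np.zeros((100, 100), bool)
        skel[50, 5:95] = True   # long horizontal path (both arms > threshold)
        skel[40:50, 50] = True  # 10 px vertical branch hitting a junction
        out = prune_skeleton(skel, 35)
        assert not out[40:50, 50].any()
        assert out[50, 5:95].all()

    def test_long_branch_survives(self):
        skel = np.zeros((100, 100), bool)
        skel[50, 5:95] = True
        skel[5:50, 50] = True  # 45 px branch, above threshold
        out = prune_skeleton(skel, 35)
        assert out[10, 50]


@pytest.fixture(scope="module")
def font_path():
    import matplotlib
    from pathlib import Path

    p = Path(matplotlib.get_data_path()) / "fonts" / "ttf" / "DejaVuSans.ttf"
    if not p.exists():
        pytest.skip("no TTF font available")
    return str(p)


class TestRendering:
    def test_render_produces_ink_on_canvas(self, font_path):
        g = render_glyph(font_path, ord("A"), 60)
        assert g is not None and g.pixels.shape == (CANVAS, CANVAS)
        assert g.pixels.any()

    def test_render_script_backs_off_point_size_on_overflow(self, font_path):
        cps = [ord("W"), ord("i")]
        rendered, size = render_script(font_path, cps, initial_point_size=700)
        assert size < 700 and size % 5 == 0
        for g in rendered.values():
            px = g.pixels
            assert not (px[0].any() or px[-1].any() or px[:, 0].any() or px[:, -1].any())

    def test_glyph_fitting_at_60_stays_at_60(self, font_path):
        rendered, size = render_script(font_path, [ord("x")], initial_point_size=60)
        assert size == 60


def test_image_io_roundtrip(tmp_path):
    mask = np.zeros((60, 60), bool)
    mask[10:50, 20:40] = True
    g = GlyphImage(pixels=mask)
    for name in ("g.png", "g.pbm"):
        save_image(g, tmp_path / name)
        back = load_image(tmp_path / name)
        assert np.array_equal(back.pixels, mask)
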