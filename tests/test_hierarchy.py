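import numpy as np
import pytest

import tagtrack as tt
from tagtrack.hierarchy import (
    FLAG_DEGENERATE,
    MatchedRegion,
    SearchConfig,
    htm_correspondences,
    match_children,
    match_template,
    refine_by_overlap,
    tracking_correspondences,
)
from tagtrack.image_parts import TEMPLATE_OVERLAP_SIZES, ImageFrame, decompose


@pytest.fixture(scope="module")
def small_pair():
    cfg = tt.PhantomConfig(
        image_size=(64, 64), inner_radius=10.0, outer_radius=22.0,
        frames=2, motion="translation", translation=(3.0, -2.0),
    )
    return cfg, tt.render_tag_image(cfg, 0), tt.render_tag_image(cfg, 1)


class TestMatchTemplate:
    def test_identity_self_match(self, small_pair):
        cfg, f0, _ = small_pair
        grid = decompose(f0.shape)
        scfg = SearchConfig()
        for tpl in grid.templates:
            r, c, h, w = tpl.rect
            if np.ptp(f0.pixels[r : r + h, c : c + w]) == 0:
                continue
            m = match_template(f0, f0, tpl, scfg)
            assert m.origin == tpl.origin
            assert m.peak_cc == pytest.approx(1.0, abs=1e-9)

    def test_translation_recovered(self, small_pair):
        cfg, f0, f1 = small_pair
        grid = decompose(f0.shape)
        scfg = SearchConfig()
        for tpl in grid.templates:
            r, c, h, w = tpl.rect
            # interior templates only: search area and true match in-bounds
            if not (16 <= r <= 32 and 16 <= c <= 32):
                continue
            if np.ptp(f0.pixels[r : r + h, c : c + w]) == 0:
                continue
            m = match_template(f0, f1, tpl, scfg)
            assert m.origin == (r + 3, c - 2)

    def test_flat_template_degenerate_fallback(self):
        flat = ImageFrame(pixels=np.full((32, 32), 0.3))
        grid = decompose((32, 32))
        m = match_template(flat, flat, grid.templates[0], SearchConfig())
        assert m.degenerate
        assert m.origin == grid.templates[0].origin


class TestRefineByOverlap:
    def test_identity_centered_sections(self, small_pair):
        """Without a target the chain keeps centered sections with zero offset."""
        cfg, f0, _ = small_pair
        grid = decompose(f0.shape)
        tpl = next(
            t for t in grid.templates
            if np.ptp(f0.pixels[t.origin[0]:t.origin[0]+16, t.origin[1]:t.origin[1]+16]) > 0
        )
        rt = MatchedRegion(tpl.origin, 16, 1.0, False)
        mov, final = refine_by_overlap(
            f0, f0, tpl, rt, TEMPLATE_OVERLAP_SIZES, SearchConfig()
        )
        assert final.size == 10
        assert mov == (tpl.origin[0] + 3, tpl.origin[1] + 3)  # centered 10x10
        assert final.origin == mov

    def test_single_step_segment_overlap(self, small_pair):
        cfg, f0, _ = small_pair
        grid = decompose(f0.shape)
        tpl = grid.templates[5]
        seg = grid.children(tpl)[0]
        rs = MatchedRegion(seg.origin, 8, 1.0, False)
        mov, final = refine_by_overlap(f0, f0, seg, rs, [6], SearchConfig())
        assert final.size == 6

    def test_nondecreasing_sizes_rejected(self, small_pair):
        cfg, f0, _ = small_pair
        grid = decompose(f0.shape)
        tpl = grid.templates[0]
        rt = MatchedRegion(tpl.origin, 16, 1.0, False)
        with pytest.raises(ValueError, match="strictly decrease"):
            refine_by_overlap(f0, f0, tpl, rt, [14, 14], SearchConfig())


class TestHtmCorrespondences:
    def test_identity_zero_displacement(self, small_pair):
        cfg, f0, _ = small_pair
        corr = htm_correspondences(f0, f0)
        assert np.abs(corr.displacements).max() == 0.0

    def test_pair_count(self, small_pair):
        cfg, f0, f1 = small_pair
        corr = htm_correspondences(f0, f1)
        assert len(corr) == 1024  # (64/16)^2 templates x 64 windows

    def test_integer_translation_exact(self):
        """All non-degenerate windows recover an exact integer shift."""
        cfg = tt.PhantomConfig(
            image_size=(128, 128), frames=2,
            motion="translation", translation=(4.0, 6.0),
        )
        f0, f1 = tt.render_tag_image(cfg, 0), tt.render_tag_image(cfg, 1)
        corr = htm_correspondences(f0, f1)
        ok = corr.ok_mask()
        assert ok.sum() > 500
        assert (corr.displacements[ok] == [4.0, 6.0]).all()

    def test_flat_windows_flagged_degenerate(self, small_pair):
        cfg, f0, f1 = small_pair
        corr = htm_correspondences(f0, f1)
        # blood pool / background windows exist and are flagged
        assert (corr.flags == FLAG_DEGENERATE).any()
        assert (~corr.ok_mask()).sum() + corr.ok_mask().sum() == len(corr)

    def test_deterministic(self, small_pair):
        cfg, f0, f1 = small_pair
        a = htm_correspondences(f0, f1)
        b = htm_correspondences(f0, f1)
        np.testing.assert_array_equal(a.reference.points, b.reference.points)
        np.testing.assert_array_equal(a.peak_cc, b.peak_cc)

    def test_dimension_mismatch_rejected(self, small_pair):
        cfg, f0, _ = small_pair
        other = ImageFrame(pixels=np.zeros((48, 64)))
        with pytest.raises(ValueError, match="dims differ"):
            htm_correspondences(f0, other)

    def test_csv_roundtrip(self, small_pair, tmp_path):
        cfg, f0, f1 = small_pair
        corr = htm_correspondences(f0, f1)
        path = tmp_path / "corr.csv"
        corr.to_csv(path)
        back = tt.Correspondences.from_csv(path)
        np.testing.assert_allclose(back.moving.points, corr.moving.points)
        np.testing.assert_allclose(back.reference.points, corr.reference.points)
        assert list(back.flags) == list(corr.flags)


class TestMatchChildren:
    def test_identity_same_relative_offsets(self, small_pair):
        cfg, f0, _ = small_pair
        grid = decompose(f0.shape)
        tpl = next(
            t for t in grid.templates
            if np.ptp(f0.pixels[t.origin[0]:t.origin[0]+16, t.origin[1]:t.origin[1]+16]) > 0
        )
        rt = MatchedRegion(tpl.origin, 16, 1.0, False)
        for seg, rs in zip(
            grid.children(tpl),
            match_children(f0, f0, grid.children(tpl), tpl.origin, rt, SearchConfig()),
        ):
            if not rs.degenerate:
                assert rs.origin == seg.origin

    def test_rotation_field_recovered_within_one_pixel(self):
        """Children of correctly anchored parents track a 5-degree rotation."""
        cfg = tt.PhantomConfig(
            image_size=(128, 128), frames=3, motion="rotation", rotation_max_deg=5.0
        )
        f0, f1 = tt.render_tag_image(cfg, 0), tt.render_tag_image(cfg, 1)
        m1 = tt.analytic_motion(cfg, 1)
        grid = decompose((128, 128))
        scfg = SearchConfig()
        checked = 0
        for tpl in grid.templates:
            r, c, h, w = tpl.rect
            if np.ptp(f0.pixels[r : r + h, c : c + w]) == 0:
                continue
            anchor = tuple(
                np.round(m1.forward(np.array(tpl.origin, float))[0]).astype(int)
            )
            parent = MatchedRegion(anchor, 16, 1.0, False)
            for seg, rs in zip(
                grid.children(tpl),
                match_children(f0, f1, grid.children(tpl), tpl.origin, parent, scfg),
            ):
                if rs.degenerate:
                    continue
                true = m1.forward(np.array(seg.origin, float))[0]
                assert np.abs(np.array(rs.origin) - true).max() <= 1.0
                checked += 1
        assert checked > 40

    def test_containment_in_padded_parent(self, small_pair):
        cfg, f0, f1 = small_pair
        grid = decompose(f0.shape)
        scfg = SearchConfig()
        for tpl in grid.templates[:4]:
            rt = match_template(f0, f1, tpl, scfg)
            for seg, rs in zip(
                grid.children(tpl),
                match_children(f0, f1, grid.children(tpl), tpl.origin, rt, scfg),
            ):
                for ax in range(2):
                    rel = seg.origin[ax] - tpl.origin[ax]
                    lo = rt.origin[ax] + rel - scfg.overlap_margin
                    hi = rt.origin[ax] + rel + scfg.overlap_margin
                    assert lo <= rs.origin[ax] <= hi or rs.degenerate


class TestTrackingCorrespondences:
    def test_identity_zero_displacement(self, small_pair):
        cfg, f0, _ = small_pair
        corr = tracking_correspondences(f0, f0)
        assert len(corr) > 0
        assert np.abs(corr.displacements).max() == 0.0
        assert corr.moving.spacing == 8.0

    def test_points_at_segment_centres(self, small_pair):
        cfg, f0, f1 = small_pair
        corr = tracking_correspondences(f0, f1)
        frac = corr.moving.points % 8.0
        np.testing.assert_allclose(frac, 3.5)

    def test_exact_translation(self, small_pair):
        cfg, f0, f1 = small_pair
        corr = tracking_correspondences(f0, f1, SearchConfig(template_search_radius=8))
        interior = np.all((corr.moving.points >= 19.5) & (corr.moving.points <= 43.5), axis=1)
        d = corr.displacements[interior]
        assert len(d) > 0
        np.testing.assert_allclose(
            d, np.broadcast_to([3.0, -2.0], d.shape), atol=1e-9
        )


def test_search_config_validation():
    with pytest.raises(ValueError):
        SearchConfig(template_search_radius=-1)
    with pytest.raises(ValueError):
        SearchConfig(overlap_margin=-2)
    with pytest.raises(ValueError):
        SearchConfig(min_peak_cc=1.5)
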