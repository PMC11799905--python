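"""Synthetic EPID renders: ground-truth bookkeeping, edge fidelity, noise."""

import numpy as np
import pytest

import stakitt as st
from .conftest import make_mini_cfg, make_mini_plan


def dense_scan_crossing(img, y_mm, x_lo, x_hi, step=1e-4):
    """Brute-force 50% crossing of a crossplane profile at row y (raw mm).

    Independent of the analyzer: scans the interpolated profile on a 1e-4 mm
    grid, takes the level midway between the window's extremes and linearly
    inverts the bracketing pair.
    """
    xs = np.arange(x_lo, x_hi, step)
    v = img.value_at(xs, np.full_like(xs, y_mm))
    level = 0.5 * (v.min() + v.max())
    f = v - level
    i = np.nonzero(np.diff(np.signbit(f)))[0][0]
    return xs[i] + step * f[i] / (f[i] - f[i + 1])


class TestGroundTruth:
    def test_zero_errors_give_zero_deviation(self, mini_clean):
        plan, cfg, img, gt = mini_clean
        assert np.all(gt.true_deviation == 0.0)
        assert np.allclose(gt.true_tip, plan.nominal_tips)

    def test_leaf_error_bookkeeping(self, mini_plan):
        err = np.zeros((2, 16))
        err[0, 4] = 1.0   # bank A retracted 1 mm
        err[1, 9] = -0.4  # bank B extended 0.4 mm
        cfg = make_mini_cfg(noise_sd=0.0, leaf_errors=err)
        _, gt = st.render_stakitt_image(mini_plan, cfg)
        assert np.allclose(gt.true_deviation[:, 0, 4], 1.0)
        assert np.allclose(gt.true_deviation[:, 1, 9], -0.4)
        # retraction moves bank A tips toward -x, bank B extension toward -x
        assert np.allclose(gt.true_tip[:, 0, 4], mini_plan.nominal_tips[:, 0, 4] - 1.0)
        assert np.allclose(gt.true_tip[:, 1, 9], mini_plan.nominal_tips[:, 1, 9] - 0.4)

    def test_backlash_shifts_between_g90_and_g270(self, mini_plan):
        backlash = np.full((2, 16), 0.27)
        cfg = make_mini_cfg(noise_sd=0.0, backlash=backlash)
        _, gt90 = st.render_stakitt_image(mini_plan, cfg, gantry=90.0)
        _, gt270 = st.render_stakitt_image(mini_plan, cfg, gantry=270.0)
        _, gt0 = st.render_stakitt_image(mini_plan, cfg, gantry=0.0)
        diff_a = gt90.true_deviation[:, 0, :] - gt270.true_deviation[:, 0, :]
        diff_b = gt90.true_deviation[:, 1, :] - gt270.true_deviation[:, 1, :]
        assert np.allclose(diff_a, 0.27)   # bank A more retracted at G90
        assert np.allclose(diff_b, -0.27)  # bank B more extended at G90
        assert np.all(gt0.true_deviation == 0.0)  # gravity off-axis at G0

    def test_ground_truth_json_round_trip(self, mini_clean, tmp_path):
        *_, gt = mini_clean
        gt.to_json(tmp_path / "gt.json")
        back = st.GroundTruth.from_json(tmp_path / "gt.json")
        assert np.array_equal(back.true_tip, gt.true_tip)
        assert back.cax_panel_mm == pytest.approx(gt.cax_panel_mm)


class TestEdgeFidelity:
    def test_rendered_edges_at_true_tip_within_5um(self, mini_clean):
        """Zero-noise 50% crossings match the analytic tip to < 0.005 mm."""
        plan, cfg, img, gt = mini_clean
        cx, cy = gt.cax_panel_mm
        for leaf in (3, 8):
            y = cy + plan.mlc.leaf_centers[leaf]
            for stk in (0, 5):
                tip_a = gt.true_tip[stk, 0, leaf]
                meas = dense_scan_crossing(img, y, cx + tip_a - 2, cx + tip_a + 2)
                assert meas - cx == pytest.approx(tip_a, abs=0.005)

    def test_rendered_edge_follows_injected_error(self, mini_plan):
        err = np.zeros((2, 16))
        err[0, 8] = -0.73
        cfg = make_mini_cfg(noise_sd=0.0, leaf_errors=err)
        img, gt = st.render_stakitt_image(mini_plan, cfg)
        cx, cy = gt.cax_panel_mm
        y = cy + mini_plan.mlc.leaf_centers[8]
        tip = gt.true_tip[2, 0, 8]
        meas = dense_scan_crossing(img, y, cx + tip - 2, cx + tip + 2)
        assert meas - cx == pytest.approx(tip, abs=0.005)
        assert tip == pytest.approx(mini_plan.nominal_tips[2, 0, 8] + 0.73)


class TestNoiseAndSeeds:
    def test_same_seed_bit_identical(self, mini_plan):
        cfg = make_mini_cfg(seed=42)
        img1, _ = st.render_stakitt_image(mini_plan, cfg)
        img2, _ = st.render_stakitt_image(mini_plan, cfg)
        assert np.array_equal(img1.pixels, img2.pixels)

    def test_different_seeds_same_statistics(self, mini_plan):
        cfg = make_mini_cfg(seed=1)
        img1, _ = st.render_stakitt_image(mini_plan, cfg, seed=1)
        img2, _ = st.render_stakitt_image(mini_plan, cfg, seed=2)
        assert not np.array_equal(img1.pixels, img2.pixels)
        d = img1.pixels - img2.pixels
        # difference of two independent noise fields: zero mean, sd*sqrt(2)
        plateau = 1 + 7 * cfg.transmission
        assert abs(d.mean()) < 1e-4
        assert d.std() == pytest.approx(np.sqrt(2) * 0.005 * plateau, rel=0.05)

    def test_pixels_remain_non_negative(self, mini_plan):
        cfg = make_mini_cfg(seed=3, noise_sd=0.05)
        img, _ = st.render_stakitt_image(mini_plan, cfg)
        assert np.all(img.pixels >= 0)


class TestNarrowing:
    def test_error_leaf_width_shrinks_along_travel(self):
        """Radiological width of a protruding error leaf falls with tip x."""
        plan = make_mini_plan()
        err = np.zeros((2, 16))
        err[0, 8] = -1.0
        cfg = make_mini_cfg(noise_sd=0.0, narrowing_slope=1.0, leaf_errors=err)
        img, gt = st.render_stakitt_image(plan, cfg)
        cx, cy = gt.cax_panel_mm
        yc = cy + plan.mlc.leaf_centers[8]
        widths = []
        for stk, c in enumerate(plan.stakitt_centers):
            xt = cx + gt.true_tip[stk, 0, 8] - 0.5  # inside the tongue
            ys = np.arange(yc - 4, yc + 4, 0.01)
            v = img.value_at(np.full_like(ys, xt), ys)
            level = 0.5 * (v.min() + 0.5 * (v[0] + v[-1]))
            below = ys[v < level]
            widths.append(below[-1] - below[0])
        assert all(np.diff(widths) < 0)

    def test_no_narrowing_without_slope(self, mini_clean):
        plan, cfg, img, gt = mini_clean
        cx, cy = gt.cax_panel_mm
        yc = cy + plan.mlc.leaf_centers[8]
        widths = []
        for c in plan.stakitt_centers:
            xt = cx + (c - plan.stakitt_width / 2) - 1.0
            ys = np.arange(yc - 6, yc + 6, 0.01)
            v = img.value_at(np.full_like(ys, xt), ys)
            widths.append(v.max() - v.min())
        assert np.ptp(widths) < 0.02  # shielded region: no leaf silhouette


class TestGeometryErrors:
    def test_comb_outside_panel_rejected(self, mini_plan):
        cfg = make_mini_cfg(panel_shape=(512, 512))
        bad = st.build_default_plan(
            mini_plan.mlc,
            stakitt_centers=mini_plan.stakitt_centers,
            stakitt_width=10.0,
            comb_retract_tip=150.0,  # beyond the 99.8 mm half panel
        )
        with pytest.raises(ValueError, match="outside the panel"):
            st.render_stakitt_image(bad, cfg)

    def test_inconsistent_mlc_rejected(self, mini_plan):
        cfg = make_mini_cfg()
        with pytest.raises(ValueError, match="inconsistent"):
            st.render_stakitt_image(mini_plan, cfg, mlc=st.millennium120())


class TestConeArc:
    def test_frame_count_and_gantry_tags(self):
        cfg = make_mini_cfg(seed=2)
        frames = st.render_cone_arc(cfg, n_frames=48)
        assert len(frames) == 48
        tags = [f.gantry_angle for f in frames]
        assert tags[0] == 0.0
        assert np.allclose(np.diff(tags), 7.5)
        assert all(f.acquisition_mode == "cine_frame" for f in frames)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            st.render_cone_arc(make_mini_cfg(), n_frames=4)

    def test_zero_sag_frames_share_center(self):
        cfg = make_mini_cfg(noise_sd=0.0)
        frames = st.render_cone_arc(cfg, n_frames=8)
        centers = [st.field_center(f) for f in frames]
        xs = [c.x for c in centers]
        ys = [c.y for c in centers]
        assert np.ptp(xs) < 0.01 and np.ptp(ys) < 0.01
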