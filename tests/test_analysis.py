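"""Leaf localization, extremum refinement and tip measurement closed loops."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import stakitt as st
from stakitt.analysis import extremum_center, locate_leaves, measure_tips
from .conftest import make_mini_cfg


class TestExtremumCenter:
    def test_symmetric_triangular_trough(self):
        y = np.arange(0.0, 25.0, 0.1)
        v = np.abs(y - 12.7)
        c = extremum_center(y, v, (10.0, 15.0), kind="min")
        assert c == pytest.approx(12.7, abs=0.1)

    def test_gaussian_dip_center_vs_dense_scan(self):
        y = np.arange(0.0, 8.0, 0.02)
        v = 1.0 - 0.8 * np.exp(-((y - 3.456) / 0.9) ** 2)
        c = extremum_center(y, v, (2.0, 5.0), kind="min")
        # oracle: dense 1e-4 scan of the same analytic profile
        yy = np.arange(2.0, 5.0, 1e-4)
        oracle = yy[np.argmin(1.0 - 0.8 * np.exp(-((yy - 3.456) / 0.9) ** 2))]
        assert c == pytest.approx(oracle, abs=0.01)

    def test_monotone_profile_rejected(self):
        y = np.arange(0.0, 10.0, 0.1)
        with pytest.raises(ValueError, match="not located"):
            extremum_center(y, y * 2.0, (2.0, 8.0), kind="min")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(center=hst.floats(min_value=4.0, max_value=6.0),
           sigma=hst.floats(min_value=0.5, max_value=1.5),
           kind=hst.sampled_from(["min", "max"]))
    def test_gaussian_extremum_recovered(self, center, sigma, kind):
        y = np.arange(0.0, 10.0, 0.02)
        bump = np.exp(-((y - center) / sigma) ** 2)
        v = 1.0 - bump if kind == "min" else 1.0 + bump
        c = extremum_center(y, v, (3.0, 7.0), kind=kind)
        assert c == pytest.approx(center, abs=0.01)


class TestLocateLeaves:
    def test_anchor_positions_match_leaf_centers(self, mini_clean):
        plan, cfg, img, gt = mini_clean
        cax = st.ImagePoint(*gt.cax_panel_mm)
        trajs, log = locate_leaves(img, plan, cax=cax)
        assert len(trajs) == plan.mlc.n_leaf_pairs
        for t in trajs:
            expected = gt.cax_panel_mm[1] + plan.mlc.leaf_centers[t.leaf_index]
            assert t.left_anchor.y == pytest.approx(expected, abs=0.05)
            assert t.right_anchor.y == pytest.approx(expected, abs=0.05)

    def test_rotation_appears_as_trajectory_slope(self, mini_plan):
        cfg = make_mini_cfg(noise_sd=0.0, rotation_deg=0.5)
        img, gt = st.render_stakitt_image(mini_plan, cfg)
        trajs, _ = locate_leaves(img, mini_plan, cax=st.ImagePoint(*gt.cax_panel_mm))
        slopes = [t.slope for t in trajs]
        assert np.median(slopes) == pytest.approx(np.tan(np.deg2rad(0.5)), rel=0.05)

    def test_wrong_plan_fails_loudly(self, mini_noisy):
        plan, cfg, img, gt = mini_noisy
        shifted = st.build_default_plan(
            plan.mlc,
            stakitt_centers=plan.stakitt_centers,
            stakitt_width=plan.stakitt_width,
            comb_protrude_tip=30.0, comb_retract_tip=55.0,
            comb_column=40.0, comb_inner_bound=28.0,
        )
        with pytest.raises(ValueError):
            locate_leaves(img, shifted, cax=st.ImagePoint(*gt.cax_panel_mm))


class TestMeasureTips:
    def test_error_free_zero_noise_deviations_vanish(self, mini_clean):
        plan, cfg, img, gt = mini_clean
        cax = st.ImagePoint(*gt.cax_panel_mm)
        df, _ = st.analyze_image(img, plan, cax)
        assert len(df) == plan.mlc.n_leaf_pairs * 2 * plan.n_stakitts
        assert df["deviation_mm"].abs().max() < 0.01

    def test_crossing_matches_dense_scan_oracle(self, mini_clean):
        """Brent-refined 50% crossing vs brute-force 1e-4 mm scan."""
        plan, cfg, img, gt = mini_clean
        cax = st.ImagePoint(*gt.cax_panel_mm)
        trajs, _ = locate_leaves(img, plan, cax=cax)
        traj = next(t for t in trajs if t.leaf_index == 7)
        ms = measure_tips(img, traj, plan, cax)
        m = next(x for x in ms if x.bank == "A" and x.stakitt_index == 2)
        # oracle along the same leaf-center row
        y = gt.cax_panel_mm[1] + plan.mlc.leaf_centers[7]
        xs = np.arange(m.nominal_tip - 2, m.nominal_tip + 2, 1e-4) + cax.x
        v = img.value_at(xs, np.full_like(xs, y))
        level = 0.5 * (v.min() + v.max())
        f = v - level
        i = np.nonzero(np.diff(np.signbit(f)))[0][0]
        oracle = xs[i] - cax.x
        assert m.measured_tip == pytest.approx(oracle, abs=0.005)

    def test_injected_error_recovered(self, mini_plan):
        err = np.zeros((2, 16))
        err[0, 7] = -0.5
        cfg = make_mini_cfg(noise_sd=0.0, leaf_errors=err)
        img, gt = st.render_stakitt_image(mini_plan, cfg)
        df, _ = st.analyze_image(img, mini_plan, st.ImagePoint(*gt.cax_panel_mm))
        hit = df[(df.leaf == 7) & (df.bank == "A")]["deviation_mm"]
        rest = df[~((df.leaf == 7) & (df.bank == "A"))]["deviation_mm"]
        assert np.abs(hit - (-0.5)).max() < 0.03
        assert rest.abs().max() < 0.03

    def test_rotation_invariance(self, mini_plan, mini_clean):
        """Deviations agree within 0.02 mm between 0 and 0.5 deg rotation."""
        _, _, img0, gt0 = mini_clean
        df0, _ = st.analyze_image(img0, mini_plan, st.ImagePoint(*gt0.cax_panel_mm))
        cfg_r = make_mini_cfg(noise_sd=0.0, rotation_deg=0.5)
        img_r, gt_r = st.render_stakitt_image(mini_plan, cfg_r)
        df_r, _ = st.analyze_image(img_r, mini_plan, st.ImagePoint(*gt_r.cax_panel_mm))
        key = ["leaf", "bank", "stakitt"]
        merged = df0.set_index(key)[["deviation_mm"]].join(
            df_r.set_index(key)[["deviation_mm"]], rsuffix="_rot")
        delta = (merged["deviation_mm"] - merged["deviation_mm_rot"]).abs()
        assert delta.max() < 0.02

    def test_cax_shift_invariance(self, mini_plan, mini_clean):
        """Shifting the panel moves absolute tips but not deviations."""
        _, _, img0, gt0 = mini_clean
        df0, _ = st.analyze_image(img0, mini_plan, st.ImagePoint(*gt0.cax_panel_mm))
        cfg_s = make_mini_cfg(noise_sd=0.0, cax_offset=(2.0, 0.0))
        img_s, gt_s = st.render_stakitt_image(mini_plan, cfg_s)
        assert gt_s.cax_panel_mm[0] - gt0.cax_panel_mm[0] == pytest.approx(2.0)
        df_s, _ = st.analyze_image(img_s, mini_plan, st.ImagePoint(*gt_s.cax_panel_mm))
        key = ["leaf", "bank", "stakitt"]
        merged = df0.set_index(key).join(df_s.set_index(key), rsuffix="_s")
        assert (merged["deviation_mm"] - merged["deviation_mm_s"]).abs().max() < 0.01

    def test_rfo_correction_closed_loop(self, mini_plan):
        cfg = make_mini_cfg(noise_sd=0.0, rfo_true=(0.3, -0.2))
        img, gt = st.render_stakitt_image(mini_plan, cfg)
        cax = st.ImagePoint(*gt.cax_panel_mm)
        matched, _ = st.analyze_image(img, mini_plan, cax, rfo=(0.3, -0.2))
        assert matched["deviation_mm"].abs().max() < 0.01
        uncorrected, _ = st.analyze_image(img, mini_plan, cax, rfo=(0.0, 0.0))
        assert uncorrected.loc[uncorrected.bank == "A", "deviation_mm"].mean() == \
            pytest.approx(0.3, abs=0.02)
        assert uncorrected.loc[uncorrected.bank == "B", "deviation_mm"].mean() == \
            pytest.approx(-0.2, abs=0.02)

    def test_sensitivity_slope_is_unity(self, mini_plan):
        """Mean measured vs injected error over +/-1.5 mm has slope 1 +/- 0.03."""
        mags = (-1.5, -0.5, 0.5, 1.5)
        means = []
        for k, mag in enumerate(mags):
            err = np.zeros((2, 16))
            err[0, (3, 7, 11)] = mag
            cfg = make_mini_cfg(leaf_errors=err, seed=60 + k)
            img, gt = st.render_stakitt_image(mini_plan, cfg)
            df, _ = st.analyze_image(img, mini_plan, st.ImagePoint(*gt.cax_panel_mm))
            means.append(df[(df.bank == "A") & df.leaf.isin((3, 7, 11))]
                         ["deviation_mm"].mean())
        slope = np.polyfit(mags, means, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.03)
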