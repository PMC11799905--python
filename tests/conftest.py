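"""Shared fixtures: a compact MLC/plan/panel for fast closed-loop tests.

The compact geometry (16 leaf pairs of 5 mm on a 512x512 panel) keeps the
simulate -> analyze loop under a second while exercising the identical code
paths as the full clinical geometry used in the acceptance tests.
"""

import numpy as np
import pytest

import stakitt as st


def make_mini_mlc() -> st.MlcModel:
    return st.MlcModel("mini", (5.0,) * 16)


def make_mini_plan() -> st.StakittPlan:
    return st.build_default_plan(
        make_mini_mlc(),
        stakitt_centers=np.arange(-50.0, 51.0, 20.0),
        stakitt_width=10.0,
        comb_protrude_tip=64.0,
        comb_retract_tip=88.0,
        comb_column=75.0,
        comb_inner_bound=62.0,
        jaw_x=(-95.0, 95.0),
    )


def make_mini_cfg(**kwargs) -> st.SimConfig:
    kwargs.setdefault("panel_shape", (512, 512))
    return st.SimConfig(**kwargs)


@pytest.fixture(scope="session")
def mini_mlc():
    return make_mini_mlc()


@pytest.fixture(scope="session")
def mini_plan():
    return make_mini_plan()


@pytest.fixture(scope="session")
def mini_clean():
    """Zero-noise, error-free compact render with its ground truth."""
    plan = make_mini_plan()
    cfg = make_mini_cfg(noise_sd=0.0)
    img, gt = st.render_stakitt_image(plan, cfg)
    return plan, cfg, img, gt


@pytest.fixture(scope="session")
def mini_noisy():
    """Default-noise, error-free compact render."""
    plan = make_mini_plan()
    cfg = make_mini_cfg(seed=5)
    img, gt = st.render_stakitt_image(plan, cfg)
    return plan, cfg, img, gt


@pytest.fixture(scope="session")
def default_plan():
    return st.build_default_plan()


@pytest.fixture(scope="session")
def full_clean_image(default_plan):
    """Error-free full-geometry render at default noise, with ground truth."""
    cfg = st.SimConfig(seed=101)
    img, gt = st.render_stakitt_image(default_plan, cfg)
    return cfg, img, gt
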