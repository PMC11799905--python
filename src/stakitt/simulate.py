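"""Synthetic EPID image generation with known ground truth.

Every acquisition the analysis consumes can be rendered here: the 6-stakitt +
comb step-and-shoot delivery, the jaw-defined 10x10 cm C90/C270 pair used to
find the collimator rotation axis, and the cone-arc cine sequence used to map
gantry-dependent panel sag.

Physics model
-------------
Each collimated edge is rendered as an erf transition,
``edge(d) = 0.5 * (1 + erf(d / s))`` with ``d`` the signed distance (mm at
isocenter) into the open side and ``s = penumbra_sigma``.  A segment's
fluence is ``t + (1 - t) * open`` where ``t`` is the leaf/jaw transmission
pedestal and ``open`` is the jaw window minus the per-leaf block windows
(erf windows in both axes, which partition unity across shared leaf edges).
Additive Gaussian pixel noise is scaled to the open-field plateau.  No
scatter kernel is modeled: the analysis only consumes 50% crossings and
local extrema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import erf

from .image import EpidImage
from .mlc import StakittPlan, MlcModel

__all__ = [
    "SimConfig",
    "GroundTruth",
    "render_stakitt_image",
    "render_cax_pair",
    "render_cone_arc",
    "gravity_sign",
]


@dataclass
class SimConfig:
    """Simulator configuration; defaults are the nominal study conditions.

    Parameters
    ----------
    penumbra_sigma
        erf scale of each field edge, mm (80-20% width ~ 1.2 * sigma).
    noise_sd
        Additive Gaussian noise SD as a fraction of the open-field signal.
    transmission
        Leaf/jaw transmission pedestal as a fraction of open signal.
    rotation_deg
        Collimator-vs-panel rotation, applied about the beam axis.
    rfo_true
        Per-bank radiation field offset (mm, retraction-positive): the
        rendered 50% radiation edge sits at light-field tip +/- rfo.
    leaf_errors, backlash
        Optional (2, n_leaf_pairs) arrays: introduced tip errors
        (mm, + = retracted) and mechanical play per leaf.
    sag_amplitude
        (ax, ay) mm: panel sag dx = ax*sin(g), dy = ay*(1 - cos(g)).
    narrowing_slope
        mm of radiological leaf-width change per 100 mm of tip travel,
        applied to error-carrying leaves with alternating parity sign.
    cax_offset
        True beam-axis position relative to the panel center, mm.
    """

    penumbra_sigma: float = 1.2
    noise_sd: float = 0.005
    transmission: float = 0.015
    rotation_deg: float = 0.0
    rfo_true: tuple[float, float] = (0.0, 0.0)
    leaf_errors: np.ndarray | None = None
    backlash: np.ndarray | None = None
    sag_amplitude: tuple[float, float] = (0.0, 0.0)
    narrowing_slope: float = 0.0
    cax_offset: tuple[float, float] = (0.0, 0.0)
    panel_shape: tuple[int, int] = (1024, 1024)
    pixel_spacing: float = 0.39
    sdd: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.penumbra_sigma <= 0:
            raise ValueError("penumbra_sigma must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def sag_offset(self, gantry: float) -> tuple[float, float]:
        """Panel sag (dx, dy) mm at a gantry angle, zero at G0 by construction."""
        g = np.deg2rad(gantry)
        ax, ay = self.sag_amplitude
        return ax * np.sin(g), ay * (1.0 - np.cos(g))

    def leaf_error_array(self, n_leaves: int) -> np.ndarray:
        if self.leaf_errors is None:
            return np.zeros((2, n_leaves))
        arr = np.asarray(self.leaf_errors, dtype=float)
        if arr.shape != (2, n_leaves):
            raise ValueError(f"leaf_errors must have shape (2, {n_leaves})")
        return arr

    def backlash_array(self, n_leaves: int) -> np.ndarray:
        if self.backlash is None:
            return np.zeros((2, n_leaves))
        arr = np.asarray(self.backlash, dtype=float)
        if arr.shape != (2, n_leaves):
            raise ValueError(f"backlash must have shape (2, {n_leaves})")
        return arr

    def panel_center(self) -> tuple[float, float]:
        ny, nx = self.panel_shape
        s = self.pixel_spacing
        return (nx - 1) / 2 * s, (ny - 1) / 2 * s


@dataclass
class GroundTruth:
    """True geometry behind a rendered stakitt image.

    ``true_tip`` and ``true_deviation`` have shape (n_stakitts, 2, n_leaves);
    tips are mm relative to the true beam axis (beam frame, crossplane) and
    deviations follow the retraction-positive convention.  Deviations exclude
    the RFO, which the analyzer removes via its own RFO parameter.
    """

    true_tip: np.ndarray
    true_deviation: np.ndarray
    cax_panel_mm: tuple[float, float]
    rfo: tuple[float, float]
    gantry_angle: float

    def to_json(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(
                {
                    "true_tip": self.true_tip.tolist(),
                    "true_deviation": self.true_deviation.tolist(),
                    "cax_panel_mm": list(self.cax_panel_mm),
                    "rfo": list(self.rfo),
                    "gantry_angle": self.gantry_angle,
                },
                fh,
            )
        return path

    @staticmethod
    def from_json(path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return GroundTruth(
            np.asarray(d["true_tip"]),
            np.asarray(d["true_deviation"]),
            tuple(d["cax_panel_mm"]),
            tuple(d["rfo"]),
            float(d["gantry_angle"]),
        )


def _edge(d, s):
    """Open fraction across an erf edge: 0 deep in the block, 1 in the open."""
    return 0.5 * (1.0 + erf(np.asarray(d) / s))


def gravity_sign(gantry: float) -> int:
    """Sign of the gravity projection onto bank A's retraction direction.

    +1 when the gantry is on the 0-180 side (bank A retracts, bank B
    extends), -1 on the 180-360 side, 0 at G0/G180 where gravity is
    perpendicular to leaf travel.
    """
    s = np.sin(np.deg2rad(gantry % 360.0))
    if abs(s) < 1e-9:
        return 0
    return 1 if s > 0 else -1


# ---------------------------------------------------------------------------
# segment renderer
# ---------------------------------------------------------------------------

class _Frame:
    """Panel <-> beam frame transform for one acquisition."""

    def __init__(self, cfg: SimConfig, beam_center: tuple[float, float]):
        ny, nx = cfg.panel_shape
        self.x_cols = np.arange(nx) * cfg.pixel_spacing
        self.y_rows = np.arange(ny) * cfg.pixel_spacing
        self.cx, self.cy = beam_center
        th = np.deg2rad(cfg.rotation_deg)
        self.cos, self.sin = np.cos(th), np.sin(th)
        self.sigma = cfg.penumbra_sigma

    def beam_coords(self, rows: slice):
        """Beam-frame (xb, yb) 2D arrays for the given row slab x all columns."""
        dx = self.x_cols[None, :] - self.cx
        dy = (self.y_rows[rows] - self.cy)[:, None]
        xb = self.cos * dx + self.sin * dy
        yb = -self.sin * dx + self.cos * dy
        return xb, yb

    def row_slab(self, y0: float, y1: float, pad: float) -> slice:
        """Panel rows covering beam-frame inplane interval [y0, y1] +/- pad."""
        # small-angle: panel y of beam (x, y) within |x| <= max extent
        extra = abs(self.sin) * (self.x_cols[-1] - self.cx) + pad
        lo = self.cy + y0 - extra
        hi = self.cy + y1 + extra
        sp = self.y_rows[1] - self.y_rows[0]
        i0 = max(0, int(np.floor(lo / sp)))
        i1 = min(len(self.y_rows), int(np.ceil(hi / sp)) + 1)
        return slice(i0, i1)


def _segment_fluence(
    frame: _Frame,
    jaw: tuple[float, float, float, float],
    blocks: list[dict],
) -> np.ndarray:
    """Open-field fraction of one step-and-shoot segment on the full panel.

    ``blocks`` entries: dict(side=+1|-1 (blocked for side*(x - tip) > 0),
    tip=float, e0=float, e1=float, narrow=None | (slope_per_mm, x0, sign)).
    """
    s = frame.sigma
    xb, yb = frame.beam_coords(slice(None))
    x0, x1, y0, y1 = jaw
    open_field = (
        (_edge(xb - x0, s) - _edge(xb - x1, s))
        * (_edge(yb - y0, s) - _edge(yb - y1, s))
    )
    for blk in blocks:
        e0, e1 = blk["e0"], blk["e1"]
        slab = frame.row_slab(e0, e1, pad=6 * s)
        xs, ys = frame.beam_coords(slab)
        if blk["side"] > 0:
            bx = _edge(xs - blk["tip"], s)  # blocked right of tip
        else:
            bx = _edge(blk["tip"] - xs, s)  # blocked left of tip
        narrow = blk.get("narrow")
        if narrow is not None:
            # apparent width change acts where the leaf tip defines the edge
            # (beam divergence through the stepped tip profile); it fades out
            # a few mm behind the tip so the leaf body stays flush with its
            # neighbours and no spurious interleaf leak appears.
            slope, xref, sign = narrow
            width = e1 - e0
            depth = (blk["tip"] - xs) if blk["side"] < 0 else (xs - blk["tip"])
            taper = np.clip(1.0 - (depth - 2.0) / 4.0, 0.0, 1.0)
            d = sign * slope * (xs - xref) / 100.0 * taper
            d = np.clip(d, -width, 0.9 * width)
            lo, hi = e0 + d / 2.0, e1 - d / 2.0
        else:
            lo, hi = e0, e1
        by = _edge(ys - lo, s) - _edge(ys - hi, s)
        open_field[slab] -= bx * by
    return np.clip(open_field, 0.0, None)


def _assemble(cfg: SimConfig, segments_open: list[np.ndarray], rng) -> np.ndarray:
    t = cfg.transmission
    total = np.zeros(cfg.panel_shape)
    for op in segments_open:
        total += t + (1.0 - t) * op
    plateau = (1.0 - t) + len(segments_open) * t
    if cfg.noise_sd > 0:
        total = total + rng.normal(0.0, cfg.noise_sd * plateau, size=total.shape)
    return np.clip(total, 0.0, None)


# ---------------------------------------------------------------------------
# stakitt delivery
# ---------------------------------------------------------------------------

def render_stakitt_image(
    plan: StakittPlan,
    cfg: SimConfig,
    gantry: float = 0.0,
    mlc: MlcModel | None = None,
    seed: int | None = None,
) -> tuple[EpidImage, GroundTruth]:
    """Render the integrated stakitt delivery image at a gantry angle.

    The true tip of each leaf is the plan's nominal (light-field) tip moved
    by ``leaf_error + rfo_true + gravity_sign * backlash / 2`` in the bank's
    retraction direction.  Returns the image plus the ground truth (tips and
    deviations relative to the true beam axis).
    """
    if mlc is not None and mlc != plan.mlc:
        raise ValueError("plan and mlc are inconsistent")
    mlc = plan.mlc
    n_leaves = mlc.n_leaf_pairs
    edges = mlc.leaf_edges

    pcx, pcy = cfg.panel_center()
    sag = cfg.sag_offset(gantry)
    beam_center = (pcx + cfg.cax_offset[0] + sag[0], pcy + cfg.cax_offset[1] + sag[1])
    frame = _Frame(cfg, beam_center)

    half_x = min(beam_center[0], 2 * pcx - beam_center[0])
    if plan.comb_retract_tip > half_x - 2 * cfg.penumbra_sigma:
        raise ValueError("comb leaves fall outside the panel")

    leaf_err = cfg.leaf_error_array(n_leaves)
    backlash = cfg.backlash_array(n_leaves)
    gsign = gravity_sign(gantry)
    grav = np.vstack([gsign * backlash[0] / 2.0, -gsign * backlash[1] / 2.0])
    dev_true_bank = leaf_err + grav  # (2, L), retraction-positive, excludes RFO
    r_total = dev_true_bank + np.asarray(cfg.rfo_true)[:, None]

    n_st = plan.n_stakitts
    true_tip = np.empty((n_st, 2, n_leaves))
    true_tip[:, 0, :] = plan.nominal_tips[:, 0, :] - r_total[0]
    true_tip[:, 1, :] = plan.nominal_tips[:, 1, :] + r_total[1]
    true_dev = np.broadcast_to(dev_true_bank, (n_st, 2, n_leaves)).copy()

    x_travel_min = float(np.min(plan.nominal_tips))

    def narrow_for(bank: int, leaf: int):
        if cfg.narrowing_slope == 0.0 or leaf_err[bank, leaf] == 0.0:
            return None
        sign = 1.0 if leaf % 2 == 0 else -1.0
        return (cfg.narrowing_slope, x_travel_min, sign)

    y_lo, y_hi = edges[0], edges[-1]
    jaw_x0, jaw_x1 = plan.jaw_x
    segments = []

    # six stakitt sub-fields
    for st in range(n_st):
        blocks = []
        for leaf in range(n_leaves):
            e0, e1 = edges[leaf], edges[leaf + 1]
            blocks.append(
                dict(side=-1, tip=true_tip[st, 0, leaf], e0=e0, e1=e1,
                     narrow=narrow_for(0, leaf))
            )
            blocks.append(
                dict(side=+1, tip=true_tip[st, 1, leaf], e0=e0, e1=e1,
                     narrow=narrow_for(1, leaf))
            )
        segments.append(
            _segment_fluence(frame, (jaw_x0, jaw_x1, y_lo, y_hi), blocks)
        )

    # comb sub-fields: left comb formed by bank A, right comb by bank B
    for side, bank in (("left", 0), ("right", 1)):
        sgn = plan.comb_sign(side)
        tips = plan.comb_tips(side)
        tips = tips - sgn * r_total[bank]  # gravity/errors act on comb leaves too
        inner = sgn * plan.comb_inner_bound
        outer = sgn * (plan.comb_retract_tip + 10.0)
        jaw = (min(inner, outer), max(inner, outer), y_lo, y_hi)
        blocks = [
            dict(side=int(sgn), tip=tips[leaf], e0=edges[leaf], e1=edges[leaf + 1],
                 narrow=narrow_for(bank, leaf))
            for leaf in range(n_leaves)
        ]
        segments.append(_segment_fluence(frame, jaw, blocks))

    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    pixels = _assemble(cfg, segments, rng)
    img = EpidImage(
        pixels=pixels,
        pixel_spacing=cfg.pixel_spacing,
        sdd=cfg.sdd,
        gantry_angle=gantry,
        collimator_angle=cfg.rotation_deg % 360.0,
        acquisition_mode="integrated",
    )
    gt = GroundTruth(
        true_tip=true_tip,
        true_deviation=true_dev,
        cax_panel_mm=beam_center,
        rfo=tuple(cfg.rfo_true),
        gantry_angle=gantry % 360.0,
    )
    return img, gt


# ---------------------------------------------------------------------------
# CAX pair and cone arc
# ---------------------------------------------------------------------------

def render_cax_pair(
    cfg: SimConfig,
    offset: tuple[float, float] = (0.0, 0.0),
    jaw_asym: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0),
    field_size: float = 100.0,
    seed: int | None = None,
) -> tuple[EpidImage, EpidImage]:
    """Jaw-defined square fields at collimator 90 and 270, gantry 0.

    ``offset`` is the collimator-rotation-axis projection relative to the
    panel center.  ``jaw_asym`` shifts the four jaws in the collimator frame
    (x1, x2, y1, y2); under the 180 degree rotation between C90 and C270 any
    asymmetry flips sign on the panel, so the average of the two field
    centers recovers the axis.
    """
    pcx, pcy = cfg.panel_center()
    c = (pcx + offset[0], pcy + offset[1])
    h = field_size / 2.0
    a1, a2, b1, b2 = jaw_asym
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    images = []
    for col_angle in (90.0, 270.0):
        th = np.deg2rad(col_angle + cfg.rotation_deg)
        cos, sin = np.cos(th), np.sin(th)
        frame = _Frame(cfg, c)
        frame.cos, frame.sin = cos, sin
        open_field = _segment_fluence(
            frame, (-h + a1, h + a2, -h + b1, h + b2), []
        )
        pixels = _assemble(cfg, [open_field], rng)
        images.append(
            EpidImage(
                pixels=pixels,
                pixel_spacing=cfg.pixel_spacing,
                sdd=cfg.sdd,
                gantry_angle=0.0,
                collimator_angle=col_angle,
                acquisition_mode="integrated",
            )
        )
    return images[0], images[1]


def render_cone_arc(
    cfg: SimConfig,
    n_frames: int = 48,
    cone_radius: float = 15.0,
    seed: int | None = None,
) -> list[EpidImage]:
    """Cine frames of a circular cone field over a full 360 degree arc.

    Each frame's cone center follows the configured sag model; frames are
    tagged with their gantry angle and returned in delivery order starting
    at G0.
    """
    if n_frames < 8:
        raise ValueError("need at least 8 frames to map a full arc")
    pcx, pcy = cfg.panel_center()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    s = cfg.penumbra_sigma
    xs = np.arange(cfg.panel_shape[1]) * cfg.pixel_spacing
    ys = np.arange(cfg.panel_shape[0]) * cfg.pixel_spacing
    frames = []
    for gantry in np.linspace(0.0, 360.0, n_frames, endpoint=False):
        sag = cfg.sag_offset(gantry)
        cx = pcx + cfg.cax_offset[0] + sag[0]
        cy = pcy + cfg.cax_offset[1] + sag[1]
        rho = np.hypot(xs[None, :] - cx, ys[:, None] - cy)
        open_field = _edge(cone_radius - rho, s)
        pixels = _assemble(cfg, [open_field], rng)
        frames.append(
            EpidImage(
                pixels=pixels,
                pixel_spacing=cfg.pixel_spacing,
                sdd=cfg.sdd,
                gantry_angle=gantry,
                collimator_angle=0.0,
                acquisition_mode="cine_frame",
            )
        )
    return frames
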