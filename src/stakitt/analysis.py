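"""Per-leaf localization and tip measurement on the stakitt image.

The comb patterns at both image edges expose every leaf as a peak (retracted)
or trough (protruding) on a vertical sub-pixel profile.  Matching extrema on
the two sides define each leaf's trajectory, which corrects for collimator /
panel rotation; leaf tips are then the 50% penumbra crossings of the profile
along the trajectory, referenced to the (sag-corrected) beam central axis and
corrected for the EPID radiation field offset (RFO).

Sign convention: deviations are retraction-positive — a positive deviation
means the leaf is retracted away from the gap (gap expansion), negative means
it extends into the gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .image import EpidImage, ImagePoint
from .mlc import StakittPlan

__all__ = [
    "LeafTrajectory",
    "LeafMeasurement",
    "locate_leaves",
    "extremum_center",
    "measure_tips",
    "estimate_noise",
]

#: tip search half-window around the nominal tip, mm
TIP_SEARCH_HALF = 3.0
#: shielded (local-minimum) window relative to the nominal edge, mm
MIN_WINDOW = (2.0, 10.0)
#: margin inside the stakitt for the local-maximum window, mm from each edge
MAX_WINDOW_MARGIN = 4.0
#: leaf-localization window as a fraction of the leaf width
LOCATE_WINDOW_FRACTION = 0.4
#: tip profiles are averaged over parallel lines spanning this leaf-width fraction
BAND_FRACTION = 0.1
N_PROFILE_LINES = 5


@dataclass(frozen=True)
class LeafTrajectory:
    """Line joining one leaf's comb centers on the two sides of the image."""

    leaf_index: int
    left_anchor: ImagePoint
    right_anchor: ImagePoint

    @property
    def direction(self) -> np.ndarray:
        d = self.right_anchor.as_array() - self.left_anchor.as_array()
        return d / np.hypot(*d)

    @property
    def slope(self) -> float:
        d = self.right_anchor.as_array() - self.left_anchor.as_array()
        return d[1] / d[0]


@dataclass
class LeafMeasurement:
    leaf_index: int
    bank: str  # "A" or "B"
    stakitt_index: int  # 1-based
    measured_tip: float  # mm crossplane from CAX
    nominal_tip: float
    deviation: float  # retraction-positive, RFO-corrected
    flags: tuple[str, ...] = ()


def extremum_center(
    positions: np.ndarray,
    values: np.ndarray,
    window: tuple[float, float],
    kind: str = "min",
) -> float:
    """Sub-sample position of the extremum of a profile inside a window.

    The discrete extremum is refined with a parabola through its neighbours.
    Raises ``ValueError`` when the extremum sits on the window boundary
    (monotone profile: the feature is not located).
    """
    lo, hi = window
    mask = (positions >= lo) & (positions <= hi)
    if mask.sum() < 3:
        raise ValueError("window too small for extremum search")
    pos = positions[mask]
    val = values[mask]
    i = int(np.argmin(val) if kind == "min" else np.argmax(val))
    if i == 0 or i == len(val) - 1:
        raise ValueError("extremum on window boundary: not located")
    y0, y1, y2 = val[i - 1], val[i], val[i + 1]
    denom = y0 - 2 * y1 + y2
    step = pos[i + 1] - pos[i]
    delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    return float(pos[i] + np.clip(delta, -1, 1) * step)


def estimate_noise(img: EpidImage) -> float:
    """Robust pixel-noise SD from first differences along (subsampled) rows."""
    d = np.diff(img.pixels[::4], axis=1).ravel()
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


# ---------------------------------------------------------------------------
# comb localization
# ---------------------------------------------------------------------------

def _comb_profile(img: EpidImage, x_col: float, y_grid: np.ndarray) -> np.ndarray:
    return img.value_at(np.full_like(y_grid, x_col), y_grid)


def _matched_filter(profile: np.ndarray, step: float, width: float) -> np.ndarray:
    """Convolve the comb profile with a box of one leaf width.

    Each comb tooth is a plateau as wide as its leaf; its extremum position
    is noise-dominated on the flat top.  Convolving with the tooth's own
    width (a matched filter) turns every tooth into a triangle whose apex is
    exactly the tooth center, so the extremum is sharp and symmetric-kernel
    smoothing cannot bias it.
    """
    n = max(3, int(round(width / step)) | 1)  # odd length
    kernel = np.full(n, 1.0 / n)
    return np.convolve(profile, kernel, mode="same")


def _template_shift(
    y: np.ndarray, profile: np.ndarray, plan: StakittPlan, side: str,
    y_center: float, max_shift: float = 3.0,
) -> float:
    """Global inplane shift of a comb pattern vs its nominal layout.

    Cross-correlates the measured comb profile with an analytic template of
    the retracted-leaf open windows; absorbs CAX offset and the bulk of any
    collimator/panel rotation at the comb column.
    """
    from scipy.special import erf

    edges = plan.mlc.leaf_edges
    retracted = ~plan.comb_protrudes(side)
    s = 1.0  # template edge scale, mm; only the correlation peak matters

    def template(yy):
        acc = np.zeros_like(yy)
        for k in np.nonzero(retracted)[0]:
            e0, e1 = edges[k] + y_center, edges[k + 1] + y_center
            acc += 0.5 * (erf((yy - e0) / s) - erf((yy - e1) / s))
        return acc

    step = y[1] - y[0]
    n_lag = int(round(max_shift / step))
    lags = np.arange(-n_lag, n_lag + 1) * step
    # template evaluated once on an extended grid, then slid by index
    y_ext = np.arange(y[0] - n_lag * step, y[-1] + (n_lag + 0.5) * step, step)
    t_ext = template(y_ext)
    p = profile - profile.mean()
    n = len(y)
    scores = np.empty(len(lags))
    for i in range(len(lags)):
        # template shifted by +lag equals the extended template sampled earlier
        t = t_ext[2 * n_lag - i: 2 * n_lag - i + n]
        scores[i] = float(np.dot(p, t - t.mean()))
    best = int(np.argmax(scores))
    if 0 < best < len(lags) - 1:
        y0, y1, y2 = scores[best - 1], scores[best], scores[best + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            best_lag = lags[best] + np.clip(0.5 * (y0 - y2) / denom, -1, 1) * step
            return float(best_lag)
    return float(lags[best])


def locate_leaves(
    img: EpidImage,
    plan: StakittPlan,
    cax: ImagePoint | None = None,
    step: float = 0.02,
) -> tuple[list[LeafTrajectory], list[str]]:
    """Locate individual leaves from the two comb patterns.

    Per side, a vertical sub-pixel profile is taken at the comb measurement
    column; protruding-leaf centers are trough extrema and retracted-leaf
    centers are peak extrema, each sought inside a window centered on the
    nominal leaf interval (after estimating the comb's global inplane shift).
    Returns the trajectories of leaves located on both sides, plus a log of
    exclusions.  More than 20% unlocated leaves is a hard error.
    """
    mlc = plan.mlc
    center = img.center if cax is None else cax
    log: list[str] = []
    side_results: dict[str, dict[int, float]] = {}

    for side in ("left", "right"):
        x_col = center.x + plan.comb_sign(side) * plan.comb_column
        if not (0 <= x_col <= img.x_mm[-1]):
            raise ValueError(f"comb column for side {side!r} is outside the image")
        edges = mlc.leaf_edges
        margin = 2.0 + max(mlc.leaf_widths)
        y_lo = max(img.y_mm[0] + 0.5, center.y + edges[0] - margin)
        y_hi = min(img.y_mm[-1] - 0.5, center.y + edges[-1] + margin)
        y = np.arange(y_lo, y_hi, step)
        profile = _comb_profile(img, x_col, y)
        shift = _template_shift(y, profile, plan, side, center.y)
        protrudes = plan.comb_protrudes(side)

        centers: dict[int, float] = {}
        widths = np.asarray(mlc.leaf_widths)
        # a genuine comb tooth modulates the profile by a sizable fraction of
        # the image's dynamic range; a flat window holds only noise extrema
        span = np.percentile(img.pixels[::4, ::4], [0.5, 99.5])
        min_contrast = 0.05 * float(span[1] - span[0])
        for width in np.unique(widths):
            filtered = _matched_filter(profile, step, float(width))
            for leaf in np.nonzero(widths == width)[0]:
                half = LOCATE_WINDOW_FRACTION * width
                c_nom = center.y + mlc.leaf_centers[leaf] + shift
                lo, hi = c_nom - half, c_nom + half
                if lo < y[0] + width / 2 or hi > y[-1] - width / 2:
                    log.append(f"leaf {leaf} side {side}: window outside image")
                    continue
                kind = "min" if protrudes[leaf] else "max"
                window_vals = filtered[(y >= lo) & (y <= hi)]
                if len(window_vals) and np.ptp(window_vals) < min_contrast:
                    log.append(f"leaf {leaf} side {side}: no comb contrast")
                    continue
                try:
                    centers[leaf] = extremum_center(y, filtered, (lo, hi), kind)
                except ValueError:
                    log.append(f"leaf {leaf} side {side}: not located")
        side_results[side] = {"x": x_col, "centers": centers}

    trajectories = []
    left, right = side_results["left"], side_results["right"]
    both = [leaf for leaf in range(mlc.n_leaf_pairs)
            if leaf in left["centers"] and leaf in right["centers"]]
    for leaf in both:
        trajectories.append(
            LeafTrajectory(
                leaf_index=leaf,
                left_anchor=ImagePoint(left["x"], left["centers"][leaf]),
                right_anchor=ImagePoint(right["x"], right["centers"][leaf]),
            )
        )
    # a protruding tooth at the very end of a comb has no outer flank and is
    # not locatable there; rebuild its trajectory from the located side plus
    # the rigid rotation slope of the fully located leaves
    if trajectories:
        slope = float(np.median([t.slope for t in trajectories]))
        span = right["x"] - left["x"]
        for leaf in range(mlc.n_leaf_pairs):
            if leaf in both:
                continue
            if leaf in left["centers"]:
                y0 = left["centers"][leaf]
                traj = LeafTrajectory(leaf, ImagePoint(left["x"], y0),
                                      ImagePoint(right["x"], y0 + slope * span))
            elif leaf in right["centers"]:
                y1 = right["centers"][leaf]
                traj = LeafTrajectory(leaf, ImagePoint(left["x"], y1 - slope * span),
                                      ImagePoint(right["x"], y1))
            else:
                continue
            log.append(f"leaf {leaf}: anchored on one comb only")
            trajectories.append(traj)
        trajectories.sort(key=lambda t: t.leaf_index)
    if len(trajectories) < 0.8 * mlc.n_leaf_pairs:
        raise ValueError(
            f"only {len(trajectories)}/{mlc.n_leaf_pairs} leaves located; "
            "check plan/image consistency"
        )
    return trajectories, log


# ---------------------------------------------------------------------------
# tip measurement
# ---------------------------------------------------------------------------

def _stakitt_windows(plan: StakittPlan, stakitt: int, leaf: int):
    """Nominal max/min/search windows for one stakitt, beam-frame mm."""
    tip_a = plan.nominal_tips[stakitt, 0, leaf]
    tip_b = plan.nominal_tips[stakitt, 1, leaf]
    margin = min(MAX_WINDOW_MARGIN, plan.stakitt_width * 0.45)
    max_win = (tip_a + margin, tip_b - margin)
    min_a = (tip_a - MIN_WINDOW[1], tip_a - MIN_WINDOW[0])
    min_b = (tip_b + MIN_WINDOW[0], tip_b + MIN_WINDOW[1])
    return tip_a, tip_b, max_win, min_a, min_b


def measure_tips(
    img: EpidImage,
    traj: LeafTrajectory,
    plan: StakittPlan,
    cax: ImagePoint,
    rfo: tuple[float, float] = (0.0, 0.0),
    noise_sd: float | None = None,
    step: float = 0.02,
    direction: np.ndarray | None = None,
) -> list[LeafMeasurement]:
    """Measure both banks' tip positions for one leaf in every stakitt.

    The profile is sampled along the leaf trajectory (averaged over a narrow
    band of parallel lines inside the leaf) and parameterized by the beam-
    frame crossplane coordinate relative to ``cax``.  Per stakitt edge the
    50% level is ``local_min + 0.5 * (local_max - local_min)`` with the local
    maximum from the stakitt's open window and the local minimum from the
    adjacent shielded window; the crossing is refined by inverse
    interpolation (Brent) and corrected for the per-bank RFO.

    ``direction`` overrides the crossplane unit vector used to parameterize
    the beam frame (normally the collimator rotation estimated over *all*
    trajectories); anchor noise on one leaf then cannot leak into its
    crossplane coordinate in proportion to its inplane offset.
    """
    leaf = traj.leaf_index
    u = traj.direction if direction is None else np.asarray(direction, dtype=float)
    u = u / np.hypot(*u)
    n_vec = np.array([-u[1], u[0]])
    a = traj.left_anchor.as_array()
    c = cax.as_array()
    # point on the leaf's own line whose beam-frame crossplane coordinate is 0
    v = traj.direction
    p0 = a - (np.dot(a - c, u) / np.dot(v, u)) * v

    width = plan.mlc.leaf_widths[leaf]
    offsets = np.linspace(-BAND_FRACTION, BAND_FRACTION, N_PROFILE_LINES) * width

    if noise_sd is None:
        noise_sd = estimate_noise(img)

    def band_value(xq: np.ndarray) -> np.ndarray:
        """Mean signal over the parallel-line band at beam-frame positions xq."""
        pts = p0[None, None, :] + np.asarray(xq)[:, None, None] * u + \
            offsets[None, :, None] * n_vec
        vals = img.value_at(pts[..., 0], pts[..., 1])
        return vals.mean(axis=1)

    results: list[LeafMeasurement] = []
    for st in range(plan.n_stakitts):
        tip_a, tip_b, max_win, min_a, min_b = _stakitt_windows(plan, st, leaf)
        xs = np.arange(tip_a - MIN_WINDOW[1] - 1.0, tip_b + MIN_WINDOW[1] + 1.0, step)
        # visibility: the whole sampled band must stay inside the panel
        ends = np.array([p0 + xs[0] * u, p0 + xs[-1] * u])
        band = np.abs(offsets).max()
        if not all(
            img.contains(px, py)
            for px, py in np.vstack([ends - band, ends + band])
        ):
            continue
        prof = band_value(xs)
        local_max = float(prof[(xs >= max_win[0]) & (xs <= max_win[1])].max())
        for bank, nominal, min_win in ((0, tip_a, min_a), (1, tip_b, min_b)):
            flags: list[str] = []
            sel = (xs >= min_win[0]) & (xs <= min_win[1])
            local_min = float(prof[sel].min())
            contrast = local_max - local_min
            if noise_sd > 0 and contrast < 10.0 * noise_sd:
                flags.append("low contrast")
            level = local_min + 0.5 * contrast
            sel_s = (xs >= nominal - TIP_SEARCH_HALF) & (xs <= nominal + TIP_SEARCH_HALF)
            xw, fw = xs[sel_s], prof[sel_s] - level
            idx = np.nonzero(np.diff(np.signbit(fw)))[0]
            if len(idx) == 0:
                results.append(
                    LeafMeasurement(leaf, "AB"[bank], st + 1, np.nan, nominal,
                                    np.nan, ("edge not found",))
                )
                continue
            if len(idx) > 1:
                flags.append("multiple crossings")
            mids = 0.5 * (xw[idx] + xw[idx + 1])
            i = idx[int(np.argmin(np.abs(mids - nominal)))]
            root = brentq(
                lambda xq: float(band_value(np.array([xq]))[0]) - level,
                xw[i], xw[i + 1], xtol=1e-7,
            )
            dev_raw = (nominal - root) if bank == 0 else (root - nominal)
            dev = dev_raw - rfo[bank]
            if abs(dev) >= 5.0:
                flags.append("out of range")
            results.append(
                LeafMeasurement(leaf, "AB"[bank], st + 1, float(root), float(nominal),
                                float(dev), tuple(flags))
            )
    return results
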