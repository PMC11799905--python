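"""Beam central axis determination and gantry-sag correction.

The projection of the collimator rotation axis onto the panel is the
absolute spatial reference for all leaf positions.  It is found from a pair
of jaw-defined square fields at collimator 90 and 270: any jaw asymmetry
flips sign under the 180 degree rotation, so the average of the two field
centers is the axis.  Because the panel sags with gantry angle, a sag map
measured from cone-arc cine frames translates the G0 axis to other angles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .image import EpidImage, ImagePoint

__all__ = [
    "BeamCax",
    "SagMap",
    "field_center",
    "compute_cax",
    "build_sag_map",
    "cax_at_gantry",
]


@dataclass(frozen=True)
class BeamCax:
    """Collimator-axis projection at gantry 0, raw image frame mm."""

    position: ImagePoint
    source_images: tuple[str, str] = ("C90", "C270")


def _profile_crossings(pos: np.ndarray, vals: np.ndarray, spline_eval) -> list[float]:
    """All 50% crossings of a sampled profile, refined with brentq.

    The level is the midpoint of the profile's plateau maximum and
    out-of-field minimum; ``spline_eval`` maps position -> interpolated value
    for sub-pixel refinement.
    """
    level = 0.5 * (vals.max() + vals.min())
    f = vals - level
    idx = np.nonzero(np.diff(np.signbit(f)))[0]
    roots = []
    for i in idx:
        roots.append(
            brentq(lambda p: spline_eval(p) - level, pos[i], pos[i + 1], xtol=1e-6)
        )
    return roots


def field_center(img: EpidImage, step: float = 0.05) -> ImagePoint:
    """Sub-pixel center of a single rectangular or circular field.

    The midpoint between the two 50% penumbra crossings is taken on the
    central crossplane profile (x) and the central inplane profile (y),
    interpolated with the image's cubic spline.
    """
    cx, cy = img.center.x, img.center.y
    margin = 2 * img.pixel_spacing

    xs = np.arange(margin, img.x_mm[-1] - margin, step)
    vx = img.value_at(xs, np.full_like(xs, cy))
    roots_x = _profile_crossings(xs, vx, lambda p: float(img.value_at(p, cy)))
    if len(roots_x) != 2:
        raise ValueError(
            f"ambiguous field edges: {len(roots_x)} 50% crossings on the crossplane profile"
        )

    ys = np.arange(margin, img.y_mm[-1] - margin, step)
    vy = img.value_at(np.full_like(ys, roots_x_mid := np.mean(roots_x)), ys)
    roots_y = _profile_crossings(ys, vy, lambda p: float(img.value_at(roots_x_mid, p)))
    if len(roots_y) != 2:
        raise ValueError(
            f"ambiguous field edges: {len(roots_y)} 50% crossings on the inplane profile"
        )
    # second pass on x at the measured y center (helps circular fields)
    y_mid = float(np.mean(roots_y))
    vx2 = img.value_at(xs, np.full_like(xs, y_mid))
    roots_x2 = _profile_crossings(xs, vx2, lambda p: float(img.value_at(p, y_mid)))
    if len(roots_x2) == 2:
        roots_x = roots_x2
    return ImagePoint(float(np.mean(roots_x)), y_mid)


def compute_cax(img_c90: EpidImage, img_c270: EpidImage) -> BeamCax:
    """Average of the C90 and C270 field centers = collimator axis at G0."""
    angles = sorted((round(img_c90.collimator_angle), round(img_c270.collimator_angle)))
    if angles != [90, 270]:
        raise ValueError(
            f"expected collimator angles 90 and 270, got {angles}"
        )
    if abs(img_c90.sdd - img_c270.sdd) > 1e-6:
        raise ValueError("C90/C270 images have different SDD")
    for img in (img_c90, img_c270):
        if img.gantry_angle % 360.0 not in (0.0,):
            warnings.warn(
                "CAX images are normally acquired at gantry 0", stacklevel=2
            )
    c1 = field_center(img_c90)
    c2 = field_center(img_c270)
    return BeamCax(
        position=ImagePoint(0.5 * (c1.x + c2.x), 0.5 * (c1.y + c2.y)),
        source_images=("C90", "C270"),
    )


@dataclass
class SagMap:
    """Gantry angle -> (dx, dy) mm panel-sag offsets relative to G0."""

    angles: np.ndarray
    offsets: np.ndarray  # (n, 2)

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float) % 360.0
        self.offsets = np.asarray(self.offsets, dtype=float)
        order = np.argsort(self.angles)
        self.angles = self.angles[order]
        self.offsets = self.offsets[order]

    @property
    def full_circle(self) -> bool:
        """True when the wrap-around gap is no larger than a cardinal step."""
        return (360.0 - float(self.angles.max() - self.angles.min())) <= 120.0

    def at(self, gantry: float) -> tuple[float, float]:
        """Linear interpolation in angle; wraps when the map spans the circle."""
        g = float(gantry) % 360.0
        ang, off = self.angles, self.offsets
        if self.full_circle:
            ang = np.concatenate([ang, [ang[0] + 360.0]])
            off = np.vstack([off, off[:1]])
            if g < ang[0]:
                g += 360.0
        elif not (ang[0] - 1e-9 <= g <= ang[-1] + 1e-9):
            raise ValueError(
                f"gantry {g:.1f} outside sag-map coverage "
                f"[{ang[0]:.1f}, {ang[-1]:.1f}]"
            )
        dx = float(np.interp(g, ang, off[:, 0]))
        dy = float(np.interp(g, ang, off[:, 1]))
        return dx, dy

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"gantry_angle": self.angles, "dx_mm": self.offsets[:, 0],
             "dy_mm": self.offsets[:, 1]}
        ).to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "SagMap":
        df = pd.read_csv(path)
        return SagMap(
            df["gantry_angle"].to_numpy(), df[["dx_mm", "dy_mm"]].to_numpy()
        )


def build_sag_map(frames: list[EpidImage]) -> SagMap:
    """Cone centers per cine frame, normalized to the frame nearest G0.

    Requires at least 8 gantry-tagged frames, one of them within 5 degrees of
    G0 (the offset there is identically (0, 0) by construction).
    """
    if len(frames) < 8:
        raise ValueError("need at least 8 cine frames to build a sag map")
    angles = np.array([f.gantry_angle for f in frames])
    dist0 = np.minimum(angles % 360.0, 360.0 - angles % 360.0)
    ref = int(np.argmin(dist0))
    if dist0[ref] > 5.0:
        raise ValueError("no cine frame within 5 degrees of gantry 0")
    centers = np.array([[p.x, p.y] for p in (field_center(f) for f in frames)])
    offsets = centers - centers[ref]
    return SagMap(angles, offsets)


def cax_at_gantry(cax: BeamCax, sag: SagMap | None, gantry: float) -> ImagePoint:
    """G0 CAX translated by the sag-map offset at ``gantry``."""
    g = float(gantry) % 360.0
    if sag is None:
        if g != 0.0:
            raise ValueError(
                "a sag map is required to correct the CAX at non-zero gantry "
                "angles; build one first (stakitt sagmap)"
            )
        return cax.position
    dx, dy = sag.at(g)
    return ImagePoint(cax.position.x + dx, cax.position.y + dy)
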