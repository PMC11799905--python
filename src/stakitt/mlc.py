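"""MLC hardware descriptions and the stakitt test-plan model.

The stakitt delivery is six 2 cm wide MLC-defined sub-fields ("stakitts")
at 4 cm center-to-center spacing, book-ended by comb patterns of alternating
protruding/retracted leaves that let the analysis locate individual leaves.
Nominal tip positions use the light-field convention (what DICOM plans
encode); the light/radiation field discrepancy is carried entirely by the
RFO parameter at measurement time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "MlcModel",
    "StakittPlan",
    "millennium120",
    "hdmlc",
    "mlc_by_name",
    "build_default_plan",
    "write_plan",
    "read_plan",
    "PlanValidationWarning",
]

BANKS = ("A", "B")  # A = left bank (tips face +x), B = right bank


class PlanValidationWarning(UserWarning):
    """Raised (as a warning) for unusual but analyzable plans."""


@dataclass(frozen=True)
class MlcModel:
    """Leaf-bank geometry: per-pair inplane widths centered on the axis.

    Both banks share the same inplane leaf boundaries.  Widths are in mm at
    the isocenter plane, ordered from the most negative-y leaf upward.
    """

    name: str
    leaf_widths: tuple[float, ...]

    def __post_init__(self):
        if any(w <= 0 for w in self.leaf_widths):
            raise ValueError("leaf widths must be positive")

    @property
    def n_leaf_pairs(self) -> int:
        return len(self.leaf_widths)

    @property
    def leaf_edges(self) -> np.ndarray:
        """Inplane boundary positions, shape (n_leaf_pairs + 1,), centered at 0."""
        edges = np.concatenate([[0.0], np.cumsum(self.leaf_widths)])
        return edges - edges[-1] / 2.0

    @property
    def leaf_centers(self) -> np.ndarray:
        e = self.leaf_edges
        return 0.5 * (e[:-1] + e[1:])

    def to_dict(self) -> dict:
        return {"name": self.name, "leaf_widths": list(self.leaf_widths)}

    @staticmethod
    def from_dict(d: dict) -> "MlcModel":
        return MlcModel(d["name"], tuple(float(w) for w in d["leaf_widths"]))


def millennium120() -> MlcModel:
    """Varian Millennium120: 10 outer 10 mm + 40 central 5 mm + 10 outer 10 mm."""
    return MlcModel("millennium120", (10.0,) * 10 + (5.0,) * 40 + (10.0,) * 10)


def hdmlc() -> MlcModel:
    """Varian HDMLC: 14 outer 5 mm + 32 central 2.5 mm + 14 outer 5 mm."""
    return MlcModel("hdmlc", (5.0,) * 14 + (2.5,) * 32 + (5.0,) * 14)


def mlc_by_name(name: str) -> MlcModel:
    try:
        return {"millennium120": millennium120, "hdmlc": hdmlc}[name]()
    except KeyError:
        raise ValueError(f"unknown MLC model {name!r}") from None


@dataclass
class StakittPlan:
    """Stakitt test-plan: nominal tips per sub-field plus comb geometry.

    ``nominal_tips`` has shape (n_stakitts, 2, n_leaf_pairs); index 0 along
    the bank axis is bank A (left, tip crossplane position = the *larger*-x
    end of the leaf) and index 1 is bank B.  All positions are light-field mm
    relative to the beam central axis.
    """

    mlc: MlcModel
    stakitt_centers: np.ndarray
    stakitt_width: float
    nominal_tips: np.ndarray
    comb_protrude_tip: float = 120.0
    comb_retract_tip: float = 150.0
    comb_column: float = 130.0
    comb_inner_bound: float = 118.0
    # leaf-index parity (0 or 1) of the protruding leaves, per (left, right) comb
    comb_protrude_parity: tuple[int, int] = (0, 1)
    carriage_shift_after: int = 3
    mu: float = 480.0
    energy: str = "6MV"
    jaw_x: tuple[float, float] = (-160.0, 160.0)

    def __post_init__(self):
        self.stakitt_centers = np.asarray(self.stakitt_centers, dtype=float)
        self.nominal_tips = np.asarray(self.nominal_tips, dtype=float)
        expected = (self.n_stakitts, 2, self.mlc.n_leaf_pairs)
        if self.nominal_tips.shape != expected:
            raise ValueError(
                f"nominal_tips shape {self.nominal_tips.shape} != {expected}"
            )
        if np.any(self.nominal_tips[:, 0, :] >= self.nominal_tips[:, 1, :]):
            raise ValueError("bank A tip must be < bank B tip for every leaf (open gap)")
        self.validate()

    @property
    def n_stakitts(self) -> int:
        return len(self.stakitt_centers)

    def validate(self) -> list[str]:
        """Soft checks: warn (and return messages) but let analysis proceed."""
        messages = []
        if self.n_stakitts != 6:
            messages.append(f"plan has {self.n_stakitts} stakitts (6 expected)")
        gaps = self.nominal_tips[:, 1, :] - self.nominal_tips[:, 0, :]
        if not np.allclose(gaps, self.stakitt_width, atol=1e-6):
            messages.append("nominal leaf gaps do not all equal stakitt_width")
        if self.n_stakitts > 1:
            spacing = np.diff(np.sort(self.stakitt_centers))
            if np.ptp(spacing) > 1e-6:
                messages.append("stakitt centers are not evenly spaced")
        if not (0 < self.carriage_shift_after < max(self.n_stakitts, 2)):
            messages.append("carriage_shift_after is not between stakitts")
        for msg in messages:
            warnings.warn(msg, PlanValidationWarning, stacklevel=3)
        return messages

    # -- comb helpers --------------------------------------------------------

    def comb_sign(self, side: str) -> float:
        return -1.0 if side == "left" else 1.0

    def comb_protrudes(self, side: str) -> np.ndarray:
        """Boolean mask over leaf pairs: which leaves protrude in this comb."""
        parity = self.comb_protrude_parity[0 if side == "left" else 1]
        idx = np.arange(self.mlc.n_leaf_pairs)
        return idx % 2 == parity

    def comb_tips(self, side: str) -> np.ndarray:
        """Signed crossplane tip position per leaf for the given comb."""
        sign = self.comb_sign(side)
        tips = np.where(
            self.comb_protrudes(side), self.comb_protrude_tip, self.comb_retract_tip
        )
        return sign * tips

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "mlc": self.mlc.to_dict(),
            "stakitt_centers": self.stakitt_centers.tolist(),
            "stakitt_width": self.stakitt_width,
            "nominal_tips": self.nominal_tips.tolist(),
            "comb_protrude_tip": self.comb_protrude_tip,
            "comb_retract_tip": self.comb_retract_tip,
            "comb_column": self.comb_column,
            "comb_inner_bound": self.comb_inner_bound,
            "comb_protrude_parity": list(self.comb_protrude_parity),
            "carriage_shift_after": self.carriage_shift_after,
            "mu": self.mu,
            "energy": self.energy,
            "jaw_x": list(self.jaw_x),
        }

    @staticmethod
    def from_dict(d: dict) -> "StakittPlan":
        for key in ("mlc", "stakitt_centers", "stakitt_width", "nominal_tips"):
            if key not in d:
                raise KeyError(f"plan file missing required field {key!r}")
        return StakittPlan(
            mlc=MlcModel.from_dict(d["mlc"]),
            stakitt_centers=np.asarray(d["stakitt_centers"], dtype=float),
            stakitt_width=float(d["stakitt_width"]),
            nominal_tips=np.asarray(d["nominal_tips"], dtype=float),
            comb_protrude_tip=float(d.get("comb_protrude_tip", 120.0)),
            comb_retract_tip=float(d.get("comb_retract_tip", 150.0)),
            comb_column=float(d.get("comb_column", 130.0)),
            comb_inner_bound=float(d.get("comb_inner_bound", 118.0)),
            comb_protrude_parity=tuple(d.get("comb_protrude_parity", (0, 1))),
            carriage_shift_after=int(d.get("carriage_shift_after", 3)),
            mu=float(d.get("mu", 480.0)),
            energy=str(d.get("energy", "6MV")),
            jaw_x=tuple(d.get("jaw_x", (-160.0, 160.0))),
        )

    def __eq__(self, other):
        if not isinstance(other, StakittPlan):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def summary_table(self):
        """Human-readable per-stakitt summary as a pandas DataFrame."""
        import pandas as pd

        rows = []
        for s, c in enumerate(self.stakitt_centers):
            rows.append(
                {
                    "stakitt": s + 1,
                    "center_mm": c,
                    "bank_A_tip_mm": float(np.median(self.nominal_tips[s, 0])),
                    "bank_B_tip_mm": float(np.median(self.nominal_tips[s, 1])),
                    "width_mm": self.stakitt_width,
                    "after_carriage_shift": s >= self.carriage_shift_after,
                }
            )
        return pd.DataFrame(rows)


def build_default_plan(mlc: MlcModel | str | None = None, **overrides) -> StakittPlan:
    """Default stakitt plan: 6 stakitts at {-100..+100} mm, 20 mm wide, 480 MU.

    Each stakitt's bank A/B nominal tips sit at center -/+ half the stakitt
    width; the carriage shift is flagged between the two central stakitts.
    """
    if mlc is None:
        mlc = millennium120()
    elif isinstance(mlc, str):
        mlc = mlc_by_name(mlc)
    centers = np.asarray(overrides.pop("stakitt_centers", np.arange(-100.0, 101.0, 40.0)))
    width = float(overrides.pop("stakitt_width", 20.0))
    n_leaves = mlc.n_leaf_pairs
    tips = np.empty((len(centers), 2, n_leaves))
    tips[:, 0, :] = (centers - width / 2.0)[:, None]
    tips[:, 1, :] = (centers + width / 2.0)[:, None]
    return StakittPlan(
        mlc=mlc,
        stakitt_centers=centers,
        stakitt_width=width,
        nominal_tips=tips,
        **overrides,
    )


def write_plan(plan: StakittPlan, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(plan.to_dict(), fh, indent=1)
    return path


def read_plan(path) -> StakittPlan:
    with open(path) as fh:
        return StakittPlan.from_dict(json.load(fh))
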