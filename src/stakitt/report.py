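"""Result aggregation, tolerance evaluation, and the evaluation experiments.

Combines per-leaf tip measurements into bank and gap statistics, flags
out-of-tolerance leaves, and drives the standard evaluation procedures:
algorithm consistency, short-term repeatability (3 SD of five consecutive
acquisitions), sensitivity to introduced errors, and the backlash use case
comparing bank means between gantry 90 and 270.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .analysis import locate_leaves, measure_tips, LeafMeasurement, estimate_noise
from .cax import BeamCax, build_sag_map, cax_at_gantry, compute_cax
from .image import EpidImage, ImagePoint
from .mlc import StakittPlan
from .simulate import SimConfig, render_stakitt_image, render_cax_pair, render_cone_arc

__all__ = [
    "StakittResult",
    "default_action_limit",
    "analyze_image",
    "summarize",
    "consistency_experiment",
    "repeatability_experiment",
    "sensitivity_experiment",
    "backlash_experiment",
    "plot_histograms",
]

MEASUREMENT_COLUMNS = [
    "leaf", "bank", "stakitt", "nominal_mm", "measured_mm", "deviation_mm", "flags",
]


def default_action_limit(gantry: float) -> float:
    """+/-0.5 mm at G0, +/-1.0 mm at the other cardinal gantry angles."""
    return 0.5 if float(gantry) % 360.0 == 0.0 else 1.0


@dataclass
class StakittResult:
    """Full per-leaf / per-gap deviation set with summary statistics."""

    measurements: pd.DataFrame
    gaps: pd.DataFrame
    bank_stats: pd.DataFrame  # index A/B/gap, columns mean/sd/n
    out_of_tolerance: pd.DataFrame
    action_limit: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_flagged(self) -> int:
        return len(self.out_of_tolerance)

    def to_json_dict(self) -> dict:
        return {
            "action_limit_mm": self.action_limit,
            "bank_stats": self.bank_stats.to_dict(orient="index"),
            "n_measurements": int(len(self.measurements)),
            "n_out_of_tolerance": self.n_flagged,
            "metadata": self.metadata,
        }


def measurements_frame(measurements: list[LeafMeasurement]) -> pd.DataFrame:
    rows = [
        {
            "leaf": m.leaf_index,
            "bank": m.bank,
            "stakitt": m.stakitt_index,
            "nominal_mm": m.nominal_tip,
            "measured_mm": m.measured_tip,
            "deviation_mm": m.deviation,
            "flags": ";".join(m.flags),
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def analyze_image(
    img: EpidImage,
    plan: StakittPlan,
    cax: ImagePoint,
    rfo: tuple[float, float] = (0.0, 0.0),
) -> tuple[pd.DataFrame, list[str]]:
    """Run the full leaf analysis on one stakitt image.

    ``cax`` must already be sag-corrected for the image's gantry angle.
    Returns the per-leaf measurement table and the exclusion log.
    """
    trajectories, log = locate_leaves(img, plan, cax=cax)
    # collimator-vs-panel rotation is rigid: one direction for all leaves
    slope = float(np.median([t.slope for t in trajectories]))
    direction = np.array([1.0, slope]) / np.hypot(1.0, slope)
    noise_sd = estimate_noise(img)
    all_measurements: list[LeafMeasurement] = []
    for traj in trajectories:
        all_measurements.extend(
            measure_tips(img, traj, plan, cax, rfo=rfo, direction=direction,
                         noise_sd=noise_sd)
        )
    return measurements_frame(all_measurements), log


def summarize(
    measurements: pd.DataFrame | list[LeafMeasurement],
    action_limit: float = 0.5,
    metadata: dict | None = None,
) -> StakittResult:
    """Gap statistics, bank means and out-of-tolerance flags.

    Gap deviations are the sum of the two opposing leaves' signed deviations
    (both retraction-positive), so positive gap deviation means the gap is
    wider than planned.
    """
    if not isinstance(measurements, pd.DataFrame):
        measurements = measurements_frame(measurements)
    if measurements.empty:
        raise ValueError("no valid measurements to summarize")
    valid = measurements.dropna(subset=["deviation_mm"])

    piv = valid.pivot_table(
        index=["leaf", "stakitt"], columns="bank", values="deviation_mm"
    )
    if not {"A", "B"} <= set(piv.columns):
        raise ValueError("mismatched leaf pairing: need both banks")
    paired = piv.dropna(subset=["A", "B"])
    gaps = pd.DataFrame(
        {
            "leaf": paired.index.get_level_values("leaf"),
            "stakitt": paired.index.get_level_values("stakitt"),
            "gap_deviation_mm": (paired["A"] + paired["B"]).to_numpy(),
        }
    ).reset_index(drop=True)

    stats = []
    for key, series in (
        ("A", valid.loc[valid["bank"] == "A", "deviation_mm"]),
        ("B", valid.loc[valid["bank"] == "B", "deviation_mm"]),
        ("gap", gaps["gap_deviation_mm"]),
    ):
        stats.append(
            {"group": key, "mean_mm": float(series.mean()),
             "sd_mm": float(series.std(ddof=1)) if len(series) > 1 else 0.0,
             "n": int(len(series))}
        )
    bank_stats = pd.DataFrame(stats).set_index("group")

    oot = valid.loc[valid["deviation_mm"].abs() > action_limit].copy()
    return StakittResult(
        measurements=measurements,
        gaps=gaps,
        bank_stats=bank_stats,
        out_of_tolerance=oot,
        action_limit=action_limit,
        metadata=metadata or {},
    )


# ---------------------------------------------------------------------------
# evaluation experiments
# ---------------------------------------------------------------------------

def _session_cax(cfg: SimConfig, seed: int) -> BeamCax:
    """Measure the session CAX from a simulated C90/C270 pair."""
    c90, c270 = render_cax_pair(cfg, offset=cfg.cax_offset, seed=seed)
    return compute_cax(c90, c270)


def consistency_experiment(
    img: EpidImage, plan: StakittPlan, cax: ImagePoint, n_runs: int = 5,
    rfo: tuple[float, float] = (0.0, 0.0),
) -> dict:
    """Repeat the full analysis on one fixed image and compare outputs.

    Returns the maximum absolute difference in measured positions across
    runs and the number of decimal places to which all runs agree.
    """
    tables = []
    for _ in range(n_runs):
        df, _log = analyze_image(img, plan, cax, rfo=rfo)
        tables.append(df["measured_mm"].to_numpy())
    stack = np.vstack(tables)
    max_diff = float(np.nanmax(np.abs(stack - stack[0])))
    decimals = 15 if max_diff == 0.0 else int(np.floor(-np.log10(max_diff)))
    return {"max_abs_diff_mm": max_diff, "decimal_places": min(decimals, 15),
            "n_runs": n_runs, "n_measurements": stack.shape[1]}


def repeatability_experiment(
    plan: StakittPlan,
    cfg: SimConfig,
    n_runs: int = 5,
    seed: int = 1,
    gantry: float = 0.0,
) -> dict:
    """Five consecutive simulated acquisitions -> per-leaf SD and 3 SD summary.

    The true leaf positions are held fixed; only the image noise is
    re-realized per run.  Repeatability is three times the standard
    deviation of the measured position, averaged over all leaf/bank/stakitt
    samples.
    """
    cax = _session_cax(cfg, seed=seed + 1000)
    runs = []
    for i in range(n_runs):
        img, _gt = render_stakitt_image(plan, cfg, gantry=gantry, seed=seed + i)
        df, _log = analyze_image(img, plan, cax.position)
        runs.append(df.set_index(["leaf", "bank", "stakitt"])["measured_mm"])
    wide = pd.concat(runs, axis=1)
    sds = wide.std(axis=1, ddof=1).dropna()
    return {
        "per_leaf_sd_mm": sds,
        "mean_sd_mm": float(sds.mean()),
        "three_sd_mm": float(3.0 * sds.mean()),
        "n_runs": n_runs,
    }


def _pick_error_leaves(plan: StakittPlan, n: int = 5, adjacent: bool = False) -> np.ndarray:
    """Inner (narrowest-width) leaves: n non-adjacent singles or n adjacent pairs."""
    widths = np.asarray(plan.mlc.leaf_widths)
    inner = np.nonzero(widths == widths.min())[0]
    if adjacent:
        start = inner[len(inner) // 2 - n // 2]
        return np.arange(start, start + n)
    idx = np.linspace(inner[0] + 1, inner[-1] - 1, n)
    return np.unique(np.round(idx).astype(int))


def sensitivity_experiment(
    plan: StakittPlan,
    cfg: SimConfig,
    magnitudes: tuple[float, ...] = (-1.5, -1.0, -0.5, -0.1, 0.1, 0.5, 1.0, 1.5),
    mode: str = "position",
    seed: int = 1,
    n_error_leaves: int = 5,
) -> tuple[pd.DataFrame, dict]:
    """Measured-minus-injected statistics for deliberate errors.

    ``mode="position"`` injects each magnitude as a tip error on five
    non-adjacent inner leaves of bank A (random-error mimic);
    ``mode="gap"`` shifts both leaves of five adjacent pairs by half the
    magnitude each, widening (positive) or narrowing the gap (systematic
    mimic).  Statistics pool all errored leaf x stakitt samples.
    """
    if mode not in ("position", "gap"):
        raise ValueError("mode must be 'position' or 'gap'")
    n_leaves = plan.mlc.n_leaf_pairs
    leaves = _pick_error_leaves(plan, n_error_leaves, adjacent=(mode == "gap"))
    cax = _session_cax(cfg, seed=seed + 2000)

    rows = []
    details: dict[float, pd.DataFrame] = {}
    for k, mag in enumerate(magnitudes):
        errors = np.zeros((2, n_leaves))
        if mode == "position":
            errors[0, leaves] = mag
        else:
            errors[0, leaves] = mag / 2.0
            errors[1, leaves] = mag / 2.0
        run_cfg = replace(cfg, leaf_errors=errors)
        img, _gt = render_stakitt_image(plan, run_cfg, gantry=0.0, seed=seed + 10 + k)
        df, _log = analyze_image(img, plan, cax.position)
        if mode == "position":
            sel = df[(df["bank"] == "A") & df["leaf"].isin(leaves)]
            err = sel["deviation_mm"] - mag
            detail = sel.assign(injected_mm=mag, error_mm=err)
        else:
            result = summarize(df, action_limit=np.inf)
            sel = result.gaps[result.gaps["leaf"].isin(leaves)]
            err = sel["gap_deviation_mm"] - mag
            detail = sel.assign(injected_mm=mag, error_mm=err)
        rows.append(
            {"mode": mode, "injected_mm": mag,
             "mean_error_mm": float(err.mean()),
             "sd_error_mm": float(err.std(ddof=1)),
             "n": int(len(err))}
        )
        details[mag] = detail
    return pd.DataFrame(rows), details


def backlash_experiment(
    plan: StakittPlan,
    cfg: SimConfig,
    backlash_per_bank: tuple[float, float] = (0.27, 0.0),
    seed: int = 1,
    gantries: tuple[float, ...] = (90.0, 0.0, 270.0),
    n_arc_frames: int = 24,
) -> pd.DataFrame:
    """Bank means at G90/G0/G270 under a gravity-direction backlash model.

    Renders the stakitt delivery at each gantry angle with the per-leaf
    backlash displacing tips by half the play in the gravity direction,
    corrects the CAX per angle with a sag map built from a simulated cone
    arc, and reports per-bank / gap means plus the G90-G270 mean difference.
    """
    n_leaves = plan.mlc.n_leaf_pairs
    backlash = np.vstack([
        np.full(n_leaves, backlash_per_bank[0]),
        np.full(n_leaves, backlash_per_bank[1]),
    ])
    run_cfg = replace(cfg, backlash=backlash)

    cax = _session_cax(run_cfg, seed=seed + 3000)
    frames = render_cone_arc(run_cfg, n_frames=n_arc_frames, seed=seed + 4000)
    sag = build_sag_map(frames)

    rows = {}
    for k, gantry in enumerate(gantries):
        img, _gt = render_stakitt_image(plan, run_cfg, gantry=gantry, seed=seed + 20 + k)
        point = cax_at_gantry(cax, sag, gantry)
        df, _log = analyze_image(img, plan, point)
        res = summarize(df, action_limit=default_action_limit(gantry),
                        metadata={"gantry": gantry})
        rows[gantry] = res.bank_stats

    table = []
    for gantry in gantries:
        bs = rows[gantry]
        table.append(
            {"gantry": f"G{int(gantry)}",
             "bank_A_mean_mm": bs.loc["A", "mean_mm"],
             "bank_A_sd_mm": bs.loc["A", "sd_mm"],
             "bank_B_mean_mm": bs.loc["B", "mean_mm"],
             "bank_B_sd_mm": bs.loc["B", "sd_mm"],
             "gap_mean_mm": bs.loc["gap", "mean_mm"],
             "gap_sd_mm": bs.loc["gap", "sd_mm"]}
        )
    out = pd.DataFrame(table).set_index("gantry")
    if 90.0 in gantries and 270.0 in gantries:
        diff = {
            "bank_A_mean_mm": out.loc["G90", "bank_A_mean_mm"] - out.loc["G270", "bank_A_mean_mm"],
            "bank_B_mean_mm": out.loc["G90", "bank_B_mean_mm"] - out.loc["G270", "bank_B_mean_mm"],
            "gap_mean_mm": out.loc["G90", "gap_mean_mm"] - out.loc["G270", "gap_mean_mm"],
        }
        out.loc["G90-G270"] = pd.Series(diff)
    return out


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def plot_histograms(result: StakittResult, bin_width: float = 0.05, span: float = 1.0):
    """Three-panel deviation histogram: bank A, bank B, and gap."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    bins = np.arange(-span, span + bin_width / 2, bin_width)
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharey=True)
    valid = result.measurements.dropna(subset=["deviation_mm"])
    series = [
        ("Bank A", valid.loc[valid["bank"] == "A", "deviation_mm"]),
        ("Bank B", valid.loc[valid["bank"] == "B", "deviation_mm"]),
        ("Gap", result.gaps["gap_deviation_mm"]),
    ]
    for ax, (title, vals) in zip(axes, series):
        ax.hist(np.clip(vals, -span, span), bins=bins, color="steelblue")
        limit = result.action_limit if title != "Gap" else result.action_limit
        ax.axvline(-limit, color="crimson", ls="--", lw=1)
        ax.axvline(limit, color="crimson", ls="--", lw=1)
        ax.set_title(title)
        ax.set_xlabel("deviation from nominal (mm)")
    axes[0].set_ylabel("count")
    fig.tight_layout()
    return fig
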