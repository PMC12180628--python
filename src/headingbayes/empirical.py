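"""Descriptive bias and variability curves from trial tables.

Per heading and condition: the bias is the circular mean of the reported
headings minus the true heading (wrapped difference, degrees) and the
spread is the sample circular SD sqrt(2 (1 - R)) in degrees — the same
estimator family the model uses for its predictions, and total on the
full-circle probe. The linear slope of bias against true heading is the
single-number summary of over- vs underestimation: positive slope means
peripheral bias (overestimation), negative slope center bias.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .angles import circular_sd_from_R, rad2deg, wrapped_diff_deg

__all__ = ["summarize_bias_sd", "fit_bias_slope", "bias_slopes"]

CURVE_COLUMNS = [
    "level",
    "participant_id",
    "condition_label",
    "theta0_deg",
    "bias_deg",
    "sd_deg",
    "n",
]


def _cell_stats(reports_deg: np.ndarray):
    ang = np.deg2rad(reports_deg)
    c = np.cos(ang).mean()
    s = np.sin(ang).mean()
    mean_deg = rad2deg(np.arctan2(s, c))
    R = float(np.hypot(c, s))
    return float(mean_deg), R


def summarize_bias_sd(trials: pd.DataFrame, level: str = "participant") -> pd.DataFrame:
    """Per-heading bias and circular SD curves from a trial table.

    ``level='participant'`` returns one curve row per (participant,
    condition, heading); empty cells of the full participant x condition x
    heading grid appear with NaN values rather than being dropped, and SD
    needs at least two trials per cell. ``level='group'`` averages the
    participant curves per (condition, heading) and adds across-participant
    standard errors (``se_bias_deg``, ``se_sd_deg``).
    """
    if level not in ("participant", "group"):
        raise ValueError(f"level must be 'participant' or 'group', got {level!r}")
    required = ["participant_id", "condition_label", "true_heading_deg",
                "reported_heading_deg"]
    missing = [c for c in required if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing required columns: {missing}")
    if len(trials) == 0:
        raise ValueError("trial table is empty")

    headings = np.sort(trials["true_heading_deg"].unique())
    participants = sorted(trials["participant_id"].unique())
    # conditions a participant actually ran (between-subject designs leave
    # the others absent, which is not a missing cell)
    ran = {
        pid: sorted(sub["condition_label"].unique())
        for pid, sub in trials.groupby("participant_id")
    }

    rows = []
    grouped = trials.groupby(
        ["participant_id", "condition_label", "true_heading_deg"]
    )["reported_heading_deg"]
    stats_map = {key: grp.to_numpy(dtype=float) for key, grp in grouped}
    for pid in participants:
        for cond in ran[pid]:
            for h in headings:
                reports = stats_map.get((pid, cond, h))
                if reports is None or len(reports) == 0:
                    rows.append([pid, cond, float(h), np.nan, np.nan, 0])
                    continue
                mean_deg, R = _cell_stats(reports)
                bias = float(wrapped_diff_deg(mean_deg, h))
                sd = (
                    float(rad2deg(circular_sd_from_R(R)))
                    if len(reports) >= 2 else np.nan
                )
                rows.append([pid, cond, float(h), bias, sd, len(reports)])
    part = pd.DataFrame(
        rows,
        columns=["participant_id", "condition_label", "theta0_deg",
                 "bias_deg", "sd_deg", "n"],
    )
    part.insert(0, "level", "participant")
    if level == "participant":
        return part

    group_rows = []
    for (cond, h), sub in part.groupby(["condition_label", "theta0_deg"]):
        bias = sub["bias_deg"].dropna()
        sd = sub["sd_deg"].dropna()
        n_p = len(bias)
        group_rows.append(
            {
                "level": "group",
                "participant_id": "",
                "condition_label": cond,
                "theta0_deg": h,
                "bias_deg": bias.mean() if n_p else np.nan,
                "sd_deg": sd.mean() if len(sd) else np.nan,
                "n": int(sub["n"].sum()),
                "se_bias_deg": bias.std(ddof=1) / np.sqrt(n_p) if n_p > 1 else np.nan,
                "se_sd_deg": sd.std(ddof=1) / np.sqrt(len(sd)) if len(sd) > 1 else np.nan,
            }
        )
    return pd.DataFrame(group_rows)


def fit_bias_slope(curve: pd.DataFrame):
    """Unweighted OLS line through the bias curve of one condition.

    Returns ``(slope, intercept)`` of bias_deg against theta0_deg; NaN
    cells are dropped first. A positive slope is peripheral bias
    (overestimation of heading eccentricity), a negative slope center bias.
    """
    sub = curve.dropna(subset=["bias_deg"])
    theta = sub["theta0_deg"].to_numpy(dtype=float)
    bias = sub["bias_deg"].to_numpy(dtype=float)
    if len(np.unique(theta)) < 2:
        raise ValueError(
            "bias-slope fit needs at least two distinct headings with data, "
            f"got {np.unique(theta).tolist()}"
        )
    slope, intercept = np.polyfit(theta, bias, 1)
    return float(slope), float(intercept)


def bias_slopes(curves: pd.DataFrame) -> pd.DataFrame:
    """Slope/intercept summary per condition from a curve table."""
    rows = []
    for cond, sub in curves.groupby("condition_label", sort=True):
        slope, intercept = fit_bias_slope(sub)
        rows.append(
            {"condition_label": cond, "slope": slope, "intercept": intercept}
        )
    return pd.DataFrame(rows)
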