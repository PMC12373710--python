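"""Saccade behavior: landing-point detection, saccade error, trial validity.

Saccade error is the Euclidean distance between the target and the saccade
landing point, in degrees of visual angle:

    error = sqrt((x_t - x_l)^2 + (y_t - y_l)^2) / px_per_deg

Trials are rejected when they contain a blink, when fixation is broken
during the fixation/visual/memory intervals (gaze outside a 2 dva radius of
screen center), or when the saccade error exceeds 2 dva.  Valid trials are
tagged low (< 0.5 dva), high (> 1.5 dva) or mid error, and near (6 deg) or
far (12 deg) eccentricity.

Landing detection is velocity based: saccade onset is the first sample after
the go cue with 2-D speed above 30 deg/s, offset the first subsequent sample
below 5 deg/s, and the landing point is the median gaze position over the
100 ms after offset.  Positions are lightly smoothed before differentiation
so tracker tremor does not trip the thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REJECT_NONE = "none"
REJECT_BLINK = "blink"
REJECT_FIXBREAK = "fixation_break"
REJECT_ERROR = "error_gt_2"

LOW_ERROR_DVA = 0.5
HIGH_ERROR_DVA = 1.5
MAX_ERROR_DVA = 2.0


@dataclass(frozen=True)
class SaccadeOutcome:
    subject: int
    trial: int
    landing_px: tuple[float, float] | None
    target_px: tuple[float, float]
    error_dva: float
    valid: bool
    reject_reason: str
    error_group: str  # low / mid / high / "" when invalid
    condition: str  # near / far
    eccentricity_deg: float


def saccade_error(
    target_px: tuple[float, float],
    landing_px: tuple[float, float],
    px_per_deg: float,
) -> float:
    """Euclidean target-landing distance converted from pixels to dva."""
    if px_per_deg <= 0:
        raise ValueError("px_per_deg must be positive")
    dx = target_px[0] - landing_px[0]
    dy = target_px[1] - landing_px[1]
    return float(np.hypot(dx, dy) / px_per_deg)


def _speed_dva(gaze: pd.DataFrame, px_per_deg: float, smooth_ms: float = 21.0) -> np.ndarray:
    """2-D gaze speed in deg/s from a (possibly noisy) trace."""
    t = gaze["time_ms"].to_numpy() / 1000.0
    if t.size < 3:
        return np.zeros(t.size)
    dt = np.median(np.diff(t))
    win = max(1, int(round(smooth_ms / 1000.0 / dt)))
    kernel = np.ones(win) / win
    x = np.convolve(gaze["x_px"].to_numpy(), kernel, mode="same")
    y = np.convolve(gaze["y_px"].to_numpy(), kernel, mode="same")
    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    return np.hypot(vx, vy) / px_per_deg


def detect_landing(
    gaze: pd.DataFrame,
    go_time_s: float,
    px_per_deg: float,
    window_s: float = 1.0,
    onset_speed: float = 30.0,
    offset_speed: float = 5.0,
    landing_window_s: float = 0.1,
) -> tuple[tuple[float, float] | None, str]:
    """Find the saccade landing point in the response window.

    Returns ``(landing, reason)``; landing is None with reason
    ``fixation_break`` when no saccade is detected within the window, or
    ``blink`` when a blink overlaps the detection window.
    """
    t = gaze["time_ms"].to_numpy() / 1000.0
    in_win = (t >= go_time_s) & (t < go_time_s + window_s + landing_window_s)
    if "blink" in gaze and gaze.loc[in_win, "blink"].to_numpy().any():
        return None, REJECT_BLINK
    speed = _speed_dva(gaze, px_per_deg)
    idx = np.flatnonzero(in_win & (t < go_time_s + window_s) & (speed > onset_speed))
    if idx.size == 0:
        return None, REJECT_FIXBREAK
    onset = idx[0]
    after = np.flatnonzero((np.arange(t.size) > onset) & (speed < offset_speed))
    if after.size == 0:
        return None, REJECT_FIXBREAK
    offset = after[0]
    sel = (t >= t[offset]) & (t < t[offset] + landing_window_s)
    if not sel.any():
        return None, REJECT_FIXBREAK
    landing = (
        float(np.median(gaze.loc[sel, "x_px"])),
        float(np.median(gaze.loc[sel, "y_px"])),
    )
    return landing, REJECT_NONE


def validate_trial(
    gaze: pd.DataFrame,
    fix_start_s: float,
    go_time_s: float,
    error_dva: float | None,
    center_px: tuple[float, float],
    px_per_deg: float,
    fixation_radius_dva: float = 2.0,
) -> tuple[bool, str]:
    """Apply the three rejection rules; the verdict is order-independent.

    A trial is invalid if it contains any blink-flagged sample, if gaze
    leaves the fixation window during fixation/visual/memory, or if the
    saccade error exceeds 2 dva.  When several rules fire the reported
    reason follows the fixed priority blink > fixation_break > error.
    """
    if bool(gaze["blink"].to_numpy().any()):
        return False, REJECT_BLINK
    t = gaze["time_ms"].to_numpy() / 1000.0
    hold = (t >= fix_start_s) & (t < go_time_s)
    dx = gaze["x_px"].to_numpy()[hold] - center_px[0]
    dy = gaze["y_px"].to_numpy()[hold] - center_px[1]
    if np.any(np.hypot(dx, dy) / px_per_deg > fixation_radius_dva):
        return False, REJECT_FIXBREAK
    if error_dva is None:
        return False, REJECT_FIXBREAK
    if error_dva > MAX_ERROR_DVA:
        return False, REJECT_ERROR
    return True, REJECT_NONE


def _error_group(error_dva: float) -> str:
    if error_dva < LOW_ERROR_DVA:
        return "low"
    if error_dva > HIGH_ERROR_DVA:
        return "high"
    return "mid"


def group_labels(outcomes: pd.DataFrame, far_ecc: float = 12.0) -> pd.DataFrame:
    """Populate error_group and condition tags on an outcomes table.

    Low error < 0.5 dva, high > 1.5 dva, mid in between (mid trials are
    excluded from the two-group contrast downstream); condition is near/far
    by eccentricity.
    """
    out = outcomes.copy()
    if len(out) == 0:
        out["error_group"] = pd.Series(dtype=str)
        out["condition"] = pd.Series(dtype=str)
        return out
    out["error_group"] = [
        _error_group(e) if v else "" for e, v in zip(out["error_dva"], out["valid"])
    ]
    out["condition"] = np.where(out["eccentricity_deg"] == far_ecc, "far", "near")
    return out


def analyze_subject(
    gaze: pd.DataFrame,
    events: pd.DataFrame,
    center_px: tuple[float, float],
    px_per_deg: float,
    far_ecc: float = 12.0,
    fixation_radius_dva: float = 2.0,
) -> pd.DataFrame:
    """Per-trial saccade outcomes for one subject.

    ``gaze`` is the subject's concatenated trace with a ``trial`` column (or
    sliceable by trial event times); ``events`` the subject's event table.
    """
    rows = []
    for _, ev in events.iterrows():
        tr = int(ev["trial"])
        if "trial" in gaze:
            g = gaze[gaze["trial"] == tr]
        else:
            t = gaze["time_ms"] / 1000.0
            g = gaze[(t >= ev["t_fix_on_s"]) & (t < ev["t_go_s"] + 1.5)]
        g = g.reset_index(drop=True)
        target_px = (
            center_px[0] + float(ev["target_x_deg"]) * px_per_deg,
            center_px[1] + float(ev["target_y_deg"]) * px_per_deg,
        )
        landing, detect_reason = detect_landing(
            g, float(ev["t_go_s"]), px_per_deg
        )
        error = (
            saccade_error(target_px, landing, px_per_deg)
            if landing is not None
            else np.nan
        )
        if detect_reason != REJECT_NONE:
            valid, reason = False, detect_reason
            # a blink anywhere in the trial dominates the reported reason
            if bool(g["blink"].to_numpy().any()):
                reason = REJECT_BLINK
        else:
            valid, reason = validate_trial(
                g,
                float(ev["t_fix_on_s"]),
                float(ev["t_go_s"]),
                error,
                center_px,
                px_per_deg,
                fixation_radius_dva,
            )
        rows.append(
            {
                "subject": int(ev["subject"]),
                "trial": tr,
                "error_dva": error,
                "valid": valid,
                "reject_reason": reason,
                "eccentricity_deg": float(ev["eccentricity_deg"]),
                "target_index": int(ev["target_index"]),
            }
        )
    return group_labels(pd.DataFrame(rows), far_ecc=far_ecc)
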