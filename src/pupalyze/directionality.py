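"""Anterior-posterior wave direction from per-frame intensity-projection
modes.

Each frame of an (N, H, W) movie is collapsed by a maximum-intensity
projection (MIP) across image columns, giving a length-H profile along the
body axis; the profile's argmax row (its "mode") tracks the dominant
muscle activation.  Row 0 is anterior, so a mode trajectory with negative
slope over a bout is a posterior-to-anterior (P-to-A) wave.

Two decision rules are provided: a robust Theil-Sen slope fit (default)
and the mode-count ratio around the median mode, kept for fidelity with
the original description although counts around a median are nearly
balanced by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import theilslopes

from .errors import InsufficientDataError, ValidationError

P_TO_A = "P_to_A"
A_TO_P = "A_to_P"
INDETERMINATE = "indeterminate"


@dataclass
class ModeTrajectory:
    frames: np.ndarray          # frame indices of active frames
    mode_row: np.ndarray        # argmax row per active frame
    activity_floor: float
    height: int


@dataclass
class DirectionCall:
    call: str
    method: str
    value: float
    threshold: float | None = None


def frame_mode_profile(stack: np.ndarray, activity_floor: float = 0.0) -> ModeTrajectory:
    """Per-frame MIP-mode rows for an (N, H, W) stack.

    The mode is the lowest row index attaining the maximum of the per-frame
    column-MIP; frames whose maximum falls below ``activity_floor`` are
    flagged inactive and excluded from the trajectory.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.size == 0:
        raise ValidationError("stack must be a non-empty (N, H, W) array")
    mip = stack.max(axis=2)                 # (N, H)
    peak = mip.max(axis=1)
    active = peak >= activity_floor
    frames = np.nonzero(active)[0]
    if frames.size == 0:
        raise InsufficientDataError("all frames inactive (empty trajectory)")
    modes = mip[frames].argmax(axis=1)      # argmax -> lowest index on ties
    return ModeTrajectory(frames, modes, float(activity_floor), stack.shape[1])


def classify_direction(
    traj: ModeTrajectory,
    method: str = "slope",
    window: tuple[int, int] | None = None,
    slope_tol: float = 1e-9,
    ratio_bands: tuple[float, float] = (0.8, 1.25),
) -> DirectionCall:
    """Call wave direction over a bout window.

    ``slope`` (default): Theil-Sen median-of-pairwise-slopes fit of mode row
    against frame; negative slope (toward row 0 = anterior) is P-to-A,
    positive is A-to-P, |slope| <= ``slope_tol`` is indeterminate.

    ``mode_ratio``: the ratio of mode counts below vs above the median mode
    row (frames at the median excluded); ratios inside ``ratio_bands`` are
    indeterminate, above the upper band P-to-A, below the lower band A-to-P.
    """
    if window is not None:
        sel = (traj.frames >= window[0]) & (traj.frames < window[1])
    else:
        sel = np.ones_like(traj.frames, dtype=bool)
    frames = traj.frames[sel]
    modes = traj.mode_row[sel]
    if frames.size < 3:
        raise InsufficientDataError("need >= 3 active frames in window")
    if method == "slope":
        slope = theilslopes(modes, frames)[0]
        if abs(slope) <= slope_tol:
            return DirectionCall(INDETERMINATE, method, float(slope), slope_tol)
        call = P_TO_A if slope < 0 else A_TO_P
        return DirectionCall(call, method, float(slope), slope_tol)
    if method == "mode_ratio":
        median = float(np.median(modes))
        n_below = int((modes > median).sum())   # larger row = posterior = below the line
        n_above = int((modes < median).sum())
        if n_above == 0 or n_below == 0:
            return DirectionCall(INDETERMINATE, method, float("nan"), median)
        ratio = n_below / n_above
        lo, hi = ratio_bands
        if ratio >= hi:
            call = P_TO_A
        elif ratio <= lo:
            call = A_TO_P
        else:
            call = INDETERMINATE
        return DirectionCall(call, method, float(ratio), median)
    raise ValidationError(f"unknown method {method!r}")


def phase_direction_summary(calls: list[tuple[str, DirectionCall]]) -> dict[str, float]:
    """Fraction of bouts per phase called P-to-A.

    ``calls`` pairs a phase label with each bout's call.  Phases with no
    calls are omitted with a warning.
    """
    phases: dict[str, list[DirectionCall]] = {}
    for phase, call in calls:
        phases.setdefault(phase, []).append(call)
    out = {}
    for phase, clist in phases.items():
        if not clist:
            warnings.warn(f"phase {phase} has no direction calls; omitted")
            continue
        out[phase] = float(np.mean([c.call == P_TO_A for c in clist]))
    return out
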