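"""Bout segmentation and phase/bout variability summaries.

A bout is a maximal run of frames bearing new muscle-activation onsets,
flanked on either side by at least ``min_gap`` (default 2) onset-free
frames; the onset-free stretches are the inter-bout (rest) intervals.
The rule operates on onsets only: an event may stay above baseline across
a gap without joining two bouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, UndefinedStatisticError, ValidationError


@dataclass
class Bout:
    """Half-open frame interval [start, end) of one activity bout."""

    start: int
    end: int
    phase: str | None = None
    movements: tuple[str, ...] = field(default_factory=tuple)
    animal_id: str | None = None
    bout_id: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"bout start {self.start} >= end {self.end}")

    @property
    def duration(self) -> int:
        return self.end - self.start


def segment_bouts(
    onset_frames,
    min_gap: int = 2,
    n_frames: int | None = None,
) -> tuple[list[Bout], list[tuple[int, int]]]:
    """Split onset frames into bouts separated by >= ``min_gap`` onset-free
    frames.

    Returns ``(bouts, rest_intervals)``.  A bout spans
    [first onset, last onset + 1).  Rest intervals are the complement of the
    bouts within [0, n_frames) when ``n_frames`` is given, otherwise just the
    gaps between consecutive bouts.  Empty input yields no bouts and (with
    ``n_frames``) one full-length rest interval.
    """
    if min_gap < 1:
        raise ValidationError("min_gap must be >= 1")
    onsets = np.unique(np.asarray(list(onset_frames), dtype=int))
    bouts: list[Bout] = []
    if onsets.size:
        # consecutive onsets with fewer than min_gap empty frames between
        # them (i.e. difference <= min_gap) belong to the same bout
        breaks = np.nonzero(np.diff(onsets) > min_gap)[0]
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks, onsets.size - 1]
        for k, (i, j) in enumerate(zip(starts, ends)):
            bouts.append(Bout(int(onsets[i]), int(onsets[j]) + 1, bout_id=k))
    rests: list[tuple[int, int]] = []
    edges = [0] if n_frames is not None else []
    for b in bouts:
        if edges:
            if b.start > edges[-1]:
                rests.append((edges[-1], b.start))
            edges[-1] = b.end
        else:
            edges.append(b.end)
    if n_frames is not None:
        if not bouts:
            if n_frames > 0:
                rests.append((0, n_frames))
        elif bouts[-1].end < n_frames:
            rests.append((bouts[-1].end, n_frames))
    else:
        rests = [
            (a.end, b.start) for a, b in zip(bouts[:-1], bouts[1:])
        ]
    return bouts, rests


def coefficient_of_variation(values) -> float:
    """CV in percent: 100 * sample SD (n-1 denominator) / mean."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise InsufficientDataError("CV needs at least two values")
    mean = v.mean()
    if mean == 0:
        raise UndefinedStatisticError("CV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


def _stats(values: np.ndarray) -> dict[str, float]:
    out = {"n": int(values.size), "mean": float("nan"), "sd": float("nan"),
           "cv": float("nan")}
    if values.size:
        out["mean"] = float(values.mean())
    if values.size >= 2:
        out["sd"] = float(values.std(ddof=1))
        if values.mean() != 0:
            out["cv"] = float(100.0 * values.std(ddof=1) / values.mean())
    return out


def summarize_phases(bouts: list[Bout]) -> pd.DataFrame:
    """Per-phase variability summary of bout durations, inter-bout (rest)
    durations, and per-animal bout counts.

    Every bout must carry a phase label.  Rest durations are measured
    between consecutive bouts of the same animal and attributed to the
    phase of the preceding bout.
    """
    for b in bouts:
        if b.phase is None:
            raise ValidationError(f"unlabeled bout {b}")
    rows = []
    phases = sorted({b.phase for b in bouts})
    by_animal: dict[str | None, list[Bout]] = {}
    for b in bouts:
        by_animal.setdefault(b.animal_id, []).append(b)
    rest_by_phase: dict[str, list[int]] = {p: [] for p in phases}
    for blist in by_animal.values():
        blist = sorted(blist, key=lambda b: b.start)
        for a, b in zip(blist[:-1], blist[1:]):
            rest_by_phase[a.phase].append(b.start - a.end)
    for phase in phases:
        durs = np.array([b.duration for b in bouts if b.phase == phase], dtype=float)
        rests = np.array(rest_by_phase[phase], dtype=float)
        counts = np.array(
            [sum(1 for b in blist if b.phase == phase) for blist in by_animal.values()],
            dtype=float,
        )
        row = {"phase": phase}
        for prefix, vals in (("bout_dur", durs), ("rest_dur", rests), ("bout_count", counts)):
            for k, val in _stats(vals).items():
                row[f"{prefix}_{k}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def assign_phases(bouts: list[Bout]) -> list[Bout]:
    """Rule-based phase onsets from movement labels.

    P1 starts with the first bout containing a Lift; P2 with the first bout
    whose movements are exactly Swings; P3 with the first bout containing a
    Crunch.  Bouts before P1 are P0.  Labels are assigned in place and the
    list is returned.
    """
    p1 = p2 = p3 = None
    for i, b in enumerate(bouts):
        if p1 is None and "Lift" in b.movements:
            p1 = i
        if p2 is None and b.movements and set(b.movements) == {"Swing"}:
            p2 = i
        if p3 is None and "Crunch" in b.movements:
            p3 = i
    for i, b in enumerate(bouts):
        if p3 is not None and i >= p3:
            b.phase = "P3"
        elif p2 is not None and i >= p2:
            b.phase = "P2"
        elif p1 is not None and i >= p1:
            b.phase = "P1"
        else:
            b.phase = "P0"
    return bouts
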