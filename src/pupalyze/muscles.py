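"""Pupal body-wall muscle roster and hemisegment map.

The pupa retains roughly half of the larval body-wall muscles through
ecdysis.  Each abdominal hemisegment (A1..A7, left and right) carries the
same roster, with three anatomical exceptions: M12 is present only in
anterior segments, and M4/M5 are absent from posterior segments (the
anterior/posterior boundary sits between A4 and A5).  Muscles group into
dorsal, lateral, and ventral dorsoventral (D-V) compartments.

Frame-coordinate convention for ROI geometry: row 0 = anterior, the last
row = posterior; the A-P body axis is vertical.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidConfigError

#: Muscle labels modeled, with their D-V compartment.
DV_COMPARTMENT: dict[str, str] = {
    "M1": "dorsal",
    "M2": "dorsal",
    "M3": "dorsal",
    "M5": "dorsal",
    "M9": "dorsal",
    "M10": "dorsal",
    "M8": "lateral",
    "M21": "lateral",
    "M22": "lateral",
    "M23": "lateral",
    "M12": "ventral",
    "M13": "ventral",
    "M15": "ventral",
    "M26": "ventral",
}

ROSTER: tuple[str, ...] = tuple(DV_COMPARTMENT)

#: Muscles restricted to anterior segments (A1-A4).
ANTERIOR_ONLY: frozenset[str] = frozenset({"M12", "M4", "M5"})

SEGMENTS: tuple[str, ...] = tuple(f"A{i}" for i in range(1, 8))
SIDES: tuple[str, ...] = ("L", "R")

#: Segment index of the first posterior segment (A5) in a 7-segment map.
AP_BOUNDARY_INDEX = 4


def natural_key(label: str) -> tuple:
    """Collation key sorting muscle labels by number (M2 < M12)."""
    return tuple(int(p) if p.isdigit() else p for p in re.split(r"(\d+)", label))


@dataclass(frozen=True)
class MuscleID:
    """One muscle cell: label x hemisegment x side, with compartment tags."""

    label: str
    segment: str
    side: str
    dv: str
    ap: str

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.label, self.segment, self.side)


@dataclass
class MuscleMap:
    """Roster of muscle cells with optional per-muscle ROI polygons.

    ``roi_geometry`` maps ``(label, segment, side)`` to an (n, 2) float array
    of polygon vertices in (row, col) frame coordinates.
    """

    muscles: list[MuscleID]
    segments: list[str]
    sides: tuple[str, ...]
    ap_boundary: int
    roi_geometry: dict[tuple[str, str, str], np.ndarray] = field(default_factory=dict)
    frame_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        seen = set()
        for m in self.muscles:
            if m.dv not in ("dorsal", "lateral", "ventral"):
                raise InvalidConfigError(f"bad dv compartment {m.dv!r} for {m.key}")
            if m.ap not in ("anterior", "posterior"):
                raise InvalidConfigError(f"bad ap compartment {m.ap!r} for {m.key}")
            if m.key in seen:
                raise InvalidConfigError(f"duplicate muscle {m.key}")
            seen.add(m.key)
        if self.frame_shape is not None:
            h, w = self.frame_shape
            for key, poly in self.roi_geometry.items():
                if poly.size == 0:
                    raise InvalidConfigError(f"empty ROI for {key}")
                if poly[:, 0].min() < 0 or poly[:, 0].max() > h or \
                   poly[:, 1].min() < 0 or poly[:, 1].max() > w:
                    raise InvalidConfigError(f"ROI for {key} outside frame {self.frame_shape}")

    @property
    def labels(self) -> list[str]:
        """Distinct muscle labels, natural-sorted."""
        return sorted({m.label for m in self.muscles}, key=natural_key)

    def cells(self, label: str) -> list[MuscleID]:
        return [m for m in self.muscles if m.label == label]

    def compartment(self, label: str) -> str:
        """D-V compartment of a muscle label."""
        return DV_COMPARTMENT[label]

    def segment_ap(self, segment: str) -> str:
        idx = self.segments.index(segment)
        return "anterior" if idx < self.ap_boundary else "posterior"

    def present(self, label: str, segment: str) -> bool:
        idx = self.segments.index(segment)
        if label in ANTERIOR_ONLY and idx >= self.ap_boundary:
            return False
        return True


def make_muscle_map(
    n_segments: int = 7,
    sides: tuple[str, ...] = SIDES,
    with_rois: bool = False,
    seg_height: int = 10,
    muscle_width: int = 3,
) -> MuscleMap:
    """Build a hemisegmental muscle map.

    With 7 segments the anterior/posterior boundary falls between A4 and A5;
    anterior-only muscles (M12, M5) are omitted from posterior segments.
    Maps with fewer segments are entirely anterior.

    When ``with_rois`` is set, each muscle cell receives a rectangular ROI
    polygon: segments stack as horizontal bands (A1 at row 0 = anterior),
    the left/right sides occupy the left/right half of the frame, and
    muscles line up as columns within their hemisegment band.
    """
    if n_segments < 1:
        raise InvalidConfigError(f"n_segments must be >= 1, got {n_segments}")
    if n_segments > len(SEGMENTS):
        raise InvalidConfigError(f"n_segments must be <= {len(SEGMENTS)}")
    segments = list(SEGMENTS[:n_segments])
    ap_boundary = min(AP_BOUNDARY_INDEX, n_segments)

    muscles: list[MuscleID] = []
    for seg_idx, seg in enumerate(segments):
        ap = "anterior" if seg_idx < ap_boundary else "posterior"
        for side in sides:
            for label in ROSTER:
                if label in ANTERIOR_ONLY and ap == "posterior":
                    continue
                muscles.append(MuscleID(label, seg, side, DV_COMPARTMENT[label], ap))

    rois: dict[tuple[str, str, str], np.ndarray] = {}
    frame_shape = None
    if with_rois:
        n_lab = len(ROSTER)
        half_w = n_lab * muscle_width
        frame_shape = (n_segments * seg_height, len(sides) * half_w)
        lab_order = sorted(ROSTER, key=natural_key)
        for m in muscles:
            seg_idx = segments.index(m.segment)
            side_idx = sides.index(m.side)
            lab_idx = lab_order.index(m.label)
            r0 = seg_idx * seg_height + 1
            r1 = (seg_idx + 1) * seg_height - 1
            c0 = side_idx * half_w + lab_idx * muscle_width
            c1 = c0 + muscle_width
            rois[m.key] = np.array(
                [[r0, c0], [r0, c1], [r1, c1], [r1, c0]], dtype=float
            )
    return MuscleMap(muscles, segments, tuple(sides), ap_boundary, rois, frame_shape)
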