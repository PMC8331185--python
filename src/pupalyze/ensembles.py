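"""Discovery of pupal muscle ensembles (PMEs) and single-muscle syllables
from co-activation, plus bout annotation with syllable events.

A PME is a set of >= 2 muscles whose activity overlaps for at least
``min_overlap_frames`` consecutive frames (default 3), in at least
``within_animal_frac`` of the bouts (or movements) of an animal, for at
least ``across_animal_frac`` of animals (defaults 0.8/0.8).  Muscles that
reach the same support on their own, but never as part of a retained
ensemble, are single-muscle syllables.

Event tables are pandas DataFrames with (at least) columns
``animal_id, bout_id, muscle, onset_frame, offset_frame``; intervals are
half-open and 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .muscles import natural_key


def _validate_events(events: pd.DataFrame) -> None:
    bad = events.index[events["offset_frame"] <= events["onset_frame"]]
    if len(bad):
        raise ValidationError(f"events with offset <= onset at rows {list(bad[:10])}")


def _activity_arrays(events: pd.DataFrame) -> tuple[int, dict[str, np.ndarray]]:
    """Per-muscle boolean activity over the events' span; returns (t0, arrays)."""
    t0 = int(events["onset_frame"].min())
    t1 = int(events["offset_frame"].max())
    arrays: dict[str, np.ndarray] = {}
    for muscle, grp in events.groupby("muscle"):
        a = np.zeros(t1 - t0, dtype=bool)
        for on, off in zip(grp["onset_frame"], grp["offset_frame"]):
            a[int(on) - t0:int(off) - t0] = True
        arrays[muscle] = a
    return t0, arrays


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, end) index pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


@dataclass
class CoactiveGroup:
    """One co-activation occurrence: a muscle set and its co-active interval."""

    members: frozenset[str]
    interval: tuple[int, int]


def coactive_groups(
    events: pd.DataFrame, min_overlap_frames: int = 3
) -> list[CoactiveGroup]:
    """Maximal co-active muscle sets within one bout.

    For every ``min_overlap_frames``-frame window, the set of muscles active
    throughout the window is a candidate; candidates are merged over
    contiguous windows into occurrences, and an occurrence that is a strict
    subset of another occurrence with an overlapping interval is not
    reported separately (no combinatorial double counting).
    """
    _validate_events(events)
    if len(events) < 2:
        return []
    w = int(min_overlap_frames)
    t0, arrays = _activity_arrays(events)
    muscles = sorted(arrays, key=natural_key)
    span = next(iter(arrays.values())).size
    if span < w:
        return []
    stack = np.stack([arrays[m] for m in muscles])  # (n_muscles, span)
    # muscle active throughout window starting at t  <=>  min over window
    win_all = np.ones((len(muscles), span - w + 1), dtype=bool)
    for k in range(w):
        win_all &= stack[:, k:span - w + 1 + k]
    occ: dict[frozenset[str], list[tuple[int, int]]] = {}
    for t in range(win_all.shape[1]):
        s = frozenset(m for i, m in enumerate(muscles) if win_all[i, t])
        if len(s) < 2:
            continue
        occ.setdefault(s, []).append((t + t0, t + w + t0))
    # merge touching/overlapping occurrences of the same set
    groups: list[CoactiveGroup] = []
    for s, ivs in occ.items():
        merged: list[tuple[int, int]] = []
        for a, b in sorted(ivs):
            if merged and a <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        groups.extend(CoactiveGroup(s, iv) for iv in merged)
    # drop strict subsets overlapping a superset's interval
    kept = []
    for g in groups:
        shadowed = any(
            g.members < h.members
            and g.interval[0] < h.interval[1]
            and h.interval[0] < g.interval[1]
            for h in groups
        )
        if not shadowed:
            kept.append(g)
    kept.sort(key=lambda g: (g.interval, sorted(g.members, key=natural_key)))
    return kept


@dataclass
class PMEEntry:
    pme_id: str
    members: frozenset[str]
    support_by_animal: dict[str, float]
    animal_frac: float


@dataclass
class SingleEntry:
    muscle: str
    support_by_animal: dict[str, float]
    animal_frac: float


@dataclass
class SyllableCatalog:
    """Discovered (or planted) syllables: PMEs plus single-muscle syllables."""

    pmes: list[PMEEntry] = field(default_factory=list)
    singles: list[SingleEntry] = field(default_factory=list)
    criteria: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sets = [p.members for p in self.pmes]
        if len(set(sets)) != len(sets):
            raise ValidationError("duplicate PME member sets")
        for p in self.pmes:
            if len(p.members) < 2:
                raise ValidationError(f"PME {p.pme_id} has fewer than 2 members")

    @property
    def pme_sets(self) -> set[frozenset[str]]:
        return {p.members for p in self.pmes}

    @property
    def single_muscles(self) -> set[str]:
        return {s.muscle for s in self.singles}

    def members(self, syllable_id: str) -> tuple[str, ...]:
        for p in self.pmes:
            if p.pme_id == syllable_id:
                return tuple(sorted(p.members, key=natural_key))
        if syllable_id in self.single_muscles:
            return (syllable_id,)
        raise KeyError(syllable_id)

    def to_json(self, path) -> None:
        payload = {
            "pmes": [
                {"id": p.pme_id, "members": sorted(p.members, key=natural_key),
                 "support_by_animal": p.support_by_animal,
                 "animal_frac": p.animal_frac}
                for p in self.pmes
            ],
            "singles": [
                {"muscle": s.muscle, "support_by_animal": s.support_by_animal,
                 "animal_frac": s.animal_frac}
                for s in self.singles
            ],
            "criteria": self.criteria,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SyllableCatalog":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            pmes=[PMEEntry(p["id"], frozenset(p["members"]),
                           p["support_by_animal"], p["animal_frac"])
                  for p in payload["pmes"]],
            singles=[SingleEntry(s["muscle"], s["support_by_animal"], s["animal_frac"])
                     for s in payload["singles"]],
            criteria=payload.get("criteria", {}),
        )


def _coactive_at_least(arrays: dict[str, np.ndarray], members: frozenset[str], w: int) -> bool:
    """True iff all members are simultaneously active for >= w consecutive frames."""
    if not members <= set(arrays):
        return False
    mask = np.logical_and.reduce([arrays[m] for m in members])
    return any(e - s >= w for s, e in _runs(mask))


def discover_pmes(
    events: pd.DataFrame,
    min_overlap_frames: int = 3,
    within_animal_frac: float = 0.8,
    across_animal_frac: float = 0.8,
    unit: str = "bout_id",
) -> SyllableCatalog:
    """Mine PMEs from a multi-animal event table.

    ``unit`` selects the support unit: ``"bout_id"`` (default) or
    ``"movement"`` occurrences.  A muscle set counts toward support in a
    unit whenever all its members are co-active there for at least
    ``min_overlap_frames`` frames.  Candidate sets are the maximal co-active
    sets observed in any unit.  After thresholding, a retained set that is
    a strict subset of another retained set must show independent evidence:
    it is kept only if it is co-active in at least half of the pooled units
    where the superset is *not* co-active (a subset that rides along with
    its superset, plus rare coincidences, is pruned; a genuinely nested
    ensemble recurring on its own is kept).
    """
    _validate_events(events)
    eps = 1e-9
    animals = sorted(events["animal_id"].unique())
    if len(animals) < 2:
        raise ValidationError("PME discovery needs >= 2 animals")
    unit_arrays: dict[str, list[dict[str, np.ndarray]]] = {a: [] for a in animals}
    candidates: set[frozenset[str]] = set()
    for (animal, _), grp in events.groupby(["animal_id", unit]):
        _, arrays = _activity_arrays(grp)
        unit_arrays[animal].append(arrays)
        for g in coactive_groups(grp, min_overlap_frames):
            candidates.add(g.members)
    for a in animals:
        if not unit_arrays[a]:
            raise ValidationError(f"animal {a} has zero units")

    def qualification(members: frozenset[str]) -> np.ndarray:
        return np.array([
            _coactive_at_least(arrays, members, min_overlap_frames)
            for a in animals
            for arrays in unit_arrays[a]
        ])

    unit_animals = np.array([a for a in animals for _ in unit_arrays[a]])
    quals = {s: qualification(s) for s in candidates}

    def support_by_animal(q: np.ndarray) -> dict[str, float]:
        return {a: float(q[unit_animals == a].mean()) for a in animals}

    supports = {s: support_by_animal(quals[s]) for s in candidates}
    n_needed = across_animal_frac * len(animals) - eps

    def animal_frac(sup: dict[str, float]) -> float:
        return float(np.mean([sup[a] >= within_animal_frac - eps for a in animals]))

    retained = [
        s for s in candidates
        if sum(sup >= within_animal_frac - eps for sup in supports[s].values()) >= n_needed
    ]
    # independent-evidence pruning for nested retained sets
    final = []
    for s in retained:
        shadowed = False
        for t in retained:
            if s < t:
                free = ~quals[t]
                if not free.any() or quals[s][free].mean() < 0.5:
                    shadowed = True
                    break
        if not shadowed:
            final.append(s)
    final.sort(key=lambda s: (len(s), tuple(sorted(s, key=natural_key))))
    pmes = [
        PMEEntry(f"PME{i + 1}", s, supports[s], float(animal_frac(supports[s])))
        for i, s in enumerate(final)
    ]
    return SyllableCatalog(
        pmes=pmes,
        criteria={
            "min_overlap_frames": min_overlap_frames,
            "within_animal_frac": within_animal_frac,
            "across_animal_frac": across_animal_frac,
            "unit": unit,
        },
    )


def single_muscle_syllables(
    events: pd.DataFrame,
    catalog: SyllableCatalog,
    within_animal_frac: float = 0.8,
    across_animal_frac: float = 0.8,
    unit: str = "bout_id",
) -> SyllableCatalog:
    """Add single-muscle syllables to a catalog of retained PMEs.

    A muscle qualifies when it is active in enough units of enough animals
    (same thresholds as PME discovery) and is not a member of any retained
    PME -- ensemble membership wins over lone-muscle status.
    """
    _validate_events(events)
    eps = 1e-9
    animals = sorted(events["animal_id"].unique())
    pme_members: set[str] = set().union(*catalog.pme_sets) if catalog.pmes else set()
    singles: list[SingleEntry] = []
    per_unit = {
        a: [set(g["muscle"]) for _, g in grp.groupby(unit)]
        for a, grp in events.groupby("animal_id")
    }
    n_needed = across_animal_frac * len(animals) - eps
    for muscle in sorted(events["muscle"].unique(), key=natural_key):
        if muscle in pme_members:
            continue
        sup = {
            a: float(np.mean([muscle in u for u in per_unit[a]])) for a in animals
        }
        qualifying = sum(s >= within_animal_frac - eps for s in sup.values())
        if qualifying >= n_needed:
            singles.append(SingleEntry(muscle, sup, qualifying / len(animals)))
    return SyllableCatalog(pmes=catalog.pmes, singles=singles, criteria=catalog.criteria)


@dataclass
class SyllableEvent:
    """One realized syllable occurrence within a bout."""

    syllable: str
    bout_id: object
    onset_frame: int
    interval: tuple[int, int]
    is_pme: bool


def annotate_syllables(
    bout_events: pd.DataFrame,
    catalog: SyllableCatalog,
    min_overlap_frames: int = 3,
) -> tuple[list[SyllableEvent], float]:
    """Annotate one bout's activations with syllable events.

    Each activation is assigned to at most one syllable event: PME events in
    order of their co-active interval onset (ties broken by catalog order),
    then single-muscle syllables.  Returns the events and the fraction of
    activations left unassigned (off-syllable activity).
    """
    if not catalog.pmes and not catalog.singles:
        raise ValidationError("catalog is empty")
    _validate_events(bout_events)
    n = len(bout_events)
    if n == 0:
        return [], 0.0
    t0, arrays = _activity_arrays(bout_events)
    bout_id = bout_events["bout_id"].iloc[0] if "bout_id" in bout_events else None
    assigned = np.zeros(n, dtype=bool)
    onsets = bout_events["onset_frame"].to_numpy()
    offsets = bout_events["offset_frame"].to_numpy()
    muscles = bout_events["muscle"].to_numpy()
    events: list[SyllableEvent] = []
    pme_occurrences: list[tuple[int, int, PMEEntry]] = []
    for p in catalog.pmes:
        if not p.members <= set(arrays):
            continue
        mask = np.logical_and.reduce([arrays[m] for m in p.members])
        for s, e in _runs(mask):
            if e - s >= min_overlap_frames:
                pme_occurrences.append((s + t0, e + t0, p))
    # maximality: larger ensembles claim their activations first, so a
    # nested ensemble's occurrence inside a superset's window (where the
    # same events explain both) yields no additional annotation, while a
    # standalone occurrence of the nested ensemble keeps its own events
    pme_occurrences.sort(key=lambda x: (-len(x[2].members), x[0], x[2].pme_id))
    for s, e, p in pme_occurrences:
        hit = np.zeros(n, dtype=bool)
        for i in range(n):
            if assigned[i] or muscles[i] not in p.members:
                continue
            # a true member's event spans the whole co-active window; require
            # at least the detection window of overlap so grazing activity of
            # a member muscle is not swept in
            if min(e, offsets[i]) - max(s, onsets[i]) >= min_overlap_frames:
                hit[i] = True
        if not hit.any():
            continue
        assigned |= hit
        events.append(SyllableEvent(
            p.pme_id, bout_id, int(onsets[hit].min()), (s, e), True,
        ))
    for single in catalog.singles:
        for i in range(n):
            if not assigned[i] and muscles[i] == single.muscle:
                assigned[i] = True
                events.append(SyllableEvent(
                    single.muscle, bout_id, int(onsets[i]),
                    (int(onsets[i]), int(offsets[i])), False,
                ))
    events.sort(key=lambda ev: (ev.onset_frame, ev.syllable))
    off_fraction = float((~assigned).sum() / n)
    return events, off_fraction


def coactive_duration_share(
    syllable_events: list[SyllableEvent], min_overlap_frames: int = 3
) -> float:
    """Mean fraction of each PME event's co-active duration represented by
    the ``min_overlap_frames`` detection window."""
    durations = [
        ev.interval[1] - ev.interval[0] for ev in syllable_events if ev.is_pme
    ]
    if not durations:
        raise InsufficientDataError("no PME events")
    return float(np.mean([min_overlap_frames / d for d in durations]))
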