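"""Ground-truthed synthetic pupal-ecdysis recordings.

The generator emulates the statistical structure the downstream analyses
assume: a multiphasic sequence (P0 twitching, P1 Lift/RollCon, P2
Swing/Brace, P3 compartmentalized blocks) built from bouts of syllable
activations.  Each planted movement activates its syllable vocabulary with
configurable recruitment-order jitter between syllables, small
within-ensemble jitter among PME members, and idiosyncratic off-syllable
activations.  Per-muscle traces convolve activation onsets with a
GCaMP-like kernel (instant rise, single-exponential decay); movies are
rendered by painting traces into hemisegment ROIs.

Neuromodulator-suppression perturbation modes remove or desynchronize
specific syllables and phases, mirroring the published Kir2.1 silencing
phenotypes of ETHRB-, CCAP-, Bursicon-, and class-I-da-expressing neurons.

Time is measured in frames at ``fps`` (default 2 Hz); all intervals are
half-open and 0-based.  Every stochastic choice flows from ``config.seed``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon

from .ensembles import PMEEntry, SingleEntry, SyllableCatalog
from .errors import InvalidConfigError
from .muscles import MuscleMap, make_muscle_map, natural_key
from .segmentation import Bout
from .signal import PeakTrain
from .syllabary import (
    DEFAULT_DIRECTIONS,
    DEFAULT_PMES,
    DEFAULT_SINGLES,
    DEFAULT_SYLLABARY,
    syllable_members,
)

PERTURBATIONS = (
    "none",
    "ethrb_suppressed",
    "ccap_suppressed",
    "burs_suppressed",
    "class1da_suppressed",
)

#: Segment ranges movements occupy (fractions of the A-P axis); movements
#: not listed span the whole axis.
_SEGMENT_RANGE: dict[str, tuple[float, float]] = {
    "Lift": (0.6, 1.0),       # posterior compartment
    "AntComp": (0.0, 0.5),    # anterior compartment
    "PostCon": (0.6, 1.0),
    "PostSwing": (0.6, 1.0),
}

EVENT_COLUMNS = (
    "animal_id", "phase", "bout_id", "movement", "muscle", "segment", "side",
    "onset_frame", "offset_frame", "peak_frame",
    "f_onset", "f_max", "length_onset_um", "length_min_um",
)


@dataclass
class PhaseSpec:
    """Bout plan for one phase.

    ``bout_movements`` lists the movement composition of each bout (cycled
    when shorter than ``n_bouts``).  Inter-bout rest durations are
    log-normal around ``interbout_median`` frames; ``tempo_sigma`` scales
    per-bout log-normal jitter of the syllable stagger and is the knob that
    makes one phase's durations more or less variable than another's.
    """

    n_bouts: int
    bout_movements: tuple[tuple[str, ...], ...]
    interbout_median: float = 20.0
    interbout_sigma: float = 0.25
    tempo_sigma: float = 0.2
    jitter_scale: float = 1.0


def default_phase_plan() -> dict[str, PhaseSpec]:
    # P2 carries the least duration noise: its execution is the most tightly
    # regulated phase, and the generator emulates that.
    return {
        "P0": PhaseSpec(5, (("P0",),), 25.0, 0.40, 0.30),
        "P1": PhaseSpec(8, (("Lift", "RollCon"),), 20.0, 0.30, 0.25),
        "P2": PhaseSpec(6, (("Swing", "Brace"),), 15.0, 0.08, 0.06, jitter_scale=0.5),
        "P3": PhaseSpec(5, (("Crunch", "AntComp", "PostCon", "PostSwing"),), 30.0, 0.35, 0.30),
    }


@dataclass
class Kinetics:
    """Ca++ indicator kernel: instant rise, exponential decay (GCaMP6s-like
    decay of ~3 s = 6 frames at 2 Hz).  Event amplitudes come from the
    planted per-contraction dF/F (see :class:`MechanicsModel`)."""

    decay_tau: float = 6.0


@dataclass
class MechanicsModel:
    """Planted per-contraction mechanics.

    dF/F (percent) and dL/L (percent shortening) are drawn from a bivariate
    normal with correlation ``fluorescence_shortening_corr``; lateral PME2
    muscles additionally carry a posterior-to-anterior shortening gradient
    (A5 > A4 > A3).
    """

    dl_mean: dict = field(default_factory=lambda: {"P0": 15.0, "P1": 30.0, "P2": 35.0, "P3": 30.0})
    dl_sd: float = 8.0
    df_mean: float = 150.0
    df_sd: float = 60.0
    fluorescence_shortening_corr: float = -0.54
    length_mean_um: float = 100.0
    length_sd_um: float = 10.0
    pme2_gradient: float = 5.0  # extra dL/L per segment toward posterior


@dataclass
class SimulationConfig:
    seed: int = 0
    fps: float = 2.0
    animal_id: str = "A0"
    phase_plan: dict[str, PhaseSpec] = field(default_factory=default_phase_plan)
    syllabary: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_SYLLABARY))
    pmes: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_PMES))
    singles: tuple[str, ...] = DEFAULT_SINGLES
    #: when set, bouts ignore the movement syllabary: every planted syllable
    #: appears in exactly round(syllable_support * n_bouts) bouts, in random
    #: order (the support-planting mode used for ensemble-recovery studies)
    syllable_support: float | None = None
    support_n_bouts: int = 20
    #: onset jitter of syllable occurrences, comparable to the inter-syllable
    #: stagger by default: recruitment order within movements is variable,
    #: while the compartmental wave progression stays organized
    recruitment_jitter_sd: float = 3.0
    within_ensemble_jitter: int = 1
    idiosyncratic_rate: float = 0.1
    syllable_stagger: int = 3
    event_duration: int = 5
    kinetics: Kinetics = field(default_factory=Kinetics)
    mechanics: MechanicsModel = field(default_factory=MechanicsModel)
    noise_sd: float = 0.02
    initial_rest: int = 60
    min_gap: int = 2
    switch_failure_p: float = 0.1
    p0_syllables_per_bout: int = 3
    perturbation: str = "none"

    def __post_init__(self) -> None:
        for name in ("idiosyncratic_rate", "switch_failure_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name}={v} outside [0, 1]")
        if self.syllable_support is not None and not 0.0 <= self.syllable_support <= 1.0:
            raise InvalidConfigError("syllable_support outside [0, 1]")
        if self.fps <= 0:
            raise InvalidConfigError("fps must be > 0")
        if self.recruitment_jitter_sd < 0 or self.within_ensemble_jitter < 0:
            raise InvalidConfigError("jitters must be non-negative")
        if self.event_duration < 1 or self.syllable_stagger < 1:
            raise InvalidConfigError("durations must be positive")
        if self.perturbation not in PERTURBATIONS:
            raise InvalidConfigError(
                f"unknown perturbation {self.perturbation!r}; choose from {PERTURBATIONS}"
            )
        for movement, syls in self.syllabary.items():
            if len(syls) == 0:
                raise InvalidConfigError(f"empty syllabary for movement {movement!r}")

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=list)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            payload = json.load(fh)
        if "seed" not in payload:
            raise InvalidConfigError("persisted configs must carry a seed")
        payload["phase_plan"] = {
            k: PhaseSpec(**{**v, "bout_movements": tuple(tuple(m) for m in v["bout_movements"])})
            for k, v in payload.get("phase_plan", {}).items()
        }
        payload["kinetics"] = Kinetics(**payload.get("kinetics", {}))
        payload["mechanics"] = MechanicsModel(**payload.get("mechanics", {}))
        payload["syllabary"] = {k: tuple(v) for k, v in payload.get("syllabary", {}).items()}
        payload["pmes"] = {k: tuple(v) for k, v in payload.get("pmes", {}).items()}
        payload["singles"] = tuple(payload.get("singles", DEFAULT_SINGLES))
        return cls(**payload)


def apply_perturbation(config: SimulationConfig, mode: str) -> SimulationConfig:
    """Return a config with a neuromodulator-suppression mode set."""
    if mode not in PERTURBATIONS:
        raise InvalidConfigError(f"unknown perturbation mode {mode!r}")
    if mode == config.perturbation:
        return config
    return dataclasses.replace(config, perturbation=mode)


@dataclass
class GroundTruth:
    """Planted truth for parameter-recovery tests."""

    phase_intervals: dict[str, tuple[int, int]]
    bouts: list[Bout]
    planted_syllables: SyllableCatalog
    recruitment_orders: dict[int, tuple[str, ...]]
    directions: dict[str, str | None]
    frame_labels: np.ndarray
    n_frames: int


@dataclass
class Recording:
    """One simulated animal: event table, per-muscle traces, ground truth."""

    events: pd.DataFrame
    traces: dict[tuple[str, str, str], np.ndarray]
    truth: GroundTruth
    config: SimulationConfig
    muscle_map: MuscleMap

    @property
    def n_frames(self) -> int:
        return self.truth.n_frames

    def bulk_trace(self) -> np.ndarray:
        return np.sum(list(self.traces.values()), axis=0)


@dataclass
class _BoutPlan:
    phase: str
    movements: tuple[str, ...]
    side: str
    desync: frozenset[str] = frozenset()   # syllables whose members desynchronize
    segment_window: tuple[float, float] | None = None
    sustained: bool = False
    excluded_muscles: frozenset[str] = frozenset()
    support_syllables: tuple[str, ...] = ()


def _build_plan(config: SimulationConfig, rng: np.random.Generator) -> list[_BoutPlan]:
    mode = config.perturbation
    plans: list[_BoutPlan] = []
    side = "L"

    def next_side() -> str:
        nonlocal side
        out = side
        if rng.random() >= config.switch_failure_p:
            side = "R" if side == "L" else "L"
        return out

    if config.syllable_support is not None:
        n = config.support_n_bouts
        tokens = list(config.pmes) + list(config.singles)
        quota = int(round(config.syllable_support * n))
        include = {t: set(rng.choice(n, size=quota, replace=False).tolist()) for t in tokens}
        for b in range(n):
            present = [t for t in tokens if b in include[t]]
            order = rng.permutation(len(present))
            plans.append(_BoutPlan(
                "P1", ("Mixed",), next_side(),
                support_syllables=tuple(present[i] for i in order),
            ))
        return plans

    phases = list(config.phase_plan)
    if mode == "class1da_suppressed":
        phases = [p for p in phases if p == "P0"]
    elif mode in ("ccap_suppressed", "burs_suppressed"):
        phases = [p for p in phases if p in ("P0", "P1")]

    for phase in phases:
        spec = config.phase_plan[phase]
        for b in range(spec.n_bouts):
            movements = spec.bout_movements[b % len(spec.bout_movements)]
            desync: frozenset[str] = frozenset()
            excluded: frozenset[str] = frozenset()
            if mode == "ethrb_suppressed" and phase == "P1":
                movements = tuple(m for m in movements if m != "Lift") or ("RollCon",)
                desync = frozenset({"PME1"})
                excluded = frozenset({"M1", "M15"})
            plans.append(_BoutPlan(
                phase, movements, next_side(),
                desync=desync,
                sustained=(mode == "class1da_suppressed"),
                excluded_muscles=excluded,
            ))

    if mode == "ccap_suppressed":
        # a single partial swing-like movement confined to posterior
        # segments, with D-V compartments desynchronized; P1-like bouts
        # continue briefly, then the recording truncates
        plans.append(_BoutPlan(
            "P1", ("Swing",), next_side(),
            desync=frozenset(s for s in config.syllabary["Swing"]),
            segment_window=(0.6, 1.0),
        ))
        for _ in range(2):
            plans.append(_BoutPlan("P1", ("RollCon",), next_side()))
    elif mode == "burs_suppressed":
        # one full-length swing-like wave (D-V desynchronized) followed by
        # sparse P3-like movements
        plans.append(_BoutPlan(
            "P1", ("Swing",), next_side(),
            desync=frozenset(s for s in config.syllabary["Swing"]),
        ))
        plans.append(_BoutPlan("P3", ("Crunch",), next_side()))
        plans.append(_BoutPlan("P3", ("AntComp",), next_side()))
    return plans


_STAGE_ORDER = ("ventral", "dorsal", "lateral")


def _stage_ordered(
    syls: tuple[str, ...],
    pmes: dict[str, tuple[str, ...]],
    rng: np.random.Generator | None,
) -> tuple[str, ...]:
    """Order a movement's syllables by their dominant D-V compartment
    (ventral leads, dorsal follows, lateral outlasts), permuting syllables
    within each stage when ``rng`` is given."""
    from .muscles import DV_COMPARTMENT

    def stage(syl: str) -> int:
        members = syllable_members(syl, pmes)
        dvs = [DV_COMPARTMENT[m] for m in members]
        best = max(_STAGE_ORDER, key=lambda c: (dvs.count(c), -_STAGE_ORDER.index(c)))
        return _STAGE_ORDER.index(best)

    staged: dict[int, list[str]] = {}
    for s in syls:
        staged.setdefault(stage(s), []).append(s)
    out: list[str] = []
    for idx in sorted(staged):
        block = staged[idx]
        if rng is not None:
            block = [block[i] for i in rng.permutation(len(block))]
        out.extend(block)
    return tuple(out)


def _repair_gaps(frames: list[int], min_gap: int) -> dict[int, int]:
    """Order-preserving map closing onset-free gaps > min_gap within a bout."""
    uniq = sorted(set(frames))
    mapping: dict[int, int] = {}
    shift = 0
    prev = None
    for u in uniq:
        nu = u - shift
        if prev is not None and nu - prev > min_gap:
            shift += nu - prev - min_gap
            nu = prev + min_gap
        mapping[u] = nu
        prev = nu
    return mapping


def _single_tokens(config: SimulationConfig) -> set[str]:
    """All bare-muscle syllable tokens: the configured singles plus any
    lone-muscle tokens appearing in the movement syllabary (Table-style
    vocabularies let PME members such as M1 or M8 also act alone)."""
    bare = {
        syl for syls in config.syllabary.values() for syl in syls
        if syl not in config.pmes
    }
    return bare | set(config.singles)


def _planted_catalog(config: SimulationConfig) -> SyllableCatalog:
    support = config.syllable_support if config.syllable_support is not None else 1.0
    return SyllableCatalog(
        pmes=[PMEEntry(pid, frozenset(members), {}, support)
              for pid, members in config.pmes.items()],
        singles=[SingleEntry(m, {}, support)
                 for m in sorted(_single_tokens(config), key=natural_key)],
        criteria={"planted": True},
    )


def simulate_recording(config: SimulationConfig, muscle_map: MuscleMap | None = None) -> Recording:
    """Simulate one animal.  Deterministic given ``config.seed``."""
    if muscle_map is None:
        muscle_map = make_muscle_map()
    for movement, syls in config.syllabary.items():
        for syl in syls:
            for m in syllable_members(syl, config.pmes):
                if m not in {mm.label for mm in muscle_map.muscles}:
                    raise InvalidConfigError(
                        f"syllabary references muscle {m} absent from map"
                    )
    rng = np.random.default_rng(config.seed)
    plans = _build_plan(config, rng)
    n_seg = len(muscle_map.segments)
    mech = config.mechanics
    rho = mech.fluorescence_shortening_corr

    rows: list[dict] = []
    truth_bouts: list[Bout] = []
    recruitment: dict[int, tuple[str, ...]] = {}
    label_spans: list[tuple[int, int, str]] = []  # (start, end, movement label)

    t = config.initial_rest
    for bout_id, bp in enumerate(plans):
        duration = config.event_duration * (4 if bp.sustained else 1)
        phase_spec = config.phase_plan.get(bp.phase, PhaseSpec(1, ((),)))
        stagger = max(1, int(round(
            config.syllable_stagger * rng.lognormal(0.0, phase_spec.tempo_sigma))))
        jitter_sd = config.recruitment_jitter_sd * phase_spec.jitter_scale
        # lead-in so negative onset jitter is not clamped at the bout start,
        # which would pin the first occurrences into a fixed order
        cursor_offset = int(round(2.0 * jitter_sd))
        bout_rows: list[dict] = []
        cursor = t + cursor_offset
        occurrence = 0
        for movement in bp.movements:
            if movement == "Mixed":
                syls = bp.support_syllables
            elif movement == "P0":
                pool = list(config.syllabary["P0"])
                k = min(len(pool), config.p0_syllables_per_bout * (3 if bp.sustained else 1))
                syls = tuple(pool[i] for i in sorted(rng.choice(len(pool), size=k, replace=False)))
                syls = tuple(syls[i] for i in rng.permutation(len(syls)))
            else:
                # movements execute a fixed compartmental program: syllables
                # run in canonical D-V stage order, but recruitment order
                # within a stage is scrambled anew each bout (unless the
                # recruitment-noise knob is zeroed for the stereotyped limit)
                syls = _stage_ordered(
                    config.syllabary[movement], config.pmes,
                    rng if jitter_sd > 0 else None,
                )
            direction = DEFAULT_DIRECTIONS.get(movement)
            lo, hi = bp.segment_window or _SEGMENT_RANGE.get(movement, (0.0, 1.0))
            seg_lo = int(round(lo * (n_seg - 1)))
            seg_hi = int(round(hi * (n_seg - 1)))
            n_syl = len(syls)
            for k, syl in enumerate(syls):
                base = cursor + k * stagger
                jitter = int(round(rng.normal(0.0, jitter_sd)))
                syl_onset = max(t, base + jitter)
                frac = k / max(1, n_syl - 1)
                if direction == "P_to_A":
                    seg_idx = int(round(seg_hi - frac * (seg_hi - seg_lo)))
                elif direction == "A_to_P":
                    seg_idx = int(round(seg_lo + frac * (seg_hi - seg_lo)))
                else:
                    seg_idx = int(rng.integers(seg_lo, seg_hi + 1))
                members = syllable_members(syl, config.pmes)
                desynced = syl in bp.desync
                # the Brace accompanies its Swing contralaterally
                if movement == "Brace" and len(muscle_map.sides) > 1:
                    side = "R" if bp.side == "L" else "L"
                else:
                    side = bp.side
                occurrence += 1
                for mi, muscle in enumerate(members):
                    if muscle in bp.excluded_muscles:
                        continue
                    if bp.segment_window is not None and not any(
                        muscle_map.present(muscle, muscle_map.segments[s])
                        for s in range(seg_lo, seg_hi + 1)
                    ):
                        continue
                    if desynced:
                        offset = mi * (duration - 1)
                    elif config.within_ensemble_jitter > 0:
                        offset = int(rng.integers(-config.within_ensemble_jitter,
                                                  config.within_ensemble_jitter + 1))
                    else:
                        offset = 0
                    onset = max(t, syl_onset + offset)
                    seg = seg_idx
                    floor_seg = seg_lo if bp.segment_window is not None else 0
                    while not muscle_map.present(muscle, muscle_map.segments[seg]) and seg > floor_seg:
                        seg -= 1
                    if not muscle_map.present(muscle, muscle_map.segments[seg]):
                        continue
                    bout_rows.append({
                        "movement": movement if movement not in ("P0", "Mixed") else "Rest",
                        "syllable": syl,
                        "syllable_occurrence": occurrence,
                        "muscle": muscle,
                        "segment": muscle_map.segments[seg],
                        "side": side,
                        "onset_frame": onset,
                        "offset_frame": onset + duration,
                        "idiosyncratic": False,
                    })
            cursor += n_syl * stagger
        if not bout_rows:
            continue
        # close onset gaps so the planted bout is one segmentable unit
        mapping = _repair_gaps([r["onset_frame"] for r in bout_rows], config.min_gap)
        for r in bout_rows:
            delta = mapping[r["onset_frame"]] - r["onset_frame"]
            r["onset_frame"] += delta
            r["offset_frame"] += delta
        # idiosyncratic activations: any non-single roster muscle, placed
        # away from the co-activity of ensembles sharing that muscle so the
        # activation is genuinely off-syllable
        k_planted = len(bout_rows)
        single_tokens = _single_tokens(config)
        pool = [m for m in muscle_map.labels
                if m not in single_tokens and m not in bp.excluded_muscles]
        rate = config.idiosyncratic_rate
        min_overlap = 3
        if pool and rate > 0 and k_planted:
            n_idio = rng.binomial(k_planted, min(1.0, rate / (1.0 - rate)))
            first = min(r["onset_frame"] for r in bout_rows)
            last = max(r["onset_frame"] for r in bout_rows)
            span0 = first
            span1 = max(r["offset_frame"] for r in bout_rows) + duration
            activity: dict[str, np.ndarray] = {}
            for r in bout_rows:
                a = activity.setdefault(r["muscle"], np.zeros(span1 - span0, dtype=bool))
                a[r["onset_frame"] - span0:r["offset_frame"] - span0] = True

            def _captured(muscle: str, onset: int) -> bool:
                # would this activation look like part of a syllable?  yes if
                # it overlaps same-muscle activity at all, or co-activity of
                # all other members of a shared ensemble long enough to form
                # a detection window
                i0, i1 = onset - span0, onset - span0 + duration
                own = activity.get(muscle)
                if own is not None and own[i0:i1].any():
                    return True
                for members in config.pmes.values():
                    if muscle not in members:
                        continue
                    others = [activity.get(m) for m in members if m != muscle]
                    if any(o is None for o in others):
                        continue
                    both = np.logical_and.reduce([o[i0:i1] for o in others])
                    run = best = 0
                    for v in both:
                        run = run + 1 if v else 0
                        best = max(best, run)
                    if best >= min_overlap:
                        return True
                return False

            for _ in range(n_idio):
                placed = False
                for _attempt in range(20):
                    muscle = pool[int(rng.integers(len(pool)))]
                    onset = int(rng.integers(first, last + 1))
                    if not _captured(muscle, onset):
                        placed = True
                        break
                if not placed:
                    # exhaustive fallback: scan muscles and onsets in random
                    # order; fail only when the bout is truly saturated
                    for mi in rng.permutation(len(pool)):
                        muscle = pool[int(mi)]
                        for on in rng.permutation(last - first + 1):
                            onset = first + int(on)
                            if not _captured(muscle, onset):
                                placed = True
                                break
                        if placed:
                            break
                if not placed:
                    continue
                if bp.segment_window is not None:
                    w_lo = int(round(bp.segment_window[0] * (n_seg - 1)))
                    w_hi = int(round(bp.segment_window[1] * (n_seg - 1)))
                else:
                    w_lo, w_hi = 0, n_seg - 1
                seg = int(rng.integers(w_lo, w_hi + 1))
                while not muscle_map.present(muscle, muscle_map.segments[seg]) and seg > w_lo:
                    seg -= 1
                if not muscle_map.present(muscle, muscle_map.segments[seg]):
                    continue
                bout_rows.append({
                    "movement": bout_rows[0]["movement"],
                    "syllable": "",
                    "syllable_occurrence": 0,
                    "muscle": muscle,
                    "segment": muscle_map.segments[seg],
                    "side": bp.side,
                    "onset_frame": onset,
                    "offset_frame": onset + duration,
                    "idiosyncratic": True,
                })
                a = activity.setdefault(muscle, np.zeros(span1 - span0, dtype=bool))
                a[onset - span0:onset - span0 + duration] = True
        first = min(r["onset_frame"] for r in bout_rows)
        last_on = max(r["onset_frame"] for r in bout_rows)
        last_off = max(r["offset_frame"] for r in bout_rows)
        # per-movement frame-label spans (planted events only)
        move_firsts: list[tuple[int, str]] = []
        for movement in bp.movements:
            label = movement if movement not in ("P0", "Mixed") else "Rest"
            ons = [r["onset_frame"] for r in bout_rows
                   if r["movement"] == label and not r["idiosyncratic"]]
            if ons:
                move_firsts.append((min(ons), label))
        move_firsts.sort()
        for i, (start, label) in enumerate(move_firsts):
            end = move_firsts[i + 1][0] if i + 1 < len(move_firsts) else last_off
            label_spans.append((start, end, label))
        for r in bout_rows:
            r["animal_id"] = config.animal_id
            r["phase"] = bp.phase
            r["bout_id"] = bout_id
            r["peak_frame"] = r["onset_frame"]
        # planted mechanics: correlated (dF/F, dL/L) pair per contraction
        for r in bout_rows:
            z1 = rng.standard_normal()
            z2 = rho * z1 + math.sqrt(1.0 - rho * rho) * rng.standard_normal()
            df = float(np.clip(mech.df_mean + mech.df_sd * z1, 5.0, 400.0))
            dl = mech.dl_mean.get(bp.phase, 25.0) + mech.dl_sd * z2
            if r["muscle"] in ("M21", "M22", "M23"):
                seg_idx = muscle_map.segments.index(r["segment"])
                dl += mech.pme2_gradient * (seg_idx - (muscle_map.ap_boundary - 1))
            dl = float(np.clip(dl, 0.5, 70.0))
            f_onset = float(np.clip(rng.normal(100.0, 5.0), 10.0, None))
            length = float(np.clip(
                rng.normal(mech.length_mean_um, mech.length_sd_um), 20.0, None))
            r["f_onset"] = round(f_onset, 3)
            r["f_max"] = round(f_onset * (1.0 + df / 100.0), 3)
            r["length_onset_um"] = round(length, 3)
            r["length_min_um"] = round(length * (1.0 - dl / 100.0), 3)
        rows.extend(bout_rows)
        truth_bouts.append(Bout(
            first, last_on + 1, phase=bp.phase,
            movements=tuple(lbl for _, lbl in move_firsts),
            animal_id=config.animal_id, bout_id=bout_id,
        ))
        occ_onsets: dict[int, tuple[int, str]] = {}
        for r in bout_rows:
            if r["idiosyncratic"]:
                continue
            occ = r["syllable_occurrence"]
            if occ not in occ_onsets or r["onset_frame"] < occ_onsets[occ][0]:
                occ_onsets[occ] = (r["onset_frame"], r["syllable"])
        recruitment[bout_id] = tuple(
            syl for _, syl in sorted(occ_onsets.values())
        )
        spec = config.phase_plan.get(bp.phase)
        median = spec.interbout_median if spec else 20.0
        sigma = spec.interbout_sigma if spec else 0.25
        rest = max(config.min_gap + 1,
                   int(round(rng.lognormal(math.log(median), sigma))))
        t = last_on + 1 + rest

    events = pd.DataFrame(rows)
    events["_mkey"] = events["muscle"].map(lambda m: natural_key(m)[1])
    events = (
        events.sort_values(["onset_frame", "_mkey"], kind="stable")
        .drop(columns="_mkey")
        .reset_index(drop=True)
    )
    tail = int(4 * config.kinetics.decay_tau)
    n_frames = int(events["offset_frame"].max()) + tail

    # phase intervals: start of a phase's first bout to the next phase's start
    phase_starts: dict[str, int] = {}
    for b in truth_bouts:
        phase_starts.setdefault(b.phase, b.start)
    ordered = sorted(phase_starts.items(), key=lambda kv: kv[1])
    phase_intervals: dict[str, tuple[int, int]] = {}
    for i, (phase, start) in enumerate(ordered):
        end = ordered[i + 1][1] if i + 1 < len(ordered) else n_frames
        phase_intervals[phase] = (0 if i == 0 else start, end)

    frame_labels = np.full(n_frames, "Rest", dtype=object)
    for start, end, label in label_spans:
        frame_labels[start:min(end, n_frames)] = label

    truth = GroundTruth(
        phase_intervals, truth_bouts, _planted_catalog(config), recruitment,
        dict(DEFAULT_DIRECTIONS), frame_labels, n_frames,
    )

    traces: dict[tuple[str, str, str], np.ndarray] = {}
    tau = config.kinetics.decay_tau
    kernel = np.exp(-np.arange(n_frames) / tau)
    by_cell = events.groupby(["muscle", "segment", "side"])
    for cell in muscle_map.muscles:
        tr = np.zeros(n_frames)
        key = cell.key
        if key in by_cell.groups:
            grp = by_cell.get_group(key)
            for on, f0, fmax in zip(grp["onset_frame"], grp["f_onset"], grp["f_max"]):
                amp = (fmax - f0) / f0
                tr[on:] += amp * kernel[: n_frames - on]
        if config.noise_sd > 0:
            tr = tr + rng.normal(0.0, config.noise_sd, n_frames)
        traces[key] = tr

    return Recording(events, traces, truth, config, muscle_map)


def simulate_cohort(
    config: SimulationConfig,
    n_animals: int,
    muscle_map: MuscleMap | None = None,
) -> tuple[list[Recording], pd.DataFrame]:
    """Simulate several animals with per-animal seeds derived from the
    config seed; returns the recordings and the concatenated event table."""
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_animals)
    recs = []
    for i, s in enumerate(seeds):
        c = dataclasses.replace(config, seed=int(s), animal_id=f"A{i}")
        recs.append(simulate_recording(c, muscle_map))
    events = pd.concat([r.events for r in recs], ignore_index=True)
    return recs, events


def render_frames(
    recording: Recording,
    frame_shape: tuple[int, int] | None = None,
    background: float = 100.0,
    gain: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    dtype=np.uint16,
) -> np.ndarray:
    """Render per-muscle traces into an (N, H, W) movie.

    Pixel intensity inside a muscle's ROI at frame t is
    ``background + gain * trace[t]`` (plus optional Gaussian pixel noise).
    Row 0 is anterior.  Requires a muscle map with ROI polygons.
    """
    mmap = recording.muscle_map
    if not mmap.roi_geometry:
        raise InvalidConfigError("muscle map has no ROIs; build it with with_rois=True")
    shape = frame_shape or mmap.frame_shape
    if shape is None:
        raise InvalidConfigError("frame_shape required")
    n = recording.n_frames
    stack = np.full((n, *shape), float(background))
    for key, poly in mmap.roi_geometry.items():
        if key not in recording.traces:
            continue
        rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape)
        if rr.size == 0:
            raise InvalidConfigError(f"ROI for {key} rasterizes to nothing")
        tr = np.clip(recording.traces[key], 0.0, None)
        stack[:, rr, cc] += gain * tr[:, None]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stack = stack + rng.normal(0.0, noise_sd, stack.shape)
    info = np.iinfo(dtype) if np.issubdtype(np.dtype(dtype), np.integer) else None
    if info is not None:
        stack = np.clip(stack, info.min, info.max)
    return stack.astype(dtype)


def simulate_wave_movie(
    direction: str,
    seed: int = 0,
    noise_sd: float = 0.0,
    n_segments: int = 7,
    gain: float = 1000.0,
    amplitude: float = 1.5,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Render a single movement's traveling activity wave.

    Returns ``(stack, bout_window)`` where the wave traverses segment bands
    toward anterior rows for ``direction="P_to_A"`` and toward posterior
    rows for ``"A_to_P"``.  ``noise_sd`` is pixel noise in intensity units
    (the wave's peak signal above background is ``gain * amplitude``).
    """
    if direction not in ("P_to_A", "A_to_P"):
        raise InvalidConfigError(f"bad direction {direction!r}")
    movement = "Swing" if direction == "P_to_A" else "Crunch"
    cfg = SimulationConfig(
        seed=seed,
        phase_plan={"P1": PhaseSpec(1, ((movement,),), 10.0, 0.0, 0.0)},
        idiosyncratic_rate=0.0,
        recruitment_jitter_sd=0.0,
        within_ensemble_jitter=0,
        noise_sd=0.0,
        initial_rest=2,
        kinetics=Kinetics(decay_tau=2.0),
        mechanics=MechanicsModel(df_mean=amplitude * 100.0, df_sd=0.0),
    )
    mmap = make_muscle_map(n_segments=n_segments, with_rois=True)
    rec = simulate_recording(cfg, mmap)
    stack = render_frames(rec, gain=gain, noise_sd=noise_sd, seed=seed, dtype=np.float64)
    b = rec.truth.bouts[0]
    return stack, (b.start, int(rec.events["offset_frame"].max()))


def simulate_coupled_peak_trains(
    coupling_p: float,
    n_frames: int = 2000,
    density: float = 0.05,
    seed: int | None = None,
) -> tuple[PeakTrain, PeakTrain]:
    """Muscle/NMJ peak trains with planted coupling probability.

    Each muscle peak is echoed in the NMJ train with probability
    ``coupling_p``; the NMJ train is topped up with independent peaks so its
    density matches the muscle train's.
    """
    if not 0.0 <= coupling_p <= 1.0:
        raise InvalidConfigError("coupling_p outside [0, 1]")
    rng = np.random.default_rng(seed)
    n_peaks = int(round(density * n_frames))
    muscle = np.sort(rng.choice(n_frames, size=n_peaks, replace=False))
    keep = rng.random(n_peaks) < coupling_p
    echoed = set(muscle[keep].tolist())
    candidates = np.setdiff1d(np.arange(n_frames), muscle)
    extra = rng.choice(candidates, size=n_peaks - int(keep.sum()), replace=False)
    nmj = np.sort(np.array(sorted(echoed | set(extra.tolist())), dtype=int))
    return (
        PeakTrain(muscle, label="muscle"),
        PeakTrain(nmj, label="nmj"),
    )
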