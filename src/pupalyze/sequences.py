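"""Activation-order sequences and gestalt (Ratcliff-Obershelp) stereotypy
scoring with a shuffled-sequence permutation null.

Two token sequences are compared with the gestalt ratio 2M/T, where M is
the total number of matched tokens found by recursively locating the
longest common contiguous block (ties broken by earliest start in the
first sequence, then the second) and recursing on both flanks, and T is
the combined length.  This is exactly ``difflib.SequenceMatcher`` with the
junk/popularity heuristics disabled, which is what we use.  Note the score
is a pure function of the *ordered* pair: the first-sequence-anchored tie
break makes it order-dependent for some pairs (e.g. ("A","B") vs
("B","A","C","B") scores 2/3 one way and 1/3 the other); sequences are
always compared in a fixed, documented order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from difflib import SequenceMatcher

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .muscles import natural_key

LEVELS = ("muscle", "syllable", "compartment", "movement")


@dataclass(frozen=True)
class TokenSequence:
    """An ordered sequence of activation tokens from one scoring unit."""

    tokens: tuple[str, ...]
    level: str = "muscle"
    animal_id: str | None = None
    phase: str | None = None
    unit_id: object = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValidationError(f"unknown level {self.level!r}")

    def __len__(self) -> int:
        return len(self.tokens)


def activation_order(
    onsets,
    labels,
    level: str = "muscle",
    animal_id: str | None = None,
    phase: str | None = None,
    unit_id: object = None,
) -> TokenSequence:
    """Order tokens by onset frame, breaking ties by natural label order
    (M2 before M12).  Repeated tokens are retained."""
    onsets = np.asarray(list(onsets))
    labels = list(labels)
    if len(onsets) != len(labels):
        raise ValidationError("onsets and labels differ in length")
    order = sorted(range(len(labels)), key=lambda i: (onsets[i], natural_key(labels[i])))
    return TokenSequence(tuple(labels[i] for i in order), level, animal_id, phase, unit_id)


def muscle_sequence(bout_events: pd.DataFrame, **src) -> TokenSequence:
    """Muscle-level activation order of one bout's event table."""
    return activation_order(
        bout_events["onset_frame"], bout_events["muscle"], "muscle", **src
    )


def compartment_sequence(
    bout_events: pd.DataFrame,
    muscle_map,
    sustain: int = 4,
    min_muscles: int = 2,
    **src,
) -> TokenSequence:
    """Compartment-level order of one bout.

    Each activation maps to its D-V x A-P tag; the compartment -- not the
    muscle -- is the sequenced unit, contributing one token per contiguous
    activation run, ordered by run onset.  A compartment's activity is held
    for ``sustain`` extra frames past each event offset, emulating the slow
    decay of the Ca++ signal the compartment-level description rides on.
    An activation run counts as a compartment token only when at least
    ``min_muscles`` distinct muscles contribute to it: a lone stray twitch
    is not a compartment-level activation.
    """
    try:
        tags = [
            f"{muscle_map.compartment(m)}-{muscle_map.segment_ap(s)}"
            for m, s in zip(bout_events["muscle"], bout_events["segment"])
        ]
    except KeyError as exc:
        raise ValidationError(f"missing compartment tag for muscle {exc}") from exc
    t0 = int(bout_events["onset_frame"].min())
    t1 = int(bout_events["offset_frame"].max()) + sustain
    onsets, labels = [], []
    muscles = bout_events["muscle"].to_numpy()
    ons = bout_events["onset_frame"].to_numpy(int)
    offs = bout_events["offset_frame"].to_numpy(int) + sustain
    for tag in sorted(set(tags)):
        idx = [i for i, t in enumerate(tags) if t == tag]
        act = np.zeros(t1 - t0, dtype=bool)
        for i in idx:
            act[ons[i] - t0:offs[i] - t0] = True
        d = np.diff(np.r_[0, act.astype(np.int8), 0])
        for start, end in zip(np.nonzero(d == 1)[0], np.nonzero(d == -1)[0]):
            contributors = {
                muscles[i] for i in idx
                if ons[i] - t0 < end and start < offs[i] - t0
            }
            if len(contributors) >= min_muscles:
                onsets.append(start + t0)
                labels.append(tag)
    return activation_order(onsets, labels, "compartment", **src)


def syllable_sequence(syllable_events, **src) -> TokenSequence:
    """Syllable-level order from annotated syllable events."""
    return activation_order(
        [ev.onset_frame for ev in syllable_events],
        [ev.syllable for ev in syllable_events],
        "syllable",
        **src,
    )


def gestalt_similarity(a, b) -> float:
    """Ratcliff-Obershelp ratio 2M/T in [0, 1] for the ordered pair (a, b)."""
    ta = a.tokens if isinstance(a, TokenSequence) else tuple(a)
    tb = b.tokens if isinstance(b, TokenSequence) else tuple(b)
    if not ta or not tb:
        raise InsufficientDataError("similarity undefined for empty sequences")
    return SequenceMatcher(None, ta, tb, autojunk=False).ratio()


@dataclass
class SSResult:
    """Pairwise similarity-score distribution with optional null statistics."""

    scores: np.ndarray
    mean: float
    sd: float
    cv: float
    n_pairs: int
    null_mean: float | None = None
    null_sd: float | None = None
    p_value: float | None = None
    null_scores: np.ndarray | None = None
    groups: dict = field(default_factory=dict)


def _group_key(seq: TokenSequence):
    return (seq.animal_id, seq.phase)


def _pair_scores(sequences: list[TokenSequence], within_groups: bool) -> np.ndarray:
    scores = []
    if within_groups:
        groups: dict = {}
        for s in sequences:
            groups.setdefault(_group_key(s), []).append(s)
        blocks = groups.values()
    else:
        blocks = [sequences]
    for block in blocks:
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                scores.append(gestalt_similarity(block[i], block[j]))
    return np.asarray(scores, dtype=float)


def pairwise_ss(
    sequences: list[TokenSequence], within_groups: bool = True
) -> SSResult:
    """Similarity scores over all unordered pairs.

    With ``within_groups`` (default) pairs are formed within each animal and
    pooled across animals; the grand mean is the mean over all pooled pairs.
    Ordered comparison: pairs are scored in list order (i before j).
    """
    if len(sequences) < 2:
        raise InsufficientDataError("need >= 2 sequences")
    scores = _pair_scores(sequences, within_groups)
    if scores.size == 0:
        raise InsufficientDataError("fewer than 2 sequences in every group")
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1)) if scores.size > 1 else 0.0
    cv = float(100.0 * sd / mean) if mean else float("nan")
    return SSResult(scores, mean, sd, cv, int(scores.size))


def shuffled_null(
    sequences: list[TokenSequence],
    n_perm: int = 1000,
    seed: int | None = None,
    within_groups: bool = True,
) -> SSResult:
    """Permutation null for sequence stereotypy.

    Each permutation independently re-orders every sequence's own tokens
    uniformly at random (lengths and token multisets preserved) and the mean
    pairwise similarity is recomputed; the one-sided p-value is
    ``(1 + #{null means >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    observed = pairwise_ss(sequences, within_groups)
    rng = np.random.default_rng(seed)
    null_means = np.empty(n_perm)
    for k in range(n_perm):
        shuffled = [
            TokenSequence(
                tuple(rng.permutation(np.array(s.tokens, dtype=object))),
                s.level, s.animal_id, s.phase, s.unit_id,
            )
            for s in sequences
        ]
        null_means[k] = _pair_scores(shuffled, within_groups).mean()
    p = float((1 + np.sum(null_means >= observed.mean)) / (n_perm + 1))
    return SSResult(
        observed.scores, observed.mean, observed.sd, observed.cv,
        observed.n_pairs,
        null_mean=float(null_means.mean()),
        null_sd=float(null_means.std(ddof=1)) if n_perm > 1 else 0.0,
        p_value=p,
        null_scores=null_means,
    )
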