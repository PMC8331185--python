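"""Default syllabary: pupal muscle ensembles (PMEs), single-muscle syllables,
and the movement -> syllable vocabulary of the pupal ecdysis sequence.

PMEs are sets of muscles repeatedly co-active for at least three consecutive
frames; together with reliably movement-associated single muscles they form
the "syllables" from which the eight canonical movements (Lift, RollCon,
Swing, Brace, Crunch, AntComp, PostCon, PostSwing) are composed.

Memberships of PME1-PME4 follow the published hemisegmental anatomy
(PME1 = M8/M13/M26, PME2 = M21-M23, PME3 = M2/M3, PME4 = M1-M3; note
PME3 is a strict subset of PME4).  Memberships of PME5-PME8 are NOT
anatomically established; the defaults below are synthetic placeholders
drawn from the remaining roster and are configurable.
"""

from __future__ import annotations

#: Default PME memberships.  PME5-PME8 are synthetic placeholders.
DEFAULT_PMES: dict[str, tuple[str, ...]] = {
    "PME1": ("M8", "M13", "M26"),
    "PME2": ("M21", "M22", "M23"),
    "PME3": ("M2", "M3"),
    "PME4": ("M1", "M2", "M3"),
    "PME5": ("M5", "M9"),       # placeholder, not anatomically established
    "PME6": ("M9", "M10"),      # placeholder
    "PME7": ("M5", "M10"),      # placeholder
    "PME8": ("M8", "M21"),      # placeholder
}

#: Single-muscle syllables that never belong to a default PME.
DEFAULT_SINGLES: tuple[str, ...] = ("M12", "M15")

MOVEMENTS: tuple[str, ...] = (
    "Lift", "RollCon", "Swing", "Brace", "Crunch",
    "AntComp", "PostCon", "PostSwing",
)

#: Frame-label classes for movement classification (movements + Rest).
MOVEMENT_CLASSES: tuple[str, ...] = MOVEMENTS + ("Rest",)

#: Movement -> ordered syllable vocabulary.  Single-muscle tokens name the
#: muscle directly.  "P0" holds the pool for the pre-ecdysis twitching phase.
DEFAULT_SYLLABARY: dict[str, tuple[str, ...]] = {
    "P0": ("PME2", "PME3", "PME5", "PME6", "M1", "M2", "M8", "M12", "M13", "M15"),
    "Lift": ("PME1", "PME4", "PME6", "M8", "M15"),
    "RollCon": ("PME2", "PME3", "PME6", "M2", "M8"),
    "Swing": ("PME1", "PME2", "PME4", "PME6", "M12", "M15"),
    "Brace": ("PME2", "M8"),
    "Crunch": ("PME1", "PME2", "PME6", "M2", "M8", "M13"),
    "AntComp": ("PME2", "PME3", "PME4", "PME5", "PME6", "PME7", "PME8", "M1", "M12"),
    "PostCon": ("PME2", "PME3", "PME6", "M8", "M26"),
    "PostSwing": ("PME1", "PME2", "PME3", "PME6", "M15"),
}

#: Propagation direction of the activity wave carried by each movement.
#: P1/P2 movements travel posterior-to-anterior; P3 movements (and the
#: Brace) anterior-to-posterior.  PostCon has no net wave.
DEFAULT_DIRECTIONS: dict[str, str | None] = {
    "Lift": "P_to_A",
    "RollCon": "P_to_A",
    "Swing": "P_to_A",
    "Brace": "A_to_P",
    "Crunch": "A_to_P",
    "AntComp": "A_to_P",
    "PostCon": None,
    "PostSwing": "A_to_P",
}

PHASES: tuple[str, ...] = ("P0", "P1", "P2", "P3")


def syllable_members(syllable: str, pmes: dict[str, tuple[str, ...]] | None = None) -> tuple[str, ...]:
    """Muscle labels behind a syllable token (a PME id or a bare muscle)."""
    pmes = DEFAULT_PMES if pmes is None else pmes
    if syllable in pmes:
        return tuple(pmes[syllable])
    return (syllable,)
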