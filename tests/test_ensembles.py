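import numpy as np
import pandas as pd
import pytest

from pupalyze.ensembles import (
    annotate_syllables,
    coactive_duration_share,
    coactive_groups,
    discover_pmes,
    single_muscle_syllables,
)
from pupalyze.errors import InsufficientDataError, ValidationError
from pupalyze.simulate import SimulationConfig, simulate_cohort, simulate_recording


def events_df(rows):
    return pd.DataFrame(rows, columns=["animal_id", "bout_id", "muscle",
                                       "onset_frame", "offset_frame"])


class TestCoactiveGroups:
    def test_triplet_with_three_frame_intersection(self):
        ev = events_df([
            ("a", 0, "M21", 10, 16),
            ("a", 0, "M22", 11, 15),
            ("a", 0, "M23", 9, 14),
        ])
        groups = coactive_groups(ev)
        assert len(groups) == 1
        assert groups[0].members == frozenset({"M21", "M22", "M23"})
        assert groups[0].interval == (11, 14)

    def test_two_frame_overlap_is_below_threshold(self):
        ev = events_df([("a", 0, "M1", 0, 5), ("a", 0, "M2", 3, 10)])
        assert coactive_groups(ev) == []

    def test_single_event_yields_nothing(self):
        assert coactive_groups(events_df([("a", 0, "M1", 0, 9)])) == []

    def test_bad_interval_rejected(self):
        with pytest.raises(ValidationError):
            coactive_groups(events_df([("a", 0, "M1", 5, 5)]))


class TestDiscovery:
    def test_planted_support_arithmetic(self):
        # one group in 9/10 bouts for both animals -> retained;
        # another in 7/10 bouts in one animal -> rejected
        rows = []
        for animal in ("a", "b"):
            for bout in range(10):
                if bout < 9:
                    rows += [(animal, bout, "M21", 0, 6), (animal, bout, "M22", 0, 6)]
                limit = 9 if animal == "a" else 7
                if bout < limit:
                    rows += [(animal, bout, "M1", 20, 26), (animal, bout, "M2", 20, 26)]
                rows += [(animal, bout, "M13", 40, 46)]
        cat = discover_pmes(events_df(rows))
        assert cat.pme_sets == {frozenset({"M21", "M22"})}

    def test_recovers_planted_ensembles_exactly(self, support_cohort):
        cfg, _, events = support_cohort
        cat = discover_pmes(events)
        assert cat.pme_sets == {frozenset(v) for v in cfg.pmes.values()}

    def test_nested_planted_ensembles_both_recovered(self, support_cohort):
        cfg, _, events = support_cohort
        cat = discover_pmes(events)
        assert frozenset({"M2", "M3"}) in cat.pme_sets          # nested subset
        assert frozenset({"M1", "M2", "M3"}) in cat.pme_sets    # its superset

    def test_raising_thresholds_never_enlarges_catalog(self, support_cohort):
        _, _, events = support_cohort
        lax = discover_pmes(events, within_animal_frac=0.7, across_animal_frac=0.7)
        strict = discover_pmes(events, within_animal_frac=0.9, across_animal_frac=0.9)
        assert strict.pme_sets <= lax.pme_sets

    def test_recovery_degrades_with_ensemble_desynchronization(self):
        planted = {frozenset(v) for v in SimulationConfig().pmes.values()}
        recovered = []
        for wj in (1, 2, 4):
            cfg = SimulationConfig(seed=2, syllable_support=0.9, support_n_bouts=12,
                                   within_ensemble_jitter=wj, idiosyncratic_rate=0.0)
            _, events = simulate_cohort(cfg, 4)
            cat = discover_pmes(events)
            recovered.append(len(cat.pme_sets & planted))
        assert recovered[0] == len(planted)
        assert recovered[0] >= recovered[1] >= recovered[2]

    def test_single_animal_rejected(self):
        ev = events_df([("a", 0, "M1", 0, 6), ("a", 0, "M2", 0, 6)])
        with pytest.raises(ValidationError):
            discover_pmes(ev)


class TestSingles:
    def test_pme_members_excluded_from_singles(self, support_cohort):
        _, _, events = support_cohort
        cat = discover_pmes(events)
        cat = single_muscle_syllables(events, cat)
        members = set().union(*cat.pme_sets)
        assert not (cat.single_muscles & members)
        # planted singles reach the support thresholds
        assert {"M12", "M15"} <= cat.single_muscles

    def test_low_support_muscle_excluded(self):
        rows = []
        for animal in ("a", "b"):
            for bout in range(10):
                rows += [(animal, bout, "M21", 0, 6), (animal, bout, "M22", 0, 6)]
                if bout < 5:
                    rows.append((animal, bout, "M13", 20, 26))
        cat = discover_pmes(events_df(rows))
        cat = single_muscle_syllables(events_df(rows), cat)
        assert "M13" not in cat.single_muscles


class TestAnnotation:
    def test_off_fraction_arithmetic(self, default_recording):
        rec = default_recording
        cat = rec.truth.planted_syllables
        grp = rec.events[rec.events["bout_id"] == rec.events["bout_id"].iloc[0]]
        events, off = annotate_syllables(grp, cat)
        n_assigned = round((1 - off) * len(grp))
        assert 0.0 <= off <= 1.0
        assert n_assigned + round(off * len(grp)) == len(grp)

    def test_fully_planted_bout_has_zero_off_fraction(self):
        rec = simulate_recording(SimulationConfig(seed=4, idiosyncratic_rate=0.0))
        cat = rec.truth.planted_syllables
        offs = [annotate_syllables(grp, cat)[1]
                for _, grp in rec.events.groupby("bout_id")]
        assert np.mean(offs) == pytest.approx(0.0, abs=1e-9)

    def test_off_fraction_tracks_planted_idiosyncratic_rate(self):
        # planted rate 0.2; the pooled off-syllable fraction over 20 seeds
        # must land within 3 binomial SDs of it
        tot = unassigned = 0.0
        for seed in range(20):
            rec = simulate_recording(SimulationConfig(seed=seed, idiosyncratic_rate=0.2))
            cat = rec.truth.planted_syllables
            for _, grp in rec.events.groupby("bout_id"):
                _, off = annotate_syllables(grp, cat)
                tot += len(grp)
                unassigned += off * len(grp)
        frac = unassigned / tot
        band = 3 * np.sqrt(0.2 * 0.8 / tot)
        assert abs(frac - 0.2) < band


class TestDurationShare:
    def test_exact_window_events_give_unit_share(self, default_recording):
        rec = default_recording
        cat = rec.truth.planted_syllables
        grp = rec.events[rec.events["bout_id"] == rec.events["bout_id"].iloc[0]]
        events, _ = annotate_syllables(grp, cat)
        share = coactive_duration_share(events)
        assert 0.0 < share <= 1.0

    @pytest.mark.parametrize("durations,expected", [
        ([3, 3, 3], 1.0),
        ([20], 0.15),
        ([3, 6], 0.75),
    ])
    def test_share_arithmetic(self, durations, expected):
        from pupalyze.ensembles import SyllableEvent
        events = [SyllableEvent("PME1", 0, 0, (0, d), True) for d in durations]
        assert coactive_duration_share(events) == pytest.approx(expected)

    def test_no_pme_events_signaled(self):
        with pytest.raises(InsufficientDataError):
            coactive_duration_share([])
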