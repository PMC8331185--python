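import numpy as np
import pytest

from pupalyze.errors import InvalidConfigError
from pupalyze.muscles import make_muscle_map
from pupalyze.sequences import muscle_sequence, pairwise_ss
from pupalyze.signal import peak_correlation
from pupalyze.simulate import (
    SimulationConfig,
    apply_perturbation,
    render_frames,
    simulate_coupled_peak_trains,
    simulate_recording,
    simulate_wave_movie,
)

N_PERTURBATION_SEEDS = 20


class TestDeterminism:
    def test_same_seed_gives_identical_event_tables(self):
        cfg = SimulationConfig(seed=42)
        a = simulate_recording(cfg)
        b = simulate_recording(cfg)
        assert a.events.to_csv(index=False) == b.events.to_csv(index=False)
        for key in a.traces:
            assert np.array_equal(a.traces[key], b.traces[key])

    def test_different_seeds_differ(self):
        a = simulate_recording(SimulationConfig(seed=1))
        b = simulate_recording(SimulationConfig(seed=2))
        assert not a.events.equals(b.events)


class TestStructure:
    def test_event_conservation(self, default_recording):
        ev = default_recording.events
        n_planted = (~ev["idiosyncratic"]).sum()
        n_idio = ev["idiosyncratic"].sum()
        assert n_planted + n_idio == len(ev)
        assert (ev.loc[ev["idiosyncratic"], "syllable"] == "").all()

    def test_every_planted_event_lies_inside_its_bout(self, default_recording):
        rec = default_recording
        bounds = {b.bout_id: (b.start, b.end) for b in rec.truth.bouts}
        for _, row in rec.events.iterrows():
            s, e = bounds[row["bout_id"]]
            assert s <= row["onset_frame"] < e

    def test_phase_intervals_ordered_and_disjoint(self, default_recording):
        iv = sorted(default_recording.truth.phase_intervals.values())
        for (a0, a1), (b0, b1) in zip(iv[:-1], iv[1:]):
            assert a0 < a1 <= b0 < b1

    def test_frame_labels_cover_all_frames(self, default_recording):
        rec = default_recording
        assert rec.truth.frame_labels.shape == (rec.n_frames,)
        assert set(np.unique(rec.truth.frame_labels)) <= {
            "Rest", "Lift", "RollCon", "Swing", "Brace", "Crunch",
            "AntComp", "PostCon", "PostSwing",
        }

    def test_anterior_only_muscles_never_posterior(self, default_recording):
        ev = default_recording.events
        bad = ev[ev["muscle"].isin(["M12", "M5"])
                 & ev["segment"].isin(["A5", "A6", "A7"])]
        assert bad.empty


class TestZeroNoiseLimit:
    def test_identical_recruitment_orders_and_unit_similarity(self):
        cfg = SimulationConfig(seed=9, recruitment_jitter_sd=0.0,
                               within_ensemble_jitter=0, idiosyncratic_rate=0.0)
        rec = simulate_recording(cfg)
        ev = rec.events[rec.events["phase"] != "P0"]
        seqs = [muscle_sequence(g, animal_id="A0", phase=p, unit_id=b)
                for (p, b), g in ev.groupby(["phase", "bout_id"])]
        res = pairwise_ss(seqs)
        assert res.mean == 1.0 and res.sd == 0.0


class TestPerturbations:
    def test_unknown_mode_rejected(self):
        with pytest.raises(InvalidConfigError):
            apply_perturbation(SimulationConfig(), "nonsense")

    def test_none_mode_is_identity(self):
        cfg = SimulationConfig(seed=1)
        assert apply_perturbation(cfg, "none") is cfg

    def test_ethrb_removes_lift_and_silences_m1_m15_in_p1(self):
        for seed in range(N_PERTURBATION_SEEDS):
            cfg = apply_perturbation(SimulationConfig(seed=seed), "ethrb_suppressed")
            rec = simulate_recording(cfg)
            p1 = rec.events[rec.events["phase"] == "P1"]
            assert "Lift" not in set(p1["movement"])
            assert not p1["muscle"].isin(["M1", "M15"]).any()

    def test_ccap_leaves_single_partial_posterior_swing(self):
        for seed in range(N_PERTURBATION_SEEDS):
            cfg = apply_perturbation(SimulationConfig(seed=seed), "ccap_suppressed")
            rec = simulate_recording(cfg)
            phases = rec.truth.phase_intervals
            assert "P2" not in phases and "P3" not in phases
            swings = rec.events[rec.events["movement"] == "Swing"]
            assert len(set(swings["bout_id"])) == 1
            assert set(swings["segment"]) <= {"A5", "A6", "A7"}

    def test_burs_gives_one_full_swing_and_sparse_p3_movements(self):
        normal_p3 = len(simulate_recording(SimulationConfig(seed=0)).events.query(
            "phase == 'P3'"))
        for seed in range(N_PERTURBATION_SEEDS):
            cfg = apply_perturbation(SimulationConfig(seed=seed), "burs_suppressed")
            rec = simulate_recording(cfg)
            swings = rec.events[rec.events["movement"] == "Swing"]
            assert len(set(swings["bout_id"])) == 1
            # full-length wave reaches anterior segments
            assert set(swings["segment"]) & {"A1", "A2"}
            n_p3 = len(rec.events.query("phase == 'P3'"))
            assert 0 < n_p3 < normal_p3

    def test_class1da_dies_before_p1(self):
        for seed in range(N_PERTURBATION_SEEDS):
            cfg = apply_perturbation(SimulationConfig(seed=seed), "class1da_suppressed")
            rec = simulate_recording(cfg)
            assert set(rec.truth.phase_intervals) == {"P0"}
            assert set(rec.events["phase"]) == {"P0"}


class TestRendering:
    def test_single_active_muscle_lights_its_roi(self):
        mmap = make_muscle_map(with_rois=True)
        rec = simulate_recording(SimulationConfig(seed=0, idiosyncratic_rate=0.0), mmap)
        # zero all traces but one
        key = next(iter(rec.traces))
        for k in rec.traces:
            rec.traces[k] = np.zeros_like(rec.traces[k])
        rec.traces[key][100] = 1.0
        stack = render_frames(rec, dtype=np.float64)
        r, c = np.unravel_index(stack[100].argmax(), stack[100].shape)
        poly = mmap.roi_geometry[key]
        assert poly[:, 0].min() <= r <= poly[:, 0].max()
        assert poly[:, 1].min() <= c <= poly[:, 1].max()

    def test_silent_movie_is_flat_background(self):
        mmap = make_muscle_map(with_rois=True)
        rec = simulate_recording(SimulationConfig(seed=0), mmap)
        for k in rec.traces:
            rec.traces[k] = np.zeros_like(rec.traces[k])
        stack = render_frames(rec, background=100.0, dtype=np.float64)
        assert np.allclose(stack, 100.0)

    def test_planted_wave_moves_mode_toward_anterior(self):
        stack, win = simulate_wave_movie("P_to_A", seed=1)
        sub = stack[win[0]:win[1]]
        mip = sub.max(axis=2)
        active = mip.max(axis=1) > 100.0 + 500.0
        modes = mip[active].argmax(axis=1)
        # first active frames sit posterior (large rows) of the last ones
        assert modes[:3].mean() > modes[-3:].mean()

    def test_missing_rois_rejected(self, default_recording):
        with pytest.raises(InvalidConfigError):
            render_frames(default_recording)


class TestCoupledTrains:
    def test_full_coupling_duplicates_the_train(self):
        a, b = simulate_coupled_peak_trains(1.0, seed=0)
        assert np.array_equal(a.peak_frames, b.peak_frames)

    def test_correlation_increases_with_coupling(self):
        means = []
        for p in (0.1, 0.5, 0.9):
            rs = [peak_correlation(*simulate_coupled_peak_trains(p, seed=s),
                                   2000, tolerance=1) for s in range(20)]
            means.append(np.mean(rs))
        assert means[0] < means[1] < means[2]


class TestConfig:
    def test_json_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=13, idiosyncratic_rate=0.25)
        path = tmp_path / "config.json"
        cfg.to_json(path)
        loaded = SimulationConfig.from_json(path)
        assert loaded == cfg

    def test_seed_mandatory_in_persisted_configs(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{}")
        with pytest.raises(InvalidConfigError):
            SimulationConfig.from_json(path)

    @pytest.mark.parametrize("kwargs", [
        {"idiosyncratic_rate": 1.4},
        {"fps": 0.0},
        {"recruitment_jitter_sd": -1.0},
        {"perturbation": "bogus"},
        {"syllabary": {"Lift": ()}},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(seed=0, **kwargs)
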