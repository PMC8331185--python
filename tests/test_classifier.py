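import numpy as np
import pytest

from pupalyze.classifier import (
    ClassifierConfig,
    EarlyStopping,
    evaluate_predictions,
    make_windows,
    predict_movements,
    train_classifier,
)
from pupalyze.errors import (
    DegenerateTrainingError,
    InsufficientDataError,
    ValidationError,
)
from pupalyze.muscles import make_muscle_map
from pupalyze.simulate import PhaseSpec, SimulationConfig, render_frames, simulate_cohort


def movie_cohort(seed, n_animals=3):
    """Small rendered movies with frame-wise movement labels."""
    plan = {
        "P1": PhaseSpec(3, (("Lift", "RollCon"),), 10.0, 0.2, 0.2),
        "P2": PhaseSpec(2, (("Swing", "Brace"),), 10.0, 0.1, 0.1),
        "P3": PhaseSpec(2, (("Crunch", "AntComp", "PostCon", "PostSwing"),), 10.0, 0.2, 0.2),
    }
    cfg = SimulationConfig(seed=seed, phase_plan=plan,
                           idiosyncratic_rate=0.05, initial_rest=15)
    mmap = make_muscle_map(with_rois=True, seg_height=4, muscle_width=1)
    recs, _ = simulate_cohort(cfg, n_animals, mmap)
    return [
        (render_frames(r, dtype=np.float32), r.truth.frame_labels,
         r.config.animal_id)
        for r in recs
    ]


def windows_from(movies):
    ds = None
    for stack, labels, aid in movies:
        d = make_windows(stack, labels, aid)
        ds = d if ds is None else ds.concat(d)
    return ds


class TestWindows:
    def test_boundary_movie_yields_single_center_window(self):
        stack = np.zeros((25, 8, 8))
        labels = np.array(["Rest"] * 25, dtype=object)
        ds = make_windows(stack, labels)
        assert len(ds) == 1
        assert ds.windows.shape == (1, 25, 8, 8)

    def test_window_count_is_frames_minus_24(self):
        ds = make_windows(np.zeros((100, 8, 8)),
                          np.array(["Rest"] * 100, dtype=object))
        assert len(ds) == 76

    def test_window_label_is_center_frame_label(self):
        labels = np.array(["Rest"] * 60, dtype=object)
        labels[30] = "Swing"
        ds = make_windows(np.zeros((60, 8, 8)), labels)
        assert ds.labels[30 - 12] == "Swing"

    def test_short_movie_rejected(self):
        with pytest.raises(InsufficientDataError):
            make_windows(np.zeros((20, 8, 8)), np.array(["Rest"] * 20, dtype=object))

    def test_window_count_conserved_over_animals(self):
        movies = movie_cohort(0, n_animals=2)
        ds = windows_from(movies)
        assert len(ds) == sum(m[0].shape[0] - 24 for m in movies)


class TestEarlyStopping:
    def test_stops_after_exactly_patience_bad_epochs(self):
        stopper = EarlyStopping(patience=10)
        assert stopper.update(1.0) is False  # first value improves on inf
        flags = [stopper.update(1.0 + 0.1 * k) for k in range(1, 11)]
        assert flags == [False] * 9 + [True]

    def test_improvement_resets_counter(self):
        stopper = EarlyStopping(patience=2)
        stopper.update(1.0)
        stopper.update(2.0)
        assert stopper.update(0.5) is False
        assert stopper.update(0.6) is False
        assert stopper.update(0.7) is True


@pytest.fixture(scope="module")
def trained():
    movies = movie_cohort(1, n_animals=3)
    ds = windows_from(movies)
    cfg = ClassifierConfig(seed=0, learning_rate=1e-3, max_epochs=60)
    model = train_classifier(ds, cfg, validation_animals=["A2"])
    return movies, ds, model


class TestTraining:

    def test_separable_movies_learned_above_chance(self, trained):
        movies, ds, model = trained
        stack, labels, _ = movies[2]  # held-out animal
        pred = predict_movements(model, stack)
        acc = float(np.mean(pred["label"].to_numpy(object) == labels))
        assert acc >= 0.8

    def test_predictions_deterministic_on_rerun(self, trained):
        movies, _, model = trained
        stack = movies[0][0]
        a = predict_movements(model, stack)
        b = predict_movements(model, stack)
        assert np.allclose(a[list(model.classes)].to_numpy(),
                           b[list(model.classes)].to_numpy())

    def test_per_frame_probabilities_sum_to_one(self, trained):
        movies, _, model = trained
        pred = predict_movements(model, movies[0][0])
        sums = pred[list(model.classes)].sum(axis=1).to_numpy()
        assert np.allclose(sums, 1.0, atol=1e-6)

    def test_single_class_dataset_rejected(self):
        ds = make_windows(np.zeros((30, 8, 8)), np.array(["Rest"] * 30, dtype=object))
        with pytest.raises(DegenerateTrainingError):
            train_classifier(ds)


class TestEvaluation:
    def test_perfect_prediction(self):
        labels = np.array(["Rest", "Swing", "Swing", "Lift"], dtype=object)
        ev = evaluate_predictions(labels, labels)
        assert ev.accuracy == 1.0
        assert np.trace(ev.confusion.to_numpy()) == 4

    def test_constant_prediction_scores_prevalence(self):
        truth = np.array(["Rest"] * 3 + ["Swing"] * 9, dtype=object)
        pred = np.array(["Rest"] * 12, dtype=object)
        assert evaluate_predictions(pred, truth).accuracy == pytest.approx(0.25)

    def test_duration_table_conserves_frames(self):
        truth = np.array(["Rest"] * 10 + ["Swing"] * 6, dtype=object)
        ev = evaluate_predictions(truth, truth, fps=2.0)
        assert ev.durations["true_duration_s"].sum() == pytest.approx(16 / 2.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_predictions(np.array(["Rest"]), np.array(["Rest", "Rest"]))
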