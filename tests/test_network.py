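"""Classifier surrogate: quantization grid, features, training, inference."""

import numpy as np
import pytest

from muscleperf.kinetics import Curve, IRFParams
from muscleperf.network import (
    DEFAULT_GRID,
    PerfusionClassGrid,
    PerfusionNetwork,
    TrainingSet,
    assemble_training_set,
    build_feature_matrix,
    build_feature_vector,
    class_to_perfusion,
    discretize_perfusion,
    load_model,
    predict_map,
    predict_voxel,
    save_model,
)
from muscleperf.simulate import generate_cohort, generate_voxel_tc, load_preset


@pytest.fixture(scope="module")
def tiny_cohort():
    spec = load_preset("testing", rng_seed=7, voxels_per_dataset=80)
    spec.datasets = spec.datasets[:3]
    return generate_cohort(spec)


@pytest.fixture(scope="module")
def tiny_trained(tiny_cohort):
    """A small network trained on truth-discretized labels (fast, learnable)."""
    studies = tiny_cohort
    ts = assemble_training_set(studies, [s.truth["F"] for s in studies])
    net = PerfusionNetwork(n_epochs=10, random_state=0).fit(ts.features, ts.labels)
    return net, ts


class TestGrid:
    def test_default_grid_endpoints_and_spacing(self):
        assert DEFAULT_GRID.values[0] == 10.0
        assert DEFAULT_GRID.values[-1] == 400.0
        assert DEFAULT_GRID.values.size == 40
        np.testing.assert_allclose(np.diff(DEFAULT_GRID.values), 10.0)

    @pytest.mark.parametrize("f, idx", [
        (10.0, 0), (400.0, 39),       # endpoints
        (72.4, 6),                     # nearest of {70, 80}
        (75.0, 7),                     # tie rounds up
        (3.0, 0), (1234.0, 39),        # out of range clips to end classes
    ])
    def test_discretize(self, f, idx):
        assert discretize_perfusion(f) == idx

    def test_round_trip_over_all_classes(self):
        for i in range(40):
            assert discretize_perfusion(class_to_perfusion(i)) == i

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            discretize_perfusion(np.nan)
        with pytest.raises(ValueError):
            class_to_perfusion(40)
        with pytest.raises(ValueError):
            PerfusionClassGrid(values=np.zeros(40))


class TestFeatures:
    def test_concatenation_order(self):
        out = build_feature_vector(np.arange(1.0, 41.0), np.arange(41.0, 81.0))
        np.testing.assert_array_equal(out, np.arange(1.0, 81.0))

    def test_zero_curves(self):
        assert np.all(build_feature_vector(np.zeros(40), np.zeros(40)) == 0)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            build_feature_vector(np.zeros(39), np.zeros(40))

    def test_voxels_of_one_study_share_aif_block(self, tiny_cohort):
        s = tiny_cohort[0]
        X = build_feature_matrix(s.masked_tc, s.aif)
        assert np.all(X[:, 40:] == s.aif.values)
        assert not np.all(X[0, :40] == X[1, :40])


class TestTrainingSet:
    def test_record_counting_and_merge(self, tiny_cohort):
        studies = tiny_cohort[:2]
        maps = [s.truth["F"] for s in studies]
        ts = assemble_training_set(studies, maps)
        assert len(ts) == sum(int(s.mask.sum()) for s in studies)
        merged = TrainingSet.concatenate([ts, ts])
        assert len(merged) == 2 * len(ts)
        assert len(merged.provenance) == 4

    def test_label_source_changes_labels_not_features(self, tiny_cohort):
        studies = tiny_cohort[:1]
        shifted = [s.truth["F"] * 1.4 for s in studies]
        a = assemble_training_set(studies, [s.truth["F"] for s in studies])
        b = assemble_training_set(studies, shifted, label_source="regular")
        np.testing.assert_array_equal(a.features, b.features)
        assert not np.array_equal(a.labels, b.labels)
        assert b.label_source == "regular"

    def test_save_load_round_trip(self, tiny_cohort, tmp_path):
        studies = tiny_cohort[:1]
        ts = assemble_training_set(studies, [s.truth["F"] for s in studies])
        ts.save(tmp_path / "ts.npz")
        back = TrainingSet.load(tmp_path / "ts.npz")
        np.testing.assert_array_equal(back.features, ts.features)
        np.testing.assert_array_equal(back.labels, ts.labels)
        assert back.provenance == ts.provenance

    def test_missing_label_map_rejected(self, tiny_cohort):
        with pytest.raises(ValueError):
            assemble_training_set(tiny_cohort[:2], [tiny_cohort[0].truth["F"]])


class TestNetwork:
    def test_loss_decreases_on_learnable_set(self, tiny_trained):
        net, _ = tiny_trained
        assert len(net.loss_curve_) == 10
        assert net.loss_curve_[-1] <= net.loss_curve_[0]

    def test_probabilities_normalised(self, tiny_trained, rng):
        net, ts = tiny_trained
        X = rng.normal(1, 1, (50, 80))
        p = net.predict_proba(X)
        assert p.shape == (50, 40)
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_estimates_always_grid_valued(self, tiny_trained, rng):
        net, _ = tiny_trained
        est = net.predict_perfusion(rng.normal(1, 1, (50, 80)))
        assert np.all(np.isin(est, DEFAULT_GRID.values))

    def test_inference_deterministic(self, tiny_trained, rng):
        net, _ = tiny_trained
        X = rng.normal(1, 1, (10, 80))
        np.testing.assert_array_equal(net.predict_proba(X), net.predict_proba(X))

    def test_training_reproducible_from_seed(self, tiny_trained):
        _, ts = tiny_trained
        a = PerfusionNetwork(n_epochs=2, random_state=5).fit(ts.features, ts.labels)
        b = PerfusionNetwork(n_epochs=2, random_state=5).fit(ts.features, ts.labels)
        for wa, wb in zip(a.coefs_, b.coefs_):
            np.testing.assert_array_equal(wa, wb)

    def test_constant_label_training_set(self, rng):
        X = rng.normal(1, 0.3, (300, 80))
        y = np.full(300, 17)
        net = PerfusionNetwork(n_epochs=5, random_state=0).fit(X, y)
        assert np.all(net.predict(X) == 17)
        assert net.predict_proba(X[:3]).shape == (3, 40)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            PerfusionNetwork().fit(np.empty((0, 80)), np.empty(0, dtype=int))

    def test_predict_voxel_contract(self, tiny_trained, rng):
        net, _ = tiny_trained
        proba, est = predict_voxel(net, rng.normal(1, 1, 80))
        assert proba.sum() == pytest.approx(1.0, abs=1e-6)
        assert est == class_to_perfusion(int(np.argmax(proba)))
        with pytest.raises(ValueError):
            predict_voxel(net, np.zeros(79))

    def test_standardize_flag_round_trips(self, tiny_trained, tmp_path):
        _, ts = tiny_trained
        net = PerfusionNetwork(n_epochs=2, random_state=1, standardize=True).fit(
            ts.features, ts.labels)
        save_model(net, tmp_path / "m.npz")
        back = load_model(tmp_path / "m.npz")
        np.testing.assert_allclose(
            back.predict_proba(ts.features[:20]), net.predict_proba(ts.features[:20]),
            atol=1e-12,
        )


class TestPredictMap:
    def test_map_prediction_matches_rowwise_inference(self, tiny_trained, tiny_cohort):
        net, _ = tiny_trained
        s = tiny_cohort[0]
        fmap = predict_map(net, s.tc, s.mask, s.aif)
        assert np.all(np.isnan(fmap[~s.mask]))
        direct = net.predict_perfusion(build_feature_matrix(s.masked_tc, s.aif))
        np.testing.assert_array_equal(fmap[s.mask], direct)

    def test_empty_mask(self, tiny_trained):
        net, _ = tiny_trained
        fmap = predict_map(net, np.zeros((4, 4, 40)), np.zeros((4, 4), bool),
                           Curve(np.zeros(40)))
        assert np.all(np.isnan(fmap))

    def test_noiseless_grid_voxels_mostly_exact(self, aif):
        # voxels whose true F sits exactly on grid points, clean curves,
        # labels from truth: an adequately trained net (standardized inputs,
        # 40 epochs) recovers the exact class on a held-out 8x8 map
        rng = np.random.default_rng(3)

        def draw(n):
            grid_F = DEFAULT_GRID.values[rng.integers(2, 36, n)]
            X, y = [], []
            for F in grid_F:
                p = IRFParams(F=float(F), t0=float(rng.uniform(2, 5)),
                              minTT=float(rng.uniform(4, 8)),
                              E=float(rng.uniform(0.3, 0.5)),
                              k=float(rng.uniform(0.1, 0.2)))
                tc = generate_voxel_tc(p, aif, snr=np.inf)
                X.append(build_feature_vector(tc, aif))
                y.append(discretize_perfusion(float(F)))
            return np.asarray(X), np.asarray(y)

        X_train, y_train = draw(6000)
        X_map, y_map = draw(64)  # an 8x8 map's worth of held-out voxels
        net = PerfusionNetwork(n_epochs=40, random_state=0,
                               standardize=True).fit(X_train, y_train)
        assert np.mean(net.predict(X_map) == y_map) >= 0.90


class TestSerialization:
    def test_save_load_preserves_inference(self, tiny_trained, tmp_path, rng):
        net, _ = tiny_trained
        save_model(net, tmp_path / "model.npz")
        back = load_model(tmp_path / "model.npz")
        X = rng.normal(1, 1, (30, 80))
        np.testing.assert_array_equal(back.predict_proba(X), net.predict_proba(X))
        np.testing.assert_array_equal(back.grid_.values, net.grid_.values)

    def test_wrong_file_rejected(self, tmp_path):
        np.savez(tmp_path / "junk.npz", header="{}")
        with pytest.raises(ValueError):
            load_model(tmp_path / "junk.npz")
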