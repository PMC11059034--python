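import numpy as np
import pytest

from uswinct.metrics import rmse
from uswinct.model import ModelConfig
from uswinct.phantom import Ellipse, PhantomSpec, make_patients
from uswinct.projection import FanBeamGeometry
from uswinct.train import (
    TrainConfig,
    USwinRestorer,
    build_pairs,
    evaluate,
    mse_loss,
    patient_kfold_split,
    train_model,
)


def tiny_model_cfg(**kw):
    base = dict(
        hidden_channels=8, n_ust_modules=1, st_blocks_per_ust=1, n_heads=2,
        window_size=4, unet_depth=2, rng_seed=0,
    )
    base.update(kw)
    return ModelConfig(**base)


@pytest.fixture(scope="module")
def pair_geom():
    return FanBeamGeometry(n_views=60, n_detectors=64, detector_spacing_mm=6.5, fov_mm=220.0)


class TestMseLoss:
    def test_identical_is_zero(self, rng):
        x = rng.random((8, 8))
        assert mse_loss(x, x) == 0.0

    def test_constant_difference_squares(self, rng):
        x = rng.random((8, 8))
        assert mse_loss(x + 0.2, x) == pytest.approx(0.04, abs=1e-12)

    def test_equals_squared_rmse(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        assert mse_loss(a, b) == pytest.approx(rmse(a, b) ** 2, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mse_loss(np.zeros((4, 4)), np.zeros((5, 4)))


class TestPatientKFold:
    def test_ten_patients_ten_folds_single_test_patient(self):
        ids = [f"p{i:02d}" for i in range(10)]
        folds = patient_kfold_split(ids, 10)
        assert len(folds) == 10
        for train_ids, test_ids in folds:
            assert len(test_ids) == 1 and len(train_ids) == 9

    def test_test_sets_partition_patients(self):
        ids = [f"p{i}" for i in range(7)]
        folds = patient_kfold_split(ids, 3, rng_seed=1)
        tests = [t for _, test in folds for t in test]
        assert sorted(tests) == sorted(ids)  # exhaustive, disjoint

    def test_two_folds_of_four_patients(self):
        folds = patient_kfold_split(["a", "b", "c", "d"], 2)
        assert [len(t) for _, t in folds] == [2, 2]

    def test_no_patient_in_both_sides(self):
        folds = patient_kfold_split([f"p{i}" for i in range(6)], 3, rng_seed=4)
        for train_ids, test_ids in folds:
            assert not set(train_ids) & set(test_ids)

    def test_seeded_determinism(self):
        ids = [f"p{i}" for i in range(8)]
        assert patient_kfold_split(ids, 4, 42) == patient_kfold_split(ids, 4, 42)

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            patient_kfold_split(["a", "b"], 3)


class TestBuildPairs:
    def test_pair_count_is_product(self, pair_geom):
        specs = make_patients(2, rng_seed=0)
        pairs = build_pairs(specs, [20.0, 50.0, 80.0], 4, pair_geom, H=32, W=32)
        assert len(pairs) == 2 * 3 * 4

    def test_static_full_view_pair_is_self_consistent(self, pair_geom):
        spec = PhantomSpec(
            components=(Ellipse((0.5, 0.5), (0.25, 0.2), 0.0, 50.0),), patient_id="s0"
        )
        (pair,) = build_pairs([spec], [20.0], 1, pair_geom, 360.0, 0.0, H=32, W=32)
        assert rmse(pair.label, pair.input) < 1e-3

    def test_values_normalized(self, pair_geom):
        specs = make_patients(1, rng_seed=2)
        (pair,) = build_pairs(specs, [20.0], 1, pair_geom, H=32, W=32)
        for arr in (pair.input, pair.label):
            assert arr.min() >= 0.0 and arr.max() <= 1.0


class _IdentityModel:
    def predict(self, x):
        return np.asarray(x)


class TestEvaluate:
    def test_row_count_and_baseline(self, pair_geom):
        specs = make_patients(1, rng_seed=3)
        pairs = build_pairs(specs, [20.0, 50.0], 1, pair_geom, H=32, W=32)
        rep = evaluate(None, pairs)
        assert len(rep.rows) == len(pairs)
        assert set(rep.rows.method) == {"limited_angle_fbp"}

    def test_identity_model_matches_baseline(self, pair_geom):
        specs = make_patients(1, rng_seed=3)
        pairs = build_pairs(specs, [20.0], 1, pair_geom, H=32, W=32)
        rep = evaluate(_IdentityModel(), pairs)
        agg = rep.aggregates()
        assert agg.loc["uswin", "rmse"] == pytest.approx(
            agg.loc["limited_angle_fbp", "rmse"], abs=1e-12
        )


class TestTraining:
    def test_single_pair_overfit_halves_loss(self, rng):
        x = rng.random((1, 32, 32))
        y = np.clip(x + rng.normal(0, 0.05, x.shape), 0, 1)
        est = USwinRestorer(
            config=tiny_model_cfg(predict_residual=True),
            epochs=100, learning_rate=1e-3, max_steps=100, rng_seed=0,
        )
        est.fit(x, y)
        assert est.loss_history_[-1] < 0.5 * est.loss_history_[0]

    def test_same_seed_reproduces_loss_history(self, rng):
        x, y = rng.random((3, 16, 16)), rng.random((3, 16, 16))
        runs = []
        for _ in range(2):
            est = USwinRestorer(
                config=tiny_model_cfg(), epochs=3, learning_rate=1e-3, rng_seed=7
            )
            est.fit(x, y)
            runs.append(est.loss_history_)
        assert runs[0] == runs[1]

    def test_loss_history_is_finite_with_length_epochs(self, rng):
        x, y = rng.random((2, 16, 16)), rng.random((2, 16, 16))
        est = USwinRestorer(config=tiny_model_cfg(), epochs=4, learning_rate=1e-4, rng_seed=1)
        est.fit(x, y)
        assert len(est.loss_history_) == 4
        assert np.all(np.isfinite(est.loss_history_))

    def test_identity_task_stays_near_zero_loss(self, rng):
        # noiseless full-view motionless data: input equals label; residual
        # start is the identity map and training must not break it
        x = rng.random((2, 16, 16))
        est = USwinRestorer(
            config=tiny_model_cfg(predict_residual=True, zero_init_residual_paths=True),
            epochs=3, learning_rate=1e-5, rng_seed=0,
        )
        est.fit(x, x.copy())
        assert est.loss_history_[0] < 1e-4
        assert est.loss_history_[-1] <= est.loss_history_[0] + 1e-8

    def test_sklearn_params_roundtrip(self):
        est = USwinRestorer(epochs=5, learning_rate=2e-4)
        params = est.get_params()
        est2 = USwinRestorer(**params)
        assert est2.get_params() == params

    def test_train_model_wrapper(self, pair_geom):
        specs = make_patients(1, rng_seed=5)
        pairs = build_pairs(specs, [20.0], 1, pair_geom, H=32, W=32)
        model, history = train_model(
            pairs, tiny_model_cfg(), TrainConfig(epochs=2, learning_rate=1e-4, rng_seed=0)
        )
        assert len(history) == 2
        assert model.predict(pairs[0].input).shape == (32, 32)

    def test_train_config_defaults(self):
        tc = TrainConfig()
        assert tc.batch_size == 1
        assert tc.epochs == 100
        assert tc.learning_rate == 1e-5
        assert tc.optimizer == "adam"
        assert tc.k_folds == 10

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError):
            USwinRestorer().predict(np.zeros((4, 4)))
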