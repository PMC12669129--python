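"""Huber loss, augmentation, rounding, and small training contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenostage import nn
from phenostage.datasetio import Manifest
from phenostage.leafreg import (
    NO_AUGMENT,
    AugmentConfig,
    RegressionBatch,
    RegressorConfig,
    augment,
    desk_config,
    huber_loss,
    predict_pairs,
    round_clamp,
    search_hyperparams,
    train_regressor,
)


class TestHuberLoss:
    @pytest.mark.parametrize(
        "error,delta,expected",
        [
            (0.0, 1.0, 0.0),
            (0.5, 1.0, 0.125),   # quadratic branch: 0.5 * 0.25
            (2.0, 1.0, 1.5),     # linear branch: 1 * (2 - 0.5)
            (-2.0, 1.0, 1.5),
            (0.3, 2.0, 0.045),
        ],
    )
    def test_analytic_values(self, error, delta, expected):
        batch = RegressionBatch([error], [0.0])
        assert huber_loss(batch, delta) == pytest.approx(expected)

    def test_sum_and_mean_reductions(self):
        batch = RegressionBatch([0.5, 2.0], [0.0, 0.0])
        assert huber_loss(batch, 1.0, "sum") == pytest.approx(1.625)
        assert huber_loss(batch, 1.0, "mean") == pytest.approx(0.8125)

    @given(e=st.floats(-10, 10), delta=st.floats(0.1, 5))
    @settings(max_examples=200, deadline=None)
    def test_piecewise_definition_and_positivity(self, e, delta):
        val = huber_loss(RegressionBatch([e], [0.0]), delta)
        if abs(e) < delta:
            assert val == pytest.approx(0.5 * e * e)
        else:
            assert val == pytest.approx(delta * (abs(e) - 0.5 * delta))
        assert val >= 0.0
        if e == 0.0:
            assert val == 0.0
        elif abs(e) > 1e-6:  # below this 0.5*e^2 can underflow to exactly 0
            assert val > 0.0

    def test_continuity_at_knee(self):
        delta = 1.3
        eps = 1e-9
        below = huber_loss(RegressionBatch([delta - eps], [0.0]), delta)
        above = huber_loss(RegressionBatch([delta + eps], [0.0]), delta)
        assert abs(below - above) < 1e-6

    def test_large_delta_recovers_half_squared_error(self, rng):
        e = rng.normal(size=50)
        batch = RegressionBatch(e, np.zeros(50))
        assert huber_loss(batch, 1e6) == pytest.approx(0.5 * (e**2).sum())

    def test_gradient_matches_finite_differences(self):
        delta = 1.0
        for e in (-2.5, -0.7, 0.3, 1.8):
            h = 1e-6
            num = (
                nn.huber_terms(np.array([e + h]), np.zeros(1), delta)[0]
                - nn.huber_terms(np.array([e - h]), np.zeros(1), delta)[0]
            ) / (2 * h)
            ana = nn.huber_grad(np.array([e]), np.zeros(1), delta)[0]
            assert ana == pytest.approx(num, abs=1e-6)
            expected = e if abs(e) < delta else delta * np.sign(e)
            assert ana == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            RegressionBatch([1, 2], [1])


class TestRoundClamp:
    @pytest.mark.parametrize(
        "raw,expected",
        [(3.4, 3), (2.5, 3), (3.5, 4), (-0.3, 0), (11.2, 10), (0.49, 0)],
    )
    def test_half_up_with_clamp(self, raw, expected):
        assert round_clamp([raw], 10)[0] == expected

    def test_invalid_max_pairs(self):
        with pytest.raises(ValueError):
            round_clamp([1.0], 0)


class TestAugment:
    def _crop(self, rng):
        return rng.integers(0, 255, size=(32, 32, 3), dtype=np.uint8)

    def test_zero_magnitudes_are_identity(self, rng):
        x = self._crop(rng)
        assert np.array_equal(augment(x, NO_AUGMENT, seed=3), x)

    def test_deterministic_per_seed(self, rng):
        x = self._crop(rng)
        cfg = AugmentConfig()
        assert np.array_equal(augment(x, cfg, seed=5), augment(x, cfg, seed=5))
        assert not np.array_equal(augment(x, cfg, seed=5), augment(x, cfg, seed=6))

    def test_values_stay_in_range_under_extreme_jitter(self, rng):
        cfg = AugmentConfig(brightness=0.9, contrast=0.9, saturation=0.9, hue=0.5,
                            hflip_p=1.0, rot_deg=45)
        for seed in range(20):
            out = augment(self._crop(rng), cfg, seed=seed)
            assert out.dtype == np.uint8
            assert out.min() >= 0 and out.max() <= 255

    def test_hflip_preserves_leaf_pair_label(self):
        """Mirroring a rosette crop leaves the countable pair structure
        unchanged: same foliage pixel mass, mirrored geometry."""
        from phenostage.synthscene import PlantSpec, render_plant

        canvas = np.zeros((120, 120, 3))
        canvas, _ = render_plant(
            PlantSpec(center_xy=(60, 60), n_pairs=3, leaf_length_px=30), canvas
        )
        flipped = canvas[:, ::-1, :]
        assert (flipped.sum(axis=2) > 0).sum() == (canvas.sum(axis=2) > 0).sum()


class TestTraining:
    def test_constant_label_dataset_converges(self, tmp_path, rng):
        """With a constant target the regressor collapses to that constant."""
        from PIL import Image

        rows = []
        for i in range(40):
            img = rng.integers(0, 255, size=(16, 16, 3), dtype=np.uint8)
            p = tmp_path / f"c{i}.png"
            Image.fromarray(img).save(p)
            rows.append(dict(crop_path=str(p), pairs=3, scene_id=i, plant_idx=0,
                             chamber_id="", split=""))
        import pandas as pd

        m = Manifest(samples=pd.DataFrame(rows))
        # 40 samples fit one batch, so each epoch is a single optimiser step
        cfg = desk_config(seed=0, input_side=16, max_epochs=250, patience=250, lr=5e-3)
        fitted = train_regressor(m, m, cfg, NO_AUGMENT)
        preds = predict_pairs(fitted, np.zeros((4, 16, 16, 3)))
        assert np.all(np.abs(preds - 3.0) < 0.5)
        # early-stopping contract: restored weights are the best epoch's
        assert fitted.history.val_loss.min() == pytest.approx(
            fitted.history.val_loss.iloc[fitted.best_epoch - 1]
        )

    def test_predictions_deterministic_and_batch_invariant(self, fitted_regressor, crop_dataset):
        _, _, test = crop_dataset
        from phenostage.leafreg import _load_crops

        x, _ = _load_crops(test, fitted_regressor.config.input_side)
        x = x[:16]
        a = predict_pairs(fitted_regressor, x)
        b = predict_pairs(fitted_regressor, x)
        one_by_one = np.concatenate([predict_pairs(fitted_regressor, x[i : i + 1]) for i in range(16)])
        assert np.array_equal(a, b)
        assert np.allclose(a, one_by_one, atol=1e-9)
        assert np.isfinite(a).all()

    def test_blank_crop_prediction_is_finite(self, fitted_regressor):
        side = fitted_regressor.config.input_side
        blank = np.zeros((1, side, side, 3))
        assert np.isfinite(predict_pairs(fitted_regressor, blank)).all()

    def test_checkpoint_roundtrip(self, fitted_regressor, tmp_path):
        from phenostage.leafreg import FittedRegressor

        path = tmp_path / "model.npz"
        fitted_regressor.save(path)
        back = FittedRegressor.load(path)
        side = fitted_regressor.config.input_side
        x = np.random.default_rng(0).random((3, side, side, 3))
        assert np.allclose(predict_pairs(back, x), predict_pairs(fitted_regressor, x))


class TestSearchHarness:
    def _tiny_manifests(self, tmp_path, rng):
        from PIL import Image
        import pandas as pd

        rows = []
        for i in range(30):
            img = np.full((16, 16, 3), (i % 5) * 40, dtype=np.uint8)
            p = tmp_path / f"s{i}.png"
            Image.fromarray(img).save(p)
            rows.append(dict(crop_path=str(p), pairs=i % 5, scene_id=i, plant_idx=0,
                             chamber_id="", split=""))
        m = Manifest(samples=pd.DataFrame(rows))
        return m, m

    def test_single_trial_returns_its_config(self, tmp_path, rng):
        tr, va = self._tiny_manifests(tmp_path, rng)
        base = desk_config(input_side=16, max_epochs=2, patience=2)
        best, table = search_hyperparams(tr, va, {"lr": (1e-4, 1e-2, "log")},
                                         n_trials=1, seed=0, base_cfg=base)
        assert len(table) == 1
        assert best.lr == pytest.approx(table.iloc[0]["lr"])

    def test_fixed_seed_reproduces_trial_sequence(self, tmp_path, rng):
        tr, va = self._tiny_manifests(tmp_path, rng)
        base = desk_config(input_side=16, max_epochs=2, patience=2)
        space = {"lr": (1e-4, 1e-2, "log"), "activation": ["relu", "leaky_relu"]}
        _, t1 = search_hyperparams(tr, va, space, n_trials=3, seed=9, base_cfg=base)
        _, t2 = search_hyperparams(tr, va, space, n_trials=3, seed=9, base_cfg=base)
        assert t1[["lr", "activation"]].equals(t2[["lr", "activation"]])


class TestModelBackend:
    def test_gradients_match_finite_differences(self, rng):
        """Full-network gradient check at 1e-4 relative tolerance."""
        model = nn.SmallConvNet(8, activation="gelu", dropout=0.0, seed=0)
        x = rng.normal(size=(2, 8, 8, 3))
        y = np.array([1.0, 3.0])

        def loss():
            return nn.huber_terms(model.forward(x), y, 1.0).sum()

        pred = model.forward(x, train=True)
        model.backward(nn.huber_grad(pred, y, 1.0))
        grads, params = model.gradients(), model.parameters()
        eps = 1e-6
        for par, gr in zip(params, grads):
            flat, gflat = par.ravel(), gr.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                up = loss()
                flat[i] = old - eps
                down = loss()
                flat[i] = old
                num = (up - down) / (2 * eps)
                assert gflat[i] == pytest.approx(num, rel=1e-3, abs=1e-7)

    def test_residual_backbone_forward_shapes(self):
        model = nn.SmallConvNet(16, backbone="residual18", seed=0)
        out = model.forward(np.zeros((2, 16, 16, 3)))
        assert out.shape == (2,)
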