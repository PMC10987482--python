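"""dZ regression: normalization, labeling, aggregation algebra, training."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refplane.dzreg import (AugmentationConfig, LabelingError,
                            NormalizationError, TrainingConfig, TrainingError,
                            aggregate_predictions, augment_batch,
                            make_training_set, normalize_tile, predict_dz,
                            reduced_config, train_model)
from refplane.nnet import ConvRegressor
from refplane.refp import iqr_filter


class TestNormalizeTile:
    def test_defaults_match_selected_values(self):
        cfg = TrainingConfig()
        assert cfg.initial_learning_rate == 1e-4
        assert cfg.lr_drop_period_epochs == 15
        assert cfg.lr_drop_factor == 0.9
        assert cfg.batch_size == 32
        assert cfg.validation_frequency_steps == 2000
        assert cfg.validation_patience == 10
        assert cfg.l2_weight_decay == 5e-4
        assert cfg.validation_fraction == 0.2
        assert cfg.n_models == 10
        assert cfg.normalization_mode == "none"
        assert cfg.network_input_px == 64

    def test_zerocenter_constant_tile_is_zero(self):
        out = normalize_tile(np.full((8, 8), 42, np.uint8), "zerocenter")
        assert np.allclose(out, 0.0)

    def test_zscore_moments(self):
        rng = np.random.default_rng(0)
        tile = rng.integers(0, 255, (64, 64)).astype(np.uint8)
        out = normalize_tile(tile, "zscore")
        assert abs(out.mean()) < 1e-5
        assert abs(out.std() - 1) < 1e-5

    def test_zscore_constant_tile_fails(self):
        with pytest.raises(NormalizationError):
            normalize_tile(np.full((8, 8), 7, np.uint8), "zscore")

    def test_avg_background_scales_background_to_one(self, optical_model):
        from refplane.synth import render_bead

        tile = render_bead(20.0, 9.0, optical_model,
                           rng=np.random.default_rng(1))
        bg = optical_model.background(9.0)
        out = normalize_tile(tile, "avg_background", bg)
        corner = out[:8, :8]  # background region
        assert corner.mean() == pytest.approx(1.0, abs=0.05)

    def test_none_is_identity(self):
        tile = np.arange(16, dtype=np.uint8).reshape(4, 4)
        assert np.array_equal(normalize_tile(tile, "none"), tile.astype(np.float32))


class TestMakeTrainingSet:
    def make_inputs(self, n_z=3, beads=8, outliers=0):
        rng = np.random.default_rng(0)
        rows, tiles = [], []
        for zi in range(n_z):
            z = 1500.0 + 7.5 * zi
            for b in range(beads):
                ss = -0.2 + 0.002 * rng.normal()
                if b < outliers:
                    ss = 3.0  # grossly out of family
                rows.append({"experiment": "e", "exposure_ms": 9.0, "fov": 0,
                             "z_um": z, "bead_id": b, "ss": ss, "ci": 1.5,
                             "background": 90.0, "saturated_count": 0})
                tiles.append(rng.integers(0, 255, (64, 64)).astype(np.uint8))
        refp = pd.DataFrame([{"experiment": "e", "exposure_ms": 9.0, "fov": 0,
                              "refp_final": 1507.5}])
        return pd.DataFrame(rows), tiles, refp

    def test_labels_are_z_minus_refp(self):
        features, tiles, refp = self.make_inputs()
        X, y, idx = make_training_set(features, tiles, refp)
        assert set(np.round(np.unique(y), 2)) == {-7.5, 0.0, 7.5}
        row = features.iloc[idx[0]]
        assert y[0] == pytest.approx(row.z_um - 1507.5)

    def test_ss_outliers_removed_per_acquisition(self):
        features, tiles, refp = self.make_inputs(n_z=4, beads=25, outliers=2)
        X, y, idx = make_training_set(features, tiles, refp)
        assert len(idx) == 4 * 25 - 4 * 2

    def test_missing_refp_fails(self):
        features, tiles, _ = self.make_inputs()
        wrong = pd.DataFrame([{"experiment": "other", "exposure_ms": 9.0,
                               "fov": 0, "refp_final": 1507.5}])
        with pytest.raises(LabelingError):
            make_training_set(features, tiles, wrong)


class TestAggregation:
    def test_constant_mock_models_give_that_constant(self):
        matrix = np.full((7, 10), 12.5)
        pred = aggregate_predictions(matrix)
        assert pred.dz_final == pytest.approx(12.5)
        assert np.allclose(pred.per_model_mean, 12.5)

    @given(st.integers(1, 12), st.integers(1, 10), st.integers(0, 2**31 - 1))
    @settings(max_examples=200, deadline=None)
    def test_two_level_mean_matches_analytic(self, n_beads, n_models, seed):
        rng = np.random.default_rng(seed)
        matrix = rng.normal(0.0, 30.0, (n_beads, n_models))
        pred = aggregate_predictions(matrix)
        expected_cols = []
        for m in range(n_models):
            col = matrix[:, m]
            keep = iqr_filter(col)
            expected_cols.append(col[keep].mean())
        assert np.allclose(pred.per_model_mean, expected_cols)
        assert pred.dz_final == pytest.approx(np.mean(expected_cols))

    def test_more_beads_do_not_degrade_aggregation(self):
        """Two-level mean accuracy is flat-to-better from 6 to 20 beads."""
        rng = np.random.default_rng(11)
        errs = {}
        for n_beads in (6, 20):
            e = []
            for _ in range(400):
                truth = rng.uniform(-30, 30)
                matrix = truth + rng.normal(0, 6.0, (n_beads, 3))
                e.append(abs(aggregate_predictions(matrix).dz_final - truth))
            errs[n_beads] = np.mean(e)
        assert errs[20] <= errs[6] * 1.05

    def test_single_gross_outlier_bead_is_neutralized(self):
        rng = np.random.default_rng(3)
        clean = rng.normal(-12.0, 0.8, (7, 5))
        dirty = clean.copy()
        dirty[0, :] += 200.0
        d_clean = aggregate_predictions(clean).dz_final
        d_dirty = aggregate_predictions(dirty).dz_final
        assert abs(d_dirty - d_clean) < 1.0


class TestAugmentation:
    def test_disabled_augmentation_is_identity(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 255, (4, 32, 32)).astype(np.float32)
        out = augment_batch(x, rng, AugmentationConfig(enabled=False))
        assert np.array_equal(out, x)

    def test_output_stays_in_pixel_range(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 255, (8, 32, 32)).astype(np.float32)
        out = augment_batch(x, rng, AugmentationConfig(), pixel_scale=2.0)
        assert out.min() >= 0.0 and out.max() <= 255.0

    def test_sharpness_preserved_on_bead_tiles(self, optical_model, lam):
        # SS measured on augmented tiles stays in family with the original
        from refplane.profile import analyze_tile
        from refplane.synth import render_bead

        rng = np.random.default_rng(4)
        tiles = np.asarray([
            render_bead(0.0, 9.0, optical_model, rng=rng) for _ in range(6)
        ], dtype=np.float32)
        # rotation/scale only (keep the bead centered for feature extraction)
        aug = AugmentationConfig(translate_px=0, jitter_frac=0.0)
        out = augment_batch(tiles, rng, aug)
        ss_raw = [analyze_tile(t, lam)[0].ss for t in tiles]
        ss_aug = [analyze_tile(t, lam)[0].ss for t in out]
        assert abs(np.mean(ss_aug) - np.mean(ss_raw)) < 0.15 * abs(np.mean(ss_raw))


def tiny_dataset(optical_model, n_per=4, seed=0):
    from refplane.synth import render_bead

    rng = np.random.default_rng(seed)
    X, y = [], []
    for dz in np.arange(-45.0, 45.1, 15.0):
        for _ in range(n_per):
            c = (31.5 + rng.uniform(-0.5, 0.5), 31.5 + rng.uniform(-0.5, 0.5))
            X.append(render_bead(dz, 9.0, optical_model, center=c, rng=rng))
            y.append(dz)
    return np.asarray(X, np.float32), np.asarray(y, np.float32)


class TestTraining:
    def test_training_beats_constant_predictor(self, optical_model):
        X, y = tiny_dataset(optical_model, n_per=24)
        cfg = reduced_config(seed=0, max_epochs=60, channels=(8, 16),
                             validation_patience=60,
                             initial_learning_rate=3e-3)
        model = train_model(X, y, cfg, model_seed=0)
        # best constant predictor achieves RMSE = sd of the validation labels;
        # the trained net must do better
        assert model.best_val_rmse < 0.9 * y.std()

    def test_same_seed_reproduces_predictions(self, optical_model):
        X, y = tiny_dataset(optical_model, n_per=6)
        cfg = reduced_config(seed=0, max_epochs=3, channels=(4, 8))
        m1 = train_model(X, y, cfg, model_seed=5)
        m2 = train_model(X, y, cfg, model_seed=5)
        probe = X[:8]
        from refplane.dzreg import predict_tiles

        assert np.array_equal(predict_tiles(m1, probe), predict_tiles(m2, probe))

    def test_dataset_smaller_than_batch_fails(self):
        X = np.zeros((8, 64, 64), np.float32)
        y = np.zeros(8, np.float32)
        with pytest.raises(TrainingError):
            train_model(X, y, reduced_config(), model_seed=0)

    def test_out_of_range_flagging_with_mock_models(self):
        from refplane.dzreg import Model

        net = ConvRegressor(32, (4,), residual=False, seed=0)
        model = Model(net=net, config=reduced_config(channels=(4,)), seed=0,
                      label_range=(-10.0, 10.0), log=[], best_val_rmse=1.0,
                      label_scale=1000.0)  # inflate predictions out of range
        rng = np.random.default_rng(0)
        tiles = rng.uniform(0, 255, (3, 64, 64)).astype(np.float32)
        pred = predict_dz([model], tiles)
        assert pred.out_of_range == (not -10 <= pred.dz_final <= 10)


class TestPersistence:
    def test_save_load_round_trip(self, optical_model, tmp_path):
        from refplane.dzreg import load_models, predict_tiles, save_models

        X, y = tiny_dataset(optical_model, n_per=6)
        cfg = reduced_config(seed=0, max_epochs=2, channels=(4, 8), n_models=2)
        from refplane.dzreg import train_ensemble

        models = train_ensemble(X, y, cfg)
        assert len(models) == 2
        # distinct member weights
        w0 = models[0].net.get_weights()[0]
        w1 = models[1].net.get_weights()[0]
        assert not np.array_equal(w0, w1)
        save_models(models, str(tmp_path))
        loaded = load_models(str(tmp_path))
        probe = X[:5]
        for a, b in zip(models, loaded):
            assert np.allclose(predict_tiles(a, probe), predict_tiles(b, probe))
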