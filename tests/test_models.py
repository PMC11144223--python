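"""Feature-extractor architecture contracts, training behaviour, and the
LightGBM stacking stage."""

import numpy as np
import pytest

from driven.models import (
    ExtractorConfig,
    PROFILES,
    build_extractor,
    early_stop_epoch,
    extract_features,
    extract_features_multi,
    fit_stacker,
    predict_proba,
    train_extractor,
)


def separable_windows(n, length, rng, gap=1.0):
    """Windows whose mean level separates the classes linearly."""
    y = rng.integers(0, 2, n)
    x = rng.normal(0.0, 0.3, size=(n, length)) + (y * gap)[:, None]
    return x, y


class TestArchitecture:
    def test_profile_feature_widths(self):
        assert PROFILES["full"]["head"] == 1280
        for profile, min_len in [("tiny", 256), ("small", 512)]:
            ext = build_extractor(ExtractorConfig(profile=profile, input_samples=min_len))
            assert ext.feature_width == PROFILES[profile]["head"]

    def test_third_last_layer_width_is_final_stage_channels(self):
        ext = build_extractor(
            ExtractorConfig(profile="tiny", input_samples=256, feature_layer="third_last")
        )
        assert ext.feature_width == PROFILES["tiny"]["stages"][-1][2]

    def test_forward_on_zeros_is_finite(self):
        ext = build_extractor(ExtractorConfig(profile="tiny", input_samples=256))
        logits = ext.forward_logits(np.zeros((3, 1, 256)))
        assert logits.shape == (3, 2)
        assert np.isfinite(logits).all()

    def test_too_short_input_names_minimum(self):
        with pytest.raises(ValueError, match="minimum supported length"):
            build_extractor(ExtractorConfig(profile="tiny", input_samples=16))

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError, match="profile"):
            ExtractorConfig(profile="huge")


class TestEarlyStopping:
    def test_strictly_decreasing_never_stops(self):
        losses = list(np.linspace(1.0, 0.1, 20))
        assert early_stop_epoch(losses, patience=8) == 20

    def test_flat_from_epoch_three_stops_at_eleven(self):
        losses = [1.0, 0.8, 0.5] + [0.5] * 20
        assert early_stop_epoch(losses, patience=8) == 11

    def test_recovery_resets_patience(self):
        losses = [1.0, 0.9, 0.9, 0.9, 0.8, 0.8, 0.8, 0.8, 0.8, 0.8, 0.8, 0.8]
        assert early_stop_epoch(losses, patience=8) == 12


class TestTraining:
    def test_separable_data_learned_quickly(self, rng):
        import time

        x, y = separable_windows(128, 256, rng)
        xv, yv = separable_windows(64, 256, rng)
        ext = build_extractor(
            ExtractorConfig(profile="tiny", input_samples=256, max_epochs=10, seed=0)
        )
        t0 = time.time()
        train_extractor(ext, (x, y), (xv, yv))
        per_epoch = (time.time() - t0) / len(ext.history["val_loss"])
        logits = ext.forward_logits(x[:, None, :])
        acc = (logits.argmax(1) == y).mean()
        assert acc > 0.95
        assert len(ext.history["val_loss"]) <= 10
        assert per_epoch < 30.0  # desk-scale trainability on one CPU

    def test_training_stops_on_patience(self, rng):
        x, y = separable_windows(64, 256, rng)
        ext = build_extractor(
            ExtractorConfig(profile="tiny", input_samples=256,
                            max_epochs=30, epochs_patience=2,
                            learning_rate=0.0, seed=0)
        )
        # zero learning rate -> validation loss can never improve after
        # the first epoch, so training must stop after 1 + patience epochs
        train_extractor(ext, (x, y), (x, y))
        assert len(ext.history["val_loss"]) == 3

    def test_empty_validation_rejected(self, rng):
        x, y = separable_windows(32, 256, rng)
        ext = build_extractor(ExtractorConfig(profile="tiny", input_samples=256))
        with pytest.raises(ValueError, match="validation"):
            train_extractor(ext, (x, y), (x[:0], y[:0]))

    def test_imbalanced_training_warns(self, rng):
        x, y = separable_windows(64, 256, rng)
        y = np.zeros_like(y)
        y[:4] = 1
        ext = build_extractor(
            ExtractorConfig(profile="tiny", input_samples=256, max_epochs=1)
        )
        with pytest.warns(UserWarning, match="imbalanced"):
            train_extractor(ext, (x, y), (x, y))


class TestFeatureExtraction:
    def test_identical_windows_give_identical_rows(self, rng):
        ext = build_extractor(ExtractorConfig(profile="tiny", input_samples=256))
        w = rng.normal(size=(1, 256))
        f = extract_features(ext, np.repeat(w, 4, axis=0))
        assert np.array_equal(f[0], f[1]) and np.array_equal(f[0], f[3])

    def test_width_arithmetic_across_channels(self, rng):
        class FakeDs:
            channel_names = ("abdominal", "spo2")
            windows = rng.normal(size=(6, 2, 256))

        exts = {
            name: build_extractor(
                ExtractorConfig(profile="tiny", input_samples=256), name
            )
            for name in FakeDs.channel_names
        }
        f = extract_features_multi(exts, FakeDs())
        assert f.shape == (6, 2 * PROFILES["tiny"]["head"])

    def test_channel_mismatch_is_an_error(self, rng):
        class FakeDs:
            channel_names = ("thoracic",)
            windows = rng.normal(size=(2, 1, 256))

        exts = {"abdominal": build_extractor(ExtractorConfig(profile="tiny", input_samples=256), "abdominal")}
        with pytest.raises(ValueError, match="thoracic"):
            extract_features_multi(exts, FakeDs())

    def test_wrong_window_length_rejected(self, rng):
        ext = build_extractor(ExtractorConfig(profile="tiny", input_samples=256))
        with pytest.raises(ValueError, match="samples"):
            extract_features(ext, rng.normal(size=(2, 100)))


class TestStacker:
    def test_separable_features_reach_high_auroc(self, rng):
        from driven.metrics import roc_auc

        n = 400
        y = rng.integers(0, 2, n)
        x = np.column_stack([y + 0.1 * rng.normal(size=n), rng.normal(size=n)])
        stacker = fit_stacker(x, y, search_budget=3, seed=0)
        probs = predict_proba(stacker, x)
        assert roc_auc(probs, y) > 0.99

    def test_budget_one_fits_single_configuration(self, rng):
        y = rng.integers(0, 2, 100)
        x = rng.normal(size=(100, 3))
        stacker = fit_stacker(x, y, search_budget=1, seed=0)
        assert len(stacker.search_results) == 1

    def test_same_seed_selects_same_hyperparameters(self, rng):
        y = rng.integers(0, 2, 200)
        x = np.column_stack([y + rng.normal(size=200), rng.normal(size=200)])
        a = fit_stacker(x, y, search_budget=4, seed=3)
        b = fit_stacker(x, y, search_budget=4, seed=3)
        assert a.params == b.params

    def test_probabilities_in_unit_interval(self, rng):
        y = rng.integers(0, 2, 100)
        x = rng.normal(size=(100, 4))
        stacker = fit_stacker(x, y, search_budget=2, seed=0)
        probs = predict_proba(stacker, rng.normal(size=(50, 4)))
        assert np.all((probs >= 0) & (probs <= 1))

    def test_monotone_in_single_informative_feature(self, rng):
        y = (rng.random(500) < 0.5).astype(int)
        x = (y * 2.0 + rng.normal(0, 0.1, 500))[:, None]
        stacker = fit_stacker(x, y, search_budget=2, seed=1)
        grid = np.linspace(-1, 3, 30)[:, None]
        probs = predict_proba(stacker, grid)
        assert probs[-1] > probs[0]
        # piecewise-constant tree output: overall trend must be non-decreasing
        assert np.sum(np.diff(probs) < -0.05) == 0

    def test_single_class_labels_rejected(self, rng):
        with pytest.raises(ValueError, match="single class"):
            fit_stacker(rng.normal(size=(20, 2)), np.ones(20), 1, 0)

    def test_feature_width_mismatch_rejected(self, rng):
        y = rng.integers(0, 2, 50)
        stacker = fit_stacker(rng.normal(size=(50, 3)), y, 1, 0)
        with pytest.raises(ValueError, match="width"):
            predict_proba(stacker, rng.normal(size=(5, 4)))
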