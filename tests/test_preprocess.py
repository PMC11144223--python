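"""Signal-conditioning contracts: trimming, robust normalisation,
spline resampling, QRS detection, SpO2 delays."""

import numpy as np
import pytest

from driven import io_formats as io
from driven.preprocess import (
    PreprocessConfig,
    delay_channel,
    detect_r_peaks,
    extract_rri,
    preprocess_recording,
    resample,
    robust_normalize,
    trim,
)
from driven.synthetic_psg import SimParams, simulate_recording


def flat_recording(duration_s=7200, rate=4):
    rng = np.random.default_rng(0)
    ch = io.Channel(rng.normal(size=int(duration_s * rate)), rate)
    return io.Recording("P0", {"abdominal": ch}, float(duration_s))


class TestTrim:
    def test_removes_setup_time_and_drops_early_events(self):
        rec = flat_recording(duration_s=480 * 60)
        ann = io.AnnotationSet(
            events=[io.Event(io.APNEA, 10 * 60, 20.0)],
            sleep_stages=np.ones(960, dtype=np.int8),
        )
        out, out_ann = trim(rec, 30.0, ann)
        assert out.duration_s == 420 * 60
        assert len(out.channels["abdominal"].samples) == 420 * 60 * 4
        assert out_ann.events == []
        assert len(out_ann.sleep_stages) == 840

    def test_zero_trim_is_identity(self):
        rec = flat_recording(duration_s=3600)
        out = trim(rec, 0.0)
        assert np.array_equal(out.channels["abdominal"].samples,
                              rec.channels["abdominal"].samples)

    def test_boundary_event_is_clipped(self):
        rec = flat_recording(duration_s=7200)
        ann = io.AnnotationSet(
            events=[io.Event(io.APNEA, 29 * 60, 120.0)],
            sleep_stages=np.ones(240, dtype=np.int8),
        )
        _, out_ann = trim(rec, 30.0, ann)
        ev = out_ann.events[0]
        assert ev.start_s == 0.0
        assert ev.duration_s == pytest.approx(60.0)

    def test_too_short_recording_raises(self):
        with pytest.raises(ValueError, match="too short"):
            trim(flat_recording(duration_s=3000), 30.0)


class TestRobustNormalize:
    def test_constant_maps_to_half(self):
        assert np.all(robust_normalize(np.full(50, 7.0)) == 0.5)

    def test_non_constant_hits_zero_and_one(self, rng):
        for _ in range(5):
            y = robust_normalize(rng.normal(size=500))
            assert y.min() == pytest.approx(0.0)
            assert y.max() == pytest.approx(1.0)
            assert np.all((y >= 0) & (y <= 1))

    def test_single_outlier_barely_moves_other_samples(self, rng):
        x = np.sin(np.arange(2000) * 0.05) + 0.1 * rng.normal(size=2000)
        clean = robust_normalize(x)
        dirty = x.copy()
        dirty[1000] = 1000 * np.abs(x).max()
        polluted = robust_normalize(dirty)
        mask = np.ones(2000, dtype=bool)
        mask[1000] = False
        assert np.abs(polluted[mask] - clean[mask]).max() < 0.01

    def test_idempotent_on_normalized_input(self, rng):
        y = robust_normalize(rng.normal(size=1000))
        again = robust_normalize(y)
        assert np.abs(again - y).max() < 0.01

    def test_all_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            robust_normalize(np.full(20, np.nan))


class TestResample:
    def test_identity_rate_reproduces_knots(self, rng):
        x = rng.normal(size=64)
        out = resample(x, 8.0, 8.0)
        assert np.allclose(out, x, atol=1e-9)

    def test_sine_against_analytic_oracle(self):
        rate_in = 4.0
        t_in = np.arange(int(120 * rate_in)) / rate_in
        x = np.sin(2 * np.pi * 0.25 * t_in)
        out = resample(x, rate_in, 64.0)
        t_out = np.minimum(np.arange(len(out)) / 64.0, t_in[-1])
        assert np.abs(out - np.sin(2 * np.pi * 0.25 * t_out)).max() < 1e-2

    def test_linear_ramp_is_exact(self):
        x = np.linspace(0.0, 5.0, 21)
        out = resample(x, 2.0, 16.0)
        t_out = np.minimum(np.arange(len(out)) / 16.0, 10.0)
        assert np.allclose(out, 0.5 * t_out, atol=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="4 samples"):
            resample(np.ones(3), 1.0, 4.0)


class TestPanTompkins:
    def test_constant_sixty_bpm_gives_unit_rri(self):
        params = SimParams(duration_h=0.25, sleep_fraction=1.0, target_ahi=0.0,
                           channel_rates={"ecg": 128}, seed=2)
        rec, _, _ = simulate_recording(params)
        rri = extract_rri(rec.channels["ecg"].samples, 128.0, 64.0)
        assert np.abs(rri - 1.0).max() <= 1.0 / 128.0

    def test_nearly_all_planted_peaks_recovered(self, short_night):
        rec, _, gt = short_night
        peaks = detect_r_peaks(rec.channels["ecg"].samples, rec.channels["ecg"].rate)
        matched = sum(np.min(np.abs(peaks - tp)) <= 0.040 for tp in gt.r_peaks)
        assert matched / len(gt.r_peaks) >= 0.99

    def test_heart_rate_step_tracks_within_five_seconds(self):
        params = SimParams(
            duration_h=0.25, sleep_fraction=1.0, target_ahi=0.0,
            channel_rates={"ecg": 128}, heart_rate_bpm=[(0.0, 60.0), (450.0, 80.0)],
            seed=4,
        )
        rec, _, _ = simulate_recording(params)
        rri = extract_rri(rec.channels["ecg"].samples, 128.0, 64.0)
        assert rri[int(440 * 64)] == pytest.approx(1.0, abs=0.02)
        assert rri[int(456 * 64)] == pytest.approx(0.75, abs=0.02)

    def test_flatline_has_no_qrs(self):
        with pytest.raises(ValueError, match="QRS"):
            detect_r_peaks(np.zeros(128 * 20), 128.0)


class TestDelayChannel:
    def test_zero_delay_identity(self, rng):
        x = rng.normal(size=100)
        assert np.array_equal(delay_channel(x, 1.0, 0.0), x)

    def test_impulse_moves_earlier(self):
        x = np.zeros(200)
        x[100] = 1.0
        out = delay_channel(x, 1.0, 10.0)
        assert out[90] == 1.0 and out[100] == 0.0

    def test_tail_is_edge_padded(self):
        x = np.arange(50, dtype=float)
        out = delay_channel(x, 1.0, 5.0)
        assert np.all(out[-5:] == 49.0)

    def test_delay_longer_than_signal_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            delay_channel(np.ones(10), 1.0, 10.0)


class TestPipelineAssembly:
    def test_all_channels_share_rate_and_length(self, short_night):
        rec, ann, _ = short_night
        cfg = PreprocessConfig(trim_min=0.0, target_rate=8.0, spo2_delays=(10.0, 15.0, 20.0, 25.0))
        out, _ = preprocess_recording(rec, cfg, ("abdominal", "thoracic", "spo2"), ann)
        lengths = {len(ch.samples) for ch in out.channels.values()}
        rates = {ch.rate for ch in out.channels.values()}
        assert len(lengths) == 1 and rates == {8.0}
        assert set(out.channels) == {
            "abdominal", "thoracic", "spo2",
            "spo2+10s", "spo2+15s", "spo2+20s", "spo2+25s",
        }

    def test_delayed_spo2_channels_are_shifted_copies(self, short_night):
        rec, _, _ = short_night
        cfg = PreprocessConfig(trim_min=0.0, target_rate=8.0, spo2_delays=(10.0,))
        out = preprocess_recording(rec, cfg, ("spo2",))
        base = out.channels["spo2"].samples
        delayed = out.channels["spo2+10s"].samples
        assert np.allclose(delayed[: len(base) - 80], base[80:])

    def test_rri_channel_added_when_enabled(self, short_night):
        rec, _, _ = short_night
        cfg = PreprocessConfig(trim_min=0.0, target_rate=8.0, spo2_delays=(), rri_enabled=True)
        out = preprocess_recording(rec, cfg, ("abdominal",))
        assert "rri" in out.channels
        assert len(out.channels["rri"].samples) == len(out.channels["abdominal"].samples)

    def test_normalization_order_configurable(self, short_night):
        rec, _, _ = short_night
        for order in (True, False):
            cfg = PreprocessConfig(trim_min=0.0, target_rate=8.0, spo2_delays=(),
                                   normalize_after_resample=order)
            out = preprocess_recording(rec, cfg, ("abdominal",))
            s = out.channels["abdominal"].samples
            assert s.min() >= -1e-9 and s.max() <= 1 + 1e-9
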