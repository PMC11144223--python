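"""Per-channel signal conditioning ahead of windowing.

The pipeline is: drop the first and last 30 min of the night (sensor set-up
time), resample every channel to a common working rate with a cubic spline,
and normalise each channel robustly — statistics are taken from the central
95 % of the samples and the min-max map is applied to the clipped z-scores,
so a handful of extreme artefacts cannot shrink the useful dynamic range.
An RR-interval (RRI) channel can be derived from ECG with the Pan-Tompkins
QRS detector, and SpO₂ can be shifted forward in time by fixed delays so a
window anchored at an event sees the late oxygen response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, find_peaks, sosfiltfilt

from .io_formats import AnnotationSet, Arousal, Channel, Desaturation, Event, Recording

EPOCH_S = 30.0


@dataclass
class PreprocessConfig:
    trim_min: float = 30.0
    target_rate: float = 64.0
    central_fraction: float = 0.95
    spo2_delays: tuple = (10.0, 15.0, 20.0, 25.0)
    rri_enabled: bool = False
    #: normalise after resampling by default; the reverse order is allowed
    normalize_after_resample: bool = True
    rri_interp: str = "step"  # or "spline"

    def __post_init__(self):
        if not 0.0 < self.central_fraction <= 1.0:
            raise ValueError("central_fraction must be in (0, 1]")


def trim(
    recording: Recording,
    trim_min: float,
    annotations: AnnotationSet | None = None,
):
    """Remove the first and last ``trim_min`` minutes.

    Events are shifted into the new time base; events outside the retained
    interval are dropped and boundary events clipped.  Returns the trimmed
    Recording, or (Recording, AnnotationSet) when annotations are given.
    """
    trim_s = trim_min * 60.0
    if trim_s < 0:
        raise ValueError("trim_min must be >= 0")
    new_dur = recording.duration_s - 2 * trim_s
    if new_dur <= 0:
        raise ValueError(
            f"recording too short: {recording.duration_s / 60:.0f} min <= "
            f"2 x {trim_min:.0f} min trim"
        )
    channels = {}
    for name, ch in recording.channels.items():
        i0 = int(round(trim_s * ch.rate))
        i1 = i0 + int(round(new_dur * ch.rate))
        channels[name] = Channel(ch.samples[i0:i1].copy(), ch.rate, ch.physical_unit)
    out = Recording(recording.patient_id, channels, new_dur, recording.start_time)
    if annotations is None:
        return out

    def shift_clip(start, dur):
        s, e = start - trim_s, start - trim_s + dur
        s2, e2 = max(s, 0.0), min(e, new_dur)
        if e2 <= s2:
            return None
        return s2, e2 - s2

    events = []
    for ev in annotations.events:
        clipped = shift_clip(ev.start_s, ev.duration_s)
        if clipped:
            events.append(Event(ev.type, *clipped, ev.source_channel))
    arousals = []
    for ar in annotations.arousals:
        clipped = shift_clip(ar.start_s, ar.duration_s)
        if clipped:
            arousals.append(Arousal(*clipped))
    desats = []
    for de in annotations.desaturations:
        clipped = shift_clip(de.start_s, de.duration_s)
        if clipped:
            desats.append(Desaturation(*clipped, de.depth_percent))
    ep0 = int(trim_s // EPOCH_S)
    n_ep = int(new_dur // EPOCH_S)
    stages = annotations.sleep_stages[ep0 : ep0 + n_ep].copy()
    return out, AnnotationSet(events, arousals, desats, stages)


def robust_normalize(samples: np.ndarray, central_fraction: float = 0.95) -> np.ndarray:
    """Outlier-immune map to [0, 1].

    Mean and SD are computed over the values inside the central
    ``central_fraction`` percentile band; z-scores are clipped to the band's
    own z-range and min-max scaled, so the output hits 0 and 1 exactly for
    any non-constant input while a lone extreme artefact moves the
    remaining samples by well under 1 %.  Constant input maps to 0.5.
    """
    x = np.asarray(samples, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size == 0:
        raise ValueError("all samples are NaN")
    if finite.size < 10:
        raise ValueError("need at least 10 finite samples")
    tail = 100.0 * (1.0 - central_fraction) / 2.0
    lo, hi = np.percentile(finite, [tail, 100.0 - tail])
    core = finite[(finite >= lo) & (finite <= hi)]
    mean, sd = core.mean(), core.std()
    if sd == 0 or hi == lo:
        return np.full_like(x, 0.5)
    z = np.clip((x - mean) / sd, (lo - mean) / sd, (hi - mean) / sd)
    zmin, zmax = (lo - mean) / sd, (hi - mean) / sd
    return (z - zmin) / (zmax - zmin)


def resample(samples: np.ndarray, rate_in: float, target_rate: float) -> np.ndarray:
    """Cubic-spline resampling onto a uniform grid over the same time span."""
    x = np.asarray(samples, dtype=float)
    if x.size < 4:
        raise ValueError("cubic-spline resampling needs at least 4 samples")
    if rate_in <= 0 or target_rate <= 0:
        raise ValueError("rates must be positive")
    duration = x.size / rate_in
    t_in = np.arange(x.size) / rate_in
    spline = CubicSpline(t_in, x, bc_type="natural")
    t_out = np.arange(int(round(duration * target_rate))) / target_rate
    out = spline(np.minimum(t_out, t_in[-1]))  # hold past the last knot
    return out


# ---------------------------------------------------------------------------
# Pan-Tompkins QRS detection and RRI
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: np.ndarray, rate: float) -> np.ndarray:
    """R-peak times (s) via the Pan-Tompkins chain.

    Zero-phase 5-15 Hz band-pass, five-point derivative, squaring, 150 ms
    moving-window integration, then adaptive dual thresholds with a 200 ms
    refractory period and RR-based search-back.  Constants are scaled to
    the working rate.
    """
    x = np.asarray(ecg, dtype=float)
    if x.size / rate < 10.0:
        raise ValueError("need at least 10 s of ECG")
    if rate < 60.0:
        raise ValueError("ECG rate must be >= 60 Hz for QRS detection")
    sos = butter(3, [5.0, 15.0], btype="bandpass", fs=rate, output="sos")
    band = sosfiltfilt(sos, x)
    deriv = np.convolve(band, np.array([1, 2, 0, -2, -1]) * (rate / 8.0), mode="same")
    mwi = np.convolve(deriv**2, np.ones(max(1, int(0.15 * rate))) / max(1, int(0.15 * rate)), mode="same")

    refractory = int(0.2 * rate)
    cand, _ = find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        raise ValueError("no QRS found")
    warm = mwi[: int(2 * rate)]
    spki = 0.25 * warm.max()
    npki = 0.5 * warm.mean()
    rr_hist: list[float] = []
    detected: list[int] = []
    last_missed: list[int] = []
    for p in cand:
        thr = npki + 0.25 * (spki - npki)
        if mwi[p] >= thr:
            if detected and rr_hist:
                rr_avg = np.mean(rr_hist[-8:])
                if (p - detected[-1]) > 1.66 * rr_avg * rate and last_missed:
                    # search-back: strongest skipped candidate above thr/2
                    back = [q for q in last_missed if mwi[q] >= thr / 2 and q > detected[-1] + refractory]
                    if back:
                        q = max(back, key=lambda i: mwi[i])
                        rr_hist.append((q - detected[-1]) / rate)
                        detected.append(q)
            if detected:
                rr_hist.append((p - detected[-1]) / rate)
            detected.append(p)
            spki = 0.125 * mwi[p] + 0.875 * spki
            last_missed = []
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki
            last_missed.append(p)
    if not detected:
        raise ValueError("no QRS found")
    # refine to the band-passed maximum within +/-100 ms
    half = int(0.1 * rate)
    times = []
    for p in detected:
        i0, i1 = max(0, p - half), min(x.size, p + half + 1)
        times.append((i0 + np.argmax(np.abs(band[i0:i1]))) / rate)
    times = np.array(sorted(set(times)))
    return times[np.concatenate(([True], np.diff(times) > 0.2))]


def extract_rri(
    ecg: np.ndarray,
    rate: float,
    target_rate: float = 64.0,
    interp: str = "step",
) -> np.ndarray:
    """Uniformly sampled RR-interval series (seconds) at ``target_rate``.

    ``step`` holds each RR value between the two beats that define it;
    ``spline`` interpolates through the interval midpoints.
    """
    peaks = detect_r_peaks(ecg, rate)
    if peaks.size < 2:
        raise ValueError("no QRS found")
    rr = np.diff(peaks)
    duration = len(ecg) / rate
    t_out = np.arange(int(round(duration * target_rate))) / target_rate
    if interp == "step":
        idx = np.clip(np.searchsorted(peaks, t_out, side="right") - 1, 0, rr.size - 1)
        return rr[idx]
    if interp == "spline":
        mid = (peaks[:-1] + peaks[1:]) / 2.0
        if mid.size < 4:
            return np.interp(t_out, mid, rr)
        return CubicSpline(mid, rr, bc_type="natural")(np.clip(t_out, mid[0], mid[-1]))
    raise ValueError(f"unknown interp {interp!r}")


def delay_channel(samples: np.ndarray, rate: float, delay_s: float) -> np.ndarray:
    """Advance the signal: output at t equals input at t + delay_s.

    A window anchored at an event onset then sees the delayed SpO₂
    response.  The trailing ``delay_s`` seconds hold the last value.
    """
    if delay_s < 0:
        raise ValueError("delay must be >= 0")
    x = np.asarray(samples, dtype=float)
    n = int(round(delay_s * rate))
    if n >= x.size:
        raise ValueError("delay is at least the signal duration")
    if n == 0:
        return x.copy()
    return np.concatenate([x[n:], np.full(n, x[-1])])


def preprocess_recording(
    recording: Recording,
    config: PreprocessConfig,
    channels: tuple[str, ...] = ("abdominal", "thoracic", "spo2"),
    annotations: AnnotationSet | None = None,
):
    """Full conditioning pipeline for the selected channels.

    Trims, resamples every channel to ``config.target_rate``, normalises,
    appends the delayed SpO₂ variants when SpO₂ is selected, and derives an
    RRI channel from ECG when enabled.  All output channels share one rate
    and length.
    """
    trimmed = trim(recording, config.trim_min, annotations)
    if annotations is not None:
        trimmed, annotations = trimmed

    def condition(samples, rate):
        if config.normalize_after_resample:
            return robust_normalize(
                resample(samples, rate, config.target_rate), config.central_fraction
            )
        return resample(
            robust_normalize(samples, config.central_fraction), rate, config.target_rate
        )

    out: dict[str, Channel] = {}
    for name in channels:
        if name == "rri":
            continue
        ch = trimmed.channels[name]
        out[name] = Channel(condition(ch.samples, ch.rate), config.target_rate, "norm")
        if name == "spo2":
            for d in config.spo2_delays:
                out[f"spo2+{d:g}s"] = Channel(
                    delay_channel(out["spo2"].samples, config.target_rate, d),
                    config.target_rate,
                    "norm",
                )
    if config.rri_enabled or "rri" in channels:
        ecg = trimmed.channels["ecg"]
        rri = extract_rri(ecg.samples, ecg.rate, config.target_rate, config.rri_interp)
        out["rri"] = Channel(
            robust_normalize(rri, config.central_fraction), config.target_rate, "norm"
        )
    lengths = {name: len(ch.samples) for name, ch in out.items()}
    n = min(lengths.values())
    if max(lengths.values()) - n > 1:
        raise AssertionError(f"channel lengths diverge after preprocessing: {lengths}")
    for ch in out.values():
        ch.samples = ch.samples[:n]
    result = Recording(recording.patient_id, out, n / config.target_rate, recording.start_time)
    if annotations is not None:
        return result, annotations
    return result
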