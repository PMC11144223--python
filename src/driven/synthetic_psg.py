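"""Synthetic overnight sleep recordings with exactly known ground truth.

The generator plants apnea and hypopnea events into an artificial night and
renders the five home-measurable channels around them:

* respiratory effort (abdominal, thoracic) — amplitude-modulated ~0.25 Hz
  sinusoids whose envelope collapses during events and becomes large and
  erratic while the subject is awake;
* nasal airflow — same carrier, reduced by more than 90 % during apneas and
  by 30-70 % during hypopneas (each lasting at least 10 s);
* SpO₂ — a 97 % baseline with delayed piecewise-exponential desaturations
  (depth >= 3 %) following each apnea and type-1 hypopnea onset;
* ECG — Gaussian R-wave templates at exactly known beat times.

Hypopnea subtypes follow the AHI scoring rules: type 1 carries a >= 3 %
desaturation starting within 45 s of event onset, type 2 an arousal within
5 s after the event end, type 3 neither (and never counts toward the AHI).
Waveform shapes are deliberately simple fixtures: they exercise every
detector in the pipeline without claiming physiological realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import (
    APNEA,
    HYPOPNEA1,
    HYPOPNEA2,
    HYPOPNEA3,
    AnnotationSet,
    Arousal,
    Channel,
    Desaturation,
    Event,
    Recording,
)

EPOCH_S = 30
RESP_FREQ_HZ = 0.25
SPO2_BASELINE = 97.0
MIN_EVENT_GAP_S = 10.0

DEFAULT_CHANNEL_RATES = {
    "abdominal": 32,
    "thoracic": 32,
    "airflow": 32,
    "spo2": 1,
    "ecg": 128,
}

#: amplitude of the airflow/effort envelope during events, relative to the
#: quiet-sleep baseline of 1.0
APNEA_FLOW_AMP = 0.02
HYPOPNEA_FLOW_AMP = 0.40
APNEA_EFFORT_AMP = 0.30
HYPOPNEA_EFFORT_AMP = 0.55

SEVERITY_BANDS = {
    "healthy": (1.0, 4.5),
    "mild": (5.5, 14.5),
    "moderate": (15.5, 29.5),
    "severe": (31.0, 55.0),
}
SEVERITY_ORDER = ("healthy", "mild", "moderate", "severe")


@dataclass
class SimParams:
    """Study conditions for one synthetic night."""

    duration_h: float = 8.0
    sleep_fraction: float = 0.875
    target_ahi: float = 15.0
    event_mix: dict = field(
        default_factory=lambda: {
            APNEA: 0.40,
            HYPOPNEA1: 0.30,
            HYPOPNEA2: 0.15,
            HYPOPNEA3: 0.15,
        }
    )
    event_duration_range: tuple = (10.0, 25.0)
    desat_depth: float = 4.0
    desat_delay: float = 15.0
    heart_rate_bpm: float | list = 60.0
    channel_rates: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_RATES))
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self):
        mix_sum = sum(self.event_mix.values())
        if abs(mix_sum - 1.0) > 1e-9:
            raise ValueError(f"event_mix must sum to 1 (got {mix_sum})")
        if self.event_duration_range[0] < 10.0:
            raise ValueError("event durations must be at least 10 s")
        if not 0.0 < self.sleep_fraction <= 1.0:
            raise ValueError("sleep_fraction must be in (0, 1]")
        if self.target_ahi < 0:
            raise ValueError("target_ahi must be >= 0")
        if self.target_ahi > 0 and self.desat_depth < 3.0:
            raise ValueError("desat_depth must be >= 3 % for scoreable events")
        if not 0.0 <= self.desat_delay <= 45.0:
            raise ValueError("desat_delay must be within [0, 45] s")


@dataclass
class GroundTruth:
    events: list[Event]
    arousals: list[Arousal]
    sleep_stages: np.ndarray  # 0 = awake, 1 = sleep, per 30 s epoch
    r_peaks: np.ndarray  # seconds
    planted_ahi: float

    @property
    def sleep_hours(self) -> float:
        return float(self.sleep_stages.sum()) * EPOCH_S / 3600.0


# ---------------------------------------------------------------------------
# stage track and event placement
# ---------------------------------------------------------------------------

def _make_sleep_stages(n_epochs: int, sleep_fraction: float, rng) -> np.ndarray:
    """Awake time as contiguous blocks: onset, offset, mid-night awakenings."""
    n_awake = int(round(n_epochs * (1.0 - sleep_fraction)))
    stages = np.ones(n_epochs, dtype=np.int8)
    if n_awake == 0:
        return stages
    onset = max(1, int(round(n_awake * 0.4)))
    tail = max(0, min(int(round(n_awake * 0.3)), n_awake - onset))
    mid = n_awake - onset - tail
    stages[:onset] = 0
    if tail:
        stages[n_epochs - tail :] = 0
    while mid > 0:
        block = min(mid, max(1, int(rng.integers(1, 4))))
        lo, hi = onset + 2, n_epochs - tail - block - 2
        if hi <= lo:
            break
        start = int(rng.integers(lo, hi))
        stages[start : start + block] = 0
        mid -= block
    return stages


def _sleep_runs(stages: np.ndarray) -> list[tuple[float, float]]:
    """Contiguous sleep intervals in seconds."""
    runs = []
    start = None
    for i, s in enumerate(stages):
        if s and start is None:
            start = i
        elif not s and start is not None:
            runs.append((start * EPOCH_S, i * EPOCH_S))
            start = None
    if start is not None:
        runs.append((start * EPOCH_S, len(stages) * EPOCH_S))
    return [(float(a), float(b)) for a, b in runs]


def _event_counts(n_ahi: int, mix: dict) -> dict:
    """Per-type counts: exactly n_ahi AHI events, largest-remainder rounding."""
    ahi_types = [APNEA, HYPOPNEA1, HYPOPNEA2]
    p_ahi = sum(mix.get(t, 0.0) for t in ahi_types)
    counts = {t: 0 for t in (*ahi_types, HYPOPNEA3)}
    if n_ahi == 0 or p_ahi == 0:
        return counts
    quotas = {t: n_ahi * mix.get(t, 0.0) / p_ahi for t in ahi_types}
    for t in ahi_types:
        counts[t] = int(quotas[t])
    rem = n_ahi - sum(counts.values())
    for t in sorted(ahi_types, key=lambda t: quotas[t] - int(quotas[t]), reverse=True)[:rem]:
        counts[t] += 1
    counts[HYPOPNEA3] = int(round(n_ahi * mix.get(HYPOPNEA3, 0.0) / p_ahi))
    return counts


def _place_events(
    runs: list[tuple[float, float]],
    types: list[str],
    params: SimParams,
    rng,
) -> list[Event]:
    """Plant typed events into sleep runs, >= 10 s of normal breathing apart.

    After an apnea or type-1 hypopnea the gap is stretched so that its
    delayed desaturation starts before the next event begins, keeping the
    subtype rules unambiguous.
    """
    n = len(types)
    if n == 0:
        return []
    lo, hi = params.event_duration_range
    durations = rng.uniform(lo, hi, size=n)
    margin = 2.0

    def min_gap_after(ev_type: str, duration: float) -> float:
        # the delayed desaturation must start before the next event begins
        if ev_type in (APNEA, HYPOPNEA1):
            return max(MIN_EVENT_GAP_S, params.desat_delay - duration + 1.0)
        return MIN_EVENT_GAP_S

    # allocate event counts to sleep runs proportional to run length, then
    # repair any run whose events (durations + minimum gaps) do not fit
    lengths = np.array([b - a - 2 * margin for a, b in runs])
    lengths = np.maximum(lengths, 0.0)
    if lengths.sum() <= 0:
        raise ValueError("no sleep available to host events")
    quotas = lengths / lengths.sum() * n
    counts = quotas.astype(int)
    for i in np.argsort(quotas - counts)[::-1][: n - counts.sum()]:
        counts[i] += 1
    bounds = np.concatenate([[0], np.cumsum(counts)])
    assigned = [list(range(bounds[r], bounds[r + 1])) for r in range(len(runs))]

    def need(idx_list):
        if not idx_list:
            return 0.0
        return float(
            durations[idx_list].sum()
            + sum(min_gap_after(types[i], durations[i]) for i in idx_list[:-1])
        )

    for _ in range(4 * n + 4):
        spare = np.array([lengths[r] - need(assigned[r]) for r in range(len(runs))])
        worst = int(np.argmin(spare))
        if spare[worst] >= 0:
            break
        best = int(np.argmax(spare))
        if not assigned[worst] or best == worst:
            break
        assigned[best].append(assigned[worst].pop())
    spare = np.array([lengths[r] - need(assigned[r]) for r in range(len(runs))])
    if spare.min() < 0:
        raise ValueError(
            f"recording too short: cannot place {n} events at "
            f"target AHI {params.target_ahi}"
        )

    # stick-breaking within each run: the minimum-gap skeleton plus
    # exponentially weighted shares of the run's slack
    events: list[Event] = []
    for r, (run_start, _run_end) in enumerate(runs):
        idx = assigned[r]
        if not idx:
            continue
        slack = lengths[r] - need(idx)
        w = rng.exponential(size=len(idx) + 1)
        extra = slack * w / w.sum()
        cursor = run_start + margin + extra[0]
        for j, i in enumerate(idx):
            events.append(Event(types[i], round(cursor, 2), round(durations[i], 2), "airflow"))
            cursor += durations[i] + min_gap_after(types[i], durations[i]) + extra[j + 1]
    events.sort(key=lambda e: e.start_s)
    return events


# ---------------------------------------------------------------------------
# waveform rendering
# ---------------------------------------------------------------------------

def _smooth_envelope(env: np.ndarray, rate: float) -> np.ndarray:
    """~1 s moving-average taper so event edges are not step artefacts."""
    w = max(1, int(round(rate)))
    kernel = np.ones(w) / w
    return np.convolve(env, kernel, mode="same")


def _respiratory_channel(
    t: np.ndarray,
    rate: float,
    events: list[Event],
    stages: np.ndarray,
    event_amps: dict,
    awake_gain: float,
    noise_sd: float,
    rng,
) -> np.ndarray:
    env = np.ones_like(t)
    for ev in events:
        amp = event_amps[APNEA] if ev.type == APNEA else event_amps["hypopnea"]
        i0, i1 = int(ev.start_s * rate), int(ev.end_s * rate)
        env[i0:i1] = amp
    awake = stages[np.minimum((t // EPOCH_S).astype(int), len(stages) - 1)] == 0
    slow = rng.normal(0.0, 1.0, size=max(2, int(t[-1] / 5.0) + 2))
    slow_t = np.interp(t, np.arange(len(slow)) * 5.0, slow)
    env = np.where(awake, awake_gain * (1.0 + 0.3 * slow_t), env)
    env = _smooth_envelope(env, rate)
    phase = 2 * np.pi * RESP_FREQ_HZ * t + rng.uniform(0, 2 * np.pi)
    x = env * np.sin(phase) + rng.normal(0.0, noise_sd, size=t.shape)
    x[awake] += rng.normal(0.0, 3 * noise_sd, size=int(awake.sum()))
    return x


def _spo2_channel(
    t: np.ndarray, desats: list[Desaturation], noise_sd: float, rng
) -> np.ndarray:
    x = np.full_like(t, SPO2_BASELINE)
    for des in desats:
        fall = 0.45 * des.duration_s
        tau_fall = fall / 3.0
        tau_rec = 0.25 * des.duration_s
        seg = (t >= des.start_s) & (t < des.start_s + fall)
        x[seg] -= des.depth_percent * (1.0 - np.exp(-(t[seg] - des.start_s) / tau_fall))
        reached = des.depth_percent * (1.0 - np.exp(-fall / tau_fall))
        rec = (t >= des.start_s + fall) & (t < des.start_s + des.duration_s + 20.0)
        x[rec] -= reached * np.exp(-(t[rec] - des.start_s - fall) / tau_rec)
    return x + rng.normal(0.0, 0.1 * max(noise_sd / 0.03, 0.5), size=t.shape)


def _beat_times(duration_s: float, heart_rate_bpm, rng) -> np.ndarray:
    if np.isscalar(heart_rate_bpm):
        schedule = [(0.0, float(heart_rate_bpm))]
    else:
        schedule = [(float(a), float(b)) for a, b in heart_rate_bpm]
    beats = []
    t = 0.5
    while t < duration_s - 0.5:
        bpm = schedule[0][1]
        for start, value in schedule:
            if t >= start:
                bpm = value
        beats.append(t)
        t += 60.0 / bpm
    return np.asarray(beats)


def _ecg_channel(t: np.ndarray, rate: float, r_peaks: np.ndarray, rng) -> np.ndarray:
    x = rng.normal(0.0, 0.01, size=t.shape)
    width = 0.012  # Gaussian R-wave sigma, seconds
    half = int(0.05 * rate)
    for tp in r_peaks:
        c = int(round(tp * rate))
        i0, i1 = max(0, c - half), min(len(t), c + half + 1)
        x[i0:i1] += np.exp(-((t[i0:i1] - tp) ** 2) / (2 * width**2))
    return x


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def simulate_recording(
    params: SimParams, patient_id: str = "SYN000"
) -> tuple[Recording, AnnotationSet, GroundTruth]:
    """Generate one synthetic night.

    Same params (including seed) produce bit-identical output.  Raises
    ``ValueError`` when the night cannot host the requested event load.
    """
    rng = np.random.default_rng(params.seed)
    n_epochs = int(params.duration_h * 3600 // EPOCH_S)
    duration_s = n_epochs * EPOCH_S
    stages = _make_sleep_stages(n_epochs, params.sleep_fraction, rng)
    sleep_hours = stages.sum() * EPOCH_S / 3600.0

    n_ahi = int(round(params.target_ahi * sleep_hours))
    if params.target_ahi > 0 and n_ahi == 0:
        raise ValueError(
            f"recording too short to host one event at target AHI "
            f"{params.target_ahi} with {sleep_hours:.2f} h sleep"
        )
    counts = _event_counts(n_ahi, params.event_mix)
    types = [t for t, c in counts.items() for _ in range(c)]
    rng.shuffle(types)
    events = _place_events(_sleep_runs(stages), types, params, rng)

    arousals: list[Arousal] = []
    desats: list[Desaturation] = []
    for ev in events:
        if ev.type in (APNEA, HYPOPNEA1):
            depth = params.desat_depth + rng.uniform(0.0, 1.5)
            start = ev.start_s + params.desat_delay
            desats.append(Desaturation(round(start, 2), round(ev.duration_s + 10.0, 2), round(depth, 2)))
        elif ev.type == HYPOPNEA2:
            arousals.append(
                Arousal(round(ev.end_s + rng.uniform(0.5, 4.5), 2), round(rng.uniform(3.0, 10.0), 2))
            )

    r_peaks = _beat_times(duration_s, params.heart_rate_bpm, rng)

    channels: dict[str, Channel] = {}
    rates = params.channel_rates
    for name in ("abdominal", "thoracic"):
        if name in rates:
            t = np.arange(int(duration_s * rates[name])) / rates[name]
            channels[name] = Channel(
                _respiratory_channel(
                    t, rates[name], events, stages,
                    {APNEA: APNEA_EFFORT_AMP, "hypopnea": HYPOPNEA_EFFORT_AMP},
                    awake_gain=1.9, noise_sd=params.noise_sd, rng=rng,
                ),
                rates[name], "mV",
            )
    if "airflow" in rates:
        t = np.arange(int(duration_s * rates["airflow"])) / rates["airflow"]
        channels["airflow"] = Channel(
            _respiratory_channel(
                t, rates["airflow"], events, stages,
                {APNEA: APNEA_FLOW_AMP, "hypopnea": HYPOPNEA_FLOW_AMP},
                awake_gain=1.2, noise_sd=params.noise_sd, rng=rng,
            ),
            rates["airflow"], "mV",
        )
    if "spo2" in rates:
        t = np.arange(int(duration_s * rates["spo2"])) / rates["spo2"]
        channels["spo2"] = Channel(
            _spo2_channel(t, desats, params.noise_sd, rng), rates["spo2"], "%"
        )
    if "ecg" in rates:
        t = np.arange(int(duration_s * rates["ecg"])) / rates["ecg"]
        channels["ecg"] = Channel(_ecg_channel(t, rates["ecg"], r_peaks, rng), rates["ecg"], "mV")

    recording = Recording(patient_id, channels, float(duration_s))
    ann = AnnotationSet(list(events), list(arousals), list(desats), stages.copy())
    planted_ahi = n_ahi / sleep_hours if sleep_hours > 0 else 0.0
    truth = GroundTruth(list(events), list(arousals), stages.copy(), r_peaks, planted_ahi)
    return recording, ann, truth


def planted_severity(ahi: float) -> str:
    if ahi < 5:
        return "healthy"
    if ahi < 15:
        return "mild"
    if ahi < 30:
        return "moderate"
    return "severe"


def simulate_cohort(
    n_patients: int,
    severity_distribution,
    seed: int,
    base_params: SimParams | None = None,
) -> list[tuple[Recording, AnnotationSet, GroundTruth]]:
    """Generate a cohort with target AHIs drawn inside each severity band.

    ``severity_distribution`` gives proportions over (healthy, mild,
    moderate, severe); patient counts use largest-remainder allocation, so
    a uniform distribution over 4 patients yields exactly one per class.
    Per-patient seeds derive deterministically from the cohort seed.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    props = np.asarray(severity_distribution, dtype=float)
    if props.shape != (4,) or abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
        raise ValueError("severity_distribution must be 4 non-negative proportions summing to 1")
    quotas = props * n_patients
    counts = quotas.astype(int)
    for i in np.argsort(quotas - counts)[::-1][: n_patients - counts.sum()]:
        counts[i] += 1
    labels = [s for s, c in zip(SEVERITY_ORDER, counts) for _ in range(c)]

    rng = np.random.default_rng(seed)
    base = base_params or SimParams()
    out = []
    for i, sev in enumerate(labels):
        lo, hi = SEVERITY_BANDS[sev]
        target = float(rng.uniform(lo, hi))
        pseed = int(rng.integers(0, 2**31 - 1))
        params = replace(base, target_ahi=target, seed=pseed)
        out.append(simulate_recording(params, patient_id=f"SYN{i:03d}"))
    return out
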