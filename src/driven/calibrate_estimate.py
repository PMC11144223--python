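"""From window probabilities to a calibrated AHI and severity class.

The estimator never counts events directly.  Each night is segmented into
30 s windows every 15 s; windows classified asleep form the denominator
and those additionally above the event-probability threshold form the
numerator of the positive-window ratio.  A weighted linear regression,
fitted on calibration patients with known AHI, maps that ratio to an AHI
estimate; weights are inversely proportional to severity-class frequency
so that rare classes are not swamped.  The event threshold itself is
chosen on validation data as the point where precision equals recall —
the natural operating point for the heavily imbalanced window stream.
Severity follows the AASM bands: healthy < 5, mild 5-15, moderate 15-30,
severe > 30 events/h (boundaries left-closed: an AHI of exactly 15 is
moderate).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

SEVERITY_ORDER = ("healthy", "mild", "moderate", "severe")


@dataclass
class CalibrationModel:
    event_threshold: float
    regression_slope: float
    regression_intercept: float
    sleep_threshold: float = 0.5
    class_weights: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.event_threshold <= 1.0 and 0.0 < self.sleep_threshold < 1.0):
            raise ValueError("thresholds must lie in (0, 1)")
        if not np.isfinite(self.regression_slope):
            raise ValueError("regression slope must be finite")


@dataclass
class AhiReport:
    patient_id: str
    total_sleep_h: float
    n_sleep_windows: int
    n_positive_windows: int
    positive_ratio: float
    ahi_estimate: float
    severity: str
    timeline: list = field(default_factory=list)  # per-step "awake"/"normal"/"event"
    event_intervals: list = field(default_factory=list)
    flags: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def select_threshold(probabilities, labels) -> float:
    """Probability threshold where precision equals recall.

    Scans every distinct probability plus {0, 1}; returns the candidate
    minimising |precision - recall|, breaking ties toward higher precision
    and then toward the higher threshold (lower positive rate).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    candidates = np.unique(np.concatenate([p, [0.0, 1.0]]))
    best = None
    for thr in candidates:
        pred = p >= thr
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        fn = int((~pred & (y == 1)).sum())
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        key = (abs(precision - recall), -precision, -thr)
        if best is None or key < best[0]:
            best = (key, thr)
    return float(best[1])


def estimate_sleep_time(
    sleep_probs, stride_s: float = 15.0, sleep_threshold: float = 0.5
) -> tuple[float, np.ndarray]:
    """Total sleep hours from per-window sleep probabilities.

    Each window step contributes ``stride_s`` seconds when classified
    asleep (probability >= threshold).
    """
    p = np.asarray(sleep_probs, dtype=float)
    if p.size == 0:
        raise ValueError("no sleep probabilities given")
    mask = p >= sleep_threshold
    return float(mask.sum() * stride_s / 3600.0), mask


def fit_ahi_regression(ratios, true_ahis, severities) -> tuple[float, float]:
    """Weighted least squares mapping positive-window ratio to AHI.

    Each patient is weighted by the inverse frequency of its severity
    class in the fitting set, so balanced classes reduce to ordinary least
    squares.
    """
    r = np.asarray(ratios, dtype=float)
    a = np.asarray(true_ahis, dtype=float)
    sev = list(severities)
    if np.ptp(r) == 0:
        raise ValueError("degenerate regression: all ratios identical")
    counts: dict[str, int] = {}
    for s in sev:
        if s not in SEVERITY_ORDER:
            raise ValueError(f"unknown severity {s!r}")
        counts[s] = counts.get(s, 0) + 1
    w = np.array([1.0 / counts[s] for s in sev])
    sw = np.sqrt(w)
    design = np.column_stack([r * sw, sw])
    coef, *_ = np.linalg.lstsq(design, a * sw, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    if not (np.isfinite(slope) and np.isfinite(intercept)):
        raise ValueError("regression produced non-finite coefficients")
    return slope, intercept


def predict_ahi(calib: CalibrationModel, positive_ratio: float) -> float:
    """Ratio -> AHI through the calibrated line, clipped at zero."""
    return max(
        0.0, calib.regression_slope * positive_ratio + calib.regression_intercept
    )


def severity_class(ahi: float) -> str:
    """AASM band; left-closed at 5/15/30 so AHI 15 is moderate."""
    if ahi < 0:
        raise ValueError("AHI must be non-negative")
    if ahi < 5:
        return "healthy"
    if ahi < 15:
        return "mild"
    if ahi < 30:
        return "moderate"
    return "severe"


def segment_night(
    event_probs,
    sleep_mask,
    event_threshold: float,
    stride_s: float = 15.0,
    window_s: float = 30.0,
) -> tuple[list[str], list[tuple[float, float]]]:
    """Per-step night timeline and merged event intervals.

    Steps are "awake", "normal" or "event"; runs of consecutive "event"
    steps merge into [first_anchor, last_anchor + window_s) intervals.
    Closely spaced true events can merge into one detected interval — a
    known smoothing effect of the 30 s window.
    """
    p = np.asarray(event_probs, dtype=float)
    m = np.asarray(sleep_mask).astype(bool)
    if p.shape != m.shape:
        raise ValueError(f"misaligned inputs: {p.shape} vs {m.shape}")
    states = [
        "awake" if not asleep else ("event" if prob >= event_threshold else "normal")
        for prob, asleep in zip(p, m)
    ]
    intervals: list[tuple[float, float]] = []
    start = None
    for i, st in enumerate(states):
        if st == "event":
            if start is None:
                start = i * stride_s
            end = i * stride_s + window_s
        elif start is not None:
            intervals.append((start, end))
            start = None
    if start is not None:
        intervals.append((start, end))
    return states, intervals


def estimate_from_probs(
    event_probs,
    sleep_probs,
    calib: CalibrationModel,
    patient_id: str = "",
    stride_s: float = 15.0,
    window_s: float = 30.0,
) -> AhiReport:
    """Assemble the full per-patient report from window probabilities.

    This is the common tail of both the learned path (model outputs) and
    the oracle path (ground-truth labels standing in for probabilities).
    """
    total_sleep_h, mask = estimate_sleep_time(sleep_probs, stride_s, calib.sleep_threshold)
    n_sleep = int(mask.sum())
    flags: list[str] = []
    if n_sleep == 0:
        return AhiReport(
            patient_id, 0.0, 0, 0, 0.0, 0.0, "undetermined",
            ["awake"] * len(mask), [], ["no predicted sleep"],
        )
    probs = np.asarray(event_probs, dtype=float)
    positive = (probs >= calib.event_threshold) & mask
    ratio = float(positive.sum()) / n_sleep
    ahi = predict_ahi(calib, ratio)
    states, intervals = segment_night(probs, mask, calib.event_threshold, stride_s, window_s)
    return AhiReport(
        patient_id=patient_id,
        total_sleep_h=total_sleep_h,
        n_sleep_windows=n_sleep,
        n_positive_windows=int(positive.sum()),
        positive_ratio=ratio,
        ahi_estimate=ahi,
        severity=severity_class(ahi),
        timeline=states,
        event_intervals=intervals,
        flags=flags,
    )


def calibrate(
    val_event_probs,
    val_event_labels,
    patient_ratios,
    patient_ahis,
    sleep_threshold: float = 0.5,
) -> CalibrationModel:
    """Fit the full calibration: event threshold plus ratio->AHI line."""
    thr = select_threshold(val_event_probs, val_event_labels)
    severities = [severity_class(a) for a in patient_ahis]
    slope, intercept = fit_ahi_regression(patient_ratios, patient_ahis, severities)
    counts: dict[str, int] = {}
    for s in severities:
        counts[s] = counts.get(s, 0) + 1
    return CalibrationModel(
        event_threshold=max(thr, 1e-9),
        regression_slope=slope,
        regression_intercept=intercept,
        sleep_threshold=sleep_threshold,
        class_weights={k: 1.0 / v for k, v in counts.items()},
    )


def plot_segmentation(report: AhiReport, path, stride_s: float = 15.0) -> None:
    """Night-timeline plot: awake, normal and event steps over hours.

    Requires matplotlib (optional dependency).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hours = np.arange(len(report.timeline)) * stride_s / 3600.0
    codes = {"awake": 0, "normal": 1, "event": 2}
    y = np.array([codes[s] for s in report.timeline])
    fig, ax = plt.subplots(figsize=(10, 2.5))
    for state, marker, color in (("awake", "x", "k"), ("normal", "^", "g"), ("event", "*", "r")):
        m = y == codes[state]
        ax.plot(hours[m], y[m], marker, color=color, markersize=3, linestyle="none", label=state)
    ax.set_yticks([0, 1, 2], ["awake", "normal", "event"])
    ax.set_xlabel("time (h)")
    ax.set_title(
        f"{report.patient_id}: AHI {report.ahi_estimate:.1f} ({report.severity}), "
        f"sleep {report.total_sleep_h:.2f} h"
    )
    ax.legend(loc="upper right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def positive_ratio(event_probs, sleep_probs, event_threshold, sleep_threshold=0.5) -> float:
    """Positive AHI-event windows over sleep-classified windows."""
    p = np.asarray(event_probs, dtype=float)
    m = np.asarray(sleep_probs, dtype=float) >= sleep_threshold
    if m.sum() == 0:
        raise ValueError("no sleep-classified windows")
    return float(((p >= event_threshold) & m).sum() / m.sum())
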