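"""Fixed-window segmentation and AASM-rule labeling.

Nights are cut into 30 s windows sampled every 15 s (consecutive windows
overlap by half).  A window is an AHI-event window when it overlaps an
apnea, type-1 hypopnea or type-2 hypopnea by at least ``overlap_s``
seconds; type-3 hypopneas never count.  A window is a sleep window when at
least half of it lies in sleep-staged epochs.  For training, the normal
windows are randomly downsampled to match the positive count.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io_formats import (
    AHI_EVENT_TYPES,
    HYPOPNEA1,
    HYPOPNEA2,
    HYPOPNEA3,
    AnnotationSet,
    Arousal,
    Desaturation,
    Event,
    Recording,
)

EPOCH_S = 30.0


@dataclass
class WindowDataset:
    """Fixed-length windows with anchors, labels and patient ids.

    ``windows`` has shape (n_windows, n_channels, window_samples); labels
    are -1 until :func:`label_windows` runs.
    """

    windows: np.ndarray
    anchors: np.ndarray  # window start times, seconds
    channel_names: tuple
    window_s: float
    stride_s: float
    rate: float
    patient_id: np.ndarray | str = ""
    event_label: np.ndarray | None = None
    sleep_label: np.ndarray | None = None

    def __post_init__(self):
        if isinstance(self.patient_id, str):
            self.patient_id = np.array([self.patient_id] * len(self.anchors))

    def __len__(self):
        return len(self.anchors)

    def subset(self, idx) -> "WindowDataset":
        return replace(
            self,
            windows=self.windows[idx],
            anchors=self.anchors[idx],
            patient_id=self.patient_id[idx],
            event_label=None if self.event_label is None else self.event_label[idx],
            sleep_label=None if self.sleep_label is None else self.sleep_label[idx],
        )


def concat_datasets(datasets: list[WindowDataset]) -> WindowDataset:
    first = datasets[0]
    return replace(
        first,
        windows=np.concatenate([d.windows for d in datasets]),
        anchors=np.concatenate([d.anchors for d in datasets]),
        patient_id=np.concatenate([d.patient_id for d in datasets]),
        event_label=None
        if first.event_label is None
        else np.concatenate([d.event_label for d in datasets]),
        sleep_label=None
        if first.sleep_label is None
        else np.concatenate([d.sleep_label for d in datasets]),
    )


def classify_hypopnea(
    event: Event,
    desaturations: list[Desaturation],
    arousals: list[Arousal],
    desat_window_s: float = 45.0,
    arousal_window_s: float = 5.0,
) -> str:
    """Assign the AHI hypopnea subtype.

    Type 1 when a desaturation of depth >= 3 % starts within 45 s of event
    onset (takes precedence); type 2 when an arousal starts within 5 s
    after the event end; type 3 otherwise (excluded from the AHI).
    """
    for des in desaturations:
        if des.depth_percent >= 3.0 and 0.0 <= des.start_s - event.start_s <= desat_window_s:
            return HYPOPNEA1
    end = event.start_s + event.duration_s
    for ar in arousals:
        if end < ar.start_s <= end + arousal_window_s:
            return HYPOPNEA2
    return HYPOPNEA3


def make_windows(
    recording: Recording,
    window_s: float = 30.0,
    stride_s: float = 15.0,
    channels: tuple | None = None,
) -> WindowDataset:
    """Segment a common-rate recording into overlapping windows."""
    names = tuple(channels) if channels else tuple(recording.channels)
    rates = {recording.channels[n].rate for n in names}
    if len(rates) != 1:
        raise ValueError(f"channels must share one rate, got {rates}")
    rate = rates.pop()
    duration = min(len(recording.channels[n].samples) for n in names) / rate
    if duration < window_s:
        raise ValueError(f"recording ({duration:.0f} s) shorter than one window")
    n_windows = int((duration - window_s) // stride_s) + 1
    wlen = int(round(window_s * rate))
    step = int(round(stride_s * rate))
    stacked = np.stack([recording.channels[n].samples for n in names])  # (C, T)
    view = np.lib.stride_tricks.sliding_window_view(stacked, wlen, axis=1)
    windows = view[:, ::step, :][:, :n_windows].transpose(1, 0, 2).copy()
    anchors = np.arange(n_windows) * stride_s
    return WindowDataset(
        windows, anchors, names, window_s, stride_s, rate, recording.patient_id
    )


def label_windows(
    dataset: WindowDataset,
    annotations: AnnotationSet,
    overlap_s: float = 1.0,
) -> WindowDataset:
    """Attach AHI-event and sleep labels; depends only on the annotations."""
    anchors = dataset.anchors
    ends = anchors + dataset.window_s
    event_label = np.zeros(len(dataset), dtype=np.int8)
    for ev in annotations.events:
        if ev.type not in AHI_EVENT_TYPES:
            continue
        ov = np.minimum(ends, ev.end_s) - np.maximum(anchors, ev.start_s)
        event_label[ov >= overlap_s] = 1

    stages = annotations.sleep_stages
    sleep_label = np.zeros(len(dataset), dtype=np.int8)
    for i, (a, b) in enumerate(zip(anchors, ends)):
        ep0, ep1 = int(a // EPOCH_S), int(np.ceil(b / EPOCH_S))
        sleep_time = 0.0
        for ep in range(ep0, min(ep1, len(stages))):
            if stages[ep]:
                sleep_time += min(b, (ep + 1) * EPOCH_S) - max(a, ep * EPOCH_S)
        sleep_label[i] = 1 if sleep_time >= 0.5 * dataset.window_s else 0
    return replace(dataset, event_label=event_label, sleep_label=sleep_label)


def balance_dataset(dataset: WindowDataset, seed: int) -> WindowDataset:
    """Downsample normal windows to the positive count, uniformly, seeded."""
    if dataset.event_label is None:
        raise ValueError("dataset must be labeled first")
    pos = np.flatnonzero(dataset.event_label == 1)
    neg = np.flatnonzero(dataset.event_label == 0)
    if pos.size == 0:
        raise ValueError("nothing to balance: no positive windows")
    if neg.size <= pos.size:
        return dataset
    rng = np.random.default_rng(seed)
    keep_neg = rng.choice(neg, size=pos.size, replace=False)
    idx = np.sort(np.concatenate([pos, keep_neg]))
    return dataset.subset(idx)


def merge_positive_windows(
    anchors: np.ndarray,
    labels: np.ndarray,
    window_s: float,
) -> list[tuple[float, float]]:
    """Merge consecutive positive windows into [start, end) intervals."""
    intervals: list[tuple[float, float]] = []
    start = None
    prev_end = None
    for a, lab in zip(anchors, labels):
        if lab:
            if start is None:
                start = a
            prev_end = a + window_s
        elif start is not None:
            intervals.append((start, prev_end))
            start = None
    if start is not None:
        intervals.append((start, prev_end))
    return intervals
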