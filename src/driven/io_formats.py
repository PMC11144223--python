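"""Reading and writing of sleep-study files.

Signals travel as European Data Format (EDF) files: a fixed 256-byte header,
one 256-byte header extension per signal, then 16-bit little-endian samples
grouped into fixed-duration data records.  This module writes 1 s records
and maps between physical and digital values with the linear scaling the
header declares, so a write/read round trip is exact up to one digital
quantisation step.

Annotations travel as profusion-flavoured XML: scored events with a name,
start and duration, plus one sleep-stage code per 30 s epoch.  Stage codes
follow the R&K convention (0 = wake, 1-5 = sleep stages); this package
collapses them to a binary awake/sleep track, which is all the AHI
estimator needs.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field

import numpy as np
from lxml import etree

EPOCH_S = 30.0

# internal event vocabulary
APNEA = "apnea"
HYPOPNEA1 = "hypopnea1"
HYPOPNEA2 = "hypopnea2"
HYPOPNEA3 = "hypopnea3"
UNSURE = "unsure"
NOISE = "noise"
AHI_EVENT_TYPES = frozenset({APNEA, HYPOPNEA1, HYPOPNEA2})
EVENT_TYPES = frozenset({APNEA, HYPOPNEA1, HYPOPNEA2, HYPOPNEA3, UNSURE, NOISE})

#: Scored-event names (NSRR-style) -> internal types.  "hypopnea" entries are
#: sub-typed afterwards from the co-recorded desaturations and arousals.
DEFAULT_EVENT_NAME_MAP: dict[str, str] = {
    "Obstructive apnea": APNEA,
    "Obstructive Apnea": APNEA,
    "Central apnea": APNEA,
    "Central Apnea": APNEA,
    "Mixed apnea": APNEA,
    "Mixed Apnea": APNEA,
    "Hypopnea": "hypopnea",
    "Unsure": UNSURE,
    "Noise": NOISE,
    "Signal artifact": NOISE,
}

#: EDF label aliases -> canonical channel names used throughout the package.
CHANNEL_ALIASES: dict[str, str] = {
    "abdominal": "abdominal",
    "abdo res": "abdominal",
    "abdo": "abdominal",
    "thoracic": "thoracic",
    "thor res": "thoracic",
    "thor": "thoracic",
    "airflow": "airflow",
    "flow": "airflow",
    "new air": "airflow",
    "spo2": "spo2",
    "sao2": "spo2",
    "ecg": "ecg",
    "ekg": "ecg",
}

REQUIRED_CHANNELS = ("abdominal", "thoracic", "spo2")


class FormatError(ValueError):
    """Raised for malformed EDF or annotation files."""


@dataclass
class Channel:
    samples: np.ndarray
    rate: float
    physical_unit: str = ""


@dataclass
class Recording:
    """Multi-channel signal container with per-channel sampling rates."""

    patient_id: str
    channels: dict[str, Channel]
    duration_s: float
    start_time: str = "00.00.00"

    def __post_init__(self):
        for name, ch in self.channels.items():
            ch.samples = np.asarray(ch.samples, dtype=float)
            if ch.rate <= 0:
                raise ValueError(f"channel {name!r}: rate must be > 0")

    def channel(self, name: str) -> Channel:
        return self.channels[name]


@dataclass
class Event:
    type: str
    start_s: float
    duration_s: float
    source_channel: str = ""

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class Arousal:
    start_s: float
    duration_s: float


@dataclass
class Desaturation:
    start_s: float
    duration_s: float
    depth_percent: float


@dataclass
class AnnotationSet:
    """Scored events, arousals, desaturations and a 30 s sleep-stage track.

    ``sleep_stages`` is binary: 0 = awake, 1 = sleep (any non-wake stage).
    Time is seconds from recording start, half-open intervals
    [start, start + duration).
    """

    events: list[Event] = field(default_factory=list)
    arousals: list[Arousal] = field(default_factory=list)
    desaturations: list[Desaturation] = field(default_factory=list)
    sleep_stages: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int8))

    def __post_init__(self):
        self.sleep_stages = np.asarray(self.sleep_stages, dtype=np.int8)

    def total_sleep_s(self) -> float:
        return float(self.sleep_stages.sum()) * EPOCH_S

    def ahi_events(self) -> list[Event]:
        return [e for e in self.events if e.type in AHI_EVENT_TYPES]


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_HDR = struct.Struct("<8s80s80s8s8s8s44s8s8s4s")


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _ascii_float(value: float, width: int = 8) -> bytes:
    """Densest %g representation that fits the fixed-width header field."""
    for precision in range(8, 0, -1):
        s = f"{value:.{precision}g}"
        if len(s) <= width:
            return s.ljust(width).encode("ascii")
    return f"{value:.0e}"[:width].ljust(width).encode("ascii")


def write_edf(recording: Recording, path) -> None:
    """Write a Recording as a 16-bit EDF file with 1 s data records."""
    if not recording.channels:
        raise ValueError("cannot write EDF with an empty channel map")
    duration = recording.duration_s
    n_records = int(round(duration))
    if abs(duration - n_records) > 1e-9:
        raise ValueError("EDF writer requires a whole number of seconds")
    names, rates, scaled, phys = [], [], [], []
    for name, ch in recording.channels.items():
        if not np.all(np.isfinite(ch.samples)):
            raise ValueError(f"channel {name!r} contains non-finite samples")
        spr = int(round(ch.rate))
        if abs(ch.rate - spr) > 1e-9 or spr <= 0:
            raise ValueError(
                f"channel {name!r}: rate {ch.rate} is not expressible as "
                "samples per 1 s record"
            )
        if len(ch.samples) != spr * n_records:
            raise ValueError(
                f"channel {name!r}: {len(ch.samples)} samples != rate x duration"
            )
        pmin, pmax = float(ch.samples.min()), float(ch.samples.max())
        if pmax <= pmin:
            pmax = pmin + 1.0
        dmin, dmax = -32768, 32767
        dig = np.round((ch.samples - pmin) / (pmax - pmin) * (dmax - dmin) + dmin)
        names.append(name)
        rates.append(spr)
        scaled.append(dig.astype("<i2"))
        phys.append((pmin, pmax, dmin, dmax, ch.physical_unit))

    ns = len(names)
    header_bytes = 256 * (1 + ns)
    with open(path, "wb") as fh:
        fh.write(
            _HDR.pack(
                _ascii("0", 8),
                _ascii(recording.patient_id, 80),
                _ascii("Startdate 01.01.2000", 80),
                _ascii("01.01.00", 8),
                _ascii(recording.start_time, 8),
                _ascii(header_bytes, 8),
                _ascii("", 44),
                _ascii(n_records, 8),
                _ascii(1, 8),
                _ascii(ns, 4),
            )
        )
        fields = [
            [_ascii(n, 16) for n in names],
            [_ascii("", 80)] * ns,
            [_ascii(p[4], 8) for p in phys],
            [_ascii_float(p[0]) for p in phys],
            [_ascii_float(p[1]) for p in phys],
            [_ascii(p[2], 8) for p in phys],
            [_ascii(p[3], 8) for p in phys],
            [_ascii("", 80)] * ns,
            [_ascii(r, 8) for r in rates],
            [_ascii("", 32)] * ns,
        ]
        for group in fields:
            fh.write(b"".join(group))
        for rec in range(n_records):
            for sig, spr in zip(scaled, rates):
                fh.write(sig[rec * spr : (rec + 1) * spr].tobytes())


def read_edf(path, canonicalize_names: bool = True) -> Recording:
    """Read an EDF file into a Recording.

    Per-signal rates come from samples-per-record / record-duration; digital
    values are mapped to physical units by the header's linear scaling.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 256:
        raise FormatError("file too short for an EDF header")
    (ver, patient, _rec, _date, start_time, hdr_b, _res, n_rec, rec_dur, ns_b) = _HDR.unpack(
        raw[:256]
    )
    if ver.strip() != b"0":
        raise FormatError("not an EDF file (version field is not '0')")
    ns = int(ns_b)
    n_records = int(n_rec)
    record_duration = float(rec_dur)
    off = 256

    def grab(width):
        nonlocal off
        out = [raw[off + i * width : off + (i + 1) * width].decode("ascii").strip() for i in range(ns)]
        off += width * ns
        return out

    labels = grab(16)
    grab(80)  # transducer
    units = grab(8)
    pmins = [float(v) for v in grab(8)]
    pmaxs = [float(v) for v in grab(8)]
    dmins = [int(v) for v in grab(8)]
    dmaxs = [int(v) for v in grab(8)]
    grab(80)  # prefiltering
    sprs = [int(v) for v in grab(8)]
    grab(32)

    rec_bytes = 2 * sum(sprs)
    data = raw[int(hdr_b):]
    have = len(data) // rec_bytes if rec_bytes else 0
    if have < n_records:
        raise FormatError(
            f"header declares {n_records} data records but record {have} is "
            "truncated or missing"
        )
    channels: dict[str, Channel] = {}
    arrays = [np.empty(n_records * spr) for spr in sprs]
    pos = 0
    for rec in range(n_records):
        for i, spr in enumerate(sprs):
            chunk = np.frombuffer(data, dtype="<i2", count=spr, offset=pos)
            arrays[i][rec * spr : (rec + 1) * spr] = chunk
            pos += 2 * spr
    for i, label in enumerate(labels):
        gain = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        physical = (arrays[i] - dmins[i]) * gain + pmins[i]
        name = label
        if canonicalize_names:
            name = CHANNEL_ALIASES.get(label.lower(), label)
        channels[name] = Channel(physical, sprs[i] / record_duration, units[i])
    return Recording(
        patient_id=patient.decode("ascii").strip(),
        channels=channels,
        duration_s=n_records * record_duration,
        start_time=start_time.decode("ascii").strip(),
    )


# ---------------------------------------------------------------------------
# Profusion-style XML annotations
# ---------------------------------------------------------------------------

_WRITE_NAMES = {
    APNEA: "Obstructive apnea",
    HYPOPNEA1: "Hypopnea",
    HYPOPNEA2: "Hypopnea",
    HYPOPNEA3: "Hypopnea",
    UNSURE: "Unsure",
    NOISE: "Noise",
}
_HYPOPNEA_SUBTYPE = {HYPOPNEA1: 1, HYPOPNEA2: 2, HYPOPNEA3: 3}


def write_annotations(ann: AnnotationSet, path) -> None:
    root = etree.Element("CMPStudyConfig")
    etree.SubElement(root, "EpochLength").text = str(int(EPOCH_S))
    scored = etree.SubElement(root, "ScoredEvents")

    def add(name, start, duration, extra=()):
        el = etree.SubElement(scored, "ScoredEvent")
        etree.SubElement(el, "Name").text = name
        etree.SubElement(el, "Start").text = f"{start:.3f}"
        etree.SubElement(el, "Duration").text = f"{duration:.3f}"
        for tag, text in extra:
            etree.SubElement(el, tag).text = text
        return el

    for ev in ann.events:
        if ev.type not in _WRITE_NAMES:
            raise ValueError(f"unknown event type {ev.type!r}")
        extra = [("Input", ev.source_channel)] if ev.source_channel else []
        if ev.type in _HYPOPNEA_SUBTYPE:
            extra.append(("HypopneaType", str(_HYPOPNEA_SUBTYPE[ev.type])))
        add(_WRITE_NAMES[ev.type], ev.start_s, ev.duration_s, extra)
    for des in ann.desaturations:
        add(
            "SpO2 desaturation",
            des.start_s,
            des.duration_s,
            [("Desaturation", f"{des.depth_percent:.2f}")],
        )
    for ar in ann.arousals:
        add("Arousal", ar.start_s, ar.duration_s)
    stages = etree.SubElement(root, "SleepStages")
    for code in ann.sleep_stages:
        etree.SubElement(stages, "SleepStage").text = "2" if code else "0"
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="utf-8"
    )


def read_annotations(
    path,
    name_map: dict[str, str] | None = None,
    strict: bool = False,
) -> AnnotationSet:
    """Parse a profusion-style XML file into an AnnotationSet.

    Event names are mapped to the internal vocabulary through ``name_map``;
    hypopneas without an explicit subtype are classified from the
    co-recorded desaturations and arousals.  Unmapped names become
    ``unsure`` with a warning unless ``strict`` is set.
    """
    name_map = dict(DEFAULT_EVENT_NAME_MAP if name_map is None else name_map)
    tree = etree.parse(str(path))
    root = tree.getroot()
    events, arousals, desats, raw_hypopneas = [], [], [], []
    for el in root.iter("ScoredEvent"):
        name = el.findtext("Name", "").strip()
        start = float(el.findtext("Start", "0"))
        duration = float(el.findtext("Duration", "0"))
        source = el.findtext("Input", "") or ""
        if name == "SpO2 desaturation":
            depth = float(el.findtext("Desaturation", "0"))
            desats.append(Desaturation(start, duration, depth))
            continue
        if name.startswith("Arousal"):
            arousals.append(Arousal(start, duration))
            continue
        mapped = name_map.get(name)
        if mapped is None:
            if strict:
                raise FormatError(f"unmapped event name {name!r}")
            warnings.warn(f"unmapped event name {name!r}; recording as 'unsure'")
            mapped = UNSURE
        if mapped == "hypopnea":
            sub = el.findtext("HypopneaType")
            if sub is not None:
                mapped = f"hypopnea{int(sub)}"
                events.append(Event(mapped, start, duration, source))
            else:
                raw_hypopneas.append(Event("hypopnea", start, duration, source))
            continue
        events.append(Event(mapped, start, duration, source))
    if raw_hypopneas:
        from .windows_labels import classify_hypopnea

        for ev in raw_hypopneas:
            ev.type = classify_hypopnea(ev, desats, arousals)
            events.append(ev)
    stages = np.array(
        [0 if el.text.strip() == "0" else 1 for el in root.iter("SleepStage")],
        dtype=np.int8,
    )
    events.sort(key=lambda e: e.start_s)
    return AnnotationSet(events, arousals, desats, stages)


# ---------------------------------------------------------------------------
# Exclusion criteria
# ---------------------------------------------------------------------------

def exclude_recording(
    recording: Recording,
    ann: AnnotationSet,
    required_channels: tuple[str, ...] = REQUIRED_CHANNELS,
) -> tuple[bool, list[str]]:
    """Apply the study's recording-quality exclusion rules.

    A recording is dropped when "unsure"/"noise" labels cover strictly more
    than one third of total sleep time, when a required channel is missing,
    or when a required channel repeats a single value throughout.
    Returns (keep, reasons); reasons list every triggered criterion.
    """
    reasons: list[str] = []
    sleep_s = ann.total_sleep_s()
    if sleep_s <= 0:
        return False, ["no sleep"]
    bad_s = sum(e.duration_s for e in ann.events if e.type in (UNSURE, NOISE))
    if bad_s > sleep_s / 3.0:
        reasons.append(
            f"unsure/noise labels cover {bad_s / 3600:.2f} h of "
            f"{sleep_s / 3600:.2f} h sleep (> 1/3)"
        )
    for name in required_channels:
        if name not in recording.channels:
            reasons.append(f"missing channel {name!r}")
        elif np.ptp(recording.channels[name].samples) == 0:
            reasons.append(f"constant channel {name!r}")
    return (not reasons), reasons
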