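"""End-to-end orchestration: recordings in, calibrated AHI reports out.

Ties the stages together with leakage-safe patient splitting, one seed for
every source of randomness, and optional on-disk caching keyed by a hash
of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import pickle
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import calibrate_estimate as cal
from . import metrics as met
from . import models as mod
from .io_formats import AnnotationSet, Recording
from .preprocess import PreprocessConfig, preprocess_recording
from .windows_labels import WindowDataset, balance_dataset, concat_datasets, label_windows, make_windows


def true_ahi(ann: AnnotationSet) -> float:
    """Annotated AHI: scored AHI events per hour of annotated sleep."""
    sleep_h = ann.total_sleep_s() / 3600.0
    if sleep_h <= 0:
        raise ValueError("no sleep in annotations")
    return len(ann.ahi_events()) / sleep_h


def split_patients(
    patient_ids,
    fractions,
    seed: int,
    links: list[tuple[str, str]] | None = None,
) -> list[list[str]]:
    """Partition patients into len(fractions) groups, never separating
    linked ids (repeat recordings of one person).

    Deterministic under the seed; partition sizes within one patient of the
    requested fractions.
    """
    ids = list(dict.fromkeys(patient_ids))
    fracs = np.asarray(fractions, dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if len(ids) < len(fracs):
        raise ValueError("fewer patients than partitions")
    parent = {i: i for i in ids}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in links or []:
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    keys = sorted(groups)
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    targets = fracs * len(ids)
    out: list[list[str]] = [[] for _ in fracs]
    filled = np.zeros(len(fracs))
    for key in keys:
        j = int(np.argmax(targets - filled))
        out[j].extend(groups[key])
        filled[j] += len(groups[key])
    for part in out:
        if not part:
            # every partition must receive at least one patient
            donor = int(np.argmax([len(p) for p in out]))
            part.append(out[donor].pop())
    return out


@dataclass
class PipelineConfig:
    channels: tuple = ("abdominal", "spo2")
    window_s: float = 30.0
    stride_s: float = 15.0
    overlap_s: float = 1.0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    extractor_profile: str = "tiny"
    max_epochs: int = 12
    stacker_budget: int = 4
    split_fractions: tuple = (0.5, 0.25, 0.25)
    seed: int = 0

    def content_hash(self) -> str:
        blob = json.dumps(
            {**asdict(self), "preprocess": asdict(self.preprocess)},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineArtifacts:
    config: PipelineConfig
    event_extractors: dict
    sleep_extractors: dict
    event_stacker: mod.StackerModel
    sleep_stacker: mod.StackerModel
    calibration: cal.CalibrationModel
    reports: list
    metrics: dict

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "PipelineArtifacts":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def prepare_patient(
    recording: Recording,
    ann: AnnotationSet,
    config: PipelineConfig,
) -> WindowDataset:
    """Preprocess one night and return its labeled window dataset."""
    rec, ann_t = preprocess_recording(
        recording, config.preprocess, config.channels, ann
    )
    ds = make_windows(rec, config.window_s, config.stride_s)
    return label_windows(ds, ann_t, config.overlap_s)


def _channel_slices(ds: WindowDataset) -> dict[str, np.ndarray]:
    return {name: ds.windows[:, i, :] for i, name in enumerate(ds.channel_names)}


def _train_task(
    train_ds: WindowDataset,
    val_ds: WindowDataset,
    label_attr: str,
    config: PipelineConfig,
    seed_offset: int,
):
    """Train per-channel extractors plus a stacker for one label column."""
    import dataclasses

    def balanced(ds, labels, seed):
        # balance_dataset downsamples the negative class; for the sleep task
        # the positive (sleep) class is the majority, so balance the inverse
        if labels.sum() > len(labels) - labels.sum():
            work = dataclasses.replace(ds, event_label=1 - labels)
            out = balance_dataset(work, seed=seed)
            return dataclasses.replace(out, event_label=1 - out.event_label)
        return balance_dataset(dataclasses.replace(ds, event_label=labels), seed=seed)

    tr_bal = balanced(train_ds, getattr(train_ds, label_attr), config.seed + seed_offset)
    va_bal = balanced(val_ds, getattr(val_ds, label_attr), config.seed + seed_offset + 1)
    input_samples = int(config.window_s * config.preprocess.target_rate)
    extractors: dict[str, mod.Extractor] = {}
    for ci, name in enumerate(train_ds.channel_names):
        ecfg = mod.ExtractorConfig(
            profile=config.extractor_profile,
            input_samples=input_samples,
            max_epochs=config.max_epochs,
            seed=config.seed + seed_offset + ci,
        )
        ext = mod.build_extractor(ecfg, name)
        mod.train_extractor(
            ext,
            (tr_bal.windows[:, ci, :], tr_bal.event_label),
            (va_bal.windows[:, ci, :], va_bal.event_label),
        )
        extractors[name] = ext
    feats_tr = mod.extract_features_multi(extractors, tr_bal)
    feats_va = mod.extract_features_multi(extractors, va_bal)
    stacker = mod.fit_stacker(
        feats_tr,
        tr_bal.event_label,
        search_budget=config.stacker_budget,
        seed=config.seed + seed_offset,
        val_features=feats_va,
        val_labels=va_bal.event_label,
        channel_names=train_ds.channel_names,
    )
    return extractors, stacker


def window_probs(
    ds: WindowDataset,
    extractors: dict,
    stacker: mod.StackerModel,
) -> np.ndarray:
    return mod.predict_proba(stacker, mod.extract_features_multi(extractors, ds))


def run_pipeline(
    patients: list[tuple[Recording, AnnotationSet]],
    config: PipelineConfig,
    workdir: str | Path | None = None,
) -> PipelineArtifacts:
    """Train, calibrate and evaluate on a cohort of (recording, annotations).

    Patients are split leakage-safely into train/validation/test by patient
    id.  Returns all fitted models, the calibration, per-test-patient
    reports and a metrics summary.  With ``workdir`` set, results are
    cached under a content hash of the configuration and reused on rerun.
    """
    cache = None
    if workdir is not None:
        cache = Path(workdir) / config.content_hash()
        cache.mkdir(parents=True, exist_ok=True)
        if (cache / "artifacts.pkl").exists():
            return PipelineArtifacts.load(cache / "artifacts.pkl")

    datasets: dict[str, WindowDataset] = {}
    ahis: dict[str, float] = {}
    for rec, ann in patients:
        try:
            datasets[rec.patient_id] = prepare_patient(rec, ann, config)
            ahis[rec.patient_id] = true_ahi(ann)
        except (KeyError, ValueError) as exc:
            raise RuntimeError(
                f"stage prepare failed for patient {rec.patient_id}: {exc}"
            ) from exc

    parts = split_patients(list(datasets), config.split_fractions, config.seed)
    train_ids, val_ids, test_ids = parts
    assert not (set(train_ids) & set(val_ids) | set(train_ids) & set(test_ids)
                | set(val_ids) & set(test_ids)), "patient leakage across splits"
    train_ds = concat_datasets([datasets[i] for i in train_ids])
    val_ds = concat_datasets([datasets[i] for i in val_ids])

    event_ext, event_stk = _train_task(train_ds, val_ds, "event_label", config, 100)
    sleep_ext, sleep_stk = _train_task(train_ds, val_ds, "sleep_label", config, 200)

    # calibration on validation patients
    val_event_probs = window_probs(val_ds, event_ext, event_stk)
    thr = cal.select_threshold(val_event_probs, val_ds.event_label)
    ratios, val_ahis = [], []
    for pid in val_ids:
        ds = datasets[pid]
        ep = window_probs(ds, event_ext, event_stk)
        sp = window_probs(ds, sleep_ext, sleep_stk)
        try:
            ratios.append(cal.positive_ratio(ep, sp, thr))
            val_ahis.append(ahis[pid])
        except ValueError:
            continue
    slope, intercept = cal.fit_ahi_regression(
        ratios, val_ahis, [cal.severity_class(a) for a in val_ahis]
    )
    calibration = cal.CalibrationModel(
        event_threshold=max(thr, 1e-9),
        regression_slope=slope,
        regression_intercept=intercept,
    )

    reports = []
    test_event_probs, test_event_labels = [], []
    for pid in test_ids:
        ds = datasets[pid]
        ep = window_probs(ds, event_ext, event_stk)
        sp = window_probs(ds, sleep_ext, sleep_stk)
        reports.append(
            cal.estimate_from_probs(
                ep, sp, calibration, pid, config.stride_s, config.window_s
            )
        )
        test_event_probs.append(ep)
        test_event_labels.append(ds.event_label)

    ep_all = np.concatenate(test_event_probs)
    el_all = np.concatenate(test_event_labels)
    sev_true = [cal.severity_class(ahis[pid]) for pid in test_ids]
    sev_pred = [r.severity for r in reports]
    ahi_err = [abs(r.ahi_estimate - ahis[pid]) for r, pid in zip(reports, test_ids)]
    summary = {
        "window_auroc": met.roc_auc(ep_all, el_all),
        "window_auprc": met.pr_auc(ep_all, el_all),
        "event_threshold": calibration.event_threshold,
        "severity": met.f1_ahi(sev_true, sev_pred),
        "mean_abs_ahi_error": float(np.mean(ahi_err)),
        "n_train": len(train_ids),
        "n_val": len(val_ids),
        "n_test": len(test_ids),
    }
    artifacts = PipelineArtifacts(
        config, event_ext, sleep_ext, event_stk, sleep_stk, calibration, reports, summary
    )
    if cache is not None:
        artifacts.save(cache / "artifacts.pkl")
        with open(cache / "metrics.json", "w") as fh:
            json.dump({**summary, "severity": {
                **summary["severity"], "confusion": summary["severity"]["confusion"].tolist()
            }}, fh, indent=2)
    return artifacts


def estimate_patient(
    recording: Recording,
    artifacts: PipelineArtifacts,
    annotations: AnnotationSet | None = None,
) -> cal.AhiReport:
    """Run the full inference path on one night with trained models."""
    config = artifacts.config
    rec = preprocess_recording(recording, config.preprocess, config.channels)
    ds = make_windows(rec, config.window_s, config.stride_s)
    ep = window_probs(ds, artifacts.event_extractors, artifacts.event_stacker)
    sp = window_probs(ds, artifacts.sleep_extractors, artifacts.sleep_stacker)
    return cal.estimate_from_probs(
        ep, sp, artifacts.calibration, recording.patient_id,
        config.stride_s, config.window_s,
    )
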