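"""Per-channel 1-D feature extractors and the gradient-boosted stacker.

Each physiological channel gets its own deep 1-D CNN, trained to separate
normal from AHI-event windows; after training, the classification head is
discarded and the global-average-pooling activations serve as a fixed-width
feature vector per window.  Features from all channels are concatenated and
a LightGBM classifier is trained on top — the stacking stage that produces
the final window probability.

The network follows the EfficientNetV2 stage layout (fused-MBConv early,
MBConv with squeeze-excitation late) with 1-D kernels of size 3 and the 2-D
stride schedule applied along time.  Three profiles scale depth and width;
the ``full`` profile keeps the reference 1280-wide pooled feature vector,
while ``small`` and ``tiny`` make desk-scale training practical.  The same
architecture, trained on sleep labels instead of event labels, provides the
sleep/awake classifier; the code path is shared and only the label column
differs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lightgbm import LGBMClassifier

from . import nn
from .metrics import pr_auc

# stage tuples: (kind, expand, channels, repeats, first_stride)
PROFILES: dict[str, dict] = {
    "full": {
        "stem": 24,
        "stages": [
            ("F", 1, 24, 2, 1),
            ("F", 4, 48, 4, 2),
            ("F", 4, 64, 4, 2),
            ("M", 4, 128, 6, 2),
            ("M", 6, 160, 9, 1),
            ("M", 6, 256, 15, 2),
        ],
        "head": 1280,
    },
    "small": {
        "stem": 16,
        "stages": [
            ("F", 1, 16, 1, 1),
            ("F", 2, 32, 2, 2),
            ("F", 2, 48, 2, 2),
            ("M", 2, 96, 3, 2),
            ("M", 4, 128, 3, 1),
            ("M", 4, 160, 3, 2),
        ],
        "head": 256,
    },
    "tiny": {
        "stem": 8,
        "stages": [
            ("F", 1, 8, 1, 1),
            ("F", 2, 16, 1, 2),
            ("M", 2, 24, 1, 2),
            ("M", 4, 32, 2, 2),
        ],
        "head": 64,
    },
}


@dataclass
class ExtractorConfig:
    profile: str = "tiny"
    input_samples: int = 1920  # 30 s x 64 Hz
    feature_layer: str = "last_gap"  # or "third_last"
    epochs_patience: int = 8
    max_epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    dropout: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.epochs_patience < 1:
            raise ValueError("patience must be >= 1")
        if self.feature_layer not in ("last_gap", "third_last"):
            raise ValueError(f"unknown feature layer {self.feature_layer!r}")


class Extractor:
    """A per-channel CNN; built by :func:`build_extractor`."""

    def __init__(self, config: ExtractorConfig, channel_name: str = ""):
        spec = PROFILES[config.profile]
        total_stride = 2 * int(
            np.prod([s[4] for s in spec["stages"]])
        )
        min_len = 4 * total_stride
        if config.input_samples < min_len:
            raise ValueError(
                f"input_samples={config.input_samples} too short for the "
                f"{config.profile!r} downsampling stack; minimum supported "
                f"length is {min_len}"
            )
        self.config = config
        self.channel_name = channel_name
        rng = np.random.default_rng(config.seed)
        blocks: list[nn.Layer] = [
            nn.Conv1d(1, spec["stem"], 3, 2, rng),
            nn.BatchNorm1d(spec["stem"]),
            nn.SiLU(),
        ]
        c_in = spec["stem"]
        for kind, expand, c_out, repeats, stride in spec["stages"]:
            for r in range(repeats):
                s = stride if r == 0 else 1
                if kind == "F":
                    blocks.append(nn.fused_mbconv(c_in, c_out, s, expand, rng))
                else:
                    blocks.append(nn.mbconv(c_in, c_out, s, expand, rng))
                c_in = c_out
        self.backbone = nn.Sequential(*blocks)
        self.head_conv = nn.Sequential(
            nn.Conv1d(c_in, spec["head"], 1, 1, rng),
            nn.BatchNorm1d(spec["head"]),
            nn.SiLU(),
        )
        self.gap = nn.GlobalAvgPool()
        self.dropout = nn.Dropout(config.dropout, np.random.default_rng(config.seed + 1))
        self.classifier = nn.Dense(spec["head"], 2, rng)
        self._pre_head_width = c_in
        self._head_width = spec["head"]
        self.trained = False
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}

    # -- introspection ------------------------------------------------------
    @property
    def feature_width(self) -> int:
        return (
            self._head_width
            if self.config.feature_layer == "last_gap"
            else self._pre_head_width
        )

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self._all().params())

    def _all(self) -> nn.Sequential:
        return nn.Sequential(self.backbone, self.head_conv)

    # -- forward/backward ---------------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.backbone.forward(x, train)
        h = self.head_conv.forward(h, train)
        h = self.gap.forward(h, train)
        h = self.dropout.forward(h, train)
        return self.classifier.forward(h, train)

    def backward(self, grad_logits: np.ndarray) -> None:
        g = self.classifier.backward(grad_logits)
        g = self.dropout.backward(g)
        g = self.gap.backward(g)
        g = self.head_conv.backward(g)
        self.backbone.backward(g)

    def params(self) -> list[nn.Param]:
        return (
            self.backbone.params()
            + self.head_conv.params()
            + self.classifier.params()
        )

    def features(self, x: np.ndarray) -> np.ndarray:
        """Pooled activations in inference mode (deterministic)."""
        h = self.backbone.forward(x, train=False)
        if self.config.feature_layer == "third_last":
            return h.mean(axis=2)
        h = self.head_conv.forward(h, train=False)
        return h.mean(axis=2)


def build_extractor(config: ExtractorConfig, channel_name: str = "") -> Extractor:
    """Instantiate a per-channel CNN for the given profile."""
    return Extractor(config, channel_name)


def early_stop_epoch(val_losses, patience: int, tol: float = 1e-9) -> int:
    """Number of epochs run under the stop rule.

    Training stops after the first epoch at which the validation loss has
    not decreased for ``patience`` consecutive epochs.
    """
    best = np.inf
    wait = 0
    for i, loss in enumerate(val_losses):
        if loss < best - tol:
            best = loss
            wait = 0
        else:
            wait += 1
            if wait >= patience:
                return i + 1
    return len(val_losses)


def _as_xy(data) -> tuple[np.ndarray, np.ndarray]:
    x, y = data
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        x = x[:, None, :]
    return x, np.asarray(y).astype(int)


def train_extractor(
    model: Extractor,
    train_data,
    val_data,
    config: ExtractorConfig | None = None,
) -> Extractor:
    """Train with Adam on categorical cross-entropy, early stopping on the
    validation loss, best-epoch weights restored.

    ``train_data`` / ``val_data`` are (windows, labels) pairs with windows
    of shape (n, input_samples) or (n, 1, input_samples).  Training data is
    expected to be class-balanced; imbalance triggers a warning only.
    """
    config = config or model.config
    x_tr, y_tr = _as_xy(train_data)
    x_va, y_va = _as_xy(val_data)
    if y_va.size == 0:
        raise ValueError("validation set is empty")
    n_pos = int(y_tr.sum())
    if abs(n_pos - (len(y_tr) - n_pos)) > max(2, 0.05 * len(y_tr)):
        warnings.warn(
            f"training labels are imbalanced ({n_pos} positive of {len(y_tr)})"
        )
    rng = np.random.default_rng(config.seed + 17)
    optimizer = nn.Adam(model.params(), lr=config.learning_rate)
    best_state = None
    best_loss = np.inf
    wait = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(y_tr))
        losses = []
        for i0 in range(0, len(order), config.batch_size):
            idx = order[i0 : i0 + config.batch_size]
            optimizer.zero_grad()
            logits = model.forward_logits(x_tr[idx], train=True)
            loss, grad = nn.softmax_cross_entropy(logits, y_tr[idx])
            model.backward(grad)
            optimizer.step()
            losses.append(loss)
        val_loss = evaluate_loss(model, x_va, y_va, config.batch_size)
        model.history["train_loss"].append(float(np.mean(losses)))
        model.history["val_loss"].append(float(val_loss))
        if val_loss < best_loss - 1e-9:
            best_loss = val_loss
            best_state = _snapshot(model)
            wait = 0
        else:
            wait += 1
            if wait >= config.epochs_patience:
                break
    if best_state is not None:
        _restore(model, best_state)
    model.trained = True
    return model


def evaluate_loss(model: Extractor, x: np.ndarray, y: np.ndarray, batch_size: int) -> float:
    total, n = 0.0, 0
    for i0 in range(0, len(y), batch_size):
        logits = model.forward_logits(x[i0 : i0 + batch_size], train=False)
        loss, _ = nn.softmax_cross_entropy(logits, y[i0 : i0 + batch_size])
        total += loss * len(logits)
        n += len(logits)
    return total / n


def _snapshot(model: Extractor) -> dict:
    state = nn.snapshot_state(nn.Sequential(model.backbone, model.head_conv))
    state["cls"] = [p.value.copy() for p in model.classifier.params()]
    return state


def _restore(model: Extractor, state: dict) -> None:
    nn.restore_state(nn.Sequential(model.backbone, model.head_conv), state)
    for p, v in zip(model.classifier.params(), state["cls"]):
        p.value[...] = v


def extract_features(
    model: Extractor, windows: np.ndarray, batch_size: int = 256
) -> np.ndarray:
    """Deterministic feature matrix [n_windows x feature_width]."""
    x = np.asarray(windows, dtype=float)
    if x.ndim == 2:
        x = x[:, None, :]
    if x.shape[2] != model.config.input_samples:
        raise ValueError(
            f"windows have {x.shape[2]} samples; model expects "
            f"{model.config.input_samples}"
        )
    out = [model.features(x[i0 : i0 + batch_size]) for i0 in range(0, len(x), batch_size)]
    return np.concatenate(out)


def extract_features_multi(
    extractors: dict[str, Extractor], dataset, batch_size: int = 256
) -> np.ndarray:
    """Concatenate per-channel features in the dataset's channel order.

    The extractor for each channel must have been built for that channel;
    a mismatch between the dataset's channels and the trained extractors
    is an error.
    """
    missing = [c for c in dataset.channel_names if c not in extractors]
    if missing:
        raise ValueError(f"no trained extractor for channels {missing}")
    mats = []
    for ci, name in enumerate(dataset.channel_names):
        ext = extractors[name]
        if ext.channel_name and ext.channel_name != name:
            raise ValueError(
                f"extractor trained on {ext.channel_name!r} given channel {name!r}"
            )
        mats.append(extract_features(ext, dataset.windows[:, ci, :], batch_size))
    return np.concatenate(mats, axis=1)


# ---------------------------------------------------------------------------
# LightGBM stacking
# ---------------------------------------------------------------------------

SEARCH_SPACE = {
    "num_leaves": (7, 63),
    "learning_rate": (0.02, 0.3),  # log-uniform
    "min_child_samples": (5, 50),
    "feature_fraction": (0.5, 1.0),
    "n_estimators": (50, 300),
}


@dataclass
class StackerModel:
    booster: LGBMClassifier
    params: dict
    feature_width: int
    channel_names: tuple = ()
    trained: bool = True
    search_results: list = field(default_factory=list)


def _sample_params(rng) -> dict:
    lo, hi = SEARCH_SPACE["learning_rate"]
    return {
        "num_leaves": int(rng.integers(*SEARCH_SPACE["num_leaves"])),
        "learning_rate": float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
        "min_child_samples": int(rng.integers(*SEARCH_SPACE["min_child_samples"])),
        "feature_fraction": float(rng.uniform(*SEARCH_SPACE["feature_fraction"])),
        "n_estimators": int(rng.integers(*SEARCH_SPACE["n_estimators"])),
    }


def fit_stacker(
    features: np.ndarray,
    labels: np.ndarray,
    search_budget: int = 8,
    seed: int = 0,
    val_features: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
    channel_names: tuple = (),
) -> StackerModel:
    """Random hyperparameter search over leaf-wise boosted trees.

    ``search_budget`` configurations are sampled from a fixed space and
    scored by validation AUPRC; when no validation split is supplied a
    seeded 80/20 split of the training windows is used.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    if y.min() == y.max():
        raise ValueError("labels contain a single class")
    rng = np.random.default_rng(seed)
    if val_features is None:
        order = rng.permutation(len(y))
        cut = max(1, int(0.2 * len(y)))
        val_idx, tr_idx = order[:cut], order[cut:]
        x_tr, y_tr = x[tr_idx], y[tr_idx]
        x_va, y_va = x[val_idx], y[val_idx]
        if y_va.min() == y_va.max() or y_tr.min() == y_tr.max():
            x_tr, y_tr, x_va, y_va = x, y, x, y
    else:
        x_tr, y_tr = x, y
        x_va, y_va = np.asarray(val_features, dtype=float), np.asarray(val_labels).astype(int)

    best = None
    results = []
    for trial in range(search_budget):
        params = _sample_params(rng)
        clf = LGBMClassifier(
            objective="binary",
            random_state=seed + trial,
            deterministic=True,
            force_row_wise=True,
            n_jobs=1,
            verbosity=-1,
            **params,
        )
        clf.fit(x_tr, y_tr)
        score = pr_auc(clf.predict_proba(x_va)[:, 1], y_va)
        results.append({"params": params, "val_auprc": float(score)})
        if best is None or score > best[0]:
            best = (score, params, clf)
    return StackerModel(
        booster=best[2],
        params=best[1],
        feature_width=x.shape[1],
        channel_names=tuple(channel_names),
        search_results=results,
    )


def predict_proba(stacker: StackerModel, features: np.ndarray) -> np.ndarray:
    """Per-window probability that the segment contains an AHI event."""
    x = np.asarray(features, dtype=float)
    if x.shape[1] != stacker.feature_width:
        raise ValueError(
            f"feature width {x.shape[1]} != trained width {stacker.feature_width}"
        )
    return stacker.booster.predict_proba(x)[:, 1]
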