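"""Gait classifiers: six feature-table models and a raw-signal sequence
model, with the feature-subset, sensor-subset, normalization, class
balancing and windowing machinery around them.

Feature models (LDA, QDA, decision tree, random forest, RBF-SVM, one
hidden-layer fully connected network) are scikit-learn estimators fitted
on selected feature columns; discriminant/margin/neural models get
per-column z-scoring with training statistics, trees and forests consume
raw features.  The sequence model is a stacked GRU
(:class:`equigait.rnn.GRUClassifier`) on windowed, 0-1-normalized
multichannel signals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_COLUMNS
from .rnn import GRUClassifier
from .types import SignalBlock

__all__ = [
    "FEATURE_SUBSETS",
    "SENSOR_SUBSETS",
    "ModelSpec",
    "TrainedModel",
    "WindowSet",
    "balance_by_duplication",
    "normalize_signals",
    "channel_minmax",
    "window_signals",
    "windows_dataset",
    "train_feature_model",
    "train_sequence_model",
    "predict",
]

log = logging.getLogger(__name__)

#: Named feature subsets: all 21 variables; the stride-timing variables
#: only; and the two classic Hildebrand-diagram variables (duty factor and
#: lateral advanced placement).
FEATURE_SUBSETS: Mapping[str, List[str]] = {
    "all": list(FEATURE_COLUMNS),
    "stride_only": [
        "stride_duration",
        "stance_duration",
        "stride_frequency",
        "duty_factor",
    ],
    "hildebrand2": ["duty_factor", "lateral_advanced_placement"],
}

#: Named sensor-site subsets. "single" is the withers sensor (a standard
#: mount carrying no limb identity); "upper_body" is poll + withers +
#: pelvis; "ub_plus_lh" adds the left hind limb sensor.
SENSOR_SUBSETS: Mapping[str, List[str]] = {
    "single": ["withers"],
    "upper_body": ["poll", "withers", "pelvis"],
    "ub_plus_lh": ["poll", "withers", "pelvis", "LH"],
    "four_limbs": ["LF", "RF", "LH", "RH"],
    "all": ["poll", "withers", "pelvis", "LF", "RF", "LH", "RH"],
}

FEATURE_MODEL_KINDS = ("lda", "qda", "tree", "forest", "svm", "fc")
_SEQUENCE_HYPERS = {
    "n_recurrent_layers",
    "width",
    "bidirectional",
    "window_length_s",
    "max_epochs",
    "lr",
}
_FC_HYPERS = {"hidden_width", "max_epochs"}


@dataclass(frozen=True)
class ModelSpec:
    """Which classifier to train and with which hyperparameters.

    ``kind`` is one of lda, qda, tree, forest, svm, fc (feature models) or
    sequence (the recurrent raw-signal model).  Defaults: fc hidden width
    40; sequence 2 recurrent layers of width 64 (desk scale; 500 is the
    full-scale option), unidirectional, 1 s windows.
    """

    kind: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_MODEL_KINDS + ("sequence",):
            raise ValueError(f"unknown model kind {self.kind!r}")
        legal = (
            _SEQUENCE_HYPERS
            if self.kind == "sequence"
            else _FC_HYPERS
            if self.kind == "fc"
            else set()
        )
        extra = set(self.hyperparameters) - legal
        if extra:
            raise ValueError(
                f"hyperparameters {sorted(extra)} not legal for kind {self.kind!r}"
            )

    def hp(self, name: str, default):
        return self.hyperparameters.get(name, default)


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to apply it: the spec,
    the class list, the input contract (feature columns or channel names)
    and frozen normalization statistics where applicable."""

    spec: ModelSpec
    estimator: object
    classes: List[str]
    feature_columns: Optional[List[str]] = None
    channel_names: Optional[List[str]] = None

    def predict(self, inputs) -> np.ndarray:
        return predict(self, inputs)


# --- dataset utilities ------------------------------------------------------


@dataclass
class WindowSet:
    """Labeled fixed-length signal windows: X is [n, length, channels]."""

    X: np.ndarray
    y: np.ndarray
    horse_ids: np.ndarray
    channel_names: List[str]

    def __len__(self) -> int:
        return len(self.X)

    def subset(self, idx) -> "WindowSet":
        idx = np.asarray(idx)
        return WindowSet(
            self.X[idx], self.y[idx], self.horse_ids[idx], list(self.channel_names)
        )


def balance_by_duplication(
    dataset: Union[pd.DataFrame, WindowSet],
    rng_seed: int = 0,
    label_column: str = "gait_label",
):
    """Upsample every class with replacement to the majority-class count.

    Intended for training folds only.  Accepts a feature table (DataFrame
    with a label column) or a :class:`WindowSet`.
    """
    if isinstance(dataset, pd.DataFrame):
        labels = dataset[label_column].to_numpy()
    else:
        labels = np.asarray(dataset.y)
    if len(labels) == 0:
        raise ValueError("cannot balance an empty dataset")
    rng = np.random.default_rng(rng_seed)
    classes, counts = np.unique(labels, return_counts=True)
    target = counts.max()
    keep: List[np.ndarray] = []
    for cls, cnt in zip(classes, counts):
        idx = np.flatnonzero(labels == cls)
        if cnt < target:
            idx = np.concatenate([idx, rng.choice(idx, target - cnt, replace=True)])
        keep.append(idx)
    order = np.concatenate(keep)
    if isinstance(dataset, pd.DataFrame):
        return dataset.iloc[order].reset_index(drop=True)
    return dataset.subset(order)


def channel_minmax(block: SignalBlock) -> Dict[str, Tuple[float, float]]:
    """Per-channel (min, max) statistics of a block."""
    return {
        name: (float(block.values[:, i].min()), float(block.values[:, i].max()))
        for i, name in enumerate(block.channel_names)
    }


def normalize_signals(
    block: SignalBlock,
    stats: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> SignalBlock:
    """Min-max scale every channel to [0, 1].

    With ``stats`` (e.g. training-set statistics) the given (min, max) are
    applied and the result clipped to [0, 1]; otherwise statistics are
    computed per recording.  A constant channel maps to 0.5 with a warning.
    """
    values = block.values.copy()
    own = stats is None
    use = channel_minmax(block) if own else stats
    for i, name in enumerate(block.channel_names):
        lo, hi = use[name]
        if hi - lo <= 0:
            warnings.warn(f"channel {name} is constant; normalized to 0.5")
            values[:, i] = 0.5
        else:
            values[:, i] = (values[:, i] - lo) / (hi - lo)
    if not own:
        np.clip(values, 0.0, 1.0, out=values)
    return SignalBlock(
        horse_id=block.horse_id,
        gait=block.gait,
        sample_rate=block.sample_rate,
        channel_names=list(block.channel_names),
        values=values,
        meta=dict(block.meta),
    )


def window_signals(
    block: SignalBlock,
    length_s: float,
    sensor_subset: Union[str, Sequence[str]] = "all",
) -> List[Tuple[np.ndarray, str, str]]:
    """Crop a block into consecutive non-overlapping windows.

    Each window is ``length_s * sample_rate`` samples of the subset's
    channels; the trailing remainder is dropped; every window inherits the
    block's gait label.  Returns (values, gait, horse_id) triples; an
    empty list (with a warning) if the block is shorter than one window.
    """
    sites = SENSOR_SUBSETS[sensor_subset] if isinstance(sensor_subset, str) else list(sensor_subset)
    sub = block.select_sites(sites)
    L = int(round(length_s * block.sample_rate))
    n = sub.n_samples // L
    if n == 0:
        log.warning(
            "block %s/%s (%.2f s) shorter than one %.0f s window",
            block.horse_id,
            block.gait.value,
            block.duration,
            length_s,
        )
        return []
    out = []
    for i in range(n):
        out.append((sub.values[i * L : (i + 1) * L].copy(), block.gait.value, block.horse_id))
    return out


def windows_dataset(
    blocks: Sequence[SignalBlock],
    length_s: float,
    sensor_subset: Union[str, Sequence[str]] = "all",
    normalize: bool = True,
) -> WindowSet:
    """Normalize (per recording), window and stack a set of blocks."""
    X, y, hid = [], [], []
    channels: Optional[List[str]] = None
    for block in blocks:
        b = normalize_signals(block) if normalize else block
        for values, gait, horse in window_signals(b, length_s, sensor_subset):
            X.append(values)
            y.append(gait)
            hid.append(horse)
            if channels is None:
                sites = (
                    SENSOR_SUBSETS[sensor_subset]
                    if isinstance(sensor_subset, str)
                    else list(sensor_subset)
                )
                channels = [c for c in b.channel_names if c.split(".")[0] in sites]
    if not X:
        raise ValueError("no windows produced from the given blocks")
    return WindowSet(
        X=np.stack(X), y=np.array(y), horse_ids=np.array(hid), channel_names=channels or []
    )


# --- model construction -----------------------------------------------------


def _build_estimator(spec: ModelSpec):
    seed = spec.rng_seed
    if spec.kind == "lda":
        core = LinearDiscriminantAnalysis()
    elif spec.kind == "qda":
        # several features are piecewise-constant within a class (integer
        # support counts, zero suspension); shrink keeps covariances
        # invertible
        core = QuadraticDiscriminantAnalysis(reg_param=1e-3)
    elif spec.kind == "tree":
        return DecisionTreeClassifier(random_state=seed)
    elif spec.kind == "forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    elif spec.kind == "svm":
        core = SVC(kernel="rbf", decision_function_shape="ovo", random_state=seed)
    elif spec.kind == "fc":
        # accuracy-plateau early stopping restores first-epoch weights when
        # a small validation slice scores 1.0 immediately; a fixed epoch
        # budget is the reliable stopping rule here
        core = MLPClassifier(
            hidden_layer_sizes=(int(spec.hp("hidden_width", 40)),),
            max_iter=int(spec.hp("max_epochs", 200)),
            random_state=seed,
        )
    else:
        raise ValueError(f"not a feature-model kind: {spec.kind}")
    return Pipeline([("scale", StandardScaler()), ("model", core)])


def train_feature_model(
    spec: ModelSpec,
    table: pd.DataFrame,
    subset: Union[str, Sequence[str]] = "all",
    label_column: str = "gait_label",
) -> TrainedModel:
    """Fit a feature-table classifier on the selected feature columns."""
    if spec.kind == "sequence":
        raise ValueError("use train_sequence_model for the sequence kind")
    if len(table) == 0:
        raise ValueError("empty training table")
    columns = FEATURE_SUBSETS[subset] if isinstance(subset, str) else list(subset)
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"feature columns missing from table: {missing}")
    y = table[label_column].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    est = _build_estimator(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # QDA collinearity etc. on tiny folds
        est.fit(table[columns].to_numpy(dtype=float), y)
    return TrainedModel(
        spec=spec,
        estimator=est,
        classes=[str(c) for c in est.classes_]
        if not isinstance(est, Pipeline)
        else [str(c) for c in est[-1].classes_],
        feature_columns=columns,
    )


def train_sequence_model(spec: ModelSpec, windows: WindowSet) -> TrainedModel:
    """Fit the recurrent raw-signal classifier on a window set."""
    if spec.kind != "sequence":
        raise ValueError("spec.kind must be 'sequence'")
    if len(windows) == 0:
        raise ValueError("empty window set")
    shapes = {w.shape for w in windows.X}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent window shapes: {shapes}")
    model = GRUClassifier(
        n_layers=int(spec.hp("n_recurrent_layers", 2)),
        width=int(spec.hp("width", 64)),
        bidirectional=bool(spec.hp("bidirectional", False)),
        max_epochs=int(spec.hp("max_epochs", 40)),
        lr=float(spec.hp("lr", 1e-2)),
        seed=spec.rng_seed,
    )
    model.fit(windows.X, windows.y)
    return TrainedModel(
        spec=spec,
        estimator=model,
        classes=[str(c) for c in model.classes_],
        channel_names=list(windows.channel_names),
    )


def predict(model: TrainedModel, inputs) -> np.ndarray:
    """Predict one gait label per feature row or signal window."""
    if model.spec.kind == "sequence":
        X = inputs.X if isinstance(inputs, WindowSet) else np.asarray(inputs)
        if len(X) == 0:
            return np.array([], dtype=object)
        if X.ndim != 3 or X.shape[2] != len(model.channel_names or []):
            raise ValueError("window shape does not match the trained model")
        return model.estimator.predict(X)
    if isinstance(inputs, pd.DataFrame):
        missing = [c for c in (model.feature_columns or []) if c not in inputs.columns]
        if missing:
            raise ValueError(f"feature columns missing: {missing}")
        X = inputs[model.feature_columns].to_numpy(dtype=float)
    else:
        X = np.asarray(inputs, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(model.feature_columns or []):
            raise ValueError("input shape does not match the trained model")
    if len(X) == 0:
        return np.array([], dtype=object)
    return model.estimator.predict(X)
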