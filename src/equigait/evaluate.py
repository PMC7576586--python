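"""Horse-disjoint cross-validation and the experiment grid.

The central protocol guarantee: strides (or signal windows) of one horse
never appear on both sides of a train/validation boundary.  Folds are
built at the horse level, balancing stride counts across folds because
breeds contribute very different stride totals.  Accuracy is
micro-averaged (trace of the confusion matrix over its total).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .classify import (
    FEATURE_SUBSETS,
    ModelSpec,
    WindowSet,
    balance_by_duplication,
    predict,
    train_feature_model,
    train_sequence_model,
)

__all__ = [
    "SplitPlan",
    "ConfusionMatrix",
    "CVResult",
    "grouped_kfold",
    "cross_validate",
    "confusion",
    "run_experiment_grid",
]

log = logging.getLogger(__name__)


@dataclass
class SplitPlan:
    """Horse-level fold assignment: ``folds`` is a list of (train_ids,
    validation_ids); ``test_ids`` is an optional held-out horse set that no
    fold ever touches."""

    folds: List[Tuple[Tuple[str, ...], Tuple[str, ...]]]
    test_ids: Tuple[str, ...] = ()

    def validate(self) -> None:
        seen_val: List[str] = []
        test = set(self.test_ids)
        for train, val in self.folds:
            if set(train) & set(val):
                raise ValueError("horse appears in both train and validation")
            if (set(train) | set(val)) & test:
                raise ValueError("test horse appears inside a CV fold")
            seen_val.extend(val)
        if len(seen_val) != len(set(seen_val)):
            raise ValueError("a horse appears in two validation folds")


@dataclass
class ConfusionMatrix:
    """Integer confusion counts; rows are truth, columns predictions."""

    classes: List[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square in the number of classes")
        if (self.counts < 0).any():
            raise ValueError("negative confusion counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def row(self, cls: str) -> Dict[str, int]:
        i = self.classes.index(cls)
        return {c: int(self.counts[i, j]) for j, c in enumerate(self.classes)}

    def top_confusion(self, cls: str) -> Optional[str]:
        """The off-diagonal column with the largest mass in the row of
        ``cls`` (None if that row has no errors)."""
        i = self.classes.index(cls)
        row = self.counts[i].astype(float).copy()
        row[i] = -1
        if row.max() <= 0:
            return None
        return self.classes[int(np.argmax(row))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def confusion(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    classes: Optional[Sequence[str]] = None,
) -> ConfusionMatrix:
    """Count matrix with rows = truth, columns = predictions."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if len(t) != len(p):
        raise ValueError("label sequences differ in length")
    if classes is None:
        classes = sorted(set(t) | set(p))
    classes = [str(c) for c in classes]
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for a, b in zip(t, p):
        if str(a) not in index or str(b) not in index:
            raise ValueError(f"label outside class list: {a!r}/{b!r}")
        counts[index[str(a)], index[str(b)]] += 1
    return ConfusionMatrix(classes=classes, counts=counts)


@dataclass
class CVResult:
    """Per-fold accuracies with their mean/SD and the pooled confusion."""

    fold_accuracies: List[float]
    pooled: ConfusionMatrix

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1)) if len(self.fold_accuracies) > 1 else 0.0


def grouped_kfold(
    horse_ids: Sequence[str],
    k: int = 5,
    rng_seed: int = 0,
    test_fraction: float = 0.0,
) -> SplitPlan:
    """Partition horses into k folds with approximately balanced stride
    counts (``horse_ids`` may repeat, one entry per stride — repeats are
    the weights).  With ``test_fraction`` > 0 that share of horses (by
    stride count) is first held out entirely.  Deterministic given seed.
    """
    ids, counts = np.unique(np.asarray(horse_ids, dtype=str), return_counts=True)
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(ids))
    ids, counts = ids[order], counts[order]

    test: List[str] = []
    if test_fraction > 0:
        target = test_fraction * counts.sum()
        got = 0
        # draw horses until the held-out stride share is reached
        for i in rng.permutation(len(ids)):
            if got >= target:
                break
            test.append(ids[i])
            got += counts[i]
        keep = ~np.isin(ids, test)
        ids, counts = ids[keep], counts[keep]

    if len(ids) < k:
        raise ValueError(f"need at least k={k} horses, got {len(ids)}")

    # Greedy balancing: biggest horses first, each into the lightest fold.
    fold_ids: List[List[str]] = [[] for _ in range(k)]
    load = np.zeros(k)
    for i in np.argsort(-counts, kind="stable"):
        j = int(np.argmin(load))
        fold_ids[j].append(ids[i])
        load[j] += counts[i]

    folds = []
    for j in range(k):
        val = tuple(sorted(fold_ids[j]))
        train = tuple(sorted(h for jj in range(k) if jj != j for h in fold_ids[jj]))
        folds.append((train, val))
    plan = SplitPlan(folds=folds, test_ids=tuple(sorted(test)))
    plan.validate()
    return plan


def _dataset_horses(dataset) -> np.ndarray:
    if isinstance(dataset, pd.DataFrame):
        return dataset["horse_id"].to_numpy(dtype=str)
    return np.asarray(dataset.horse_ids, dtype=str)


def _dataset_labels(dataset) -> np.ndarray:
    if isinstance(dataset, pd.DataFrame):
        return dataset["gait_label"].to_numpy(dtype=str)
    return np.asarray(dataset.y, dtype=str)


def _take(dataset, mask: np.ndarray):
    if isinstance(dataset, pd.DataFrame):
        return dataset.loc[mask].reset_index(drop=True)
    return dataset.subset(np.flatnonzero(mask))


def cross_validate(
    spec: ModelSpec,
    dataset: Union[pd.DataFrame, WindowSet],
    plan: SplitPlan,
    subset: Union[str, Sequence[str]] = "all",
    predictor=None,
) -> CVResult:
    """Run the horse-disjoint k-fold protocol.

    Per fold: training strides are class-balanced by duplication, the
    model is fitted and applied to the validation strides, and the
    confusion accumulated.  A ``predictor(train_set, val_set) -> labels``
    callable may replace model fitting (used for oracle tests).  Horse
    leakage is asserted on every fold.
    """
    plan.validate()
    horses = _dataset_horses(dataset)
    labels = _dataset_labels(dataset)
    classes = sorted(set(labels))
    fold_acc: List[float] = []
    pooled = np.zeros((len(classes), len(classes)), dtype=int)
    for train_ids, val_ids in plan.folds:
        if set(train_ids) & set(val_ids):
            raise ValueError("horse leakage across the train/validation boundary")
        tr_mask = np.isin(horses, train_ids)
        va_mask = np.isin(horses, val_ids)
        if set(horses[tr_mask]) & set(horses[va_mask]):
            raise AssertionError("horse leakage across the train/validation boundary")
        train_set = _take(dataset, tr_mask)
        val_set = _take(dataset, va_mask)
        if predictor is not None:
            preds = np.asarray(predictor(train_set, val_set), dtype=str)
        else:
            train_set = balance_by_duplication(train_set, rng_seed=spec.rng_seed)
            train_classes = set(_dataset_labels(train_set))
            missing = set(_dataset_labels(val_set)) - train_classes
            if missing:
                log.warning(
                    "fold training set missing classes %s; they cannot be "
                    "predicted in this fold",
                    sorted(missing),
                )
            if spec.kind == "sequence":
                model = train_sequence_model(spec, train_set)
            else:
                model = train_feature_model(spec, train_set, subset=subset)
            preds = np.asarray(predict(model, val_set if spec.kind == "sequence" else val_set), dtype=str)
        cm = confusion(labels[va_mask], preds, classes=classes)
        fold_acc.append(cm.accuracy)
        pooled += cm.counts
    return CVResult(
        fold_accuracies=fold_acc,
        pooled=ConfusionMatrix(classes=classes, counts=pooled),
    )


def _exclude_gaits(dataset, gaits: Sequence[str]):
    labels = _dataset_labels(dataset)
    mask = ~np.isin(labels, list(gaits))
    return _take(dataset, mask)


def run_experiment_grid(
    grid: Mapping[str, object],
    features: Optional[pd.DataFrame] = None,
    window_sets: Optional[Mapping[str, WindowSet]] = None,
    k: int = 5,
    rng_seed: int = 0,
) -> Tuple[pd.DataFrame, Dict[str, CVResult]]:
    """Run every cell of an experiment grid under a shared split plan.

    ``grid`` keys:

    * ``feature_models``: {"kinds": [...], "subsets": [...]} — needs
      ``features``;
    * ``sequence``: {"sensor_subsets": [...], "window_s": float,
      "bidirectional": bool, ...} — needs ``window_sets`` keyed by sensor
      subset name;
    * ``exclude_gaits``: labels removed from the data before splitting.

    Returns a tidy results table (one row per cell and fold) and the
    per-cell :class:`CVResult` objects keyed by cell name.
    """
    rows: List[Dict[str, object]] = []
    results: Dict[str, CVResult] = {}
    excluded = list(grid.get("exclude_gaits", []))

    def _run(cell: str, spec: ModelSpec, dataset, subset="all"):
        ds = _exclude_gaits(dataset, excluded) if excluded else dataset
        plan = grouped_kfold(_dataset_horses(ds), k=k, rng_seed=rng_seed)
        res = cross_validate(spec, ds, plan, subset=subset)
        results[cell] = res
        for i, acc in enumerate(res.fold_accuracies):
            rows.append(
                {
                    "cell": cell,
                    "kind": spec.kind,
                    "subset": subset if spec.kind != "sequence" else "",
                    "fold": i,
                    "accuracy": acc,
                    "mean_accuracy": res.mean_accuracy,
                    "sd_accuracy": res.sd_accuracy,
                }
            )

    fm = grid.get("feature_models")
    if fm:
        if features is None:
            raise ValueError("feature_models cells require a feature table")
        for kind in fm["kinds"]:
            if kind == "sequence":
                raise ValueError("sensor-subset/sequence cells do not take feature subsets")
            for subset in fm["subsets"]:
                if subset not in FEATURE_SUBSETS:
                    raise ValueError(f"unknown feature subset {subset!r}")
                spec = ModelSpec(kind=kind, rng_seed=rng_seed)
                _run(f"{kind}/{subset}", spec, features, subset=subset)

    seq = grid.get("sequence")
    if seq:
        if window_sets is None:
            raise ValueError("sequence cells require window sets per sensor subset")
        for sensors in seq["sensor_subsets"]:
            if sensors not in window_sets:
                raise ValueError(f"no window set supplied for sensors {sensors!r}")
            spec = ModelSpec(
                kind="sequence",
                hyperparameters={
                    key: seq[key]
                    for key in ("width", "n_recurrent_layers", "bidirectional", "max_epochs", "lr")
                    if key in seq
                },
                rng_seed=rng_seed,
            )
            _run(f"sequence/{sensors}", spec, window_sets[sensors])

    return pd.DataFrame(rows), results
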