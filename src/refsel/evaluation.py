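"""Hold-out validation of fixed signatures: accuracy, multi-class MCC,
per-class accuracy and label-shuffle controls.

The protocol mirrors the selection pipeline's numerical validation: split the
data into a training (default 90 %) and a validation (10 %) part, run the
repeated selection on the training part, then score the best signature on the
held-out part for every classifier family, alongside comparison signatures
and a shuffled-label control.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import UndefinedMetricWarning
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import train_test_split

from .data_model import ExpressionDataset, zscore_normalize
from .importance import ClassifierSpec, build_estimator, instance_seed
from .selector import RepeatedSelectionResult, run_repeated


def mcc(y_true: Sequence[str], y_pred: Sequence[str]) -> float:
    """Multi-class Matthews correlation coefficient from the confusion matrix.

    Uses the K×K generalization (covariance of true and predicted indicator
    matrices, normalized); degenerate denominators (e.g. single-class
    predictions) return 0 by convention so reports stay total.
    """
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    if len(y_true) == 0:
        raise ValueError("empty input")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UndefinedMetricWarning)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return float(matthews_corrcoef(list(y_true), list(y_pred)))


def per_class_accuracy(
    y_true: Sequence[str],
    predictions: Mapping[str, Sequence[str]],
    classes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Class × family matrix: fraction of class-c samples family f got right."""
    y_true = np.asarray([str(y) for y in y_true])
    if classes is None:
        classes = sorted(set(y_true))
    known = set(classes)
    out = {}
    for fam, y_pred in predictions.items():
        y_pred = np.asarray([str(y) for y in y_pred])
        if len(y_pred) != len(y_true):
            raise ValueError(f"predictions for {fam!r} misaligned with samples")
        unknown = set(y_pred) - known - set(y_true)
        if unknown:
            raise ValueError(f"unknown class in predictions for {fam!r}: {unknown}")
        out[fam] = [
            float((y_pred[y_true == c] == c).mean()) for c in classes
        ]
    return pd.DataFrame(out, index=pd.Index(classes, name="class"))


@dataclass
class EvaluationReport:
    """Per-family hold-out metrics for one signature.

    ``family_metrics`` holds ``accuracy_mean``, ``accuracy_sd`` and ``mcc`` per
    classifier family (sd is the population standard deviation when several
    evaluations are aggregated, 0 for a single split).  ``per_class`` is the
    class × family accuracy matrix.
    """

    signature: list[str]
    family_metrics: dict[str, dict[str, float]]
    per_class: pd.DataFrame
    global_accuracy: float
    global_mcc: float
    test_class_counts: dict[str, int] = field(default_factory=dict)
    shuffle: "EvaluationReport | None" = None

    def to_dict(self) -> dict:
        d = {
            "signature": self.signature,
            "family_metrics": self.family_metrics,
            "global_accuracy": self.global_accuracy,
            "global_mcc": self.global_mcc,
            "per_class_accuracy": {
                fam: {str(c): float(v) for c, v in col.items()}
                for fam, col in self.per_class.items()
            },
        }
        if self.shuffle is not None:
            d["shuffle"] = self.shuffle.to_dict()
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.family_metrics).T.rename_axis("family")


def evaluate_signature(
    ds_train: ExpressionDataset,
    ds_test: ExpressionDataset,
    signature: Sequence[str],
    specs: Sequence[ClassifierSpec],
    seed: int = 0,
) -> EvaluationReport:
    """Train each family on the signature columns of ``ds_train`` and score it
    on ``ds_test`` (accuracy, MCC, per-class accuracy).

    Deterministic given ``seed``.  Every signature feature must be present in
    both datasets.
    """
    signature = sorted(set(signature))
    if not signature:
        raise ValueError("empty signature")
    # raises KeyError naming the features if absent from either side
    train = ds_train.subset_features(signature)
    test = ds_test.subset_features(signature)
    y_train = np.asarray(train.labels)
    y_test = np.asarray(test.labels)

    family_metrics: dict[str, dict[str, float]] = {}
    predictions: dict[str, np.ndarray] = {}
    for spec in specs:
        est = build_estimator(spec, instance_seed(seed, spec.family, 0))
        est.fit(train.values, y_train)
        y_pred = np.asarray(est.predict(test.values)).astype(str)
        predictions[spec.family] = y_pred
        family_metrics[spec.family] = {
            "accuracy_mean": float((y_pred == y_test).mean()),
            "accuracy_sd": 0.0,
            "mcc": mcc(y_test, y_pred),
        }
    per_class = per_class_accuracy(y_test, predictions, classes=sorted(set(y_test)))
    accs = [m["accuracy_mean"] for m in family_metrics.values()]
    mccs = [m["mcc"] for m in family_metrics.values()]
    return EvaluationReport(
        signature=list(signature),
        family_metrics=family_metrics,
        per_class=per_class,
        global_accuracy=float(np.mean(accs)),
        global_mcc=float(np.mean(mccs)),
        test_class_counts={
            c: int((y_test == c).sum()) for c in sorted(set(y_test))
        },
    )


def shuffle_control(
    ds_train: ExpressionDataset,
    ds_test: ExpressionDataset,
    signature: Sequence[str],
    specs: Sequence[ClassifierSpec],
    seed: int = 0,
) -> EvaluationReport:
    """As :func:`evaluate_signature`, but with the test labels permuted
    uniformly at random (seeded) — the null control for the classifiers."""
    rng = np.random.default_rng(seed)
    shuffled = list(np.asarray(ds_test.labels)[rng.permutation(ds_test.n_samples)])
    ds_null = ExpressionDataset(
        sample_ids=list(ds_test.sample_ids),
        feature_ids=list(ds_test.feature_ids),
        values=ds_test.values.copy(),
        labels=shuffled,
        batch_ids=list(ds_test.batch_ids) if ds_test.batch_ids else None,
    )
    return evaluate_signature(ds_train, ds_null, signature, specs, seed=seed)


def holdout_protocol(
    ds: ExpressionDataset,
    specs: Sequence[ClassifierSpec],
    train_fraction: float = 0.9,
    threshold: float = 0.90,
    reduction_rate: float = 0.20,
    k: int = 10,
    min_size: int = 1,
    n_runs: int = 10,
    seed: int = 0,
    normalize: str = "pooled",
    with_shuffle: bool = False,
) -> tuple[set[str], EvaluationReport, RepeatedSelectionResult]:
    """Stratified hold-out validation of the selection pipeline.

    Splits ``ds`` into a stratified training (``train_fraction``) and
    validation part, runs the repeated selection on the training part, then
    evaluates the best signature on the validation part.

    ``normalize`` controls where the z-score step happens: ``"pooled"``
    normalizes the full dataset before splitting (the historical protocol this
    reproduces), ``"split"`` normalizes training and validation parts
    separately (leakage-safe, recommended for new analyses), ``"none"`` leaves
    values untouched.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    if normalize not in ("pooled", "split", "none"):
        raise ValueError(f"unknown normalize mode {normalize!r}")
    if normalize == "pooled":
        ds = zscore_normalize(ds)
    idx_train, idx_test = train_test_split(
        np.arange(ds.n_samples),
        train_size=train_fraction,
        stratify=ds.labels,
        random_state=seed,
    )
    ds_train = ds.subset_samples(sorted(idx_train))
    ds_test = ds.subset_samples(sorted(idx_test))
    if normalize == "split":
        ds_train = zscore_normalize(ds_train)
        ds_test = zscore_normalize(ds_test)

    repeated = run_repeated(
        ds_train, specs,
        threshold=threshold, reduction_rate=reduction_rate,
        k=k, min_size=min_size, n_runs=n_runs, base_seed=seed,
    )
    signature = repeated.best_signature
    report = evaluate_signature(ds_train, ds_test, signature, specs, seed=seed)
    if with_shuffle:
        report.shuffle = shuffle_control(
            ds_train, ds_test, signature, specs, seed=seed
        )
    return signature, report, repeated
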