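"""Per-instance classifier training and feature-importance extraction.

One *instance* is one classifier family trained on the training side of one
cross-validation fold.  Families based on ensembles of decision trees
(gradient boosting, random forest, bagging) score a feature by the number of
internal tree nodes that split on it; the five linear families (SGD, linear
SVC, logistic regression, passive-aggressive, ridge) score it by the summed
absolute value of its fitted coefficients across class rows.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import (
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression, RidgeClassifier, SGDClassifier
from sklearn.svm import SVC

from .data_model import ExpressionDataset, FoldAssignment

#: Families whose importance is the split frequency of the fitted trees.
TREE_FAMILIES = frozenset({"gradient-boosting", "random-forest", "bagging"})

#: Families whose importance is the absolute value of fitted coefficients.
COEF_FAMILIES = frozenset(
    {
        "stochastic-gradient-descent",
        "support-vector-classifier",
        "logistic-regression",
        "passive-aggressive",
        "ridge",
    }
)

#: The eight families of the heterogeneous ensemble, in canonical order.
DEFAULT_FAMILIES = (
    "stochastic-gradient-descent",
    "support-vector-classifier",
    "gradient-boosting",
    "random-forest",
    "logistic-regression",
    "passive-aggressive",
    "ridge",
    "bagging",
)

#: Default estimator count for the three tree-ensemble families.
DEFAULT_N_ESTIMATORS = 300


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family plus hyperparameters.

    ``importance_mode`` is determined by the family: ``"tree-split-frequency"``
    for the tree ensembles, ``"coefficient-magnitude"`` for the linear families.
    Hyperparameters are passed through to scikit-learn; tree ensembles default
    to ``n_estimators=300``.
    """

    family: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in TREE_FAMILIES | COEF_FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")
        object.__setattr__(
            self, "hyperparameters", dict(self.hyperparameters)
        )

    @property
    def importance_mode(self) -> str:
        return (
            "tree-split-frequency"
            if self.family in TREE_FAMILIES
            else "coefficient-magnitude"
        )

    def __hash__(self) -> int:  # hyperparameters dict is frozen by convention
        return hash((self.family, tuple(sorted(self.hyperparameters.items()))))


def default_specs(
    families: Sequence[str] = DEFAULT_FAMILIES,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
    hyperparameters: Mapping[str, Mapping[str, object]] | None = None,
) -> list[ClassifierSpec]:
    """Specs for the given families with per-family hyperparameter overrides."""
    hyperparameters = hyperparameters or {}
    specs = []
    for fam in families:
        hp: dict[str, object] = {}
        if fam in TREE_FAMILIES:
            hp["n_estimators"] = n_estimators
        hp.update(hyperparameters.get(fam, {}))
        specs.append(ClassifierSpec(fam, hp))
    return specs


def build_estimator(spec: ClassifierSpec, seed: int):
    """Construct the (unfitted) scikit-learn estimator for a spec.

    All stochastic estimators receive ``random_state=seed``.  The linear SVC
    uses the linear kernel (required for coefficient extraction); the
    passive-aggressive family uses the hinge-loss PA-I update as provided by
    ``SGDClassifier(learning_rate="pa1")``.
    """
    hp = dict(spec.hyperparameters)
    fam = spec.family
    if fam == "stochastic-gradient-descent":
        return SGDClassifier(random_state=seed, **hp)
    if fam == "support-vector-classifier":
        hp.setdefault("kernel", "linear")
        return SVC(random_state=seed, **hp)
    if fam == "gradient-boosting":
        hp.setdefault("n_estimators", DEFAULT_N_ESTIMATORS)
        return GradientBoostingClassifier(random_state=seed, **hp)
    if fam == "random-forest":
        hp.setdefault("n_estimators", DEFAULT_N_ESTIMATORS)
        return RandomForestClassifier(random_state=seed, **hp)
    if fam == "logistic-regression":
        hp.setdefault("max_iter", 1000)
        return LogisticRegression(**hp)
    if fam == "passive-aggressive":
        hp.setdefault("loss", "hinge")
        hp.setdefault("penalty", None)
        hp.setdefault("learning_rate", "pa1")
        hp.setdefault("eta0", 1.0)
        return SGDClassifier(random_state=seed, **hp)
    if fam == "ridge":
        return RidgeClassifier(**hp)
    if fam == "bagging":
        hp.setdefault("n_estimators", DEFAULT_N_ESTIMATORS)
        return BaggingClassifier(random_state=seed, **hp)
    raise ValueError(f"unknown classifier family {fam!r}")


def instance_seed(run_seed: int, family: str, fold: int) -> int:
    """Deterministic per-instance seed derived from (run seed, family, fold).

    Stable across processes and platforms (CRC32, not Python's salted hash),
    so repeated runs differ only through the run seed.
    """
    return zlib.crc32(f"{run_seed}:{family}:{fold}".encode()) & 0x7FFFFFFF


@dataclass
class InstanceResult:
    """Importance vector, ranking and held-out accuracy of one instance."""

    spec: ClassifierSpec
    fold: int
    importance: dict[str, float]
    ranking: list[str]
    holdout_accuracy: float

    def to_dict(self) -> dict:
        return {
            "family": self.spec.family,
            "hyperparameters": dict(self.spec.hyperparameters),
            "fold": self.fold,
            "importance": self.importance,
            "ranking": self.ranking,
            "holdout_accuracy": self.holdout_accuracy,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def tree_split_frequencies(
    trees: Sequence[Sequence[str]], features: Sequence[str]
) -> dict[str, int]:
    """Count, per feature, the internal tree nodes splitting on it.

    ``trees`` is a list of fitted-tree descriptions, each the list of split
    features of its internal nodes.  Features never split map to 0; a split on
    an unknown feature id is an error.
    """
    known = set(features)
    counts = {f: 0 for f in features}
    for tree in trees:
        for f in tree:
            if f not in known:
                raise ValueError(f"split on unknown feature id {f!r}")
            counts[f] += 1
    return counts


def extract_split_features(model, feature_ids: Sequence[str]) -> list[list[str]]:
    """Explicitly walk every fitted tree of a tree-ensemble model and list the
    feature ids of its internal (non-leaf) nodes.

    This deliberately bypasses the impurity-based ``feature_importances_`` of
    scikit-learn: the score used here is split *frequency*.
    """
    estimators = np.asarray(model.estimators_, dtype=object).ravel()
    out: list[list[str]] = []
    for est in estimators:
        tree = est.tree_
        split_idx = tree.feature[tree.feature >= 0]
        out.append([feature_ids[i] for i in split_idx])
    return out


def coefficient_magnitudes(
    coefs: np.ndarray, feature_ids: Sequence[str]
) -> dict[str, float]:
    """Importance = sum over class rows of |coefficient| per feature column.

    Binary classifiers supply a single row, where this reduces to the plain
    absolute coefficient.  Summation across rows is symmetric in the classes
    and scale-monotone.
    """
    coefs = np.atleast_2d(np.asarray(coefs, dtype=float))
    if coefs.shape[1] != len(feature_ids):
        raise ValueError(
            f"coefficient matrix has {coefs.shape[1]} columns but "
            f"{len(feature_ids)} features"
        )
    scores = np.abs(coefs).sum(axis=0)
    return {f: float(s) for f, s in zip(feature_ids, scores)}


def rank_features(importance: Mapping[str, float]) -> list[str]:
    """Feature ids by decreasing importance; ties broken lexicographically."""
    if not importance:
        raise ValueError("empty importance mapping")
    return sorted(importance, key=lambda f: (-importance[f], f))


def train_instance(
    spec: ClassifierSpec,
    ds: ExpressionDataset,
    folds: FoldAssignment,
    fold: int,
    seed: int,
) -> InstanceResult:
    """Train one (family × fold) instance and extract its importance vector.

    The model is fitted on all samples outside ``fold``, scored on the fold,
    and the importance extracted in the family's mode.  Fully deterministic
    given ``seed`` (the per-instance seed is derived from it).
    """
    train_idx, test_idx = folds.train_test(fold)
    y = np.asarray(ds.labels)
    if len(set(y[train_idx])) < 2:
        raise ValueError(f"training split of fold {fold} is missing a class")
    est = build_estimator(spec, instance_seed(seed, spec.family, fold))
    est.fit(ds.values[train_idx], y[train_idx])
    accuracy = float(est.score(ds.values[test_idx], y[test_idx]))

    if ds.n_features == 1:
        importance = {ds.feature_ids[0]: 1.0}
    elif spec.importance_mode == "tree-split-frequency":
        trees = extract_split_features(est, ds.feature_ids)
        importance = {
            f: float(c)
            for f, c in tree_split_frequencies(trees, ds.feature_ids).items()
        }
    else:
        importance = coefficient_magnitudes(est.coef_, ds.feature_ids)

    return InstanceResult(
        spec=spec,
        fold=fold,
        importance=importance,
        ranking=rank_features(importance),
        holdout_accuracy=accuracy,
    )
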