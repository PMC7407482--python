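"""Expression-data container, delimited-text I/O, panel filtering, normalization
and stratified partitioning.

The central object is :class:`ExpressionDataset`: a samples × features matrix of
(nondimensional) expression values with one class label per sample and an
optional study/batch identifier per sample.  Tables are plain delimited text
(comma or tab, autodetected), first column = sample id, one named column for
the label and optionally one for the batch; every other column is a feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)


def _find_duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


@dataclass
class ExpressionDataset:
    """Labelled samples × features expression matrix.

    Parameters
    ----------
    sample_ids : unique sample identifiers (rows).
    feature_ids : unique feature identifiers (columns), e.g. ``"hsa-miR-122"``.
    values : 2-d float array, shape ``(n_samples, n_features)``, no missing values.
    labels : one class label per sample.
    batch_ids : optional one study/batch identifier per sample.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    labels: list[str]
    batch_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.labels = [str(l) for l in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d matrix")
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"values has {n} rows but {len(self.sample_ids)} sample ids"
            )
        if p != len(self.feature_ids):
            raise ValueError(
                f"values has {p} columns but {len(self.feature_ids)} feature ids"
            )
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("labels length must equal sample count")
        dups = _find_duplicates(self.sample_ids)
        if dups:
            raise ValueError(f"duplicate sample ids: {dups}")
        dups = _find_duplicates(self.feature_ids)
        if dups:
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.batch_ids is not None:
            self.batch_ids = [str(b) for b in self.batch_ids]
            if len(self.batch_ids) != len(self.sample_ids):
                raise ValueError("batch_ids length must equal sample count")
        if np.isnan(self.values).any():
            i, j = map(int, np.argwhere(np.isnan(self.values))[0])
            raise ValueError(
                f"missing value for sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def feature_index(self, feature_ids: Iterable[str]) -> list[int]:
        lookup = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in lookup]
        if missing:
            raise KeyError(f"features not in dataset: {missing}")
        return [lookup[f] for f in feature_ids]

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionDataset":
        """Restrict to the given features, in the given order."""
        idx = self.feature_index(feature_ids)
        return replace(
            self,
            feature_ids=list(feature_ids),
            values=self.values[:, idx].copy(),
        )

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionDataset":
        indices = list(indices)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in indices],
            values=self.values[indices].copy(),
            labels=[self.labels[i] for i in indices],
            batch_ids=(
                [self.batch_ids[i] for i in indices] if self.batch_ids else None
            ),
        )

    def to_frame(
        self, label_column: str = "label", batch_column: str = "batch"
    ) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.feature_ids,
        )
        df[label_column] = self.labels
        if self.batch_ids is not None:
            df[batch_column] = self.batch_ids
        return df


@dataclass
class FoldAssignment:
    """Stratified k-fold partition: one fold index in ``[0, k)`` per sample."""

    k: int
    assignment: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.ndim != 1:
            raise ValueError("assignment must be 1-d")
        if self.assignment.min() < 0 or self.assignment.max() >= self.k:
            raise ValueError("fold indices must lie in [0, k)")

    def train_test(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        if not 0 <= fold < self.k:
            raise ValueError(f"fold {fold} outside [0, {self.k})")
        test = np.flatnonzero(self.assignment == fold)
        train = np.flatnonzero(self.assignment != fold)
        return train, test


def _detect_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def load_expression_table(
    path: str | Path,
    label_column: str = "label",
    batch_column: str | None = None,
    impute_missing: bool = False,
) -> ExpressionDataset:
    """Read a delimited expression table into a validated dataset.

    The first column holds sample ids; one column (``label_column``) holds class
    labels; all remaining columns are features.  Comma vs. tab is autodetected
    from the header row.  Missing expression cells are a hard error unless
    ``impute_missing`` is set, in which case they are filled with the per-feature
    mean.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    labels = df[label_column].astype(str).tolist()
    batch_ids = None
    drop = [label_column]
    if batch_column is not None:
        if batch_column not in df.columns:
            raise ValueError(f"batch column {batch_column!r} not found in {path}")
        batch_ids = df[batch_column].astype(str).tolist()
        drop.append(batch_column)
    expr = df.drop(columns=drop)
    try:
        values = expr.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression cell in {path}: {exc}") from exc
    if np.isnan(values).any():
        if impute_missing:
            col_means = np.nanmean(values, axis=0)
            idx = np.where(np.isnan(values))
            values[idx] = np.take(col_means, idx[1])
        else:
            i, j = map(int, np.argwhere(np.isnan(values))[0])
            raise ValueError(
                f"missing value for sample {expr.index[i]!r}, "
                f"feature {expr.columns[j]!r} (set impute_missing to fill)"
            )
    return ExpressionDataset(
        sample_ids=[str(s) for s in expr.index],
        feature_ids=[str(c) for c in expr.columns],
        values=values,
        labels=labels,
        batch_ids=batch_ids,
    )


def save_expression_table(
    ds: ExpressionDataset,
    path: str | Path,
    label_column: str = "label",
    batch_column: str = "batch",
) -> None:
    """Write a dataset as delimited text (tab for ``.tsv``, comma otherwise)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    ds.to_frame(label_column, batch_column).to_csv(path, sep=sep)


def read_panel(path: str | Path) -> list[str]:
    """Read a feature panel: one feature id per line, ``#`` comments allowed."""
    panel: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                panel.append(line)
    return panel


read_feature_list = read_panel


def write_feature_list(features: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for f in features:
            fh.write(f"{f}\n")


def filter_to_panel(
    ds: ExpressionDataset, panel: Sequence[str]
) -> ExpressionDataset:
    """Restrict a dataset to the features of a panel, in panel order.

    Panel members absent from the dataset are reported via a warning log and
    dropped; an empty intersection is an error.
    """
    if not panel:
        raise ValueError("panel is empty")
    present = set(ds.feature_ids)
    kept = [f for f in panel if f in present]
    missing = [f for f in panel if f not in present]
    if not kept:
        raise ValueError("no panel feature is present in the dataset")
    if missing:
        logger.warning(
            "%d of %d panel features absent from dataset: %s",
            len(missing), len(panel), ", ".join(missing[:20]),
        )
    return ds.subset_features(kept)


def zscore_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Z-score each feature: ``(x - mean) / sigma`` with the population sigma.

    Zero-variance features map to all-zeros rather than NaN so that feature
    indices stay stable through the elimination recursion; a constant feature
    carries no class information and is eliminated by scoring anyway.
    """
    mean = ds.values.mean(axis=0)
    sd = ds.values.std(axis=0)  # population (ddof=0)
    centered = ds.values - mean
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
    return replace(ds, values=z)


def merge_datasets(
    parts: Sequence[ExpressionDataset],
    feature_policy: str = "intersection",
    part_names: Sequence[str] | None = None,
) -> ExpressionDataset:
    """Concatenate datasets sample-wise, tagging each sample's batch id with the
    identity of the part it came from (multi-study aggregation).

    ``feature_policy="strict"`` requires identical feature lists;
    ``"intersection"`` restricts to the common features (ordered as in the
    first part).
    """
    if not parts:
        raise ValueError("need at least one dataset to merge")
    if feature_policy not in ("intersection", "strict"):
        raise ValueError(f"unknown feature_policy {feature_policy!r}")
    if part_names is None:
        part_names = [f"part{i}" for i in range(len(parts))]
    if len(part_names) != len(parts):
        raise ValueError("part_names length must match parts")

    if feature_policy == "strict":
        for p in parts[1:]:
            if p.feature_ids != parts[0].feature_ids:
                raise ValueError("'strict' merge requires identical feature ids")
        common = list(parts[0].feature_ids)
    else:
        shared = set(parts[0].feature_ids)
        for p in parts[1:]:
            shared &= set(p.feature_ids)
        if not shared:
            raise ValueError("empty feature intersection across parts")
        common = [f for f in parts[0].feature_ids if f in shared]

    aligned = [p.subset_features(common) for p in parts]
    sample_ids = [s for p in aligned for s in p.sample_ids]
    dups = _find_duplicates(sample_ids)
    if dups:
        raise ValueError(f"duplicate sample ids across parts: {dups}")
    return ExpressionDataset(
        sample_ids=sample_ids,
        feature_ids=common,
        values=np.vstack([p.values for p in aligned]),
        labels=[l for p in aligned for l in p.labels],
        batch_ids=[
            name for p, name in zip(aligned, part_names) for _ in p.sample_ids
        ],
    )


def stratified_folds(
    ds: ExpressionDataset, k: int, seed: int
) -> FoldAssignment:
    """Stratified k-fold partition preserving per-class sample ratios.

    Deterministic given ``seed``.  Every class must have at least ``k`` samples;
    the offending class is named otherwise.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray(ds.labels)
    for cls in ds.classes:
        n_cls = int((labels == cls).sum())
        if n_cls < k:
            raise ValueError(
                f"class {cls!r} has only {n_cls} samples, fewer than k={k}"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(ds.n_samples, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(ds.values, labels)):
        assignment[test_idx] = fold
    return FoldAssignment(k=k, assignment=assignment, seed=seed)
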