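"""Comparison selectors: homogeneous single-family recursive ensemble,
K-best univariate F-score selection and random signatures.

Externally produced signatures (e.g. from genetic-algorithm selectors) can be
evaluated through the same harness as plain feature lists; they are not
generated here.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np

from .data_model import ExpressionDataset
from .importance import ClassifierSpec
from .selector import SelectionTrajectory, run_selection


def homogeneous_selection(
    ds: ExpressionDataset,
    family: ClassifierSpec | None = None,
    threshold: float = 0.90,
    reduction_rate: float = 0.20,
    k: int = 10,
    seed: int = 0,
    min_size: int = 1,
) -> SelectionTrajectory:
    """Recursive elimination with a single classifier family (``N_c = k``).

    Defaults to the linear support-vector family; identical recursion and
    parameters to the heterogeneous selection, with a one-element spec list.
    """
    if family is None:
        family = ClassifierSpec("support-vector-classifier")
    return run_selection(
        ds, [family],
        threshold=threshold, reduction_rate=reduction_rate,
        k=k, seed=seed, min_size=min_size,
    )


def univariate_f_scores(ds: ExpressionDataset) -> dict[str, float]:
    """One-way ANOVA F statistic per feature over the class groupings.

    F = (between-group mean square) / (within-group mean square).  A feature
    constant within every class but varying between classes has zero
    within-group variance and yields ``+inf`` (perfect separation); a feature
    with zero between- and within-group variance (0/0) yields 0.
    """
    labels = np.asarray(ds.labels)
    classes = ds.classes
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    groups = [ds.values[labels == c] for c in classes]
    for c, g in zip(classes, groups):
        if len(g) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    n = ds.n_samples
    K = len(classes)
    grand = ds.values.mean(axis=0)
    ss_between = sum(
        len(g) * (g.mean(axis=0) - grand) ** 2 for g in groups
    )
    ss_within = sum(((g - g.mean(axis=0)) ** 2).sum(axis=0) for g in groups)
    msb = ss_between / (K - 1)
    msw = ss_within / (n - K)
    scores: dict[str, float] = {}
    for j, f in enumerate(ds.feature_ids):
        if msw[j] > 0:
            scores[f] = float(msb[j] / msw[j])
        else:
            scores[f] = math.inf if msb[j] > 0 else 0.0
    return scores


def select_k_best(scores: Mapping[str, float], k: int) -> set[str]:
    """The ``k`` top-scoring features; ties broken lexicographically,
    infinite scores sort above all finite ones."""
    if not 1 <= k <= len(scores):
        raise ValueError(f"k={k} outside [1, {len(scores)}]")
    order = sorted(scores, key=lambda f: (-scores[f], f))
    return set(order[:k])


def random_signatures(
    features: Sequence[str], k: int, n: int, seed: int = 0
) -> list[set[str]]:
    """``n`` distinct random feature sets of size ``k``, drawn without
    replacement within each set; deterministic given ``seed``."""
    if k > len(features):
        raise ValueError(f"k={k} exceeds the {len(features)} available features")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[set[str]] = []
    seen: set[frozenset[str]] = set()
    attempts = 0
    while len(out) < n:
        draw = frozenset(rng.choice(len(features), size=k, replace=False).tolist())
        attempts += 1
        if draw in seen:
            if attempts > 1000 * n:
                raise ValueError(
                    f"cannot draw {n} distinct size-{k} subsets of "
                    f"{len(features)} features"
                )
            continue
        seen.add(draw)
        out.append({features[i] for i in draw})
    return out
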