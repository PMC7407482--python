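"""Recursive heterogeneous-ensemble feature selection.

At every iteration each classifier family is trained once per stratified fold
on the current feature subset.  Each of the ``N_c = families × folds``
instances ranks the features; a feature's ensemble score is

    s_f = N_t / N_c,

the fraction of instances whose top-``S`` ranked features contain it, where
``S`` is the next (20 %-reduced) target size.  The ``S`` top-scoring features
are retained and the procedure recurses until the mean held-out accuracy over
all instances drops below a threshold (default 0.90) or a minimum size is
reached.  The signature finally reported is the smallest feature set whose
measured mean accuracy stayed at or above the threshold.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import ExpressionDataset, FoldAssignment, stratified_folds
from .importance import ClassifierSpec, InstanceResult, train_instance

logger = logging.getLogger(__name__)


@dataclass
class EnsembleScoreTable:
    """Per-feature vote counts for one elimination iteration.

    ``n_t[f]`` counts the classifier instances whose top-``S`` set contains
    feature ``f``; ``n_c`` is the total instance count; ``score(f) = n_t/n_c``.
    """

    n_t: dict[str, int]
    n_c: int
    S: int

    def score(self, feature: str) -> float:
        return self.n_t[feature] / self.n_c

    @property
    def scores(self) -> dict[str, float]:
        return {f: n / self.n_c for f, n in self.n_t.items()}

    def to_dict(self) -> dict:
        return {"n_c": self.n_c, "S": self.S, "n_t": self.n_t}


@dataclass
class SelectionIteration:
    """Record of one elimination iteration (accuracies measured on features_in)."""

    features_in: list[str]
    S_next: int
    instance_accuracies: list[float]
    mean_accuracy: float
    score_table: EnsembleScoreTable
    features_out: list[str]
    family_accuracies: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "size_in": len(self.features_in),
            "size_out": len(self.features_out),
            "S_next": self.S_next,
            "mean_accuracy": self.mean_accuracy,
            "family_accuracies": self.family_accuracies,
            "features_in": self.features_in,
            "features_out": self.features_out,
            "score_table": self.score_table.to_dict(),
        }


@dataclass
class SelectionTrajectory:
    """Ordered elimination iterations plus the stop reason and config snapshot."""

    iterations: list[SelectionIteration]
    stop_reason: str
    config: dict

    def sizes(self) -> list[int]:
        return [len(it.features_in) for it in self.iterations]

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "stop_reason": self.stop_reason,
            "iterations": [it.to_dict() for it in self.iterations],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_tidy(self) -> pd.DataFrame:
        """Tidy per-iteration table for accuracy-vs-size curves."""
        rows = []
        for i, it in enumerate(self.iterations):
            row = {
                "iteration": i,
                "size": len(it.features_in),
                "mean_accuracy": it.mean_accuracy,
            }
            row.update(
                {f"accuracy_{fam}": a for fam, a in it.family_accuracies.items()}
            )
            rows.append(row)
        return pd.DataFrame(rows)


def top_s_membership(ranking: Sequence[str], S: int) -> set[str]:
    """The first ``S`` ids of a ranking, as a set."""
    if not 1 <= S <= len(ranking):
        raise ValueError(f"S={S} outside [1, {len(ranking)}]")
    return set(ranking[:S])


def score_features(
    rankings: Sequence[Sequence[str]], S: int
) -> EnsembleScoreTable:
    """Vote table over ``N_c`` instance rankings: N_t counts top-``S`` membership."""
    if not rankings:
        raise ValueError("need at least one ranking")
    features = set(rankings[0])
    for r in rankings[1:]:
        if set(r) != features:
            raise ValueError("rankings cover inconsistent feature sets")
    n_t = {f: 0 for f in sorted(features)}
    for r in rankings:
        for f in top_s_membership(r, S):
            n_t[f] += 1
    return EnsembleScoreTable(n_t=n_t, n_c=len(rankings), S=S)


def next_subset_size(S_current: int, reduction_rate: float) -> int:
    """Next target size: floor of a ``reduction_rate`` cut, strictly decreasing.

    ``max(1, min(S_current - 1, floor((1 - rate) * S_current)))`` — the guard
    prevents stalling for small sizes and guarantees termination.
    """
    if S_current < 2:
        raise ValueError("S_current must be >= 2")
    if not 0 < reduction_rate < 1:
        raise ValueError("reduction_rate must be in (0, 1)")
    return max(1, min(S_current - 1, math.floor((1 - reduction_rate) * S_current)))


def _mean_ranks(rankings: Sequence[Sequence[str]]) -> dict[str, float]:
    pos: dict[str, float] = {f: 0.0 for f in rankings[0]}
    for r in rankings:
        for i, f in enumerate(r):
            pos[f] += i
    return {f: p / len(rankings) for f, p in pos.items()}


def _retain(
    table: EnsembleScoreTable, rankings: Sequence[Sequence[str]], S: int
) -> list[str]:
    # Tie-break at the s_f boundary: score desc, mean rank asc, id asc.
    mean_rank = _mean_ranks(rankings)
    order = sorted(table.n_t, key=lambda f: (-table.n_t[f], mean_rank[f], f))
    return order[:S]


def run_selection(
    ds: ExpressionDataset,
    specs: Sequence[ClassifierSpec],
    threshold: float = 0.90,
    reduction_rate: float = 0.20,
    k: int = 10,
    seed: int = 0,
    min_size: int = 1,
    folds: FoldAssignment | None = None,
) -> SelectionTrajectory:
    """Run the recursive ensemble elimination on a dataset.

    Folds are drawn once per run and reused across iterations, so accuracy
    changes along the trajectory reflect feature elimination rather than fold
    resampling.  The iteration that falls below the threshold is still
    recorded, so trajectories can be plotted past the stop.  Deterministic
    given ``seed``.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if ds.n_features < 2:
        raise ValueError("need at least 2 features to select from")
    if folds is None:
        folds = stratified_folds(ds, k, seed)
    elif folds.k != k:
        raise ValueError("provided folds disagree with k")

    features = list(ds.feature_ids)
    iterations: list[SelectionIteration] = []
    stop_reason = "min-size-reached"
    while True:
        sub = ds.subset_features(features)
        results: list[InstanceResult] = [
            train_instance(spec, sub, folds, fold, seed)
            for spec in specs
            for fold in range(k)
        ]
        accuracies = [r.holdout_accuracy for r in results]
        mean_accuracy = float(np.mean(accuracies))
        family_acc = {
            spec.family: float(
                np.mean([r.holdout_accuracy for r in results if r.spec is spec])
            )
            for spec in specs
        }
        S_next = next_subset_size(len(features), reduction_rate)
        rankings = [r.ranking for r in results]
        table = score_features(rankings, S_next)
        retained = _retain(table, rankings, S_next)
        iterations.append(
            SelectionIteration(
                features_in=features,
                S_next=S_next,
                instance_accuracies=accuracies,
                mean_accuracy=mean_accuracy,
                score_table=table,
                features_out=retained,
                family_accuracies=family_acc,
            )
        )
        logger.info(
            "iteration %d: %d features, mean accuracy %.4f -> keep %d",
            len(iterations), len(features), mean_accuracy, S_next,
        )
        if mean_accuracy < threshold:
            stop_reason = "below-threshold"
            break
        if len(retained) <= min_size:
            stop_reason = "min-size-reached"
            break
        features = retained

    return SelectionTrajectory(
        iterations=iterations,
        stop_reason=stop_reason,
        config={
            "threshold": threshold,
            "reduction_rate": reduction_rate,
            "k": k,
            "seed": seed,
            "min_size": min_size,
            "families": [s.family for s in specs],
        },
    )


def select_signature(
    traj: SelectionTrajectory, threshold: float
) -> set[str]:
    """The smallest feature set whose measured mean accuracy is >= threshold.

    Accuracies are measured on the set each iteration enters with, so this is
    the ``features_in`` of the last qualifying iteration.  If no iteration
    qualifies, the initial feature set is returned with a warning.
    """
    if not traj.iterations:
        raise ValueError("empty trajectory")
    qualifying = [
        it for it in traj.iterations if it.mean_accuracy >= threshold
    ]
    if not qualifying:
        warnings.warn(
            "no iteration reached the accuracy threshold; "
            "falling back to the initial feature set",
            stacklevel=2,
        )
        return set(traj.iterations[0].features_in)
    return set(qualifying[-1].features_in)


def signature_accuracy(traj: SelectionTrajectory, threshold: float) -> float:
    """Mean accuracy measured on the signature set of a trajectory."""
    qualifying = [
        it for it in traj.iterations if it.mean_accuracy >= threshold
    ]
    target = qualifying[-1] if qualifying else traj.iterations[0]
    return target.mean_accuracy


@dataclass
class RepeatedSelectionResult:
    """Outcome of repeated selection runs with consecutive seeds."""

    trajectories: list[SelectionTrajectory]
    signatures: list[set[str]]
    frequency: dict[str, int]
    best_signature: set[str]
    best_run: int

    def frequency_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.frequency.items(), key=lambda kv: (-kv[1], kv[0])),
            columns=["feature", "frequency"],
        )


def run_repeated(
    ds: ExpressionDataset,
    specs: Sequence[ClassifierSpec],
    threshold: float = 0.90,
    reduction_rate: float = 0.20,
    k: int = 10,
    min_size: int = 1,
    n_runs: int = 10,
    base_seed: int = 0,
) -> RepeatedSelectionResult:
    """Run the selection ``n_runs`` times with seeds ``base_seed .. base_seed+n-1``.

    Returns all trajectories, a per-feature table counting the runs whose final
    signature contains the feature (signature-stability analysis), and the
    signature of the run with the highest signature-level mean accuracy.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    trajectories = []
    signatures = []
    sig_accs = []
    for i in range(n_runs):
        traj = run_selection(
            ds, specs,
            threshold=threshold, reduction_rate=reduction_rate,
            k=k, seed=base_seed + i, min_size=min_size,
        )
        trajectories.append(traj)
        signatures.append(select_signature(traj, threshold))
        sig_accs.append(signature_accuracy(traj, threshold))
    frequency: dict[str, int] = {}
    for sig in signatures:
        for f in sig:
            frequency[f] = frequency.get(f, 0) + 1
    best_run = int(np.argmax(sig_accs))
    return RepeatedSelectionResult(
        trajectories=trajectories,
        signatures=signatures,
        frequency=frequency,
        best_signature=signatures[best_run],
        best_run=best_run,
    )
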