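"""Seeded generator of synthetic expression datasets.

The generator emulates the statistical structure the selection method assumes:
a Gaussian expression matrix (processed, approximately centered expression),
a configurable number of classes with planted informative features
(class-dependent mean shifts in units of the noise standard deviation),
additive per-batch offsets emulating multi-study aggregation, and class
imbalance.  The ground-truth planted feature set is retrievable, which makes
parameter-recovery testing possible without any data downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import ExpressionDataset

#: Per-study (sample count, class index) plan of the multi-class benchmark
#: design this generator emulates: 16 studies, 845 samples, 10 tumor classes.
MULTICLASS_STUDY_PLAN: tuple[tuple[int, int], ...] = (
    (33, 0), (72, 0), (49, 0), (50, 0),   # breast
    (108, 1),                             # esophageal
    (44, 2),                              # head & neck
    (57, 3), (115, 3), (64, 3),           # liver
    (21, 4), (50, 4),                     # prostate
    (38, 5),                              # glioblastoma
    (75, 6),                              # colorectal
    (24, 7),                              # non-small-cell lung
    (15, 8),                              # gastric
    (30, 9),                              # ovarian
)

#: Feature-panel size of the circulating-miRNA benchmark design.
PANEL_SIZE = 253

#: Class imbalance of the binary (TNBC-style) benchmark design.
IMBALANCED_CASE, IMBALANCED_CONTROL = 139, 44


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic dataset.

    ``planted`` lists ``(feature index, per-class mean shifts in sigma units)``
    pairs; all other features are pure ``Normal(0, noise_sd)`` noise
    independent of class.  ``batch_plan`` optionally fixes per-batch
    ``(size, class index)`` blocks (study emulation); otherwise samples are
    assigned to ``n_batches`` cyclically.  ``raw_scale`` exponentiates the
    matrix into a log-normal raw scale for testing the normalization path.
    """

    n_classes: int
    samples_per_class: tuple[int, ...]
    n_features: int
    planted: tuple[tuple[int, tuple[float, ...]], ...] = ()
    noise_sd: float = 1.0
    n_batches: int = 1
    batch_sd: float = 0.0
    seed: int = 0
    class_names: tuple[str, ...] | None = None
    batch_plan: tuple[tuple[int, int], ...] | None = None
    raw_scale: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples_per_class", tuple(int(s) for s in self.samples_per_class)
        )
        object.__setattr__(
            self,
            "planted",
            tuple((int(i), tuple(float(s) for s in shifts))
                  for i, shifts in self.planted),
        )
        if self.class_names is not None:
            object.__setattr__(self, "class_names", tuple(self.class_names))
        if self.batch_plan is not None:
            object.__setattr__(
                self,
                "batch_plan",
                tuple((int(n), int(c)) for n, c in self.batch_plan),
            )
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if len(self.samples_per_class) != self.n_classes:
            raise ValueError("samples_per_class length must equal n_classes")
        if any(s < 1 for s in self.samples_per_class):
            raise ValueError("every class needs at least one sample")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.batch_sd < 0:
            raise ValueError("batch_sd must be >= 0")
        idx = [i for i, _ in self.planted]
        if len(set(idx)) != len(idx):
            raise ValueError("planted feature indices must be distinct")
        if any(i < 0 or i >= self.n_features for i in idx):
            raise ValueError("planted feature index out of range")
        for i, shifts in self.planted:
            if len(shifts) != self.n_classes:
                raise ValueError(
                    f"planted feature {i} needs one shift per class"
                )
        if self.class_names is not None and len(self.class_names) != self.n_classes:
            raise ValueError("class_names length must equal n_classes")
        if self.batch_plan is not None:
            if len(self.batch_plan) != self.n_batches:
                raise ValueError("batch_plan length must equal n_batches")
            per_class = [0] * self.n_classes
            for n, c in self.batch_plan:
                if not 0 <= c < self.n_classes:
                    raise ValueError(f"batch_plan class index {c} out of range")
                per_class[c] += n
            if tuple(per_class) != self.samples_per_class:
                raise ValueError(
                    "batch_plan sizes do not aggregate to samples_per_class"
                )

    @property
    def n_samples(self) -> int:
        return sum(self.samples_per_class)

    def feature_ids(self) -> list[str]:
        width = max(3, len(str(self.n_features - 1)))
        return [f"mir-{i:0{width}d}" for i in range(self.n_features)]

    def labels(self) -> list[str]:
        names = self.class_names or tuple(
            f"class{c}" for c in range(self.n_classes)
        )
        return [
            names[c]
            for c in range(self.n_classes)
            for _ in range(self.samples_per_class[c])
        ]


def cycle_code_shifts(
    n_classes: int, n_planted: int, effect: float
) -> list[list[float]]:
    """Signed binary class codes for planted features, as per-feature shift
    lists (``±effect`` sigma units per class).

    The codes are the vertices of a closed walk on the ``n_planted``-cube that
    flips each coordinate direction in turn, twice around.  Consequences, by
    construction: (a) consecutive classes differ on exactly one planted
    feature, by ``2·effect`` sigma, and all other class pairs differ on at
    least two, so the classes are jointly well separated; (b) each planted
    feature separates two class pairs that agree on every other planted
    feature, so removing any single planted feature makes two class pairs
    distributionally identical and caps attainable accuracy at
    ``1 - 2/n_classes`` (for ``n_classes = 2·n_planted``).  That is what makes
    every planted feature individually necessary, and recovery falsifiable.
    """
    if n_planted < 2:
        raise ValueError("need at least 2 planted features for a code")
    if n_classes > 2 * n_planted:
        raise ValueError(
            f"cycle code supports at most {2 * n_planted} classes "
            f"for {n_planted} planted features"
        )
    bits = [0] * n_planted
    vertices = [tuple(bits)]
    for step in range(2 * n_planted - 1):
        bits[step % n_planted] ^= 1
        vertices.append(tuple(bits))
    vertices = vertices[:n_classes]
    return [
        [effect if v[j] else -effect for v in vertices]
        for j in range(n_planted)
    ]


def generate(spec: SyntheticSpec) -> ExpressionDataset:
    """Draw the dataset a spec describes; bit-identical across calls per seed."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features
    labels = spec.labels()
    class_index = np.repeat(
        np.arange(spec.n_classes), np.asarray(spec.samples_per_class)
    )
    values = rng.normal(0.0, spec.noise_sd, size=(n, p))
    for idx, shifts in spec.planted:
        values[:, idx] += spec.noise_sd * np.asarray(shifts)[class_index]

    if spec.batch_plan is not None:
        batch_of_sample = np.empty(n, dtype=int)
        # consume each class's sample block in batch_plan order
        cursor = np.cumsum([0] + list(spec.samples_per_class[:-1])).astype(int)
        for b, (size, c) in enumerate(spec.batch_plan):
            batch_of_sample[cursor[c]: cursor[c] + size] = b
            cursor[c] += size
    else:
        batch_of_sample = np.arange(n) % spec.n_batches
    offsets = rng.normal(0.0, spec.batch_sd, size=spec.n_batches)
    values += offsets[batch_of_sample][:, None]
    if spec.raw_scale:
        values = np.exp(values)

    width = max(4, len(str(n - 1)))
    return ExpressionDataset(
        sample_ids=[f"s{i:0{width}d}" for i in range(n)],
        feature_ids=spec.feature_ids(),
        values=values,
        labels=labels,
        batch_ids=[f"batch{b}" for b in batch_of_sample],
    )


def planted_feature_ids(spec: SyntheticSpec) -> set[str]:
    """Ground-truth ids of the planted (informative) features."""
    ids = spec.feature_ids()
    return {ids[i] for i, _ in spec.planted}


def multiclass_study_spec(
    effect: float = 3.0,
    n_planted: int = 5,
    noise_sd: float = 1.0,
    batch_sd: float = 0.5,
    seed: int = 0,
    n_features: int = PANEL_SIZE,
    planted_indices: Sequence[int] | None = None,
) -> SyntheticSpec:
    """The multi-class benchmark design: 845 samples over 16 study batches,
    10 tumor classes, 253 panel features, ``n_planted`` informative features
    with signed-code ``±effect`` sigma class shifts.
    """
    samples_per_class = [0] * 10
    for size, c in MULTICLASS_STUDY_PLAN:
        samples_per_class[c] += size
    if planted_indices is None:
        # spread through the panel rather than bunched at one end
        step = max(1, n_features // (n_planted + 1))
        planted_indices = [step * (j + 1) for j in range(n_planted)]
    shifts = cycle_code_shifts(10, n_planted, effect)
    return SyntheticSpec(
        n_classes=10,
        samples_per_class=tuple(samples_per_class),
        n_features=n_features,
        planted=tuple(
            (idx, tuple(s)) for idx, s in zip(planted_indices, shifts)
        ),
        noise_sd=noise_sd,
        n_batches=len(MULTICLASS_STUDY_PLAN),
        batch_sd=batch_sd,
        seed=seed,
        batch_plan=MULTICLASS_STUDY_PLAN,
    )


def generate_imbalanced_binary(
    n_case: int = IMBALANCED_CASE,
    n_control: int = IMBALANCED_CONTROL,
    n_features: int = PANEL_SIZE,
    planted: Sequence[tuple[int, tuple[float, float]]] = (),
    noise_sd: float = 1.0,
    seed: int = 0,
) -> ExpressionDataset:
    """Two-class dataset with the requested imbalance (labels "case"/"other").

    The default sizes emulate the binary subtype benchmark (139 cases vs. 44
    controls, 183 samples).  Note the majority-class floor any selector must
    beat: a constant predictor scores ``n_case / (n_case + n_control)``.
    """
    if n_case < 2 or n_control < 2:
        raise ValueError("n_case and n_control must both be >= 2")
    spec = SyntheticSpec(
        n_classes=2,
        samples_per_class=(n_case, n_control),
        n_features=n_features,
        planted=tuple((i, tuple(s)) for i, s in planted),
        noise_sd=noise_sd,
        seed=seed,
        class_names=("case", "other"),
    )
    return generate(spec)
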