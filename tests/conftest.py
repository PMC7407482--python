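import numpy as np
import pytest

from refsel.importance import ClassifierSpec, default_specs
from refsel.synthetic import SyntheticSpec, cycle_code_shifts, generate

#: Lightweight hyperparameters used throughout the suite so that the tree
#: ensembles stay cheap while keeping the same extraction code paths.
FAST_TREE_HP = {
    "gradient-boosting": {"n_estimators": 10},
    "random-forest": {"n_estimators": 10},
    "bagging": {"n_estimators": 10},
}


def planted_spec(
    n_classes: int = 4,
    per_class: int = 20,
    n_features: int = 12,
    n_planted: int = 2,
    effect: float = 3.0,
    seed: int = 1,
    **kwargs,
) -> SyntheticSpec:
    """Small dataset spec with signed-code planted features for quick tests."""
    shifts = cycle_code_shifts(n_classes, n_planted, effect)
    step = max(1, n_features // (n_planted + 1))
    planted = tuple(
        (step * (j + 1), tuple(s)) for j, s in enumerate(shifts)
    )
    return SyntheticSpec(
        n_classes=n_classes,
        samples_per_class=(per_class,) * n_classes,
        n_features=n_features,
        planted=planted,
        seed=seed,
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_planted_ds():
    """80 samples, 12 features, 4 classes, 2 strongly planted features."""
    return generate(planted_spec())


@pytest.fixture(scope="session")
def fast_specs():
    """Two cheap, deterministic families for selector-level tests."""
    return [
        ClassifierSpec("ridge"),
        ClassifierSpec("logistic-regression"),
    ]


@pytest.fixture(scope="session")
def all_family_specs():
    """All eight families with small tree ensembles."""
    return default_specs(n_estimators=10)
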