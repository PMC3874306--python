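"""Connects GA individuals to one-vs-rest SVM evaluation.

Two fitness variants are supported: the summed per-class training MSE
alone (``mse_train``) or that plus the summed MSE on the test partition
(``mse_train_plus_test``).  Lower is better; both are deterministic for a
fixed seed and parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError, DataError, SpecselError
from .ga_engine import Individual
from .spectral_data import SampleSet, project_variables
from .svm_core import (
    OvrModel,
    SvmParams,
    count_strict_errors,
    summed_train_mse,
    train_ovr,
)

VARIANTS = ("mse_train", "mse_train_plus_test")


@dataclass(frozen=True)
class FitnessSpec:
    variant: str
    svm_params: SvmParams
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigError(
                f"unknown fitness variant {self.variant!r}; expected {VARIANTS}"
            )


def _train_projected(
    ind: Individual, train: SampleSet, spec: FitnessSpec
) -> tuple[OvrModel, SampleSet]:
    proj_train = project_variables(train, ind)
    present = set(proj_train.labels)
    for c in proj_train.class_levels:
        if c not in present:
            raise DataError(f"class {c!r} missing from the training partition")
    model = train_ovr(proj_train, spec.svm_params, rng_seed=spec.rng_seed)
    return model, proj_train


def evaluate_fitness(
    ind: Individual, train: SampleSet, test: SampleSet, spec: FitnessSpec
) -> float:
    """Project both partitions onto the individual's variables, train a
    one-vs-rest model on the projected training set, and sum the per-class
    binary MSEs (training only, or training + test per the variant)."""
    if spec.variant == "mse_train_plus_test" and len(test) == 0:
        raise ConfigError("mse_train_plus_test requires a non-empty test partition")
    try:
        model, proj_train = _train_projected(ind, train, spec)
        fitness = summed_train_mse(model, proj_train)
        if spec.variant == "mse_train_plus_test":
            fitness += summed_train_mse(model, project_variables(test, ind))
    except SpecselError as exc:
        raise type(exc)(f"genes {ind.genes}: {exc}") from exc
    return float(fitness)


class FitnessEvaluator:
    """Caching callable for :func:`evaluate_fitness`.

    The cache is keyed by the sorted gene tuple, so gene order never
    affects the value and re-encountered subsets are not retrained.
    """

    def __init__(self, train: SampleSet, test: SampleSet, spec: FitnessSpec):
        self.train = train
        self.test = test
        self.spec = spec
        self._cache: dict[tuple[int, ...], float] = {}

    def __call__(self, ind: Individual) -> float:
        key = ind.key()
        if key not in self._cache:
            self._cache[key] = evaluate_fitness(
                Individual(key), self.train, self.test, self.spec
            )
        return self._cache[key]

    @property
    def cache_size(self) -> int:
        return len(self._cache)


@dataclass(frozen=True)
class ErrorReport:
    """Strict error counts for one variable subset across the three roles.

    Counts are ``None`` (not-applicable) for empty partitions.
    """

    genes: tuple[int, ...]
    train_errors: int | None
    test_errors: int | None
    commercial_errors: int | None
    train_size: int
    test_size: int
    commercial_size: int


def evaluate_report(
    ind: Individual,
    train: SampleSet,
    test: SampleSet,
    commercial: SampleSet,
    spec: FitnessSpec,
) -> ErrorReport:
    """Strict error counts on train / test / commercial for the model
    trained on the projected training partition."""
    model, proj_train = _train_projected(ind, train, spec)

    def _count(part: SampleSet) -> int | None:
        if len(part) == 0:
            return None
        return count_strict_errors(model, project_variables(part, ind))

    return ErrorReport(
        genes=ind.genes,
        train_errors=count_strict_errors(model, proj_train),
        test_errors=_count(test),
        commercial_errors=_count(commercial),
        train_size=len(train),
        test_size=len(test),
        commercial_size=len(commercial),
    )
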