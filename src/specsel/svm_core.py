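"""Soft-margin SVM layer: kernels, binary training, one-vs-rest machinery,
classification MSE, strict error accounting, and the random parameter search.

The quadratic program is solved by libsvm (via scikit-learn's ``SVC``),
which is deterministic for a fixed training set; decision values are then
recomputed here from the stored dual expansion so that the kernel code in
this module is the single source of truth at prediction time.

Features are standardized per variable (training statistics only) before
any kernel evaluation; the standardizer is part of the trained model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVC

from .errors import ConfigError, ConvergenceError, DataError
from .spectral_data import SampleSet

# large C values make libsvm's SMO slow on overlapping data; the cap only
# guards against outright cycling
_MAX_ITER = 100_000_000


# ---------------------------------------------------------------------------
# kernels


@dataclass(frozen=True)
class KernelSpec:
    """One of the three admitted kernels.

    ``sigma`` is the gaussian width (required iff kind == "gaussian");
    ``order`` is the polynomial order (required iff kind == "polynomial").
    """

    kind: str = "gaussian"
    sigma: float | None = None
    order: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "gaussian", "polynomial"):
            raise ConfigError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "gaussian":
            if self.sigma is None or self.sigma <= 0:
                raise ConfigError("gaussian kernel requires sigma > 0")
        elif self.sigma is not None:
            raise ConfigError(f"sigma is only valid for the gaussian kernel")
        if self.kind == "polynomial":
            if self.order is None or int(self.order) < 1:
                raise ConfigError("polynomial kernel requires order >= 1")
        elif self.order is not None:
            raise ConfigError("order is only valid for the polynomial kernel")


def kernel_matrix(spec: KernelSpec, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Gram matrix K[i, j] = K(X[i], Y[j])."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if X.shape[1] != Y.shape[1]:
        raise DataError(
            f"kernel operands differ in length: {X.shape[1]} vs {Y.shape[1]}"
        )
    dots = X @ Y.T
    if spec.kind == "linear":
        return dots
    if spec.kind == "polynomial":
        return (dots + 1.0) ** int(spec.order)
    # gaussian: ||x-y||^2 = ||x||^2 + ||y||^2 - 2<x,y>
    sq = (
        np.sum(X * X, axis=1)[:, None]
        + np.sum(Y * Y, axis=1)[None, :]
        - 2.0 * dots
    )
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-sq / (2.0 * spec.sigma**2))


def kernel_eval(spec: KernelSpec, x: Sequence[float], y: Sequence[float]) -> float:
    """Scalar kernel value for two spectra of equal length."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise DataError(f"kernel operands differ in length: {x.shape} vs {y.shape}")
    return float(kernel_matrix(spec, x[None, :], y[None, :])[0, 0])


# ---------------------------------------------------------------------------
# parameters and models


@dataclass(frozen=True)
class SvmParams:
    """Soft-margin penalty C, optimizer stopping tolerance, and kernel."""

    C: float
    epsilon: float
    kernel: KernelSpec

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ConfigError("C must be positive")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")


@dataclass(frozen=True)
class Standardizer:
    """Per-variable affine map fitted on training data."""

    mean: np.ndarray
    scale: np.ndarray  # std with zeros replaced by 1 (constant columns)

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(mean, scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mean) / self.scale


@dataclass(frozen=True)
class BinaryModel:
    """A trained two-class machine in dual form.

    ``dual_coefficients[i]`` is the product alpha_i * y_i for support
    vector i; the decision value is their kernel expansion plus ``bias``.
    Support vectors are stored in standardized coordinates.
    """

    support_vectors: np.ndarray
    dual_coefficients: np.ndarray
    bias: float
    kernel: KernelSpec
    standardizer: Standardizer
    params: SvmParams
    training_summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.support_vectors) != len(self.dual_coefficients):
            raise DataError("support vectors and dual coefficients mismatch")
        if len(self.support_vectors) < 1:
            raise DataError("model has no support vectors")

    @property
    def n_features(self) -> int:
        return self.support_vectors.shape[1]


@dataclass(frozen=True)
class OvrModel:
    """One binary machine per class (that class = +1, rest = -1)."""

    per_class: dict
    class_levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.per_class) != set(self.class_levels):
            raise DataError("per_class keys must equal class_levels")

    @property
    def n_features(self) -> int:
        return next(iter(self.per_class.values())).n_features


# ---------------------------------------------------------------------------
# training


def _binary_labels(sample_set: SampleSet) -> np.ndarray:
    y = np.empty(len(sample_set))
    for i, s in enumerate(sample_set):
        if s.label in ("+1", "1"):
            y[i] = 1.0
        elif s.label == "-1":
            y[i] = -1.0
        else:
            raise DataError(
                f"binary training expects labels in {{+1,-1}}; got {s.label!r}"
            )
    return y


def _fit_binary(X: np.ndarray, y: np.ndarray, params: SvmParams) -> BinaryModel:
    """Fit one +1/-1 machine on raw features; standardization happens here."""
    if not (np.any(y > 0) and np.any(y < 0)):
        raise DataError("both classes must be present in binary training data")
    std = Standardizer.fit(X)
    Xs = std.transform(X)
    kern = params.kernel
    if kern.kind == "linear":
        svc = SVC(C=params.C, kernel="linear", tol=params.epsilon,
                  max_iter=_MAX_ITER)
    elif kern.kind == "polynomial":
        svc = SVC(C=params.C, kernel="poly", degree=int(kern.order), gamma=1.0,
                  coef0=1.0, tol=params.epsilon, max_iter=_MAX_ITER)
    else:
        svc = SVC(C=params.C, kernel="rbf", gamma=1.0 / (2.0 * kern.sigma**2),
                  tol=params.epsilon, max_iter=_MAX_ITER)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            svc.fit(Xs, y)
        except ConvergenceWarning:
            raise ConvergenceError(
                f"SVM training did not converge within {_MAX_ITER} iterations"
            ) from None
    # classes_ is sorted (-1, +1), so decision_function > 0 predicts +1 and
    # dual_coef_ already carries the alpha_i * y_i signs.
    model = BinaryModel(
        support_vectors=np.array(svc.support_vectors_, dtype=np.float64),
        dual_coefficients=np.array(svc.dual_coef_[0], dtype=np.float64),
        bias=float(svc.intercept_[0]),
        kernel=kern,
        standardizer=std,
        params=params,
        training_summary={},
    )
    f = _decision_values_std(model, Xs)
    miscls = int(np.sum(np.where(f > 0, 1.0, -1.0) != y))
    object.__setattr__(
        model, "training_summary",
        {"train_size": int(len(y)), "misclassified": miscls},
    )
    return model


def train_binary_svm(
    train: SampleSet, params: SvmParams, rng_seed: int = 0
) -> BinaryModel:
    """Train a single soft-margin machine on a set labeled {+1, -1}.

    Deterministic for identical inputs; ``rng_seed`` is accepted for
    interface symmetry (the solver itself has no stochastic component).
    """
    if len(train) == 0:
        raise DataError("empty training set")
    return _fit_binary(train.matrix, _binary_labels(train), params)


def _decision_values_std(model: BinaryModel, Xs: np.ndarray) -> np.ndarray:
    K = kernel_matrix(model.kernel, Xs, model.support_vectors)
    return K @ model.dual_coefficients + model.bias


def decision_values(model: BinaryModel, X: np.ndarray) -> np.ndarray:
    """Vectorized f(x) over the rows of a raw-feature matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.n_features:
        raise DataError(
            f"input has {X.shape[1]} variables; model expects {model.n_features}"
        )
    return _decision_values_std(model, model.standardizer.transform(X))


def decision_value(model: BinaryModel, x: Sequence[float]) -> float:
    """f(x) = sum_i dual_i * K(sv_i, x) + b; its sign is the predicted class."""
    return float(decision_values(model, np.asarray(x, dtype=np.float64)[None, :])[0])


def _sign(values: np.ndarray) -> np.ndarray:
    # f == 0 counts as the negative side so every sample has a definite side
    return np.where(values > 0, 1.0, -1.0)


def classification_mse(model: BinaryModel, eval_set: SampleSet) -> float:
    """Mean over all samples of (f(x) - y)^2 restricted to misclassified ones.

    Correctly-sided samples contribute 0, so the value is 0 exactly when
    every sample lies on its own side of the hyperplane.
    """
    if len(eval_set) == 0:
        raise DataError("classification_mse over an empty set")
    y = _binary_labels(eval_set)
    f = decision_values(model, eval_set.matrix)
    wrong = _sign(f) != y
    residuals = np.where(wrong, f - y, 0.0)
    return float(np.mean(residuals**2))


def _mse_from_values(f: np.ndarray, y: np.ndarray) -> float:
    wrong = _sign(f) != y
    residuals = np.where(wrong, f - y, 0.0)
    return float(np.mean(residuals**2))


def train_ovr(train: SampleSet, params: SvmParams, rng_seed: int = 0) -> OvrModel:
    """Train one binary machine per class (class = +1, rest = -1)."""
    if len(train.class_levels) < 2:
        raise DataError("one-vs-rest training needs at least 2 classes")
    labels = train.labels
    X = train.matrix
    per_class = {}
    for c in train.class_levels:
        y = np.where(labels == c, 1.0, -1.0)
        if not np.any(y > 0):
            raise DataError(f"class {c!r} absent from the training set")
        per_class[c] = _fit_binary(X, y, params)
    return OvrModel(per_class=per_class, class_levels=train.class_levels)


def ovr_decision_values(model: OvrModel, X: np.ndarray) -> np.ndarray:
    """Matrix of decision values, one column per class in class_levels order."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    return np.column_stack(
        [decision_values(model.per_class[c], X) for c in model.class_levels]
    )


def predict_argmax(model: OvrModel, x: Sequence[float]) -> str:
    """Class with the largest decision value; ties go to the earlier class."""
    f = ovr_decision_values(model, np.asarray(x, dtype=np.float64)[None, :])[0]
    return model.class_levels[int(np.argmax(f))]


def count_argmax_errors(model: OvrModel, eval_set: SampleSet) -> int:
    """Errors under the largest-decision-value rule (companion diagnostic)."""
    if len(eval_set) == 0:
        raise DataError("error counting over an empty set")
    f = ovr_decision_values(model, eval_set.matrix)
    predicted = np.array(model.class_levels, dtype=object)[np.argmax(f, axis=1)]
    return int(np.sum(predicted != eval_set.labels))


def count_strict_errors(model: OvrModel, eval_set: SampleSet) -> int:
    """Errors under the strict rule: a sample is correct only when EVERY
    machine places it on the proper side (+1 for its own class, -1 for all
    others)."""
    if len(eval_set) == 0:
        raise DataError("error counting over an empty set")
    f = ovr_decision_values(model, eval_set.matrix)
    signs = _sign(f)
    labels = eval_set.labels
    wanted = np.array(
        [[1.0 if c == lab else -1.0 for c in model.class_levels] for lab in labels]
    )
    correct = np.all(signs == wanted, axis=1)
    return int(np.sum(~correct))


def summed_train_mse(model: OvrModel, sample_set: SampleSet) -> float:
    """Sum over classes of the binary classification MSE on ``sample_set``."""
    if len(sample_set) == 0:
        raise DataError("MSE over an empty set")
    X = sample_set.matrix
    labels = sample_set.labels
    total = 0.0
    for c in model.class_levels:
        y = np.where(labels == c, 1.0, -1.0)
        f = decision_values(model.per_class[c], X)
        total += _mse_from_values(f, y)
    return total


# ---------------------------------------------------------------------------
# random hyperparameter search


@dataclass(frozen=True)
class ParamRanges:
    """Sampling ranges for the random search.

    C and epsilon are drawn log-uniformly from 10^[lo, hi]; sigma is drawn
    uniformly.  Defaults span the magnitudes of the reference settings
    (C around 1e3-1e4, epsilon 1e-6..1e-4, radial width 2..10).
    """

    c_log10: tuple[float, float] = (-1.0, 5.0)
    epsilon_log10: tuple[float, float] = (-7.0, -2.0)
    sigma: tuple[float, float] = (0.5, 20.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("c_log10", self.c_log10),
            ("epsilon_log10", self.epsilon_log10),
            ("sigma", self.sigma),
        ):
            if lo > hi:
                raise ConfigError(f"{name}: min {lo} > max {hi}")
        if self.sigma[0] <= 0:
            raise ConfigError("sigma range must be positive")


def random_parameter_search(
    train: SampleSet,
    n_combinations: int = 100,
    ranges: ParamRanges | None = None,
    rng_seed: int = 0,
) -> list[tuple[SvmParams, float]]:
    """Score ``n_combinations`` random (C, epsilon, sigma) triples.

    Each triple trains a full one-vs-rest model on ``train`` and is scored
    by its summed per-class training MSE.  The list is returned ascending
    by score (draw order breaks ties), deterministically for a fixed seed.
    """
    if n_combinations < 1:
        raise ConfigError("n_combinations must be >= 1")
    ranges = ranges or ParamRanges()
    rng = np.random.default_rng(rng_seed)
    results = []
    for i in range(n_combinations):
        c = 10.0 ** rng.uniform(*ranges.c_log10)
        eps = 10.0 ** rng.uniform(*ranges.epsilon_log10)
        sigma = rng.uniform(*ranges.sigma)
        params = SvmParams(C=c, epsilon=eps, kernel=KernelSpec("gaussian", sigma=sigma))
        model = train_ovr(train, params, rng_seed=rng_seed)
        mse = summed_train_mse(model, train)
        results.append((params, mse, i))
    results.sort(key=lambda t: (t[1], t[2]))
    return [(p, m) for p, m, _ in results]


# ---------------------------------------------------------------------------
# serialization


def _kernel_to_dict(k: KernelSpec) -> dict:
    return {"kind": k.kind, "sigma": k.sigma, "order": k.order}


def _kernel_from_dict(d: dict) -> KernelSpec:
    return KernelSpec(d["kind"], sigma=d["sigma"], order=d["order"])


def binary_model_to_dict(model: BinaryModel) -> dict:
    return {
        "support_vectors": model.support_vectors.tolist(),
        "dual_coefficients": model.dual_coefficients.tolist(),
        "bias": model.bias,
        "kernel": _kernel_to_dict(model.kernel),
        "standardizer": {
            "mean": model.standardizer.mean.tolist(),
            "scale": model.standardizer.scale.tolist(),
        },
        "params": {
            "C": model.params.C,
            "epsilon": model.params.epsilon,
            "kernel": _kernel_to_dict(model.params.kernel),
        },
        "training_summary": model.training_summary,
    }


def binary_model_from_dict(d: dict) -> BinaryModel:
    params = SvmParams(
        C=d["params"]["C"],
        epsilon=d["params"]["epsilon"],
        kernel=_kernel_from_dict(d["params"]["kernel"]),
    )
    return BinaryModel(
        support_vectors=np.array(d["support_vectors"], dtype=np.float64),
        dual_coefficients=np.array(d["dual_coefficients"], dtype=np.float64),
        bias=float(d["bias"]),
        kernel=_kernel_from_dict(d["kernel"]),
        standardizer=Standardizer(
            mean=np.array(d["standardizer"]["mean"], dtype=np.float64),
            scale=np.array(d["standardizer"]["scale"], dtype=np.float64),
        ),
        params=params,
        training_summary=dict(d["training_summary"]),
    )


def save_ovr_model(model: OvrModel, path: str | Path) -> None:
    doc = {
        "class_levels": list(model.class_levels),
        "per_class": {c: binary_model_to_dict(m) for c, m in model.per_class.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def load_ovr_model(path: str | Path) -> OvrModel:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return OvrModel(
        per_class={c: binary_model_from_dict(d) for c, d in doc["per_class"].items()},
        class_levels=tuple(doc["class_levels"]),
    )


def save_search_report(
    results: list[tuple[SvmParams, float]], path: str | Path, seed: int | None = None
) -> None:
    """CSV report (rank, C, epsilon, sigma, mse_train), best first."""
    lines = []
    if seed is not None:
        lines.append(f"# seed: {seed}")
    lines.append("rank,C,epsilon,sigma,mse_train")
    for rank, (params, mse) in enumerate(results, start=1):
        lines.append(
            f"{rank},{params.C:.17g},{params.epsilon:.17g},"
            f"{params.kernel.sigma:.17g},{mse:.17g}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
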