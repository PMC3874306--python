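import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specsel import (
    ConfigError,
    DataError,
    KernelSpec,
    SvmParams,
    classification_mse,
    count_argmax_errors,
    count_strict_errors,
    decision_value,
    from_arrays,
    kernel_eval,
    predict_argmax,
    random_parameter_search,
    train_binary_svm,
    train_ovr,
)
from specsel.svm_core import (
    BinaryModel,
    ParamRanges,
    Standardizer,
    decision_values,
    load_ovr_model,
    ovr_decision_values,
    save_ovr_model,
    summed_train_mse,
)

from conftest import make_blobs_2d, make_multiclass_2d

LINEAR = KernelSpec("linear")
GAUSS2 = KernelSpec("gaussian", sigma=2.0)
POLY2 = KernelSpec("polynomial", order=2)

finite_vec = st.lists(
    st.floats(-50, 50, allow_nan=False), min_size=1, max_size=8
)


def linear_params(C=10_000.0):
    return SvmParams(C=C, epsilon=1e-6, kernel=LINEAR)


def gaussian_params(C=10_000.0, sigma=2.0):
    return SvmParams(C=C, epsilon=1e-6, kernel=KernelSpec("gaussian", sigma=sigma))


class TestKernels:
    def test_linear_dot_product(self):
        assert kernel_eval(LINEAR, [1, 2], [3, 4]) == pytest.approx(11.0, abs=1e-12)

    def test_gaussian_self_is_one(self):
        x = np.array([0.3, -2.0, 5.5])
        assert kernel_eval(GAUSS2, x, x) == pytest.approx(1.0, abs=1e-12)

    def test_polynomial_identity(self):
        assert kernel_eval(POLY2, [1, 0], [1, 0]) == pytest.approx(4.0, abs=1e-12)

    def test_gaussian_closed_form(self):
        x, y = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        expected = np.exp(-2.0 / (2 * 4.0))
        assert kernel_eval(GAUSS2, x, y) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            kernel_eval(LINEAR, [1, 2], [1, 2, 3])

    @settings(max_examples=50, deadline=None)
    @given(finite_vec, st.integers(0, 10_000))
    def test_symmetry_property(self, x, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=len(x))
        for spec in (LINEAR, GAUSS2, POLY2):
            assert kernel_eval(spec, x, y) == pytest.approx(
                kernel_eval(spec, y, x), rel=1e-12, abs=1e-12
            )

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_gaussian_bounds(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=4), rng.normal(size=4)
        k = kernel_eval(GAUSS2, x, y)
        assert 0.0 < k <= 1.0

    def test_spec_validation(self):
        with pytest.raises(ConfigError):
            KernelSpec("gaussian")
        with pytest.raises(ConfigError):
            KernelSpec("gaussian", sigma=-1.0)
        with pytest.raises(ConfigError):
            KernelSpec("polynomial")
        with pytest.raises(ConfigError):
            KernelSpec("linear", sigma=1.0)
        with pytest.raises(ConfigError):
            KernelSpec("sigmoid")


class TestBinaryTraining:
    def test_separable_zero_errors(self, separable_binary):
        model = train_binary_svm(separable_binary, linear_params())
        assert model.training_summary["misclassified"] == 0
        assert classification_mse(model, separable_binary) == 0.0

    def test_determinism_bitwise(self, separable_binary):
        a = train_binary_svm(separable_binary, gaussian_params(), rng_seed=7)
        b = train_binary_svm(separable_binary, gaussian_params(), rng_seed=7)
        np.testing.assert_array_equal(a.dual_coefficients, b.dual_coefficients)
        np.testing.assert_array_equal(a.support_vectors, b.support_vectors)
        assert a.bias == b.bias

    def test_single_class_error(self):
        sset = from_arrays(np.random.default_rng(0).normal(size=(5, 2)),
                           ["+1"] * 5, ["train"] * 5)
        with pytest.raises(DataError, match="both classes"):
            train_binary_svm(sset, linear_params())

    def test_nonbinary_labels_rejected(self):
        sset = from_arrays(np.ones((2, 2)), ["20", "25"], ["train"] * 2)
        with pytest.raises(DataError, match=r"\{\+1,-1\}"):
            train_binary_svm(sset, linear_params())

    def test_c_tradeoff_on_mislabeled_point(self):
        # one flipped label: a huge C must not misclassify more points than
        # a tiny C (penalty monotonicity)
        rng = np.random.default_rng(11)
        X = np.vstack([rng.normal([3, 0], 1.0, (15, 2)),
                       rng.normal([-3, 0], 1.0, (15, 2))])
        labels = ["+1"] * 15 + ["-1"] * 15
        labels[0] = "-1"  # mislabeled deep inside the +1 cluster
        sset = from_arrays(X, labels, ["train"] * 30)
        m_hi = train_binary_svm(sset, gaussian_params(C=1e6, sigma=1.0))
        m_lo = train_binary_svm(sset, gaussian_params(C=1e-3, sigma=1.0))
        assert (m_hi.training_summary["misclassified"]
                <= m_lo.training_summary["misclassified"])

    def test_c_monotonicity_grid(self):
        rng = np.random.default_rng(23)
        X = np.vstack([rng.normal([1.0, 0], 1.2, (20, 2)),
                       rng.normal([-1.0, 0], 1.2, (20, 2))])
        sset = from_arrays(X, ["+1"] * 20 + ["-1"] * 20, ["train"] * 40)
        errors = [
            train_binary_svm(sset, gaussian_params(C=c, sigma=1.0))
            .training_summary["misclassified"]
            for c in (1e-3, 1e-1, 1e1, 1e3, 1e5)
        ]
        assert all(a >= b for a, b in zip(errors, errors[1:]))


class TestDecisionValues:
    def test_interior_point_positive(self, separable_binary):
        model = train_binary_svm(separable_binary, linear_params())
        assert decision_value(model, [10.0, 0.0]) > 0
        assert decision_value(model, [-10.0, 0.0]) < 0

    def test_margin_support_vectors(self, separable_binary):
        # KKT: support vectors with 0 < alpha < C sit on the margin, |f| = 1
        model = train_binary_svm(separable_binary, linear_params(C=10.0))
        free = np.abs(model.dual_coefficients) < 10.0 - 1e-6
        assert free.any()
        raw_svs = (model.support_vectors * model.standardizer.scale
                   + model.standardizer.mean)
        for sv, is_free in zip(raw_svs, free):
            if is_free:
                assert abs(abs(decision_value(model, sv)) - 1.0) < 1e-4

    def test_determinism(self, separable_binary):
        model = train_binary_svm(separable_binary, gaussian_params())
        x = [0.7, -0.3]
        assert decision_value(model, x) == decision_value(model, x)

    def test_dimension_mismatch(self, separable_binary):
        model = train_binary_svm(separable_binary, linear_params())
        with pytest.raises(DataError, match="variables"):
            decision_value(model, [1.0, 2.0, 3.0])


def manual_negation_model():
    """Hand-built linear model with f(x) = -x in one dimension."""
    return BinaryModel(
        support_vectors=np.array([[1.0]]),
        dual_coefficients=np.array([-1.0]),
        bias=0.0,
        kernel=LINEAR,
        standardizer=Standardizer(mean=np.zeros(1), scale=np.ones(1)),
        params=linear_params(),
        training_summary={},
    )


class TestClassificationMse:
    def test_perfect_separation_zero(self, separable_binary):
        model = train_binary_svm(separable_binary, linear_params())
        assert classification_mse(model, separable_binary) == 0.0

    def test_single_misclassified_closed_form(self):
        model = manual_negation_model()
        sset = from_arrays(np.array([[1.0]]), ["+1"], ["train"])
        # f(1) = -1, label +1 -> (-1 - 1)^2 / 1 = 4
        assert classification_mse(model, sset) == pytest.approx(4.0)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(31)
        X = np.vstack([rng.normal([0.8, 0], 1.5, (15, 2)),
                       rng.normal([-0.8, 0], 1.5, (15, 2))])
        sset = from_arrays(X, ["+1"] * 15 + ["-1"] * 15, ["train"] * 30)
        model = train_binary_svm(sset, gaussian_params(C=1.0, sigma=1.0))
        expected = 0.0
        for s in sset:
            f = decision_value(model, s.spectrum)
            y = 1.0 if s.label == "+1" else -1.0
            side = 1.0 if f > 0 else -1.0
            if side != y:
                expected += (f - y) ** 2
        expected /= len(sset)
        assert classification_mse(model, sset) == pytest.approx(expected, rel=1e-12)
        assert expected > 0  # the fixture really is noisy

    def test_empty_set_error(self, separable_binary):
        model = train_binary_svm(separable_binary, linear_params())
        empty = from_arrays(np.empty((0, 2)), [], [], class_levels=["+1", "-1"])
        with pytest.raises(DataError):
            classification_mse(model, empty)

    def test_zero_iff_no_misclassification(self):
        model = manual_negation_model()
        wrong = from_arrays(np.array([[1.0]]), ["+1"], ["train"])
        right = from_arrays(np.array([[1.0]]), ["-1"], ["train"])
        assert classification_mse(model, wrong) > 0
        assert classification_mse(model, right) == 0.0


class TestOneVsRest:
    def test_five_class_model_count(self, high_fixture, reference_params):
        model = train_ovr(high_fixture["train"], reference_params)
        assert len(model.per_class) == 5
        assert model.class_levels == ("20", "25", "50", "70", "100")

    def test_seven_class_model_count(self):
        from specsel import generate_dataset, low_concentration_config, split_by_role
        dataset, _ = generate_dataset(low_concentration_config(seed=3))
        train, _, _ = split_by_role(dataset)
        model = train_ovr(train, gaussian_params(sigma=5.0))
        assert len(model.per_class) == 7

    def test_two_class_symmetry(self, separable_binary):
        model = train_ovr(separable_binary, gaussian_params(sigma=3.0))
        rng = np.random.default_rng(2)
        for x in rng.normal(scale=3.0, size=(10, 2)):
            f_pos = decision_value(model.per_class["+1"], x)
            f_neg = decision_value(model.per_class["-1"], x)
            assert f_pos == pytest.approx(-f_neg, abs=1e-4)

    def test_absent_class_named(self):
        sset = from_arrays(np.random.default_rng(0).normal(size=(4, 2)),
                           ["a", "a", "b", "b"], ["train"] * 4,
                           class_levels=["a", "b", "ghost"])
        with pytest.raises(DataError, match="ghost"):
            train_ovr(sset, linear_params())

    def test_too_few_classes(self):
        sset = from_arrays(np.ones((3, 2)), ["a"] * 3, ["train"] * 3)
        with pytest.raises(DataError, match="2 classes"):
            train_ovr(sset, linear_params())


class TestPredictArgmax:
    def test_interior_points(self, separable_multiclass, reference_params):
        model = train_ovr(separable_multiclass, reference_params)
        for k in range(3):
            theta = 2 * np.pi * k / 3
            x = 10.0 * np.array([np.cos(theta), np.sin(theta)])
            assert predict_argmax(model, x) == f"c{k}"

    def test_tie_breaks_to_first_class(self):
        constant = manual_negation_model()
        from specsel.svm_core import OvrModel
        model = OvrModel(per_class={"a": constant, "b": constant},
                         class_levels=("a", "b"))
        assert predict_argmax(model, [0.5]) == "a"

    def test_argmax_matches_loop_oracle(self, separable_multiclass, reference_params):
        model = train_ovr(separable_multiclass, reference_params)
        rng = np.random.default_rng(9)
        for x in rng.normal(scale=8.0, size=(25, 2)):
            best, best_f = None, -np.inf
            for c in model.class_levels:
                f = decision_value(model.per_class[c], x)
                if f > best_f:
                    best, best_f = c, f
            assert predict_argmax(model, x) == best


class TestStrictErrors:
    def test_separable_zero_strict_errors(self, separable_multiclass, reference_params):
        model = train_ovr(separable_multiclass, reference_params)
        assert count_strict_errors(model, separable_multiclass) == 0

    def test_own_machine_negative_counts_as_error(self):
        from specsel.svm_core import OvrModel
        neg = manual_negation_model()  # f(x) = -x
        model = OvrModel(per_class={"a": neg, "b": neg}, class_levels=("a", "b"))
        sset = from_arrays(np.array([[1.0]]), ["a"], ["train"])
        # machine 'a' says -1 for its own class -> strict error, even though
        # argmax (tie -> first class) is correct
        assert count_argmax_errors(model, sset) == 0
        assert count_strict_errors(model, sset) == 1

    def test_strict_at_least_argmax_random_sets(self, reference_params):
        for seed in range(20):
            sset = make_multiclass_2d(seed=seed, n_classes=3, n_per=8,
                                      separation=3.0, noise=2.0)
            model = train_ovr(sset, gaussian_params(C=10.0, sigma=2.0))
            assert (count_strict_errors(model, sset)
                    >= count_argmax_errors(model, sset))

    def test_empty_set_error(self, separable_multiclass, reference_params):
        model = train_ovr(separable_multiclass, reference_params)
        empty = from_arrays(np.empty((0, 2)), [], [],
                            class_levels=list(separable_multiclass.class_levels))
        with pytest.raises(DataError):
            count_strict_errors(model, empty)


class TestRandomParameterSearch:
    def test_sorted_ascending(self, separable_multiclass):
        results = random_parameter_search(separable_multiclass,
                                          n_combinations=8, rng_seed=0)
        mses = [m for _, m in results]
        assert mses == sorted(mses)
        assert all(mses[0] <= m for m in mses)

    def test_single_combination(self, separable_multiclass):
        results = random_parameter_search(separable_multiclass,
                                          n_combinations=1, rng_seed=0)
        assert len(results) == 1

    def test_separable_top_entry_zero(self, separable_multiclass):
        results = random_parameter_search(separable_multiclass,
                                          n_combinations=15, rng_seed=1)
        assert results[0][1] == 0.0

    def test_determinism(self, separable_multiclass):
        a = random_parameter_search(separable_multiclass, n_combinations=5, rng_seed=4)
        b = random_parameter_search(separable_multiclass, n_combinations=5, rng_seed=4)
        assert [(p.C, p.epsilon, p.kernel.sigma, m) for p, m in a] == \
               [(p.C, p.epsilon, p.kernel.sigma, m) for p, m in b]

    def test_invalid_ranges(self):
        with pytest.raises(ConfigError):
            ParamRanges(c_log10=(5.0, -1.0))
        with pytest.raises(ConfigError):
            ParamRanges(sigma=(-1.0, 2.0))

    def test_invalid_count(self, separable_multiclass):
        with pytest.raises(ConfigError):
            random_parameter_search(separable_multiclass, n_combinations=0)


class TestSerialization:
    def test_ovr_round_trip_exact(self, separable_multiclass, reference_params,
                                  tmp_path):
        model = train_ovr(separable_multiclass, reference_params)
        path = tmp_path / "model.json"
        save_ovr_model(model, path)
        loaded = load_ovr_model(path)
        assert loaded.class_levels == model.class_levels
        rng = np.random.default_rng(6)
        X = rng.normal(scale=5.0, size=(10, 2))
        np.testing.assert_array_equal(
            ovr_decision_values(model, X), ovr_decision_values(loaded, X)
        )
        assert summed_train_mse(loaded, separable_multiclass) == \
               summed_train_mse(model, separable_multiclass)
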