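import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpselect import (
    KernelSpec,
    evaluate_accuracy,
    feature_weights,
    gci_select,
    greedy_correlation_filter,
    kernel_value,
    pearson_correlation,
    rfe_rank,
    select_top,
    stratified_split,
    train_svm,
)

from conftest import make_matrix


def two_point_set():
    return make_matrix([[-1.0], [1.0]], [-1, 1])


class TestKernelValue:
    def test_polynomial_degree_two(self):
        k = KernelSpec("polynomial", p=2)
        assert kernel_value(k, [1.0, 1.0], [1.0, 1.0]) == pytest.approx(9.0)  # (2+1)^2

    def test_rbf_zero_distance(self):
        k = KernelSpec("rbf", sigma=2.0)
        assert kernel_value(k, [1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.0)

    def test_rbf_at_two_sigma_squared(self):
        sigma = 1.5
        k = KernelSpec("rbf", sigma=sigma)
        # ||xa - xb||^2 = 2 sigma^2  ->  exp(-1)
        xa = np.array([0.0])
        xb = np.array([np.sqrt(2.0) * sigma])
        assert kernel_value(k, xa, xb) == pytest.approx(np.exp(-1.0))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            kernel_value(KernelSpec("linear"), [1.0], [1.0, 2.0])

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            KernelSpec("laplacian")


class TestTrainSvm:
    def test_symmetric_margin(self):
        model = train_svm(two_point_set(), KernelSpec("linear"), C=1e6)
        assert model.w[0] == pytest.approx(1.0, abs=1e-6)
        assert model.bias == pytest.approx(0.0, abs=1e-6)
        assert model.support_vectors.shape[0] == 2

    def test_single_class_rejected(self):
        gm = make_matrix([[0.0], [1.0]], [1, 1])
        with pytest.raises(ValueError, match="both classes"):
            train_svm(gm)

    def test_poly_degree_one_matches_linear_accuracy(self, causal_data):
        pair = stratified_split(causal_data, 0.5, seed=0)
        acc_lin = evaluate_accuracy(train_svm(pair.train, KernelSpec("linear")), pair.test)
        acc_poly = evaluate_accuracy(
            train_svm(pair.train, KernelSpec("polynomial", p=1)), pair.test
        )
        assert acc_poly == pytest.approx(acc_lin)

    def test_rbf_wide_sigma_approaches_linear(self):
        data = two_point_set()
        lin = train_svm(data, KernelSpec("linear"), C=1e6)
        rbf = train_svm(data, KernelSpec("rbf", sigma=100.0), C=1e6)
        grid = np.linspace(-1, 1, 9).reshape(-1, 1)
        np.testing.assert_allclose(
            rbf.decision_values(grid), lin.decision_values(grid), atol=1e-3
        )

    def test_linear_decision_matches_primal_form(self, causal_data):
        pair = stratified_split(causal_data, 0.5, seed=1)
        model = train_svm(pair.train, KernelSpec("linear"))
        primal = pair.test.values @ model.w + model.bias
        np.testing.assert_allclose(model.decision_values(pair.test.values), primal, atol=1e-6)


class TestFeatureWeights:
    def test_linear_absolute_w(self):
        gm = make_matrix([[0.0, 0.0], [1.0, -2.0], [0.5, -1.0], [0.1, 0.3]], [-1, 1, 1, -1])
        model = train_svm(gm, KernelSpec("linear"))
        np.testing.assert_allclose(feature_weights(model), np.abs(model.w))

    def test_zero_column_gets_zero_weight(self):
        gm = make_matrix([[0.0, -1.0], [0.0, 1.0], [0.0, 2.0], [0.0, -2.0]], [1, -1, -1, 1])
        w = feature_weights(train_svm(gm, KernelSpec("linear")))
        assert w[0] == pytest.approx(0.0, abs=1e-9)

    def test_nonlinear_matches_bruteforce_dual_sum(self, causal_data):
        model = train_svm(causal_data, KernelSpec("rbf", sigma=3.0))
        # oracle: explicit loop over support vectors, sum alpha_i y_i x_ij
        brute = np.zeros(causal_data.n_snps)
        for coef, sv in zip(model.dual_coef, model.support_vectors):
            brute += coef * sv
        np.testing.assert_allclose(feature_weights(model), np.abs(brute), atol=1e-10)


class TestPearsonCorrelation:
    def test_identity_and_antisymmetry(self):
        x = np.arange(10.0)
        data = np.column_stack([x, -x])
        corr = pearson_correlation(data)
        assert corr[0, 0] == pytest.approx(1.0)
        assert corr[0, 1] == pytest.approx(-1.0)

    def test_textbook_value(self):
        data = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 7.0]])
        corr = pearson_correlation(data)
        # hand computation: cov = 5/ (sqrt(2) * sqrt(114/9)) = 15/sqrt(228)
        expected = 15.0 / np.sqrt(228.0)
        assert corr[0, 1] == pytest.approx(expected, abs=1e-12)
        assert corr[0, 1] == pytest.approx(np.corrcoef(data, rowvar=False)[0, 1])

    def test_constant_column_convention(self):
        data = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        corr = pearson_correlation(data)
        assert corr[0, 1] == 0.0
        assert corr[1, 1] == 1.0


def brute_force_gci(weights, corr, threshold):
    """Independent trace of the 5-step selection: sort, scan, pick, reorder."""
    order = sorted(range(len(weights)), key=lambda j: (-weights[j], j))
    picked = [order[0]]
    for j in order[1:]:
        if abs(corr[j, picked[-1]]) < threshold:
            picked.append(j)
    unpicked = [j for j in order if j not in picked]
    return picked + unpicked, picked


class TestGreedyCorrelationFilter:
    def test_correlated_runnerup_deferred(self):
        # weights g1>g2>g3; g1-g2 correlated above threshold, g3 clean
        weights = np.array([3.0, 2.0, 1.0])
        corr = np.array([[1.0, 0.95, 0.1], [0.95, 1.0, 0.2], [0.1, 0.2, 1.0]])
        adjusted, flags = greedy_correlation_filter(weights, corr, 0.5)
        assert adjusted == [0, 2, 1]
        np.testing.assert_array_equal(flags, [True, True, False])

    def test_threshold_one_picks_everything(self):
        weights = np.array([1.0, 3.0, 2.0])
        corr = np.eye(3)
        adjusted, flags = greedy_correlation_filter(weights, corr, 1.0)
        assert adjusted == [1, 2, 0]
        assert flags.all()

    def test_all_correlated_picks_only_top(self):
        weights = np.array([1.0, 2.0, 3.0])
        corr = np.full((3, 3), 0.99)
        np.fill_diagonal(corr, 1.0)
        adjusted, flags = greedy_correlation_filter(weights, corr, 0.5)
        assert adjusted[0] == 2
        assert flags.sum() == 1

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_matches_bruteforce_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        d = int(rng.integers(2, 12))
        weights = rng.random(d)
        raw = rng.uniform(-1, 1, (d, d))
        corr = (raw + raw.T) / 2
        np.fill_diagonal(corr, 1.0)
        threshold = float(rng.uniform(0.1, 1.0))
        adjusted, flags = greedy_correlation_filter(weights, corr, threshold)
        expected_adjusted, expected_picked = brute_force_gci(weights, corr, threshold)
        assert adjusted == expected_adjusted
        assert [a for a, f in zip(adjusted, flags) if f] == expected_picked
        assert sorted(adjusted) == list(range(d))  # permutation


class TestGciSelect:
    def test_permutation_and_picked_invariant(self, causal_data):
        ranking = gci_select(causal_data, corr_threshold=0.6)
        assert sorted(ranking.snp_ids) == sorted(causal_data.snp_ids)
        corr = pearson_correlation(causal_data.values)
        pos = {sid: j for j, sid in enumerate(causal_data.snp_ids)}
        picked = [sid for sid, f in zip(ranking.snp_ids, ranking.picked) if f]
        for prev, cur in zip(picked, picked[1:]):
            assert abs(corr[pos[cur], pos[prev]]) < 0.6

    def test_duplicate_column_filtered(self, causal_data):
        dup = causal_data.values.copy()
        dup[:, 5] = dup[:, 0]  # exact copy of a causal SNP
        gm = causal_data.with_values(dup, causal_data.snp_ids)
        ranking = gci_select(gm, corr_threshold=0.8)
        picked = {sid for sid, f in zip(ranking.snp_ids, ranking.picked) if f}
        assert not {"X1", "X6"} <= picked  # the two identical columns never both picked

    def test_threshold_validation(self, null_data):
        with pytest.raises(ValueError):
            gci_select(null_data, corr_threshold=0.0)


class TestRfe:
    def test_noise_feature_eliminated_first(self):
        rng = np.random.default_rng(0)
        y = np.repeat([1, -1], 20)
        signal = y + 0.1 * rng.normal(size=40)
        signal2 = y + 0.2 * rng.normal(size=40)
        noise = np.zeros(40)
        gm = make_matrix(np.column_stack([signal, noise, signal2]), y)
        ranking = rfe_rank(gm)
        assert ranking[-1] == "X2"  # zero-weight noise dropped in round one
        assert sorted(ranking) == ["X1", "X2", "X3"]

    def test_agrees_with_gci_on_dominant_snp(self, causal_data):
        # make X1 overwhelmingly dominant by boosting its separation
        vals = causal_data.values.copy()
        vals[:, 0] = causal_data.labels * 2.0
        gm = causal_data.with_values(vals, causal_data.snp_ids).subset_snps(range(8))
        assert rfe_rank(gm)[0] == gci_select(gm).snp_ids[0] == "X1"

    def test_needs_three_features(self):
        gm = make_matrix([[0.0, 1.0], [1.0, 0.0]], [1, -1])
        with pytest.raises(ValueError):
            rfe_rank(gm)


class TestSelectTopEvaluate:
    def test_select_top_bounds(self, null_data):
        ranking = gci_select(null_data)
        with pytest.raises(ValueError):
            select_top(null_data, ranking, 0)
        with pytest.raises(ValueError):
            select_top(null_data, ranking, null_data.n_snps + 1)
        full = select_top(null_data, ranking, null_data.n_snps)
        assert sorted(full.snp_ids) == sorted(null_data.snp_ids)

    def test_select_top_keeps_subjects_and_labels(self, null_data):
        ranking = gci_select(null_data)
        top = select_top(null_data, ranking, 5)
        assert top.n_snps == 5
        assert top.subject_ids == null_data.subject_ids
        np.testing.assert_array_equal(top.labels, null_data.labels)
        assert top.snp_ids == ranking.snp_ids[:5]

    def test_perfect_predictions_score_100(self):
        gm = make_matrix([[-1.0], [-0.5], [0.5], [1.0]], [-1, -1, 1, 1])
        model = train_svm(gm, KernelSpec("linear"), C=100.0)
        assert evaluate_accuracy(model, gm) == pytest.approx(100.0)

    def test_empty_test_set_rejected(self, null_data):
        model = train_svm(null_data)
        empty = null_data.subset_subjects(np.array([], dtype=int))
        with pytest.raises(ValueError, match="empty"):
            evaluate_accuracy(model, empty)
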