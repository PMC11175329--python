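import numpy as np
import pytest

from freezenir.metrics import build_confusion, total_accuracy
from freezenir.simca import (
    MAX_COMPONENTS,
    classify,
    fit_class_pca,
    fit_simca,
    reduced_distance,
    select_k_parsimonious,
)
from freezenir.spectra_io import NO_MATCH, SpectraSet, split_calibration_validation


def brute_force_loo_k(X, max_k):
    """Independent oracle: explicit LOO loop, SVD recomputed per fold,
    leverage-corrected channel-wise prediction error, 1% parsimony rule."""
    n, p = X.shape
    max_k = min(max_k, MAX_COMPONENTS, n - 2, p)
    press = np.zeros(max_k)
    for k in range(1, max_k + 1):
        for i in range(n):
            train = np.delete(X, i, axis=0)
            mean = train.mean(axis=0)
            _, _, vt = np.linalg.svd(train - mean, full_matrices=False)
            V = vt[: min(k, vt.shape[0])].T
            x = X[i] - mean
            e = x - V @ (V.T @ x)
            h = np.sum(V**2, axis=1)
            press[k - 1] += float(np.sum((e / np.maximum(1 - h, 1e-3)) ** 2))
    best = press.min()
    return int(np.flatnonzero(press <= best * 1.01 + 1e-30)[0]) + 1


class TestComponentSelection:
    def test_recovers_rank_two_structure(self, rng):
        V, _ = np.linalg.qr(rng.standard_normal((50, 2)))
        T = rng.standard_normal((20, 2)) * [2.0, 1.0]
        X = 1.0 + T @ V.T + 1e-6 * rng.standard_normal((20, 50))
        assert fit_class_pca(X).k == 2

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_pure_noise_gives_one_component(self, seed):
        # no structure beyond the mean: the PRESS curve is flat-to-rising
        # and the parsimony rule settles on a single component
        noise_rng = np.random.default_rng(seed)
        X = 0.5 + 0.01 * noise_rng.standard_normal((8, 30))
        model = fit_class_pca(X)
        assert model.k == 1
        assert np.all(model.press >= 0.95 * model.press[0])

    def test_never_exceeds_component_cap(self, rng):
        X = rng.standard_normal((40, 60))  # full-rank, structureless
        assert fit_class_pca(X, max_k=40).k <= MAX_COMPONENTS

    @pytest.mark.parametrize("n,p,seed", [(8, 20, 0), (10, 20, 1), (12, 24, 2)])
    def test_matches_brute_force_loo_oracle(self, n, p, seed):
        rng = np.random.default_rng(seed)
        V, _ = np.linalg.qr(rng.standard_normal((p, 3)))
        T = rng.standard_normal((n, 3)) * [3.0, 1.5, 0.7]
        X = T @ V.T + 0.05 * rng.standard_normal((n, p))
        model = fit_class_pca(X)
        assert model.k == brute_force_loo_k(X, MAX_COMPONENTS)

    def test_parsimony_prefers_smaller_k_on_flat_press(self):
        assert select_k_parsimonious(np.array([10.0, 9.95, 9.93, 9.92])) == 1
        assert select_k_parsimonious(np.array([10.0, 5.0, 4.97, 4.99])) == 2

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 4"):
            fit_class_pca(rng.standard_normal((3, 10)))

    def test_zero_variance_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            fit_class_pca(np.ones((6, 10)))


class TestReducedDistance:
    @pytest.fixture
    def model(self, rng):
        V, _ = np.linalg.qr(rng.standard_normal((40, 2)))
        T = rng.standard_normal((30, 2)) * [2.0, 1.0]
        X = 0.8 + T @ V.T + 1e-4 * rng.standard_normal((30, 40))
        return fit_class_pca(X)

    def test_zero_at_class_mean(self, model):
        assert reduced_distance(model, model.mean)[0] == pytest.approx(0.0, abs=1e-8)

    def test_one_score_sd_along_first_loading(self, model):
        c = np.sqrt(model.score_variances[0])
        x = model.mean + c * model.loadings[:, 0]
        f_ratio, t2 = model.statistics(x)
        assert t2[0] == pytest.approx(1.0, abs=1e-8)  # T^2 = 1 by construction
        assert f_ratio[0] == pytest.approx(0.0, abs=1e-6)
        _, t2_crit = model.critical_limits(0.95)
        d = reduced_distance(model, x)
        assert d[0] == pytest.approx(np.sqrt(1.0 / t2_crit), rel=1e-6)

    def test_unit_residual_f_ratio_by_construction(self, model, rng):
        P, k = model.mean.size, model.k
        e = rng.standard_normal(P)
        e -= model.loadings @ (model.loadings.T @ e)  # orthogonal to the model
        e *= np.sqrt(model.residual_variance_s0 * (P - k)) / np.linalg.norm(e)
        f_ratio, t2 = model.statistics(model.mean + e)
        assert f_ratio[0] == pytest.approx(1.0, rel=1e-8)
        assert t2[0] == pytest.approx(0.0, abs=1e-10)

    def test_monotone_in_orthogonal_residual(self, model, rng):
        e = rng.standard_normal(model.mean.size)
        e -= model.loadings @ (model.loadings.T @ e)
        e /= np.linalg.norm(e)
        scales = [0.0, 0.1, 0.5, 1.0, 5.0]
        dists = [reduced_distance(model, model.mean + s * e)[0] for s in scales]
        assert all(b >= a for a, b in zip(dists, dists[1:]))

    def test_invariant_under_calibration_row_permutation(self, rng):
        V, _ = np.linalg.qr(rng.standard_normal((30, 2)))
        X = rng.standard_normal((16, 2)) @ V.T + 0.01 * rng.standard_normal((16, 30))
        probe = rng.standard_normal(30)
        m1 = fit_class_pca(X)
        m2 = fit_class_pca(X[rng.permutation(16)])
        assert m1.k == m2.k
        assert reduced_distance(m1, probe)[0] == pytest.approx(
            reduced_distance(m2, probe)[0], rel=1e-8
        )


class TestClassify:
    def test_calibration_members_mostly_accepted_at_095(self, default_medium):
        model = fit_simca(default_medium)
        result = classify(model, default_medium)
        labels = np.asarray(default_medium.labels)
        for cls in model.classes:
            members = np.flatnonzero(labels == cls)
            rate = np.mean([cls in result.accepted[i] for i in members])
            # threshold semantics: ~95% of genuine members accepted, judged
            # with binomial slack at n=60
            assert rate >= 0.88

    def test_constructed_outlier_rejected(self, default_medium, rng):
        model = fit_simca(default_medium)
        from freezenir.preprocess import second_derivative

        work = second_derivative(default_medium, model.pretreatment)
        cm = model.class_models["fresh"]
        e = rng.standard_normal(cm.mean.size)
        e -= cm.loadings @ (cm.loadings.T @ e)
        e *= 10 * np.sqrt(cm.resid_sq_mean) / np.linalg.norm(e)
        outlier = work.subset([0]).with_absorbance(work.absorbance[:1] + e)
        result = classify(model, outlier, pretreated=True)
        assert result.assigned == [NO_MATCH]

    def test_default_scenario_holdout_accuracy(self, default_medium):
        split = split_calibration_validation(default_medium, 2 / 3, seed=1)
        model = fit_simca(split.calibration)
        result = classify(model, split.validation)
        table = build_confusion(split.validation.labels, result)
        assert total_accuracy(table) >= 95.0

    def test_threshold_limits(self, default_medium):
        sub = default_medium.subset(range(0, 180, 2))  # 30/class for speed
        labels = np.asarray(sub.labels)
        near_one = fit_simca(sub, probability_threshold=0.999)
        res = classify(near_one, sub)
        assert all(l in acc for l, acc in zip(labels, res.accepted))
        near_zero = fit_simca(sub, probability_threshold=0.001)
        res = classify(near_zero, sub)
        rejected = sum(a == NO_MATCH for a in res.assigned)
        assert rejected >= 0.85 * sub.n_samples
        vanishing = fit_simca(sub, probability_threshold=1e-6)
        res = classify(vanishing, sub)
        assert all(a == NO_MATCH for a in res.assigned)

    def test_grid_mismatch_rejected(self, default_medium):
        model = fit_simca(default_medium)
        other = SpectraSet(
            np.linspace(900, 1700, 64),
            np.ones((1, 64)),
            ["x"],
        )
        with pytest.raises(ValueError, match="grid"):
            classify(model, other)

    def test_sklearn_pca_agrees_on_loadings_subspace(self, rng):
        """Cross-check: class PCA spans the same subspace as scikit-learn."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        V, _ = np.linalg.qr(rng.standard_normal((30, 3)))
        X = rng.standard_normal((25, 3)) @ V.T + 0.01 * rng.standard_normal((25, 30))
        model = fit_class_pca(X)
        ref = sklearn.PCA(n_components=model.k).fit(X)
        # projection matrices agree even if individual vectors flip sign
        P_ours = model.loadings @ model.loadings.T
        P_ref = ref.components_.T @ ref.components_
        assert np.allclose(P_ours, P_ref, atol=1e-6)
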