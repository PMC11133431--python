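import numpy as np
import pytest

import parcelcorr as pc
from parcelcorr.pls import (AnnotationMatrix, _pls_core, _zscore,
                            bootstrap_ratios, component_significance,
                            fit_pls, gene_score_map, select_features,
                            variance_explained)
from parcelcorr.spin import SpinNullEnsemble


def _annot(parc, values, source="gene"):
    ids = tuple(f"g{i:03d}" for i in range(values.shape[1]))
    return AnnotationMatrix(parc, ids, values, source=source)


def test_constant_columns_dropped_with_logged_names(parc31, caplog):
    rng = np.random.default_rng(1)
    values = rng.standard_normal((31, 5))
    values[:, 2] = 7.0
    with caplog.at_level("INFO"):
        annot = _annot(parc31, values)
    assert annot.n_features == 4
    assert "g002" in caplog.text


def test_single_column_equal_to_response_gives_perfect_component(parc31):
    y = pc.make_autocorrelated_map(parc31, 0.4, seed=2)
    annot = _annot(parc31, y.values[:, None])
    model = fit_pls(annot, y, 1)
    c = model.components[0]
    assert c.r_obs == pytest.approx(1.0)
    assert c.variance_explained == pytest.approx(100.0)
    assert np.linalg.norm(c.weights) == pytest.approx(1.0)


def test_first_weights_match_normalized_cross_covariance(parc31, rng):
    # closed-form oracle: for a single response the covariance-maximizing
    # first direction is the normalized cross-covariance vector X^T y
    for trial in range(10):
        X = rng.standard_normal((31, 200))
        yv = rng.standard_normal(31)
        y = pc.ParcelMap(parc31, yv)
        model = fit_pls(_annot(parc31, X), y, 1)
        Xz, yz = _zscore(X), _zscore(yv)
        oracle = Xz.T @ yz
        oracle /= np.linalg.norm(oracle)
        cos = abs(oracle @ model.components[0].weights)
        assert cos > 0.999


def test_matches_sklearn_nipals_weights(parc31, rng):
    from sklearn.cross_decomposition import PLSRegression
    X = rng.standard_normal((31, 40))
    yv = rng.standard_normal(31)
    Xz, yz = _zscore(X), _zscore(yv)
    W, T, cov = _pls_core(Xz, yz, 4)
    sk = PLSRegression(n_components=4, scale=False).fit(Xz, yz)
    for k in range(4):
        cos = abs(sk.x_weights_[:, k] @ W[:, k])
        assert cos == pytest.approx(1.0, abs=1e-8)


def test_captured_covariance_nonincreasing_on_standard_instances(parc31, rng):
    for trial in range(10):
        X = rng.standard_normal((31, 50))
        y = rng.standard_normal(31)
        _, _, cov = _pls_core(_zscore(X), _zscore(y), 5)
        assert np.all(np.diff(cov) <= 1e-10)


def test_sign_orientation_r_obs_nonnegative_and_idempotent(parc31, rng):
    X = rng.standard_normal((31, 60))
    y = pc.ParcelMap(parc31, rng.standard_normal(31))
    model = fit_pls(_annot(parc31, X), y, 3)
    for c in model.components:
        assert c.r_obs >= 0
        # re-orienting an oriented component changes nothing
        keep = ~c.scores.missing
        r = np.corrcoef(c.scores.values[keep], y.values[keep])[0, 1]
        assert r == pytest.approx(c.r_obs)


def test_orthogonalized_predictors_give_null_first_component(parc31, rng):
    y = pc.make_autocorrelated_map(parc31, 0.4, seed=3)
    X = rng.standard_normal((31, 80))
    yz = _zscore(y.values)
    X = X - np.outer(yz, yz @ X) / (yz @ yz)   # residualize columns
    model = fit_pls(_annot(parc31, X), y, 2)
    ens = pc.make_spin_ensemble(parc31, 500, seed=4)
    p = component_significance(model, _annot(parc31, X), y, ens)
    assert model.components[0].r_obs < 0.5
    assert p[0] > 0.05


def test_n_components_beyond_rank_errors(parc31, rng):
    X = rng.standard_normal((31, 5))
    y = pc.ParcelMap(parc31, rng.standard_normal(31))
    with pytest.raises(ValueError, match="n_components"):
        fit_pls(_annot(parc31, X), y, 6)


def test_all_missing_response_errors(parc31, rng):
    X = rng.standard_normal((31, 5))
    y = pc.ParcelMap(parc31, np.full(31, np.nan))
    with pytest.raises(ValueError, match="missing"):
        fit_pls(_annot(parc31, X), y, 2)


def test_planted_component_detected_by_spin_test(dkt62):
    # power check: rank-1 planted correspondence with weak noise
    target = pc.make_autocorrelated_map(dkt62, 0.5, seed=5)
    cfg = pc.SynthConfig(seed=6, loading_dist="fixed", loading_sd=2.0,
                         feature_lengthscale=0.0)
    X, _ = pc.make_annotation_matrix(dkt62, target, cfg)
    model = fit_pls(X, target, 5)
    ens = pc.make_spin_ensemble(dkt62, 1000, seed=7)
    p = component_significance(model, X, target, ens)
    assert p[0] <= 0.01


def test_identity_ensemble_gives_p_one_for_all_components(parc31, rng):
    X = rng.standard_normal((31, 40))
    y = pc.ParcelMap(parc31, rng.standard_normal(31))
    annot = _annot(parc31, X)
    model = fit_pls(annot, y, 3)
    ens = SpinNullEnsemble(10, np.tile(np.arange(31), (10, 1)),
                           parcellation=parc31, seed=0)
    p = component_significance(model, annot, y, ens)
    assert (p == 1.0).all()


def test_bootstrap_flags_noiseless_column_as_infinite(parc31):
    y = pc.make_autocorrelated_map(parc31, 0.4, seed=8)
    annot = _annot(parc31, y.values[:, None])
    model = fit_pls(annot, y, 1)
    br = bootstrap_ratios(annot, y, model, n_boot=150, seed=9)
    assert np.isinf(br[0, 0])
    assert model.components[0].br_infinite[0]


def test_bootstrap_requires_at_least_100_resamples(parc31):
    y = pc.make_autocorrelated_map(parc31, 0.4, seed=8)
    annot = _annot(parc31, y.values[:, None])
    model = fit_pls(annot, y, 1)
    with pytest.raises(ValueError, match="n_boot"):
        bootstrap_ratios(annot, y, model, n_boot=50, seed=9)


def test_bootstrap_recovery_of_informative_features(parc31):
    # planted equal-SNR loadings, white null columns: reliable features
    # should be flagged and null features largely spared
    target = pc.make_autocorrelated_map(parc31, 0.5, seed=10)
    cfg = pc.SynthConfig(seed=11, n_parcels=31, loading_dist="fixed",
                         feature_lengthscale=0.0)
    X, truth = pc.make_annotation_matrix(parc31, target, cfg)
    model = fit_pls(X, target, 5)
    bootstrap_ratios(X, target, model, n_boot=500, seed=12)
    br1 = np.abs(model.components[0].br)
    info = truth["informative"]
    assert np.mean(br1[info] > 3) >= 0.8
    assert np.mean(br1[~info] > 3) <= 0.05


class TestSelectFeatures:
    def test_threshold_membership(self):
        pos, neg = select_features([3.5, -4.0, 2.9], ("f1", "f2", "f3"))
        assert pos == ("f1",) and neg == ("f2",)

    def test_all_below_threshold_gives_empty_lists(self):
        pos, neg = select_features([1.0, -2.0, 3.0])  # strict inequality
        assert pos == () and neg == ()

    def test_infinite_ratios_included_with_sign(self):
        pos, neg = select_features([np.inf, -np.inf, 0.0], ("a", "b", "c"))
        assert pos == ("a",) and neg == ("b",)

    def test_nonpositive_threshold_errors(self):
        with pytest.raises(ValueError):
            select_features([1.0], threshold=0.0)


class TestScoresAndVariance:
    def test_gene_score_map_matches_response_in_rank_one_case(self, parc31):
        y = pc.make_autocorrelated_map(parc31, 0.4, seed=13)
        model = fit_pls(_annot(parc31, y.values[:, None]), y, 1)
        smap = gene_score_map(model.components[0])
        # equal to y up to positive scaling
        r = np.corrcoef(smap.values, y.values)[0, 1]
        assert r == pytest.approx(1.0)

    def test_score_map_correlates_with_response_at_r_obs(self, parc31, rng):
        X = rng.standard_normal((31, 30))
        y = pc.ParcelMap(parc31, rng.standard_normal(31))
        model = fit_pls(_annot(parc31, X), y, 2)
        for c in model.components:
            r = np.corrcoef(c.scores.values, y.values)[0, 1]
            assert r == pytest.approx(c.r_obs, rel=1e-10)

    def test_left_only_parcellation_gives_31_value_map(self, parc31, rng):
        X = rng.standard_normal((31, 30))
        y = pc.ParcelMap(parc31, rng.standard_normal(31))
        model = fit_pls(_annot(parc31, X), y, 1)
        smap = gene_score_map(model.components[0])
        assert smap.values.size == 31
        assert set(smap.parcellation.hemispheres) == {"left"}

    def test_eleven_region_annotation_supported(self):
        # emulates sparse developmental-atlas coverage: 11 regions
        parc11 = pc.make_sphere_parcellation(11, seed=14, hemispheres="left")
        rng = np.random.default_rng(15)
        X = rng.standard_normal((11, 50))
        y = pc.ParcelMap(parc11, rng.standard_normal(11))
        model = fit_pls(_annot(parc11, X), y, 5)
        assert model.n_components == 5

    def test_variance_explained_orthogonal_and_identical(self, parc31, rng):
        yv = rng.standard_normal(31)
        y = pc.ParcelMap(parc31, yv)
        assert variance_explained(pc.ParcelMap(parc31, yv.copy()), y) == \
            pytest.approx(100.0)
        # Gram-Schmidt an orthogonal score vector
        z = rng.standard_normal(31)
        yc = yv - yv.mean()
        z = z - z.mean()
        z -= (z @ yc) / (yc @ yc) * yc
        assert variance_explained(pc.ParcelMap(parc31, z), y) == \
            pytest.approx(0.0, abs=1e-10)

    def test_zero_variance_scores_error(self, parc31, rng):
        y = pc.ParcelMap(parc31, rng.standard_normal(31))
        with pytest.raises(ValueError, match="variance"):
            variance_explained(pc.ParcelMap(parc31, np.ones(31)), y)


def test_weight_recovery_against_planted_loadings(parc31):
    # parameter recovery at the equal-SNR design; the achievable correlation
    # is bounded by chance-correlation noise from the null columns
    # (~1/sqrt(30) per feature), so the check is against that realistic level
    target = pc.make_autocorrelated_map(parc31, 0.5, seed=16)
    cfg = pc.SynthConfig(seed=17, n_parcels=31, loading_dist="fixed",
                         feature_lengthscale=0.0)
    X, truth = pc.make_annotation_matrix(parc31, target, cfg)
    model = fit_pls(X, target, 1)
    r = np.corrcoef(model.components[0].weights, truth["loadings"])[0, 1]
    assert r > 0.7
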