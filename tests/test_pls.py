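"""NIPALS PLS1 engine: oracle equivalence, CV, jackknife, Hotelling T2."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ciderdry as cd
from conftest import RECOVERY_EQUATION, random_regression


def ols_oracle(X, y):
    """Independent normal-equations solution on centered data."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    b = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)
    return b, y.mean() - b @ X.mean(axis=0)


class TestFit:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 1))
        y = 3.0 * X[:, 0]
        model = cd.fit_pls1(X, y, 1)
        assert model.b_raw[0] == pytest.approx(3.0)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)
        metrics = cd.cross_validate(X, y, 1, n_segments=5, seed=0).metrics
        assert metrics.r2 == pytest.approx(1.0)
        assert metrics.rmsec < 1e-12

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("autoscale", [True, False])
    def test_full_rank_equals_ols(self, seed, autoscale):
        n, p = 6 + 2 * seed % 14 + 3, 2 + seed % 5
        X, y = random_regression(seed, n=max(n, p + 2), p=p)
        model = cd.fit_pls1(X, y, p, autoscale=autoscale)
        b, intercept = ols_oracle(X, y)
        np.testing.assert_allclose(model.b_raw, b, rtol=1e-8)
        assert model.intercept == pytest.approx(intercept, rel=1e-8, abs=1e-10)
        np.testing.assert_allclose(model.predict(X), X @ b + intercept, rtol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_scores_are_orthogonal(self, seed):
        X, y = random_regression(seed, n=15, p=6)
        model = cd.fit_pls1(X, y, 4)
        G = model.t_scores.T @ model.t_scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() <= 1e-8 * np.abs(np.diag(G)).max()

    def test_prediction_consistent_between_coefficients_and_factors(self):
        X, y = random_regression(7, n=14, p=5)
        model = cd.fit_pls1(X, y, 3)
        # factor expansion: yhat = y_mean + T q
        via_factors = model.y_mean + model.t_scores @ model.q_loadings
        np.testing.assert_allclose(model.predict(X), via_factors, rtol=1e-10)

    def test_feature_names_carried_from_dataframe(self):
        X, y = random_regression(1, n=10, p=3)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        model = cd.fit_pls1(df, y, 2)
        assert model.feature_names == ("a", "b", "c")

    def test_zero_variance_column_is_named(self):
        X, y = random_regression(2, n=10, p=3)
        X[:, 1] = 5.0
        df = pd.DataFrame(X, columns=["a", "const", "c"])
        with pytest.raises(ValueError, match="const"):
            cd.fit_pls1(df, y, 2)

    def test_rank_deficiency_stops_extraction_with_error(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 3))
        X = np.hstack([X, X[:, :1]])  # duplicated column, rank 3
        y = rng.normal(size=12)
        with pytest.raises(ValueError):
            cd.fit_pls1(X, y, 4)
        cd.fit_pls1(X, y, 3)  # extractable depth is fine

    def test_too_many_factors_rejected(self):
        X, y = random_regression(3, n=6, p=10)
        with pytest.raises(ValueError, match="n_factors"):
            cd.fit_pls1(X, y, 6)  # n - 1 = 5 caps the request


class TestExplainedVariance:
    def test_rank_one_chemistry_is_one_factor(self):
        rng = np.random.default_rng(5)
        t = rng.normal(size=20)
        X = np.outer(t, [1.0, -2.0, 0.5])
        y = 2.0 * t
        model = cd.fit_pls1(X, y, 1, autoscale=False)
        evx, evy = cd.explained_variance(model)
        assert evx[0] == pytest.approx(100.0)
        assert evy[0] == pytest.approx(100.0)

    def test_unrelated_response_has_negligible_y_variance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 3))
        y = rng.normal(size=200)
        model = cd.fit_pls1(X, y, 3)
        _, evy = cd.explained_variance(model)
        assert evy.sum() < 10.0

    @pytest.mark.parametrize("seed", range(5))
    def test_variance_shares_are_valid_percentages(self, seed):
        X, y = random_regression(seed, n=16, p=5)
        model = cd.fit_pls1(X, y, 4)
        evx, evy = cd.explained_variance(model)
        for ev in (evx, evy):
            assert (ev >= -1e-10).all()
            assert ev.sum() <= 100.0 + 1e-8
        # cumulative y-variance is non-decreasing by construction
        assert (np.diff(np.cumsum(evy)) >= -1e-10).all()


class TestFactorSelection:
    @pytest.mark.parametrize(
        "curve,expected",
        [
            ([1.0, 1.0, 1.0], 1),                 # flat: no improvement anywhere
            ([1.0, 0.5, 0.499, 0.498], 2),        # plateau after the second factor
            ([3.0, 2.0, 1.0], 3),                 # steep to the end: cap at length
            ([2.0], 1),
        ],
    )
    def test_plateau_rule(self, curve, expected):
        assert cd.select_n_factors(curve, plateau_tol=0.01) == expected

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            cd.select_n_factors([])


class TestCrossValidation:
    def test_same_seed_reproduces_everything(self):
        X, y = random_regression(8, n=20, p=4)
        a = cd.cross_validate(X, y, 2, n_segments=5, seed=42)
        b = cd.cross_validate(X, y, 2, n_segments=5, seed=42)
        assert a.metrics == b.metrics
        for sa, sb in zip(a.segments, b.segments):
            np.testing.assert_array_equal(sa, sb)

    def test_leave_one_out_partition(self):
        X, y = random_regression(9, n=12, p=3)
        result = cd.cross_validate(X, y, 2, n_segments=12, seed=0)
        assert len(result.segments) == 12
        assert all(len(s) == 1 for s in result.segments)

    def test_noiseless_linear_data_has_zero_cv_error(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(30, 3))
        y = X @ [1.0, -2.0, 0.5] + 4.0
        result = cd.cross_validate(X, y, 3, n_segments=10, seed=1)
        assert result.metrics.rmsecv < 1e-6

    def test_sec_exceeds_rmsec_by_the_df_correction(self):
        X, y = random_regression(11, n=25, p=4)
        m = cd.cross_validate(X, y, 2, n_segments=5, seed=3).metrics
        n = 25
        # residual mean is ~0 after centering, so SEC ~= RMSEC * sqrt(n/(n-1))
        assert m.sec == pytest.approx(m.rmsec * np.sqrt(n / (n - 1)), rel=1e-6)
        assert m.sec >= m.rmsec

    def test_segment_bounds_validated(self):
        X, y = random_regression(12, n=10, p=3)
        for bad in (1, 11):
            with pytest.raises(ValueError):
                cd.cross_validate(X, y, 2, n_segments=bad, seed=0)


class TestJackknife:
    def test_zero_variance_submodels_make_nonzero_coefficients_significant(self):
        X, y = random_regression(13, n=15, p=3)
        model = cd.fit_pls1(X, y, 2)
        unc = cd.jackknife_uncertainty(model, [model, model, model])
        assert (unc.standard_error == 0).all()
        assert unc.significant.all() == bool(np.all(model.b_weighted != 0))
        np.testing.assert_array_equal(unc.lower, unc.upper)

    def test_interval_always_brackets_the_point(self):
        X, y = random_regression(14, n=40, p=5)
        result = cd.cross_validate(X, y, 3, n_segments=8, seed=2)
        unc = cd.jackknife_uncertainty(result.model, result.submodels)
        assert (unc.lower <= unc.b_weighted + 1e-12).all()
        assert (unc.upper >= unc.b_weighted - 1e-12).all()

    def test_requires_two_submodels(self):
        X, y = random_regression(15, n=10, p=3)
        model = cd.fit_pls1(X, y, 2)
        with pytest.raises(ValueError):
            cd.jackknife_uncertainty(model, [model])

    def test_screens_signal_from_noise_in_simulation(self):
        """Informative variables keep significance, a pure-noise column loses
        it, across seeded replicates (20-segment CV, n = 60)."""
        reps = 30
        informative = np.zeros(5)
        noise_hits = 0
        for rep in range(reps):
            config = cd.SyntheticConfig(
                n_samples=60, seed=2000 + rep,
                true_equation=RECOVERY_EQUATION, panel_noise_sd=0.5,
            )
            chem = cd.generate_chemistry(config)
            y = cd.generate_panel_scores(chem, config)
            X = chem[list(RECOVERY_EQUATION.variables)].copy()
            X["noise_var"] = np.random.default_rng(9000 + rep).normal(size=len(X))
            result = cd.cross_validate(X, y, 6, n_segments=20, seed=rep)
            unc = cd.jackknife_uncertainty(result.model, result.submodels, alpha=0.05)
            informative += unc.significant[:5]
            noise_hits += unc.significant[5]
        assert (informative / reps >= 0.9).all()
        assert noise_hits / reps <= 0.1


class TestHotelling:
    def test_centroid_scores_flag_nothing(self):
        model = cd.fit_pls1(*random_regression(16, n=12, p=3), n_factors=2)
        model.t_scores = np.zeros_like(model.t_scores)
        report = cd.hotelling_t2(model)
        assert (report.t2 == 0).all()
        assert report.flagged == []

    def test_constructed_outlier_is_flagged(self):
        config = cd.SyntheticConfig(
            n_samples=40, seed=3001, true_equation=RECOVERY_EQUATION,
            panel_noise_sd=0.5, outlier_spec=cd.OutlierSpec(1, 10.0),
        )
        chem, scores, outlier_ids = cd.generate_dataset(config)
        X = chem[[c for c in chem.columns if c != "sample_id"]]
        model = cd.fit_pls1(X, scores, 3, sample_ids=chem["sample_id"])
        report = cd.hotelling_t2(model, alpha=0.05)
        assert outlier_ids[0] in report.flagged
        assert report.sample_ids[int(np.argmax(report.t2))] == outlier_ids[0]

    def test_flagging_invariant_under_sample_relabeling(self):
        X, y = random_regression(17, n=25, p=4)
        model = cd.fit_pls1(X, y, 3)
        base = set(np.flatnonzero(
            cd.hotelling_t2(model).t2 > cd.hotelling_t2(model).critical_value
        ))
        perm = np.random.default_rng(0).permutation(25)
        model_p = cd.fit_pls1(X[perm], y[perm], 3)
        permuted = {int(perm[i]) for i in np.flatnonzero(
            cd.hotelling_t2(model_p).t2 > cd.hotelling_t2(model_p).critical_value
        )}
        assert base == permuted


@pytest.mark.parametrize("seed,n_factors", [(0, 1), (1, 2), (2, 3), (3, 4)])
def test_predictions_match_sklearn_reference(seed, n_factors):
    """Independent cross-check against scikit-learn's PLS implementation."""
    sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
    X, y = random_regression(seed + 50, n=18, p=5)
    mine = cd.fit_pls1(X, y, n_factors)
    ref = sklearn_pls.PLSRegression(n_components=n_factors, scale=True).fit(X, y)
    np.testing.assert_allclose(
        mine.predict(X), ref.predict(X).ravel(), rtol=1e-8, atol=1e-10
    )


@settings(max_examples=20)
@given(
    seed=st.integers(0, 10_000),
    n=st.integers(8, 20),
    p=st.integers(2, 6),
)
def test_pls_never_beats_ols_in_training_fit(seed, n, p):
    """With fewer factors than rank, the training residual can only grow."""
    X, y = random_regression(seed, n=max(n, p + 2), p=p)
    full = cd.fit_pls1(X, y, p)
    partial = cd.fit_pls1(X, y, max(p - 1, 1))
    rss = lambda m: float(np.sum((y - m.predict(X)) ** 2))
    assert rss(partial) >= rss(full) - 1e-8 * max(rss(full), 1.0)
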