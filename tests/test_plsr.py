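"""PLS1 estimator, cross-validated component selection, serialization."""

import numpy as np
import pytest

from leafspec import plsr
from leafspec.plsr import (
    PLSRError,
    PLSRModel,
    cross_validate,
    fit_plsr,
    restrict_band,
    select_ncomp,
)


def latent_data(n=120, p=200, k=3, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    L = rng.standard_normal((k, p))
    S = rng.standard_normal((n, k))
    X = S @ L
    y = S @ rng.standard_normal(k)
    if noise:
        # full-rank X so more than k components stay extractable
        X = X + rng.normal(0, 0.1 * noise, X.shape)
        y = y + rng.normal(0, noise, n)
    return X, y


class TestFit:
    def test_constructed_rank3_target_fits_exactly(self):
        X, y = latent_data(k=3)
        model = fit_plsr(X, y, 3)
        assert model.training_summary["r2_train"] >= 0.999

    def test_centering_consistency(self):
        X, y = latent_data(noise=0.3)
        model = fit_plsr(X, y, 4)
        assert model.predict(X.mean(axis=0)[None, :])[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_order_invariance(self):
        X, y = latent_data(n=40, p=30, noise=0.3)
        rng = np.random.default_rng(1)
        perm = rng.permutation(40)
        m1 = fit_plsr(X, y, 4)
        m2 = fit_plsr(X[perm], y[perm], 4)
        assert np.allclose(m1.coefficients, m2.coefficients, atol=1e-10)

    def test_scale_equivariance(self):
        X, y = latent_data(n=40, p=30, noise=0.3)
        m1 = fit_plsr(X, y, 4)
        m2 = fit_plsr(X, 3.5 * y, 4)
        assert np.allclose(m2.coefficients, 3.5 * m1.coefficients)
        assert m2.intercept == pytest.approx(3.5 * m1.intercept)

    def test_adding_component_never_increases_training_ss(self):
        X, y = latent_data(n=60, p=40, k=6, noise=0.5)
        prev = np.inf
        for k in range(1, 7):
            m = fit_plsr(X, y, k)
            ss = float(np.sum((y - m.predict(X)) ** 2))
            assert ss <= prev + 1e-9
            prev = ss

    def test_degenerate_target_and_rank_errors(self):
        X, _ = latent_data(n=20, p=10)
        with pytest.raises(PLSRError, match="degenerate"):
            fit_plsr(X, np.ones(20), 2)
        with pytest.raises(PLSRError, match="samples"):
            fit_plsr(X, np.arange(20.0), 20)

    def test_full_rank_ols_equivalence_n_gt_p(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 6))
        y = rng.standard_normal(30)
        m = fit_plsr(X, y, 6)
        Xc = X - X.mean(axis=0)
        beta = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        assert np.abs(m.predict(X) - (y.mean() + Xc @ beta)).max() < 1e-8

    def test_matches_sklearn_nipals(self):
        """Independent cross-check: scikit-learn's PLS with scale=False."""
        from sklearn.cross_decomposition import PLSRegression

        X, y = latent_data(n=50, p=40, k=5, noise=0.3, seed=2)
        ours = fit_plsr(X, y, 5)
        theirs = PLSRegression(n_components=5, scale=False).fit(X, y)
        assert np.allclose(ours.coefficients, theirs.coef_.ravel(), atol=1e-8)

    def test_coefficient_and_score_forms_agree(self):
        rng = np.random.default_rng(11)
        X, y = latent_data(n=60, p=50, k=4, noise=0.2, seed=11)
        model = fit_plsr(X, y, 4)
        for _ in range(20):
            Xnew = rng.standard_normal((7, 50))
            assert np.abs(model.predict(Xnew) - model.predict_scores_form(Xnew)).max() < 1e-10


class TestCrossValidation:
    def test_press_identity(self):
        X, y = latent_data(n=60, p=40, noise=0.5)
        cv = cross_validate(X, y, max_k=6, folds=5, seed=0)
        assert np.allclose(cv.press, cv.n * cv.rmsep_cv**2)

    def test_determinism(self):
        X, y = latent_data(n=60, p=40, noise=0.5)
        cv1 = cross_validate(X, y, max_k=6, folds=5, seed=3)
        cv2 = cross_validate(X, y, max_k=6, folds=5, seed=3)
        assert np.array_equal(cv1.rmsep_cv, cv2.rmsep_cv)

    def test_noise_free_rank3_selects_small_k(self):
        X, y = latent_data(n=200, p=300, k=3, seed=5)
        cv = cross_validate(X, y, max_k=10, folds=10, seed=1)
        assert select_ncomp(cv) <= 4

    def test_grouped_folds_keep_groups_together(self):
        X, y = latent_data(n=60, p=20, noise=0.5)
        groups = np.repeat(np.arange(20), 3)
        folds = plsr._make_folds(60, 5, 0, groups)
        for f in folds:
            gset = set(groups[f])
            for other in folds:
                if other is not f:
                    assert gset.isdisjoint(set(groups[other]))

    def test_selection_rules(self):
        from leafspec.plsr import CVResult

        curve = CVResult(
            components=np.arange(1, 10),
            rmsep_cv=np.array([5.0, 3, 2, 1, 2, 3, 4, 1, 2], float),
            press=np.zeros(9),
            n=50,
            rmsep_se=np.full(9, 4.5),
        )
        assert select_ncomp(curve) == 4  # ties (k=4, k=8) break toward smaller k
        assert select_ncomp(curve, one_se_rule=True) == 1  # flat within 1 SE


class TestBandRestriction:
    def test_400_900_gives_501_columns(self):
        grid = np.arange(400, 2401)
        X = np.random.default_rng(0).uniform(0.1, 0.6, (5, grid.size))
        Xr, gr = restrict_band(X, grid, 400, 900)
        assert Xr.shape[1] == 501 and gr[0] == 400 and gr[-1] == 900

    def test_full_band_identity(self):
        grid = np.arange(400, 2401)
        X = np.random.default_rng(0).uniform(0.1, 0.6, (5, grid.size))
        Xr, gr = restrict_band(X, grid, 400, 2400)
        assert np.array_equal(Xr, X) and np.array_equal(gr, grid)

    def test_empty_band(self):
        with pytest.raises(PLSRError):
            restrict_band(np.ones((3, 10)), np.arange(400, 410), 900, 1000)

    def test_visible_signal_survives_restriction(self):
        """Signal confined to 450-700 nm: the restricted-band model loses
        almost nothing relative to full band."""
        rng = np.random.default_rng(8)
        grid = np.arange(400, 2401)
        sig = np.exp(-0.5 * ((grid - 575) / 60.0) ** 2)
        z = rng.standard_normal(150)
        X = 0.4 + 0.05 * np.outer(z, sig) + rng.normal(0, 0.002, (150, grid.size))
        y = 10 + 2 * z + rng.normal(0, 0.05, 150)
        tr, va = slice(0, 100), slice(100, None)

        def val_r2(Xa):
            m = fit_plsr(Xa[tr], y[tr], 3)
            pred = m.predict(Xa[va])
            return float(np.corrcoef(y[va], pred)[0, 1] ** 2)

        full = val_r2(X)
        Xr, _ = restrict_band(X, grid, 400, 900)
        restricted = val_r2(Xr)
        assert abs(full - restricted) < 0.02


class TestSerialization:
    def test_json_round_trip_predictions(self, tmp_path):
        X, y = latent_data(n=40, p=30, noise=0.3)
        grid = np.arange(400, 430)
        m = fit_plsr(X, y, 4, wavelength_grid=grid, trait_name="Narea")
        m.to_json(tmp_path / "m.json")
        back = PLSRModel.from_json(tmp_path / "m.json")
        assert np.allclose(back.predict(X), m.predict(X))
        assert back.trait_name == "Narea" and back.n_components == 4

    def test_coefficient_csv_round_trip(self, tmp_path):
        X, y = latent_data(n=40, p=30, noise=0.3)
        grid = np.arange(400, 430)
        m = fit_plsr(X, y, 4, wavelength_grid=grid, trait_name="LMA")
        m.to_coefficient_csv(tmp_path / "m.csv")
        back = PLSRModel.from_coefficient_csv(tmp_path / "m.csv")
        # centering is folded into the intercept on import
        expect = m.predict(X)
        got = back.intercept + X @ back.coefficients
        assert np.allclose(got, expect - m.intercept + back.intercept)
        assert np.allclose(back.coefficients, m.coefficients)

    def test_sparse_external_coefficient_model(self, tmp_path, small_dataset):
        """A published-style sparse model (22 wavelengths + intercept)
        applied to full-range records yields finite predictions."""
        records, _, _ = small_dataset
        wl = np.linspace(450, 2300, 22).astype(int)
        lines = ["wavelength_nm,coefficient"] + [f"{w},{c:.6f}" for w, c in zip(wl, np.random.default_rng(0).normal(0, 5, 22))]
        path = tmp_path / "external.csv"
        path.write_text("# trait=LMA intercept=60.0 n_components=9\n" + "\n".join(lines) + "\n")
        model = PLSRModel.from_coefficient_csv(path)
        preds = model.predict_records(records[:5])
        assert np.all(np.isfinite(preds))

    def test_grid_mismatch_lists_missing(self, small_dataset):
        records, _, _ = small_dataset
        model = PLSRModel(
            trait_name="x",
            wavelength_grid=np.arange(300, 330),
            coefficients=np.zeros(30),
            intercept=0.0,
            n_components=1,
            x_center=np.zeros(30),
            y_center=0.0,
        )
        with pytest.raises(PLSRError, match="300"):
            model.predict_records(records[:1])
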