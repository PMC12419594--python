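"""MaxEnt core: feature expansion, the L1-penalized Gibbs fit and its KKT
certificate, output transforms, tuning, and k-fold variability."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from musselscape.errors import FitError, NotFittedError
from musselscape.maxent import (
    SpeciesModel,
    TuningResult,
    expand_features,
    fit_maxent,
    kfold_sd,
    penalized_objective,
    tune_beta,
)


def lbfgs_oracle(fp, fb, beta_multiplier):
    """Independent dense-optimizer solution of the same penalized objective.

    Splits lambda = u - v with u, v >= 0 so the L1 term becomes linear and
    the problem is smooth-bounded, then solves with L-BFGS-B.  Shares no code
    with the proximal-gradient path under test.
    """
    n_pres, m = fp.shape
    p_mean = fp.mean(axis=0)
    beta_j = beta_multiplier * fb.std(axis=0) / np.sqrt(n_pres)

    def obj(z):
        u, v = z[:m], z[m:]
        lam = u - v
        a = fb @ lam
        amax = a.max()
        logz = amax + np.log(np.sum(np.exp(a - amax)))
        q = np.exp(a - logz)
        val = logz - lam @ p_mean + beta_j @ (u + v)
        g = q @ fb - p_mean
        return val, np.concatenate([g + beta_j, -g + beta_j])

    res = minimize(
        obj,
        np.zeros(2 * m),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * m),
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    lam = res.x[:m] - res.x[m:]
    return penalized_objective(lam, fp, fb, beta_j)


def random_micro_instance(rng):
    """Presence rows are drawn from the background rows (with a bias toward
    high feature sums), as in real presence/background data; this keeps the
    presence means inside the background hull so the optimum is bounded."""
    n_bg = int(rng.integers(8, 21))
    n_pres = int(rng.integers(3, n_bg - 1))
    m = int(rng.integers(1, 5))
    fb = rng.random((n_bg, m))
    w = np.exp(fb.sum(axis=1))
    idx = rng.choice(n_bg, size=n_pres, replace=False, p=w / w.sum())
    return fb[idx], fb


class TestFeatureExpansion:
    @pytest.fixture
    def table(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "x": rng.normal(size=30),
                "y": rng.normal(size=30),
                "b": rng.integers(0, 2, size=30).astype(float),
            },
            index=[f"c{i}" for i in range(30)],
        )
        return df

    def test_linear_only_gives_one_rescaled_feature(self, table):
        fs = expand_features(
            table[["x"]], table.index, {"x": "continuous"}, classes=("linear",)
        )
        assert len(fs) == 1
        vals = fs.transform(table[["x"]])
        assert vals.min() == 0.0 and vals.max() == 1.0

    def test_linear_quadratic_product_count_for_two_covariates(self, table):
        fs = expand_features(
            table[["x", "y"]],
            table.index,
            {"x": "continuous", "y": "continuous"},
            classes=("linear", "quadratic", "product"),
        )
        assert len(fs) == 5  # 2 linear + 2 quadratic + 1 product

    def test_binary_covariate_gets_categorical_only(self, table):
        fs = expand_features(table[["b"]], table.index, {"b": "binary"})
        assert {f.kind for f in fs.features} == {"categorical"}
        assert len(fs) == 2

    def test_constant_covariate_contributes_nothing(self, table):
        df = table.assign(flat=1.0)
        fs = expand_features(
            df, table.index, {"x": "continuous", "y": "continuous", "b": "binary", "flat": "continuous"}
        )
        assert "flat" in fs.skipped_covariates
        assert all(f.covariate != "flat" for f in fs.features)

    def test_knots_strictly_inside_range(self, table):
        fs = expand_features(
            table[["x"]], table.index, {"x": "continuous"}, classes=("hinge", "threshold"),
            n_knots=10,
        )
        assert all(0.0 < f.knot < 1.0 for f in fs.features)


class TestFit:
    def test_two_atom_closed_form(self):
        # background split evenly over feature values {0,1}, presence mean
        # 0.75, no penalty: matching E_q[f] = e^l/(1+e^l) = 0.75 gives l = ln 3
        fb = np.array([[0.0], [1.0]] * 10)
        fp = np.array([[1.0]] * 3 + [[0.0]])
        fit = fit_maxent(fp, fb, 0.0, kkt_tol=1e-9)
        assert fit.lam[0] == pytest.approx(np.log(3), abs=1e-6)

    def test_empty_features_give_uniform_distribution(self):
        fit = fit_maxent(np.zeros((5, 2)), np.zeros((10, 2)), 1.0)
        assert np.all(fit.lam == 0)
        assert fit.log_normalizer == pytest.approx(np.log(10))
        assert fit.entropy == pytest.approx(np.log(10))

    def test_raw_distribution_sums_to_one_over_background(self):
        rng = np.random.default_rng(1)
        fp, fb = random_micro_instance(rng)
        fit = fit_maxent(fp, fb, 1.0)
        raw = np.exp(fb @ fit.lam - fit.log_normalizer)
        assert raw.sum() == pytest.approx(1.0, abs=1e-10)

    def test_kkt_certificate_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            fp, fb = random_micro_instance(rng)
            for beta in (0.5, 2.0):
                fit = fit_maxent(fp, fb, beta)
                assert fit.kkt_slack <= 1e-4

    def test_objective_matches_dense_optimizer_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            fp, fb = random_micro_instance(rng)
            for beta in (0.0, 1.0):
                fit = fit_maxent(fp, fb, beta, kkt_tol=1e-7)
                assert fit.objective == pytest.approx(
                    lbfgs_oracle(fp, fb, beta), abs=1e-5
                )

    def test_stronger_penalty_shrinks_l1_norm(self):
        rng = np.random.default_rng(4)
        fp, fb = random_micro_instance(rng)
        l1 = {
            b: np.abs(fit_maxent(fp, fb, b).lam).sum() for b in (1.0, 15.0)
        }
        assert l1[15.0] <= l1[1.0] + 1e-8

    def test_zero_presences_is_fit_error(self):
        with pytest.raises(FitError):
            fit_maxent(np.zeros((0, 2)), np.zeros((5, 2)), 1.0)


class TestPredict:
    def _model(self, lam, fs, logz, h):
        return SpeciesModel(
            species_id="s",
            feature_set=fs,
            lam=lam,
            beta_multiplier=1.0,
            log_normalizer=logz,
            entropy=h,
            n_presence=5,
        )

    def test_empty_model_predicts_one_half_logistic(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"x": rng.normal(size=12)}, index=[f"c{i}" for i in range(12)])
        fs = expand_features(df, df.index, {"x": "continuous"}, classes=("linear",))
        n = len(df)
        model = self._model(np.zeros(1), fs, np.log(n), np.log(n))
        preds = model.predict(df, transform="logistic")
        assert np.allclose(preds, 0.5)

    def test_logistic_preserves_raw_ordering(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"x": rng.normal(size=40)}, index=[f"c{i}" for i in range(40)])
        fs = expand_features(df, df.index, {"x": "continuous"}, classes=("linear", "quadratic"))
        fb = fs.transform(df)
        fit = fit_maxent(fb[:10] * 0.9 + 0.05, fb, 1.0)
        model = self._model(fit.lam, fs, fit.log_normalizer, fit.entropy)
        raw = model.predict(df, transform="raw").to_numpy()
        logistic = model.predict(df, transform="logistic").to_numpy()
        cloglog = model.predict(df, transform="cloglog").to_numpy()
        order = np.argsort(raw)
        assert (np.diff(logistic[order]) >= 0).all()
        assert (np.diff(cloglog[order]) >= 0).all()
        assert ((logistic > 0) & (logistic < 1)).all()

    def test_prediction_clamps_outside_background_range(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]}, index=list("abcd"))
        fs = expand_features(df.loc[["a", "b"]], ["a", "b"], {"x": "continuous"}, classes=("linear",))
        vals = fs.transform(df)
        assert vals.max() == 1.0  # c, d clamp to the background max

    def test_unfitted_model_raises(self):
        df = pd.DataFrame({"x": [0.0, 1.0]}, index=["a", "b"])
        fs = expand_features(df, df.index, {"x": "continuous"}, classes=("linear",))
        model = self._model(None, fs, 0.0, 0.0)
        with pytest.raises(NotFittedError):
            model.predict(df)


class TestTuning:
    def test_single_value_grid_is_chosen(self):
        rng = np.random.default_rng(7)
        fp, fb = random_micro_instance(rng)
        result = tune_beta(fp, fb, grid=[3])
        assert result.chosen_beta == 3.0

    def test_separable_data_prefers_weak_penalty(self):
        # presences are the top background points on feature 0: a strong
        # signal that weak regularization should exploit
        rng = np.random.default_rng(8)
        fb = np.column_stack([rng.random(200), rng.random(200)])
        fp = fb[np.argsort(fb[:, 0])[-30:]]
        result = tune_beta(fp, fb, grid=[1, 5, 15])
        assert result.chosen_beta == 1.0

    def test_ties_resolve_to_smallest_beta(self):
        # all-zero features: every fit is the empty model, AUC identical
        fp, fb = np.zeros((4, 2)), np.zeros((10, 2))
        result = tune_beta(fp, fb, grid=[2, 7])
        assert result.chosen_beta == 2.0


class TestKfoldSD:
    def test_identical_folds_give_zero_sd(self):
        rng = np.random.default_rng(9)
        fb = rng.random((30, 2))
        fp = np.tile(rng.random((1, 2)), (6, 1))  # duplicated presences
        sd = kfold_sd(fp, fb, fb, beta_multiplier=1.0, k=3, seed=0)
        assert np.allclose(sd, 0.0, atol=1e-6)

    def test_two_fold_sd_matches_direct_recomputation(self):
        from musselscape.maxent import _transform_scores

        rng = np.random.default_rng(10)
        fb = rng.random((25, 2))
        fp = rng.random((4, 2))
        k, seed = 2, 3
        sd = kfold_sd(fp, fb, fb, 1.0, k=k, seed=seed)
        order = np.random.default_rng(seed).permutation(4)
        folds = np.array_split(order, k)
        preds = []
        for fold in folds:
            keep = np.setdiff1d(order, fold)
            fit = fit_maxent(fp[keep], fb, 1.0)
            preds.append(
                _transform_scores(fb @ fit.lam - fit.log_normalizer, fit.entropy, "logistic")
            )
        assert np.allclose(sd, np.std(preds, axis=0), atol=1e-8)

    def test_sd_nonnegative(self):
        rng = np.random.default_rng(11)
        fb = rng.random((20, 3))
        fp = rng.random((8, 3))
        assert (kfold_sd(fp, fb, fb, 2.0, k=4, seed=1) >= 0).all()

    def test_fewer_presences_than_folds_advises_smaller_k(self):
        with pytest.raises(FitError, match="smaller k"):
            kfold_sd(np.zeros((3, 1)), np.zeros((5, 1)), np.zeros((5, 1)), 1.0, k=10)
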