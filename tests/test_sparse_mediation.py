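import numpy as np
import pandas as pd
import pytest

from triomed import (
    DatasetError,
    classify_multi,
    compare_modules,
    default_lambda_grid,
    filter_strong_effects,
    fit_multi_mediation,
    lambda_path,
    penalty_weight,
)
from triomed.simulate import make_fixture
from triomed.sparse_mediation import MultiMediationFit, _cd_lasso


@pytest.fixture(scope="module")
def sparse_fixture():
    return make_fixture("sparse-mediation-20", seed=3)


def _standardized(ds, truth):
    """The design the solver sees: z-scored exposures and mediator."""
    X = ds.rna[truth.ict_genes].to_numpy()
    X = (X - X.mean(0)) / X.std(0)
    e = ds.adt["PROT1"].to_numpy()
    e = (e - e.mean()) / e.std()
    return X, e, truth.d_latent


class TestPenalty:
    def test_weight_function(self):
        assert penalty_weight(1) == 1.0
        assert penalty_weight(16) == 2.0

    def test_default_grid_spans_printed_range(self):
        g = default_lambda_grid()
        assert g[0] == 0.005 and g[-1] == 0.03 and len(g) == 11
        assert (np.diff(g) > 0).all()

    def test_negative_lambda_rejected(self, sparse_fixture):
        ds, truth = sparse_fixture
        with pytest.raises(DatasetError, match="non-negative"):
            fit_multi_mediation(ds, "PROT1", truth.ict_genes, None, -0.1,
                                outcome=truth.d_latent)


class TestSolver:
    def test_lambda_zero_equals_least_squares(self, sparse_fixture):
        ds, truth = sparse_fixture
        fit = fit_multi_mediation(ds, "PROT1", truth.ict_genes, None, 0.0,
                                  outcome=truth.d_latent, tol=1e-10)
        X, e, d = _standardized(ds, truth)
        n = len(e)
        A = np.column_stack([np.ones(n), X])
        alpha_ols = np.linalg.lstsq(A, e, rcond=None)[0]
        B = np.column_stack([np.ones(n), X, e])
        out_ols = np.linalg.lstsq(B, d, rcond=None)[0]
        np.testing.assert_allclose(fit.alpha, alpha_ols[1:], atol=1e-6)
        np.testing.assert_allclose(fit.delta, out_ols[1:-1], atol=1e-6)
        assert fit.beta == pytest.approx(out_ols[-1], abs=1e-6)

    def test_huge_lambda_zeroes_everything_but_beta(self, sparse_fixture):
        ds, truth = sparse_fixture
        fit = fit_multi_mediation(ds, "PROT1", truth.ict_genes, None, 10.0,
                                  outcome=truth.d_latent)
        assert (fit.alpha == 0).all()
        assert (fit.delta == 0).all()
        # with all exposures dropped, beta is the simple regression slope of
        # the (centered) outcome on the standardized mediator
        X, e, d = _standardized(ds, truth)
        ec, dc = e - e.mean(), d - d.mean()
        assert fit.beta == pytest.approx((ec @ dc) / (ec @ ec), abs=1e-8)

    def test_soft_threshold_closed_form_single_exposure(self):
        rng = np.random.default_rng(0)
        n = 500
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std()          # orthonormalized: x.x/n = 1
        y = 0.3 * x + rng.normal(size=n)
        lam, w = 0.1, 1.3
        _, b, _, conv, _ = _cd_lasso(y, x[:, None], np.array([lam * w]), tol=1e-12)
        z = (x @ (y - y.mean())) / n
        expected = np.sign(z) * max(abs(z) - lam * w, 0.0)
        assert conv
        assert b[0] == pytest.approx(expected, abs=1e-8)

    def test_objective_never_increases(self, sparse_fixture):
        ds, truth = sparse_fixture
        # check_objective asserts monotone decrease inside every sweep
        fit = fit_multi_mediation(ds, "PROT1", truth.ict_genes, None, 0.01,
                                  outcome=truth.d_latent, check_objective=True)
        assert fit.converged

    def test_decoupled_and_joint_paths_agree(self, sparse_fixture):
        ds, truth = sparse_fixture
        kw = dict(outcome=truth.d_latent, tol=1e-12)
        a = fit_multi_mediation(ds, "PROT1", truth.ict_genes, None, 0.012,
                                mode="decoupled", **kw)
        b = fit_multi_mediation(ds, "PROT1", truth.ict_genes, None, 0.012,
                                mode="joint", **kw)
        np.testing.assert_allclose(a.alpha, b.alpha, atol=1e-10)
        np.testing.assert_allclose(a.delta, b.delta, atol=1e-10)
        assert a.beta == pytest.approx(b.beta, abs=1e-10)

    def test_sklearn_lasso_oracle_for_mediator_equation(self, sparse_fixture):
        sklearn = pytest.importorskip("sklearn.linear_model")
        ds, truth = sparse_fixture
        lam = 0.02
        w = penalty_weight(len(truth.ict_genes))
        fit = fit_multi_mediation(ds, "PROT1", truth.ict_genes, None, lam,
                                  outcome=truth.d_latent, tol=1e-10)
        X, e, _ = _standardized(ds, truth)
        ref = sklearn.Lasso(alpha=lam * w, fit_intercept=True, tol=1e-10,
                            max_iter=100_000).fit(X, e)
        np.testing.assert_allclose(fit.alpha, ref.coef_, atol=1e-5)


class TestPath:
    def test_single_point_grid_selected(self, sparse_fixture):
        ds, truth = sparse_fixture
        res = lambda_path(ds, "PROT1", truth.ict_genes, None,
                          grid=[0.02], outcome=truth.d_latent)
        assert res.lambda_star == 0.02
        assert len(res.fits) == 1

    def test_empty_grid_rejected(self, sparse_fixture):
        ds, truth = sparse_fixture
        with pytest.raises(DatasetError, match="empty lambda grid"):
            lambda_path(ds, "PROT1", truth.ict_genes, None, grid=[],
                        outcome=truth.d_latent)

    def test_support_is_monotone_and_contains_truth(self, sparse_fixture):
        ds, truth = sparse_fixture
        res = lambda_path(ds, "PROT1", truth.ict_genes, None,
                          outcome=truth.d_latent)
        ks = [f.k_nonzero for f in res.fits]
        assert all(k2 <= k1 for k1, k2 in zip(ks, ks[1:]))
        selected = set(res.selected.support_alpha) | set(res.selected.support_delta)
        assert {"ICT000", "ICT001", "ICT002"} <= selected

    def test_bic_minimum_attained_at_selection(self, sparse_fixture):
        ds, truth = sparse_fixture
        res = lambda_path(ds, "PROT1", truth.ict_genes, None,
                          outcome=truth.d_latent)
        assert res.bics[res.selected_index] == res.bics.min()


class TestFilterAndClassify:
    def _ptt(self, eta2s):
        return pd.DataFrame({
            "protein": "P", "coding_gene": "G",
            "ict_gene": [f"T{i}" for i in range(len(eta2s))],
            "eta2": eta2s, "is_ptt": True,
        })

    def test_strict_threshold(self):
        out = filter_strong_effects(self._ptt([0.05, 0.11, -0.3]), "P")
        assert out == ["T1", "T2"]

    def test_boundary_value_excluded(self):
        out = filter_strong_effects(self._ptt([0.1, -0.1, 0.100001]), "P")
        assert out == ["T2"]

    def test_zero_threshold_keeps_all(self):
        out = filter_strong_effects(self._ptt([0.01, -0.02]), "P", threshold=0.0)
        assert out == ["T0", "T1"]

    def test_missing_protein_is_error(self):
        with pytest.raises(DatasetError, match="no PTT rows"):
            filter_strong_effects(self._ptt([0.5]), "OTHER")

    @pytest.mark.parametrize("alpha,delta,beta,expected", [
        (0.3, 0.0, 0.5, "full"),
        (0.3, -0.1, 0.5, "partial"),
        (0.0, 0.2, 0.5, "null"),
        (0.0, 0.0, 0.5, "dropped"),
        (0.3, 0.0, 0.0, "dropped"),   # beta = 0 kills the indirect path
    ])
    def test_classify_rules(self, alpha, delta, beta, expected):
        fit = MultiMediationFit(
            exposures=["T"], phi0=0.0, omega0=0.0,
            alpha=np.array([alpha]), delta=np.array([delta]), beta=beta,
            lam=0.01, weight=1.0, rss_mediator=1.0, rss_outcome=1.0,
            n=10, converged=True, n_sweeps=1,
        )
        assert classify_multi(fit)["class"].iloc[0] == expected


class TestCompareModules:
    def _m2(self, classes):
        return pd.DataFrame({
            "ict_gene": [f"T{i}" for i in range(len(classes))],
            "class": classes,
            "indirect": np.linspace(0.1, 0.3, len(classes)),
            "delta": np.linspace(-0.2, 0.2, len(classes)),
        })

    def _m3(self, classes):
        return pd.DataFrame({
            "ict_gene": [f"T{i}" for i in range(len(classes))],
            "class": classes,
        })

    def test_identical_classifications_are_diagonal(self):
        out = compare_modules(self._m2(["full", "partial", "none"]),
                              self._m3(["full", "partial", "null"]))
        trans = out["transitions"]
        assert trans.loc["full", "full"] == 1
        assert trans.loc["partial", "partial"] == 1
        assert trans.loc["null", "null"] == 1
        assert trans.to_numpy().sum() == 3

    def test_dropped_genes_counted_in_na_column(self):
        out = compare_modules(self._m2(["full", "partial"]),
                              self._m3(["dropped", "partial"]))
        assert out["transitions"].loc["full", "NA"] == 1
        assert out["effect_sizes"].loc["dropped", "n"] == 1

    def test_disjoint_keys_is_error(self):
        m3 = self._m3(["full"])
        m3["ict_gene"] = ["OTHER"]
        with pytest.raises(DatasetError, match="no shared"):
            compare_modules(self._m2(["full"]), m3)
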