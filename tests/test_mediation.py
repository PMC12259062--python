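import numpy as np
import pandas as pd
import pytest

from triomed import (
    DatasetError,
    MediationFit,
    SimConfig,
    classify_mediation,
    fit_single_mediation,
    scan_mediation,
    simulate_citeseq,
)

TRIO = ("PROT1", "CODG1", "ICT000")


def _binary_sim(seed=0, **kw):
    defaults = dict(n_samples={"healthy": 3, "severe": 3}, cells_per_sample=80,
                    n_ict=3, n_background=2, seed=seed)
    defaults.update(kw)
    return simulate_citeseq(SimConfig(**defaults))


def _latent_sim(seed=0, **kw):
    defaults = dict(n_samples={"healthy": 4, "severe": 4}, cells_per_sample=125,
                    n_ict=3, n_background=2, outcome_mode="continuous_latent",
                    seed=seed)
    defaults.update(kw)
    return simulate_citeseq(SimConfig(**defaults))


class TestDecomposition:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_total_effect_equals_single_regression_slope(self, seed):
        """Linear-mediation identity: the slope of OLS(D ~ X_t) equals
        delta + alpha*beta on any dataset without covariates."""
        ds, truth = _latent_sim(seed=seed, eta2=[0.5, 0, 0], delta=[0.3, 0, 0],
                                beta=0.4)
        fit = fit_single_mediation(ds, TRIO, outcome=truth.d_latent)
        x = ds.rna["ICT000"].to_numpy()
        X = np.column_stack([np.ones_like(x), x])
        slope = np.linalg.lstsq(X, truth.d_latent, rcond=None)[0][1]
        assert fit.total == pytest.approx(slope, abs=1e-8)
        assert fit.total == fit.delta + fit.indirect  # exact by construction

    def test_recovers_planted_coefficients(self):
        ds, truth = _latent_sim(seed=9, n_samples={"healthy": 4, "severe": 4},
                                cells_per_sample=200, eta2=[0.5, 0, 0],
                                delta=[0.0, 0, 0], beta=0.4, sigma_u=0.0)
        fit = fit_single_mediation(ds, TRIO, outcome=truth.d_latent)
        assert fit.alpha == pytest.approx(0.5, abs=3 * fit.se_alpha)
        assert fit.beta == pytest.approx(0.4, abs=3 * fit.se_beta)
        assert abs(fit.delta) < 3 * fit.se_delta
        assert fit.indirect == pytest.approx(0.2, abs=0.06)

    def test_null_indirect_rarely_flagged(self):
        """With alpha = 0 planted, |indirect| should stay within 3 Sobel SEs."""
        hits = 0
        reps = 40
        for seed in range(reps):
            ds, truth = _latent_sim(seed=seed, eta2=[0.0, 0, 0],
                                    delta=[0.3, 0, 0], beta=0.4,
                                    cells_per_sample=60)
            fit = fit_single_mediation(ds, TRIO, outcome=truth.d_latent)
            if abs(fit.indirect) > 3 * fit.se_indirect:
                hits += 1
        assert hits <= 2

    def test_sign_flip_of_exposure_leaves_indirect_and_total_invariant(self):
        ds, truth = _latent_sim(seed=4, eta2=[0.5, 0, 0], delta=[0.2, 0, 0],
                                beta=0.4)
        fit = fit_single_mediation(ds, TRIO, outcome=truth.d_latent)
        flipped = ds.subset_cells(np.ones(ds.n_cells, dtype=bool))
        flipped.rna["ICT000"] = -flipped.rna["ICT000"]
        fit2 = fit_single_mediation(flipped, TRIO, outcome=truth.d_latent)
        # relabeling the exposure axis flips alpha and delta while beta is
        # untouched, so indirect and total flip sign with unchanged magnitude
        # (the flipped model describes the same joint distribution)
        assert fit2.alpha == pytest.approx(-fit.alpha, abs=1e-10)
        assert fit2.delta == pytest.approx(-fit.delta, abs=1e-10)
        assert fit2.beta == pytest.approx(fit.beta, abs=1e-10)
        assert fit2.indirect == pytest.approx(-fit.indirect, abs=1e-10)
        assert fit2.total == pytest.approx(-fit.total, abs=1e-10)
        assert fit2.se_indirect == pytest.approx(fit.se_indirect, abs=1e-10)


class TestBinaryContrast:
    def test_contrast_coding_and_shift_detection(self):
        ds, truth = _binary_sim(seed=8, x_shift=[0.8, 0, 0], eta2=[0.6, 0, 0],
                                cells_per_sample=150)
        fit = fit_single_mediation(ds, TRIO, group_pair=("healthy", "severe"))
        assert fit.contrast == ("healthy", "severe")
        # case group has elevated X -> positive total effect on D
        assert fit.total > 0

    def test_empty_group_is_error(self):
        ds, _ = _binary_sim(seed=1)
        with pytest.raises(DatasetError, match="constant phenotype"):
            fit_single_mediation(ds, TRIO, group_pair=("healthy", "nonexistent"))

    def test_bootstrap_agrees_with_sobel_when_well_powered(self):
        ds, truth = _binary_sim(seed=3, x_shift=[0.8, 0, 0], eta2=[0.8, 0, 0],
                                protein_shift=0.5, cells_per_sample=200)
        sobel = fit_single_mediation(ds, TRIO, group_pair=("healthy", "severe"))
        boot = fit_single_mediation(ds, TRIO, group_pair=("healthy", "severe"),
                                    bootstrap=499, seed=0)
        assert (sobel.p_indirect < 0.05) == (boot.p_indirect < 0.05)


class TestClassification:
    @pytest.mark.parametrize("p_ind,p_dir,expected", [
        (0.01, 0.40, "full"),
        (0.01, 0.01, "partial"),
        (0.40, 0.01, "none"),
        (0.40, 0.40, "not_daICT"),
        (0.049, 0.05, "full"),      # boundary: strict < on both sides
    ])
    def test_rules(self, p_ind, p_dir, expected):
        fit = MediationFit(phi0=0, alpha=1, omega0=0, beta=1, delta=1,
                           indirect=1, total=2, se_alpha=1, se_beta=1,
                           se_delta=1, se_indirect=1, p_indirect=p_ind,
                           p_delta=p_dir, n=100, contrast=("a", "b"))
        assert classify_mediation(fit) == expected


class TestScan:
    def test_empty_ptt_table_gives_empty_output(self):
        ds, _ = _binary_sim(seed=0)
        empty = pd.DataFrame(columns=["protein", "coding_gene", "ict_gene", "is_ptt"])
        out = scan_mediation(ds, empty, ("healthy", "severe"))
        assert len(out) == 0

    def test_planted_mediators_recalled(self):
        ds, truth = _binary_sim(seed=12, n_ict=10, cells_per_sample=100,
                                n_samples={"healthy": 4, "severe": 4},
                                x_shift=[0.8, 0.8, 0.8, 0.8] + [0.0] * 6,
                                eta2=[0.7, 0.7, 0.7, 0.7] + [0.0] * 6)
        ptt = pd.DataFrame({
            "protein": "PROT1", "coding_gene": "CODG1",
            "ict_gene": truth.ict_genes, "is_ptt": True,
        })
        out = scan_mediation(ds, ptt, ("healthy", "severe"))
        planted = out[out.ict_gene.isin(truth.ict_genes[:4])]
        assert planted["is_daict"].sum() >= 3
        # one row per (protein, ICT gene), deduplicated over coding genes
        assert out[["protein", "ict_gene"]].duplicated().sum() == 0
        # BH adjustment can only make calls more conservative
        adj = scan_mediation(ds, ptt, ("healthy", "severe"), adjust="bh")
        assert adj["is_daict"].sum() <= out["is_daict"].sum()
        assert (adj["p_indirect"] >= out["p_indirect"] - 1e-15).all()
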