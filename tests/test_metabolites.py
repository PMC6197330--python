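"""Transforms, interaction models, PCA, and the random-intercept LMM."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import eisakit as ek
from eisakit.metabolites import (
    PanelError,
    estimate_glog_lambda,
    fit_interaction_lm,
    fit_random_intercept_lmm,
    glog,
    lmm_lrt,
    patient_panel_lmm,
    pca_scores,
    transform_panel,
)


class TestTransforms:
    def test_log2_elementwise(self):
        panel = pd.DataFrame([[1.0, 2.0, 4.0]], index=["m"], columns=list("abc"))
        out = transform_panel(panel, "log2")
        assert np.allclose(out.to_numpy(), [[0.0, 1.0, 2.0]])

    def test_log2_rejects_nonpositive_with_hint(self):
        panel = pd.DataFrame([[1.0, 0.0]], index=["m"], columns=list("ab"))
        with pytest.raises(PanelError, match="glog"):
            transform_panel(panel, "log2")

    def test_glog_approaches_log2_for_large_x(self):
        lam = 1.0
        x = np.array([1e4, 1e5, 1e6])
        assert np.allclose(glog(x, lam), np.log2(x), rtol=1e-6)

    def test_glog_monotone(self):
        x = np.linspace(0.0, 100, 500)
        y = glog(x, 3.0)
        assert (np.diff(y) > 0).all()

    def test_glog_stabilizes_variance_of_nb_like_intensities(self):
        rng = np.random.default_rng(12)
        means = np.repeat([10, 20, 40, 80, 100], 40)
        # NB-like: var = mu + 0.2 mu^2
        r = 1 / 0.2
        raw = rng.negative_binomial(r, r / (r + means[:, None]), (len(means), 20)) + 0.0
        panel = pd.DataFrame(raw)
        lam = estimate_glog_lambda(panel)
        trans = transform_panel(panel, "glog", lam=lam)
        raw_sd = panel.std(axis=1).groupby(means).mean()
        glog_sd = trans.std(axis=1).groupby(means).mean()
        assert raw_sd.max() / raw_sd.min() > 5
        assert glog_sd.max() / glog_sd.min() < 3


class TestInteractionLm:
    def _panel(self, cell_means, n=3):
        design = ek.make_metabolite_design(n)
        g = (design.genotype == "mutant").astype(int)
        t = (design.treatment == "DEX").astype(int)
        vals = [cell_means[(gi, ti)] for gi, ti in zip(g, t)]
        panel = pd.DataFrame([vals], index=["m"], columns=design.sample_id)
        return panel, design

    def test_additive_cells_give_zero_interaction(self):
        panel, design = self._panel({(0, 0): 10, (0, 1): 12, (1, 0): 11, (1, 1): 13})
        fit = fit_interaction_lm(panel, design.genotype, design.treatment)
        assert fit.beta_interaction.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert fit.interaction_pvalue.iloc[0] > 0.99

    def test_noiseless_interaction_exact(self):
        panel, design = self._panel({(0, 0): 10, (0, 1): 12, (1, 0): 11, (1, 1): 15})
        fit = fit_interaction_lm(panel, design.genotype, design.treatment)
        assert fit.beta_interaction.iloc[0] == pytest.approx(2.0, abs=1e-12)

    def test_empty_cell_rejected(self):
        design = ek.make_metabolite_design(2)
        keep = ~((design.genotype == "mutant") & (design.treatment == "DEX"))
        panel = pd.DataFrame(
            np.ones((1, keep.sum())), index=["m"],
            columns=design.sample_id[keep],
        )
        with pytest.raises(PanelError, match="cell"):
            fit_interaction_lm(
                panel, design.genotype[keep], design.treatment[keep]
            )

    def test_null_interaction_p_uniform(self):
        design = ek.make_metabolite_design(5)
        truth = ek.make_metabolite_truth(
            [f"m{i}" for i in range(500)], 15, sigma=0.3
        )
        panel = ek.simulate_metabolites(design, truth, 15)
        fits = fit_interaction_lm(
            transform_panel(panel, "log2"), design.genotype, design.treatment
        )
        assert stats.kstest(fits.interaction_pvalue, "uniform").pvalue > 0.01
        typei = (fits.interaction_pvalue < 0.05).mean()
        assert abs(typei - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 500)

    def test_label_swap_flips_interaction_sign(self):
        rng = np.random.default_rng(16)
        design = ek.make_metabolite_design(4)
        panel = pd.DataFrame(
            rng.normal(10, 1, (5, len(design))), columns=design.sample_id
        )
        a = fit_interaction_lm(panel, design.genotype, design.treatment)
        flipped = design.treatment.map({"DEX": "CTR", "CTR": "DEX"})
        b = fit_interaction_lm(panel, design.genotype, flipped)
        assert np.allclose(a.beta_interaction, -b.beta_interaction)


class TestPca:
    def test_two_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(18)
        base = rng.normal(0, 0.1, (20, 10))
        base[:, 5:] += 3.0  # strong one-axis separation
        panel = pd.DataFrame(base)
        out = pca_scores(panel)
        pc1 = out["scores"]["PC1"]
        assert (pc1.iloc[:5] * pc1.iloc[5:].mean() < 0).all()
        assert out["variance_explained"]["PC1"] > 0.9

    def test_rotation_isometry(self):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(8, 6))
        Q, _ = np.linalg.qr(rng.normal(size=(8, 8)))
        a = pca_scores(pd.DataFrame(X))["scores"].to_numpy()
        b = pca_scores(pd.DataFrame(Q @ X))["scores"].to_numpy()
        da = np.linalg.norm(a[:, None, :] - a[None, :, :], axis=2)
        db = np.linalg.norm(b[:, None, :] - b[None, :, :], axis=2)
        assert np.allclose(da, db, atol=1e-8)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(20)
        panel = pd.DataFrame(rng.normal(size=(5, 7)))
        out = pca_scores(panel)
        X = panel.to_numpy().T
        Xc = X - X.mean(axis=0)
        recon = out["scores"].to_numpy() @ out["loadings"].to_numpy().T
        assert np.allclose(recon, Xc, atol=1e-10)

    def test_scores_orthogonal_loadings_orthonormal(self):
        rng = np.random.default_rng(21)
        out = pca_scores(pd.DataFrame(rng.normal(size=(6, 9))))
        S = out["scores"].to_numpy()
        L = out["loadings"].to_numpy()
        assert np.allclose(S.T @ S, np.diag(np.diag(S.T @ S)), atol=1e-8)
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_constant_feature_dropped_when_scaling(self):
        panel = pd.DataFrame(
            [[1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4], [4, 3, 2, 1]]
        )
        out = pca_scores(panel, scale=True)
        assert 0 not in out["loadings"].index


class TestLmm:
    def _simulate(self, n, sigma_b, sigma_e, beta_trt=0.5, seed=0):
        truth = ek.make_patient_truth(
            ["m"], seed, beta_treatment=beta_trt, sigma_b=sigma_b, sigma_e=sigma_e
        )
        return ek.simulate_patients(n, truth, seed)

    def test_boundary_sigma_b_zero(self):
        df = self._simulate(40, sigma_b=0.0, sigma_e=0.5, seed=2)
        fit = fit_random_intercept_lmm(df.value, df.age, df.treatment, df.patient_id)
        total = fit.sigma_b2 + fit.sigma_e2
        assert fit.sigma_b2 / total <= 0.05

    def test_balanced_paired_design_matches_paired_oracle(self):
        df = self._simulate(25, sigma_b=1.0, sigma_e=0.4, seed=3)
        fit = fit_random_intercept_lmm(df.value, df.age, df.treatment, df.patient_id)
        wide = df.pivot_table(index="patient_id", columns="treatment", values="value")
        diff = (wide["Off"] - wide["On"]).to_numpy()
        n = len(diff)
        assert fit.params["treatment"] == pytest.approx(diff.mean(), abs=1e-6)
        # ML variance (1/n) of the within-patient differences
        assert fit.se["treatment"] == pytest.approx(
            np.sqrt(diff.var(ddof=0) / n), abs=1e-6
        )

    def test_variance_components_recovered(self):
        df = self._simulate(200, sigma_b=1.0, sigma_e=0.5, seed=5)
        fit = fit_random_intercept_lmm(df.value, df.age, df.treatment, df.patient_id)
        assert np.sqrt(fit.sigma_b2) == pytest.approx(1.0, rel=0.15)
        assert np.sqrt(fit.sigma_e2) == pytest.approx(0.5, rel=0.15)

    def test_matches_statsmodels_mixedlm_ml(self):
        df = self._simulate(30, sigma_b=0.8, sigma_e=0.3, seed=7)
        fit = fit_random_intercept_lmm(df.value, df.age, df.treatment, df.patient_id)
        import statsmodels.formula.api as smf

        d = df.assign(off=(df.treatment == "Off").astype(float))
        ref = smf.mixedlm("value ~ age + off", d, groups=d.patient_id).fit(reml=False)
        assert fit.params["treatment"] == pytest.approx(ref.params["off"], abs=1e-6)
        assert fit.llf == pytest.approx(ref.llf, abs=1e-5)
        assert fit.sigma_e2 == pytest.approx(ref.scale, rel=1e-4)

    def test_constant_treatment_rejected(self):
        df = self._simulate(10, sigma_b=0.5, sigma_e=0.3, seed=9)
        df["treatment"] = "On"
        with pytest.raises(PanelError, match="confound"):
            fit_random_intercept_lmm(df.value, df.age, df.treatment, df.patient_id)

    def test_llf_at_optimum_beats_ols_boundary(self):
        for seed in range(5):
            df = self._simulate(15, sigma_b=0.9, sigma_e=0.4, seed=seed)
            fit = fit_random_intercept_lmm(
                df.value, df.age, df.treatment, df.patient_id
            )
            from eisakit.metabolites import _lmm_profile

            X = np.column_stack(
                [np.ones(len(df)), df.age, (df.treatment == "Off").astype(float)]
            )
            groups = pd.factorize(df.patient_id)[0]
            _, _, llf0, _ = _lmm_profile(df.value.to_numpy(), X, groups, 0.0)
            assert fit.llf >= llf0 - 1e-10


class TestLmmLrt:
    def test_constant_treatment_effect_zero_stat(self):
        truth = ek.make_patient_truth(["m"], 1, beta_treatment=0.0, sigma_b=0.5,
                                      sigma_e=0.3)
        df = ek.simulate_patients(10, truth, 1)
        full = fit_random_intercept_lmm(df.value, df.age, df.treatment, df.patient_id)
        red = fit_random_intercept_lmm(
            df.value, df.age, df.treatment, df.patient_id, include_treatment=False
        )
        out = lmm_lrt(full, red)
        assert out["stat"] >= 0.0

    def test_null_p_uniform_across_metabolites(self):
        truth = ek.make_patient_truth(
            [f"m{i:03d}" for i in range(300)], 25, beta_treatment=0.0,
            sigma_b=0.5, sigma_e=0.3,
        )
        panel = ek.simulate_patients(8, truth, 25)
        fits = patient_panel_lmm(panel)
        assert stats.kstest(fits.pvalue, "uniform").pvalue > 0.01

    def test_power_at_unit_effect_five_patients(self):
        # beta_treatment = 1*sigma_e with 5 patients x 2 states.  The paired
        # contrast has SE sqrt(2*sigma_e^2/5), i.e. noncentrality z = 1.58,
        # whose large-sample chi2(1) power at alpha=0.05 is ~0.35; require at
        # least that.
        truth = ek.make_patient_truth(
            [f"m{i:03d}" for i in range(500)], 27, beta_treatment=0.3,
            sigma_b=0.5, sigma_e=0.3,
        )
        panel = ek.simulate_patients(5, truth, 27)
        fits = patient_panel_lmm(panel)
        assert (fits.pvalue < 0.05).mean() >= 0.35

    def test_misordered_models_rejected(self):
        truth = ek.make_patient_truth(["m"], 1)
        df = ek.simulate_patients(5, truth, 1)
        full = fit_random_intercept_lmm(df.value, df.age, df.treatment, df.patient_id)
        with pytest.raises(PanelError):
            lmm_lrt(full, full)
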