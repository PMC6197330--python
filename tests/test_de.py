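"""NB-GLM differential expression: oracles, calibration, and recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import eisakit as ek
from eisakit import de
from eisakit.de import (
    DesignError,
    ModelSpec,
    adjust_bh,
    build_model_matrix,
    call_de,
    estimate_dispersions,
    fit_nb_glm,
    lrt,
    nb_loglik,
    size_factors,
    wald_test,
)
from conftest import bh_textbook


class TestModelMatrix:
    def test_interaction_design_columns(self):
        design = ek.make_cross_model_design(1)
        spec = ModelSpec(
            terms=("genotype", "mutated_gene", "time", "genotype:mutated_gene"),
            reduced=("genotype", "mutated_gene", "time"),
            references=(("genotype", "wild_type"), ("mutated_gene", "fdx1b")),
        )
        X = build_model_matrix(design, spec.terms, spec.reference_map)
        assert list(X.columns) == [
            "Intercept",
            "genotype[mutant]",
            "mutated_gene[rx3]",
            "time[ZT13]",
            "genotype[mutant]:mutated_gene[rx3]",
        ]
        assert np.linalg.matrix_rank(X.to_numpy()) == 5

    def test_reduced_not_subset_rejected(self):
        with pytest.raises(DesignError):
            ModelSpec(terms=("a",), reduced=("b",))

    def test_rank_deficiency_detected(self):
        design = pd.DataFrame({"a": ["x", "x", "y", "y"], "b": ["u", "u", "v", "v"]})
        with pytest.raises(DesignError, match="rank"):
            build_model_matrix(design, ("a", "b"))


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        c = pd.DataFrame({"a": [5, 10, 20], "b": [5, 10, 20]})
        assert np.allclose(size_factors(c), 1.0)

    def test_doubled_column_exact_scaling(self):
        c = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = size_factors(c)
        assert np.allclose(sf.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)])

    def test_matches_direct_median_of_ratios(self):
        rng = np.random.default_rng(3)
        c = pd.DataFrame(rng.poisson(50, (200, 4)) + 1)
        sf = size_factors(c).to_numpy()
        # independent direct computation
        logc = np.log(c.to_numpy(float))
        ref = logc.mean(axis=1)
        raw = np.exp(np.median(logc - ref[:, None], axis=0))
        raw = raw / np.exp(np.mean(np.log(raw)))
        assert np.allclose(sf, raw, atol=1e-12)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(4)
        c = pd.DataFrame(rng.poisson(30, (100, 3)) + 1)
        sf1 = size_factors(c)
        sf2 = size_factors(c.sample(frac=1, random_state=0))
        assert np.allclose(sf1, sf2)

    def test_no_common_gene_errors_with_hint(self):
        c = pd.DataFrame({"a": [5, 0], "b": [0, 5]})
        with pytest.raises(DesignError, match="pseudo_reference"):
            size_factors(c)
        assert np.all(size_factors(c, pseudo_reference=True) > 0)


class TestDispersions:
    def _sim(self, alpha, n=10, n_genes=300, mean=200, seed=0):
        rng = np.random.default_rng(seed)
        if alpha == 0:
            mat = rng.poisson(mean, (n_genes, 2 * n))
        else:
            r = 1 / alpha
            mat = rng.negative_binomial(r, r / (r + mean), (n_genes, 2 * n))
        counts = pd.DataFrame(mat)
        cells = pd.Series(["a"] * n + ["b"] * n)
        sf = pd.Series(1.0, index=counts.columns)
        return estimate_dispersions(counts, cells, sf)

    def test_poisson_null_recovery(self):
        disp = self._sim(0.0)
        assert disp["alpha"].median() <= 0.01

    def test_alpha_point1_recovered(self):
        disp = self._sim(0.1)
        assert 0.05 <= disp["alpha"].median() <= 0.2

    def test_constant_counts_shrink_to_trend(self):
        counts = pd.DataFrame(np.full((20, 6), 50))
        cells = pd.Series(["a"] * 3 + ["b"] * 3)
        sf = pd.Series(1.0, index=counts.columns)
        disp = estimate_dispersions(counts, cells, sf)
        assert (disp["alpha_mom"] == 0).all()
        assert (disp["alpha"] >= de.ALPHA_MIN).all()

    def test_all_zero_gene_flagged(self):
        counts = pd.DataFrame(np.vstack([np.zeros(6), np.full(6, 20)]))
        disp = estimate_dispersions(
            counts, pd.Series(["a"] * 3 + ["b"] * 3), pd.Series(1.0, index=range(6))
        )
        assert not disp.loc[0, "usable"] and np.isnan(disp.loc[0, "alpha"])


class TestNbGlm:
    def test_intercept_only_closed_form(self):
        X = pd.DataFrame({"Intercept": np.ones(4)})
        fit = fit_nb_glm([10, 10, 10, 10], X, alpha=0.0)
        assert fit.coef_log2[0] == pytest.approx(np.log2(10), abs=1e-8)
        assert np.allclose(fit.mu, 10)

    def test_two_group_doubling_gives_unit_log2fc(self):
        X = pd.DataFrame({"Intercept": np.ones(6), "grp": [0, 0, 0, 1, 1, 1]})
        fit = fit_nb_glm([10, 10, 10, 20, 20, 20], X, alpha=0.0)
        assert fit.coef_log2[1] == pytest.approx(1.0, abs=1e-8)

    def test_optimality_against_random_perturbations(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(
            {"Intercept": np.ones(8), "x": rng.standard_normal(8)}
        )
        for alpha in (0.0, 0.1):
            y = rng.poisson(20, 8)
            fit = fit_nb_glm(y, X, alpha=alpha)
            for _ in range(100):
                pert = fit.coef + rng.normal(0, 0.05, size=2)
                mu = np.exp(X.to_numpy() @ pert)
                assert nb_loglik(y, mu, alpha) <= fit.llf + 1e-9

    def test_poisson_path_matches_independent_poisson_mle(self):
        # alpha=0 must reduce exactly to a Poisson GLM; refit with a generic
        # optimizer on the Poisson log-likelihood
        rng = np.random.default_rng(13)
        X = pd.DataFrame({"Intercept": np.ones(10), "x": rng.standard_normal(10)})
        y = rng.poisson(15, 10)
        fit = fit_nb_glm(y, X, alpha=0.0)
        Xv = X.to_numpy()

        def nll(b):
            mu = np.exp(Xv @ b)
            return -(y @ np.log(mu) - mu.sum())

        res = optimize.minimize(nll, np.zeros(2), method="BFGS", tol=1e-12)
        assert np.allclose(fit.coef, res.x, atol=1e-6)


class TestLrtWald:
    def _fit_pair(self, y, alpha=0.05):
        rng = np.random.default_rng(0)
        X_full = pd.DataFrame(
            {"Intercept": np.ones(8), "a": [0, 0, 0, 0, 1, 1, 1, 1],
             "b": [0, 0, 1, 1, 0, 0, 1, 1]}
        )
        X_red = X_full[["Intercept", "a"]]
        return (
            fit_nb_glm(y, X_full, alpha=alpha),
            fit_nb_glm(y, X_red, alpha=alpha),
        )

    def test_full_equals_reduced_gives_stat_zero(self):
        X = pd.DataFrame({"Intercept": np.ones(4)})
        f = fit_nb_glm([5, 6, 7, 8], X, alpha=0.1)
        r = lrt(f, f.__class__(**{**f.__dict__, "df_model": 0, "names": []}))
        assert r["stat"] == pytest.approx(0.0, abs=1e-10)
        assert r["pvalue"] == pytest.approx(1.0)

    def test_non_nested_rejected(self):
        X1 = pd.DataFrame({"Intercept": np.ones(4), "a": [0, 1, 0, 1]})
        X2 = pd.DataFrame({"Intercept": np.ones(4), "b": [0, 0, 1, 1]})
        f1 = fit_nb_glm([5, 6, 7, 8], X1, alpha=0.0)
        f2 = fit_nb_glm([5, 6, 7, 8], X2, alpha=0.0)
        with pytest.raises(DesignError):
            lrt(f1, f2)

    def test_lrt_matches_generic_optimizer_refit(self):
        rng = np.random.default_rng(21)
        alpha = 0.05
        r = 1 / alpha
        for _ in range(20):
            mean = rng.uniform(20, 200)
            y = rng.negative_binomial(r, r / (r + mean), 8)
            full, red = self._fit_pair(y, alpha)
            if not (full.converged and red.converged):
                continue
            mine = lrt(full, red)

            def nll(b, X):
                mu = np.exp(X @ b)
                return -nb_loglik(y, mu, alpha)

            stats_ = []
            for Xdf in (
                pd.DataFrame({"i": np.ones(8), "a": [0, 0, 0, 0, 1, 1, 1, 1],
                              "b": [0, 0, 1, 1, 0, 0, 1, 1]}),
                pd.DataFrame({"i": np.ones(8), "a": [0, 0, 0, 0, 1, 1, 1, 1]}),
            ):
                X = Xdf.to_numpy()
                res = optimize.minimize(
                    nll, np.zeros(X.shape[1]), args=(X,), method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
                )
                stats_.append(-res.fun)
            oracle_stat = max(0.0, 2 * (stats_[0] - stats_[1]))
            assert mine["stat"] == pytest.approx(oracle_stat, abs=1e-4)

    def test_wald_zero_coefficient_p_near_one(self):
        X = pd.DataFrame({"Intercept": np.ones(6), "g": [0, 0, 0, 1, 1, 1]})
        fit = fit_nb_glm([10, 10, 10, 10, 10, 10], X, alpha=0.0)
        w = wald_test(fit, "g")
        assert w["log2FC"] == pytest.approx(0.0, abs=1e-6)
        assert w["pvalue"] > 0.99

    def test_null_lrt_p_uniform(self):
        rng = np.random.default_rng(29)
        alpha = 0.05
        r = 1 / alpha
        pvals = []
        X = pd.DataFrame(
            {"Intercept": np.ones(12), "a": [0] * 6 + [1] * 6,
             "b": ([0] * 3 + [1] * 3) * 2}
        )
        for _ in range(400):
            y = rng.negative_binomial(r, r / (r + 100), 12)
            full = fit_nb_glm(y, X, alpha=alpha)
            red = fit_nb_glm(y, X[["Intercept", "a"]], alpha=alpha)
            pvals.append(lrt(full, red)["pvalue"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestBH:
    def test_step_up_definition_example(self):
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_p_unchanged(self):
        assert adjust_bh([0.3])[0] == pytest.approx(0.3)

    def test_matches_textbook_implementation_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = rng.uniform(size=int(rng.integers(1, 60)))
            assert np.allclose(adjust_bh(p), bh_textbook(p), atol=1e-12)

    def test_nan_passthrough_and_range_check(self):
        out = adjust_bh([0.1, np.nan, 0.5])
        assert np.isnan(out[1]) and np.isfinite(out[0])
        with pytest.raises(ValueError):
            adjust_bh([1.5])


class TestCallDe:
    def test_threshold_rules(self):
        res = pd.DataFrame(
            {
                "padj": [0.005, 0.02, 0.005, 0.005],
                "log2FC": [0.30, 2.0, -0.30, 0.1],
            },
            index=["up_ok", "fails_padj", "down_ok", "small_fc"],
        )
        calls = call_de(res, alpha=0.01, lfc_min=0.25)
        assert calls == {"up": ["up_ok"], "down": ["down_ok"]}

    def test_recovery_of_planted_effects(self):
        gene_ids = [f"g{i:04d}" for i in range(300)]
        design = ek.make_rnaseq_design(3)
        truth = ek.make_gene_truth(
            gene_ids, 31, dispersion=0.05, n_txn_up=50, n_txn_down=50,
            base_mean_median=500, base_mean_sigma=0.3,
        )
        counts, _ = ek.simulate_counts(gene_ids, design, truth, 31)
        spec = ModelSpec(terms=("genotype",), references=(("genotype", "wild_type"),))
        res = de.de_table(counts.exonic, design, spec, coef="genotype[mutant]")
        calls = call_de(res, alpha=0.05, lfc_min=0.25)
        up = set(truth.loc[truth.delta_txn > 0, "gene_id"])
        down = set(truth.loc[truth.delta_txn < 0, "gene_id"])
        correct = len(up & set(calls["up"])) + len(down & set(calls["down"]))
        assert correct / (len(up) + len(down)) >= 0.7
        # sign agreement for strong effects
        strong = truth.loc[truth.delta_txn != 0, "gene_id"]
        signs = np.sign(res.loc[strong, "log2FC"])
        assert (signs == np.sign(truth.set_index("gene_id").loc[strong, "delta_txn"])).mean() >= 0.99
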