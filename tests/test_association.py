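"""Association module: fast REML solver against the generic mixed-model
fitter, OLS fallback behavior, invariances and null calibration."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sdbexpr import ModelSpec, SimulationConfig, simulate_all
from sdbexpr.association import (ExpressionStudy, fallback_ols, fit_study,
                                 fit_transcript)
from sdbexpr.lmm import RandomInterceptDesign

from conftest import COV_A, COV_B


def _random_mixed_data(rng, n=60, n_groups=12, chip_sd=0.5):
    X = np.column_stack([np.ones(n), rng.normal(size=n),
                         rng.normal(size=n),
                         rng.integers(0, 2, n).astype(float)])
    groups = np.repeat(np.arange(n_groups), n // n_groups)
    y = (X @ [1.0, 0.5, 0.1, 0.2]
         + np.repeat(rng.normal(0, chip_sd, n_groups), n // n_groups)
         + rng.normal(0, 1, n))
    return X, groups, y


class TestRemlSolver:
    def test_agrees_with_generic_reml_fitter(self, rng):
        """The profiled solver must reproduce statsmodels MixedLM REML
        estimates (the independent oracle) on random datasets."""
        from statsmodels.regression.mixed_linear_model import MixedLM
        for _ in range(8):
            X, groups, y = _random_mixed_data(rng)
            fit = RandomInterceptDesign(X, groups).fit(y)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = MixedLM(y, X, groups=groups).fit(reml=True)
            np.testing.assert_allclose(fit.beta, ref.fe_params, rtol=1e-4,
                                       atol=1e-6)
            np.testing.assert_allclose(fit.sigma2, ref.scale, rtol=1e-3)
            assert fit.group_var == pytest.approx(
                float(np.asarray(ref.cov_re)[0, 0]), rel=5e-2, abs=1e-4)
            # statsmodels' fixed-effect SEs come from the joint-likelihood
            # Hessian; the GLS plug-in SEs agree to a few percent
            np.testing.assert_allclose(fit.se, ref.bse_fe, rtol=8e-2)

    def test_batched_scan_matches_single_fits(self, rng):
        X, groups, _ = _random_mixed_data(rng)
        design = RandomInterceptDesign(X, groups)
        Y = np.column_stack([_random_mixed_data(rng)[2] for _ in range(20)])
        batch = design.fit_many(Y)
        for j, bf in enumerate(batch):
            single = design.fit(Y[:, j])
            # the REML surface can be nearly flat in lambda, so the two
            # optimizers may settle on slightly different variance
            # ratios; estimates must agree far within sampling error
            np.testing.assert_allclose(bf.beta, single.beta, rtol=2e-2,
                                       atol=2e-3)
            np.testing.assert_allclose(bf.se, single.se, rtol=1e-2)

    def test_zero_variance_component_matches_ols(self, rng):
        """With no group effect in the data the REML solution collapses
        to OLS (the null-variance limit)."""
        n = 80
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        groups = np.repeat(np.arange(16), 5)
        y = X @ [1.0, 0.4] + rng.normal(0, 1, n)
        fit = RandomInterceptDesign(X, groups).fit(y)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        if fit.on_boundary:
            np.testing.assert_allclose(fit.beta, beta_ols, rtol=1e-6)
        else:
            # tiny spurious variance component: still near OLS
            np.testing.assert_allclose(fit.beta, beta_ols, rtol=1e-2)


def _study_from_arrays(rng, n=60, n_genes=30, chip_sd=0.4, beta=0.0,
                       trait="avgO2"):
    ph = pd.DataFrame({
        "age": rng.normal(65, 9, n),
        "sex": rng.integers(0, 2, n).astype(float),
        trait: np.clip(rng.normal(94, 2, n), 60, 100),
        "stratum": "s1",
        "group": np.repeat([f"c{i}" for i in range(n // 5)], 5),
    }, index=[f"S{i}" for i in range(n)])
    zt = (ph[trait] - ph[trait].mean()) / ph[trait].std(ddof=1)
    expr = pd.DataFrame(
        rng.normal(size=(n, n_genes)) + beta * zt.to_numpy()[:, None]
        + np.repeat(rng.normal(0, chip_sd, (n // 5, n_genes)), 5, axis=0),
        index=ph.index, columns=[f"T{i}" for i in range(n_genes)])
    tmap = {f"T{i}": f"G{i}" for i in range(n_genes)}
    return ExpressionStudy(name="X", expression=expr, transcript_map=tmap,
                           phenotypes=ph, group_col="group")


class TestFitTranscript:
    def test_one_sample_per_group_falls_back_to_ols(self, rng):
        study = _study_from_arrays(rng)
        study.phenotypes["solo"] = [f"g{i}" for i in
                                    range(len(study.phenotypes))]
        spec = ModelSpec(trait="avgO2", covariates=["age", "sex"],
                         random_intercept="solo")
        est, model = fit_transcript(study, "T0", spec, "s1")
        assert model == "ols"
        ref = fallback_ols(study, "T0", spec, "s1")
        assert est.beta == pytest.approx(ref.beta)
        assert est.se == pytest.approx(ref.se)

    def test_small_sample_still_fits(self, rng):
        study = _study_from_arrays(rng, n=10)
        spec = ModelSpec(trait="avgO2", covariates=["age", "sex"])
        est = fallback_ols(study, "T1", spec, "s1")
        assert np.isfinite(est.se) and est.se > 0

    def test_degenerate_inputs_raise(self, rng):
        study = _study_from_arrays(rng)
        study.expression["T2"] = 1.0
        spec = ModelSpec(trait="avgO2", covariates=["age"])
        with pytest.raises(ValueError, match="degenerate"):
            fit_transcript(study, "T2", spec, "s1")

    def test_collinear_covariates_named(self, rng):
        study = _study_from_arrays(rng)
        study.phenotypes["age_copy"] = study.phenotypes["age"]
        spec = ModelSpec(trait="avgO2", covariates=["age", "age_copy"])
        with pytest.raises(ValueError, match="age"):
            fit_transcript(study, "T0", spec, "s1")

    def test_trait_sign_flip_flips_beta_only(self, rng):
        """Reversing the trait axis flips the sign of the effect but
        leaves its magnitude, SE and p unchanged."""
        study = _study_from_arrays(rng, beta=0.3)
        spec = ModelSpec(trait="avgO2", covariates=["age", "sex"])
        est, _ = fit_transcript(study, "T0", spec, "s1")
        flipped = study.phenotypes.copy()
        flipped["avgO2"] = 100.0 - flipped["avgO2"] + 1e-9
        study2 = ExpressionStudy(name="X", expression=study.expression,
                                 transcript_map=study.transcript_map,
                                 phenotypes=flipped, group_col="group")
        est2, _ = fit_transcript(study2, "T0", spec, "s1")
        assert est2.beta == pytest.approx(-est.beta, rel=1e-8)
        assert est2.se == pytest.approx(est.se, rel=1e-8)
        assert est2.p_two == pytest.approx(est.p_two, rel=1e-8)

    def test_orthogonal_covariate_leaves_beta_unchanged(self):
        """On noiseless data a covariate orthogonal to both trait and
        expression cannot move the estimate."""
        n = 40
        trait = np.linspace(80, 99, n)
        y = 0.25 * trait
        ortho = np.sin(np.arange(n) * 7.3)
        ortho -= np.polyval(np.polyfit(trait, ortho, 1), trait)  # de-trend
        ph = pd.DataFrame({"avgO2": trait, "ortho": ortho, "stratum": "s1",
                           "group": [f"c{i//4}" for i in range(n)]},
                          index=[f"S{i}" for i in range(n)])
        expr = pd.DataFrame({"T0": y + np.linspace(0, 1e-9, n)},
                            index=ph.index)
        study = ExpressionStudy(name="X", expression=expr,
                                transcript_map={"T0": "G0"}, phenotypes=ph,
                                group_col="group")
        base = fallback_ols(study, "T0", ModelSpec(trait="avgO2"), "s1")
        with_cov = fallback_ols(
            study, "T0", ModelSpec(trait="avgO2", covariates=["ortho"]), "s1")
        assert with_cov.beta == pytest.approx(base.beta, abs=1e-8)


class TestFitStudy:
    def test_single_stratum_equals_per_stratum_fit(self, rng):
        study = _study_from_arrays(rng, beta=0.2)
        spec = ModelSpec(trait="avgO2", covariates=["age", "sex"])
        table = fit_study(study, spec)
        est, _ = fit_transcript(study, "T3", spec, "s1")
        row = table.set_index("transcript").loc["T3"]
        assert row["beta"] == pytest.approx(est.beta, rel=5e-3, abs=2e-3)
        assert row["se"] == pytest.approx(est.se, rel=5e-3)
        assert row["p"] == pytest.approx(est.p_two, rel=5e-2)

    def test_multi_stratum_pooling_shrinks_se(self, small_sim):
        """Combining strata must always yield a smaller SE than any
        single stratum (information pooling)."""
        _, sim = small_sim
        study = sim["study_a"]
        spec = ModelSpec(trait="avgO2", covariates=COV_A)
        table = fit_study(study, spec)
        t0 = table.iloc[0]["transcript"]
        ses = [fit_transcript(study, t0, spec, s)[0].se
               for s in study.strata]
        combined = table.set_index("transcript").loc[t0, "se"]
        assert combined < min(ses)

    def test_planted_effect_recovered_per_sd(self, rng):
        """A 0.5-per-SD planted effect is recovered within its own CI."""
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            study = _study_from_arrays(r, n=100, n_genes=5, beta=0.5)
            spec = ModelSpec(trait="avgO2", covariates=["age", "sex"])
            row = fit_study(study, spec).iloc[0]
            # beta_sd is the per-SD effect; its CI should cover 0.5
            lo = row["beta_sd"] - 1.96 * row["se_sd"]
            hi = row["beta_sd"] + 1.96 * row["se_sd"]
            hits += int(lo <= 0.5 <= hi)
        assert hits >= 8

    def test_null_p_uniform(self, null_sim):
        """With nothing planted, association p-values must be uniform
        (KS test at alpha=0.01) in both cohort designs."""
        _, sim = null_sim
        for study, cov in ((sim["study_a"], COV_A), (sim["study_b"], COV_B)):
            table = fit_study(study, ModelSpec(trait="minO2",
                                               covariates=cov))
            ks = stats.kstest(table["p"], "uniform")
            assert ks.pvalue > 0.01, f"{study.name}: KS {ks}"

    def test_bmi_adjustment_keeps_discoveries(self, small_sim):
        """When BMI does not load on expression, adding it as a
        covariate must preserve >=90% of discovered genes."""
        from sdbexpr.core_stats import bh_fdr
        _, sim = small_sim
        study = sim["study_b"]
        base = fit_study(study, ModelSpec(trait="avgO2", covariates=COV_B))
        adj = fit_study(study, ModelSpec(trait="avgO2", covariates=COV_B,
                                         include_bmi=True))
        g_base = set(base.loc[bh_fdr(base["p"].to_numpy()).q < 0.05, "gene"])
        # allow borderline drift across the hard threshold: a discovery
        # counts as retained if it stays under a slightly relaxed gate
        g_adj = set(adj.loc[bh_fdr(adj["p"].to_numpy()).q < 0.10, "gene"])
        assert g_base, "fixture produced no discoveries to compare"
        assert len(g_base & g_adj) / len(g_base) >= 0.9
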