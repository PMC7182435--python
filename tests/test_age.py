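"""Growth-curve fitting and the hierarchical computed-age (cdpc) model."""

import math

import numpy as np
import pandas as pd
import pytest

from molardev import synthetic
from molardev.age import (
    AgeModelConfig,
    default_growth_model,
    fit_growth_model,
    compute_cdpc,
    robustness_compare,
    weight_only_age,
)


class TestGrowthModel:
    def test_noise_free_fit_recovers_generating_curve(self, noise_free_config):
        embryos, _ = synthetic.generate_cohort(noise_free_config)
        true = noise_free_config.growth_params["FVB"]
        fit = fit_growth_model(embryos, "FVB")
        assert fit.slope == pytest.approx(true.slope, abs=1e-6)
        assert fit.predict_weight(14.0) == pytest.approx(true.weight(14.0), abs=1e-6)

    def test_default_calibration_hits_printed_anchors(self):
        g = default_growth_model()
        assert g.predict_weight(14.0) == pytest.approx(150.0, abs=1.0)
        assert g.predict_weight(15.0) == pytest.approx(250.0, abs=1.0)

    def test_two_point_fit_matches_closed_form(self):
        # log-linear through (13 d, 100 mg) and (15 d, 400 mg): slope ln(4)/2
        table = pd.DataFrame(
            dict(embryo_id=["a", "b"], strain=["S", "S"], litter_id=["l1", "l2"],
                 dpc=[13.0, 15.0], weight_mg=[100.0, 400.0])
        )
        fit = fit_growth_model(table, "S")
        assert fit.slope == pytest.approx(math.log(4) / 2, abs=1e-12)

    def test_single_dpc_value_is_an_error(self):
        table = pd.DataFrame(
            dict(embryo_id=["a", "b"], strain=["S", "S"], litter_id=["l", "l"],
                 dpc=[14.0, 14.0], weight_mg=[150.0, 160.0])
        )
        with pytest.raises(ValueError, match="growth"):
            fit_growth_model(table, "S")


class TestWeightOnlyAge:
    def test_inverse_identity(self):
        g = default_growth_model()
        table = pd.DataFrame(
            dict(embryo_id=["a"], weight_mg=[float(g.predict_weight(14.0))])
        )
        assert weight_only_age(table, g)["age"].iloc[0] == pytest.approx(14.0, abs=1e-12)

    def test_printed_anchor_250mg_is_15d(self):
        g = default_growth_model()
        table = pd.DataFrame(dict(embryo_id=["a"], weight_mg=[250.0]))
        assert weight_only_age(table, g)["age"].iloc[0] == pytest.approx(15.0, abs=0.01)

    def test_strictly_increasing_in_weight(self):
        g = default_growth_model()
        grid = np.linspace(60.0, 590.0, 200)
        table = pd.DataFrame(dict(embryo_id=[str(i) for i in range(200)], weight_mg=grid))
        ages = weight_only_age(table, g)["age"].to_numpy()
        assert (np.diff(ages) > 0).all()

    def test_extrapolation_warns(self):
        g = default_growth_model()
        table = pd.DataFrame(dict(embryo_id=["a"], weight_mg=[10.0]))
        with pytest.warns(UserWarning, match="calibrated"):
            weight_only_age(table, g)


class TestComputeCdpc:
    def test_degenerate_noise_free_posterior_returns_dpc(self):
        g = default_growth_model()
        table = pd.DataFrame(
            dict(embryo_id=["a"], litter_id=["l"], dpc=[14.0],
                 weight_mg=[float(g.predict_weight(14.0))])
        )
        cfg = AgeModelConfig(pregnancy_effect_max=0.0, conception_offset_sd=0.0,
                             within_litter_sd=0.0, residual_sd=0.05)
        est = compute_cdpc(table, g, cfg)
        assert est["cdpc"].iloc[0] == pytest.approx(14.0, abs=1e-9)
        assert est["ci_low"].iloc[0] <= est["cdpc"].iloc[0] <= est["ci_high"].iloc[0]

    def test_200mg_embryo_sits_near_14_5_cdpc(self):
        # printed anchor: ~200 mg around 14.5 cdpc
        g = default_growth_model()
        table = pd.DataFrame(
            dict(embryo_id=["a"], litter_id=["l"], dpc=[14.5], weight_mg=[200.0])
        )
        est = compute_cdpc(table, g, AgeModelConfig(residual_sd=0.05))
        assert est["cdpc"].iloc[0] == pytest.approx(14.5, abs=0.25)

    def test_recovery_beats_dpc_and_weight_only(self, default_cohort):
        embryos, latents = default_cohort
        truth = latents.embryos.set_index("embryo_id")["true_age"]
        err_c, err_d, err_w = [], [], []
        for strain in ("FVB", "DUHi"):
            sub = embryos[embryos["strain"] == strain]
            growth = fit_growth_model(embryos, strain)
            est = compute_cdpc(sub, growth, AgeModelConfig(), ci=False)
            wo = weight_only_age(sub, growth)
            t = truth.reindex(sub["embryo_id"]).to_numpy()
            err_c += list(est["cdpc"].to_numpy() - t)
            err_d += list(sub["dpc"].to_numpy() - t)
            err_w += list(wo["age"].to_numpy() - t)
        rmse = lambda e: float(np.sqrt(np.mean(np.square(e))))  # noqa: E731
        assert rmse(err_c) < rmse(err_w) < rmse(err_d)

    def test_within_litter_cdpc_monotone_in_weight(self, cohort_with_cdpc):
        for _, grp in cohort_with_cdpc.groupby("litter_id"):
            g = grp.sort_values("weight_mg")
            assert (np.diff(g["cdpc"]) >= -1e-9).all()

    def test_posterior_multipliers_respect_bound(self, default_cohort):
        embryos, _ = default_cohort
        sub = embryos[embryos["strain"] == "FVB"]
        growth = fit_growth_model(embryos, "FVB")
        cfg = AgeModelConfig(pregnancy_effect_max=0.10)
        est = compute_cdpc(sub, growth, cfg, ci=False)
        assert est["litter_multiplier"].between(0.9, 1.1).all()
        assert est["litter_offset"].between(-0.75, 0.75).all()

    def test_shrinkage_of_litter_offsets(self, default_cohort):
        # posterior litter offsets spread less than raw per-litter residuals
        embryos, _ = default_cohort
        sub = embryos[embryos["strain"] == "FVB"]
        growth = fit_growth_model(embryos, "FVB")
        est = compute_cdpc(sub, growth, AgeModelConfig(), ci=False)
        wo = weight_only_age(sub, growth).set_index("embryo_id")["age"]
        raw = (
            sub.assign(resid=wo.reindex(sub["embryo_id"]).to_numpy() - sub["dpc"])
            .groupby("litter_id")["resid"].mean()
        )
        post = est.join(sub.set_index("embryo_id")["litter_id"], on="embryo_id") \
                  .groupby("litter_id")["litter_offset"].first()
        assert post.std() < raw.std()

    def test_weight_only_limit_of_single_litter_zero_offset_priors(self):
        g = default_growth_model()
        rng = np.random.default_rng(0)
        w = g.predict_weight(14.0 + rng.normal(0, 0.1, 6))
        table = pd.DataFrame(
            dict(embryo_id=[f"e{i}" for i in range(6)], litter_id=["l"] * 6,
                 dpc=[14.0] * 6, weight_mg=w)
        )
        cfg = AgeModelConfig(pregnancy_effect_max=0.0, conception_offset_sd=0.0,
                             within_litter_sd=0.5, residual_sd=1e-6)
        est = compute_cdpc(table, g, cfg, ci=False)
        wo = weight_only_age(table, g)
        np.testing.assert_allclose(est["cdpc"], wo["age"], atol=1e-3)

    def test_non_positive_weight_rejected(self):
        g = default_growth_model()
        table = pd.DataFrame(
            dict(embryo_id=["a"], litter_id=["l"], dpc=[14.0], weight_mg=[-1.0])
        )
        with pytest.raises(ValueError, match="weight"):
            compute_cdpc(table, g, AgeModelConfig())

    def test_grid_posterior_matches_mcmc_cross_check(self):
        """Independent oracle: emcee sampling of the same hierarchical density.

        One litter, four embryos; latents (c, m, u_1..u_4). The grid backend
        marginalizes u analytically; the sampler does not — agreement of the
        posterior mean ages validates both routes.
        """
        emcee = pytest.importorskip("emcee")
        g = default_growth_model()
        rng = np.random.default_rng(3)
        dpc = np.full(4, 14.0)
        c_true, m_true = 0.2, 1.05
        u_true = rng.normal(0, 0.125, 4)
        w = g.predict_weight(dpc + c_true + u_true) * m_true * np.exp(rng.normal(0, 0.05, 4))
        table = pd.DataFrame(
            dict(embryo_id=[f"e{i}" for i in range(4)], litter_id=["l"] * 4,
                 dpc=dpc, weight_mg=w)
        )
        cfg = AgeModelConfig(residual_sd=0.05, grid_size=81)
        est = compute_cdpc(table, g, cfg, ci=False)

        sc, su, se, r = 0.25, 0.125, 0.05, 0.10
        logw = np.log(w)

        def logpost(theta):
            c, m = theta[0], theta[1]
            u = theta[2:]
            if abs(c) > 0.75 or not (1 - r < m < 1 + r):
                return -np.inf
            lp = -0.5 * (c / sc) ** 2 - 0.5 * np.sum((u / su) ** 2)
            mu = g.predict_log_weight(dpc + c + u) + np.log(m)
            return lp - 0.5 * np.sum(((logw - mu) / se) ** 2)

        nwalk, ndim = 32, 6
        p0 = np.column_stack([
            rng.normal(0, 0.05, nwalk),
            1 + rng.normal(0, 0.02, nwalk),
            rng.normal(0, 0.05, (nwalk, 4)).reshape(nwalk, 4),
        ])
        sampler = emcee.EnsembleSampler(nwalk, ndim, logpost)
        state = sampler.run_mcmc(p0, 4000, progress=False)
        chain = sampler.get_chain(discard=1000, flat=True)
        ages_mcmc = dpc + chain[:, 0:1] + chain[:, 2:]
        np.testing.assert_allclose(est["cdpc"], ages_mcmc.mean(axis=0), atol=0.02)


class TestRobustnessCompare:
    def test_identity(self):
        est = pd.DataFrame(dict(embryo_id=["a", "b", "c"], cdpc=[14.0, 14.5, 15.0]))
        rep = robustness_compare(est, est.copy())
        assert rep["rank_correlation"] == pytest.approx(1.0)
        assert rep["max_abs_delta"] == 0.0

    def test_monotone_transform_preserves_rank_correlation(self):
        est_a = pd.DataFrame(dict(embryo_id=list("abcd"), cdpc=[14.0, 14.2, 14.7, 15.1]))
        est_b = est_a.assign(cdpc=np.exp(est_a["cdpc"] / 3))
        assert robustness_compare(est_a, est_b)["rank_correlation"] == pytest.approx(1.0)

    def test_mismatched_embryo_sets_rejected(self):
        est_a = pd.DataFrame(dict(embryo_id=["a", "b"], cdpc=[14.0, 14.5]))
        est_b = pd.DataFrame(dict(embryo_id=["a", "c"], cdpc=[14.0, 14.5]))
        with pytest.raises(ValueError, match="embryo sets"):
            robustness_compare(est_a, est_b)

    def test_pregnancy_bounds_give_concordant_ages(self, default_cohort):
        embryos, _ = default_cohort
        sub = embryos[embryos["strain"] == "DUHi"]
        growth = fit_growth_model(embryos, "DUHi")
        e10 = compute_cdpc(sub, growth, AgeModelConfig(pregnancy_effect_max=0.10), ci=False)
        e20 = compute_cdpc(sub, growth, AgeModelConfig(pregnancy_effect_max=0.20), ci=False)
        assert robustness_compare(e10, e20)["rank_correlation"] > 0.95
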