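import numpy as np
import pytest

from geofgm.model import (FIXED_EFFECT_PRIOR_VAR, MCMCConfig, ModelSpec,
                          SmoothConfig, assemble_predictor, build_design,
                          log_posterior, run_mcmc, update_variance)
from geofgm.spatial import RegionGraph

from ._oracles import (intercept_only_frame, logistic_quadrature, mc_se,
                       one_covariate_frame)


@pytest.fixture(scope="module")
def spatial_spec():
    return ModelSpec(linear_terms=["mother_cut", "urban"],
                     smooth_terms={"age_girl": SmoothConfig(6, 3, 2)},
                     spatial_structured=True, spatial_unstructured=True)


class TestBuildDesign:
    def test_normative_only_has_no_spatial_blocks(self, single_year_survey,
                                                  kenya_graph):
        ds, _ = single_year_survey
        spec = ModelSpec(linear_terms=["mother_cut"],
                         smooth_terms={"prop_cut": SmoothConfig(6, 3, 2)})
        frame = build_design(ds, kenya_graph, spec)
        assert {b.kind for b in frame.blocks} == {"linear", "smooth"}

    def test_intercept_only(self, single_year_survey, kenya_graph):
        ds, _ = single_year_survey
        frame = build_design(ds, kenya_graph, ModelSpec())
        assert len(frame.blocks) == 1
        assert np.array_equal(frame.blocks[0].X,
                              np.ones((frame.n, 1)))

    def test_block_dimensions_match_level_and_knot_counts(
            self, single_year_survey, kenya_graph, spatial_spec):
        ds, _ = single_year_survey
        frame = build_design(ds, kenya_graph, spatial_spec)
        lin = frame.block("linear")
        assert lin.p == 3  # intercept + mother_cut + urban (both numeric)
        assert frame.block("s(age_girl)").p == 6 + 3 + 1
        assert frame.block("f_str").p == kenya_graph.n_regions
        assert frame.block("f_unstr").p == kenya_graph.n_regions
        assert frame.block("f_str").rank == 7

    def test_categorical_dummy_coding(self, single_year_survey, kenya_graph):
        ds, _ = single_year_survey
        spec = ModelSpec(linear_terms=["religion"],
                         reference_levels={"religion": "christian"})
        frame = build_design(ds, kenya_graph, spec)
        names = frame.block("linear").columns
        n_levels = ds.records["religion"].nunique()
        assert len(names) == 1 + n_levels - 1
        assert all("christian" not in nm for nm in names[1:])

    def test_unknown_covariate_raises(self, single_year_survey, kenya_graph):
        ds, _ = single_year_survey
        with pytest.raises(ValueError, match="unknown covariate"):
            build_design(ds, kenya_graph, ModelSpec(linear_terms=["nope"]))

    def test_missing_smooth_policies(self, small_survey, kenya_graph):
        ds, _ = small_survey  # 2003 wave lacks attitude items
        smooth = {"prop_support": SmoothConfig(4, 3, 2)}
        drop = build_design(ds, kenya_graph, ModelSpec(
            smooth_terms=smooth, missing_smooth_policy="drop"))
        zero = build_design(ds, kenya_graph, ModelSpec(
            smooth_terms=smooth, missing_smooth_policy="zero"))
        n2003 = (ds.records["survey_year"] == 2003).sum()
        assert drop.n_dropped == n2003
        assert zero.n_dropped == 0 and zero.n == drop.n + n2003
        block = zero.block("s(prop_support)")
        assert np.allclose(block.X[~block.obs_rows], 0.0)


class TestPredictorAndPosterior:
    def test_constant_predictor(self, single_year_survey, kenya_graph):
        ds, _ = single_year_survey
        frame = build_design(ds, kenya_graph, ModelSpec())
        eta = assemble_predictor(frame, {"linear": np.array([1.7])})
        assert np.allclose(eta, 1.7)

    def test_block_sum(self, single_year_survey, kenya_graph, spatial_spec):
        ds, _ = single_year_survey
        frame = build_design(ds, kenya_graph, spatial_spec)
        rng = np.random.default_rng(0)
        params = {b.name: rng.standard_normal(b.p) for b in frame.blocks}
        eta = assemble_predictor(frame, params)
        manual = sum(b.X @ params[b.name] for b in frame.blocks)
        assert np.allclose(eta, manual)
        with pytest.raises(ValueError, match="dimension"):
            assemble_predictor(frame, {**params, "linear": np.zeros(99)})

    def test_duplicating_rows_doubles_loglik(self, single_year_survey,
                                             kenya_graph):
        from geofgm.data_model import SurveyDataset
        import pandas as pd

        ds, _ = single_year_survey
        spec = ModelSpec(linear_terms=["mother_cut"])
        frame1 = build_design(ds, kenya_graph, spec)
        df2 = pd.concat([ds.records, ds.records.assign(
            girl_id=ds.records["girl_id"] + "_dup")], ignore_index=True)
        frame2 = build_design(SurveyDataset(df2), kenya_graph, spec)
        params = {"linear": np.array([0.3, -0.8])}
        # difference of log posterior and log prior isolates the likelihood
        lp1 = log_posterior(frame1, params, {})
        lp2 = log_posterior(frame2, params, {})
        prior = -0.5 * np.sum(params["linear"]**2) / FIXED_EFFECT_PRIOR_VAR
        assert lp2 - prior == pytest.approx(2 * (lp1 - prior), rel=1e-10)

    def test_term_by_term_oracle(self):
        """Log posterior equals an independent term-by-term summation on a
        tiny fully spatial model."""
        from geofgm.data_model import SurveyDataset
        import pandas as pd

        graph = RegionGraph.from_edges(["A", "B", "C"],
                                       [("A", "B"), ("B", "C")])
        rng = np.random.default_rng(4)
        n = 20
        df = pd.DataFrame({
            "girl_id": [f"g{i}" for i in range(n)],
            "mother_id": [f"m{i}" for i in range(n)],
            "cluster_id": "c0",
            "region_id": rng.choice(["A", "B", "C"], n),
            "survey_year": 2014, "y": rng.integers(0, 2, n),
            "age_girl": rng.integers(0, 15, n),
            "age_mother": 30, "mother_cut": rng.integers(0, 2, n),
            "mother_supports_continuation": 1.0,
            "mother_believes_religious_obligation": 0.0,
            "ethnicity": "e", "religion": "r", "education": "none",
            "wealth_quintile": "middle", "urban": 0, "weight": 1.0,
        })
        spec = ModelSpec(linear_terms=["mother_cut"],
                         spatial_structured=True, spatial_unstructured=True,
                         hyper_a=1.0, hyper_b=0.0005)
        frame = build_design(SurveyDataset(df), graph, spec)
        params = {"linear": rng.standard_normal(2),
                  "f_str": rng.standard_normal(3),
                  "f_unstr": rng.standard_normal(3)}
        tau2 = {"f_str": 0.7, "f_unstr": 1.2}
        got = log_posterior(frame, params, tau2)

        eta = assemble_predictor(frame, params)
        want = float(np.sum(df["y"].to_numpy() * eta - np.log1p(np.exp(eta))))
        want += -0.5 * np.sum(params["linear"]**2) / FIXED_EFFECT_PRIOR_VAR
        q = np.array([[1., -1, 0], [-1, 2, -1], [0, -1, 1]])
        f = params["f_str"]
        want += (-0.5 * f @ q @ f / tau2["f_str"]
                 - 0.5 * 2 * np.log(tau2["f_str"]))
        u = params["f_unstr"]
        want += (-0.5 * u @ u / tau2["f_unstr"]
                 - 0.5 * 3 * np.log(tau2["f_unstr"]))
        for name in ("f_str", "f_unstr"):
            want += -2.0 * np.log(tau2[name]) - 0.0005 / tau2[name]
        assert got == pytest.approx(want, abs=1e-8)

    def test_zero_rows_posterior_is_prior(self, single_year_survey,
                                          kenya_graph):
        ds, _ = single_year_survey
        frame = build_design(ds, kenya_graph, ModelSpec())
        frame.y = frame.y[:0]
        import dataclasses
        empty = dataclasses.replace(frame)
        empty.blocks = [dataclasses.replace(frame.blocks[0],
                                            X=frame.blocks[0].X[:0])]
        lp = log_posterior(empty, {"linear": np.array([2.0])}, {})
        assert lp == pytest.approx(-0.5 * 4.0 / FIXED_EFFECT_PRIOR_VAR)

    def test_nonpositive_tau_raises(self, single_year_survey, kenya_graph,
                                    spatial_spec):
        ds, _ = single_year_survey
        frame = build_design(ds, kenya_graph, spatial_spec)
        params = {b.name: np.zeros(b.p) for b in frame.blocks}
        tau2 = {b.name: 0.5 for b in frame.blocks if b.K is not None}
        tau2["f_str"] = -1.0
        with pytest.raises(ValueError, match="tau2"):
            log_posterior(frame, params, tau2)


class TestMCMC:
    def test_intercept_only_matches_quadrature(self):
        frame = intercept_only_frame(5, 5)
        cfg = MCMCConfig(n_iter=20000, burn_in=1000, thin=1, seed=2)
        samples = run_mcmc(frame, cfg)
        chain = samples.beta0
        p_chain = 1 / (1 + np.exp(-chain))
        oracle = logistic_quadrature(np.ones((10, 1)),
                                     np.r_[np.ones(5), np.zeros(5)])
        se = mc_se(p_chain)
        assert abs(p_chain.mean() - oracle["p_mean"]) < 3 * se

    def test_same_seed_identical_draws(self, single_year_survey, kenya_graph,
                                       spatial_spec):
        ds, _ = single_year_survey
        frame = build_design(ds, kenya_graph, spatial_spec)
        cfg = MCMCConfig(n_iter=400, burn_in=100, thin=2, seed=5)
        s1 = run_mcmc(frame, cfg)
        s2 = run_mcmc(frame, cfg)
        for name in s1.coef:
            assert np.array_equal(s1.coef[name], s2.coef[name])

    def test_strong_covariate_recovery(self):
        rng = np.random.default_rng(8)
        n = 600
        x = rng.standard_normal(n)
        beta_true = 2.0
        y = (rng.random(n) < 1 / (1 + np.exp(-beta_true * x))).astype(float)
        frame = one_covariate_frame(x, y)
        samples = run_mcmc(frame, MCMCConfig(6000, 500, 1, seed=3))
        chain = samples.coef["linear"][:, 1]
        oracle = logistic_quadrature(np.column_stack([np.ones(n), x]), y,
                                     n_grid=300)
        assert abs(chain.mean() - oracle["mean"][1]) < 3 * mc_se(chain)
        # the credible interval agrees with the quadrature interval, and the
        # generating coefficient lies in (or near) it
        lo, hi = np.quantile(chain, [0.025, 0.975])
        assert lo == pytest.approx(oracle["q"][1][0.025], abs=0.05)
        assert hi == pytest.approx(oracle["q"][1][0.975], abs=0.05)

    def test_degenerate_response_rejected(self, single_year_survey,
                                          kenya_graph):
        ds, _ = single_year_survey
        frame = build_design(ds, kenya_graph, ModelSpec())
        frame.y = np.ones_like(frame.y)
        with pytest.raises(ValueError, match="all 0 or all 1"):
            run_mcmc(frame, MCMCConfig(400, 100, 2, seed=0))

    def test_sum_to_zero_constraints_every_draw(self, single_year_survey,
                                                kenya_graph, spatial_spec):
        ds, _ = single_year_survey
        frame = build_design(ds, kenya_graph, spatial_spec)
        samples = run_mcmc(frame, MCMCConfig(500, 200, 3, seed=1))
        assert np.abs(samples.coef["f_str"].mean(axis=1)).max() < 1e-8
        assert np.abs(samples.coef["f_unstr"].mean(axis=1)).max() < 1e-8
        sm = frame.block("s(age_girl)")
        fitted = samples.coef["s(age_girl)"] @ sm.X.T
        assert np.abs(fitted.mean(axis=1)).max() < 1e-8

    def test_region_relabeling_invariance(self):
        """Exchanging labels of two regions with identical data leaves the
        posterior invariant up to relabeling."""
        from geofgm.data_model import SurveyDataset
        import pandas as pd

        rng = np.random.default_rng(9)
        n_per = 40
        base = {"cluster_id": "c", "survey_year": 2014, "age_girl": 7,
                "age_mother": 30, "mother_cut": 0,
                "mother_supports_continuation": 1.0,
                "mother_believes_religious_obligation": 0.0,
                "ethnicity": "e", "religion": "r", "education": "none",
                "wealth_quintile": "middle", "urban": 0, "weight": 1.0}
        rows = []
        yy = rng.integers(0, 2, n_per)
        for region in ("A", "B", "C"):
            for i in range(n_per):
                rows.append({**base, "girl_id": f"{region}{i}",
                             "mother_id": f"{region}m{i}",
                             "region_id": region,
                             "y": int(yy[i]) if region in ("A", "B") else
                             int(rng.integers(0, 2))})
        df = pd.DataFrame(rows)
        # triangle graph: nodes A and B are graph-automorphic
        graph = RegionGraph.from_edges(
            ["A", "B", "C"], [("A", "B"), ("B", "C"), ("A", "C")])
        spec = ModelSpec(spatial_structured=True, spatial_unstructured=True)
        frame = build_design(SurveyDataset(df), graph, spec)
        cfg = MCMCConfig(3000, 500, 2, seed=4)
        s1 = run_mcmc(frame, cfg)
        swap = df.copy()
        swap["region_id"] = swap["region_id"].map(
            {"A": "B", "B": "A", "C": "C"})
        frame2 = build_design(SurveyDataset(swap), graph, spec)
        s2 = run_mcmc(frame2, cfg)
        m1 = s1.coef["f_str"].mean(axis=0)
        m2 = s2.coef["f_str"].mean(axis=0)
        # identical data in A and B => swapped fits agree within MC error
        se = max(mc_se(s1.coef["f_str"][:, j]) for j in range(3))
        assert np.allclose(m1, m2[[1, 0, 2]], atol=4 * se)


class TestUpdateVariance:
    def test_closed_form_mean_at_zero_coefficients(self):
        rng = np.random.default_rng(0)
        K = np.eye(4)
        a, b = 3.0, 2.0
        draws = [update_variance(np.zeros(4), K, a, b, rng) for _ in range(20000)]
        # IG(a + rank/2, b) mean = b / (a + rank/2 - 1) = 2 / 4
        assert np.mean(draws) == pytest.approx(b / (a + 2 - 1), rel=0.05)

    def test_scaling_quadruples_scale_increment(self):
        from geofgm.smoothers import rw_penalty

        K = rw_penalty(6, 2).K
        f = np.random.default_rng(1).standard_normal(6)
        assert (2 * f) @ K @ (2 * f) == pytest.approx(4 * (f @ K @ f))

    def test_reproducible_draw(self):
        K = np.eye(3)
        d1 = update_variance(np.ones(3), K, 1.0, 0.0005,
                             np.random.default_rng(7))
        d2 = update_variance(np.ones(3), K, 1.0, 0.0005,
                             np.random.default_rng(7))
        assert d1 == d2

    def test_invalid_hyperparameters(self):
        with pytest.raises(ValueError):
            update_variance(np.ones(3), np.eye(3), -1.0, 1.0,
                            np.random.default_rng(0))


class TestConfigs:
    def test_mcmc_config_validation(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=100, burn_in=200, thin=1)
        with pytest.raises(ValueError, match="stored"):
            MCMCConfig(n_iter=300, burn_in=200, thin=50)
        assert MCMCConfig().n_stored == (20000 - 2000) // 50

    def test_spec_rejects_overlapping_terms(self):
        with pytest.raises(ValueError, match="both"):
            ModelSpec(linear_terms=["age_girl"],
                      smooth_terms={"age_girl": SmoothConfig()})
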