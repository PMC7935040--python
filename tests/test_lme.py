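import warnings

import numpy as np
import pandas as pd
import pytest

from connctl import (
    LmeFixtureConfig,
    StudyTable,
    fit_lme,
    generate_lme_fixture,
    model1_spec,
    model2_spec,
    parse_formula,
    regional_effects,
    stepwise_select,
)

TRUE_BETAS = {"degree": 0.36, "rgm": 0.44, "degree:rgm": 0.04, "tiv": 0.1}


@pytest.fixture(scope="module")
def fixture_table():
    cfg = LmeFixtureConfig(
        true_betas=TRUE_BETAS, n_subjects=40, n_regions=30, seed=7,
        random_intercept_sd=0.5, residual_sd=1.0,
    )
    return generate_lme_fixture(cfg)


class TestParseFormula:
    def test_model1_terms(self):
        spec = model1_spec("ac")
        assert spec.response == "ac"
        assert spec.fixed_terms == ("tiv", "regions", "degree", "rgm", "degree:rgm")

    def test_model2_terms(self):
        spec = model2_spec("mc")
        assert spec.response == "mc"
        assert spec.fixed_terms == (
            "tiv", "regions", "degree", "regions:degree", "rgm", "regions:rgm"
        )

    def test_strength_alias(self):
        spec = parse_formula("ac ~ strength + rgm")
        assert spec.fixed_terms == ("degree", "rgm")

    def test_random_literal_accepted(self):
        spec = parse_formula("ac ~ tiv + (1|participants)")
        assert spec.fixed_terms == ("tiv",)

    def test_random_slope_rejected(self):
        with pytest.raises(ValueError, match="random"):
            parse_formula("ac ~ tiv + (degree|participants)")

    def test_bad_response(self):
        with pytest.raises(ValueError, match="response"):
            parse_formula("volume ~ tiv")

    def test_unknown_variable(self):
        with pytest.raises(ValueError, match="unknown variable"):
            parse_formula("ac ~ thickness")

    def test_missing_tilde(self):
        with pytest.raises(ValueError, match="~"):
            parse_formula("ac + tiv")


class TestFitAgainstStatsmodels:
    """Dual-route check: in-package profiled fitter vs statsmodels MixedLM."""

    def test_ml_fit_matches(self, fixture_table):
        import statsmodels.api as sm

        from connctl.lme import _build_design

        spec = model1_spec("ac")
        mine = fit_lme(fixture_table, spec, method="ML")
        X, _, _ = _build_design(fixture_table.scaled, spec.fixed_terms)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm.MixedLM(
                fixture_table.scaled["ac"].to_numpy(),
                X.to_numpy(),
                groups=fixture_table.scaled["subject_id"].to_numpy(),
            ).fit(reml=False)
        assert mine.log_likelihood == pytest.approx(ref.llf, abs=1e-5)
        for i, name in enumerate(X.columns):
            assert mine.coefficients[name].beta == pytest.approx(
                ref.fe_params[i], abs=1e-4
            )
            assert mine.coefficients[name].se == pytest.approx(
                ref.bse_fe[i], rel=1e-3
            )
        assert mine.group_var == pytest.approx(
            float(np.asarray(ref.cov_re).ravel()[0]), rel=1e-2
        )

    def test_reml_betas_match(self, fixture_table):
        import statsmodels.api as sm

        from connctl.lme import _build_design

        spec = model1_spec("ac")
        mine = fit_lme(fixture_table, spec, method="REML")
        X, _, _ = _build_design(fixture_table.scaled, spec.fixed_terms)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm.MixedLM(
                fixture_table.scaled["ac"].to_numpy(),
                X.to_numpy(),
                groups=fixture_table.scaled["subject_id"].to_numpy(),
            ).fit(reml=True)
        for i, name in enumerate(X.columns):
            assert mine.coefficients[name].beta == pytest.approx(
                ref.fe_params[i], abs=1e-3
            )


class TestFitContracts:
    def test_recovers_truth_within_ci(self, fixture_table):
        res = fit_lme(fixture_table, model1_spec("ac"))
        assert res.converged
        for name, truth in (("degree", 0.36), ("rgm", 0.44), ("degree:rgm", 0.04)):
            c = res.coefficients[name]
            # generous window: 5 SEs
            assert abs(c.beta - truth) < 5 * c.se

    def test_ci_bounds_bracket_beta(self, fixture_table):
        res = fit_lme(fixture_table, model1_spec("ac"))
        for c in res.coefficients.values():
            assert c.ci_low <= c.beta <= c.ci_high

    def test_bonferroni_family_sizes(self, fixture_table):
        res = fit_lme(fixture_table, model1_spec("ac"))
        n_regions = fixture_table.n_regions
        for name, c in res.coefficients.items():
            m = n_regions - 1 if c.term == "regions" else 1
            assert c.p_bonf == pytest.approx(min(1.0, c.p_raw * m))

    def test_single_participant_rejected(self, fixture_table):
        one = fixture_table.scaled[
            fixture_table.scaled.subject_id == "sub-001"
        ].copy()
        T = StudyTable(data=one, scaled=one)
        with pytest.raises(ValueError, match="2 participants"):
            fit_lme(T, model1_spec("ac"))

    def test_rank_deficient_design_names_aliased(self, fixture_table):
        df = fixture_table.scaled.copy()
        df["rgm"] = df["strength"]  # exact duplicate column
        T = StudyTable(data=df, scaled=df)
        with pytest.raises(ValueError, match="aliased"):
            fit_lme(T, parse_formula("ac ~ degree + rgm"))

    def test_invalid_method(self, fixture_table):
        with pytest.raises(ValueError, match="method"):
            fit_lme(fixture_table, model1_spec("ac"), method="MAP")

    def test_estimates_invariant_to_row_shuffling(self, fixture_table):
        res = fit_lme(fixture_table, model1_spec("ac"))
        df = fixture_table.scaled.sample(frac=1.0, random_state=11).reset_index(
            drop=True
        )
        res_shuffled = fit_lme(StudyTable(data=df, scaled=df), model1_spec("ac"))
        for name in res.coefficients:
            assert res.coefficients[name].beta == pytest.approx(
                res_shuffled.coefficients[name].beta, abs=1e-8
            )


class TestStepwise:
    def test_strong_effect_retained_noise_behavior(self, fixture_table):
        base = parse_formula("ac ~ tiv + regions")
        spec, trace = stepwise_select(
            fixture_table, base, ["degree", "rgm", "degree:rgm"]
        )
        assert "degree" in spec.fixed_terms and "rgm" in spec.fixed_terms
        kept = trace.set_index("term")["kept"]
        assert bool(kept["degree"]) and bool(kept["rgm"])

    def test_lr_nonnegative(self, fixture_table):
        _, trace = stepwise_select(
            fixture_table, parse_formula("ac ~ tiv"), ["degree", "rgm", "degree:rgm"]
        )
        assert (trace["lr_stat"] >= 0).all()

    def test_duplicate_candidate_rejected(self, fixture_table):
        with pytest.raises(ValueError, match="already in model"):
            stepwise_select(fixture_table, parse_formula("ac ~ tiv + degree"), ["degree"])

    def test_duplicated_column_surfaces_rank_error(self, fixture_table):
        df = fixture_table.scaled.copy()
        df["rgm"] = df["strength"]
        T = StudyTable(data=df, scaled=df)
        with pytest.raises(ValueError, match="aliased"):
            stepwise_select(T, parse_formula("ac ~ degree"), ["rgm"])

    def test_empty_candidates(self, fixture_table):
        with pytest.raises(ValueError, match="empty"):
            stepwise_select(fixture_table, model1_spec("ac"), [])

    def test_noise_term_rarely_retained(self):
        """Type-I calibration at reduced replication count (full 200-rep run
        lives in the acceptance suite): 60 reps, expect ~5% retention."""
        kept = 0
        reps = 60
        for seed in range(reps):
            cfg = LmeFixtureConfig(
                true_betas={"degree": 0.4}, n_subjects=15, n_regions=12, seed=seed
            )
            t = generate_lme_fixture(cfg)
            _, trace = stepwise_select(
                t, parse_formula("ac ~ degree"), ["rgm"]
            )
            kept += int(trace["kept"].iloc[0])
        # Binomial(60, 0.05): central 99% interval is [0, 8]
        assert kept <= 8


@pytest.fixture(scope="module")
def model2_fit():
    cfg = LmeFixtureConfig(
        true_betas={"degree": 0.3, "rgm": 0.3}, n_subjects=30, n_regions=20, seed=5
    )
    t = generate_lme_fixture(cfg)
    return t, fit_lme(t, model2_spec("ac"))


class TestRegionalEffects:
    def test_row_count_and_bonferroni(self, model2_fit):
        t, res = model2_fit
        for family in ("regions:rgm", "regions:degree"):
            eff = regional_effects(res, family)
            assert len(eff) == t.n_regions
            np.testing.assert_allclose(
                eff["p_bonf"], np.minimum(1.0, eff["p_raw"] * t.n_regions)
            )

    def test_model1_rejected(self, fixture_table):
        res = fit_lme(fixture_table, model1_spec("ac"))
        with pytest.raises(ValueError, match="absent"):
            regional_effects(res, "regions:rgm")

    def test_bad_family(self, model2_fit):
        _, res = model2_fit
        with pytest.raises(ValueError, match="family"):
            regional_effects(res, "regions:tiv")

    def test_planted_regional_effect_detected(self):
        """One region's rgm slope boosted far above the rest."""
        rng = np.random.default_rng(21)
        ns, nr = 40, 12
        cfg = LmeFixtureConfig(
            true_betas={"rgm": 0.2}, n_subjects=ns, n_regions=nr, seed=3,
            residual_sd=0.5,
        )
        t = generate_lme_fixture(cfg)
        df = t.scaled.copy()
        target = sorted(df["region_name"].unique())[4]
        boost = 2.0
        mask = df["region_name"] == target
        df.loc[mask, "ac"] += boost * df.loc[mask, "rgm"]
        T = StudyTable(data=df, scaled=df)
        eff = regional_effects(fit_lme(T, model2_spec("ac")), "regions:rgm")
        top = eff.loc[eff["beta"].idxmax()]
        assert top["region"] == target
        assert top["p_bonf"] < 0.05
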