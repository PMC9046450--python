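"""Control-pool sampling, regression fitting and conditional Z-scores."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_ols
from isletquant.errors import ConfigurationError, DataError
from isletquant.synthetic import (
    MITO_CHANNELS,
    CohortConfig,
    IntensityModelParams,
    gen_deficient_cohort,
    gen_intensity_table,
)
from isletquant.intensity import background_correct, log_transform
from isletquant.zscore import (
    build_control_pool,
    classify_deficiency,
    compute_z,
    fit_control_model,
    score_cohort,
    validate_residuals,
)


def _prep(table):
    return log_transform(background_correct(table, MITO_CHANNELS), MITO_CHANNELS)


class TestControlPool:
    def test_min_rule(self, default_params):
        frames = []
        for mouse, n in (("m1", 50), ("m2", 50), ("m3", 48)):
            cohort = CohortConfig(
                n_mice_per_group=1, islets_per_mouse=n, groups=(("WT", "44w"),), seed=1
            )
            t = gen_intensity_table(cohort, {("WT", "44w"): default_params})
            t["mouse_id"] = mouse
            frames.append(t)
        table = pd.concat(frames, ignore_index=True)
        pool = build_control_pool(table, "genotype == 'WT'", seed=0)
        assert len(pool) == 3 * 48
        assert (pool.groupby("mouse_id").size() == 48).all()

    def test_single_mouse_takes_all(self, default_params, caplog):
        cohort = CohortConfig(
            n_mice_per_group=1, islets_per_mouse=30, groups=(("WT", "44w"),), seed=1
        )
        table = gen_intensity_table(cohort, {("WT", "44w"): default_params})
        pool = build_control_pool(table, "genotype == 'WT'", seed=0)
        assert len(pool) == 30

    def test_empty_selection_raises(self, control_table):
        with pytest.raises(DataError, match="selects no ROIs"):
            build_control_pool(control_table, "genotype == 'nope'", seed=0)

    def test_seeded_sampling_reproducible(self, control_table):
        a = build_control_pool(control_table, "genotype == 'WT'", seed=5)
        b = build_control_pool(control_table, "genotype == 'WT'", seed=5)
        assert a["roi_id"].tolist() == b["roi_id"].tolist()


class TestFitControlModel:
    def test_five_point_closed_form(self, five_point_pool):
        """OLS on the printed 5-point pool: slope 0.9, intercept 1.3,
        SEE = sqrt(1.9 / 3)."""
        model = fit_control_model(five_point_pool, min_pool_size=5)
        fit = model.subunits["ndufb8"]
        assert fit.slope == pytest.approx(0.9, abs=1e-10)
        assert fit.intercept == pytest.approx(1.3, abs=1e-10)
        assert fit.see == pytest.approx(np.sqrt(1.9 / 3), abs=1e-10)

    def test_matches_bruteforce_summation_oracle(self, control_table):
        prepped = _prep(control_table)
        model = fit_control_model(prepped)
        x = prepped["tomm20_log"].to_numpy()
        for sub in ("ndufb8", "mtco1"):
            slope, intercept, see = brute_force_ols(x, prepped[f"{sub}_log"].to_numpy())
            assert model.subunits[sub].slope == pytest.approx(slope, abs=1e-10)
            assert model.subunits[sub].intercept == pytest.approx(intercept, abs=1e-10)
            assert model.subunits[sub].see == pytest.approx(see, abs=1e-10)

    def test_perfect_fit_refused(self):
        x = np.arange(1.0, 13.0)
        pool = pd.DataFrame(
            {"tomm20_log": x, "ndufb8_log": 2 * x, "mtco1_log": 2 * x, "insulin_log": x}
        )
        with pytest.raises(DataError, match="SEE = 0"):
            fit_control_model(pool)

    def test_zero_variance_refused(self):
        pool = pd.DataFrame(
            {
                "tomm20_log": np.ones(12),
                "ndufb8_log": np.random.default_rng(0).normal(size=12),
                "mtco1_log": np.ones(12),
                "insulin_log": np.ones(12),
            }
        )
        with pytest.raises(DataError, match="variance"):
            fit_control_model(pool)

    def test_pool_floor(self, five_point_pool):
        with pytest.raises(DataError, match="floor"):
            fit_control_model(five_point_pool)  # default floor is 10

    def test_parameter_recovery(self, default_params):
        """At n = 2000 the fitted slope/intercept/SEE recover the generative
        values within 3 standard errors."""
        cohort = CohortConfig(
            n_mice_per_group=1, islets_per_mouse=2000, groups=(("WT", "44w"),), seed=8
        )
        prepped = _prep(gen_intensity_table(cohort, {("WT", "44w"): default_params}))
        model = fit_control_model(prepped)
        n = len(prepped)
        x = prepped["tomm20_log"].to_numpy()
        sxx = ((x - x.mean()) ** 2).sum()
        fit = model.subunits["ndufb8"]
        se_slope = default_params.see_N / np.sqrt(sxx)
        assert abs(fit.slope - default_params.beta1_N) < 3 * se_slope
        se_int = default_params.see_N * np.sqrt(1 / n + x.mean() ** 2 / sxx)
        assert abs(fit.intercept - default_params.beta0_N) < 3 * se_int
        se_see = default_params.see_N / np.sqrt(2 * (n - 2))
        assert abs(fit.see - default_params.see_N) < 3 * se_see


class TestResidualDiagnostics:
    def test_report_covers_both_subunits(self, control_table):
        prepped = _prep(control_table)
        model = fit_control_model(prepped)
        report = validate_residuals(model, prepped)
        assert set(report) == {"ndufb8", "mtco1"}
        assert all(0 <= p <= 1 for p in report.values())

    def test_heavy_tails_warn(self, caplog):
        rng = np.random.default_rng(42)
        x = rng.normal(6, 0.4, 500)
        pool = pd.DataFrame(
            {
                "tomm20_log": x,
                "ndufb8_log": 0.4 + 0.9 * x + rng.standard_t(1, 500) * 0.2,
                "mtco1_log": 0.7 + 0.85 * x + rng.normal(0, 0.2, 500),
                "insulin_log": rng.normal(6.5, 0.4, 500),
            }
        )
        model = fit_control_model(pool)
        with caplog.at_level("WARNING"):
            report = validate_residuals(model, pool)
        assert report["ndufb8"] < 0.01
        assert any("normality" in r.message for r in caplog.records)


class TestComputeZ:
    def test_identity_point_scores_zero(self, five_point_pool):
        model = fit_control_model(five_point_pool, min_pool_size=5)
        rec = pd.DataFrame(
            {
                "tomm20_log": [3.0],  # the pool mean
                "ndufb8_log": [1.3 + 0.9 * 3.0],  # on the regression line
                "mtco1_log": [1.3 + 0.9 * 3.0],
                "insulin_log": [4.0],
            }
        )
        z = compute_z(rec, model)
        assert z["tomm20_z"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert z["ndufb8_z"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_five_point_test_roi(self, five_point_pool):
        """ROI (x, y) = (3, 2): predicted 4.0, so Z = -2 / SEE."""
        model = fit_control_model(five_point_pool, min_pool_size=5)
        rec = pd.DataFrame(
            {"tomm20_log": [3.0], "ndufb8_log": [2.0], "mtco1_log": [2.0],
             "insulin_log": [4.0]}
        )
        z = compute_z(rec, model)
        see = np.sqrt(1.9 / 3)
        assert z["ndufb8_z"].iloc[0] == pytest.approx(-2.0 / see, abs=1e-10)

    def test_standardization_identity(self, control_table):
        """On the fitting pool itself, Tomm20_Z has mean 0 and SD 1."""
        prepped = _prep(control_table)
        pool = build_control_pool(prepped, "genotype == 'WT'", seed=3)
        model = fit_control_model(pool)
        z = compute_z(pool, model)
        assert abs(z["tomm20_z"].mean()) < 1e-10
        assert abs(z["tomm20_z"].std(ddof=1) - 1) < 1e-10

    def test_excluded_tomm20_blocks_conditional_scores(self, five_point_pool):
        model = fit_control_model(five_point_pool, min_pool_size=5)
        rec = pd.DataFrame(
            {"tomm20_log": [np.nan], "ndufb8_log": [2.0], "mtco1_log": [2.0],
             "insulin_log": [4.0]}
        )
        z = compute_z(rec, model)
        assert np.isnan(z["ndufb8_z"].iloc[0])
        assert z["z_missing_reason"].iloc[0] == "tomm20 excluded"

    def test_monotone_in_subunit_intensity(self, five_point_pool):
        model = fit_control_model(five_point_pool, min_pool_size=5)
        y = np.linspace(5, 1, 9)
        rec = pd.DataFrame(
            {"tomm20_log": 3.0, "ndufb8_log": y, "mtco1_log": y, "insulin_log": 4.0}
        )
        z = compute_z(rec, model)["ndufb8_z"].to_numpy()
        assert (np.diff(z) < 0).all()

    def test_gain_invariance(self, control_table):
        """A global multiplicative gain (common to reference and test) leaves
        every Z-score unchanged: the log-scale shift is absorbed."""
        prepped = _prep(control_table)
        scored, _ = score_cohort(prepped, "genotype == 'WT'", seed=2)
        boosted = prepped.copy()
        for ch in MITO_CHANNELS:
            boosted[f"{ch}_log"] = boosted[f"{ch}_log"] + np.log(1.7)
        scored2, _ = score_cohort(boosted, "genotype == 'WT'", seed=2)
        for col in ("tomm20_z", "ndufb8_z", "mtco1_z", "insulin_z"):
            np.testing.assert_allclose(scored[col], scored2[col], atol=1e-9)


class TestDeficiencyRecovery:
    def test_shift_recovery(self, default_params):
        """Strata shifted by k x SEE score a mean conditional Z of -k
        (500 islets per stratum, pooled over 3 seeds), strictly decreasing
        in k within every seed."""
        shifts = (0.0, 2.0, 3.0)
        per_seed = []
        for seed in (101, 202, 303):
            strata = gen_deficient_cohort(default_params, shifts, 500, seed=seed)
            ref = gen_intensity_table(
                CohortConfig(
                    n_mice_per_group=4, islets_per_mouse=500,
                    groups=(("CTRL", "na"),), seed=seed + 1000,
                ),
                {("CTRL", "na"): default_params},
            )
            ref["shift"] = np.nan
            prepped = _prep(pd.concat([ref, strata], ignore_index=True))
            scored, _ = score_cohort(prepped, "genotype == 'CTRL'", seed=seed)
            means = scored.groupby("shift")["ndufb8_z"].mean()
            assert means[0.0] > means[2.0] > means[3.0]
            per_seed.append(means)
        pooled = sum(per_seed) / len(per_seed)
        for k in shifts:
            assert pooled[k] == pytest.approx(-k, abs=0.1)


class TestClassification:
    @pytest.mark.parametrize(
        "z, expected", [(-3.5, "deficient"), (-2.5, "low"), (0.0, "normal"), (1.0, "normal")]
    )
    def test_default_categories(self, z, expected):
        assert classify_deficiency([z]).iloc[0] == expected

    def test_non_monotone_thresholds_refused(self):
        with pytest.raises(ConfigurationError):
            classify_deficiency([0.0], thresholds=(-3.0, -2.0))


class TestClassificationProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        z=st.floats(min_value=-20, max_value=20),
        low=st.floats(min_value=-5, max_value=0),
        gap=st.floats(min_value=0.1, max_value=5),
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_category_consistent_with_thresholds(self, z, low, gap):
        """The category always agrees with the threshold definition."""
        deficient = low - gap
        cat = classify_deficiency([z], thresholds=(low, deficient)).iloc[0]
        if z < deficient:
            assert cat == "deficient"
        elif z < low:
            assert cat == "low"
        else:
            assert cat == "normal"


class TestScoreCohort:
    def test_population_strata_scored_against_beta_reference(self, default_params):
        """Alpha-cell records are scored against a model fitted on beta cells."""
        cohort = CohortConfig(
            n_mice_per_group=2, islets_per_mouse=30, groups=(("WT", "44w"),), seed=12
        )
        beta = gen_intensity_table(cohort, {("WT", "44w"): default_params})
        beta["cell_population"] = "beta"
        alpha_params = IntensityModelParams(mu_T=5.7)  # lower mitochondrial mass
        alpha = gen_intensity_table(cohort, {("WT", "44w"): alpha_params})
        alpha["cell_population"] = "alpha"
        alpha["roi_id"] = alpha["roi_id"] + "_a"
        table = _prep(pd.concat([beta, alpha], ignore_index=True))
        scored, model = score_cohort(
            table, "genotype == 'WT' and cell_population == 'beta'", seed=0
        )
        assert len(scored) == len(table)
        mean_alpha = scored.loc[scored["cell_population"] == "alpha", "tomm20_z"].mean()
        assert mean_alpha < -0.4  # lower mass shows up as negative Z vs beta model

    def test_determinism(self, control_table):
        prepped = _prep(control_table)
        a, _ = score_cohort(prepped, "genotype == 'WT'", seed=7)
        b, _ = score_cohort(prepped, "genotype == 'WT'", seed=7)
        pd.testing.assert_frame_equal(a, b)
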