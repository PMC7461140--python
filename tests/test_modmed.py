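"""Moderated mediation: coefficients, conditional effects, F tests, Johnson-Neyman."""

import numpy as np
import pytest
from scipy import stats

import specmed as sp
from specmed.modmed import NestingError, interaction_f_test
from specmed.mediation import fit_ols
import pandas as pd


class TestFitOnStudyTable:
    def test_mediator_model_coefficients(self, modmed_fit):
        assert modmed_fit.a1 == pytest.approx(-94.60, rel=0.01)
        assert modmed_fit.a3 == pytest.approx(2.759, rel=0.01)

    def test_outcome_model_fit_statistics(self, modmed_fit):
        assert modmed_fit.outcome_model.r2 == pytest.approx(0.90, rel=0.02)
        assert modmed_fit.outcome_model.f_stat == pytest.approx(66.25, rel=0.02)

    def test_degrees_of_freedom(self, modmed_fit):
        assert modmed_fit.outcome_model.df_resid == 30
        assert modmed_fit.mediator_model.df_resid == 31

    def test_moderated_direct_path_variant_changes_df(self, study_frame):
        spec = sp.ModMedSpec(moderate_cprime=True)
        fit = sp.ModeratedMediation.from_dataframe(
            study_frame, "f_combined", "chg_dmv", "sv", "time_days", spec=spec
        ).fit()
        assert fit.outcome_model.df_resid == 29  # n - 6

    def test_constant_moderator_rejected(self, study_frame):
        with pytest.raises(ValueError, match="distinct"):
            sp.ModeratedMediation(
                study_frame.f_combined,
                study_frame.chg_dmv,
                study_frame.sv,
                np.full(35, 28.0),
            )


class TestConditionalIndirect:
    @pytest.mark.parametrize("w,expected,rel", [(21, 344.99, 0.01), (28, 46.28, 0.02)])
    def test_point_estimates_match_study(self, modmed_fit, w, expected, rel):
        ce = modmed_fit.conditional_indirect(w, boot=sp.BootConfig(n_boot=200, seed=1))
        assert ce.theta == pytest.approx(expected, rel=rel)

    def test_exact_algebra_on_coefficients(self, modmed_fit):
        for w in (21.0, 25.5, 35.0):
            expected = (modmed_fit.a1 + modmed_fit.a3 * w) * (
                modmed_fit.b1 + modmed_fit.b2 * w
            )
            ce = modmed_fit.conditional_indirect(w, boot=sp.BootConfig(n_boot=50, seed=0))
            assert ce.theta == pytest.approx(expected, abs=1e-12)

    def test_unmoderated_paths_give_constant_indirect_effect(self, study_frame):
        spec = sp.ModMedSpec(moderate_a=False, moderate_b=False, moderate_cprime=True)
        fit = sp.ModeratedMediation.from_dataframe(
            study_frame, "f_combined", "chg_dmv", "sv", "time_days", spec=spec
        ).fit()
        thetas = [fit.theta_a(w) * fit.theta_b(w) for w in (21, 28, 35)]
        assert thetas[0] == pytest.approx(thetas[1]) == pytest.approx(thetas[2])
        assert thetas[0] == pytest.approx(fit.a1 * fit.b1)

    def test_summary_table_matches_table3_point_estimates(self, modmed_fit):
        tbl = modmed_fit.summary_table(boot=sp.BootConfig(n_boot=1000, seed=2))
        assert tbl.theta.tolist() == pytest.approx([344.99, 46.28, 8.07], rel=0.02)
        assert bool(tbl.significant[0])  # mediation significant at 21 days only

    def test_aggregate_decomposition(self, modmed_fit):
        agg = modmed_fit.aggregate_effects()
        assert agg["indirect"] == pytest.approx(2804.153, rel=0.01)
        assert agg["total"] == pytest.approx(2844.715, rel=0.01)
        assert agg["vaf_percent"] == pytest.approx(98.57, abs=0.2)

    def test_goodman_on_first_order_paths(self, modmed_fit):
        g = modmed_fit.goodman()
        assert g.z == pytest.approx(3.29, abs=0.05)
        assert g.p < 0.001


class TestInteractionFTest:
    def test_predictor_by_time_interaction(self, study_frame, modmed_fit):
        reduced = fit_ols(
            study_frame.chg_dmv,
            pd.DataFrame({"x": study_frame.f_combined, "w": study_frame.time_days}),
        )
        f, df1, df2, dr2, p = interaction_f_test(reduced, _canonical(modmed_fit.mediator_model))
        assert (df1, df2) == (1, 31)
        assert dr2 == pytest.approx(0.1848, abs=0.002)
        assert f == pytest.approx(9.89, rel=0.02)
        assert p < 0.01

    def test_mediator_by_time_interaction(self, study_frame, modmed_fit):
        reduced = fit_ols(
            study_frame.sv,
            pd.DataFrame(
                {
                    "x": study_frame.f_combined,
                    "w": study_frame.time_days,
                    "m": study_frame.chg_dmv,
                }
            ),
        )
        f, df1, df2, dr2, p = interaction_f_test(reduced, _canonical(modmed_fit.outcome_model))
        assert (df1, df2) == (1, 30)
        assert f == pytest.approx(28.32, rel=0.02)
        assert dr2 == pytest.approx(0.096, abs=0.002)

    def test_identical_models_give_null_comparison(self, modmed_fit):
        fit = modmed_fit.mediator_model
        f, df1, _, dr2, p = interaction_f_test(fit, fit)
        assert f == 0.0 and dr2 == 0.0 and p == 1.0

    def test_non_nested_models_rejected(self, study_frame):
        f1 = fit_ols(study_frame.sv, pd.DataFrame({"a": study_frame.f_combined}))
        f2 = fit_ols(study_frame.sv, pd.DataFrame({"b": study_frame.chg_dmv}))
        with pytest.raises(NestingError):
            interaction_f_test(f1, f2)


def _canonical(fit):
    return fit  # coefficient indices are already canonical x/m/w labels


class TestJohnsonNeyman:
    def test_predictor_path_significant_through_30_days(self, modmed_fit):
        region = modmed_fit.johnson_neyman(path="a", alpha=0.05)
        assert len(region.boundaries) == 1
        assert region.boundaries[0] == pytest.approx(30.0, abs=1.0)
        assert region.significant_below and not region.significant_above
        assert region.significant_at(21.0) and not region.significant_at(34.0)

    def test_mediator_path_significant_through_28_days(self, modmed_fit):
        region = modmed_fit.johnson_neyman(path="b", alpha=0.05)
        assert region.boundaries[0] == pytest.approx(28.0, abs=1.0)
        assert region.significant_below

    @pytest.mark.parametrize("path", ["a", "b"])
    def test_agrees_with_grid_oracle(self, modmed_fit, path):
        """Scan w in 0.01 steps; sign changes of |t| - t_crit must bracket the boundaries."""
        fit = modmed_fit.mediator_model if path == "a" else modmed_fit.outcome_model
        main, inter = ("x", "x:w") if path == "a" else ("m", "m:w")
        b0 = fit.coefficients[main]
        b1 = fit.coefficients[inter]
        v00 = fit.covariance.loc[main, main]
        v01 = fit.covariance.loc[main, inter]
        v11 = fit.covariance.loc[inter, inter]
        tc = stats.t.ppf(0.975, fit.df_resid)
        grid = np.arange(21.0, 35.0, 0.01)
        tval = np.abs(b0 + b1 * grid) / np.sqrt(v00 + 2 * grid * v01 + grid**2 * v11)
        crossings = grid[np.flatnonzero(np.diff(np.sign(tval - tc)))]
        region = modmed_fit.johnson_neyman(path=path, alpha=0.05)
        assert len(crossings) == len(region.boundaries)
        for c, b in zip(crossings, region.boundaries):
            assert abs(c - b) <= 0.011

    def test_unmoderated_path_rejected(self, study_frame):
        spec = sp.ModMedSpec(moderate_a=True, moderate_b=False)
        fit = sp.ModeratedMediation.from_dataframe(
            study_frame, "f_combined", "chg_dmv", "sv", "time_days", spec=spec
        ).fit()
        with pytest.raises(ValueError, match="not moderated"):
            fit.johnson_neyman(path="b")


class TestParameterRecovery:
    def test_interaction_estimates_recovered_on_synthetic_data(self):
        """Median relative error of a1, a3, b1, b2 <= 10% at n = 500."""
        truth = sp.MediationTruth(
            a=-90.0, b=-30.0, c_prime=40.0, a3=2.5, b2=0.9,
            sd_m=0.1, sd_y=0.3, intercept_m=4.0, intercept_y=60.0, n=500,
        )
        errs = {k: [] for k in ("a1", "a3", "b1", "b2")}
        for seed in range(20):
            ds = sp.simulate_mediation(
                sp.MediationTruth(**{**vars(truth), "seed": seed})
            )
            f = ds.to_frame()
            fit = sp.fit_modmed(f.f_combined, f.chg_dmv, f.sv, f.time_days)
            errs["a1"].append(abs((fit.a1 - truth.a) / truth.a))
            errs["a3"].append(abs((fit.a3 - truth.a3) / truth.a3))
            errs["b1"].append(abs((fit.b1 - truth.b) / truth.b))
            errs["b2"].append(abs((fit.b2 - truth.b2) / truth.b2))
        for k, v in errs.items():
            assert np.median(v) <= 0.10, f"{k}: median rel err {np.median(v):.3f}"

    def test_null_interactions_covered_by_their_cis(self):
        """With a3 = b2 = 0 truth, interaction CIs cover zero in most replicates."""
        hits = 0
        reps = 20
        for seed in range(reps):
            ds = sp.simulate_mediation(
                sp.MediationTruth(a=-15, b=-8, c_prime=50, n=300, seed=1000 + seed)
            )
            f = ds.to_frame()
            fit = sp.fit_modmed(f.f_combined, f.chg_dmv, f.sv, f.time_days)
            ok = True
            for model, term in ((fit.mediator_model, "x:w"), (fit.outcome_model, "m:w")):
                est = model.coefficients[term]
                se = model.standard_errors[term]
                tc = stats.t.ppf(0.975, model.df_resid)
                ok &= abs(est) <= tc * se
            hits += ok
        assert hits >= 0.9 * reps
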