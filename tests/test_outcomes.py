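import dataclasses
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import igsense as ig
from conftest import make_outcome_tables


class TestOutlierScreen:
    def test_single_constructed_outlier_removed(self):
        rng = np.random.default_rng(0)
        vals = np.clip(rng.standard_normal(59), -2.5, 2.5).tolist() + [5.0]
        kept, removed = ig.remove_outliers(vals)
        assert removed == [59]
        assert len(kept) == 59

    def test_values_within_two_sd_all_kept(self):
        rng = np.random.default_rng(1)
        vals = np.clip(rng.standard_normal(40), -1.9, 1.9)
        kept, removed = ig.remove_outliers(vals)
        assert removed == []

    def test_zero_threshold_keeps_only_exact_mean(self):
        kept, removed = ig.remove_outliers([1.0, 2.0, 3.0], k_sd=0.0)
        assert kept == [1] and removed == [0, 2]

    def test_all_equal_input_keeps_everything(self):
        kept, removed = ig.remove_outliers([2.0] * 5)
        assert len(kept) == 5 and removed == []

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.standard_normal(30)
        vals[3] = 6.0
        kept_a, _ = ig.remove_outliers(vals)
        perm = rng.permutation(30)
        kept_b, _ = ig.remove_outliers(vals[perm])
        assert np.allclose(
            np.sort(vals[kept_a]), np.sort(vals[perm][kept_b])
        )

    def test_non_iterative_single_pass(self):
        """Mean/SD come from the full input: a masked second outlier stays."""
        vals = list(np.zeros(20)) + [10.0, 100.0]
        _, removed = ig.remove_outliers(vals)
        assert removed == [21]  # 10.0 survives because 100.0 inflates the SD


class TestTertileSplit:
    @pytest.mark.parametrize(
        "n,expected", [(59, (20, 19, 20)), (9, (3, 3, 3)), (10, (3, 4, 3)), (60, (20, 20, 20))]
    )
    def test_group_sizes(self, n, expected):
        rng = np.random.default_rng(3)
        labels = ig.tertile_split(rng.standard_normal(n))
        sizes = tuple((labels == g).sum() for g in ("Low", "Medium", "High"))
        assert sizes == expected

    def test_rank_ordering(self):
        vals = np.array([5.0, 1.0, 3.0, 2.0, 6.0, 4.0])
        labels = ig.tertile_split(vals)
        assert list(labels) == ["High", "Low", "Medium", "Low", "High", "Medium"]

    def test_ties_broken_by_stable_order(self):
        labels = ig.tertile_split([1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        assert list(labels) == ["Low", "Low", "Medium", "Medium", "High", "High"]


class TestLinearAndExponential:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(4)
        z = ig.standardize_estimates(rng.standard_normal(30))
        ses = 2 + rng.random(30)
        sens, outc = make_outcome_tables(z, 2.0 * z + 100.0, ses)
        res = ig.fit_linear_outcome(sens, outc)
        assert res.coef("slope_z")["estimate"] == pytest.approx(2.0, abs=1e-8)
        assert res.coef("ses")["estimate"] == pytest.approx(0.0, abs=1e-8)

    def test_duplicated_covariate_rejected(self):
        rng = np.random.default_rng(5)
        z = ig.standardize_estimates(rng.standard_normal(20))
        sens, outc = make_outcome_tables(z, 100 + z, z)  # ses duplicates slope_z
        with pytest.raises(ValueError, match="collinear"):
            ig.fit_linear_outcome(sens, outc)

    def test_insufficient_data_rejected(self):
        sens, outc = make_outcome_tables([0.0, 1.0, -1.0], [100, 101, 99], [2, 3, 4])
        with pytest.raises(ValueError):
            ig.fit_linear_outcome(sens, outc)

    def test_exact_exponential_recovery(self):
        rng = np.random.default_rng(6)
        z = ig.standardize_estimates(rng.standard_normal(40))
        ses = 2 + rng.random(40)
        sens, outc = make_outcome_tables(z, 100 + 3 * np.exp(z), ses)
        res = ig.fit_exponential_outcome(sens, outc)
        assert res.coef("exp_slope_z")["estimate"] == pytest.approx(3.0, abs=1e-6)

    def test_exponential_loses_to_linear_on_linear_data(self):
        rng = np.random.default_rng(7)
        wins = 0
        for rep in range(20):
            z = ig.standardize_estimates(rng.standard_normal(60))
            ses = 2 + rng.random(60)
            y = 100 + 4 * z + 5 * rng.standard_normal(60)
            sens, outc = make_outcome_tables(z, y, ses)
            lin = ig.fit_linear_outcome(sens, outc)
            expo = ig.fit_exponential_outcome(sens, outc)
            wins += lin.aic < expo.aic
        assert wins > 10


class TestAdditiveModel:
    def test_noise_free_linear_data_collapses_to_line(self):
        rng = np.random.default_rng(8)
        z = ig.standardize_estimates(rng.standard_normal(50))
        ses = 2 + rng.random(50)
        sens, outc = make_outcome_tables(z, 100 + 5 * z, ses)
        res = ig.fit_gam_outcome(sens, outc)
        assert res.smooth_edf == pytest.approx(1.0, abs=0.1)
        assert res.adjusted_r2 > 0.999

    def test_additive_beats_linear_aic_on_nonlinear_data(self):
        rng = np.random.default_rng(9)
        wins = 0
        for rep in range(15):
            z = ig.standardize_estimates(rng.standard_normal(60))
            ses = 2 + rng.random(60)
            y = 100 + 3.75 * np.exp(z) + 6 * rng.standard_normal(60)
            sens, outc = make_outcome_tables(z, y, ses)
            gam = ig.fit_gam_outcome(sens, outc)
            lin = ig.fit_linear_outcome(sens, outc)
            wins += gam.aic < lin.aic
        assert wins > 7

    def test_basis_autoshrink_warns_on_few_unique_values(self):
        z = np.tile([-1.0, -0.5, 0.0, 0.5, 1.0], 4)
        rng = np.random.default_rng(10)
        sens, outc = make_outcome_tables(
            z, 100 + z + 0.1 * rng.standard_normal(20), 2 + rng.random(20)
        )
        with pytest.warns(UserWarning, match="shrinking spline basis"):
            ig.fit_gam_outcome(sens, outc)

    def test_small_sample_rejected(self):
        rng = np.random.default_rng(11)
        z = ig.standardize_estimates(rng.standard_normal(8))
        sens, outc = make_outcome_tables(z, 100 + z, 2 + rng.random(8))
        with pytest.raises(ValueError):
            ig.fit_gam_outcome(sens, outc)

    def test_agrees_with_mgcv_reference(self, tmp_path):
        """Independent oracle: mgcv's REML penalized-spline fit."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(12)
        n = 60
        z = ig.standardize_estimates(rng.standard_normal(n))
        ses = 2 + 2 * rng.random(n)
        y = 100 + 3.75 * np.exp(z) + 2 * (ses - 3) + 9 * rng.standard_normal(n)
        sens, outc = make_outcome_tables(z, y, ses)
        res = ig.fit_gam_outcome(sens, outc)
        csv = tmp_path / "d.csv"
        pd.DataFrame({"y": y, "x": z, "ses": ses}).to_csv(csv, index=False)
        script = (
            "suppressMessages(library(mgcv));"
            f"d <- read.csv('{csv}');"
            "fit <- gam(y ~ s(x, k=10, bs='ps') + ses, data=d, method='REML');"
            "s <- summary(fit);"
            "cat(s$s.table[1,'edf'], s$s.table[1,'p-value'], s$r.sq, AIC(fit),"
            "    s$p.table['ses','t value'], sep=',')"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        edf, pval, r2, aic, ses_t = map(float, out.stdout.strip().split(","))
        assert res.smooth_edf == pytest.approx(edf, abs=1.0)
        assert res.adjusted_r2 == pytest.approx(r2, abs=0.05)
        assert res.aic == pytest.approx(aic, abs=3.0)
        assert res.parametric["ses"].tstat == pytest.approx(ses_t, abs=0.3)
        assert (res.smooth_p < 0.01) == (pval < 0.01)


class TestStratifiedAndPartition:
    def test_group_sizes_and_fits(self):
        rng = np.random.default_rng(13)
        z = ig.standardize_estimates(rng.standard_normal(59))
        ses = 2 + rng.random(59)
        y = 100 + 3.75 * np.exp(z) + 6 * rng.standard_normal(59)
        sens, outc = make_outcome_tables(z, y, ses)
        strata = ig.stratify_and_fit(sens, outc)
        assert [s.group for s in strata] == ["Low", "Medium", "High"]
        assert [s.n for s in strata] == [20, 19, 20]

    def test_effect_confined_to_top_tertile(self):
        rng = np.random.default_rng(14)
        high_hits = low_hits = 0
        for rep in range(15):
            z = ig.standardize_estimates(rng.standard_normal(60))
            ses = 2 + rng.random(60)
            y = 100 + 12 * np.maximum(z - 0.4, 0) ** 2 + 4 * rng.standard_normal(60)
            sens, outc = make_outcome_tables(z, y, ses)
            strata = {s.group: s for s in ig.stratify_and_fit(sens, outc)}
            high_hits += strata["High"].result.smooth_p < 0.05
            low_hits += strata["Low"].result.smooth_p < 0.05
        assert high_hits > low_hits

    def test_partition_shares_sum_to_total(self):
        rng = np.random.default_rng(15)
        z = ig.standardize_estimates(rng.standard_normal(60))
        ses = 2 + 2 * rng.random(60)
        y = 100 + 3.75 * np.exp(z) + 2 * ses + 6 * rng.standard_normal(60)
        sens, outc = make_outcome_tables(z, y, ses)
        shares = ig.partial_r2(sens, outc)
        assert shares["smooth"] + shares["ses"] == pytest.approx(
            shares["total"], abs=1e-10
        )

    def test_null_ses_contributes_nothing(self):
        rng = np.random.default_rng(16)
        z = ig.standardize_estimates(rng.standard_normal(80))
        ses = 2 + 2 * rng.random(80)  # independent of z, no effect on y
        y = 100 + 3.75 * np.exp(z) + 5 * rng.standard_normal(80)
        sens, outc = make_outcome_tables(z, y, ses)
        shares = ig.partial_r2(sens, outc)
        assert abs(shares["ses"]) < 0.05
        assert shares["smooth"] > 0.2


class TestSubindexModels:
    def test_index_identical_to_fsiq_gives_identical_fit(self):
        rng = np.random.default_rng(17)
        z = ig.standardize_estimates(rng.standard_normal(40))
        ses = 2 + rng.random(40)
        y = 100 + 3.75 * np.exp(z) + 6 * rng.standard_normal(40)
        sens, outc = make_outcome_tables(z, y, ses, vci=y, vsi=y, wmi=y)
        gam = ig.fit_gam_outcome(sens, outc)
        sub = ig.fit_subindex_models(sens, outc)
        for idx in ("vci", "vsi", "wmi"):
            assert sub[idx].smooth_f == pytest.approx(gam.smooth_f)
            assert sub[idx].adjusted_r2 == pytest.approx(gam.adjusted_r2)

    def test_lower_noise_index_detects_effect_more_often(self):
        rng = np.random.default_rng(18)
        quiet_wins = 0
        for rep in range(15):
            z = ig.standardize_estimates(rng.standard_normal(60))
            ses = 2 + rng.random(60)
            signal = 3.75 * np.exp(z)
            quiet = 100 + signal + 4 * rng.standard_normal(60)
            noisy = 100 + signal + 20 * rng.standard_normal(60)
            sens, outc = make_outcome_tables(z, quiet, ses, vci=quiet, vsi=noisy, wmi=quiet)
            sub = ig.fit_subindex_models(sens, outc)
            quiet_wins += sub["vci"].smooth_p <= sub["vsi"].smooth_p
        assert quiet_wins >= 11


class TestGroupLevelMixedModels:
    def test_looking_lmm_recovers_generating_ig_effect(self, design, metrics, small_cohort):
        infants, records = small_cohort
        res = ig.fit_looking_lmm(records, metrics)
        truth = np.mean([p.sensitivity_ig for p in infants])
        row = res.coef("information_gain_z")
        # generating effect inside a generous confidence band
        assert abs(row["estimate"] - truth) < 4 * row["se"]
        assert res.coef("trial_index")["estimate"] < 0

    def test_latency_lmm_exact_under_noise_free_generation(self, design, metrics):
        from test_simulate import zeroed_hyperparams

        infants = ig.simulate_infants(n=6, hyperparams=zeroed_hyperparams(), seed=0)
        records = ig.simulate_study(design, metrics, infants, seed=1, truncate=False)
        res = ig.fit_latency_lmm(records)
        assert res.coef("unpredictable")["estimate"] == pytest.approx(180.0, abs=1.0)
        assert res.coef("unpredictable")["pvalue"] < 1e-6

    def test_latency_lmm_rejects_single_level_trial_type(self, metrics):
        from igsense.task import DesignConfig
        from test_simulate import zeroed_hyperparams

        design = ig.generate_design(
            DesignConfig(predictability_counts={1.00: 16}), seed=0
        )
        m = ig.compute_design_metrics(design)
        infants = ig.simulate_infants(n=4, hyperparams=zeroed_hyperparams(), seed=0)
        records = ig.simulate_study(design, m, infants, seed=1, truncate=False)
        with pytest.raises(ValueError, match="single level"):
            ig.fit_latency_lmm(records)

    def test_looking_lmm_rejects_collinear_metrics(self, design, metrics, small_cohort):
        _, records = small_cohort
        broken = metrics.copy()
        broken["surprise"] = broken["information_gain"]
        with pytest.raises(ValueError, match="collinear"):
            ig.fit_looking_lmm(records, broken)
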