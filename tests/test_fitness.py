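"""NB GLM fitting, dispersion shrinkage, contrasts, moderated testing, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import barseqfit as bf
from barseqfit.fitness import (
    build_design,
    estimate_dispersions,
    fit_nb_glm,
    fitness_contrasts,
    squeeze_var,
)
from barseqfit.fitness import test_contrast as contrast_test


def _design_and_offsets(sheet, counts, intercept=False, reference=None):
    design = build_design(sheet, intercept=intercept, reference=reference)
    offsets = pd.Series(0.0, index=counts.columns)
    return design, offsets


class TestBuildDesign:
    def test_cell_means_shape_and_rank(self, two_condition_sheet):
        d = build_design(two_condition_sheet)
        assert d.X.shape == (12, 4)
        assert np.linalg.matrix_rank(d.X.to_numpy()) == 4
        assert set(d.cells.values()) == {
            ("control", "T1"), ("control", "T3"), ("copper", "T1"), ("copper", "T3")
        }

    def test_intercept_variant_same_rank_with_baseline(self, two_condition_sheet):
        d = build_design(two_condition_sheet, intercept=True, reference="control")
        assert d.X.shape == (12, 4)
        assert "(Intercept)" in d.X.columns
        assert np.linalg.matrix_rank(d.X.to_numpy()) == 4

    def test_encodings_give_identical_fitted_cell_means(self, two_condition_sheet):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.poisson(200, size=(6, 12)),
            index=[f"S{i}" for i in range(6)],
            columns=two_condition_sheet["sample"],
        )
        lfcs = []
        for intercept in (False, True):
            d, o = _design_and_offsets(
                two_condition_sheet, counts, intercept, "control"
            )
            fit = fit_nb_glm(counts, d, 0.05, o)
            c = fitness_contrasts(d, "control")["copper-vs-control"]
            lfcs.append(contrast_test(fit, c)["logFC"])
        assert np.abs(lfcs[0] - lfcs[1]).max() < 1e-8

    def test_missing_cell_is_named_in_error(self, two_condition_sheet):
        sheet = two_condition_sheet[
            ~((two_condition_sheet.treatment == "copper")
              & (two_condition_sheet.time == "T3"))
        ]
        d = build_design(sheet)
        with pytest.raises(ValueError, match="copper.*T3"):
            fitness_contrasts(d, "control")


class TestEstimateDispersions:
    def test_poisson_counts_give_near_zero_common_dispersion(
        self, two_condition_sheet
    ):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(
            rng.poisson(300, size=(80, 12)),
            index=[f"S{i}" for i in range(80)],
            columns=two_condition_sheet["sample"],
        )
        d, o = _design_and_offsets(two_condition_sheet, counts)
        disp = estimate_dispersions(counts, d, o)
        assert disp.common <= 0.01

    def test_nb_dispersion_recovered_within_20_percent(self, two_condition_sheet):
        rng = np.random.default_rng(5)
        phi = 0.1
        mu = 500.0
        counts = pd.DataFrame(
            rng.negative_binomial(1 / phi, 1 / (1 + phi * mu), size=(300, 12)),
            index=[f"S{i}" for i in range(300)],
            columns=two_condition_sheet["sample"],
        )
        d, o = _design_and_offsets(two_condition_sheet, counts)
        disp = estimate_dispersions(counts, d, o)
        assert float(disp.shrunk.median()) == pytest.approx(phi, rel=0.2)

    def test_shrunk_value_lies_between_raw_and_common(self, two_condition_sheet):
        rng = np.random.default_rng(6)
        counts = pd.DataFrame(
            rng.poisson(300, size=(40, 12)),
            index=[f"S{i}" for i in range(40)],
            columns=two_condition_sheet["sample"],
        )
        # one wildly overdispersed strain
        phi = 2.0
        counts.iloc[0] = rng.negative_binomial(1 / phi, 1 / (1 + phi * 300), 12)
        d, o = _design_and_offsets(two_condition_sheet, counts)
        disp = estimate_dispersions(counts, d, o)
        raw0, shrunk0 = disp.raw.iloc[0], disp.shrunk.iloc[0]
        assert disp.common < shrunk0 < raw0

    def test_zero_residual_df_warns_and_uses_common(self):
        sheet = pd.DataFrame(
            {
                "sample": ["a", "b"],
                "treatment": ["c", "c"],
                "time": ["T1", "T3"],
                "replicate": [1, 1],
            }
        )
        counts = pd.DataFrame({"a": [10], "b": [20]}, index=["S1"])
        d, o = _design_and_offsets(sheet, counts)
        with pytest.warns(UserWarning, match="zero residual df"):
            disp = estimate_dispersions(counts, d, o)
        assert (disp.shrunk == disp.common).all()


class TestFitNbGlm:
    def test_single_cell_fitted_mean_is_arithmetic_mean(self):
        sheet = pd.DataFrame(
            {
                "sample": ["a", "b", "c"],
                "treatment": ["x", "x", "x"],
                "time": ["T1", "T1", "T1"],
                "replicate": [1, 2, 3],
            }
        )
        counts = pd.DataFrame({"a": [10], "b": [20], "c": [30]}, index=["S1"])
        d, o = _design_and_offsets(sheet, counts)
        fit = fit_nb_glm(counts, d, 0.1, o)
        assert float(np.exp(fit.coef.iloc[0, 0])) == pytest.approx(20.0, abs=1e-9)

    def test_two_cell_contrast_is_log2_ratio_of_means(self, two_condition_sheet):
        sheet = two_condition_sheet[two_condition_sheet.treatment == "control"]
        counts = pd.DataFrame(
            {s: [10 if "T1" in s else 40] for s in sheet["sample"]}, index=["S1"]
        )
        d, o = _design_and_offsets(sheet, counts)
        fit = fit_nb_glm(counts, d, 0.05, o)
        c = fitness_contrasts(d, "control")["control:T3-T1"]
        assert float(contrast_test(fit, c)["logFC"].iloc[0]) == pytest.approx(
            2.0, abs=1e-9
        )

    def test_coefficients_match_direct_likelihood_maximization(
        self, two_condition_sheet
    ):
        # independent oracle: generic numerical maximization of the NB
        # log-likelihood; offsets constant within cells so the MLE and the
        # cell-mean estimator coincide
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(
            rng.poisson([150, 450, 80, 900] * 3, size=(1, 12)),
            index=["S1"],
            columns=two_condition_sheet.sort_values(["treatment", "time"])["sample"],
        )
        sheet = two_condition_sheet.set_index("sample").loc[counts.columns].reset_index()
        phi = 0.05
        d, o = _design_and_offsets(sheet, counts)
        fit = fit_nb_glm(counts, d, phi, o)
        X = d.X.loc[counts.columns].to_numpy()
        y = counts.iloc[0].to_numpy(dtype=float)

        def negll(beta):
            mu = np.exp(X @ beta)
            r = 1 / phi
            return -np.sum(
                stats.nbinom.logpmf(y, r, r / (r + mu))
            )

        res = optimize.minimize(negll, np.full(4, np.log(y.mean())), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        np.testing.assert_allclose(fit.coef.iloc[0].to_numpy(), res.x, atol=1e-6)

    def test_zero_cell_strain_is_flagged_with_fallback_logfc(
        self, two_condition_sheet
    ):
        counts = pd.DataFrame(
            {s: [0 if ("copper" in s and "T3" in s) else 100]
             for s in two_condition_sheet["sample"]},
            index=["S1"],
        )
        d, o = _design_and_offsets(two_condition_sheet, counts)
        fit = fit_nb_glm(counts, d, 0.05, o)
        c = fitness_contrasts(d, "control")["copper-vs-control"]
        res = contrast_test(fit, c)
        assert bool(res["flagged"].iloc[0])
        assert np.isnan(res["PValue"].iloc[0])
        assert np.isfinite(res["logFC"].iloc[0]) and res["logFC"].iloc[0] < 0


class TestFitnessContrasts:
    def test_time_constant_reference_counts_give_zero_logfc(
        self, two_condition_sheet
    ):
        counts = pd.DataFrame(
            {s: [250] for s in two_condition_sheet["sample"]}, index=["S1"]
        )
        d, o = _design_and_offsets(two_condition_sheet, counts)
        fit = fit_nb_glm(counts, d, 0.02, o)
        cons = fitness_contrasts(d, "control")
        for c in cons.values():
            assert abs(float(contrast_test(fit, c)["logFC"].iloc[0])) < 1e-12

    def test_identical_temporal_scaling_cancels_in_treatment_fitness(
        self, two_condition_sheet
    ):
        counts = pd.DataFrame(
            {s: [100 if "T1" in s else 700] for s in two_condition_sheet["sample"]},
            index=["S1"],
        )
        d, o = _design_and_offsets(two_condition_sheet, counts)
        fit = fit_nb_glm(counts, d, 0.02, o)
        c = fitness_contrasts(d, "control")["copper-vs-control"]
        assert abs(float(contrast_test(fit, c)["logFC"].iloc[0])) < 1e-12

    def test_simulated_selection_recovered_as_s_times_generations(self):
        # one carrier at s=0.1 over ~16 generations -> 1.6 log2 units,
        # recovered as the mean over replicate simulations
        lib = bf.make_barcode_library(40, seed=30)
        strains = bf.make_strain_pool(lib, bias_fold_range=22.0, seed=31)
        fm = bf.FitnessMap.neutral(lib.strain_ids, ["control", "treatment"])
        fm.table.loc["S001", "treatment"] = 0.1
        ests = []
        for seed in range(50):
            exp = bf.simulate_experiment(
                bf.SerialBatchDesign(seed=700 + seed, depth=30_000),
                strains=strains, fitness=fm, library=lib,
            )
            res = bf.fit_fitness(exp.counts, exp.sample_sheet, reference="control")
            ests.append(res.wide_logfc().loc["S001", "treatment-vs-control"])
        assert np.mean(ests) == pytest.approx(1.6, abs=0.1)


class TestTestContrast:
    def test_null_pvalues_are_approximately_uniform(self):
        # pooled over 5 simulations to test the calibration property rather
        # than one draw's sampling noise (the 5% KS critical value at n=80
        # is itself 0.152)
        pvals = []
        for seed in range(5):
            exp = bf.simulate_experiment(
                bf.SerialBatchDesign(seed=40 + seed, depth=30_000), n_strains=80
            )
            res = bf.fit_fitness(exp.counts, exp.sample_sheet, reference="control")
            pvals.append(
                res.table.loc[
                    res.table.contrast == "treatment-vs-control", "PValue"
                ].dropna()
            )
        p = pd.concat(pvals)
        assert stats.kstest(p, "uniform").statistic < 0.15

    def test_constant_counts_give_zero_statistic_unit_pvalue(
        self, two_condition_sheet
    ):
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(
            rng.poisson(300, size=(10, 12)),
            index=[f"S{i}" for i in range(10)],
            columns=two_condition_sheet["sample"],
        )
        counts.iloc[0] = 300  # identical in every sample of every cell
        d, o = _design_and_offsets(two_condition_sheet, counts)
        fit = fit_nb_glm(counts, d, 0.02, o)
        c = fitness_contrasts(d, "control")["copper-vs-control"]
        res = contrast_test(fit, c)
        assert float(res["F"].iloc[0]) == pytest.approx(0.0, abs=1e-18)
        assert float(res["PValue"].iloc[0]) == pytest.approx(1.0)

    def test_power_to_detect_large_shift_at_depth_1e4(self):
        lib = bf.make_barcode_library(30, seed=50)
        strains = bf.make_strain_pool(lib, bias_fold_range=1.0, seed=51)
        fm = bf.FitnessMap.neutral(lib.strain_ids, ["control", "treatment"])
        fm.table.loc["S001", "treatment"] = 0.15
        exp = bf.simulate_experiment(
            bf.SerialBatchDesign(seed=52, depth=10_000),
            strains=strains, fitness=fm, library=lib,
        )
        res = bf.fit_fitness(exp.counts, exp.sample_sheet, reference="control")
        t = res.table[res.table.contrast == "treatment-vs-control"]
        assert float(t.set_index("strain_id").loc["S001", "PValue"]) < 0.01


class TestSqueezeVar:
    def test_posterior_lies_between_raw_and_prior(self):
        rng = np.random.default_rng(9)
        df = 8.0
        s2 = 0.5 * rng.chisquare(df, size=200) / df
        post, d0, s02 = squeeze_var(s2, df)
        assert d0 > 0 and s02 > 0
        lo = np.minimum(s2, s02) - 1e-12
        hi = np.maximum(s2, s02) + 1e-12
        assert ((post >= lo) & (post <= hi)).all()


class TestAdjustFdr:
    def test_hand_computed_step_up(self):
        out = bf.adjust_fdr(np.array([0.01, 0.02, 0.03]))
        np.testing.assert_allclose(out, [0.03, 0.03, 0.03])

    def test_all_unit_pvalues_stay_unit(self):
        assert (bf.adjust_fdr(np.ones(5)) == 1.0).all()

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=100)
        # independent oracle: literal BH step-up definition
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        np.testing.assert_allclose(bf.adjust_fdr(p), adj, rtol=1e-12)

    def test_na_pvalues_excluded_from_denominator(self):
        p = pd.Series([0.01, np.nan, 0.04])
        out = bf.adjust_fdr(p)
        assert np.isnan(out.iloc[1])
        np.testing.assert_allclose(out[[0, 2]], [0.02, 0.04])

    def test_fdr_monotone_in_p_within_contrast(self):
        rng = np.random.default_rng(11)
        p = pd.Series(rng.uniform(size=50))
        out = bf.adjust_fdr(p)
        srt = out[np.argsort(p.to_numpy())].to_numpy()
        assert (np.diff(srt) >= -1e-15).all()
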