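"""Tests for microcosm processing and mixed-model inference."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cwmfd import GeneratorConfig, default_pool, generate_experiment
from cwmfd.microcosm_analysis import (
    MicrocosmRecord,
    aicc,
    all_subsets_aicc,
    assemblage_mean_regressions,
    corrected_abundances,
    fit_lmm,
    mass_loss,
    microbial_correction,
    monoculture_consumption_rate,
    mortality_rate,
    process_microcosms,
)


def rec(mid="m1", aid="a1", start=None, dead=None, li=7000.0, lf=5000.0, d=56.0):
    return MicrocosmRecord(
        microcosm_id=mid,
        assemblage_id=aid,
        start_counts=start if start is not None else {"Ps": 8},
        dead_counts=dead or {},
        litter_initial_mg=li,
        litter_final_mg=lf,
        duration_days=d,
    )


class TestMassLoss:
    @pytest.mark.parametrize(
        "initial, final, expected",
        [(7000, 4200, 40.0), (7000, 7000, 0.0), (7000, 5250, 25.0)],
    )
    def test_percentage(self, initial, final, expected):
        assert mass_loss(rec(li=initial, lf=final)) == pytest.approx(expected)

    def test_final_above_initial_rejected(self):
        with pytest.raises(ValueError):
            rec(li=5000, lf=5001)


class TestMortality:
    @pytest.mark.parametrize(
        "dead, expected, excluded",
        [(2, 0.25, False), (4, 0.50, False), (5, 0.625, True)],
    )
    def test_rate_and_strict_exclusion(self, pool, dead, expected, excluded):
        r = rec(start={"Ps": 8}, dead={"Ps": dead})
        assert mortality_rate(r) == pytest.approx(expected)
        proc = process_microcosms([r], pool, microbial_rate=0.0)
        assert bool(proc.loc[0, "excluded"]) is excluded

    def test_dead_above_start_rejected(self):
        with pytest.raises(ValueError):
            rec(start={"Ps": 3}, dead={"Ps": 4})


class TestMicrobialCorrection:
    def test_hand_computed(self):
        r = rec(li=7000, lf=4200, d=56)  # loss 2800 mg
        assert microbial_correction(r, 30.38) == pytest.approx(1098.72)

    def test_floored_at_zero(self):
        r = rec(li=7000, lf=6900, d=56)  # loss 100 < 30.38*56
        assert microbial_correction(r, 30.38) == 0.0

    def test_zero_rate_is_identity(self):
        r = rec(li=7000, lf=4200)
        assert microbial_correction(r, 0.0) == pytest.approx(2800.0)

    def test_rate_estimated_from_blanks(self, pool):
        blanks = [
            rec(mid=f"b{i}", aid="blank", start={}, li=7000, lf=7000 - 30 * 56)
            for i in range(3)
        ]
        proc = process_microcosms(blanks + [rec(li=7000, lf=4200)], pool)
        assert proc.attrs["microbial_rate_mg_day"] == pytest.approx(30.0)
        got = proc.set_index("microcosm_id").loc["m1", "isopod_consumption_mg"]
        assert got == pytest.approx(2800 - 30 * 56)


class TestMonocultureRate:
    def test_hand_computed_single_record(self, pool):
        r = rec(aid="Ps", start={"Ps": 10}, li=7000, lf=4200, d=56)
        proc = process_microcosms([r], pool, microbial_rate=30.38)
        out = monoculture_consumption_rate(proc)
        # 1098.72 / (10 * 56)
        assert out.loc[0, "rate_mean"] == pytest.approx(1.962, abs=1e-3)

    def test_zero_consumption_gives_zero_rate(self, pool):
        r = rec(aid="Ps", start={"Ps": 10}, li=7000, lf=6950, d=56)
        proc = process_microcosms([r], pool, microbial_rate=30.38)
        assert monoculture_consumption_rate(proc).loc[0, "rate_mean"] == 0.0

    def test_generator_round_trip_recovers_species_mean(self, pool):
        """Monoculture stream regenerates the P. scaber rate within 3 SE."""
        cfg = GeneratorConfig(seed=7)
        records, _ = generate_experiment({}, pool, cfg)
        proc = process_microcosms(records, pool, microbial_rate=cfg.microbial_rate_mean)
        out = monoculture_consumption_rate(proc).set_index("species_id")
        ps = pool["Ps"]
        n_ind, reps = cfg.monoculture_individuals, cfg.replicates
        # per-record rate noise: individual draws plus the microbial residual
        var_ind = ps.consumption_sd**2 / n_ind
        var_micro = (cfg.microbial_rate_sd / n_ind) ** 2
        se = np.sqrt((var_ind + var_micro) / reps)
        assert abs(out.loc["Ps", "rate_mean"] - ps.consumption_rate) < 3 * se


class TestCorrectedMetrics:
    def test_no_deaths_matches_design_metrics(self, pool, dissim):
        from cwmfd.functional_metrics import cwm, rao_fdiv

        counts = {"Oa": 2, "Av": 6}
        r = rec(start=counts)
        proc = process_microcosms([r], pool, microbial_rate=0.0)
        assert proc.loc[0, "cwm_mg_day"] == pytest.approx(
            cwm(counts, pool, "consumption_rate")
        )
        assert proc.loc[0, "fdiv_corrected"] == pytest.approx(rao_fdiv(counts, dissim))

    def test_half_death_weighting_hand_computed(self, pool):
        r = rec(start={"Oa": 2, "Av": 6}, dead={"Av": 2})
        proc = process_microcosms([r], pool, microbial_rate=0.0)
        # effective (2, 5): (2*0.87 + 5*1.80) / 7
        assert proc.loc[0, "cwm_mg_day"] == pytest.approx(1.534285, abs=1e-5)
        assert proc.loc[0, "cwm_g_cum"] == pytest.approx(1.534285 * 56 / 1000, abs=1e-6)

    def test_survivor_mode_and_richness_drop(self, pool):
        r = rec(start={"Oa": 2, "Av": 6}, dead={"Oa": 2})
        half = process_microcosms([r], pool, microbial_rate=0.0)
        surv = process_microcosms([r], pool, microbial_rate=0.0, dead_correction="survivors")
        assert half.loc[0, "richness"] == 2  # 0.5 * 2 dead leaves Oa present
        assert surv.loc[0, "richness"] == 1
        assert surv.loc[0, "cwm_mg_day"] == pytest.approx(1.80)
        assert corrected_abundances(r, "survivors") == {"Oa": 0, "Av": 6}


def _lmm_frame(y, x, groups):
    n = len(y)
    return pd.DataFrame(
        {
            "mass_loss_isopod_pct": y,
            "cwm_g_cum": x,
            "fdiv_corrected": 0.0,
            "richness": 2,
            "assemblage_id": groups,
        }
    )


class TestFitLMM:
    def test_matches_ols_closed_form_without_group_variance(self):
        """Data whose residuals have zero between-group means force the
        random-intercept variance to its boundary; the ML log-likelihood
        then equals the closed-form Gaussian OLS log-likelihood."""
        rng = np.random.default_rng(0)
        groups = np.repeat([f"a{j}" for j in range(8)], 10)
        x = np.repeat(rng.uniform(0, 1, 8), 10)
        eps = rng.normal(0, 2.0, 80)
        eps -= pd.Series(eps).groupby(pd.Series(groups)).transform("mean").to_numpy()
        y = 1.0 + 3.0 * x + eps
        fit = fit_lmm(_lmm_frame(y, x, groups), ("CWM",))

        X = np.column_stack([np.ones(80), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        sigma2 = resid @ resid / 80
        ll_ols = -0.5 * 80 * (np.log(2 * np.pi * sigma2) + 1)
        assert fit.loglik == pytest.approx(ll_ols, abs=1e-4)
        assert fit.sigma_u == pytest.approx(0.0, abs=1e-3)

    def test_null_model_intercept_is_grand_mean_when_balanced(self):
        rng = np.random.default_rng(1)
        groups = np.repeat([f"a{j}" for j in range(6)], 5)
        y = rng.normal(10, 2, 30)
        fit = fit_lmm(_lmm_frame(y, 0.0, groups), ())
        assert fit.params["Intercept"] == pytest.approx(y.mean(), abs=1e-6)
        assert fit.k == 3

    def test_nested_loglik_monotone(self, processed):
        """ML log-likelihood never decreases when a fixed-effect set grows."""
        fits = {}
        for r in range(4):
            for s in itertools.combinations(("CWM", "FDiv", "SR"), r):
                fits[s] = fit_lmm(
                    processed[processed.treatment == "assemblage"], s
                ).loglik
        for s, ll in fits.items():
            for t, ll_t in fits.items():
                if set(s) < set(t):
                    assert ll_t >= ll - 1e-6

    def test_unknown_term_errors(self, processed):
        with pytest.raises(ValueError, match="unknown fixed effects"):
            fit_lmm(processed, ("Biomass",))


class TestAICc:
    def test_formula_hand_computed(self):
        # -2*(-10) + 2*2 + 2*2*3/(10-3)
        assert aicc(-10.0, 2, 10) == pytest.approx(25.714286, abs=1e-6)

    def test_reduces_to_aic_for_large_n(self):
        assert aicc(-10.0, 2, 10**6) == pytest.approx(20 + 4, abs=1e-4)

    def test_undefined_when_sample_too_small(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


class TestAllSubsets:
    def test_eight_models_sorted_weights_sum_to_one(self, processed):
        ms = all_subsets_aicc(processed)
        t = ms.table
        assert len(t) == 8
        assert t.AICc.is_monotonic_increasing
        assert t.weight.sum() == pytest.approx(1.0)
        assert ((t.weight > 0) & (t.weight <= 1)).all()
        assert "Massloss~1" in set(t.model)  # null model present
        assert t.loc[t.model == "Massloss~1", "k"].iloc[0] == 3

    def test_n_counts_only_kept_assemblage_records(self, processed):
        ms = all_subsets_aicc(processed)
        kept = processed[(processed.treatment == "assemblage") & ~processed.excluded]
        assert ms.n == len(kept)

    def test_equal_aicc_pair_splits_weight(self):
        # two models with equal AICc and no others -> weights 0.5 each
        d = np.array([0.0, 0.0])
        w = np.exp(-d / 2) / np.exp(-d / 2).sum()
        assert np.allclose(w, [0.5, 0.5])


class TestAssemblageRegressions:
    def test_collinear_points_fit_exactly(self, pool):
        rows = []
        for i, aid in enumerate(["a1", "a2", "a3"]):
            rows.append(
                {
                    "assemblage_id": aid,
                    "treatment": "assemblage",
                    "excluded": False,
                    "mass_loss_isopod_pct": float(i),
                    "cwm_g_cum": float(i),
                    "fdiv_corrected": 0.5,
                    "richness": 2 + i,
                }
            )
        out = assemblage_mean_regressions(pd.DataFrame(rows)).set_index("predictor")
        assert out.loc["CWM", "slope"] == pytest.approx(1.0)
        assert out.loc["CWM", "r_squared"] == pytest.approx(1.0)
        assert np.isnan(out.loc["FDiv", "slope"])  # constant predictor

    def test_too_few_assemblages_errors(self, processed):
        two = processed[processed.assemblage_id.isin(["HH1", "HL1"])]
        with pytest.raises(ValueError, match=">= 3 assemblages"):
            assemblage_mean_regressions(two)
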