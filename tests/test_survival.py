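"""Kaplan-Meier, log-rank, Cox (Efron), Table-1 analysis and nomination."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from dgcproteo.io import AnnotationTable, ClinicalTable
from dgcproteo.quantify import RatioMatrix
from dgcproteo.survival import (
    cox_fit,
    kaplan_meier,
    logrank_test,
    nominate_genomic_targets,
    nominate_proteomic_targets,
    protein_survival_screen,
    table1_analysis,
    upper_quartile_flag,
)


def efron_loglik_oracle(beta, x, times, events):
    """Loop-based Efron partial log-likelihood for one covariate."""
    eta = beta * np.asarray(x, dtype=float)
    w = np.exp(eta)
    ll = 0.0
    for t in sorted(set(times[events == 1])):
        risk = times >= t
        dead = (times == t) & (events == 1)
        d = int(dead.sum())
        s0 = w[risk].sum()
        s0d = w[dead].sum()
        ll += eta[dead].sum()
        for ell in range(d):
            ll -= np.log(s0 - ell / d * s0d)
    return ll


class TestKaplanMeier:
    def test_no_events_curve_stays_at_one(self):
        km = kaplan_meier([5, 8, 12], [0, 0, 0])
        assert float(km.survival_function_at_times(12).iloc[0]) == 1.0

    def test_two_deaths(self):
        km = kaplan_meier([1, 2], [1, 1])
        assert float(km.survival_function_at_times(1).iloc[0]) == pytest.approx(0.5)
        assert float(km.survival_function_at_times(2).iloc[0]) == pytest.approx(0.0)

    def test_hand_product_limit_with_censoring(self):
        # deaths at 2, 5, 8; censored at 3 and 6; alive past 10
        times = np.array([2.0, 3.0, 5.0, 6.0, 8.0, 10.0])
        events = np.array([1, 0, 1, 0, 1, 0])
        km = kaplan_meier(times, events)
        # S(2)=5/6, S(5)=5/6*3/4, S(8)=5/6*3/4*1/2
        assert float(km.survival_function_at_times(2).iloc[0]) == pytest.approx(5 / 6)
        assert float(km.survival_function_at_times(5).iloc[0]) == pytest.approx(5 / 8)
        assert float(km.survival_function_at_times(8).iloc[0]) == pytest.approx(5 / 16)


class TestLogrank:
    def test_identical_groups(self):
        times = np.array([1, 2, 3, 1, 2, 3], dtype=float)
        events = np.array([1, 1, 0, 1, 1, 0])
        groups = np.array([0, 0, 0, 1, 1, 1])
        res = logrank_test(times, events, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_hand_computed_two_group_toy(self):
        # group A deaths at 1, 2; group B deaths at 3, 4; no censoring
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 1, 1])
        groups = np.array(["A", "A", "B", "B"])
        res = logrank_test(times, events, groups)
        assert res.statistic == pytest.approx(49 / 17)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [1, 1], ["A", "A"])

    def test_trend_weights_boost_ordered_hazards(self):
        rng = np.random.default_rng(0)
        stats_ordered, stats_scrambled = [], []
        for _ in range(20):
            n = 120
            g = rng.integers(1, 4, size=n)
            t = -np.log(rng.random(n)) / np.exp(0.5 * (g - 1))
            e = np.ones(n, dtype=int)
            stats_ordered.append(logrank_test(t, e, g, trend_weights=[1, 2, 3]).statistic)
            stats_scrambled.append(logrank_test(t, e, g, trend_weights=[2, 1, 3]).statistic)
        assert np.mean(stats_ordered) > np.mean(stats_scrambled)

    def test_score_identity_with_binary_cox(self):
        rng = np.random.default_rng(1)
        n = 200
        x = (rng.random(n) < 0.5).astype(float)
        t = -np.log(rng.random(n)) / np.exp(0.6 * x)
        c = rng.uniform(0.2, 3.0, size=n)
        times, events = np.minimum(t, c), (t <= c).astype(int)
        lr = logrank_test(times, events, x)
        fit = cox_fit(pd.DataFrame({"x": x}), times, events)
        wald_chi2 = float(fit.coefficients["z"].iloc[0]) ** 2
        assert lr.statistic == pytest.approx(wald_chi2, rel=0.10)


class TestCox:
    def test_balanced_groups_zero_coefficient(self):
        times = np.array([1, 2, 3, 4, 1, 2, 3, 4], dtype=float)
        events = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        fit = cox_fit(pd.DataFrame({"x": x}), times, events)
        assert fit.coef.iloc[0] == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_grid_search_oracle_on_small_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 9))
        x = rng.normal(size=n)
        times = np.sort(rng.uniform(1, 10, size=n))  # distinct -> no ties
        events = rng.random(n) < 0.7
        events[0] = True
        fit = cox_fit(pd.DataFrame({"x": x}), times, events.astype(int))
        # two-stage grid maximization of the loop-based partial likelihood
        grid = np.arange(-6.0, 6.0, 1e-3)
        ll = [efron_loglik_oracle(b, x, times, events.astype(int)) for b in grid]
        best = grid[int(np.argmax(ll))]
        fine = np.arange(best - 2e-3, best + 2e-3, 1e-7)
        llf = [efron_loglik_oracle(b, x, times, events.astype(int)) for b in fine]
        best = fine[int(np.argmax(llf))]
        assert fit.coef.iloc[0] == pytest.approx(best, abs=1e-6)

    def test_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(7)
        n = 150
        x = rng.normal(size=n)
        g = (rng.random(n) < 0.4).astype(float)
        t = np.ceil(5 * -np.log(rng.random(n)) / np.exp(0.5 * x - 0.3 * g))
        e = (rng.random(n) < 0.75).astype(int)
        df = pd.DataFrame({"x": x, "g": g, "T": t, "E": e})
        fit = cox_fit(df[["x", "g"]], t, e)
        cph = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit.coef.to_numpy(), cph.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(
            fit.coefficients["se"].to_numpy(), cph.standard_errors_.to_numpy(), atol=1e-5
        )

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(pd.DataFrame({"x": [1.0, 1.0, 1.0]}), [1, 2, 3], [1, 1, 0])

    def test_complete_separation_capped_with_warning(self, caplog):
        times = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        events = np.ones(6, dtype=int)
        x = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        fit = cox_fit(pd.DataFrame({"x": x}), times, events)
        assert fit.separation
        assert abs(fit.coef.iloc[0]) <= 15.0


class TestTable1:
    def _clinical(self, seed=0, n=150, trend=0.8):
        from dgcproteo.simulate import CohortConfig, SurvivalSpec, generate_cohort

        cfg = CohortConfig(
            seed=seed,
            n_patients=n,
            survival=SurvivalSpec(
                subtype_trend_ln_hr=trend, target_ln_hr=0.0, protective_ln_hr=0.0
            ),
        )
        return generate_cohort(cfg).clinical

    def test_single_covariate_model_equals_cox_fit(self):
        clin = self._clinical()
        fits = table1_analysis(clin)
        direct = cox_fit(
            clin.data[["age"]].astype(float),
            clin.data["os_months"],
            clin.data["event"],
        )
        assert fits["univariate"]["age"].coef.iloc[0] == pytest.approx(
            direct.coef.iloc[0]
        )

    def test_planted_trend_recovered_within_ci(self):
        clin = self._clinical(seed=3, n=200, trend=1.0)
        fits = table1_analysis(clin)
        tab = fits["multivariate_trend"].coefficients.loc["subtype_trend"]
        lo, hi = np.log(tab["ci_lower"]), np.log(tab["ci_upper"])
        assert lo <= 1.0 <= hi

    def test_requires_subtype_labels(self):
        clin = self._clinical()
        clin.data.drop(columns="subtype", inplace=True)
        with pytest.raises(ValueError, match="subtype"):
            table1_analysis(clin)


def _ratio_matrix(lr: pd.DataFrame) -> RatioMatrix:
    det = pd.DataFrame(True, index=lr.index, columns=lr.columns)
    return RatioMatrix(lr, det, det, ~det, ~det)


def _clinical_from(times, events, patients) -> ClinicalTable:
    n = len(patients)
    return ClinicalTable(
        pd.DataFrame(
            {
                "age": 60.0,
                "gender": ["male"] * n,
                "site": ["body"] * n,
                "stage": ["III"] * n,
                "chemo": 1,
                "os_months": times,
                "event": events,
            },
            index=patients,
        )
    )


class TestScreenAndNomination:
    def test_ln_hr_sign_flips_with_value_negation(self):
        rng = np.random.default_rng(2)
        patients = [f"P{i}" for i in range(40)]
        values = rng.normal(size=40)
        lr = pd.DataFrame([values], index=["A"], columns=patients)
        t = -np.log(rng.random(40)) / np.exp(0.8 * (values > np.median(values)))
        clin = _clinical_from(np.round(t + 0.1, 3), np.ones(40, dtype=int), patients)
        up = protein_survival_screen(_ratio_matrix(lr), clin)
        down = protein_survival_screen(_ratio_matrix(-lr), clin)
        assert up.loc["A", "ln_hr"] == pytest.approx(-down.loc["A", "ln_hr"], rel=1e-6)

    def test_rarely_detected_protein_skipped(self):
        patients = [f"P{i}" for i in range(10)]
        lr = pd.DataFrame([np.zeros(10)], index=["A"], columns=patients)
        det = pd.DataFrame(False, index=["A"], columns=patients)
        det.iloc[0, :4] = True
        ratios = RatioMatrix(lr, det, det, ~det, ~det)
        clin = _clinical_from(np.arange(1.0, 11.0), np.ones(10, dtype=int), patients)
        assert len(protein_survival_screen(ratios, clin)) == 0

    def _nomination_inputs(self):
        screen = pd.DataFrame(
            {
                "n": [84, 84, 84, 84],
                "ln_hr": [np.log(1.8), np.log(1.8), np.log(1.8), np.log(0.5)],
                "hr": [1.8, 1.8, 1.8, 0.5],
                "cox_p": [0.01, 0.01, 0.01, 0.01],
                "logrank_p": [0.01, 0.01, 0.01, 0.01],
                "skipped": False,
            },
            index=pd.Index(["HIT", "EDGE", "NODRUG", "PROT"], name="protein"),
        )
        over = pd.DataFrame(
            {"fraction_all": [0.6, 0.5, 0.6, 0.6], "fraction_detected": 0.7},
            index=screen.index,
        )
        anno = AnnotationTable(
            pd.DataFrame(
                {
                    "druggable": [True, True, False, True],
                    "category": ["kinase", "enzyme", "", "gpcr"],
                    "stomach_specific": False,
                    "genomic_target": [False, False, False, True],
                },
                index=screen.index,
            )
        )
        return screen, over, anno

    def test_proteomic_criteria_walkthrough(self):
        screen, over, anno = self._nomination_inputs()
        nom = nominate_proteomic_targets(over, anno, screen)
        assert "HIT" in nom.index  # druggable, 60% overexpressed, HR 1.8, p 0.01
        assert "EDGE" not in nom.index  # fraction exactly 0.5 -> strict >
        assert "NODRUG" not in nom.index  # not druggable
        assert "PROT" not in nom.index  # HR < 1

    def test_genomic_screen_annotates_without_survival_gate(self):
        screen, over, anno = self._nomination_inputs()
        gen = nominate_genomic_targets(screen, anno, over)
        assert list(gen.index) == ["PROT"]
        assert not bool(gen.loc["PROT", "survival_unfavorable"])
        assert bool(gen.loc["PROT", "better_os"])


class TestUpperQuartile:
    def test_linear_interpolation_quartile(self):
        values = pd.Series(np.arange(1.0, 9.0), index=[f"P{i}" for i in range(8)])
        high = upper_quartile_flag(values)
        # Q3 of 1..8 = 6.25 -> high are 7 and 8
        assert list(values.index[high]) == ["P6", "P7"]

    def test_all_equal_all_high(self):
        values = pd.Series([2.0] * 5)
        assert upper_quartile_flag(values).all()

    def test_undetected_excluded_from_percentile(self):
        values = pd.Series([1.0, 2.0, 3.0, 4.0, np.nan, np.nan])
        high = upper_quartile_flag(values)
        assert not high[4] and not high[5]
        assert high[3]

    def test_few_detected_all_low(self):
        values = pd.Series([1.0, 2.0, np.nan, np.nan])
        assert not upper_quartile_flag(values).any()
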