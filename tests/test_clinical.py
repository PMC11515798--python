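import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

import periomed as pm
from periomed.clinical import (
    apply_rate_ratio,
    encode_design,
    fit_logistic,
    fit_nb_outcome,
    fit_ordinal_mediator,
    median_dichotomize,
    prediction_grid,
    treat_to_target,
)


def records_from_pcts(pcts, sites=100, visit=26):
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(len(pcts))],
        "visit_month": visit,
        "sites_total": sites,
        "sites_ppd5": [int(p * sites) for p in pcts],
        "sites_bleeding": 0,
        "sites_al13": 0,
    })


class TestMedianDichotomize:
    def test_strictly_below_median_rule(self):
        rec = records_from_pcts([0.10, 0.20, 0.30])
        ind = median_dichotomize(rec, "ppd5", 26)
        assert ind.tolist() == [1, 0, 0]

    def test_all_equal_gives_all_zero(self):
        rec = records_from_pcts([0.2, 0.2, 0.2, 0.2])
        assert median_dichotomize(rec, "ppd5", 26).tolist() == [0, 0, 0, 0]

    def test_invariant_to_monotone_rescaling(self):
        rec = records_from_pcts([0.05, 0.1, 0.22, 0.4, 0.44])
        a = median_dichotomize(rec, "ppd5", 26)
        doubled = rec.assign(sites_total=rec.sites_total * 2)  # halves every pct
        b = median_dichotomize(doubled, "ppd5", 26)
        assert a.tolist() == b.tolist()

    def test_split_near_half_on_generated_data(self, default_cohort):
        rec = default_cohort.clinical
        ind = median_dichotomize(rec, "bleeding", 26)
        assert 0.45 <= ind.mean() <= 0.55

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match=">= 2 subjects"):
            median_dichotomize(records_from_pcts([0.1]), "ppd5", 26)


class TestTreatToTarget:
    @pytest.mark.parametrize("count, expected", [(0, True), (4, True), (5, False)])
    def test_boundary(self, count, expected):
        assert treat_to_target(count) is expected

    def test_vectorized(self):
        assert treat_to_target(pd.Series([3, 4, 5])).tolist() == [True, True, False]


def simulate_logistic(n, beta_per_01, seed):
    rng = np.random.default_rng(seed)
    normo = rng.uniform(0, 1, n)
    cov = pd.DataFrame({
        "age_band": rng.choice(["<45", "45<55", ">55"], n),
        "sex": rng.choice(["F", "M"], n),
        "smoking": rng.choice(["yes", "no"], n),
    })
    eta = -0.5 + beta_per_01 * (normo / 0.1)
    y = pd.Series((rng.random(n) < expit(eta)).astype(int))
    return y, pd.Series(normo), cov


class TestFitLogistic:
    def test_single_class_outcome_errors(self):
        y, x, cov = simulate_logistic(50, 0.0, 0)
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(pd.Series(np.ones(50, int)), x, cov)

    def test_null_effect_ci_coverage(self):
        covered = 0
        for s in range(100):
            y, x, cov = simulate_logistic(500, 0.0, 1000 + s)
            r = fit_logistic(y, x, cov)
            lo, hi = r.effects.loc["normobiotic_per_0.1", ["lower", "upper"]]
            covered += lo <= 1.0 <= hi
        assert covered >= 93

    def test_recovers_or_126(self):
        # per-0.1 odds ratio of 1.26: the study's strongest dysbiosis association
        logs = []
        for s in range(50):
            y, x, cov = simulate_logistic(2000, np.log(1.26), 2000 + s)
            logs.append(fit_logistic(y, x, cov).params["normobiotic_per_0.1"])
        m, se = np.mean(logs), np.std(logs, ddof=1) / np.sqrt(len(logs))
        assert abs(m - np.log(1.26)) < 3 * se

    def test_perfect_separation_names_variable(self):
        n = 40
        y = pd.Series([0] * 20 + [1] * 20)
        x = pd.Series(np.concatenate([np.zeros(20), np.ones(20)]))
        cov = pd.DataFrame({"age_band": ["<45"] * n, "sex": ["F"] * n,
                            "smoking": ["no"] * n})
        with pytest.raises(ValueError, match="separation"):
            fit_logistic(y, x, cov)


class TestFitOrdinalMediator:
    def test_null_treatment_effect(self):
        rng = np.random.default_rng(3)
        n = 2000
        t = pd.Series(rng.integers(0, 2, n))
        cat = pd.Series(rng.integers(0, 4, n))
        b = pd.Series(rng.integers(0, 2, n))
        r = fit_ordinal_mediator(cat, t, b, po_check=False)
        lo, hi = r.effects.loc["treatment", ["lower", "upper"]]
        assert lo <= 1.0 <= hi

    def test_degenerate_categories_error(self):
        with pytest.raises(ValueError, match="3 realized"):
            fit_ordinal_mediator(pd.Series([1] * 10), pd.Series([0, 1] * 5),
                                 pd.Series([0] * 10))

    def test_non_proportional_effects_flagged(self):
        # treatment effect differs wildly across thresholds
        rng = np.random.default_rng(4)
        n = 1500
        t = rng.integers(0, 2, n)
        p_ge = np.stack([
            expit(0.5 + 2.5 * t),
            expit(-0.5 - 1.5 * t),
            expit(-1.5 - 1.5 * t),
        ], axis=1)
        p_ge = np.minimum.accumulate(p_ge, axis=1)
        u = rng.random((n, 1))
        cat = (u < p_ge).sum(axis=1)
        r = fit_ordinal_mediator(pd.Series(cat), pd.Series(t),
                                 pd.Series(rng.integers(0, 2, n)))
        assert r.extra["prop_odds_flag"]

    def test_proportional_data_not_flagged(self, default_baseline_subjects):
        subj = default_baseline_subjects
        r = fit_ordinal_mediator(
            subj["category"], (subj["arm"] == "antibiotic").astype(int),
            subj["baseline_normobiotic"],
            subj[["age_band", "sex", "smoking"]],
        )
        assert not r.extra["prop_odds_flag"]


class TestFitNbOutcome:
    def simulate_counts(self, n, seed, sites_factor=1):
        rng = np.random.default_rng(seed)
        rec = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "sites_total": rng.integers(110, 160, n) * sites_factor,
            "arm": rng.choice(["antibiotic", "placebo"], n),
            "category": rng.integers(0, 4, n),
            "age_band": rng.choice(["<45", "45<55", ">55"], n),
            "sex": rng.choice(["F", "M"], n),
            "smoking": rng.choice(["yes", "no"], n),
        })
        eta = (np.log(0.055) + np.log(0.82) * (rec["arm"] == "antibiotic")
               + np.log(0.72) * rec["category"])
        mu = rec["sites_total"] * np.exp(eta)
        rec["sites_al13"] = rng.poisson(mu)
        return rec

    def test_poisson_limit_matches_poisson_glm(self):
        rec = self.simulate_counts(2000, 0)
        nb = fit_nb_outcome(rec, predictors=("treatment", "category"))
        X = sm.add_constant(encode_design(rec, ("treatment", "category")),
                            prepend=True)
        pois = sm.GLM(rec["sites_al13"], X, family=sm.families.Poisson(),
                      offset=np.log(rec["sites_total"].astype(float))).fit()
        assert nb.dispersion < 0.01
        assert np.allclose(nb.params[["treatment", "category"]],
                           pois.params[["treatment", "category"]], atol=0.01)

    def test_offset_invariance(self):
        a = fit_nb_outcome(self.simulate_counts(3000, 5),
                           predictors=("treatment", "category"))
        b = fit_nb_outcome(self.simulate_counts(3000, 5, sites_factor=2),
                           predictors=("treatment", "category"))
        for name in ("treatment", "category"):
            joint_se = np.hypot(a.bse[name], b.bse[name])
            assert abs(a.params[name] - b.params[name]) < 3 * joint_se

    def test_count_exceeding_sites_rejected(self):
        rec = self.simulate_counts(20, 1)
        rec.loc[0, "sites_al13"] = rec.loc[0, "sites_total"] + 1
        with pytest.raises(ValueError, match="exceeds"):
            fit_nb_outcome(rec, predictors=("treatment",))

    def test_needs_a_predictor(self):
        with pytest.raises(ValueError, match="at least one predictor"):
            fit_nb_outcome(self.simulate_counts(20, 1), predictors=())


@pytest.fixture(scope="module")
def nb_fit(default_final_records):
    return fit_nb_outcome(
        default_final_records,
        predictors=("treatment", "category", "age", "smoking"),
    )


class TestPredictionGrid:

    def test_multiplicative_along_every_axis(self, nb_fit):
        grid = prediction_grid(nb_fit, sites_total=146)
        arm_ratio = grid.pivot_table(index=["smoking", "age_band", "category"],
                                     columns="arm", values="expected_sites")
        ratios = arm_ratio["antibiotic"] / arm_ratio["placebo"]
        assert np.allclose(ratios, ratios.iloc[0])
        cat_tab = grid.pivot_table(index=["smoking", "age_band", "arm"],
                                   columns="category", values="expected_sites")
        steps = cat_tab[1] / cat_tab[0]
        assert np.allclose(steps, np.exp(nb_fit.params["category"]))

    def test_doubling_sites_doubles_cells(self, nb_fit):
        g1 = prediction_grid(nb_fit, sites_total=146)
        g2 = prediction_grid(nb_fit, sites_total=292)
        assert np.allclose(g2["expected_sites"], 2 * g1["expected_sites"])

    def test_unknown_age_level_errors(self, default_final_records):
        rec = default_final_records.copy()
        rec.loc[0, "age_band"] = "ancient"
        with pytest.raises(ValueError, match="age_band"):
            fit_nb_outcome(rec, predictors=("treatment", "age"))

    def test_worked_example_arithmetic(self):
        # a 19% treatment reduction applied to 8 expected sites
        assert round(apply_rate_ratio(8.0, 1 - 0.19), 1) == 6.5
        # the same reduction for a smoker at 14.91 expected sites
        assert round(14.91 - apply_rate_ratio(14.91, 1 - 0.19), 1) == 2.8
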