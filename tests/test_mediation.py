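import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import gamma

import periomed as pm
from periomed.mediation import (
    MEDIATOR,
    OUTCOME,
    TREATMENT,
    NBPriors,
    SamplerConfig,
    backdoor_adjustment_sets,
    build_study_dag,
    fit_bayesian_nb,
    mediation_difference,
    run_mediation_analysis,
)

from conftest import merge_final_visit


def brute_force_minimal_sets(dag, exposure, outcome, forbidden=()):
    """Oracle: test every candidate subset with networkx d-separation on the
    graph with the exposure's outgoing edges removed."""
    g = dag.copy()
    g.remove_edges_from(list(g.out_edges(exposure)))
    candidates = sorted(set(dag.nodes) - {exposure, outcome}
                        - nx.descendants(dag, exposure) - set(forbidden))
    valid = []
    for size in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            z = frozenset(combo)
            if any(v <= z for v in valid):
                continue
            if nx.is_d_separator(g, {exposure}, {outcome}, set(z)):
                valid.append(z)
    return sorted(valid, key=lambda s: (len(s), sorted(s)))


def dag_from_edges(edges):
    g = nx.DiGraph()
    g.add_edges_from(edges)
    return g


class TestStudyDag:
    def test_acyclic(self):
        assert nx.is_directed_acyclic_graph(build_study_dag())

    def test_treatment_is_randomized(self):
        dag = build_study_dag()
        assert list(dag.predecessors(TREATMENT)) == []

    def test_mediator_parents(self):
        dag = build_study_dag()
        assert set(dag.predecessors(MEDIATOR)) == {
            TREATMENT, "baseline_characteristics", "age", "sex", "smoking"}


class TestBackdoorSets:
    def test_study_dag_total_effect_unadjusted(self):
        sets = backdoor_adjustment_sets(build_study_dag(), TREATMENT, OUTCOME,
                                        forbidden=(MEDIATOR,))
        assert sets == [frozenset()]

    def test_study_dag_mediator_outcome_needs_confounders(self):
        sets = backdoor_adjustment_sets(build_study_dag(), MEDIATOR, OUTCOME)
        assert all({"age", "sex", "smoking"} <= s for s in sets)

    @pytest.mark.parametrize(
        "edges, exposure, outcome",
        [
            ([("Z", "A"), ("Z", "B"), ("A", "B")], "A", "B"),          # fork
            ([("A", "M"), ("M", "B")], "A", "B"),                       # chain
            ([("U1", "X"), ("U1", "C"), ("U2", "C"), ("U2", "Y"),
              ("X", "Y")], "X", "Y"),                                    # M-bias
            ([("W", "X"), ("W", "Y"), ("V", "X"), ("V", "Y"),
              ("X", "M"), ("M", "Y")], "X", "Y"),                        # two confounders
        ],
    )
    def test_matches_brute_force_oracle(self, edges, exposure, outcome):
        dag = dag_from_edges(edges)
        assert (backdoor_adjustment_sets(dag, exposure, outcome)
                == brute_force_minimal_sets(dag, exposure, outcome))

    def test_study_dag_matches_oracle_both_effects(self):
        dag = build_study_dag()
        for exposure, forbidden in [(TREATMENT, (MEDIATOR,)), (MEDIATOR, ())]:
            assert (backdoor_adjustment_sets(dag, exposure, OUTCOME, forbidden)
                    == brute_force_minimal_sets(dag, exposure, OUTCOME, forbidden))

    def test_forbidden_removes_only_option(self):
        dag = dag_from_edges([("Z", "A"), ("Z", "B"), ("A", "B")])
        assert backdoor_adjustment_sets(dag, "A", "B", forbidden=("Z",)) == []

    def test_exposure_equals_outcome_errors(self):
        with pytest.raises(ValueError):
            backdoor_adjustment_sets(build_study_dag(), TREATMENT, TREATMENT)


class TestBayesianNb:
    def test_posterior_agrees_with_ml(self, default_final_records):
        fit = fit_bayesian_nb(default_final_records,
                              predictors=("treatment", "category"),
                              sampler=SamplerConfig(seed=1))
        ml = pm.fit_nb_outcome(default_final_records,
                               predictors=("treatment", "category"))
        draws = fit.coefficient_draws("treatment")
        assert abs(np.median(draws) - ml.params["treatment"]) < 3 * draws.std()
        assert max(fit.rhat.values()) < 1.05

    def test_poisson_limit_matches_gamma_posterior(self):
        # intercept-only, huge fixed size (Poisson limit), diffuse prior:
        # the per-site rate posterior is Gamma(sum y, sum sites)
        rng = np.random.default_rng(0)
        n = 200
        sites = rng.integers(110, 160, n)
        lam = 0.05
        rec = pd.DataFrame({
            "sites_total": sites,
            "sites_al13": rng.poisson(lam * sites),
            "arm": "placebo", "category": 0, "age_band": "<45",
            "sex": "F", "smoking": "no",
        })
        fit = fit_bayesian_nb(
            rec, predictors=("category",),
            priors=NBPriors(coef_scale=50.0, fix_size=1e6),
            sampler=SamplerConfig(seed=3, n_steps=3000, burn_in=1500),
        )
        rate_draws = np.exp(fit.draws["const"].to_numpy())
        post = gamma(a=rec["sites_al13"].sum(), scale=1.0 / sites.sum())
        mcse = rate_draws.std() / math.sqrt(min(fit.ess.values()))
        assert abs(rate_draws.mean() - post.mean()) < 4 * mcse + 0.02 * post.std()
        assert rate_draws.std() == pytest.approx(post.std(), rel=0.2)

    def test_empty_data_errors(self):
        with pytest.raises(ValueError, match="prior-dominated"):
            fit_bayesian_nb(pd.DataFrame(columns=["sites_al13", "sites_total",
                                                  "arm", "category"]))


class TestMediationDifference:
    def test_identical_draws_identity_pairing(self):
        draws = np.log(np.linspace(0.5, 0.9, 500))
        res = mediation_difference(draws, draws, pairing="identity")
        assert res.indirect_rr == pytest.approx(1.0)
        assert res.indirect_ci == (pytest.approx(1.0), pytest.approx(1.0))

    def test_identical_draws_random_pairing_centered_at_one(self):
        draws = np.log(np.linspace(0.5, 0.9, 2000))
        res = mediation_difference(draws, draws, pairing_seed=5)
        assert res.indirect_ci[0] < 1.0 < res.indirect_ci[1]
        assert res.indirect_rr == pytest.approx(1.0, abs=0.02)

    def test_point_mass_difference_identity(self):
        # the study's printed effects: total 0.73, direct 0.82 -> indirect 0.89
        t = np.full(1000, math.log(0.73))
        d = np.full(1000, math.log(0.82))
        res = mediation_difference(t, d)
        assert round(res.indirect_rr, 2) == 0.89
        assert res.total_rr == pytest.approx(0.73)
        assert res.direct_rr == pytest.approx(0.82)

    def test_independent_normals_convolve(self):
        rng = np.random.default_rng(8)
        t = rng.normal(-0.3, 0.10, 40_000)
        d = rng.normal(-0.2, 0.07, 40_000)
        res = mediation_difference(t, d, pairing_seed=1)
        ind = res.draws_indirect
        assert ind.mean() == pytest.approx(-0.1, abs=3 * 0.122 / 200)
        assert ind.std() == pytest.approx(math.hypot(0.10, 0.07), rel=0.03)

    def test_length_mismatch_requires_permission(self):
        with pytest.raises(ValueError, match="draw counts differ"):
            mediation_difference(np.zeros(10), np.zeros(12),
                                 allow_subsample=False)
        res = mediation_difference(np.zeros(10), np.zeros(12))
        assert len(res.draws_indirect) == 10


class TestRunMediationAnalysis:
    def test_full_run_on_generated_cohort(self, default_final_records):
        res, report = run_mediation_analysis(default_final_records,
                                             sampler=SamplerConfig(seed=2))
        assert report["total_model"]["adjustment_set"] == []
        assert report["direct_model"]["adjustment_set"] == ["age", "sex",
                                                            "smoking"]
        assert len(res.draws_indirect) == len(res.draws_total)
        assert res.indirect_ci[0] < res.indirect_rr < res.indirect_ci[1]

    def test_dag_without_confounder_edges_drops_adjustment(self,
                                                           default_final_records):
        dag = build_study_dag()
        for c in ("age", "sex", "smoking"):
            dag.remove_edge(c, OUTCOME)
            dag.remove_edge(c, MEDIATOR)
        _, report = run_mediation_analysis(default_final_records, dag=dag,
                                           sampler=SamplerConfig(seed=2))
        assert report["direct_model"]["predictors"] == ["treatment", "category"]
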