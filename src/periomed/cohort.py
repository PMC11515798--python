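"""Synthetic randomized two-arm periodontitis cohorts with known ground truth.

Emulates the design of a randomized, double-blind adjunctive-antibiotics
trial: ~163 patients sampled repeatedly over 26 months, subgingival
communities drawn from a two-community (dysbiotic / normobiotic) mixture,
an ordinal microbial-response mediator, and a negative-binomial count of
sites with further attachment loss >= 1.3 mm as the clinical outcome.

The generative chain is::

    covariates (age band, sex, smoking)  ~ independent categorical draws
    arm                                  ~ randomized, independent of covariates
    baseline dysbiotic proportion theta0 ~ Beta(patient params)
    baseline normobiotic indicator B     = 1[theta0 < 0.5]
    response category C in {0,1,2,3}     ~ proportional-odds(arm, B, covariates)
    per-visit true dysbiosis score s_v   = archetype[C][v] + trunc. Gaussian noise
    taxa counts per sample               ~ Multinomial(N_v, s_v*phi_dys + (1-s_v)*phi_norm)
    library size N_v                     ~ lognormal
    sites with AL >= 1.3 mm (final visit)~ NegBin(mean = sites_total * exp(eta), size r)

where phi_dys / phi_norm are community compositions drawn once per cohort
from Dirichlet concentration vectors with disjoint "signature" taxa
(pathobionts vs. commensals), and eta is the configured outcome linear
predictor (treatment, category, smoking, age).

Every latent quantity is returned in ``SyntheticCohort.truth`` so that each
downstream stage (topic fitting, trajectory clustering, clinical and
mediation models) can be validated against known ground truth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .counts import TaxaCountTable

logger = logging.getLogger(__name__)

__all__ = [
    "PATHOBIONTS",
    "COMMENSALS",
    "CATEGORY_NAMES",
    "OrdinalMediatorParams",
    "NBOutcomeParams",
    "CohortConfig",
    "CohortTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_healthy_controls",
    "implied_total_effect",
    "calibrate_total_effect",
]

#: Signature taxa of the dysbiotic community (periodontal pathobionts).
PATHOBIONTS = (
    "Porphyromonas gingivalis",
    "Porphyromonas endodontalis",
    "Fusobacterium nucleatum subsp. vincentii",
    "Treponema denticola",
    "Fretibacterium sp.",
    "Prevotella sp.",
)

#: Signature taxa of the normobiotic community (oral commensals).
COMMENSALS = (
    "Veillonella rogosae",
    "Veillonella parvula",
    "Veillonella dispar",
    "Rothia dentocariosa",
    "Fusobacterium nucleatum subsp. animalis",
)

CATEGORY_NAMES = {
    0: "non-responder",
    1: "indifferent",
    2: "short-term responder",
    3: "responder",
}

AGE_BANDS = ("<45", "45<55", ">55")


@dataclass
class OrdinalMediatorParams:
    """Proportional-odds model generating the response category (0..3).

    P(C >= k) = expit(eta - cutpoints[k-1]) with
    eta = treatment_log_odds*T + baseline_normo_log_odds*B + covariate terms;
    higher category means better microbial response.
    """

    treatment_log_odds: float = math.log(6.42)
    baseline_normo_log_odds: float = math.log(7.8)
    age_band_log_odds: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sex_male_log_odds: float = 0.0
    smoking_log_odds: float = 0.0
    cutpoints: tuple[float, float, float] = (0.0, 1.25, 2.5)


@dataclass
class NBOutcomeParams:
    """Negative-binomial (NB2) model for the count of sites with further
    attachment loss >= 1.3 mm at the final visit.

    mean = sites_total * exp(intercept + treatment_log_rr*T
    + category_log_rr*C + smoking_log_rr*S + age terms); the size
    (inverse-dispersion) parameter r gives variance mu + mu^2/r.
    """

    log_rate_intercept: float = math.log(8.14 / 146.0)
    treatment_log_rr: float = math.log(0.82)
    category_log_rr: float = math.log(0.72)
    smoking_log_rr: float = math.log(1.85)
    age_band_log_rr: tuple[float, float, float] = (
        0.0,
        math.log(9.60 / 8.14),
        math.log(11.93 / 8.14),
    )
    sex_male_log_rr: float = 0.0
    size: float = 4.0  # NB inverse-dispersion (variance = mu + mu^2/size)


def _default_archetypes() -> dict[int, tuple[float, ...]]:
    # mean dysbiosis score at visits [0, 2, 8, 14, 26] months; final-visit
    # means are strictly decreasing in category (ordinality of the mediator)
    return {
        0: (0.85, 0.80, 0.80, 0.80, 0.85),  # dysbiotic throughout
        1: (0.45, 0.70, 0.55, 0.65, 0.72),  # no consistent pattern
        2: (0.85, 0.30, 0.40, 0.55, 0.65),  # early shift, later relapse
        3: (0.85, 0.10, 0.12, 0.15, 0.20),  # shift maintained to 26 months
    }


@dataclass
class CohortConfig:
    """Full parameterisation of the synthetic trial."""

    n_patients: int = 163
    allocation: float = 0.5
    visit_months: tuple[int, ...] = (0, 2, 8, 14, 26)
    vocab_size: int = 200
    library_size_mean: float = 20000.0
    library_log_sd: float = 0.3
    signature_concentration: float = 30.0
    background_concentration: float = 0.5
    baseline_theta_patients: tuple[float, float] = (2.0, 1.0)
    baseline_theta_healthy: tuple[float, float] = (1.0, 20.0)
    mediator_model: OrdinalMediatorParams = field(default_factory=OrdinalMediatorParams)
    outcome_model: NBOutcomeParams = field(default_factory=NBOutcomeParams)
    trajectory_archetypes: dict[int, tuple[float, ...]] = field(
        default_factory=_default_archetypes
    )
    trajectory_noise_sd: float = 0.1
    age_band_probs: tuple[float, float, float] = (0.25, 0.45, 0.30)
    prop_female: float = 0.5
    prop_smoker: float = 0.35
    sites_total_mean: float = 136.0
    sites_total_sd: float = 8.0
    seed: int = 0

    # ----- derived vocabulary / community parameters -------------------
    def taxon_ids(self) -> list[str]:
        named = list(PATHOBIONTS) + list(COMMENSALS)
        if self.vocab_size < len(named):
            raise ValueError(
                f"vocab_size must be >= {len(named)} to hold the signature taxa"
            )
        generic = [f"Taxon{i:03d} sp." for i in range(self.vocab_size - len(named))]
        return named + generic

    def dys_topic_params(self) -> np.ndarray:
        conc = np.full(self.vocab_size, self.background_concentration)
        conc[: len(PATHOBIONTS)] = self.signature_concentration
        return conc

    def norm_topic_params(self) -> np.ndarray:
        conc = np.full(self.vocab_size, self.background_concentration)
        conc[len(PATHOBIONTS): len(PATHOBIONTS) + len(COMMENSALS)] = (
            self.signature_concentration
        )
        return conc

    # ----- validation ---------------------------------------------------
    def validate(self) -> None:
        if self.n_patients < 8:
            raise ValueError(
                "n_patients must be >= 8 (four response categories in two arms)"
            )
        if not 0.0 < self.allocation < 1.0:
            raise ValueError("allocation must be in (0, 1)")
        months = list(self.visit_months)
        if months[0] != 0 or any(b <= a for a, b in zip(months, months[1:])):
            raise ValueError("visit_months must be strictly increasing and start at 0")
        for name in ("signature_concentration", "background_concentration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("baseline_theta_patients", "baseline_theta_healthy"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValueError(f"{name} parameters must be strictly positive")
        if self.library_size_mean <= 0:
            raise ValueError("library_size_mean must be positive")
        if self.outcome_model.size <= 0:
            raise ValueError("outcome_model.size must be strictly positive")
        if set(self.trajectory_archetypes) != {0, 1, 2, 3}:
            raise ValueError("trajectory_archetypes must have categories 0..3")
        n_visits = len(months)
        for cat, arch in self.trajectory_archetypes.items():
            if len(arch) != n_visits:
                raise ValueError(
                    f"trajectory_archetypes[{cat}] must have {n_visits} entries"
                )
            if any(not 0.0 <= v <= 1.0 for v in arch):
                raise ValueError(f"trajectory_archetypes[{cat}] must lie in [0, 1]")
        finals = [self.trajectory_archetypes[c][-1] for c in (0, 1, 2, 3)]
        if any(b >= a for a, b in zip(finals, finals[1:])):
            raise ValueError(
                "final-visit archetype means must strictly decrease with category"
            )
        if abs(sum(self.age_band_probs) - 1.0) > 1e-9:
            raise ValueError("age_band_probs must sum to 1")
        if self.trajectory_noise_sd < 0:
            raise ValueError("trajectory_noise_sd must be non-negative")

    # ----- (de)serialisation -------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["trajectory_archetypes"] = {
            int(k): list(v) for k, v in data["trajectory_archetypes"].items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        data = yaml.safe_load(Path(path).read_text())
        med = data["mediator_model"]
        med["age_band_log_odds"] = tuple(med["age_band_log_odds"])
        med["cutpoints"] = tuple(med["cutpoints"])
        data["mediator_model"] = OrdinalMediatorParams(**med)
        out = data["outcome_model"]
        out["age_band_log_rr"] = tuple(out["age_band_log_rr"])
        data["outcome_model"] = NBOutcomeParams(**out)
        data["trajectory_archetypes"] = {
            int(k): tuple(v) for k, v in data["trajectory_archetypes"].items()
        }
        for key in ("visit_months", "age_band_probs", "baseline_theta_patients",
                    "baseline_theta_healthy"):
            data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class CohortTruth:
    """Realised latent variables of a simulated cohort."""

    subjects: pd.DataFrame      # subject_id, category, theta0, baseline_normobiotic
    samples: pd.DataFrame       # sample_id, true_dysbiotic_proportion
    phi_dys: np.ndarray         # dysbiotic community composition (simplex)
    phi_norm: np.ndarray        # normobiotic community composition (simplex)


@dataclass
class SyntheticCohort:
    count_table: TaxaCountTable
    metadata: pd.DataFrame      # sample_id (index), subject_id, visit_month, arm
    clinical: pd.DataFrame | None
    truth: CohortTruth


# ---------------------------------------------------------------------------


def _draw_covariates(rng: np.random.Generator, n: int, config: CohortConfig):
    age_band = rng.choice(len(AGE_BANDS), size=n, p=config.age_band_probs)
    sex_male = (rng.random(n) >= config.prop_female).astype(int)
    smoking = (rng.random(n) < config.prop_smoker).astype(int)
    return age_band, sex_male, smoking


def _mediator_eta(config: CohortConfig, treated, baseline_normo, age_band,
                  sex_male, smoking) -> np.ndarray:
    m = config.mediator_model
    age_eff = np.asarray(m.age_band_log_odds)[age_band]
    return (m.treatment_log_odds * treated
            + m.baseline_normo_log_odds * baseline_normo
            + age_eff + m.sex_male_log_odds * sex_male
            + m.smoking_log_odds * smoking)


def _category_probs(config: CohortConfig, eta: np.ndarray) -> np.ndarray:
    """n x 4 matrix of proportional-odds category probabilities."""
    cuts = np.asarray(config.mediator_model.cutpoints)
    p_ge = expit(eta[:, None] - cuts[None, :])        # P(C >= 1..3)
    p = np.empty((len(eta), 4))
    p[:, 0] = 1.0 - p_ge[:, 0]
    p[:, 1] = p_ge[:, 0] - p_ge[:, 1]
    p[:, 2] = p_ge[:, 1] - p_ge[:, 2]
    p[:, 3] = p_ge[:, 2]
    return p


def _outcome_eta(config: CohortConfig, treated, category, age_band, sex_male,
                 smoking) -> np.ndarray:
    o = config.outcome_model
    age_eff = np.asarray(o.age_band_log_rr)[age_band]
    return (o.log_rate_intercept
            + o.treatment_log_rr * treated
            + o.category_log_rr * category
            + o.smoking_log_rr * smoking
            + o.sex_male_log_rr * sex_male
            + age_eff)


def _draw_counts(rng: np.random.Generator, scores: np.ndarray,
                 phi_dys: np.ndarray, phi_norm: np.ndarray,
                 config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    mu_log = math.log(config.library_size_mean) - 0.5 * config.library_log_sd ** 2
    sizes = np.maximum(
        1, rng.lognormal(mu_log, config.library_log_sd, size=len(scores)).astype(int)
    )
    probs = scores[:, None] * phi_dys[None, :] + (1 - scores[:, None]) * phi_norm[None, :]
    counts = np.empty((len(scores), config.vocab_size), dtype=np.int64)
    for i in range(len(scores)):
        counts[i] = rng.multinomial(sizes[i], probs[i])
    return counts, sizes


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Simulate one randomized two-arm cohort; deterministic given ``config.seed``."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    months = list(config.visit_months)

    phi_dys = rng.dirichlet(config.dys_topic_params())
    phi_norm = rng.dirichlet(config.norm_topic_params())

    subject_ids = [f"S{i + 1:04d}" for i in range(n)]
    n_treated = int(round(n * config.allocation))
    treated = np.zeros(n, dtype=int)
    treated[rng.permutation(n)[:n_treated]] = 1

    age_band, sex_male, smoking = _draw_covariates(rng, n, config)
    theta0 = rng.beta(*config.baseline_theta_patients, size=n)
    baseline_normo = (theta0 < 0.5).astype(int)

    eta_med = _mediator_eta(config, treated, baseline_normo, age_band, sex_male,
                            smoking)
    pcat = _category_probs(config, eta_med)
    u = rng.random(n)
    category = (u[:, None] > pcat.cumsum(axis=1)[:, :3]).sum(axis=1)

    arch = np.array([config.trajectory_archetypes[c] for c in range(4)])
    scores = arch[category] + rng.normal(0.0, config.trajectory_noise_sd,
                                         size=(n, len(months)))
    scores = np.clip(scores, 0.0, 1.0)

    sample_ids, sample_subject, sample_visit, flat_scores = [], [], [], []
    for j, m in enumerate(months):
        for i, sid in enumerate(subject_ids):
            sample_ids.append(f"{sid}_V{m:02d}")
            sample_subject.append(sid)
            sample_visit.append(m)
            flat_scores.append(scores[i, j])
    flat_scores = np.asarray(flat_scores)

    counts, _ = _draw_counts(rng, flat_scores, phi_dys, phi_norm, config)
    count_df = pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"),
                            columns=config.taxon_ids())
    table = TaxaCountTable(count_df)

    arm = np.where(treated == 1, "antibiotic", "placebo")
    metadata = pd.DataFrame(
        {
            "subject_id": sample_subject,
            "visit_month": sample_visit,
            "arm": np.tile(arm, len(months)),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # ----- clinical records --------------------------------------------
    sites_total = np.clip(
        np.round(rng.normal(config.sites_total_mean, config.sites_total_sd, size=n)),
        108, 168,
    ).astype(int)
    eta_out = _outcome_eta(config, treated, category, age_band, sex_male, smoking)
    mu = sites_total * np.exp(eta_out)
    r = config.outcome_model.size
    al13_final = rng.negative_binomial(r, r / (r + mu))
    al13_final = np.minimum(al13_final, sites_total)  # cannot exceed measured sites

    records = []
    final_month = months[-1]
    for j, m in enumerate(months):
        s = scores[:, j]
        # site-level disease links: ~18% of sites with PPD >= 5 mm in a fully
        # dysbiotic mouth, ~2% in a normobiotic one (so the treat-to-target
        # endpoint of <= 4 affected sites is attainable after response)
        p_ppd = expit(-4.2 + 3.2 * s)
        p_bleed = expit(-1.8 + 1.8 * s)
        ppd5 = rng.binomial(sites_total, p_ppd)
        bleeding = rng.binomial(sites_total, p_bleed)
        if m == 0:
            al13 = np.zeros(n, dtype=int)
        elif m == final_month:
            al13 = al13_final
        else:
            al13 = rng.binomial(al13_final, m / final_month)
        for i, sid in enumerate(subject_ids):
            records.append(
                {
                    "subject_id": sid,
                    "visit_month": m,
                    "sites_total": sites_total[i],
                    "sites_ppd5": int(ppd5[i]),
                    "sites_bleeding": int(bleeding[i]),
                    "sites_al13": int(al13[i]),
                    "age_band": AGE_BANDS[age_band[i]],
                    "sex": "M" if sex_male[i] else "F",
                    "smoking": "yes" if smoking[i] else "no",
                    "arm": "antibiotic" if treated[i] else "placebo",
                }
            )
    clinical = pd.DataFrame.from_records(records)

    truth = CohortTruth(
        subjects=pd.DataFrame(
            {
                "subject_id": subject_ids,
                "category": category,
                "theta0": theta0,
                "baseline_normobiotic": baseline_normo,
            }
        ).set_index("subject_id"),
        samples=pd.DataFrame(
            {"true_dysbiotic_proportion": flat_scores},
            index=pd.Index(sample_ids, name="sample_id"),
        ),
        phi_dys=phi_dys,
        phi_norm=phi_norm,
    )
    return SyntheticCohort(table, metadata, clinical, truth)


def generate_healthy_controls(config: CohortConfig | None = None, n: int = 40,
                              seed: int | None = None) -> SyntheticCohort:
    """Single-visit samples from periodontally healthy subjects.

    Dysbiotic proportions are drawn from the healthy Beta (mass near 0);
    no clinical outcome records are produced. Uses ``config.seed + 1`` by
    default so a paired patient cohort and its controls differ.
    """
    config = config or CohortConfig()
    config.validate()
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)

    phi_dys = rng.dirichlet(config.dys_topic_params())
    phi_norm = rng.dirichlet(config.norm_topic_params())
    scores = rng.beta(*config.baseline_theta_healthy, size=n)
    counts, _ = _draw_counts(rng, scores, phi_dys, phi_norm, config)

    sample_ids = [f"H{i + 1:04d}_V00" for i in range(n)]
    subject_ids = [f"H{i + 1:04d}" for i in range(n)]
    count_df = pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"),
                            columns=config.taxon_ids())
    metadata = pd.DataFrame(
        {"subject_id": subject_ids, "visit_month": 0, "arm": "healthy"},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = CohortTruth(
        subjects=pd.DataFrame(index=pd.Index(subject_ids, name="subject_id")),
        samples=pd.DataFrame(
            {"true_dysbiotic_proportion": scores},
            index=pd.Index(sample_ids, name="sample_id"),
        ),
        phi_dys=phi_dys,
        phi_norm=phi_norm,
    )
    return SyntheticCohort(TaxaCountTable(count_df), metadata, None, truth)


# ---------------------------------------------------------------------------


def implied_total_effect(config: CohortConfig | None = None, n_mc: int = 100_000,
                         seed: int | None = None) -> tuple[float, float]:
    """Marginal (unadjusted) treatment rate ratio implied by the generator.

    The configured outcome model conditions on the mediator category, so
    the marginal treatment effect — what a treatment-only regression
    estimates — is the direct effect attenuated (or amplified) by the
    treatment-induced shift in the category distribution. This helper
    evaluates it by Monte Carlo over the covariate/baseline distribution,
    using the same draws under both arms (the category distribution is
    integrated analytically given each draw).

    Returns ``(rate_ratio, mc_standard_error)``.
    """
    config = config or CohortConfig()
    config.validate()
    if n_mc < 10_000:
        raise ValueError("n_mc must be >= 10000")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    age_band, sex_male, smoking = _draw_covariates(rng, n_mc, config)
    theta0 = rng.beta(*config.baseline_theta_patients, size=n_mc)
    b = (theta0 < 0.5).astype(int)
    o = config.outcome_model
    cat_weights = np.exp(o.category_log_rr * np.arange(4))

    def arm_mean(treated: int) -> np.ndarray:
        eta_med = _mediator_eta(config, np.full(n_mc, treated), b, age_band,
                                sex_male, smoking)
        pcat = _category_probs(config, eta_med)
        eta_out = _outcome_eta(config, np.full(n_mc, treated), 0, age_band,
                               sex_male, smoking)
        return np.exp(eta_out) * (pcat @ cat_weights)

    m1, m0 = arm_mean(1), arm_mean(0)
    rr = m1.mean() / m0.mean()
    # batch-means MC standard error of the ratio
    n_batches = 20
    idx = np.array_split(np.arange(n_mc), n_batches)
    batch_rr = np.array([m1[i].mean() / m0[i].mean() for i in idx])
    se = batch_rr.std(ddof=1) / math.sqrt(n_batches)
    return float(rr), float(se)


def calibrate_total_effect(config: CohortConfig | None = None,
                           target_rr: float = 0.73, n_mc: int = 200_000) -> CohortConfig:
    """Return a config whose implied marginal treatment rate ratio equals
    ``target_rr``, by root-finding on the per-category outcome effect while
    holding the direct treatment effect fixed.

    The generator's conditional defaults (strong mediator uptake, strong
    per-category effect) imply a marginal effect stronger than a given
    observed total; this solves for the per-category log-rate-ratio that
    reconciles them, using common random numbers so the objective is smooth.
    """
    config = config or CohortConfig()
    config.validate()

    def objective(cat_lrr: float) -> float:
        cfg = replace(config, outcome_model=replace(config.outcome_model,
                                                    category_log_rr=cat_lrr))
        rr, _ = implied_total_effect(cfg, n_mc=n_mc, seed=config.seed)
        return rr - target_rr

    lo, hi = -2.0, 0.0
    if objective(lo) * objective(hi) > 0:
        raise ValueError(
            "target total effect not attainable by varying the category effect"
        )
    root = brentq(objective, lo, hi, xtol=1e-5)
    calibrated = replace(
        config, outcome_model=replace(config.outcome_model, category_log_rr=root)
    )
    logger.info("calibrated category_log_rr=%.4f for target total RR %.3f",
                root, target_rr)
    return calibrated
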