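# Methods

`periomed` implements an end-to-end analysis of how the subgingival
microbiome mediates the effect of adjunctive systemic antibiotics on
periodontal attachment loss, together with a synthetic-cohort generator
that provides ground truth for every stage. This note records the models,
the defaults and why they were chosen, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Two-topic community model and the dysbiosis score

Taxa count tables (samples × taxa, non-negative integers) are modelled
with latent Dirichlet allocation. Each sample is a mixture over K latent
taxa distributions ("topics"); K is fixed at 2 so the topics admit a
direct ecological reading as a *dysbiotic* community (driven by
pathobionts such as *Porphyromonas gingivalis*, *Treponema denticola*,
*Fusobacterium nucleatum* subsp. *vincentii*) and a *normobiotic* one
(driven by commensals: three *Veillonella* species, *Rothia
dentocariosa*, *F. nucleatum* subsp. *animalis*). The per-sample loading
on the dysbiotic topic — which for K = 2 equals the relative proportion of
the dysbiotic to the normobiotic topic — is the **dysbiosis score** in
[0, 1].

Inference is collapsed Gibbs sampling over token-level topic assignments
with symmetric Dirichlet priors (`alpha = 50/K` on document-topic,
`eta = 0.1` on topic-word — common defaults for count tables of this
sparsity). Point estimates are Rao-Blackwellised posterior means over
post-burn-in sweeps (defaults: 150 sweeps, 50 burn-in; the log-likelihood
proxy trace is retained and a still-trending heuristic sets a
`convergence_warning` flag rather than raising). A collapsed sampler was
chosen over variational EM because its posterior is exactly enumerable on
tiny corpora, which gives the test suite a brute-force oracle: on corpora
of ≤ 8 tokens, posterior mean loadings and pairwise token co-assignment
probabilities are compared against exhaustive enumeration of all K^N
assignment vectors (agreement within 0.02).

Topics are identified *by labelling, never by index*: the topic with the
greater summed topic-word mass on a pathobiont reference list is labelled
dysbiotic, with the evidence and margin recorded; a margin within 1e-6 of
zero raises an ambiguity error instead of guessing. This makes label
switching across seeds immaterial. New samples are scored against a
fitted model by **fold-in**: topic-word distributions held fixed,
assignments Gibbs-sampled for the new samples only; taxa unseen at
training are dropped with the dropped-count fraction logged.

Two caveats are inherent to collapsed sampling and documented rather than
hidden: (i) permuting sample order changes the RNG stream, so
permutation-equivariance of the loadings is only approximate (tested to
within 0.05 on separable corpora); (ii) on small ambiguous corpora the
chain mixes between the two symmetric modes, so loadings shrink toward
0.5 — the co-assignment oracle is the sharper check there.

## Preprocessing

Pooled tables from heterogeneous studies are filtered per study: a taxon
is kept for a study's samples only if its total count within that study
reaches the minimum-abundance threshold (default 100, inclusive cut),
removing suspiciously rare sequence variants; a taxon retained in one
study but not another stays as an all-zero column for the latter, so the
pooled vocabulary is the union. The threshold is interpreted per study
because between-study depth differences make a pooled cut
uninterpretable. Aggregation to genus or species sums columns by the
leading tokens of the Linnaean label and conserves per-sample totals
exactly.

## Response patterns

Per-subject dysbiosis trajectories over the visit schedule are clustered
with agglomerative hierarchical clustering (Ward linkage, Euclidean
distance — the standard choice for recovering trajectory shapes; linkage
is configurable). Missing visits are imputed by last observation carried
forward, which preserves shape without dropping subjects (a
drop-incomplete mode exists); subjects without a baseline sample are
excluded and logged. The tree is cut at k = 4, matching the four named
patterns, and each *cluster* is mapped to a category from its mean
trajectory relative to a normobiosis cut of 0.5 (the natural midpoint of
a two-topic proportion; configurable):

| code | name | rule (baseline, first post-treatment visit, final visit) |
|---|---|---|
| 0 | non-responder | ≥ cut at all three |
| 3 | responder | < cut at first post-treatment and at final |
| 2 | short-term responder | < cut at first post-treatment, ≥ cut at final |
| 1 | indifferent | anything else |

Codes are ordinal in clinical response (0 worst). Two clusters may map to
the same name (warning, not error): categories label clusters.

## Clinical models

* **Median dichotomisation**: site counts are converted to percentages of
  total sites; the indicator is 1 strictly below the within-visit median
  (ties count as "above" — the literal reading of "below median").
* **Treat-to-target**: ≤ 4 sites with probing depth ≥ 5 mm, boundary
  inclusive.
* **Logistic associations**: outcome indicator ~ normobiotic proportion +
  age + sex + smoking; the exposure coefficient is reported per 0.1
  increase of the normobiotic proportion, stated prominently because an
  odds ratio for a compositional exposure is meaningless without its
  unit.
* **Ordinal mediator model**: proportional-odds logit of the response
  category on treatment, a baseline-normobiotic indicator, and
  covariates. The MLE receives a **one-step Jeffreys-prior (Firth-type)
  adjusted-score correction** by default: at n ≈ 163 with strong binary
  predictors the proportional-odds MLE overstates odds ratios by 5–13%
  (measured over 1000 simulated trials), and the one-step correction
  removes that O(1/n) bias at negligible cost (geometric means 6.51 vs a
  true 6.42 and 7.83 vs 7.80 over 1000 trials); `bias_reduction=False`
  restores the raw MLE. A Brant-style heuristic (per-threshold binary
  logits compared at 3 SE) flags proportional-odds violations.
* **Outcome model**: NB2 negative-binomial regression of the count of
  sites with further attachment loss ≥ 1.3 mm, log link, log(total
  sites) offset (so coefficients are per-site log rate ratios),
  dispersion estimated by ML. The response category enters as ordinal
  numeric 0–3 (one constant per-step rate ratio) by default; a
  categorical-dummies mode exists for grid-style presentations, whose
  per-step ratios are then free — with ordinal coding the prediction
  grid's category steps are constant by construction.
* **Prediction grid**: expected affected sites = sites_total ×
  exp(linear predictor) over arm × smoking × age band × category; fully
  multiplicative, so any one predictor moves every cell by its rate
  ratio. `sites_total` is an explicit parameter (146 by default).

## Causal mediation

The study design is a DAG: randomized treatment; an ordinal microbial
response pattern as mediator; the attachment-loss count as outcome;
age, sex and smoking as mediator–outcome confounders; baseline
characteristics influencing the mediator only. Backdoor adjustment sets
are derived by explicit path enumeration with d-separation blocking
rules and exhaustive subset search (the graphs are small; the
implementation is tested against an independent d-separation oracle on
every DAG in the suite). For the study DAG this yields: total effect —
empty adjustment set (randomization); mediator→outcome — {age, sex,
smoking} (plus treatment) in every minimal set.

Because mediator (ordinal) and outcome (count) live on different scales,
the mediation estimand is the **difference method on the log-rate
scale**: a total-effect model (treatment + offset only) and a
direct-effect model (treatment + category + age + sex + smoking + offset)
are fitted as Bayesian NB2 regressions, and the indirect effect is the
posterior of c − c′, the difference of the two treatment coefficients.
Priors are weakly informative — normal(0, 2.5) on log-rate coefficients,
half-normal (scale 10) on the inverse dispersion — and configurable.
Sampling uses an affine-invariant ensemble sampler initialised at the ML
fit (default 16+ walkers, 2000 steps, 1000 burn-in, thinning 5); split
R-hat and effective sample size are computed by dividing the ensemble
into four walker groups, and any R-hat above 1.05 fails loudly by
default. The two models are fitted independently, so their draws admit no
canonical pairing; draws are paired uniformly at random with a fixed seed
(the distribution of c − c′ is the convolution regardless of pairing).
Point estimates are posterior medians with 95% equal-tailed credible
intervals; for point-mass posteriors the identity indirect RR =
total RR / direct RR holds exactly. A wide indirect interval is reported
as evidence for the *presence*, not the magnitude, of mediation.

## Synthetic cohort generator

The generator emulates a randomized, two-arm (placebo vs. adjunctive
antibiotics), 26-month trial of 163 patients sampled at months
0/2/8/14/26, and is the ground-truth source for every downstream check.
Generative chain: independent covariates (age bands <45 / 45<55 / >55
with probabilities 0.25/0.45/0.30; 50% female; 35% smokers); randomized
allocation (exactly half treated, permuted); a baseline dysbiotic
proportion θ₀ ~ Beta(2, 1) defining the baseline-normobiotic indicator
(θ₀ < 0.5, about 25% of patients); a response category drawn from the
proportional-odds model; per-visit true dysbiosis scores = category
archetype mean + truncated Gaussian noise (SD 0.1, clipped to [0, 1]);
taxa counts multinomial over s·φ_dys + (1−s)·φ_norm with lognormal
library sizes (mean 20 000 reads); and a final-visit NB2 count of sites
with further attachment loss.

The default effect sizes are the conditional models' headline values:
treatment log-odds log 6.42 and baseline-normobiotic log-odds log 7.8 in
the mediator model (cutpoints 0, 1.25, 2.5, chosen so all four categories
are well populated in both arms); per-category log-rate-ratio log 0.72,
direct treatment log-rate-ratio log 0.82, smoking log 1.85, and age-band
effects log 1.18 / log 1.47 in the outcome model (NB size 4, i.e.
moderate overdispersion). Mediator-model covariate effects default to
zero: their values are otherwise unconstrained, and any nonzero value
makes age/smoking confound the category→outcome association, so the
two-predictor outcome model would no longer estimate the configured
per-category effect — the DAG keeps the confounder edges and the
coefficients are one assignment away for users who want confounded
scenarios. The Beta(2, 1) baseline reflects that a dichotomised baseline
state must have non-trivial prevalence in both classes for its odds
ratio to be estimable with the precision the conditional model implies;
the *scores* at baseline are archetype-driven (mean 0.85, dysbiosis
dominated) regardless.

The archetypes (visits 0/2/8/14/26) are: non-responder
(0.85, 0.80, 0.80, 0.80, 0.85), indifferent (0.45, 0.70, 0.55, 0.65,
0.72), short-term responder (0.85, 0.30, 0.40, 0.55, 0.65), responder
(0.85, 0.10, 0.12, 0.15, 0.20); final-visit means are strictly
decreasing in category (enforced at validation), which is what makes the
category ordinal. Site-level secondary outcomes use logistic links to
the current true score (≈18% of sites with PPD ≥ 5 mm in a fully
dysbiotic mouth vs. ≈2% in a normobiotic one, so the treat-to-target
endpoint is attainable after successful response).

An important structural fact, surfaced by `implied_total_effect`: the
conditional defaults imply a *marginal* treatment rate ratio of ≈ 0.59,
stronger than a typical observed total effect, because a treatment OR of
6.42 on the mediator combined with a per-category RR of 0.72 mediates
aggressively. `calibrate_total_effect` therefore root-finds the
per-category effect (holding the direct effect fixed, common random
numbers for smoothness) so the implied marginal effect matches a target
total (0.73 by default; the calibrated per-category log-RR is ≈ −0.12).
Marginal-total recovery experiments use the calibrated configuration.

What the generator does **not** emulate: sequencing error, chimeras or
denoising artefacts; multi-centre stratification; compositional batch
effects between platforms; informative missingness (every subject attends
every visit); within-subject autocorrelation of scores beyond the
category archetype; death/dropout. Passing tests therefore demonstrate
that the estimators recover known truth under the stated generative
model — not that the pipeline is robust to the full messiness of real
16S data.

## Numerical choices and degenerate inputs

Seeds are explicit everywhere (generator config, Gibbs samplers, ensemble
MCMC, draw pairing); all results are deterministic given seeds. Gibbs
seeds are reduced mod 2³¹−1 for the numba RNG. Validation errors name the
offending field or cell (configs, count tables, trajectories). All-zero
samples are rejected at table construction; a filter that would remove
every taxon errors with the per-taxon totals; a cohort of fewer than 8
patients is refused (four categories × two arms). Ties: median split
sends values at the median to "above"; topic labelling refuses margins
within 1e-6. NB fits falling back on non-convergence carry a flag rather
than raising; ensemble fits with R-hat > 1.05 raise by default.

## Experiment sizes

The bundled experiments (tests and `scripts/acceptance.py`) use: 200
simulated trials of n = 163 for each recovery experiment (Monte-Carlo SE
of a geometric mean ≈ 2.5% — small enough to detect estimator bias,
cheap enough to re-run); 100 size-reduced cohorts (20 patients, 2000
reads, 60 sweeps) for topic-labelling accuracy, where label recovery
depends on community separation rather than depth; 10 full-size cohorts
for clustering agreement; and 100 null-mediation trials (reduced MCMC:
1500 steps, 700 burn-in) for indirect-interval coverage. These sizes are
the package's standing defaults for its own validation experiments.

## Known limitations

* The dysbiosis score is a two-topic proportion, not an absolute load;
  it is identified only up to the fitted vocabulary and reference lists.
* The ordinal category is assigned at cluster level; subjects near a
  cluster boundary inherit their cluster's label.
* The difference method assumes no exposure–mediator interaction on the
  log-rate scale and no unmeasured mediator–outcome confounding;
  counterfactual (natural) direct/indirect effects are out of scope.
* The Bayesian NB sampler is an ensemble method on a low-dimensional
  posterior; for much larger models a gradient-based sampler would be
  preferable.
* Real-data odds ratios for the dysbiosis–outcome associations are not
  reproducible from synthetic data; the logistic machinery is validated
  by simulation recovery only.
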