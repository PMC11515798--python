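"""Two-topic latent community model and the dysbiosis score.

Subgingival 16S samples are modelled as mixtures of K latent taxa
communities (latent Dirichlet allocation); with K fixed at 2 the two
communities are labelled *dysbiotic* and *normobiotic* from their mass on
reference pathobiont / commensal taxa, and a sample's loading on the
dysbiotic community — the relative proportion of the dysbiotic to the
normobiotic topic — is its dysbiosis score.

Inference is collapsed Gibbs sampling with Rao-Blackwellised posterior-mean
point estimates, which keeps the posterior amenable to exhaustive
enumeration on tiny corpora (the sampler's test oracle). Topics across
seeds are identified by labelling, never by index, so label switching
between runs is immaterial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from ._lda import gibbs_fold_in, gibbs_lda
from .cohort import COMMENSALS, PATHOBIONTS
from .counts import TaxaCountTable

logger = logging.getLogger(__name__)

__all__ = [
    "TopicModelFit",
    "TopicLabeling",
    "AmbiguousLabelingError",
    "ContrastResult",
    "fit_topics",
    "label_topics",
    "dysbiosis_score",
    "fold_in",
    "healthy_vs_disease_contrast",
]


@dataclass
class TopicModelFit:
    """Fitted topic model: per-topic taxa distributions and per-sample loadings."""

    K: int
    topic_word: np.ndarray          # K x V, rows on the simplex
    doc_topic: np.ndarray           # D x K, rows on the simplex
    alpha: float
    eta: float
    seed: int
    n_iterations: int
    burn_in: int
    loglik_trace: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    convergence_warning: bool = False
    assignment_samples: np.ndarray | None = field(default=None, repr=False)

    def doc_topic_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.doc_topic, index=self.sample_ids,
                            columns=[f"topic{k}" for k in range(self.K)])


@dataclass
class TopicLabeling:
    """Which topic is dysbiotic, with the evidence behind the call."""

    dysbiotic_topic_index: int
    normobiotic_topic_index: int
    evidence: dict
    margin: float


class AmbiguousLabelingError(ValueError):
    """Raised when reference-taxa evidence cannot separate the two topics."""


def _tokens(counts: np.ndarray):
    rows, cols = np.nonzero(counts)
    reps = counts[rows, cols]
    return np.repeat(rows, reps).astype(np.int64), np.repeat(cols, reps).astype(np.int64)


def fit_topics(
    table: TaxaCountTable,
    K: int = 2,
    alpha: float | None = None,
    eta: float = 0.1,
    seed: int = 0,
    n_iterations: int = 150,
    burn_in: int = 50,
    store_assignments: bool = False,
) -> TopicModelFit:
    """Fit a K-topic model by collapsed Gibbs sampling.

    Parameters
    ----------
    alpha, eta
        Symmetric Dirichlet concentrations; ``alpha`` defaults to ``50 / K``.
    n_iterations, burn_in
        Total Gibbs sweeps and the number discarded before posterior
        averaging. Deterministic given ``seed``.
    store_assignments
        Keep the post-burn-in token-assignment draws (for small corpora /
        posterior diagnostics).
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if n_iterations <= burn_in:
        raise ValueError("n_iterations must exceed burn_in")
    counts = table.counts.to_numpy()
    D, V = counts.shape
    if D == 0 or V == 0:
        raise ValueError("count table is empty")
    if alpha is None:
        alpha = 50.0 / K
    doc_ids, word_ids = _tokens(counts)
    doc_topic, topic_word, ll, z_samples = gibbs_lda(
        doc_ids, word_ids, K, V, D, float(alpha), float(eta),
        int(n_iterations), int(burn_in), int(seed) % (2**31 - 1), store_assignments,
    )
    # renormalise away accumulated rounding
    doc_topic = doc_topic / doc_topic.sum(axis=1, keepdims=True)
    topic_word = topic_word / topic_word.sum(axis=1, keepdims=True)

    warn = _still_trending(ll)
    if warn:
        logger.warning("log-likelihood proxy still trending at the final sweep; "
                       "consider more iterations")
    return TopicModelFit(
        K=K, topic_word=topic_word, doc_topic=doc_topic, alpha=float(alpha),
        eta=float(eta), seed=int(seed), n_iterations=int(n_iterations),
        burn_in=int(burn_in), loglik_trace=ll, sample_ids=table.sample_ids,
        taxon_ids=table.taxon_ids, convergence_warning=warn,
        assignment_samples=z_samples if store_assignments else None,
    )


def _still_trending(ll: np.ndarray) -> bool:
    # trend heuristic on the last half of the trace: flag if the fitted slope
    # projected over that window exceeds 3 sweep-to-sweep noise SDs
    half = ll[len(ll) // 2:]
    if len(half) < 10:
        return False
    x = np.arange(len(half), dtype=float)
    slope, intercept = np.polyfit(x, half, 1)
    resid_sd = np.std(half - (slope * x + intercept))
    if resid_sd == 0:
        return False
    return abs(slope) * len(half) > 3.0 * resid_sd


def label_topics(
    fit: TopicModelFit,
    pathobiont_list=PATHOBIONTS,
    commensal_list=COMMENSALS,
    rel_tol: float = 1e-6,
) -> TopicLabeling:
    """Label the topic with the greater pathobiont mass as dysbiotic.

    Evidence is the summed topic-word mass of each topic on the pathobiont
    and commensal reference lists; the margin is the between-topic
    difference in pathobiont mass. Refuses (raises
    :class:`AmbiguousLabelingError`) when the margin is within ``rel_tol``
    of zero — such fits need manual labelling.
    """
    if fit.K != 2:
        raise ValueError("labeling is defined for two-topic fits")
    pathobiont_list, commensal_list = set(pathobiont_list), set(commensal_list)
    if not pathobiont_list or not commensal_list:
        raise ValueError("reference lists must be nonempty")
    if pathobiont_list & commensal_list:
        raise ValueError("reference lists must be disjoint")
    vocab = {t: j for j, t in enumerate(fit.taxon_ids)}
    path_idx = [vocab[t] for t in pathobiont_list if t in vocab]
    comm_idx = [vocab[t] for t in commensal_list if t in vocab]
    if not path_idx and not comm_idx:
        raise ValueError("no reference taxa present in the fitted vocabulary")

    path_mass = fit.topic_word[:, path_idx].sum(axis=1) if path_idx else np.zeros(2)
    comm_mass = fit.topic_word[:, comm_idx].sum(axis=1) if comm_idx else np.zeros(2)
    margin = float(path_mass[0] - path_mass[1])
    if abs(margin) <= rel_tol * max(path_mass.max(), 1e-300):
        raise AmbiguousLabelingError(
            f"pathobiont masses {path_mass.tolist()} do not separate the topics; "
            "label manually"
        )
    dys = 0 if margin > 0 else 1
    evidence = {
        k: {"pathobiont_mass": float(path_mass[k]), "commensal_mass": float(comm_mass[k])}
        for k in range(2)
    }
    return TopicLabeling(
        dysbiotic_topic_index=dys,
        normobiotic_topic_index=1 - dys,
        evidence=evidence,
        margin=abs(margin),
    )


def dysbiosis_score(fit: TopicModelFit, labeling: TopicLabeling) -> pd.Series:
    """Per-sample dysbiosis score: the loading on the dysbiotic topic.

    With K = 2 this equals dys / (dys + norm), the relative proportion of
    the dysbiotic to the normobiotic topic.
    """
    if labeling.dysbiotic_topic_index >= fit.K:
        raise ValueError("labeling does not match the fit")
    return pd.Series(fit.doc_topic[:, labeling.dysbiotic_topic_index],
                     index=fit.sample_ids, name="dysbiosis_score")


def fold_in(
    fit: TopicModelFit,
    new_table: TaxaCountTable,
    labeling: TopicLabeling,
    seed: int = 0,
    n_iterations: int = 200,
    burn_in: int = 100,
) -> pd.Series:
    """Score new samples against a fitted model without refitting.

    Topic-word distributions are held fixed at the fit's point estimates
    and only the new samples' assignments are Gibbs-sampled. Taxa absent
    from the fitted vocabulary are dropped (the dropped count fraction is
    logged); a new sample whose every taxon is unseen is an error.
    """
    vocab = {t: j for j, t in enumerate(fit.taxon_ids)}
    shared = [t for t in new_table.taxon_ids if t in vocab]
    if not shared:
        raise ValueError("no overlap between the new table and the fitted vocabulary")
    sub = new_table.counts[shared]
    dropped = 1.0 - sub.to_numpy().sum() / new_table.counts.to_numpy().sum()
    if dropped > 0:
        logger.info("fold_in: dropped %.1f%% of counts (taxa outside the fitted "
                    "vocabulary)", 100 * dropped)
    empty = sub.index[sub.sum(axis=1) == 0].tolist()
    if empty:
        raise ValueError(
            f"samples with no taxa overlapping the fitted vocabulary: {empty}"
        )
    counts = np.zeros((len(sub), len(fit.taxon_ids)), dtype=np.int64)
    col_idx = np.array([vocab[t] for t in shared])
    counts[:, col_idx] = sub.to_numpy()
    doc_ids, word_ids = _tokens(counts)
    doc_topic = gibbs_fold_in(
        doc_ids, word_ids, np.ascontiguousarray(fit.topic_word), len(sub),
        fit.alpha, int(n_iterations), int(burn_in), int(seed) % (2**31 - 1),
    )
    doc_topic = doc_topic / doc_topic.sum(axis=1, keepdims=True)
    return pd.Series(doc_topic[:, labeling.dysbiotic_topic_index],
                     index=sub.index, name="dysbiosis_score")


@dataclass
class ContrastResult:
    median_healthy: float
    median_untreated: float
    difference: float
    statistic: float
    p_value: float


def healthy_vs_disease_contrast(scores_healthy, scores_untreated) -> ContrastResult:
    """Compare dysbiosis scores of healthy vs. untreated periodontitis samples.

    Reports group medians, their difference (healthy minus untreated) and a
    two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.
    """
    h = np.asarray(scores_healthy, dtype=float)
    u = np.asarray(scores_untreated, dtype=float)
    if len(h) < 2 or len(u) < 2:
        raise ValueError("each group needs at least 2 samples")
    stat, p = mannwhitneyu(h, u, alternative="two-sided")
    return ContrastResult(
        median_healthy=float(np.median(h)),
        median_untreated=float(np.median(u)),
        difference=float(np.median(h) - np.median(u)),
        statistic=float(stat),
        p_value=float(p),
    )
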