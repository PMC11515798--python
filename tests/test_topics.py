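import numpy as np
import pandas as pd
import pytest

import periomed as pm
from periomed.counts import TaxaCountTable
from periomed.topics import (
    AmbiguousLabelingError,
    TopicModelFit,
    dysbiosis_score,
    fit_topics,
    fold_in,
    healthy_vs_disease_contrast,
    label_topics,
)

from lda_oracle import enumerate_posterior


def table_from(counts, samples, taxa):
    return TaxaCountTable(pd.DataFrame(counts, index=samples, columns=taxa))


def fake_fit(topic_word, taxon_ids, doc_topic=None, sample_ids=None):
    doc_topic = doc_topic if doc_topic is not None else np.array([[0.5, 0.5]])
    sample_ids = sample_ids or [f"s{i}" for i in range(len(doc_topic))]
    return TopicModelFit(
        K=2, topic_word=np.asarray(topic_word, dtype=float),
        doc_topic=np.asarray(doc_topic, dtype=float), alpha=1.0, eta=0.1,
        seed=0, n_iterations=10, burn_in=5, loglik_trace=np.zeros(10),
        sample_ids=sample_ids, taxon_ids=list(taxon_ids),
    )


class TestFitTopics:
    def test_disjoint_vocabularies_separate(self):
        t = table_from([[500, 500, 0, 0], [0, 0, 500, 500]], ["s1", "s2"],
                       ["a sp.", "b sp.", "c sp.", "d sp."])
        fit = fit_topics(t, K=2, alpha=0.1, eta=0.1, seed=3,
                         n_iterations=300, burn_in=100)
        own = fit.doc_topic.argmax(axis=1)
        assert own[0] != own[1]
        assert fit.doc_topic[0, own[0]] >= 0.9
        assert fit.doc_topic[1, own[1]] >= 0.9
        assert fit.topic_word[own[0], :2].sum() >= 0.9
        assert fit.topic_word[own[1], 2:].sum() >= 0.9

    def test_single_taxon_degenerate(self):
        t = table_from([[10], [5]], ["s1", "s2"], ["a sp."])
        fit = fit_topics(t, K=2, alpha=1.0, eta=0.1, seed=0,
                         n_iterations=50, burn_in=10)
        assert np.allclose(fit.topic_word, 1.0)

    def test_iterations_must_exceed_burn_in(self):
        t = table_from([[3]], ["s1"], ["a sp."])
        with pytest.raises(ValueError, match="burn_in"):
            fit_topics(t, n_iterations=10, burn_in=10)

    def test_gibbs_matches_enumeration_oracle(self):
        # 2 samples x 3 taxa, 6 tokens: exact posterior by enumerating 2^6
        counts = np.array([[2, 1, 0], [0, 1, 2]])
        t = table_from(counts, ["s1", "s2"], ["a sp.", "b sp.", "c sp."])
        alpha, eta = 0.5, 0.3
        fit = fit_topics(t, K=2, alpha=alpha, eta=eta, seed=5,
                         n_iterations=8000, burn_in=1000, store_assignments=True)
        rows, cols = np.nonzero(counts)
        doc_ids = np.repeat(rows, counts[rows, cols])
        word_ids = np.repeat(cols, counts[rows, cols])
        doc_oracle, co_oracle = enumerate_posterior(doc_ids, word_ids, K=2, V=3,
                                                    D=2, alpha=alpha, eta=eta)
        assert np.abs(fit.doc_topic - doc_oracle).max() < 0.02
        z = fit.assignment_samples
        co_gibbs = np.mean(z[:, :, None] == z[:, None, :], axis=0)
        assert np.abs(co_gibbs - co_oracle).max() < 0.02

    def test_score_tracks_generator_truth(self, small_cohort):
        fit = fit_topics(small_cohort.count_table, seed=1, n_iterations=80,
                         burn_in=30)
        lab = label_topics(fit)
        s = dysbiosis_score(fit, lab)
        truth = small_cohort.truth.samples.loc[s.index,
                                               "true_dysbiotic_proportion"]
        assert np.corrcoef(s, truth)[0, 1] >= 0.9

    def test_approximate_sample_order_invariance(self):
        # a well-separated corpus, where the doc-topic posterior is
        # concentrated; collapsed sampling is only approximately
        # permutation-equivariant, hence the tolerance
        rng = np.random.default_rng(0)
        counts = rng.multinomial(1000, [0.49, 0.49, 0.01, 0.01], size=3)
        counts = np.vstack([counts, rng.multinomial(1000, [0.01, 0.01, 0.49,
                                                           0.49], size=3)])
        samples = [f"s{i}" for i in range(6)]
        taxa = ["a sp.", "b sp.", "c sp.", "d sp."]
        t = table_from(counts, samples, taxa)
        perm = [3, 1, 5, 0, 2, 4]
        tp = table_from(counts[perm], [samples[i] for i in perm], taxa)
        kw = dict(K=2, alpha=0.5, eta=0.1, seed=9, n_iterations=600, burn_in=200)
        f1, f2 = fit_topics(t, **kw), fit_topics(tp, **kw)
        s1 = pd.Series(f1.doc_topic[:, label_topics(
            f1, ("a sp.",), ("c sp.",)).dysbiotic_topic_index], index=samples)
        s2 = pd.Series(f2.doc_topic[:, label_topics(
            f2, ("a sp.",), ("c sp.",)).dysbiotic_topic_index],
            index=[samples[i] for i in perm])
        assert (s1 - s2.reindex(samples)).abs().max() <= 0.05


class TestLabeling:
    def test_clear_margin(self):
        fit = fake_fit([[0.6, 0.05, 0.35], [0.05, 0.6, 0.35]],
                       ["Porphyromonas gingivalis", "Veillonella parvula",
                        "Taxon000 sp."])
        lab = label_topics(fit)
        assert lab.dysbiotic_topic_index == 0
        assert lab.margin == pytest.approx(0.55)
        assert lab.evidence[0]["pathobiont_mass"] == pytest.approx(0.6)

    def test_tie_is_ambiguous(self):
        fit = fake_fit([[0.3, 0.7], [0.3, 0.7]],
                       ["Porphyromonas gingivalis", "Veillonella parvula"])
        with pytest.raises(AmbiguousLabelingError):
            label_topics(fit)

    def test_no_reference_taxa_errors(self):
        fit = fake_fit([[1.0], [1.0]], ["Unknown sp."])
        with pytest.raises(ValueError, match="no reference taxa"):
            label_topics(fit)

    def test_overlapping_lists_rejected(self):
        fit = fake_fit([[1.0], [1.0]], ["Porphyromonas gingivalis"])
        with pytest.raises(ValueError, match="disjoint"):
            label_topics(fit, ("Porphyromonas gingivalis",),
                         ("Porphyromonas gingivalis",))


class TestDysbiosisScore:
    def test_equal_loadings_give_half(self):
        fit = fake_fit([[1.0, 0.0], [0.0, 1.0]],
                       ["Porphyromonas gingivalis", "Veillonella parvula"],
                       doc_topic=[[0.5, 0.5], [1.0, 0.0]],
                       sample_ids=["s1", "s2"])
        lab = label_topics(fit)
        s = dysbiosis_score(fit, lab)
        assert s["s1"] == pytest.approx(0.5)
        assert s["s2"] == pytest.approx(1.0)

    def test_complementarity(self, small_cohort):
        fit = fit_topics(small_cohort.count_table, seed=2, n_iterations=60,
                         burn_in=20)
        lab = label_topics(fit)
        s = dysbiosis_score(fit, lab)
        normo = fit.doc_topic[:, lab.normobiotic_topic_index]
        assert np.abs(s.to_numpy() + normo - 1.0).max() < 1e-8


@pytest.fixture(scope="module")
def fitted(small_cohort):
    fit = fit_topics(small_cohort.count_table, seed=1, n_iterations=80,
                     burn_in=30)
    return fit, label_topics(fit)


class TestFoldIn:

    def test_self_consistency(self, small_cohort, fitted):
        fit, lab = fitted
        train_scores = dysbiosis_score(fit, lab)
        sub = small_cohort.count_table.subset_samples(train_scores.index[:20])
        folded = fold_in(fit, sub, lab, seed=4)
        assert (folded - train_scores[folded.index]).abs().max() <= 0.05

    def test_pure_dysbiotic_sample_scores_high(self, fitted):
        fit, lab = fitted
        top = np.argsort(fit.topic_word[lab.dysbiotic_topic_index])[-5:]
        counts = np.zeros((1, len(fit.taxon_ids)), dtype=int)
        counts[0, top] = 200
        t = TaxaCountTable(pd.DataFrame(counts, index=["new"],
                                        columns=fit.taxon_ids))
        s = fold_in(fit, t, lab, seed=0)
        assert s["new"] > 0.9

    def test_zero_overlap_errors(self, fitted):
        fit, lab = fitted
        t = table_from([[5]], ["new"], ["Unseen sp."])
        with pytest.raises(ValueError, match="overlap"):
            fold_in(fit, t, lab)

    def test_monotone_in_dysbiotic_counts(self, fitted):
        fit, lab = fitted
        top = np.argsort(fit.topic_word[lab.dysbiotic_topic_index])[-3:]
        other = np.argsort(fit.topic_word[lab.normobiotic_topic_index])[-3:]
        scores = []
        for extra in (0, 300, 900):
            counts = np.zeros((1, len(fit.taxon_ids)), dtype=int)
            counts[0, other] = 200
            counts[0, top] += extra
            t = TaxaCountTable(pd.DataFrame(counts, index=["new"],
                                            columns=fit.taxon_ids))
            scores.append(fold_in(fit, t, lab, seed=11)["new"])
        assert scores[0] <= scores[1] <= scores[2]


class TestContrast:
    def test_identical_groups_null(self):
        r = healthy_vs_disease_contrast([0.2, 0.3, 0.4], [0.2, 0.3, 0.4])
        assert r.difference == 0
        assert r.p_value > 0.9

    def test_tiny_groups_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            healthy_vs_disease_contrast([0.2], [0.1, 0.3])

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(1)
        r = healthy_vs_disease_contrast(rng.uniform(0, 0.2, 30),
                                        rng.uniform(0.6, 1.0, 30))
        assert r.difference < 0
        assert r.p_value < 1e-6
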