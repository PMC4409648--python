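"""Classifier training and posterior scoring against independent oracles.

The oracle here is a deliberately naive reimplementation of the model's
math: plain counting for the conditional tables and a direct product
evaluation of the two-class posterior, with no log-space tricks.  The
package implementation must agree with it to near machine precision.
"""

import itertools
import math

import numpy as np
import pytest

from radtriage.bayes_classifier import (
    ClassifierConfig,
    TrainingError,
    classify,
    log_likelihoods,
    posterior_probability,
    train,
)
from radtriage.corpus_io import ClinicalReport, Corpus, Label
from radtriage.preprocess import TokenBag

FEATURE_WORDS = ("alpha", "beta", "gamma", "delta")


def corpus_from_bags(bags):
    """Build a corpus whose reports preprocess to exactly the given bags.

    ``bags`` is a list of (label, set-of-feature-words); the words avoid
    phrases, triggers and stop words so the pipeline passes them through.
    """
    reports = []
    for i, (label, feats) in enumerate(bags):
        body = " ".join(sorted(feats)) if feats else "."
        reports.append(
            ClinicalReport(
                report_id=f"d{i:02d}",
                raw_text=f"IMPRESSION: {body}\n",
                label=label,
            )
        )
    return Corpus(reports=reports)


# ---------------------------------------------------------------- oracle

def oracle_tables(bags, alpha=1.0, lo=0.01, hi=0.99):
    n_high = sum(1 for lab, _ in bags if lab is Label.high)
    n_low = len(bags) - n_high
    vocab = set().union(*(f for _, f in bags)) if bags else set()
    cond_h, cond_l = {}, {}
    for f in vocab:
        dh = sum(1 for lab, feats in bags if lab is Label.high and f in feats)
        dl = sum(1 for lab, feats in bags if lab is Label.low and f in feats)
        cond_h[f] = min(hi, max(lo, (dh + alpha) / (n_high + 2 * alpha)))
        cond_l[f] = min(hi, max(lo, (dl + alpha) / (n_low + 2 * alpha)))
    return cond_h, cond_l


def oracle_posterior(bag, cond_h, cond_l, prior):
    """Direct term-by-term product form of the two-class posterior."""
    lh = ll = 1.0
    for f in bag:
        if f in cond_h:
            lh *= cond_h[f]
            ll *= cond_l[f]
    return prior * lh / (prior * lh + (1 - prior) * ll)


def _random_training_bags(rng, n_docs):
    """Random labeled feature-subsets guaranteed to cover both classes."""
    while True:
        bags = [
            (
                Label.high if rng.random() < 0.5 else Label.low,
                {w for w in FEATURE_WORDS if rng.random() < 0.5},
            )
            for _ in range(n_docs)
        ]
        labs = {lab for lab, _ in bags}
        if labs == {Label.high, Label.low}:
            return bags


# ----------------------------------------------------------------- tests

class TestTrain:
    def test_balanced_synthetic_corpus_counts(self, training_corpus, trained_model):
        assert trained_model.n_high == 50
        assert trained_model.n_low == 50

    def test_smoothed_document_frequency_hand_example(self):
        # one feature in all highs and no lows, alpha=1: 51/52 vs 1/52
        bags = [(Label.high, {"alpha"}) for _ in range(50)] + [
            (Label.low, set()) for _ in range(50)
        ]
        model = train(corpus_from_bags(bags))
        assert model.cond_prob_high["alpha"] == pytest.approx(51 / 52, abs=1e-15)
        assert model.cond_prob_low["alpha"] == pytest.approx(1 / 52, abs=1e-15)

    def test_symmetric_feature_gets_equal_conditionals(self):
        bags = (
            [(Label.high, {"alpha"}), (Label.high, set())] * 2
            + [(Label.low, {"alpha"}), (Label.low, set())] * 2
        )
        model = train(corpus_from_bags(bags))
        assert model.cond_prob_high["alpha"] == model.cond_prob_low["alpha"]

    def test_single_class_corpus_fatal(self):
        bags = [(Label.high, {"alpha"}), (Label.high, {"beta"})]
        with pytest.raises(TrainingError, match="both classes"):
            train(corpus_from_bags(bags))

    def test_empty_corpus_fatal(self):
        with pytest.raises(TrainingError):
            train(Corpus(reports=[]))

    def test_unlabeled_report_fatal(self):
        c = Corpus(reports=[ClinicalReport("u", "IMPRESSION: alpha")])
        with pytest.raises(TrainingError, match="no label"):
            train(c)

    def test_tables_share_vocabulary_and_respect_clamps(self, trained_model):
        assert set(trained_model.cond_prob_high) == set(trained_model.cond_prob_low)
        for table in (trained_model.cond_prob_high, trained_model.cond_prob_low):
            assert all(0.01 <= p <= 0.99 for p in table.values())


class TestPosterior:
    @pytest.mark.parametrize("prior", [0.1, 0.25, 0.5, 0.9])
    def test_empty_bag_posterior_equals_prior(self, trained_model, prior):
        bag = TokenBag(features=frozenset())
        assert posterior_probability(bag, trained_model, prior) == pytest.approx(
            prior, abs=1e-12
        )

    def test_toy_single_feature_arithmetic(self):
        # vocab {"alpha"}: P(f|H)=0.9, P(f|L)=0.1 via 9-1 / 1-9 doc splits
        bags = [(Label.high, {"alpha"})] * 8 + [(Label.high, set())] * 0
        bags += [(Label.low, set())] * 8 + [(Label.low, {"alpha"})] * 0
        model = train(corpus_from_bags(bags))
        assert model.cond_prob_high["alpha"] == pytest.approx(0.9)
        assert model.cond_prob_low["alpha"] == pytest.approx(0.1)
        post = posterior_probability({"alpha"}, model, 0.5)
        assert post == pytest.approx(0.9, abs=1e-12)

    def test_matches_direct_product_oracle_on_small_problems(self):
        """Log-space implementation vs direct product evaluation, exact to
        1e-12, over vocabularies <= 4 features and <= 8 training docs."""
        rng = np.random.default_rng(2024)
        for n_docs in range(2, 9):
            for _ in range(5):
                bags = _random_training_bags(rng, n_docs)
                model = train(corpus_from_bags(bags))
                cond_h, cond_l = oracle_tables(bags)
                assert model.cond_prob_high == pytest.approx(cond_h, abs=1e-15)
                assert model.cond_prob_low == pytest.approx(cond_l, abs=1e-15)
                for k in range(len(FEATURE_WORDS) + 1):
                    for feats in itertools.combinations(FEATURE_WORDS, k):
                        for prior in (0.1, 0.25, 0.5, 0.9):
                            expected = oracle_posterior(set(feats), cond_h, cond_l, prior)
                            got = posterior_probability(set(feats), model, prior)
                            assert got == pytest.approx(expected, abs=1e-12)

    def test_log_space_agrees_with_direct_product_on_large_bags(self, trained_model):
        rng = np.random.default_rng(7)
        vocab = sorted(trained_model.vocabulary)
        for _ in range(50):
            size = int(rng.integers(1, 21))
            bag = set(rng.choice(vocab, size=min(size, len(vocab)), replace=False))
            direct = oracle_posterior(
                bag, trained_model.cond_prob_high, trained_model.cond_prob_low, 0.5
            )
            got = posterior_probability(bag, trained_model, 0.5)
            assert got == pytest.approx(direct, abs=1e-9)

    def test_out_of_vocabulary_features_are_skipped(self, trained_model):
        bag_known = {sorted(trained_model.vocabulary)[0]}
        bag_extra = bag_known | {"zzzneverseen"}
        assert posterior_probability(
            bag_extra, trained_model, 0.5
        ) == posterior_probability(bag_known, trained_model, 0.5)

    def test_invalid_prior_rejected(self, trained_model):
        with pytest.raises(ValueError):
            posterior_probability(set(), trained_model, 1.5)


class TestMonotonicity:
    def _seeded_bags(self, model, n=100, seed=123):
        rng = np.random.default_rng(seed)
        vocab = sorted(model.vocabulary)
        out = []
        for _ in range(n):
            size = int(rng.integers(0, 8))
            out.append(frozenset(rng.choice(vocab, size=size, replace=False)))
        return out

    def test_posterior_nondecreasing_in_prior(self, trained_model):
        priors = np.linspace(0.01, 0.99, 50)
        for bag in self._seeded_bags(trained_model):
            posts = [posterior_probability(bag, trained_model, p) for p in priors]
            assert all(b >= a - 1e-12 for a, b in zip(posts, posts[1:]))

    def test_high_count_nonincreasing_in_threshold(self, trained_model, test_corpus):
        from radtriage.evaluation import evaluate_grid

        thresholds = list(np.linspace(0.01, 0.99, 50))
        cells = evaluate_grid(test_corpus, trained_model, [0.5], thresholds)
        highs = [c.cm.tp + c.cm.fp for c in cells]
        assert all(b <= a for a, b in zip(highs, highs[1:]))

    def test_raising_prior_never_flips_high_to_low(self, trained_model):
        th = 0.8
        bags = self._seeded_bags(trained_model, n=60, seed=5)
        for p1, p2 in [(0.1, 0.3), (0.3, 0.5), (0.5, 0.9)]:
            for bag in bags:
                high1 = posterior_probability(bag, trained_model, p1) >= th
                high2 = posterior_probability(bag, trained_model, p2) >= th
                assert not (high1 and not high2)


class TestClassify:
    def test_empty_bag_report_scores_prior_and_thresholds(self):
        bags = [(Label.high, {"alpha"})] * 2 + [(Label.low, {"beta"})] * 2
        model = train(corpus_from_bags(bags))
        normal = ClinicalReport("n", "IMPRESSION: no evidence of fracture\n")
        s = classify(normal, model, classifier_config=ClassifierConfig(0.10, 0.50))
        assert s.posterior == pytest.approx(0.10, abs=1e-12)
        assert s.label_assigned is Label.low
        s = classify(normal, model, classifier_config=ClassifierConfig(0.50, 0.50))
        assert s.posterior == pytest.approx(0.50, abs=1e-12)
        assert s.label_assigned is Label.high  # threshold comparison is inclusive

    def test_synthetic_high_report_scores_high(self, trained_model):
        r = ClinicalReport("h", "IMPRESSION: nodule identified. possible developing mass.\n")
        s = classify(r, trained_model, classifier_config=ClassifierConfig(0.5, 0.8))
        assert s.posterior > 0.8
        assert s.label_assigned is Label.high
        assert s.features_used >= 2

    def test_empty_report_propagates_error(self, trained_model):
        with pytest.raises(ValueError, match="empty"):
            classify(ClinicalReport("e", "  "), trained_model)
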