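"""Naive Bayesian priority classifier for free-text clinical reports.

The classifier scores a report's bag of words with the two-class
posterior

    P(H | f_1..f_k) = P_p * L_H / (P_p * L_H + (1 - P_p) * L_L)

where ``L_H = prod_i P(f_i | H)`` and ``L_L = prod_i P(f_i | L)`` under
the naive independence assumption, ``P_p`` is the user-settable prior
probability that an incoming report is high-priority, and a report is
labeled high-priority when the posterior reaches the threshold ``P_th``.

Per-feature conditionals are document frequencies with Laplace
smoothing, clamped away from 0 and 1 — the canonical Bayesian
spam-filter convention, which prevents a single unseen feature from
annihilating the product.  Features absent from the training vocabulary
contribute nothing (skipping is equivalent to any constant factor
applied to both classes, and keeps scores stable as vocabularies grow).
Products are accumulated as sums of logs and the posterior is formed via
a numerically stable log-odds sigmoid, so bags of hundreds of features
cannot underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .corpus_io import ClinicalReport, Corpus, Label
from .preprocess import PreprocessConfig, TokenBag, to_token_bag
from .section_extractor import extract_impression


class TrainingError(ValueError):
    """Corpus unsuitable for training (empty, unlabeled, single-class)."""


@dataclass(frozen=True)
class ClassifierConfig:
    """Operating parameters of the classifier.

    prior_pp
        Prior probability P_p that a report is high-priority.  Raising it
        biases the classifier toward flagging, trading false positives
        for fewer (clinically costlier) false negatives.
    threshold_pth
        Posterior cutoff P_th at which a report is labeled high-priority,
        typically above 0.5.  The comparison is inclusive: a posterior
        exactly at the threshold is high.
    smoothing_alpha
        Laplace pseudo-count added to the per-class document frequencies.
    clamp_low / clamp_high
        Bounds applied to every stored conditional probability.
    """

    prior_pp: float = 0.5
    threshold_pth: float = 0.8
    smoothing_alpha: float = 1.0
    clamp_low: float = 0.01
    clamp_high: float = 0.99

    def __post_init__(self) -> None:
        if not 0.0 <= self.prior_pp <= 1.0:
            raise ValueError(f"prior_pp must be in [0,1], got {self.prior_pp}")
        if not 0.0 <= self.threshold_pth <= 1.0:
            raise ValueError(f"threshold_pth must be in [0,1], got {self.threshold_pth}")
        if self.smoothing_alpha <= 0:
            raise ValueError("smoothing_alpha must be positive")
        if not 0.0 < self.clamp_low < self.clamp_high < 1.0:
            raise ValueError("need 0 < clamp_low < clamp_high < 1")


@dataclass
class TrainedModel:
    """Per-feature conditional probability tables plus training counts."""

    n_high: int
    n_low: int
    cond_prob_high: dict[str, float]
    cond_prob_low: dict[str, float]
    smoothing_alpha: float = 1.0
    clamp_low: float = 0.01
    clamp_high: float = 0.99

    def __post_init__(self) -> None:
        if set(self.cond_prob_high) != set(self.cond_prob_low):
            raise ValueError("class tables must share one vocabulary")
        for table in (self.cond_prob_high, self.cond_prob_low):
            for f, p in table.items():
                if not self.clamp_low <= p <= self.clamp_high:
                    raise ValueError(
                        f"stored probability for {f!r} outside clamp bounds: {p}"
                    )

    @property
    def vocabulary(self) -> frozenset[str]:
        return frozenset(self.cond_prob_high)


@dataclass(frozen=True)
class ScoredReport:
    report_id: str
    posterior: float
    label_assigned: Label
    features_used: int


def _clamp(p: float, lo: float, hi: float) -> float:
    return min(hi, max(lo, p))


def train(
    corpus: Corpus,
    preprocess_config: PreprocessConfig | None = None,
    classifier_config: ClassifierConfig | None = None,
) -> TrainedModel:
    """Fit conditional probability tables from a fully labeled corpus.

    For every feature f in the union of training bags,

        P(f | H) = clamp((d_H(f) + alpha) / (n_high + 2*alpha))

    where ``d_H(f)`` counts high-priority documents whose bag contains f
    (document frequency, not term frequency), and symmetrically for the
    low-priority class.
    """
    cfg = classifier_config or ClassifierConfig()
    pp_cfg = preprocess_config or PreprocessConfig()

    bags: list[tuple[Label, TokenBag]] = []
    for report in corpus:
        if report.label is None:
            raise TrainingError(f"report {report.report_id!r} has no label")
        if not report.raw_text.strip():
            raise TrainingError(f"report {report.report_id!r} has empty text")
        section = extract_impression(report)
        bags.append((report.label, to_token_bag(section.text, pp_cfg, report.report_id)))

    n_high = sum(1 for lab, _ in bags if lab is Label.high)
    n_low = len(bags) - n_high
    if len(bags) == 0:
        raise TrainingError("cannot train on an empty corpus")
    if n_high == 0 or n_low == 0:
        raise TrainingError(
            f"training corpus must contain both classes (got {n_high} high, {n_low} low)"
        )

    df_high: dict[str, int] = {}
    df_low: dict[str, int] = {}
    for lab, bag in bags:
        table = df_high if lab is Label.high else df_low
        for f in bag.features:
            table[f] = table.get(f, 0) + 1

    a = cfg.smoothing_alpha
    vocab = sorted(set(df_high) | set(df_low))
    cond_high = {
        f: _clamp((df_high.get(f, 0) + a) / (n_high + 2 * a), cfg.clamp_low, cfg.clamp_high)
        for f in vocab
    }
    cond_low = {
        f: _clamp((df_low.get(f, 0) + a) / (n_low + 2 * a), cfg.clamp_low, cfg.clamp_high)
        for f in vocab
    }
    return TrainedModel(
        n_high=n_high,
        n_low=n_low,
        cond_prob_high=cond_high,
        cond_prob_low=cond_low,
        smoothing_alpha=a,
        clamp_low=cfg.clamp_low,
        clamp_high=cfg.clamp_high,
    )


def log_likelihoods(bag: TokenBag | Iterable[str], model: TrainedModel) -> tuple[float, float]:
    """(log L_H, log L_L) over the bag's in-vocabulary features.

    The empty product is 1 (log 0.0), so an empty bag scores exactly the
    prior.  Exposed separately so a prior/threshold sweep can score each
    report once.
    """
    features = bag.features if isinstance(bag, TokenBag) else frozenset(bag)
    llh = 0.0
    lll = 0.0
    for f in sorted(features):
        ph = model.cond_prob_high.get(f)
        if ph is None:
            continue  # out-of-vocabulary features are skipped
        llh += math.log(ph)
        lll += math.log(model.cond_prob_low[f])
    return llh, lll


def posterior_from_log_likelihoods(llh: float, lll: float, prior_pp: float) -> float:
    """Stable two-class posterior from per-class log-likelihoods."""
    if prior_pp <= 0.0:
        return 0.0
    if prior_pp >= 1.0:
        return 1.0
    # posterior = 1 / (1 + exp(log(1-p) + lll - log(p) - llh))
    log_odds = (math.log(prior_pp) + llh) - (math.log1p(-prior_pp) + lll)
    if log_odds >= 0:
        return 1.0 / (1.0 + math.exp(-log_odds))
    z = math.exp(log_odds)
    return z / (1.0 + z)


def posterior_probability(
    bag: TokenBag | Iterable[str], model: TrainedModel, prior_pp: float
) -> float:
    """Posterior probability that the report behind ``bag`` is high-priority."""
    if not 0.0 <= prior_pp <= 1.0:
        raise ValueError(f"prior_pp must be in [0,1], got {prior_pp}")
    if model.n_high < 1 or model.n_low < 1:
        raise TrainingError("model is not trained (needs >=1 document per class)")
    llh, lll = log_likelihoods(bag, model)
    return posterior_from_log_likelihoods(llh, lll, prior_pp)


def classify(
    report: ClinicalReport,
    model: TrainedModel,
    preprocess_config: PreprocessConfig | None = None,
    classifier_config: ClassifierConfig | None = None,
) -> ScoredReport:
    """Score one report end-to-end: extract -> scrub -> bag -> posterior.

    The assigned label is high iff posterior >= threshold_pth.
    """
    cfg = classifier_config or ClassifierConfig()
    pp_cfg = preprocess_config or PreprocessConfig()
    section = extract_impression(report)
    bag = to_token_bag(section.text, pp_cfg, report.report_id)
    post = posterior_probability(bag, model, cfg.prior_pp)
    label = Label.high if post >= cfg.threshold_pth else Label.low
    used = sum(1 for f in bag.features if f in model.cond_prob_high)
    return ScoredReport(
        report_id=report.report_id,
        posterior=post,
        label_assigned=label,
        features_used=used,
    )


def classify_corpus(
    corpus: Corpus,
    model: TrainedModel,
    preprocess_config: PreprocessConfig | None = None,
    classifier_config: ClassifierConfig | None = None,
) -> list[ScoredReport]:
    """Classify every report in corpus order (sorted by report_id)."""
    return [
        classify(r, model, preprocess_config, classifier_config) for r in corpus
    ]
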