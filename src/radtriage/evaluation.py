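"""Evaluation: confusion matrices, the four classification metrics,
false-negative rate, Cohen's kappa, score histograms, and operating-point
grids over (prior, threshold).

High-priority is the positive class throughout.  Metrics are carried at
full precision as fractions of 100 and rounded only for presentation; a
metric with a zero denominator is reported as undefined (``None``),
never silently as 0 or 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .bayes_classifier import (
    ClassifierConfig,
    ScoredReport,
    TrainedModel,
    log_likelihoods,
    posterior_from_log_likelihoods,
)
from .corpus_io import Corpus, Label
from .preprocess import PreprocessConfig, to_token_bag
from .section_extractor import extract_impression


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The four headline metrics plus false-negative rate, as percentages.

    ``None`` marks a metric whose denominator was zero (undefined).
    """

    precision: Optional[float]
    recall: Optional[float]
    f_measure: Optional[float]
    accuracy: Optional[float]
    fn_rate: Optional[float]

    def rounded(self, ndigits: int = 2) -> dict[str, Optional[float]]:
        """Presentation form: two decimals, matching the printed tables."""
        return {
            k: (None if v is None else round(v, ndigits))
            for k, v in self.__dict__.items()
        }


@dataclass(frozen=True)
class ScoreHistogram:
    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]


def confusion(
    scored: Iterable[ScoredReport], gold: Mapping[str, Optional[Label]]
) -> ConfusionMatrix:
    """Count TP/FP/TN/FN of assigned labels against gold labels."""
    tp = fp = tn = fn = 0
    for s in scored:
        g = gold.get(s.report_id)
        if g is None:
            raise EvaluationError(f"report {s.report_id!r} has no gold label")
        if s.label_assigned is Label.high:
            if g is Label.high:
                tp += 1
            else:
                fp += 1
        else:
            if g is Label.low:
                tn += 1
            else:
                fn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Precision, recall, F-measure, accuracy and FN rate (percent).

    precision = 100*TP/(TP+FP);  recall = 100*TP/(TP+FN);
    F = 2*precision*recall/(precision+recall)  (from unrounded values);
    accuracy = 100*(TP+TN)/total;  fn_rate = 100*FN/total.
    """
    precision = 100.0 * cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp > 0 else None
    recall = 100.0 * cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else None
    if precision is None or recall is None or precision + recall == 0:
        f_measure = None
    else:
        f_measure = 2.0 * precision * recall / (precision + recall)
    accuracy = 100.0 * (cm.tp + cm.tn) / cm.total if cm.total > 0 else None
    fn_rate = 100.0 * cm.fn / cm.total if cm.total > 0 else None
    return MetricsReport(
        precision=precision,
        recall=recall,
        f_measure=f_measure,
        accuracy=accuracy,
        fn_rate=fn_rate,
    )


def score_histogram(
    posteriors: Iterable[float], bin_width: float = 0.1
) -> ScoreHistogram:
    """Histogram of posteriors over [0,1] in half-open bins of bin_width.

    Bins are [k*w, (k+1)*w) with the final bin closed at 1.0, so the
    counts always conserve the number of scored reports.
    """
    if not 0.0 < bin_width <= 1.0:
        raise ValueError(f"bin_width must be in (0,1], got {bin_width}")
    n_bins = int(np.ceil(round(1.0 / bin_width, 12)))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 1.0)
    edges[-1] = 1.0
    values = np.asarray(list(posteriors), dtype=float)
    if values.size and ((values < 0).any() or (values > 1).any()):
        raise ValueError("posteriors must lie in [0,1]")
    counts, _ = np.histogram(values, bins=edges)  # numpy closes the last bin
    return ScoreHistogram(
        bin_edges=tuple(float(e) for e in edges),
        counts=tuple(int(c) for c in counts),
    )


def cohens_kappa(
    ratings_a: Sequence[Label | str], ratings_b: Sequence[Label | str]
) -> float:
    """Cohen's kappa for two parallel low/high rating sequences.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the observed agreement
    fraction and p_e the chance agreement from the raters' marginals.
    Returns 1.0 in the degenerate perfect-agreement case p_o = p_e = 1.
    """
    if len(ratings_a) != len(ratings_b):
        raise EvaluationError(
            f"rating sequences differ in length: {len(ratings_a)} vs {len(ratings_b)}"
        )
    if len(ratings_a) == 0:
        raise EvaluationError("rating sequences must be non-empty")
    a = [Label(x) for x in ratings_a]
    b = [Label(x) for x in ratings_b]
    n = len(a)
    p_o = sum(1 for x, y in zip(a, b) if x == y) / n
    p_e = 0.0
    for cls in Label:
        p_e += (sum(1 for x in a if x == cls) / n) * (sum(1 for y in b if y == cls) / n)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


@dataclass(frozen=True)
class GridCell:
    prior_pp: float
    threshold_pth: float
    cm: ConfusionMatrix
    metrics: MetricsReport


def evaluate_grid(
    corpus: Corpus,
    model: TrainedModel,
    priors: Sequence[float],
    thresholds: Sequence[float],
    preprocess_config: PreprocessConfig | None = None,
) -> list[GridCell]:
    """Confusion matrix + metrics at every (prior, threshold) pair.

    Each report is preprocessed and its per-class log-likelihoods
    computed exactly once; posteriors are then formed per prior and
    thresholds applied without rescoring, so the grid is consistent with
    classify() by construction.
    """
    if not priors or not thresholds:
        raise EvaluationError("priors and thresholds must be non-empty")
    pp_cfg = preprocess_config or PreprocessConfig()
    gold: dict[str, Label] = {}
    loglik: list[tuple[str, float, float]] = []
    for report in corpus:
        if report.label is None:
            raise EvaluationError(f"report {report.report_id!r} has no gold label")
        gold[report.report_id] = report.label
        section = extract_impression(report)
        bag = to_token_bag(section.text, pp_cfg, report.report_id)
        llh, lll = log_likelihoods(bag, model)
        loglik.append((report.report_id, llh, lll))

    cells: list[GridCell] = []
    for prior in priors:
        posteriors = [
            (rid, posterior_from_log_likelihoods(llh, lll, prior))
            for rid, llh, lll in loglik
        ]
        for th in thresholds:
            tp = fp = tn = fn = 0
            for rid, post in posteriors:
                assigned_high = post >= th
                if assigned_high and gold[rid] is Label.high:
                    tp += 1
                elif assigned_high:
                    fp += 1
                elif gold[rid] is Label.low:
                    tn += 1
                else:
                    fn += 1
            cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
            cells.append(
                GridCell(
                    prior_pp=prior,
                    threshold_pth=th,
                    cm=cm,
                    metrics=compute_metrics(cm),
                )
            )
    return cells


def grid_to_dataframe(cells: Sequence[GridCell]) -> pd.DataFrame:
    """Flatten grid cells into the evaluation CSV schema."""
    rows = []
    for c in cells:
        m = c.metrics
        rows.append(
            {
                "prior_pp": c.prior_pp,
                "threshold_pth": c.threshold_pth,
                "tp": c.cm.tp,
                "fp": c.cm.fp,
                "tn": c.cm.tn,
                "fn": c.cm.fn,
                "precision": "undefined" if m.precision is None else round(m.precision, 2),
                "recall": "undefined" if m.recall is None else round(m.recall, 2),
                "f_measure": "undefined" if m.f_measure is None else round(m.f_measure, 2),
                "accuracy": "undefined" if m.accuracy is None else round(m.accuracy, 2),
                "fn_rate": "undefined" if m.fn_rate is None else round(m.fn_rate, 2),
            }
        )
    return pd.DataFrame(rows)


def histogram_to_dataframe(hist: ScoreHistogram) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin_start": hist.bin_edges[:-1],
            "bin_end": hist.bin_edges[1:],
            "count": hist.counts,
        }
    )
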