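"""Scoring predicted networks against gold standards.

Implements the standard confusion battery (TPR, FPR, ACC, PPV, MCC) and
ROC AUC, pooled over an explicit candidate-pair universe or aggregated per
target gene / per regulator.  The universe — which ordered (regulator,
target) pairs count as possible edges — is always an explicit argument:
benchmarks differ on whether it is all ordered pairs or only
regulator-restricted pairs, so it is never inferred silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .simulate import GoldStandardNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "PerGeneAUCSummary",
    "confusion_metrics",
    "roc_auc",
    "per_gene_auc",
    "evaluate_prediction",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn


@dataclass
class MetricsReport:
    """One row of the benchmark battery: TPR, FPR, ACC, PPV, MCC (+ AUC)."""

    tpr: float
    fpr: float
    acc: float
    ppv: float
    mcc: float
    auc: float | None = None
    counts: ConfusionCounts | None = None

    def to_dict(self) -> dict:
        d = {
            "FPR": self.fpr,
            "TPR": self.tpr,
            "ACC": self.acc,
            "PPV": self.ppv,
            "MCC": self.mcc,
        }
        if self.auc is not None:
            d["AUC"] = self.auc
        return d


def confusion_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Confusion-derived battery from explicit counts.

    Conventions for the degenerate corners (so batch evaluation never
    aborts): PPV is 0 when nothing was predicted positive; MCC is 0 when any
    marginal factor of its denominator is 0.

    Raises
    ------
    ValueError
        If the gold standard has no positives or no negatives — every rate
        would be undefined.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    if counts.positives == 0 or counts.negatives == 0:
        raise ValueError("gold standard must contain positives and negatives")
    tpr = tp / counts.positives
    fpr = fp / counts.negatives
    acc = (tp + tn) / (tp + fp + fn + tn)
    if tp + fp == 0:
        logger.info("no positive predictions: PPV set to 0")
        ppv = 0.0
    else:
        ppv = tp / (tp + fp)
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        logger.info("degenerate MCC denominator: MCC set to 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom2)
    return MetricsReport(tpr, fpr, acc, ppv, float(mcc), counts=counts)


def _positive_pairs(gold) -> set:
    if isinstance(gold, GoldStandardNetwork):
        return set(gold.edges)
    return set(gold)


def roc_auc(scores, gold, universe) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) formulation.

    Ties count 1/2, which makes this identical to the trapezoidal area over
    all score thresholds.  Pairs in `universe` missing from `scores` are
    treated as score 0 (unpredicted).

    Parameters
    ----------
    scores : mapping (regulator, target) -> float
    gold : GoldStandardNetwork or set of positive pairs
    universe : iterable of ordered pairs to rank (>= 1 positive and >= 1
        negative required).
    """
    positives = _positive_pairs(gold)
    universe = list(universe)
    labels = np.array([pair in positives for pair in universe], dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("universe needs at least one positive and one negative pair")
    s = np.array([float(scores.get(pair, 0.0)) for pair in universe])
    ranks = rankdata(s)  # average ranks: ties contribute 1/2
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class PerGeneAUCSummary:
    """Per-gene AUC distribution along one axis (by target or by regulator)."""

    per_gene: dict
    min: float
    max: float
    median: float
    mean: float
    cutoff: float
    count_above: int
    fraction_above: float  # percentage of eligible genes with AUC > cutoff
    n_excluded: int = 0
    excluded: list = field(default_factory=list)


def per_gene_auc(
    scores,
    gold,
    universe,
    axis: str = "by_target",
    cutoff: float = 0.8,
) -> PerGeneAUCSummary:
    """AUC aggregated per target gene or per regulator.

    Genes whose slice of the universe lacks either a positive or a negative
    pair are excluded from the distribution and reported in the summary
    (their AUC is undefined).

    Parameters
    ----------
    axis : "by_target" or "by_regulator"
        Group the universe by the pair's target (candidate-TF ranking per
        TG) or by its regulator (target ranking per TF).
    cutoff : float
        Threshold for the `count_above` / `fraction_above` summary
        (strictly greater).
    """
    if axis not in ("by_target", "by_regulator"):
        raise ValueError("axis must be 'by_target' or 'by_regulator'")
    key = (lambda p: p[1]) if axis == "by_target" else (lambda p: p[0])
    groups: dict = {}
    for pair in universe:
        groups.setdefault(key(pair), []).append(pair)

    per_gene, excluded = {}, []
    positives = _positive_pairs(gold)
    for gene in sorted(groups):
        pairs = groups[gene]
        n_pos = sum(p in positives for p in pairs)
        if n_pos == 0 or n_pos == len(pairs):
            excluded.append(gene)
            continue
        per_gene[gene] = roc_auc(scores, positives, pairs)
    if not per_gene:
        raise ValueError("no gene has both a positive and a negative pair")

    vals = np.array(list(per_gene.values()))
    count_above = int((vals > cutoff).sum())
    return PerGeneAUCSummary(
        per_gene=per_gene,
        min=float(vals.min()),
        max=float(vals.max()),
        median=float(np.median(vals)),
        mean=float(vals.mean()),
        cutoff=cutoff,
        count_above=count_above,
        fraction_above=100.0 * count_above / len(vals),
        n_excluded=len(excluded),
        excluded=excluded,
    )


def evaluate_prediction(
    pred, gold, universe, threshold: float = 0.0
) -> MetricsReport:
    """Full benchmark row for a predicted network against a gold standard.

    Predictions are binarised at ``strength > threshold`` for the confusion
    battery; the continuous strengths feed the AUC.

    Parameters
    ----------
    pred : WeightedNetwork or mapping (regulator, target) -> strength
    gold : GoldStandardNetwork or set of positive pairs
    universe : iterable of ordered candidate pairs (explicit, never
        inferred).
    threshold : float
        Binarisation cut for calling an edge predicted.

    Raises
    ------
    ValueError
        If the prediction scores pairs outside the universe's gene set
        (identifier mismatch).
    """
    scores = pred.scores() if hasattr(pred, "scores") else dict(pred)
    universe = list(universe)
    uni = set(universe)
    stray = sorted(set(scores) - uni)
    if stray:
        raise ValueError(
            f"predicted pairs outside the evaluation universe: {stray[:10]}"
        )
    positives = _positive_pairs(gold)
    tp = fp = fn = tn = 0
    for pair in universe:
        predicted = scores.get(pair, 0.0) > threshold
        actual = pair in positives
        if predicted and actual:
            tp += 1
        elif predicted:
            fp += 1
        elif actual:
            fn += 1
        else:
            tn += 1
    report = confusion_metrics(ConfusionCounts(tp, fp, fn, tn))
    report.auc = roc_auc(scores, positives, universe)
    return report
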