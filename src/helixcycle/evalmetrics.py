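"""Evaluation toolkit: multiclass clustering metrics, gene–pseudotime
correlation and one-way ANOVA of pseudotime across phases.

Because the stage calls are unsupervised clusters, classification-style
metrics (accuracy, macro precision/recall/F1) are computed after an optimal
Hungarian matching of predicted to true labels; the partition metrics
(RI, ARI, NMI) are label-matching-invariant and computed on the raw
partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import scipy.stats
from scipy.optimize import linear_sum_assignment
from sklearn import metrics as skm


@dataclass
class MetricsReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_fscore: float
    rand_index: float
    adjusted_rand_index: float
    nmi: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def match_labels(pred, truth) -> dict:
    """Best bijection predicted-label → true-label by Hungarian assignment.

    Maximizes total agreement on the confusion matrix. Predicted labels
    beyond the size of the true label set (or vice versa) are matched to
    themselves' leftovers arbitrarily but deterministically.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    pl = sorted(set(pred.tolist()))
    tl = sorted(set(truth.tolist()))
    conf = np.zeros((len(pl), len(tl)))
    p_idx = {l: i for i, l in enumerate(pl)}
    t_idx = {l: i for i, l in enumerate(tl)}
    for p, t in zip(pred, truth):
        conf[p_idx[p], t_idx[t]] += 1
    # pad to square so every predicted label gets an image
    k = max(len(pl), len(tl))
    padded = np.zeros((k, k))
    padded[: len(pl), : len(tl)] = conf
    rows, cols = linear_sum_assignment(-padded)
    mapping = {}
    for r, c in zip(rows, cols):
        if r < len(pl):
            mapping[pl[r]] = tl[c] if c < len(tl) else pl[r]
    return mapping


def classification_metrics(pred, truth) -> MetricsReport:
    """The seven-metric report used throughout evaluation.

    Accuracy and the macro-averaged precision/recall/F1 are computed after
    `match_labels`; classes absent from the matched predictions contribute 0
    to the macro averages. RI is the pairwise-agreement fraction, ARI its
    chance-corrected form, NMI uses the arithmetic-mean normalization.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    if len(set(truth.tolist())) < 2:
        raise ValueError("truth must contain at least 2 classes")
    mapping = match_labels(pred, truth)
    mapped = np.asarray([mapping[p] for p in pred])
    labels = sorted(set(truth.tolist()))
    prec, rec, f1, _ = skm.precision_recall_fscore_support(
        truth, mapped, labels=labels, average="macro", zero_division=0
    )
    return MetricsReport(
        accuracy=float(skm.accuracy_score(truth, mapped)),
        macro_precision=float(prec),
        macro_recall=float(rec),
        macro_fscore=float(f1),
        rand_index=float(skm.rand_score(truth, pred)),
        adjusted_rand_index=float(skm.adjusted_rand_score(truth, pred)),
        nmi=float(skm.normalized_mutual_info_score(
            truth, pred, average_method="arithmetic")),
    )


def pearson_pseudotime_correlation(expr, pseudotime) -> tuple[float, float]:
    """Pearson r between one gene's expression and pseudotime, with p-value."""
    expr = np.asarray(expr, dtype=float)
    pseudotime = np.asarray(pseudotime, dtype=float)
    if expr.size != pseudotime.size or expr.size < 3:
        raise ValueError("need two equal-length vectors with at least 3 cells")
    if np.std(expr) == 0 or np.std(pseudotime) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = scipy.stats.pearsonr(expr, pseudotime)
    return float(r), float(p)


def anova_oneway(values, groups) -> tuple[float, float]:
    """Classical one-way ANOVA of `values` across the levels of `groups`."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    samples = [values[groups == g] for g in sorted(set(groups.tolist()))]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups each with >= 2 members")
    f, p = scipy.stats.f_oneway(*samples)
    return float(f), float(p)
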