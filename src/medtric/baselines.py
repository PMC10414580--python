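"""Baseline multi-label metrics MedTric is compared against.

Label-based metrics (micro/macro precision, recall, F1) pool or average
per-class binary counts; example-based metrics (Hamming loss, accuracy,
precision, recall, F1, subset accuracy) average per-instance set statistics;
the Challenge Metric is the weighted-accuracy score of the PhysioNet/CinC
2020-21 ECG challenge, normalised against the all-normal prediction set.

Conventions: example-based precision divides by |z| and recall by |y| (the
standard meaning); any 0/0 ratio is defined as 0.  Hamming loss is a loss
(lower is better); every other metric rewards (higher is better); the
Challenge Metric can go negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .label_model import DiagnosisCatalog, EvaluationSet, MetricConfig, ValidationError

__all__ = [
    "PerClassCounts",
    "per_class_counts",
    "label_based",
    "example_based",
    "challenge_metric",
    "all_metrics",
]


@dataclass
class PerClassCounts:
    """tp/fp/fn per catalog code; tp_j + fn_j equals the prevalence n_j."""

    tp: dict[str, int]
    fp: dict[str, int]
    fn: dict[str, int]

    def pooled(self) -> tuple[int, int, int]:
        return sum(self.tp.values()), sum(self.fp.values()), sum(self.fn.values())


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def per_class_counts(evaluation_set: EvaluationSet) -> PerClassCounts:
    codes = evaluation_set.catalog.codes
    tp = dict.fromkeys(codes, 0)
    fp = dict.fromkeys(codes, 0)
    fn = dict.fromkeys(codes, 0)
    for pair in evaluation_set.pairs:
        for c in pair.truth & pair.prediction:
            tp[c] += 1
        for c in pair.prediction - pair.truth:
            fp[c] += 1
        for c in pair.truth - pair.prediction:
            fn[c] += 1
    return PerClassCounts(tp=tp, fp=fp, fn=fn)


def label_based(evaluation_set: EvaluationSet) -> dict[str, float]:
    """Macro and micro precision/recall/F1 over the catalog classes.

    Macro averages the per-class binary metrics unweighted (favouring rare
    classes); micro pools tp/fp/fn before computing (favouring common ones).
    """
    counts = per_class_counts(evaluation_set)
    codes = evaluation_set.catalog.codes
    precisions, recalls, f1s = [], [], []
    for c in codes:
        p = _safe_div(counts.tp[c], counts.tp[c] + counts.fp[c])
        r = _safe_div(counts.tp[c], counts.tp[c] + counts.fn[c])
        precisions.append(p)
        recalls.append(r)
        f1s.append(_safe_div(2 * p * r, p + r))
    tp, fp, fn = counts.pooled()
    micro_p = _safe_div(tp, tp + fp)
    micro_r = _safe_div(tp, tp + fn)
    return {
        "macro_precision": float(np.mean(precisions)),
        "macro_recall": float(np.mean(recalls)),
        "macro_f1": float(np.mean(f1s)),
        "micro_precision": micro_p,
        "micro_recall": micro_r,
        "micro_f1": _safe_div(2 * micro_p * micro_r, micro_p + micro_r),
    }


def example_based(evaluation_set: EvaluationSet) -> dict[str, float]:
    """Hamming loss, accuracy, precision, recall, F1 and subset accuracy.

    All are per-instance set statistics averaged over the N instances;
    Hamming loss normalises the symmetric difference by the catalog size P.
    """
    P = evaluation_set.catalog.size
    N = evaluation_set.n_instances
    hamming = accuracy = precision = recall = f1 = subset = 0.0
    for pair in evaluation_set.pairs:
        y, z = pair.truth, pair.prediction
        inter = len(y & z)
        hamming += len(y ^ z) / P
        accuracy += _safe_div(inter, len(y | z))
        precision += _safe_div(inter, len(z))
        recall += inter / len(y)
        f1 += _safe_div(2 * inter, len(z) + len(y))
        subset += 1.0 if y == z else 0.0
    return {
        "hamming_loss": hamming / N,
        "accuracy": accuracy / N,
        "precision": precision / N,
        "recall": recall / N,
        "f1": f1 / N,
        "subset_accuracy": subset / N,
    }


def _cm_total(
    evaluation_set: EvaluationSet,
    weights: np.ndarray,
    predictions: list[frozenset[str]],
) -> float:
    """t(Y, Z) = sum_jk w_jk a_jk with a_jk the normalised co-occurrence of
    predicted code k alongside true code j."""
    catalog = evaluation_set.catalog
    A = np.zeros((catalog.size, catalog.size))
    for pair, pred in zip(evaluation_set.pairs, predictions):
        union = len(pair.truth | pred)
        if union == 0:
            continue
        inc = 1.0 / union
        for cj in pair.truth:
            j = catalog.index(cj)
            for ck in pred:
                A[j, catalog.index(ck)] += inc
    return float(np.sum(weights * A))


def challenge_metric(
    evaluation_set: EvaluationSet,
    weights: np.ndarray | None = None,
    normal_code: str | None = None,
    config: MetricConfig | None = None,
) -> float:
    """PhysioNet Challenge Metric: weighted accuracy normalised so that
    predicting the normal class everywhere scores 0 and perfection scores 1.

    ``weights`` defaults to the config's similarity matrix; ``normal_code``
    defaults to the catalog's.  Unbounded below: predictions similar to the
    normal class can outscore genuine partial detections.
    """
    catalog = evaluation_set.catalog
    if weights is None:
        if config is None:
            raise ValidationError("challenge_metric needs weights or a config")
        weights = config.similarity
    weights = np.asarray(weights, dtype=float)
    if normal_code is None:
        normal_code = catalog.normal_code
    if normal_code is None or normal_code not in catalog:
        raise ValidationError("challenge_metric needs a normal class in the catalog")
    if weights.shape != (catalog.size, catalog.size):
        raise ValidationError("weight matrix shape must match the catalog")
    if not np.allclose(np.diag(weights), 1.0):
        raise ValidationError("weight matrix must have unit diagonal")

    actual = [p.prediction for p in evaluation_set.pairs]
    perfect = [p.truth for p in evaluation_set.pairs]
    all_normal = [frozenset({normal_code})] * evaluation_set.n_instances

    t_actual = _cm_total(evaluation_set, weights, actual)
    t_perfect = _cm_total(evaluation_set, weights, perfect)
    t_normal = _cm_total(evaluation_set, weights, all_normal)
    denom = t_perfect - t_normal
    if abs(denom) < 1e-15:
        raise ValidationError(
            "degenerate Challenge Metric normaliser: perfect and all-normal "
            "totals coincide"
        )
    return (t_actual - t_normal) / denom


def all_metrics(
    evaluation_set: EvaluationSet, config: MetricConfig
) -> dict[str, float]:
    """Every baseline plus MedTric, keyed by name — the `compare` table."""
    from .core import medtric  # local import to avoid a cycle

    out: dict[str, float] = {"medtric": medtric(evaluation_set, config).score}
    out.update(label_based(evaluation_set))
    eb = example_based(evaluation_set)
    out.update({f"example_{k}" if not k.startswith(("hamming", "subset")) else k: v
                for k, v in eb.items()})
    if evaluation_set.catalog.normal_code is not None:
        out["challenge_metric"] = challenge_metric(evaluation_set, config=config)
    return out
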