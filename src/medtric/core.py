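"""The MedTric score.

MedTric scores a multi-label diagnostic system from its (truth, prediction)
set pairs alone, encoding four clinical principles: missed diagnoses are
penalised more than over-diagnoses, wrong (disjoint) diagnoses worst of all;
per-diagnosis significance weights; partial credit for predicting clinically
similar conditions; and an extra penalty for predicting contradictory pairs.
Every per-label contribution is divided by that label's prevalence n_j in the
evaluation set, which makes the final score invariant to the class mix of the
dataset.

Per instance i and catalog code j the contribution is

    a_i(j) =  s_j / n_j                                  if j correct (in y and z)
             -s_j / n_j                                  if j missed  (in y only)
              s_j / n* * [ mean_{k in y} w_jk  - 1 ]     if j extra   (in z only)
              0                                          otherwise

with n* the largest prevalence among the instance's truth codes, plus a
contradiction penalty b_i(j) = -(1/n_j) * sum over predicted k of s_k C_jk for
each predicted j.  Instance totals t_i are summed over the dataset and
normalised between the all-empty prediction (score 0) and the perfect
prediction (score 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .label_model import (
    EvaluationSet,
    InstancePair,
    MetricConfig,
    ValidationError,
)

__all__ = [
    "InstanceScoreBreakdown",
    "MedtricResult",
    "label_contribution",
    "contradiction_penalty",
    "instance_score",
    "medtric",
    "clinical_order_margin",
    "margin_from_counts",
]


@dataclass
class InstanceScoreBreakdown:
    """Per-code reward/penalty decomposition of one instance's score t_i."""

    instance_id: str
    per_code_a: dict[str, float]
    per_code_b: dict[str, float]
    total: float


@dataclass
class MedtricResult:
    """Normalised MedTric score with its normalisation anchors.

    ``score = (raw_t - null_t) / (perfect_t - null_t)`` where ``null_t`` is
    the total of the all-empty prediction set and ``perfect_t`` the total of
    predicting every truth exactly.
    """

    score: float
    raw_t: float
    null_t: float
    perfect_t: float
    breakdowns: list[InstanceScoreBreakdown] | None = None


def _effective_n(code: str, prevalence: Mapping[str, int], floor: int) -> int:
    n = prevalence.get(code, 0)
    return n if n > 0 else floor


def label_contribution(
    code: str,
    truth: frozenset[str],
    prediction: frozenset[str],
    prevalence: Mapping[str, int],
    config: MetricConfig,
) -> float:
    """The reward/penalty a_i(j) of one catalog code for one instance.

    Correct codes earn s_j/n_j, missed codes lose s_j/n_j, and extra codes
    lose at most s_j/n* scaled down by the mean similarity of the extra code
    to the instance's true codes (n* = max prevalence over the truth codes).
    A code in neither set contributes 0.
    """
    in_truth = code in truth
    in_pred = code in prediction
    if not in_truth and not in_pred:
        return 0.0
    s_j = config.s(code)
    if in_truth:
        n_j = prevalence.get(code, 0)
        if n_j <= 0:
            raise ValidationError(
                f"truth code {code!r} has zero prevalence; the evaluation set "
                "was not built from these pairs"
            )
        return s_j / n_j if in_pred else -s_j / n_j
    # extra prediction: partial penalty weighted by similarity to the truth
    n_star = max(
        _effective_n(c, prevalence, config.prevalence_floor) for c in truth
    )
    mean_w = sum(config.w(code, k) for k in truth) / len(truth)
    return (s_j / n_star) * (mean_w - 1.0)


def contradiction_penalty(
    code: str,
    prediction: frozenset[str],
    prevalence: Mapping[str, int],
    config: MetricConfig,
) -> float:
    """b_i(j): penalty for predicting ``code`` alongside contradicting codes.

    Each member of a predicted contradictory pair incurs its own penalty
    (the pair is penalised from both sides, each with its own 1/n_j factor).
    Codes never seen in any ground truth use the configured prevalence floor.
    """
    if code not in prediction:
        return 0.0
    total = sum(
        config.s(k) for k in prediction if k != code and config.contradicts(code, k)
    )
    if total == 0.0:
        return 0.0
    n_j = _effective_n(code, prevalence, config.prevalence_floor)
    return -total / n_j


def instance_score(
    pair: InstancePair,
    evaluation_set: EvaluationSet,
    config: MetricConfig,
) -> InstanceScoreBreakdown:
    """t_i = sum over catalog codes of a_i(j) + b_i(j).

    Only codes in the truth or the prediction can contribute, so the sum is
    taken over their union.
    """
    prevalence = evaluation_set.prevalence
    per_a: dict[str, float] = {}
    per_b: dict[str, float] = {}
    total = 0.0
    for code in pair.truth | pair.prediction:
        a = label_contribution(code, pair.truth, pair.prediction, prevalence, config)
        b = contradiction_penalty(code, pair.prediction, prevalence, config)
        per_a[code] = a
        per_b[code] = b
        total += a + b
    return InstanceScoreBreakdown(
        instance_id=pair.instance_id, per_code_a=per_a, per_code_b=per_b, total=total
    )


def _total(
    evaluation_set: EvaluationSet,
    config: MetricConfig,
    predictions: Mapping[str, frozenset[str]] | None = None,
) -> float:
    """t(Y, Z): dataset total, optionally with substituted predictions."""
    total = 0.0
    for pair in evaluation_set.pairs:
        if predictions is not None:
            pair = InstancePair(
                pair.instance_id, pair.truth, predictions[pair.instance_id]
            )
        total += instance_score(pair, evaluation_set, config).total
    return total


def medtric(
    evaluation_set: EvaluationSet,
    config: MetricConfig,
    with_breakdowns: bool = False,
) -> MedtricResult:
    """Compute the normalised MedTric score of an evaluation set.

    The raw total is normalised so that the inactive classifier (predicting
    nothing) scores exactly 0 and the perfect classifier exactly 1.
    """
    config.check_truths(evaluation_set)

    breakdowns = None
    raw_t = 0.0
    if with_breakdowns:
        breakdowns = [
            instance_score(p, evaluation_set, config) for p in evaluation_set.pairs
        ]
        raw_t = sum(b.total for b in breakdowns)
    else:
        raw_t = _total(evaluation_set, config)

    empty = frozenset()
    null_t = _total(
        evaluation_set, config,
        {p.instance_id: empty for p in evaluation_set.pairs},
    )
    perfect_t = _total(
        evaluation_set, config,
        {p.instance_id: p.truth for p in evaluation_set.pairs},
    )
    denom = perfect_t - null_t
    if denom <= 0:
        raise ValidationError(
            "degenerate evaluation set: perfect and null totals coincide"
        )
    return MedtricResult(
        score=(raw_t - null_t) / denom,
        raw_t=raw_t,
        null_t=null_t,
        perfect_t=perfect_t,
        breakdowns=breakdowns,
    )


# ---------------------------------------------------------------------------
# Clinical-order guarantee margin
# ---------------------------------------------------------------------------


def margin_from_counts(
    code: str,
    tp: int,
    fp: int,
    fn: int,
    n_k: int,
    n_star: int,
    config: MetricConfig,
) -> float:
    """xi_k computed from per-class counts.

    xi_k = (s_k / n_k) * [ fp * (n_k / n*) * (1 - w*_k) - 2 * fn ]

    with w*_k the smallest similarity of code k to any other code.  The
    margin compares the per-class score a pure missed-diagnosis classifier
    attains against the worst-case score of a pure over-diagnosis classifier;
    xi_k < 0 for all k certifies that missed diagnoses rank below
    over-diagnoses (the clinical order) for this class configuration.
    """
    del tp  # cancels in the margin (tp - fn - n_k = -2 fn)
    i = config.catalog.index(code)
    row = config.similarity[i]
    if len(row) > 1:
        w_star = min(row[j] for j in range(len(row)) if j != i)
    else:
        w_star = 1.0
    s_k = config.s(code)
    return (s_k / n_k) * (fp * (n_k / n_star) * (1.0 - w_star) - 2.0 * fn)


def clinical_order_margin(
    evaluation_set: EvaluationSet, config: MetricConfig
) -> dict[str, float]:
    """Per-class margin xi_k over the evaluation set's observed counts.

    Uses each class's false positives, false negatives and prevalence, with
    n* the maximum prevalence over all classes.  A negative margin for every
    class certifies the clinical-order guarantee region; e.g. with arbitrary
    similarity weights the region covers fp_k <= 2 fn_k, widening as the
    smallest similarity w*_k grows or the class becomes rarer than the most
    frequent one.
    """
    tp: dict[str, int] = {c: 0 for c in evaluation_set.catalog.codes}
    fp: dict[str, int] = {c: 0 for c in evaluation_set.catalog.codes}
    fn: dict[str, int] = {c: 0 for c in evaluation_set.catalog.codes}
    for pair in evaluation_set.pairs:
        for c in pair.truth & pair.prediction:
            tp[c] += 1
        for c in pair.prediction - pair.truth:
            fp[c] += 1
        for c in pair.truth - pair.prediction:
            fn[c] += 1
    n_star = max(
        (evaluation_set.n(c) for c in evaluation_set.catalog.codes), default=0
    )
    n_star = max(n_star, 1)
    out = {}
    for c in evaluation_set.catalog.codes:
        n_k = _effective_n(c, evaluation_set.prevalence, config.prevalence_floor)
        out[c] = margin_from_counts(c, tp[c], fp[c], fn[c], n_k, n_star, config)
    return out
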