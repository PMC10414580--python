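"""Deliberately naive reference implementations used only as test oracles.

Everything here is written as literal double loops over instances and catalog
codes, straight from the defining formulas, with no shared code or shortcuts
from the production implementation.  Inputs are plain lists/dicts.
"""

from __future__ import annotations

import math


def naive_prevalence(truths: list[set], codes: list[str]) -> dict[str, int]:
    return {c: sum(1 for y in truths if c in y) for c in codes}


def naive_medtric(
    truths: list[set],
    preds: list[set],
    codes: list[str],
    s: dict[str, float],
    w: dict[str, dict[str, float]],
    C: dict[str, dict[str, int]],
    floor: int = 1,
) -> float:
    """Literal per-label scoring, instance totals and null/perfect
    normalisation."""
    n = naive_prevalence(truths, codes)

    def eff_n(code):
        return n[code] if n[code] > 0 else floor

    def total(pred_list):
        t = 0.0
        for y, z in zip(truths, pred_list):
            ti = 0.0
            n_star = max(eff_n(c) for c in y)
            for j in codes:
                # reward / penalty term
                if j in z and j in y:
                    ti += s[j] / n[j]
                elif j in y and j not in z:
                    ti += -s[j] / n[j]
                elif j in z and j not in y:
                    mean_w = sum(w[j][k] for k in y) / len(y)
                    ti += (s[j] / n_star) * (mean_w - 1.0)
                # contradiction term
                if j in z:
                    pen = 0.0
                    for k in z:
                        if k != j and C[j][k]:
                            pen += s[k]
                    ti += -pen / eff_n(j)
            t += ti
        return t

    raw = total(preds)
    null = total([set() for _ in truths])
    perfect = total([set(y) for y in truths])
    return (raw - null) / (perfect - null)


def naive_label_based(truths, preds, codes):
    tp = {c: 0 for c in codes}
    fp = {c: 0 for c in codes}
    fn = {c: 0 for c in codes}
    for y, z in zip(truths, preds):
        for c in codes:
            if c in z and c in y:
                tp[c] += 1
            elif c in z:
                fp[c] += 1
            elif c in y:
                fn[c] += 1

    def div(a, b):
        return a / b if b else 0.0

    P = len(codes)
    macro_p = sum(div(tp[c], tp[c] + fp[c]) for c in codes) / P
    macro_r = sum(div(tp[c], tp[c] + fn[c]) for c in codes) / P
    macro_f1 = 0.0
    for c in codes:
        p = div(tp[c], tp[c] + fp[c])
        r = div(tp[c], tp[c] + fn[c])
        macro_f1 += div(2 * p * r, p + r)
    macro_f1 /= P
    TP, FP, FN = sum(tp.values()), sum(fp.values()), sum(fn.values())
    micro_p = div(TP, TP + FP)
    micro_r = div(TP, TP + FN)
    return {
        "macro_precision": macro_p,
        "macro_recall": macro_r,
        "macro_f1": macro_f1,
        "micro_precision": micro_p,
        "micro_recall": micro_r,
        "micro_f1": div(2 * micro_p * micro_r, micro_p + micro_r),
    }


def naive_example_based(truths, preds, codes):
    def div(a, b):
        return a / b if b else 0.0

    P, N = len(codes), len(truths)
    ham = acc = prec = rec = f1 = sub = 0.0
    for y, z in zip(truths, preds):
        ham += len(y.symmetric_difference(z)) / P
        acc += div(len(y & z), len(y | z))
        prec += div(len(y & z), len(z))
        rec += div(len(y & z), len(y))
        f1 += div(2 * len(y & z), len(y) + len(z))
        sub += 1.0 if y == z else 0.0
    return {
        "hamming_loss": ham / N,
        "accuracy": acc / N,
        "precision": prec / N,
        "recall": rec / N,
        "f1": f1 / N,
        "subset_accuracy": sub / N,
    }


def naive_challenge_metric(truths, preds, codes, w, normal):
    """Literal weighted confusion-matrix score with all-normal normalisation."""

    def total(pred_list):
        t = 0.0
        for j in codes:
            for k in codes:
                a_jk = 0.0
                for y, z in zip(truths, pred_list):
                    if k in z and j in y:
                        a_jk += 1.0 / len(y | z)
                t += w[j][k] * a_jk
        return t

    raw = total(preds)
    s_normal = total([{normal} for _ in truths])
    s_perfect = total([set(y) for y in truths])
    return (raw - s_normal) / (s_perfect - s_normal)


def naive_classify(y: set, z: set) -> tuple[str, int]:
    """Independent predicate-based classification of a prediction."""
    assert y, "truth must be non-empty"
    if z == y:
        return ("perfect", 0)
    if z.issubset(y) and z != y:
        return ("missed", len(y - z))
    if y.issubset(z) and z != y:
        return ("over", len(z - y))
    if len(y & z) == 0 and len(z) > 0:
        return ("wrong", len(z))
    return ("mixed", 0)
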