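"""Monte-Carlo stress tests of evaluation metrics.

Two simulation studies probe whether a metric behaves clinically:

* **Monotonicity** — sample a ground truth, generate candidate predictions
  from a synthetic classifier with per-class sensitivity p and specificity q,
  bucket the pure-type candidates by diagnosis kind and degree, and check
  that the metric ranks the buckets in clinical order
  (wrong, worst degree first) < (missed) < (over) < perfect.
  The monotonicity rate tau is the percentage of sampled truths for which
  the full strict chain holds.

* **Prevalence dispersion** — mix two classes in a random proportion
  alpha ~ U(0,1), hold the classifier's per-class quality fixed (sensitivity
  p_M for the frequent class, p_m for the rare one, specificity q) and
  measure the standard deviation sigma of the metric as alpha varies.  A
  prevalence-invariant metric has sigma near 0; a large sigma means the
  metric's value is driven by the class mix rather than by classifier
  quality.

Both experiments score metrics through the production implementations in
:mod:`medtric.core` and :mod:`medtric.baselines`; losses (Hamming) are
negated for ordering comparisons so that "higher is clinically better"
holds uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .baselines import example_based, label_based
from .core import medtric
from .label_model import (
    DiagnosisCatalog,
    DiagnosisKind,
    InstancePair,
    MetricConfig,
    build_evaluation_set,
    classify_prediction,
)

__all__ = [
    "RandomClassifierParams",
    "MonotonicityParams",
    "DispersionParams",
    "ExperimentResult",
    "METRIC_NAMES",
    "evaluate_metric",
    "random_prediction",
    "bucket_candidates",
    "monotonicity_rate",
    "prevalence_subset",
    "dispersion",
    "synthesize_dataset",
    "default_truth_sampler",
]


# ---------------------------------------------------------------------------
# Parameters and results
# ---------------------------------------------------------------------------


@dataclass
class RandomClassifierParams:
    """Synthetic per-class Bernoulli classifier: each true code is predicted
    with probability p (sensitivity) and each absent code with probability
    1 - q (one minus specificity)."""

    sensitivity: float = 0.8
    specificity: float = 0.95
    candidate_budget: int = 200
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.sensitivity < 1 and 0 < self.specificity < 1):
            raise ValueError("sensitivity and specificity must lie in (0, 1)")
        if self.candidate_budget < 1:
            raise ValueError("candidate_budget must be positive")


@dataclass
class MonotonicityParams:
    samples: int = 100          # rho: ground truths probed per repeat
    repeats: int = 10           # n: independent repeats for spread
    classifier: RandomClassifierParams = field(default_factory=RandomClassifierParams)
    max_resample_factor: int = 50  # cap on resampling degenerate truths

    def __post_init__(self) -> None:
        if self.samples < 1 or self.repeats < 1:
            raise ValueError("samples and repeats must be positive")


@dataclass
class DispersionParams:
    p_M: float = 0.9            # sensitivity on the frequent class
    p_m: float = 0.5            # sensitivity on the rare class
    q: float = 0.95             # specificity on every class
    alpha_draws: int = 50       # eta: mixing proportions drawn per repeat
    subset_size: int = 100      # l: instances per mixed dataset
    repeats: int = 10           # n
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_m <= self.p_M < 1):
            raise ValueError("need 0 < p_m <= p_M < 1")
        if not (0 < self.q < 1):
            raise ValueError("specificity q must lie in (0, 1)")
        if self.alpha_draws < 1 or self.subset_size < 1 or self.repeats < 1:
            raise ValueError("alpha_draws, subset_size and repeats must be positive")


@dataclass
class SampleRecord:
    """Outcome of one monotonicity sample: which buckets were present and
    whether the strict chain held."""

    truth: frozenset[str]
    bucket_keys: tuple[tuple[DiagnosisKind, int], ...]
    satisfied: bool


@dataclass
class ExperimentResult:
    """A tau or sigma estimate with its replicate values and parameter echo."""

    metric_name: str
    estimate: float
    replicate_values: list[float]
    params: dict
    sample_records: list[list[SampleRecord]] | None = None
    skipped_samples: int = 0


# ---------------------------------------------------------------------------
# Metric registry (all evaluated through the production implementations)
# ---------------------------------------------------------------------------

_LOSSES = {"hamming_loss"}

_EXAMPLE_KEYS = {
    "hamming_loss", "accuracy", "precision", "recall", "f1", "subset_accuracy",
}
_LABEL_KEYS = {
    "macro_precision", "macro_recall", "macro_f1",
    "micro_precision", "micro_recall", "micro_f1",
}

METRIC_NAMES = ("medtric",) + tuple(sorted(_EXAMPLE_KEYS | _LABEL_KEYS))

# a metric is a registry name or any callable(pairs, catalog, config) -> float
Metric = str | Callable[[Sequence[InstancePair], DiagnosisCatalog, MetricConfig], float]


def evaluate_metric(
    metric: Metric,
    pairs: Sequence[InstancePair],
    catalog: DiagnosisCatalog,
    config: MetricConfig,
) -> float:
    """Evaluate one metric (registry name or callable) on instance pairs."""
    if callable(metric):
        return float(metric(pairs, catalog, config))
    evaluation_set = build_evaluation_set(pairs, catalog)
    if metric == "medtric":
        return medtric(evaluation_set, config).score
    if metric in _EXAMPLE_KEYS:
        return example_based(evaluation_set)[metric]
    if metric in _LABEL_KEYS:
        return label_based(evaluation_set)[metric]
    raise KeyError(f"unknown metric {metric!r}; choose from {METRIC_NAMES}")


def _metric_key(metric: Metric) -> str:
    return metric if isinstance(metric, str) else getattr(metric, "__name__", repr(metric))


def _oriented(key: str, value: float) -> float:
    return -value if key in _LOSSES else value


# ---------------------------------------------------------------------------
# Synthetic classifier and dataset generators
# ---------------------------------------------------------------------------


def random_prediction(
    truth: frozenset[str],
    catalog: DiagnosisCatalog,
    params: RandomClassifierParams,
    rng: np.random.Generator,
) -> frozenset[str]:
    """Draw one prediction: keep each true code w.p. p, add each absent code
    w.p. 1 - q, independently across codes."""
    p, q = params.sensitivity, params.specificity
    u = rng.random(catalog.size)
    pred = []
    for i, code in enumerate(catalog.codes):
        if code in truth:
            if u[i] < p:
                pred.append(code)
        elif u[i] < 1.0 - q:
            pred.append(code)
    return frozenset(pred)


def bucket_candidates(
    truth: frozenset[str], candidates: Iterable[frozenset[str]]
) -> dict[tuple[DiagnosisKind, int], list[frozenset[str]]]:
    """Group pure-type candidates by (kind, degree); mixed candidates (both
    missed and extra labels) fall outside the taxonomy and are discarded."""
    buckets: dict[tuple[DiagnosisKind, int], list[frozenset[str]]] = {}
    for cand in candidates:
        cls = classify_prediction(truth, cand)
        if cls.kind is DiagnosisKind.MIXED:
            continue
        buckets.setdefault((cls.kind, cls.degree), []).append(cand)
    return buckets


def synthesize_dataset(
    catalog: DiagnosisCatalog,
    n_instances: int,
    label_cardinality_distribution: Mapping[int, float] | None = None,
    class_propensities: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
    config: MetricConfig | None = None,
) -> list[frozenset[str]]:
    """Generate multi-label ground truths with controlled cardinality and
    per-class prevalence skew.

    Cardinality is drawn from ``label_cardinality_distribution`` (default:
    uniform over {1, 2, 3}, a typical diagnostic label density); codes are
    drawn without replacement with probability proportional to their
    propensity.  Truths containing a contradictory pair (per ``config``) are
    rejection-resampled.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if label_cardinality_distribution is None:
        label_cardinality_distribution = {1: 1 / 3, 2: 1 / 3, 3: 1 / 3}
    cards = np.array(sorted(label_cardinality_distribution))
    card_p = np.array([label_cardinality_distribution[int(k)] for k in cards], float)
    if np.any(card_p < 0) or card_p.sum() <= 0:
        raise ValueError("cardinality distribution must be non-negative, non-zero")
    card_p = card_p / card_p.sum()
    if cards.min() < 1 or cards.max() > catalog.size:
        raise ValueError("cardinalities must lie in [1, P]")

    if class_propensities is None:
        prop = np.ones(catalog.size)
    else:
        if any(v <= 0 for v in class_propensities.values()):
            raise ValueError("class propensities must be positive")
        prop = np.array([class_propensities.get(c, 0.0) for c in catalog.codes])
        if np.any(prop <= 0):
            raise ValueError("every catalog code needs a positive propensity")
    prop = prop / prop.sum()

    codes = np.array(catalog.codes)
    truths: list[frozenset[str]] = []
    while len(truths) < n_instances:
        k = int(rng.choice(cards, p=card_p))
        picked = frozenset(rng.choice(codes, size=k, replace=False, p=prop))
        if config is not None and config.contradictory_pairs_in(picked):
            continue
        truths.append(picked)
    return truths


def default_truth_sampler(
    catalog: DiagnosisCatalog, config: MetricConfig | None = None
) -> Callable[[np.random.Generator], frozenset[str]]:
    """Single-truth sampler matching :func:`synthesize_dataset` defaults."""

    def sample(rng: np.random.Generator) -> frozenset[str]:
        return synthesize_dataset(catalog, 1, rng=rng, config=config)[0]

    return sample


# ---------------------------------------------------------------------------
# Experiment 1: clinical-order monotonicity rate tau
# ---------------------------------------------------------------------------

_KIND_RANK = {
    DiagnosisKind.WRONG: 0,
    DiagnosisKind.MISSED: 1,
    DiagnosisKind.OVER: 2,
    DiagnosisKind.PERFECT: 3,
}

_CHAIN_TOL = 1e-12


def _clinical_sort_key(key: tuple[DiagnosisKind, int]) -> tuple[int, int]:
    kind, degree = key
    # within a kind, higher degree is clinically worse and must score lower
    return (_KIND_RANK[kind], -degree)


def chain_satisfied(bucket_scores: Mapping[tuple[DiagnosisKind, int], float]) -> bool:
    """True when scores strictly increase along the clinical order of the
    present buckets; ties (within 1e-12) count as violations."""
    keys = sorted(bucket_scores, key=_clinical_sort_key)
    vals = [bucket_scores[k] for k in keys]
    return all(b - a > _CHAIN_TOL for a, b in zip(vals, vals[1:]))


def monotonicity_rate(
    metric: Metric | Sequence[Metric],
    dataset_sampler: Callable[[np.random.Generator], frozenset[str]],
    params: MonotonicityParams,
    catalog: DiagnosisCatalog,
    config: MetricConfig,
    record_samples: bool = False,
) -> ExperimentResult | dict[str, ExperimentResult]:
    """Estimate tau, the percentage of sampled truths for which a metric
    ranks the error buckets in strict clinical order.

    For each sampled truth, ``candidate_budget`` predictions are drawn from
    the synthetic classifier, bucketed by (kind, degree), and each bucket is
    scored as the mean singleton-set metric value of its members.  Truths
    yielding fewer than two non-empty buckets are resampled.  Passing a list
    of metric names scores every metric on the same candidate draws.
    """
    single = isinstance(metric, str) or callable(metric)
    metrics = [metric] if single else list(metric)
    names = [_metric_key(m) for m in metrics]
    by_key = dict(zip(names, metrics))
    results: dict[str, list[float]] = {m: [] for m in names}
    records: dict[str, list[list[SampleRecord]]] = {m: [] for m in names}
    skipped = 0

    base = np.random.SeedSequence(params.classifier.rng_seed)
    for repeat_seed in base.spawn(params.repeats):
        rng = np.random.default_rng(repeat_seed)
        passed = {m: 0 for m in names}
        repeat_records: dict[str, list[SampleRecord]] = {m: [] for m in names}
        done = 0
        attempts = 0
        max_attempts = params.samples * params.max_resample_factor
        while done < params.samples:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    "could not draw enough truths with >= 2 candidate buckets; "
                    "check the classifier parameters"
                )
            truth = dataset_sampler(rng)
            candidates = [
                random_prediction(truth, catalog, params.classifier, rng)
                for _ in range(params.classifier.candidate_budget)
            ]
            buckets = bucket_candidates(truth, candidates)
            if len(buckets) < 2:
                skipped += 1
                continue
            done += 1
            cache: dict[tuple[str, frozenset[str]], float] = {}
            for m in names:
                scores = {}
                for key, members in buckets.items():
                    vals = []
                    for cand in members:
                        ck = (m, cand)
                        if ck not in cache:
                            pair = InstancePair("s", truth, cand)
                            cache[ck] = evaluate_metric(by_key[m], [pair], catalog, config)
                        vals.append(cache[ck])
                    scores[key] = _oriented(m, float(np.mean(vals)))
                ok = chain_satisfied(scores)
                passed[m] += ok
                if record_samples:
                    repeat_records[m].append(
                        SampleRecord(truth, tuple(sorted(buckets, key=_clinical_sort_key)), ok)
                    )
        for m in names:
            results[m].append(100.0 * passed[m] / params.samples)
            if record_samples:
                records[m].append(repeat_records[m])

    def _pack(m: str) -> ExperimentResult:
        return ExperimentResult(
            metric_name=m,
            estimate=float(np.mean(results[m])),
            replicate_values=results[m],
            params={
                "rho": params.samples,
                "repeats": params.repeats,
                "p": params.classifier.sensitivity,
                "q": params.classifier.specificity,
                "gamma": params.classifier.candidate_budget,
                "seed": params.classifier.rng_seed,
            },
            sample_records=records[m] if record_samples else None,
            skipped_samples=skipped,
        )

    packed = {m: _pack(m) for m in names}
    return packed[names[0]] if single else packed


# ---------------------------------------------------------------------------
# Experiment 2: prevalence dispersion sigma
# ---------------------------------------------------------------------------


def prevalence_subset(
    catalog: DiagnosisCatalog,
    a_M: str,
    a_m: str,
    alpha: float,
    l: int,
    rng: np.random.Generator,
) -> list[frozenset[str]]:
    """l single-label truths: {a_M} with probability alpha, else {a_m}."""
    if a_M == a_m:
        raise ValueError("the two mixed classes must differ")
    if a_M not in catalog or a_m not in catalog:
        raise ValueError("both classes must be in the catalog")
    draws = rng.random(l) < alpha
    return [frozenset({a_M if d else a_m}) for d in draws]


def _dispersion_prediction(
    truth: frozenset[str],
    catalog: DiagnosisCatalog,
    sensitivity: Mapping[str, float],
    q: float,
    rng: np.random.Generator,
) -> frozenset[str]:
    u = rng.random(catalog.size)
    pred = []
    for i, code in enumerate(catalog.codes):
        if code in truth:
            if u[i] < sensitivity[code]:
                pred.append(code)
        elif u[i] < 1.0 - q:
            pred.append(code)
    return frozenset(pred)


def dispersion(
    metric: Metric | Sequence[Metric],
    params: DispersionParams,
    catalog: DiagnosisCatalog,
    config: MetricConfig,
    a_M: str | None = None,
    a_m: str | None = None,
) -> ExperimentResult | dict[str, ExperimentResult]:
    """Estimate sigma(M): the standard deviation of a metric as the mixing
    proportion alpha of two classes varies uniformly on (0, 1).

    Per repeat, ``alpha_draws`` proportions are drawn; each yields a mixed
    dataset of ``subset_size`` single-label truths and synthetic predictions
    with fixed per-class quality (p_M, p_m, q).  sigma is the standard
    deviation of the metric over the draws.  Passing a list of metric names
    evaluates all of them on the same generated datasets, so sigmas are
    directly comparable.
    """
    single = isinstance(metric, str) or callable(metric)
    metrics = [metric] if single else list(metric)
    names = [_metric_key(m) for m in metrics]
    by_key = dict(zip(names, metrics))
    if a_M is None:
        a_M = catalog.codes[0]
    if a_m is None:
        a_m = catalog.codes[1 % catalog.size]
    sens = {a_M: params.p_M, a_m: params.p_m}

    sigmas: dict[str, list[float]] = {m: [] for m in names}
    base = np.random.SeedSequence(params.rng_seed)
    for repeat_seed in base.spawn(params.repeats):
        rng = np.random.default_rng(repeat_seed)
        values: dict[str, list[float]] = {m: [] for m in names}
        for _ in range(params.alpha_draws):
            alpha = rng.random()
            truths = prevalence_subset(catalog, a_M, a_m, alpha, params.subset_size, rng)
            pairs = [
                InstancePair(
                    str(i), t,
                    _dispersion_prediction(t, catalog, sens, params.q, rng),
                )
                for i, t in enumerate(truths)
            ]
            for m in names:
                values[m].append(evaluate_metric(by_key[m], pairs, catalog, config))
        for m in names:
            # population std: the Monte-Carlo estimate of (E[M^2]-E[M]^2)^1/2
            sigmas[m].append(float(np.std(values[m])))

    def _pack(m: str) -> ExperimentResult:
        return ExperimentResult(
            metric_name=m,
            estimate=float(np.mean(sigmas[m])),
            replicate_values=sigmas[m],
            params={
                "p_M": params.p_M, "p_m": params.p_m, "q": params.q,
                "eta": params.alpha_draws, "l": params.subset_size,
                "repeats": params.repeats, "seed": params.rng_seed,
                "a_M": a_M, "a_m": a_m,
            },
        )

    packed = {m: _pack(m) for m in names}
    return packed[names[0]] if single else packed
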