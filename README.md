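# medtric

Clinically aligned evaluation of multi-label diagnostic systems.

## The problem

Computational diagnostic systems — ECG classifiers, chest-X-ray readers,
clinical-text coders — are multi-label: each patient sample may carry several
diagnoses drawn from a finite catalog. The metrics usually borrowed from
machine learning (micro/macro F1, Hamming loss, subset accuracy, example-based
accuracy) ignore two facts of clinical practice:

1. **Error types are not interchangeable.** A *wrong* diagnosis (prediction
   disjoint from the truth) is worse than a *missed* diagnosis (a proper
   subset of the truth), which is worse than an *over*-diagnosis (a proper
   superset). Standard metrics routinely invert this order — e.g. Hamming
   loss penalises missing k conditions exactly as much as adding k spurious
   ones, and micro-F1 can rank an always-missing classifier above an
   always-over-predicting one.
2. **Prevalence is not performance.** Most multi-label metrics move when the
   class mix of the evaluation dataset changes, even if per-class detection
   quality is fixed, so a weakness on a rare class can be invisible.

This package implements **MedTric**, a score built around those constraints,
alongside all the standard baselines and two Monte-Carlo experiments that
quantify how any metric behaves on both counts.

## The score

For an evaluation set of pairs (yᵢ, ẑᵢ) over P diagnosis codes, with
per-class prevalence nⱼ (occurrences of code j among the ground truths),
significance weights sⱼ > 0, a similarity matrix w ∈ (0,1)^{P×P} with unit
diagonal, and a binary contradiction matrix C, each code contributes per
instance

```
aᵢ(j) =  sⱼ/nⱼ                                    j correct   (j ∈ ẑᵢ ∩ yᵢ)
        -sⱼ/nⱼ                                    j missed    (j ∈ yᵢ − ẑᵢ)
         sⱼ/n* · [ (1/|yᵢ|) Σ_{k∈yᵢ} w_jk − 1 ]    j extra     (j ∈ ẑᵢ − yᵢ)
         0                                         otherwise
```

with n* = max{nₖ : k ∈ yᵢ}, plus a contradiction penalty
bᵢ(j) = −(1/nⱼ) Σ_{k∈ẑᵢ} sₖ C_jk for every predicted j. Instance totals
tᵢ = Σⱼ aᵢ(j) + bᵢ(j) are summed over the dataset and normalised between the
all-empty prediction Φ and the perfect prediction:

```
M_med = ( t(Y,Z) − t(Y,Φ) ) / ( t(Y,Y) − t(Y,Φ) )
```

so predicting nothing scores exactly 0 and perfection exactly 1. Because
each contribution is divided by its class prevalence, the score is invariant
to the dataset's class mix; because n* ≥ nⱼ and w_jk < 1, a missed label is
always penalised more than an extra one. The per-class margin
ξₖ = (sₖ/nₖ)[fpₖ(nₖ/n*)(1−w*ₖ) − 2 fnₖ] certifies the full clinical order:
ξₖ < 0 for every class whenever false positives stay below twice the false
negatives (three times when the smallest similarity w*ₖ is 1/3, wider still
for rare classes).

## Worked example

`examples/config.yaml` defines a six-code ECG-flavoured catalog (normal class
`NSR`, a `STach`/`NSR` contradiction, equal significance, constant
off-diagonal similarity 0.5). `examples/labels.csv` holds five instances,
including one missed diagnosis (`p01`), one over-diagnosis (`p03`) and one
wrong diagnosis (`p04`).

```
$ medtric compare --config examples/config.yaml --labels examples/labels.csv
medtric: 0.697917
macro_precision: 0.666667
macro_recall: 0.500000
macro_f1: 0.555556
micro_precision: 0.750000
micro_recall: 0.750000
micro_f1: 0.750000
hamming_loss: 0.133333
example_accuracy: 0.633333
example_precision: 0.700000
example_recall: 0.733333
example_f1: 0.693333
subset_accuracy: 0.400000
challenge_metric: 0.611650
```

MedTric's 0.698 sits below the micro-F1 of 0.75 mainly because of the wrong
diagnosis on `p04` (a disjoint prediction scores below even an empty one) —
the kind of clinically important distinction the pooled counts behind
micro-F1 cannot see. Other subcommands: `medtric score` (MedTric only, with
an optional per-instance/per-code breakdown CSV), `medtric monotonicity` and
`medtric dispersion` (the two experiments below) and `medtric simulate`
(synthetic dataset generation).

As a quick intuition anchor: a singleton instance with three equally
significant true conditions and one of them missed scores exactly 2/3.

## The experiments

`medtric.experiments` stress-tests any registered metric (or any callable)
with a synthetic classifier that detects each true code with sensitivity p
and each absent code with probability 1−q:

* **Monotonicity rate τ** — per sampled ground truth, candidate predictions
  are bucketed by error kind and degree, each bucket scored as the mean
  singleton-set metric value, and the strict chain
  wrong… < missed… < over… < perfect checked; τ is the percentage of truths
  for which the chain holds. On a 10-class catalog with w₀ = 0.8, MedTric's
  τ is 100% in every repeat across the four (p, q) settings
  (0.8, 0.95), (0.8, 0.90), (0.6, 0.95), (0.6, 0.90), while subset accuracy's
  τ is 0% and Hamming loss fails every sample that contains both a
  one-missed and an over-diagnosis bucket.
* **Prevalence dispersion σ** — two classes are mixed in a random proportion
  α ~ U(0,1) with fixed per-class quality (p_M = 0.9 on the frequent class,
  p_m = 0.5 on the rare one, specificity q); σ is the standard deviation of
  the metric over the α draws. Lower σ means the metric tracks classifier
  quality rather than dataset composition; MedTric's σ is consistently below
  example-based F1's and accuracy's on shared draws.

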