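# Methods

## Model and scope

The package evaluates a multi-label diagnostic classifier from its output
label sets alone. The classifier itself — feature extraction, probability
scores, thresholding — is treated as a black box; the unit of analysis is the
set P of (ground truth yᵢ, prediction ẑᵢ) pairs over a finite catalog of P
diagnosis codes. Label-ranking metrics (AUC, coverage) that need access to
scores are out of scope by design.

Every prediction is classified into exactly one of five kinds: *perfect*
(ẑ = y), *missed* (ẑ ⊊ y, including the empty prediction), *over* (y ⊊ ẑ),
*wrong* (ẑ ∩ y = ∅, ẑ ≠ ∅) and *mixed* (partial overlap with both missed and
extra labels). The first four come with a degree (labels missed, labels
added, labels wrongly asserted); mixed predictions are scored term-by-term by
the same per-label rules but fall outside the pure-type taxonomy used by the
monotonicity experiment, which discards them when bucketing.

## MedTric

Per-label contributions, contradiction penalties, instance totals and the
null/perfect normalisation are implemented exactly as stated in the README.
Numerical and structural choices:

* **Empty ground truths are rejected.** The missed/extra terms divide by
  |yᵢ| and maximise over yᵢ, which is undefined for an empty truth; "no
  finding" must be encoded as an explicit normal class (as ECG catalogs do
  with normal sinus rhythm). The empty *prediction* is valid and anchors the
  score at 0.
* **Prevalence nⱼ counts ground-truth memberships in the evaluation set
  itself**, never predictions and never an external reference population.
  This makes the score a property of the (truths, predictions) pair alone
  and gives exact invariance under dataset duplication.
* **n\*** (the denominator of the extra-prediction term) is the maximum
  prevalence over the *instance's own truth codes*, recomputed per instance;
  on a singleton evaluation set it is 1.
* **Prevalence floor.** A predicted code that never occurs in any truth has
  nⱼ = 0, which would make the contradiction penalty 1/nⱼ undefined; such
  codes use a configurable positive floor (default 1 — the most conservative
  choice, keeping the penalty finite and maximal).
* **Contradiction penalties apply from both sides**: each member of a
  predicted contradictory pair incurs its own penalty with its own 1/nⱼ
  factor, because the penalty term sums over predicted codes independently.
  Ground truths containing a contradictory pair are rejected at validation,
  which guarantees the closed forms t(Y,Φ) = −Σⱼ sⱼ·[nⱼ>0] and
  t(Y,Y) = +Σⱼ sⱼ·[nⱼ>0].
* **Significance weights are taken raw.** The score is invariant to scaling
  all sⱼ by a common factor (numerator and denominator of the normalisation
  scale together), so no internal normalisation is performed.
* A scalar similarity w₀ broadcasts to all off-diagonal entries; the default
  is 0.5 when a full matrix is not supplied. Off-diagonal similarities must
  lie strictly in (0,1): w = 1 would erase the missed/extra asymmetry the
  metric exists to encode, w = 0 would make an extra prediction as bad as a
  missed one.
* Score comparisons in tests use 1e−9 absolute tolerance; the normalisation
  anchors (0 and 1) are exact to 1e−12.

The per-class margin ξₖ = (sₖ/nₖ)[fpₖ(nₖ/n\*)(1−w\*ₖ) − 2·fnₖ] (with w\*ₖ the
smallest similarity of class k to any other class, and n\* here the maximum
prevalence over all classes, the form under which the guarantee is derived)
is exposed both from raw per-class counts and from a full evaluation set.
ξₖ < 0 for all k certifies the wrong < missed < over < perfect ordering; the
conservative region is fpₖ ≤ 2·fnₖ, extending to fpₖ < 3·fnₖ when w\*ₖ = 1/3
and further for classes rarer than the most frequent one.

## Baselines

Label-based (macro/micro precision, recall, F1), example-based (Hamming loss,
accuracy, precision, recall, F1, subset accuracy) and the PhysioNet/CinC
2020-21 Challenge Metric are implemented from their defining formulas. Two
conventions worth making explicit:

* **Example-based precision divides by |ẑᵢ| and recall by |yᵢ|** — the
  standard meanings. (Some presentations print the two denominators
  swapped; the inequality analyses that motivate this package use the
  standard convention, and so do we.)
* **0/0 ratios are defined as 0** (affects classes never present and never
  predicted, and empty-prediction instances). This is pinned by tests.

The Challenge Metric builds the soft confusion matrix
a_jk = Σᵢ I(aₖ ∈ ẑᵢ ∧ aⱼ ∈ yᵢ)/|ẑᵢ ∪ yᵢ|, scores t = Σ w_jk a_jk and
normalises between the all-normal prediction set and perfection. Its weight
matrix defaults to the MedTric similarity matrix when not supplied
separately. The metric is unbounded below — the package's tests construct a
symmetric weight matrix under which predicting a genuinely present condition
scores *negative* while predicting only the normal class scores 0.

## Experiments

**Synthetic classifier.** f_random includes each true code with probability p
(sensitivity) and each absent code with probability 1−q (specificity q),
independently across codes. This emulates a bank of per-class binary
detectors with homogeneous quality; it does not emulate correlated errors,
within-instance label dependence, or confidence thresholding.

**Monotonicity (τ).** Per sampled truth, Γ = 200 candidates are drawn (Γ is
a free parameter of the harness; 200 gives well-populated buckets at the
default classifier settings without waste), pure-type candidates are grouped
into (kind, degree) buckets, and each bucket is scored as the **mean**
singleton-set metric value of its members — the expected score of that error
pattern (the reduction over a bucket is otherwise unconstrained; the mean is
the natural choice and is exact here because, under equal significance and
constant w₀, all members of a bucket score identically). The chain is
checked with strict inequalities at 1e−12 tolerance over the buckets that are
present — a missing degree level does not fail a sample, but a tie does
(which is exactly why Hamming loss and subset accuracy score τ = 0). Samples
with fewer than two buckets are resampled. Singleton-set scoring means
MedTric's prevalences are ≡ 1 there, and dataset-level metrics (micro/macro)
are computed on the one-instance set.

For MedTric with equal prevalence, equal significance and constant w₀, the
chain holds *deterministically* whenever every feasible over-degree e
satisfies e·(1−w₀) < 2. On the default 10-class catalog with w₀ = 0.8 and
truths of size ≥ 1, e ≤ 9 gives e·(1−w₀) ≤ 1.8 < 2 — so τ = 100% is a
theorem under these settings, and the experiment verifies the implementation
rather than sampling luck.

**Dispersion (σ).** Two designated classes are mixed: each of l = 100
instances carries the single-label truth {a_M} with probability α, else
{a_m}, with α ~ U(0,1) redrawn η = 50 times per repeat. Predictions use
sensitivity p_M = 0.9 for a_M, p_m = 0.5 for a_m and specificity q (0.95 and
0.99 are both exercised). σ is the population standard deviation of the η
metric values — the Monte-Carlo estimate of (E[M²] − E[M]²)^½ — and the
experiment is repeated n = 10 times for spread. The mixing proportions
define the *ground-truth* composition (the predictions then follow from the
fixed per-class quality). All metrics passed in one call are evaluated on
the same generated datasets, so their σ values are directly comparable.

**Synthetic datasets.** The generator draws a label cardinality (default:
uniform over {1, 2, 3}, a typical diagnostic label density), then codes
without replacement with probability proportional to per-class propensities
(default: uniform), rejection-resampling truths that contain a contradictory
pair. It emulates the label structure of multi-label diagnostic datasets —
finite catalog, low cardinality, controllable prevalence skew — but not
label co-occurrence structure or any relationship between sample content and
labels, so results on it demonstrate metric behaviour, not classifier
performance on real data.

**Problem sizes.** The bundled experiments run at ρ = 100 truths × n = 10
repeats × 4 classifier settings for monotonicity and η = 50 × l = 100 ×
n = 10 × 2 specificity settings for dispersion — the same design sizes as the
analyses they verify, which complete in seconds on one core.

## Reproducibility

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` spawning (one child stream per repeat), so every
experiment result is bit-reproducible for a given seed, and reports embed the
seed. Scores themselves are deterministic functions of the inputs.

## Known limitations

* Worked scoring tables whose intermediate rows depend on
  dataset-specific significance/similarity configurations are not reproduced
  (those configurations live in supplementary material that is user-supplied
  here); only the configuration-independent anchors (0 for the empty
  prediction, 1 for the perfect one) are asserted.
* The Challenge Metric as deployed in the PhysioNet challenge uses
  that dataset's expert weight matrix; here the metric runs with whatever
  weights the user configures, defaulting to the MedTric similarity matrix.
* Dispersion magnitudes depend on the catalog size and q through the extra
  predictions; only the *ordering* of σ across metrics on shared draws is
  asserted, not figure-level values.
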