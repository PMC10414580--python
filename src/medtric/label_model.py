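"""Domain types for multi-label diagnostic evaluation.

A diagnostic dataset is reduced, for evaluation purposes, to a collection of
(ground-truth label set, predicted label set) pairs over a finite catalog of
diagnosis codes.  Everything downstream — the MedTric score, the baseline
metrics, the simulation experiments — consumes the validated
:class:`EvaluationSet` built here, together with a :class:`MetricConfig`
holding the clinical knowledge (significance weights, similarity matrix,
contradiction matrix).
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "DiagnosisCatalog",
    "InstancePair",
    "EvaluationSet",
    "MetricConfig",
    "DiagnosisKind",
    "DiagnosisClassification",
    "ValidationError",
    "build_evaluation_set",
    "classify_prediction",
]


class ValidationError(ValueError):
    """Raised when labels, pairs or configuration violate an invariant."""


# ---------------------------------------------------------------------------
# Catalog and instances
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiagnosisCatalog:
    """The finite set of P diagnosis codes a system may emit.

    Parameters
    ----------
    codes
        Ordered, unique, non-empty code strings.  The order fixes the
        row/column order of every matrix in :class:`MetricConfig`.
    normal_code
        Optional member of ``codes`` designating the "no finding" class
        (e.g. normal sinus rhythm in an ECG catalog).  "No finding" ground
        truths must carry this code explicitly; the empty truth set is
        rejected everywhere.
    """

    codes: tuple[str, ...]
    normal_code: str | None = None

    def __post_init__(self) -> None:
        if len(self.codes) < 1:
            raise ValidationError("catalog must contain at least one code")
        if any(not c for c in self.codes):
            raise ValidationError("catalog codes must be non-empty strings")
        if len(set(self.codes)) != len(self.codes):
            dupes = [c for c, k in Counter(self.codes).items() if k > 1]
            raise ValidationError(f"duplicate catalog codes: {dupes}")
        if self.normal_code is not None and self.normal_code not in self.codes:
            raise ValidationError(
                f"normal_code {self.normal_code!r} is not in the catalog"
            )

    @property
    def size(self) -> int:
        return len(self.codes)

    def index(self, code: str) -> int:
        try:
            return self._index[code]
        except AttributeError:
            object.__setattr__(
                self, "_index", {c: i for i, c in enumerate(self.codes)}
            )
            return self._index[code]

    def __contains__(self, code: object) -> bool:
        return code in self.codes

    def __iter__(self):
        return iter(self.codes)

    def __len__(self) -> int:
        return len(self.codes)


@dataclass(frozen=True)
class InstancePair:
    """One evaluation instance: ground-truth set y and prediction set z."""

    instance_id: str
    truth: frozenset[str]
    prediction: frozenset[str]

    def __init__(
        self,
        instance_id: str,
        truth: Iterable[str],
        prediction: Iterable[str],
    ) -> None:
        object.__setattr__(self, "instance_id", str(instance_id))
        object.__setattr__(self, "truth", frozenset(truth))
        object.__setattr__(self, "prediction", frozenset(prediction))


# ---------------------------------------------------------------------------
# Classification of a prediction against its ground truth
# ---------------------------------------------------------------------------


class DiagnosisKind(str, enum.Enum):
    """Clinical taxonomy of a prediction relative to its ground truth."""

    PERFECT = "perfect"  # z == y
    MISSED = "missed"    # z is a proper subset of y (incl. empty z)
    OVER = "over"        # y is a proper subset of z
    WRONG = "wrong"      # z and y disjoint, z non-empty
    MIXED = "mixed"      # partial overlap with both missed and extra labels


@dataclass(frozen=True)
class DiagnosisClassification:
    """Kind plus degree (how many labels missed / extra / wrongly asserted)."""

    kind: DiagnosisKind
    degree: int


def classify_prediction(
    truth: frozenset[str] | set[str], prediction: frozenset[str] | set[str]
) -> DiagnosisClassification:
    """Classify a prediction as perfect / missed / over / wrong / mixed.

    The five kinds partition all (truth, prediction) pairs with non-empty
    truth.  Degrees: 0 for perfect, ``|y - z|`` for missed, ``|z - y|`` for
    over, ``|z|`` for wrong, 0 for mixed.
    """
    truth = frozenset(truth)
    prediction = frozenset(prediction)
    if not truth:
        raise ValidationError("ground truth must be non-empty")
    if prediction == truth:
        return DiagnosisClassification(DiagnosisKind.PERFECT, 0)
    if prediction < truth:
        return DiagnosisClassification(DiagnosisKind.MISSED, len(truth - prediction))
    if truth < prediction:
        return DiagnosisClassification(DiagnosisKind.OVER, len(prediction - truth))
    if not (prediction & truth):
        # prediction != truth and truth non-empty, so prediction non-empty here
        return DiagnosisClassification(DiagnosisKind.WRONG, len(prediction))
    return DiagnosisClassification(DiagnosisKind.MIXED, 0)


# ---------------------------------------------------------------------------
# Metric configuration
# ---------------------------------------------------------------------------


@dataclass
class MetricConfig:
    """Clinical knowledge driving the MedTric score.

    Attributes
    ----------
    catalog
        The code catalog; fixes the index order of the matrices.
    significance
        Map code -> s_j > 0.  Relative importance of each diagnosis;
        the score is invariant to rescaling all s_j by a common factor.
    similarity
        P x P array w_jk with unit diagonal and off-diagonal entries in
        (0, 1): partial credit for predicting a condition clinically
        similar to a true one.
    contradiction
        P x P symmetric 0/1 array with zero diagonal; C_jk = 1 marks
        mutually exclusive diagnoses.  Predicting a contradictory pair
        incurs an extra penalty; a ground truth containing one is invalid.
    prevalence_floor
        Positive integer substituted for n_j when a predicted code never
        occurs in any ground truth (keeps the 1/n_j penalty finite and
        maximal).  Default 1.
    """

    catalog: DiagnosisCatalog
    significance: dict[str, float]
    similarity: np.ndarray
    contradiction: np.ndarray
    prevalence_floor: int = 1

    @classmethod
    def create(
        cls,
        catalog: DiagnosisCatalog,
        significance: float | Mapping[str, float] = 1.0,
        similarity: float | np.ndarray | Sequence[Sequence[float]] = 0.5,
        contradiction: Iterable[tuple[str, str]] | np.ndarray | None = None,
        prevalence_floor: int = 1,
    ) -> "MetricConfig":
        """Build a config, broadcasting scalar shorthands.

        A scalar ``significance`` applies to every class; a scalar
        ``similarity`` w0 fills all off-diagonal entries; ``contradiction``
        may be a list of code pairs (set symmetrically) or a full matrix.
        """
        P = catalog.size
        if isinstance(significance, Mapping):
            missing = set(catalog.codes) - set(significance)
            if missing:
                raise ValidationError(f"significance missing codes: {sorted(missing)}")
            sig = {c: float(significance[c]) for c in catalog.codes}
        else:
            sig = {c: float(significance) for c in catalog.codes}

        if np.isscalar(similarity):
            w0 = float(similarity)  # type: ignore[arg-type]
            w = np.full((P, P), w0)
            np.fill_diagonal(w, 1.0)
        else:
            w = np.asarray(similarity, dtype=float)

        if contradiction is None:
            C = np.zeros((P, P))
        elif isinstance(contradiction, np.ndarray):
            C = np.asarray(contradiction, dtype=float)
        else:
            C = np.zeros((P, P))
            for a, b in contradiction:
                if a not in catalog or b not in catalog:
                    raise ValidationError(f"contradiction pair ({a}, {b}) not in catalog")
                i, j = catalog.index(a), catalog.index(b)
                C[i, j] = C[j, i] = 1.0

        cfg = cls(
            catalog=catalog,
            significance=sig,
            similarity=w,
            contradiction=C,
            prevalence_floor=int(prevalence_floor),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        P = self.catalog.size
        if any(s <= 0 for s in self.significance.values()):
            raise ValidationError("significance weights must be strictly positive")
        w = self.similarity
        if w.shape != (P, P):
            raise ValidationError(f"similarity matrix must be {P}x{P}, got {w.shape}")
        if not np.allclose(np.diag(w), 1.0):
            raise ValidationError("similarity matrix must have unit diagonal")
        off = w[~np.eye(P, dtype=bool)]
        if off.size and (np.any(off <= 0) or np.any(off >= 1)):
            raise ValidationError(
                "off-diagonal similarity weights must lie strictly in (0, 1)"
            )
        C = self.contradiction
        if C.shape != (P, P):
            raise ValidationError(f"contradiction matrix must be {P}x{P}, got {C.shape}")
        if not np.array_equal(C, C.T):
            raise ValidationError("contradiction matrix must be symmetric")
        if np.any(np.diag(C) != 0):
            raise ValidationError("contradiction matrix must have zero diagonal")
        if not np.all(np.isin(C, (0.0, 1.0))):
            raise ValidationError("contradiction matrix entries must be 0 or 1")
        if self.prevalence_floor < 1:
            raise ValidationError("prevalence_floor must be a positive integer")

    # -- helpers used throughout scoring ------------------------------------

    def s(self, code: str) -> float:
        return self.significance[code]

    def w(self, code_j: str, code_k: str) -> float:
        return float(self.similarity[self.catalog.index(code_j), self.catalog.index(code_k)])

    def contradicts(self, code_j: str, code_k: str) -> bool:
        return bool(self.contradiction[self.catalog.index(code_j), self.catalog.index(code_k)])

    @property
    def has_contradictions(self) -> bool:
        return bool(np.any(self.contradiction))

    def contradictory_pairs_in(self, codes: frozenset[str]) -> list[tuple[str, str]]:
        out = []
        lst = sorted(codes)
        for i, a in enumerate(lst):
            for b in lst[i + 1:]:
                if self.contradicts(a, b):
                    out.append((a, b))
        return out

    def check_truths(self, evaluation_set: "EvaluationSet") -> None:
        """Reject ground truths containing a contradictory pair."""
        if not self.has_contradictions:
            return
        for pair in evaluation_set.pairs:
            bad = self.contradictory_pairs_in(pair.truth)
            if bad:
                raise ValidationError(
                    f"instance {pair.instance_id!r}: ground truth contains "
                    f"contradictory pair(s) {bad}"
                )


# ---------------------------------------------------------------------------
# Evaluation set
# ---------------------------------------------------------------------------


@dataclass
class EvaluationSet:
    """A validated collection of instance pairs plus prevalence bookkeeping.

    ``prevalence[j]`` is n_j: the number of instances whose *ground truth*
    contains code j.  Predictions never contribute to prevalence.
    """

    catalog: DiagnosisCatalog
    pairs: tuple[InstancePair, ...]
    prevalence: dict[str, int] = field(repr=False)

    @property
    def n_instances(self) -> int:
        return len(self.pairs)

    def n(self, code: str) -> int:
        return self.prevalence.get(code, 0)


def build_evaluation_set(
    pairs: Sequence[InstancePair],
    catalog: DiagnosisCatalog,
    config: MetricConfig | None = None,
) -> EvaluationSet:
    """Validate pairs against the catalog and compute prevalence counts.

    Raises :class:`ValidationError` for unknown codes (naming the instance
    and the code), empty ground truths, and — when ``config`` is given —
    ground truths containing a contradictory pair.
    """
    if len(pairs) < 1:
        raise ValidationError("an evaluation set needs at least one instance")
    prevalence: Counter[str] = Counter()
    for pair in pairs:
        if not pair.truth:
            raise ValidationError(
                f"instance {pair.instance_id!r}: empty ground truth is not allowed; "
                "encode 'no finding' with the catalog's normal code"
            )
        for code in pair.truth | pair.prediction:
            if code not in catalog:
                raise ValidationError(
                    f"instance {pair.instance_id!r}: code {code!r} is not in the catalog"
                )
        if config is not None:
            bad = config.contradictory_pairs_in(pair.truth)
            if bad:
                raise ValidationError(
                    f"instance {pair.instance_id!r}: ground truth contains "
                    f"contradictory pair(s) {bad}"
                )
        prevalence.update(pair.truth)
    return EvaluationSet(
        catalog=catalog,
        pairs=tuple(pairs),
        prevalence={c: prevalence.get(c, 0) for c in catalog.codes if prevalence.get(c, 0)},
    )
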