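"""MedTric scoring: per-label terms, instance totals, normalisation,
invariances and the clinical-order margin."""

from __future__ import annotations

import numpy as np
import pytest

from medtric import (
    DiagnosisCatalog,
    InstancePair,
    MetricConfig,
    build_evaluation_set,
    clinical_order_margin,
    contradiction_penalty,
    instance_score,
    label_contribution,
    margin_from_counts,
    medtric,
)

from conftest import make_contingency, random_evaluation_set, random_valid_config

TOL = 1e-9


def singleton_set(truth, pred, catalog):
    return build_evaluation_set([InstancePair("i", truth, pred)], catalog)


class TestLabelContribution:
    def test_correct_code(self):
        cat = DiagnosisCatalog(("A", "B"))
        cfg = MetricConfig.create(cat, significance=1.0)
        got = label_contribution("A", frozenset({"A"}), frozenset({"A"}), {"A": 4}, cfg)
        assert got == pytest.approx(0.25, abs=TOL)

    def test_missed_code(self):
        cat = DiagnosisCatalog(("A", "B"))
        cfg = MetricConfig.create(cat, significance={"A": 2.0, "B": 1.0})
        got = label_contribution("A", frozenset({"A"}), frozenset(), {"A": 4}, cfg)
        assert got == pytest.approx(-0.5, abs=TOL)

    def test_extra_code_similarity_weighted(self):
        # extra code with w=0.5 to both truth codes and n* = 5:
        # (1/5) * (0.5 - 1) = -0.1
        cat = DiagnosisCatalog(("A", "B", "E"))
        cfg = MetricConfig.create(cat, similarity=0.5)
        got = label_contribution(
            "E", frozenset({"A", "B"}), frozenset({"E"}), {"A": 5, "B": 3}, cfg
        )
        assert got == pytest.approx(-0.1, abs=TOL)

    def test_absent_code_contributes_zero(self):
        cat = DiagnosisCatalog(("A", "B"))
        cfg = MetricConfig.create(cat)
        assert label_contribution("B", frozenset({"A"}), frozenset({"A"}), {"A": 1}, cfg) == 0.0

    def test_extra_penalty_strictly_between_missed_and_zero(self):
        """Missed penalties always dominate extra-prediction penalties:
        -s_j/n_j < extra term < 0 over randomised configs."""
        rng = np.random.default_rng(42)
        cat = DiagnosisCatalog(tuple(f"c{i}" for i in range(5)))
        for _ in range(50):
            cfg = random_valid_config(cat, rng)
            truth = frozenset(rng.choice(cat.codes, size=int(rng.integers(1, 5)), replace=False))
            extras = [c for c in cat.codes if c not in truth]
            if not extras:
                continue
            code = extras[int(rng.integers(len(extras)))]
            prevalence = {c: int(rng.integers(1, 10)) for c in truth}
            extra = label_contribution(code, truth, frozenset({code}), prevalence, cfg)
            n_star = max(prevalence.values())
            assert -cfg.s(code) / n_star < extra < 0
            # and the missed penalty for the same code at any truth prevalence
            # would be at least as large in magnitude
            assert abs(extra) < cfg.s(code) / min(prevalence.values()) + TOL


class TestContradictionPenalty:
    def test_zero_matrix(self):
        cat = DiagnosisCatalog(("A", "B"))
        cfg = MetricConfig.create(cat)
        assert contradiction_penalty("A", frozenset({"A", "B"}), {"A": 1, "B": 1}, cfg) == 0.0

    def test_both_sides_penalized(self):
        cat = DiagnosisCatalog(("hypo", "hyper"))
        cfg = MetricConfig.create(cat, contradiction=[("hypo", "hyper")])
        pred = frozenset({"hypo", "hyper"})
        prevalence = {"hypo": 2, "hyper": 5}
        assert contradiction_penalty("hypo", pred, prevalence, cfg) == pytest.approx(-0.5)
        assert contradiction_penalty("hyper", pred, prevalence, cfg) == pytest.approx(-0.2)

    def test_code_not_predicted(self):
        cat = DiagnosisCatalog(("hypo", "hyper"))
        cfg = MetricConfig.create(cat, contradiction=[("hypo", "hyper")])
        assert contradiction_penalty("hypo", frozenset({"hyper"}), {"hyper": 1}, cfg) == 0.0

    def test_floor_when_never_prevalent(self):
        cat = DiagnosisCatalog(("hypo", "hyper"))
        cfg = MetricConfig.create(cat, contradiction=[("hypo", "hyper")], prevalence_floor=1)
        # "hypo" never appears in any truth -> n substituted by the floor
        got = contradiction_penalty("hypo", frozenset({"hypo", "hyper"}), {"hyper": 3}, cfg)
        assert got == pytest.approx(-1.0)


class TestInstanceScore:
    def test_perfect_two_label_singleton(self):
        cat = DiagnosisCatalog(("A", "B"))
        cfg = MetricConfig.create(cat)
        es = singleton_set({"A", "B"}, {"A", "B"}, cat)
        assert instance_score(es.pairs[0], es, cfg).total == pytest.approx(2.0)

    def test_empty_prediction(self):
        cat = DiagnosisCatalog(("A", "B", "C"))
        cfg = MetricConfig.create(cat)
        es = singleton_set({"A", "B", "C"}, set(), cat)
        assert instance_score(es.pairs[0], es, cfg).total == pytest.approx(-3.0)

    def test_wrong_prediction(self):
        cat = DiagnosisCatalog(("A", "B"))
        cfg = MetricConfig.create(cat, similarity=0.5)
        es = singleton_set({"A"}, {"B"}, cat)
        assert instance_score(es.pairs[0], es, cfg).total == pytest.approx(-1.5)

    def test_breakdown_consistency(self):
        rng = np.random.default_rng(7)
        cat = DiagnosisCatalog(tuple(f"c{i}" for i in range(4)))
        cfg = random_valid_config(cat, rng)
        es = random_evaluation_set(cat, rng)
        for pair in es.pairs:
            b = instance_score(pair, es, cfg)
            assert b.total == pytest.approx(
                sum(b.per_code_a.values()) + sum(b.per_code_b.values()), abs=1e-12
            )
            for code, val in b.per_code_b.items():
                assert val <= 0.0
                if code not in pair.prediction:
                    assert val == 0.0


class TestMedtricScore:
    def test_toy_contingencies_both_cases(self, prevalence_case1, prevalence_case2, equal_config):
        assert medtric(prevalence_case1, equal_config).score == pytest.approx(5 / 6, abs=TOL)
        assert medtric(prevalence_case2, equal_config).score == pytest.approx(5 / 6, abs=TOL)

    def test_normalization_anchors_any_config(self):
        """Inactive classifier scores exactly 0, perfect exactly 1, for any
        valid configuration and evaluation set."""
        rng = np.random.default_rng(11)
        cat = DiagnosisCatalog(tuple(f"c{i}" for i in range(5)))
        for _ in range(20):
            cfg = random_valid_config(cat, rng, with_contradictions=True)
            es = random_evaluation_set(cat, rng, config=cfg)
            empty = build_evaluation_set(
                [InstancePair(p.instance_id, p.truth, set()) for p in es.pairs], cat
            )
            perfect = build_evaluation_set(
                [InstancePair(p.instance_id, p.truth, p.truth) for p in es.pairs], cat
            )
            assert medtric(empty, cfg).score == pytest.approx(0.0, abs=1e-12)
            assert medtric(perfect, cfg).score == pytest.approx(1.0, abs=1e-12)

    def test_one_of_three_missed_scores_two_thirds(self):
        cat = DiagnosisCatalog(("a", "b", "c"))
        cfg = MetricConfig.create(cat)
        es = singleton_set({"a", "b", "c"}, {"a", "b"}, cat)
        assert medtric(es, cfg).score == pytest.approx(2 / 3, abs=TOL)

    def test_significance_scale_invariance(self):
        rng = np.random.default_rng(3)
        cat = DiagnosisCatalog(tuple(f"c{i}" for i in range(4)))
        cfg = random_valid_config(cat, rng)
        es = random_evaluation_set(cat, rng)
        base = medtric(es, cfg).score
        for c in (0.01, 7.5, 1e3):
            scaled = MetricConfig.create(
                cat,
                significance={k: v * c for k, v in cfg.significance.items()},
                similarity=cfg.similarity,
                contradiction=cfg.contradiction,
            )
            assert medtric(es, scaled).score == pytest.approx(base, abs=TOL)

    def test_duplication_invariance(self):
        rng = np.random.default_rng(5)
        cat = DiagnosisCatalog(tuple(f"c{i}" for i in range(4)))
        cfg = random_valid_config(cat, rng)
        es = random_evaluation_set(cat, rng, n_max=8)
        base = medtric(es, cfg).score
        for m in (2, 5):
            dup = build_evaluation_set(
                [
                    InstancePair(f"{p.instance_id}-{r}", p.truth, p.prediction)
                    for r in range(m)
                    for p in es.pairs
                ],
                cat,
            )
            assert medtric(dup, cfg).score == pytest.approx(base, abs=TOL)

    def test_per_instance_monotonicity(self):
        """Dropping one more correct label or adding one more extra label
        strictly lowers t_i; a wrong diagnosis scores below the all-missed
        (empty) prediction."""
        rng = np.random.default_rng(13)
        cat = DiagnosisCatalog(tuple(f"c{i}" for i in range(6)))
        for _ in range(20):
            cfg = random_valid_config(cat, rng)
            truth = frozenset(rng.choice(cat.codes, size=3, replace=False))
            es = singleton_set(truth, truth, cat)

            def t(pred):
                return instance_score(
                    InstancePair("i", truth, pred), es, cfg
                ).total

            # progressively miss more
            order = sorted(truth)
            totals = [t(frozenset(order[:k])) for k in range(len(order), -1, -1)]
            assert all(a > b for a, b in zip(totals, totals[1:]))
            # progressively add extras
            extras = [c for c in cat.codes if c not in truth]
            pred = set(truth)
            prev = t(frozenset(pred))
            for e in extras:
                pred.add(e)
                cur = t(frozenset(pred))
                assert cur < prev
                prev = cur
            # any wrong diagnosis below the empty prediction
            wrong = frozenset(extras[:2])
            assert t(wrong) < t(frozenset())

    def test_contradiction_penalty_lowers_score(self, xab_catalog):
        plain = MetricConfig.create(xab_catalog)
        contra = MetricConfig.create(xab_catalog, contradiction=[("X", "B")])
        es = make_contingency([({"A"}, {"A", "X", "B"}, 5)], xab_catalog)
        assert medtric(es, contra).score < medtric(es, plain).score


class TestClinicalOrderMargin:
    def test_no_false_positives_negative_margin(self):
        cat = DiagnosisCatalog(("A", "B"))
        cfg = MetricConfig.create(cat)
        assert margin_from_counts("A", tp=3, fp=0, fn=2, n_k=5, n_star=5, config=cfg) < 0

    def test_conservative_bound_fp_at_most_twice_fn(self):
        """With n_k = n* and any similarity in (0,1), fp <= 2 fn keeps the
        margin negative."""
        rng = np.random.default_rng(17)
        cat = DiagnosisCatalog(tuple(f"c{i}" for i in range(4)))
        for _ in range(200):
            cfg = random_valid_config(cat, rng)
            fn = int(rng.integers(1, 30))
            fp = int(rng.integers(0, 2 * fn + 1))
            n = int(rng.integers(fn, fn + 50))
            code = cat.codes[int(rng.integers(cat.size))]
            assert margin_from_counts(code, n - fn, fp, fn, n, n, cfg) < 0

    def test_w_star_one_third_extends_to_thrice(self):
        cat = DiagnosisCatalog(("A", "B"))
        cfg = MetricConfig.create(cat, similarity=1 / 3)
        for fn in (1, 4, 9):
            for fp in range(0, 3 * fn):
                assert margin_from_counts("A", 10 - fn, fp, fn, 10, 10, cfg) < 0
            # at exactly fp = 3 fn the margin hits zero: boundary of the region
            assert margin_from_counts("A", 10 - fn, 3 * fn, fn, 10, 10, cfg) == pytest.approx(0.0)

    def test_margin_from_evaluation_set(self, xab_catalog, equal_config):
        # X: 2 fn, 0 fp -> negative; B: 1 fp, 0 fn -> positive margin
        es = make_contingency(
            [({"X", "A"}, {"A"}, 2), ({"A"}, {"A", "B"}, 1)], xab_catalog
        )
        xi = clinical_order_margin(es, equal_config)
        assert xi["X"] < 0
        assert xi["B"] > 0
        assert xi["A"] == pytest.approx(0.0)
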