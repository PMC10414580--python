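"""Shared fixtures: small catalogs, configs and the worked toy datasets."""

from __future__ import annotations

import numpy as np
import pytest

from medtric import (
    DiagnosisCatalog,
    InstancePair,
    MetricConfig,
    build_evaluation_set,
)


@pytest.fixture
def ecg_catalog() -> DiagnosisCatalog:
    """A small ECG-flavoured catalog with a normal class."""
    return DiagnosisCatalog(
        codes=("NSR", "CRBBB", "AF", "QAb", "LAD", "STach", "TInv"),
        normal_code="NSR",
    )


@pytest.fixture
def xab_catalog() -> DiagnosisCatalog:
    return DiagnosisCatalog(codes=("X", "A", "B"))


@pytest.fixture
def equal_config(xab_catalog) -> MetricConfig:
    return MetricConfig.create(xab_catalog)


def make_contingency(counts: list[tuple[set, set, int]], catalog):
    """Expand (truth, prediction, multiplicity) rows into an evaluation set."""
    pairs = []
    for k, (truth, pred, mult) in enumerate(counts):
        pairs.extend(
            InstancePair(f"r{k}i{i}", truth, pred) for i in range(mult)
        )
    return build_evaluation_set(pairs, catalog)


@pytest.fixture
def prevalence_case1(xab_catalog):
    """1000 instances: {X,A} detected half the time, {A,B} always."""
    return make_contingency(
        [({"X", "A"}, {"X", "A"}, 50),
         ({"X", "A"}, {"A"}, 50),
         ({"A", "B"}, {"A", "B"}, 900)],
        xab_catalog,
    )


@pytest.fixture
def prevalence_case2(xab_catalog):
    """Same classifier quality, inverted prevalence."""
    return make_contingency(
        [({"X", "A"}, {"X", "A"}, 450),
         ({"X", "A"}, {"A"}, 450),
         ({"A", "B"}, {"A", "B"}, 100)],
        xab_catalog,
    )


def random_valid_config(catalog, rng: np.random.Generator, with_contradictions=False):
    """A random configuration satisfying every invariant."""
    P = catalog.size
    sig = {c: float(rng.uniform(0.1, 3.0)) for c in catalog.codes}
    w = rng.uniform(0.05, 0.95, size=(P, P))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 1.0)
    C = np.zeros((P, P))
    if with_contradictions and P >= 2:
        i, j = rng.choice(P, size=2, replace=False)
        C[i, j] = C[j, i] = 1.0
    return MetricConfig.create(catalog, significance=sig, similarity=w, contradiction=C)


def random_evaluation_set(catalog, rng: np.random.Generator, n_max=20, config=None):
    """Random pairs with non-empty truths (avoiding contradictions if asked)."""
    codes = list(catalog.codes)
    N = int(rng.integers(1, n_max + 1))
    pairs = []
    while len(pairs) < N:
        k = int(rng.integers(1, len(codes) + 1))
        truth = set(rng.choice(codes, size=k, replace=False))
        if config is not None and config.contradictory_pairs_in(frozenset(truth)):
            continue
        mask = rng.random(len(codes)) < 0.35
        pred = {c for c, m in zip(codes, mask) if m}
        pairs.append(InstancePair(f"i{len(pairs)}", truth, pred))
    return build_evaluation_set(pairs, catalog, config)
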