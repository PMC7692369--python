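"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import mupsrules as m
from mupsrules import datasets


# -- fixtures --------------------------------------------------------------


@pytest.fixture(scope="session")
def excerpt():
    """The 20 printed formulations, raw (f2 decision)."""
    return datasets.load_study_excerpt()


@pytest.fixture(scope="session")
def excerpt_prepared(excerpt):
    """Excerpt after binarization, discretization and two-copy transform."""
    return m.prepare_table(excerpt)


@pytest.fixture(scope="session")
def clean_table():
    """Noise-free synthetic study table (180 formulations)."""
    cfg = m.GeneratorConfig(seed=7, inconsistency=0.0)
    table, truth = m.generate_table(cfg)
    return m.prepare_table(table), truth


@pytest.fixture(scope="session")
def noisy_table():
    """Synthetic study table at the default 10% inconsistency."""
    cfg = m.GeneratorConfig(seed=7)
    table, truth = m.generate_table(cfg)
    return m.prepare_table(table), truth


def toy_table(values: dict, labels, preferences: dict | None = None) -> m.DecisionTable:
    """Small decision table from literal columns; preferences default gain."""
    data = pd.DataFrame(values)
    data.index = pd.RangeIndex(1, len(data) + 1)
    preferences = preferences or {}
    attrs = [
        m.Attribute(name, kind="numeric", preference=preferences.get(name, "gain"))
        for name in data.columns
    ]
    decision = pd.Series(list(labels), index=data.index, dtype=int)
    return m.DecisionTable(data, attrs, decision, decision_name="class")


# -- brute-force oracles ---------------------------------------------------


def oracle_dominates(table: m.DecisionTable, i: int, j: int) -> bool:
    """Pairwise weak dominance by explicit per-attribute comparison."""
    for a in table.attributes:
        vi = table.data[a.base].iloc[i]
        vj = table.data[a.base].iloc[j]
        if a.preference == "gain":
            if not vi >= vj:
                return False
        elif a.preference == "cost":
            if not vi <= vj:
                return False
        else:
            if vi != vj:
                return False
    return True


def oracle_cone(table: m.DecisionTable, obj, direction: str) -> set:
    ids = table.objects
    pos = ids.index(obj)
    members = set()
    for q, other in enumerate(ids):
        dominates = (
            oracle_dominates(table, q, pos)
            if direction == "dominating"
            else oracle_dominates(table, pos, q)
        )
        if dominates:
            members.add(other)
    return members


def oracle_approximation(table: m.DecisionTable, union: m.ClassUnion):
    """(lower, upper) sets by exhaustive pairwise enumeration."""
    ids = table.objects
    members = {o for o, inside in zip(ids, union.members(table.decision)) if inside}
    cone_dir = "dominating" if union.kind == "at_least" else "dominated"
    dual_dir = "dominated" if union.kind == "at_least" else "dominating"
    lower = {o for o in ids if oracle_cone(table, o, cone_dir) <= members}
    upper = {o for o in ids if oracle_cone(table, o, dual_dir) & members}
    return lower, upper


def random_small_table(rng: np.random.Generator) -> m.DecisionTable:
    """Random table with <= 8 objects, <= 3 attributes, small value grids."""
    n = int(rng.integers(2, 9))
    n_attr = int(rng.integers(1, 4))
    values = {
        f"a{j}": rng.integers(0, 4, size=n).astype(float) for j in range(n_attr)
    }
    prefs = {
        f"a{j}": rng.choice(["gain", "cost"]) for j in range(n_attr)
    }
    labels = rng.integers(1, 3, size=n)
    if len(set(labels)) == 1:  # keep both classes present
        labels[0] = 3 - labels[0]
    return toy_table(values, labels, prefs)
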