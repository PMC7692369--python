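"""Monotonic decision-rule induction and rule quality measures.

Rules have the form "if E then H" where the premise E is a conjunction of
elementary threshold conditions (>= / > on gain-type attribute copies,
<= / < on cost-type copies, equality on binaries) and the conclusion H is
a union of decision classes.  Induction follows a sequential-covering
scheme in the DomLEM family: rules are grown one condition at a time until
they are consistent at the requested consistency threshold, pruned to a
minimal premise, and the covered positive objects removed until the whole
positive region of the union is covered.

Rule quality: support (objects matching premise and conclusion), strength
(support / table size), confidence (support / premise matches) and a
Bayesian confirmation measure computed from the 2x2 contingency of premise
match x conclusion membership.  Four confirmation measures are available:

* ``s``: P(H|E) - P(H|not E)  (default)
* ``c``: P(E and H) - P(E) P(H)
* ``f``: Kemeny-Oppenheim, (P(E|H) - P(E|not H)) / (P(E|H) + P(E|not H))
* ``l``: log10 likelihood ratio, log10 [ P(E|H) / P(E|not H) ]

All four are positive exactly when the premise raises the probability of
the conclusion, zero under statistical independence, negative under
anti-association; degenerate contingencies yield NaN.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .approximations import AT_LEAST, ClassUnion
from .information_system import COST, GAIN, DecisionTable

CONFIRMATION_MEASURES = ("s", "c", "f", "l")

_GAIN_OPS = (">=", ">")
_COST_OPS = ("<=", "<")


@dataclass(frozen=True)
class ElementaryCondition:
    """One threshold condition on a (copy of a) condition attribute."""

    attribute: str
    op: str
    threshold: float

    def __post_init__(self) -> None:
        if self.op not in (">=", ">", "<=", "<", "=="):
            raise ValueError(f"unknown relation {self.op!r}")

    def evaluate(self, values) -> np.ndarray:
        v = np.asarray(values)
        if self.op == ">=":
            return v >= self.threshold
        if self.op == ">":
            return v > self.threshold
        if self.op == "<=":
            return v <= self.threshold
        if self.op == "<":
            return v < self.threshold
        return v == self.threshold


@dataclass(frozen=True)
class Rule:
    """A minimal monotonic decision rule E -> H with its quality metrics."""

    conditions: tuple[ElementaryCondition, ...]
    conclusion: ClassUnion
    support: int = 0
    strength: float = 0.0
    confidence: float = 0.0
    confirmation: float = float("nan")

    def matches(self, table) -> np.ndarray:
        """Boolean premise-match mask over a DecisionTable or DataFrame."""
        if isinstance(table, DecisionTable):
            getter = table.column
            n = table.n_objects
        else:
            getter = lambda name: table[name]  # noqa: E731
            n = len(table)
        mask = np.ones(n, dtype=bool)
        for cond in self.conditions:
            mask &= np.asarray(cond.evaluate(getter(cond.attribute)))
        return mask

    @property
    def attributes(self) -> frozenset:
        return frozenset(c.attribute for c in self.conditions)

    def describe(self, classes=None, binary_attrs: frozenset = frozenset()) -> str:
        if not self.conditions:
            premise = "always"
        else:
            parts = []
            for c in self.conditions:
                if c.attribute in binary_attrs:
                    presence = (c.op in (">=", ">", "==") and c.threshold > 0) or (
                        c.op == "==" and c.threshold == 1
                    )
                    parts.append(
                        f"{'presence' if presence else 'absence'} of {c.attribute}"
                    )
                else:
                    parts.append(f"{c.attribute} {c.op} {c.threshold:g}")
            premise = "if " + " and ".join(parts)
        return f"{premise}, then {self.conclusion.describe(classes)}"


# -- rule metrics ----------------------------------------------------------


def _contingency(premise: np.ndarray, conclusion: np.ndarray) -> tuple[int, int, int, int]:
    a = int(np.sum(premise & conclusion))
    b = int(np.sum(premise & ~conclusion))
    c = int(np.sum(~premise & conclusion))
    d = int(np.sum(~premise & ~conclusion))
    return a, b, c, d


def confirmation_from_counts(a: int, b: int, c: int, d: int, measure: str = "s") -> float:
    """Bayesian confirmation of H by E from the 2x2 contingency counts.

    ``a``=|E,H|, ``b``=|E,not H|, ``c``=|not E,H|, ``d``=|not E,not H|.
    Degenerate margins (premise matching all or no objects, or a one-class
    table) return NaN as the undefined flag.
    """
    n = a + b + c + d
    if measure == "s":
        if a + b == 0 or c + d == 0:
            return float("nan")
        return a / (a + b) - c / (c + d)
    if measure == "c":
        if n == 0:
            return float("nan")
        return (a * d - b * c) / n**2
    if measure in ("f", "l"):
        if a + c == 0 or b + d == 0:
            return float("nan")
        p_e_h = a / (a + c)
        p_e_nh = b / (b + d)
        if measure == "f":
            if p_e_h + p_e_nh == 0:
                return float("nan")
            return (p_e_h - p_e_nh) / (p_e_h + p_e_nh)
        if p_e_h == 0 and p_e_nh == 0:
            return float("nan")
        if p_e_nh == 0:
            return float("inf")
        if p_e_h == 0:
            return float("-inf")
        return math.log10(p_e_h / p_e_nh)
    raise ValueError(f"unknown confirmation measure {measure!r}")


def rule_support(rule: Rule, table: DecisionTable) -> int:
    """Objects satisfying every elementary condition and the conclusion."""
    premise = rule.matches(table)
    conclusion = rule.conclusion.members(table.decision)
    return int(np.sum(premise & conclusion))


def rule_strength(rule: Rule, table: DecisionTable) -> float:
    """Support divided by the number of objects in the table."""
    if table.n_objects == 0:
        raise ValueError("empty table")
    return rule_support(rule, table) / table.n_objects


def rule_confidence(rule: Rule, table: DecisionTable) -> float:
    premise = rule.matches(table)
    matched = int(np.sum(premise))
    if matched == 0:
        return 0.0
    conclusion = rule.conclusion.members(table.decision)
    return float(np.sum(premise & conclusion) / matched)


def confirmation(rule: Rule, table: DecisionTable, measure: str = "s") -> float:
    premise = rule.matches(table)
    conclusion = rule.conclusion.members(table.decision)
    return confirmation_from_counts(*_contingency(premise, conclusion), measure=measure)


def score_rule(rule: Rule, table: DecisionTable, measure: str = "s") -> Rule:
    """Return the rule with support/strength/confidence/confirmation filled."""
    premise = rule.matches(table)
    conclusion = rule.conclusion.members(table.decision)
    a, b, c, d = _contingency(premise, conclusion)
    matched = a + b
    return dc_replace(
        rule,
        support=a,
        strength=a / table.n_objects,
        confidence=a / matched if matched else 0.0,
        confirmation=confirmation_from_counts(a, b, c, d, measure=measure),
    )


def truncate_strength(strength: float, digits: int = 4) -> float:
    """Display convention for rule strength: truncation (not rounding)."""
    scale = 10**digits
    return math.floor(strength * scale + 1e-12) / scale


# -- rule sets -------------------------------------------------------------


@dataclass
class RuleSet:
    """Rules induced for one class union, strongest (by confirmation) first."""

    rules: list[Rule]
    union: ClassUnion
    consistency: float = 1.0
    measure: str = "s"

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def sorted(self) -> "RuleSet":
        """Rank by confirmation descending, ties by support descending."""
        key = lambda r: (  # noqa: E731
            -(r.confirmation if np.isfinite(r.confirmation) else -np.inf),
            -r.support,
        )
        return RuleSet(sorted(self.rules, key=key), self.union,
                       self.consistency, self.measure)

    def coverage(self, table: DecisionTable) -> np.ndarray:
        mask = np.zeros(table.n_objects, dtype=bool)
        for r in self.rules:
            mask |= r.matches(table)
        return mask

    def to_dataframe(self) -> pd.DataFrame:
        """Printed-table layout: one column per attribute used, plus metrics."""
        attrs: list[str] = []
        for r in self.rules:
            for c in r.conditions:
                if c.attribute not in attrs:
                    attrs.append(c.attribute)
        rows = []
        for i, r in enumerate(self.rules, start=1):
            row = {"No. of Rule": i}
            for name in attrs:
                conds = [c for c in r.conditions if c.attribute == name]
                row[name] = " and ".join(
                    f"{c.op}{c.threshold:g}" if c.op != "==" else f"{c.threshold:g}"
                    for c in conds
                ) or "-"
            row["Rule Support"] = r.support
            row["Rule Strength"] = f"{truncate_strength(r.strength):.4f}"
            row["Confirmation Measure"] = (
                f"{r.confirmation:.2f}" if np.isfinite(r.confirmation) else "n/a"
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json_records(self) -> list[dict]:
        return [
            {
                "conditions": [
                    {"attribute": c.attribute, "op": c.op, "threshold": float(c.threshold)}
                    for c in r.conditions
                ],
                "conclusion": {"kind": r.conclusion.kind, "t": r.conclusion.t},
                "support": r.support,
                "strength": r.strength,
                "confidence": r.confidence,
                "confirmation": None if not np.isfinite(r.confirmation) else r.confirmation,
            }
            for r in self.rules
        ]


# -- induction -------------------------------------------------------------


def _candidate_entries(table: DecisionTable, union: ClassUnion):
    """(base column, op) pairs admissible for this union's rules.

    For an upward union, gain copies carry >= conditions and cost copies
    <= conditions; the dual holds for a downward union because its rules
    point toward the worse classes.
    """
    entries = []
    seen = set()
    for a in table.attributes:
        if a.preference == GAIN:
            op = ">=" if union.kind == AT_LEAST else "<="
        elif a.preference == COST:
            op = "<=" if union.kind == AT_LEAST else ">="
        else:
            continue
        key = (a.base, op)
        if key not in seen:
            seen.add(key)
            entries.append(key)
    return entries


def induce_rules(
    table: DecisionTable,
    union: ClassUnion,
    consistency: float = 1.0,
    measure: str = "s",
) -> RuleSet:
    """Sequential-covering induction of minimal monotonic rules.

    ``consistency`` is the minimum admissible rule confidence with respect
    to the union (1.0 = classical certain rules drawn from the lower
    approximation; lower values admit rules covering mildly inconsistent
    objects, in the variable-consistency spirit).  The returned rules
    jointly cover every object of the union's positive region.
    """
    if not 0.0 < consistency <= 1.0:
        raise ValueError("consistency threshold must lie in (0, 1]")
    union.validate(table)
    in_union = np.asarray(union.members(table.decision))
    entries = _candidate_entries(table, union)
    values = {col: table.data[col].to_numpy(dtype=float) for col, _ in entries}
    n = table.n_objects

    # positive region: union members whose cone-consistency clears the bar
    positive = in_union.copy()
    if in_union.any() and not in_union.all():
        cons = _union_consistency(table, union)
        positive = in_union & (cons >= consistency - 1e-12)

    if not positive.any():
        warnings.warn(
            f"empty positive region for {union.kind} {union.t}; no rules induced",
            stacklevel=2,
        )
        return RuleSet([], union, consistency, measure)

    # Precompute, per candidate (column, op), the n x n_thresholds match
    # matrix over the observed-value grid; candidate scores then reduce to
    # boolean-matrix / vector products.
    grids = []
    for col, op in entries:
        v = values[col]
        thresholds = np.unique(v)
        cmp = (
            v[:, None] >= thresholds[None, :]
            if op == ">="
            else v[:, None] <= thresholds[None, :]
        )
        grids.append((col, op, thresholds, cmp.astype(np.float32)))

    uncovered = positive.copy()
    rules: list[Rule] = []
    while uncovered.any():
        conds: list[tuple[str, str, float]] = []
        cov = np.ones(n, dtype=bool)

        def consistent(mask: np.ndarray) -> bool:
            m = int(mask.sum())
            return m > 0 and int((mask & in_union).sum()) / m >= consistency - 1e-12

        while not consistent(cov):
            best = None
            base = cov & uncovered
            if not base.any():
                break
            cov_f = cov.astype(np.float32)
            base_f = base.astype(np.float32)
            n_cov = cov_f.sum()
            for col, op, thresholds, cmp in grids:
                tot = cov_f @ cmp
                pos = base_f @ cmp
                with np.errstate(invalid="ignore", divide="ignore"):
                    prec = np.where(tot > 0, pos / np.maximum(tot, 1.0), -1.0)
                # require the condition to actually shrink the cover
                prec = np.where(tot < n_cov, prec, -1.0)
                j = int(np.lexsort((-pos, -prec))[0])
                if prec[j] < 0:
                    continue
                cand = (float(prec[j]), float(pos[j]), col, op, float(thresholds[j]))
                if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                    best = cand
            if best is None:
                break
            _, _, col, op, thr = best
            conds.append((col, op, thr))
            cov = cov & ElementaryCondition(col, op, thr).evaluate(values[col])

        if not consistent(cov):
            # cannot separate these objects at this threshold (identical
            # descriptions across classes); drop them from the target set
            warnings.warn(
                f"{int((cov & uncovered).sum())} positive objects not separable "
                f"at consistency {consistency}; left uncovered",
                stacklevel=2,
            )
            uncovered &= ~cov
            continue

        # prune to a minimal premise
        changed = True
        while changed and conds:
            changed = False
            for i in range(len(conds)):
                trial = conds[:i] + conds[i + 1:]
                mask = np.ones(n, dtype=bool)
                for col, op, thr in trial:
                    mask &= ElementaryCondition(col, op, thr).evaluate(values[col])
                if consistent(mask):
                    conds = trial
                    cov = mask
                    changed = True
                    break

        # generalize: relax each threshold to the most permissive observed
        # value that keeps the rule consistent (greedy growth overshoots
        # toward the pure extreme; this walks back to the class boundary)
        for i, (col, op, thr) in enumerate(conds):
            others = np.ones(n, dtype=bool)
            for j, (c2, o2, t2) in enumerate(conds):
                if j != i:
                    others &= ElementaryCondition(c2, o2, t2).evaluate(values[c2])
            grid = np.unique(values[col])
            cands = grid[grid < thr][::-1] if op == ">=" else grid[grid > thr]
            best_thr = thr
            for v in cands:
                mask = others & ElementaryCondition(col, op, float(v)).evaluate(values[col])
                if consistent(mask):
                    best_thr = float(v)
                else:
                    break
            conds[i] = (col, op, best_thr)
        cov = np.ones(n, dtype=bool)
        for col, op, thr in conds:
            cov &= ElementaryCondition(col, op, thr).evaluate(values[col])

        rule = Rule(
            conditions=tuple(ElementaryCondition(c, o, t) for c, o, t in conds),
            conclusion=union,
        )
        rules.append(score_rule(rule, table, measure=measure))
        uncovered &= ~cov

    return RuleSet(rules, union, consistency, measure).sorted()


def _union_consistency(table: DecisionTable, union: ClassUnion) -> np.ndarray:
    """Per-object cone-consistency with respect to one union."""
    from .approximations import dominance_matrix

    dom = dominance_matrix(table)
    in_union = np.asarray(union.members(table.decision))
    cone = dom if union.kind == AT_LEAST else dom.T
    sizes = cone.sum(axis=0).astype(float)
    hits = (cone & in_union[:, None]).sum(axis=0).astype(float)
    return hits / sizes


def check_minimality(
    rule: Rule, table: DecisionTable, consistency: float = 1.0
) -> bool:
    """True iff no single condition can be dropped while the rule stays
    admissible (confidence with respect to its conclusion >= threshold)."""
    in_union = np.asarray(rule.conclusion.members(table.decision))

    def admissible(conds) -> bool:
        mask = np.ones(table.n_objects, dtype=bool)
        for c in conds:
            mask &= np.asarray(c.evaluate(table.column(c.attribute)))
        m = int(mask.sum())
        return m > 0 and int((mask & in_union).sum()) / m >= consistency - 1e-12

    if not admissible(rule.conditions):
        return False
    for i in range(len(rule.conditions)):
        if admissible(rule.conditions[:i] + rule.conditions[i + 1:]):
            return False
    return True
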