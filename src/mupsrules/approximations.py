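"""Dominance cones, class unions and rough approximations.

This is the rough-set core that separates consistent from inconsistent
formulations before any rule is induced.  An object *x* weakly dominates
*y* when *x* is at least as good on every gain-type attribute and at most
as high on every cost-type attribute (nominal attributes, if any remain,
must match exactly).  On a two-copy table — where each attribute carries
both a gain and a cost declaration over the same values — dominance
therefore reduces to per-attribute equality, and the approximations
coincide with the classical indiscernibility-based ones; with declared
preference directions the full dominance machinery applies.

Class labels are ordinal with 1 the best class, so the upward union
"at least as good as class t" contains the labels <= t and the downward
union "at most as good as class t" the labels >= t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .information_system import COST, GAIN, DecisionTable

AT_LEAST = "at_least"
AT_MOST = "at_most"
DOMINATING = "dominating"
DOMINATED = "dominated"


@dataclass(frozen=True)
class ClassUnion:
    """An upward (``at_least``) or downward (``at_most``) union of classes."""

    kind: str
    t: int

    def __post_init__(self) -> None:
        if self.kind not in (AT_LEAST, AT_MOST):
            raise ValueError(f"unknown union kind {self.kind!r}")

    def members(self, decision) -> np.ndarray:
        labels = np.asarray(decision, dtype=int)
        # class 1 is best: "at least class t" keeps the labels <= t
        return labels <= self.t if self.kind == AT_LEAST else labels >= self.t

    def contains_class(self, label: int) -> bool:
        return label <= self.t if self.kind == AT_LEAST else label >= self.t

    def describe(self, classes=None) -> str:
        if classes is not None:
            classes = sorted(classes)
            single = (self.kind == AT_LEAST and self.t == classes[0]) or (
                self.kind == AT_MOST and self.t == classes[-1]
            )
            if single:
                return f"class {self.t}"
        word = "at least" if self.kind == AT_LEAST else "at most"
        return f"{word} class {self.t}"

    def validate(self, table: DecisionTable) -> None:
        if self.t not in table.classes:
            raise ValueError(f"union references nonexistent class {self.t}")


def upward(t: int) -> ClassUnion:
    return ClassUnion(AT_LEAST, t)


def downward(t: int) -> ClassUnion:
    return ClassUnion(AT_MOST, t)


def own_union(label: int, classes) -> ClassUnion:
    """The non-trivial union a class certifies: upward for the best label,
    downward for the worst, upward otherwise."""
    classes = sorted(classes)
    if label == classes[-1]:
        return downward(label)
    return upward(label)


@dataclass(frozen=True)
class DominanceCone:
    origin: object
    direction: str
    members: frozenset


@dataclass(frozen=True)
class ClassUnionApproximation:
    union: ClassUnion
    lower: frozenset
    upper: frozenset
    gamma: float

    @property
    def boundary(self) -> frozenset:
        return self.upper - self.lower


# -- dominance -------------------------------------------------------------


def dominance_matrix(table: DecisionTable) -> np.ndarray:
    """Boolean matrix ``D[i, j]`` = object i weakly dominates object j."""
    n = table.n_objects
    dom = np.ones((n, n), dtype=bool)
    for attr in table.attributes:
        v = table.data[attr.base].to_numpy()
        if attr.preference == GAIN:
            dom &= v[:, None] >= v[None, :]
        elif attr.preference == COST:
            dom &= v[:, None] <= v[None, :]
        else:
            dom &= v[:, None] == v[None, :]
    return dom


def dominance_cone(table: DecisionTable, obj, direction: str = DOMINATING) -> DominanceCone:
    """Cone of objects dominating (or dominated by) ``obj``.

    The dominating cone of x is {y : y weakly dominates x}; the dominated
    cone is {y : x weakly dominates y}.  Both contain x (reflexivity).
    """
    if direction not in (DOMINATING, DOMINATED):
        raise ValueError(f"unknown cone direction {direction!r}")
    ids = table.objects
    try:
        pos = ids.index(obj)
    except ValueError:
        raise KeyError(f"unknown object id {obj!r}") from None
    dom = dominance_matrix(table)
    mask = dom[:, pos] if direction == DOMINATING else dom[pos, :]
    return DominanceCone(
        origin=obj,
        direction=direction,
        members=frozenset(np.asarray(ids, dtype=object)[mask]),
    )


# -- approximations --------------------------------------------------------


def _approx_masks(dom: np.ndarray, in_union: np.ndarray, kind: str):
    """Lower/upper boolean masks for one union given the dominance matrix."""
    if kind == AT_LEAST:
        cone_of = dom  # cone_of[:, x] = dominating cone of x
        # lower: every object dominating x is in the union
        lower = ~np.any(cone_of & ~in_union[:, None], axis=0)
        # upper: some object dominated by x is in the union
        upper = np.any(dom & in_union[None, :], axis=1)
    else:
        lower = ~np.any(dom.T & ~in_union[:, None], axis=0)
        upper = np.any(dom.T & in_union[None, :], axis=1)
    return lower, upper


def _nontrivial_unions(classes) -> list[ClassUnion]:
    classes = sorted(classes)
    ups = [upward(t) for t in classes[:-1]]
    downs = [downward(t) for t in classes[1:]]
    return ups + downs


def quality_of_classification(table: DecisionTable) -> float:
    """Fraction of objects outside every union boundary (gamma).

    gamma = 1 exactly when no two objects are dominance-inconsistent.
    """
    dom = dominance_matrix(table)
    labels = np.asarray(table.decision, dtype=int)
    in_boundary = np.zeros(table.n_objects, dtype=bool)
    for union in _nontrivial_unions(table.classes):
        lower, upper = _approx_masks(dom, union.members(labels), union.kind)
        in_boundary |= upper & ~lower
    return float(np.mean(~in_boundary))


def union_approximations(table: DecisionTable, union: ClassUnion) -> ClassUnionApproximation:
    """Lower/upper approximation and boundary of one union of classes."""
    union.validate(table)
    dom = dominance_matrix(table)
    labels = np.asarray(table.decision, dtype=int)
    lower, upper = _approx_masks(dom, union.members(labels), union.kind)
    ids = np.asarray(table.objects, dtype=object)
    return ClassUnionApproximation(
        union=union,
        lower=frozenset(ids[lower]),
        upper=frozenset(ids[upper]),
        gamma=quality_of_classification(table),
    )


def object_consistency(table: DecisionTable, obj, union: ClassUnion) -> float:
    """Fraction of the object's relevant cone lying inside the union.

    For an upward union the dominating cone is inspected, for a downward
    union the dominated cone; 1.0 means the object is fully consistent
    with the union's monotonicity requirement.
    """
    union.validate(table)
    ids = table.objects
    try:
        pos = ids.index(obj)
    except ValueError:
        raise KeyError(f"unknown object id {obj!r}") from None
    dom = dominance_matrix(table)
    cone = dom[:, pos] if union.kind == AT_LEAST else dom[pos, :]
    in_union = union.members(table.decision)
    return float(np.sum(cone & in_union) / np.sum(cone))


def consistency_by_object(table: DecisionTable) -> np.ndarray:
    """Per-object consistency with its own class union (vectorized).

    The best class is checked against its upward union, the worst against
    its downward union.  Used as sampling weight by variable-consistency
    bagging.
    """
    dom = dominance_matrix(table)
    labels = np.asarray(table.decision, dtype=int)
    out = np.ones(table.n_objects, dtype=float)
    for c in table.classes:
        union = own_union(c, table.classes)
        in_union = union.members(labels)
        cone = dom if union.kind == AT_LEAST else dom.T
        sizes = cone.sum(axis=0).astype(float)
        hits = (cone & in_union[:, None]).sum(axis=0).astype(float)
        frac = hits / sizes
        mask = labels == c
        out[mask] = frac[mask]
    return out


def approximation_report(table: DecisionTable) -> dict:
    """JSON-ready report: per-union lower/upper/boundary ids and gamma."""
    report = {"gamma": quality_of_classification(table), "unions": []}
    for union in _nontrivial_unions(table.classes):
        approx = union_approximations(table, union)
        report["unions"].append(
            {
                "kind": union.kind,
                "t": union.t,
                "lower": sorted(approx.lower),
                "upper": sorted(approx.upper),
                "boundary": sorted(approx.boundary),
            }
        )
    return report
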