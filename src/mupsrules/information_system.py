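"""Ordinal decision tables ("information systems") for formulation data.

A decision table holds one row per formulation, a set of condition
attributes (tableting-process parameters and tablet-mass composition) and a
single decision attribute: either the raw f2 dissolution-similarity factor
or the ordinal class derived from it (class 1 = release profile preserved,
class 2 = release profile changed; class 1 is the preferred class).

The module also provides the three standard pre-processing steps used
before dominance-based rule induction:

* :func:`binarize_nominal` — one-hot expansion of a nominal attribute
  (e.g. coating type 1/2/3 into ``Coating_1``, ``Coating_2``, ``Coating_3``),
* :func:`clone_gain_cost` — the non-invasive "two copy" transformation that
  declares every attribute of unknown preference direction once as
  gain-type (larger is better) and once as cost-type (smaller is better),
* :func:`discretize_decision` — the sharp f2 >= 50 class cut.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: Ordinal class labels.  Class order is total and class 1 is best.
CLASS_SIMILAR = 1  #: release profile preserved after tableting (f2 >= 50)
CLASS_DIFFERENT = 2  #: release profile changed after tableting (f2 < 50)

#: Default f2 threshold separating the two classes.
F2_THRESHOLD = 50.0

NOMINAL = "nominal"
NUMERIC = "numeric"

GAIN = "gain"
COST = "cost"
NONE = "none"


@dataclass(frozen=True)
class Attribute:
    """Declaration of one condition attribute.

    Parameters
    ----------
    name:
        Attribute name as it appears in rules and reports.
    kind:
        ``"nominal"`` (finite unordered domain, matched by equality) or
        ``"numeric"`` (ordered values).
    preference:
        ``"gain"`` if larger values favour the better class, ``"cost"`` if
        smaller values do, ``"none"`` if unknown / unordered.  Attributes of
        unknown preference are later duplicated into a gain and a cost copy
        by :func:`clone_gain_cost`.
    values:
        Finite set of admissible values, or ``None``.
    bounds:
        Inclusive numeric range ``(lo, hi)``, or ``None``.
    base:
        Name of the underlying value column in the table.  The two copies
        produced by :func:`clone_gain_cost` share one ``base`` column, so
        the transformation never duplicates data.
    """

    name: str
    kind: str = NUMERIC
    preference: str = NONE
    values: frozenset | None = None
    bounds: tuple[float, float] | None = None
    base: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in (NOMINAL, NUMERIC):
            raise ValueError(f"unknown attribute kind {self.kind!r}")
        if self.preference not in (GAIN, COST, NONE):
            raise ValueError(f"unknown preference {self.preference!r}")
        if self.base is None:
            object.__setattr__(self, "base", self.name)
        if self.values is not None and not isinstance(self.values, frozenset):
            object.__setattr__(self, "values", frozenset(self.values))

    @property
    def is_binary(self) -> bool:
        return self.values is not None and self.values <= {0, 1, 0.0, 1.0}

    def admits(self, value) -> bool:
        """Whether ``value`` lies in the declared domain."""
        if pd.isna(value):
            return False
        if self.values is not None:
            if any(np.isclose(value, v) if isinstance(v, (int, float)) else value == v
                   for v in self.values):
                return True
            return False
        if self.bounds is not None:
            lo, hi = self.bounds
            return lo <= value <= hi
        return True


class DecisionTable:
    """Objects x condition attributes plus one ordinal decision attribute.

    ``data`` holds the value grid (one column per *base* attribute), and
    ``decision`` the per-object decision value — either a raw numeric f2 or
    an integer class label (1 best).  ``metadata`` keeps columns excluded
    from the condition attributes (e.g. the retained f2 after
    discretization).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        attributes: Sequence[Attribute],
        decision: pd.Series,
        decision_name: str = "class",
        metadata: pd.DataFrame | None = None,
        validate: bool = True,
    ) -> None:
        self.data = data
        self.attributes = list(attributes)
        self.decision = decision
        self.decision_name = decision_name
        self.metadata = metadata
        if validate:
            self.validate()

    # -- basic accessors ---------------------------------------------------

    @property
    def n_objects(self) -> int:
        return len(self.data)

    @property
    def objects(self) -> list:
        return list(self.data.index)

    @property
    def attribute_names(self) -> list[str]:
        return [a.name for a in self.attributes]

    def attribute(self, name: str) -> Attribute:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(f"no attribute named {name!r}")

    def column(self, name: str) -> pd.Series:
        """Values behind an attribute (resolving gain/cost copies)."""
        try:
            a = self.attribute(name)
            return self.data[a.base]
        except KeyError:
            if name in self.data.columns:
                return self.data[name]
            raise

    @property
    def classes(self) -> list[int]:
        return sorted(int(c) for c in pd.unique(self.decision))

    def class_members(self, label: int) -> np.ndarray:
        return np.asarray(self.decision == label)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if self.n_objects == 0:
            raise ValueError("no objects: the decision table is empty")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate object identifiers: {dupes}")
        if len(self.decision) != self.n_objects:
            raise ValueError("decision length does not match object count")
        if self.decision.isna().any():
            missing = self.data.index[self.decision.isna()].tolist()
            raise ValueError(f"missing decision labels for objects {missing}")
        for a in self.attributes:
            if a.base not in self.data.columns:
                raise ValueError(f"attribute {a.name!r}: column {a.base!r} missing")
            col = self.data[a.base]
            bad = [v for v in col if not a.admits(v)]
            if bad:
                raise ValueError(
                    f"value outside declared domain for attribute {a.name!r}: {bad[:5]}"
                )

    # -- derived tables ----------------------------------------------------

    def replace(self, validate: bool = True, **kwargs) -> "DecisionTable":
        args = dict(
            data=self.data,
            attributes=self.attributes,
            decision=self.decision,
            decision_name=self.decision_name,
            metadata=self.metadata,
        )
        args.update(kwargs)
        return DecisionTable(**args, validate=validate)

    def subset(self, index) -> "DecisionTable":
        """Row subset by positional indices (bootstrap / CV folds).

        Duplicated positions (bootstrap with replacement) get fresh
        object identifiers so the table stays valid.
        """
        idx = np.asarray(index)
        data = self.data.iloc[idx].reset_index(drop=True)
        data.index = pd.RangeIndex(1, len(idx) + 1)
        decision = self.decision.iloc[idx].reset_index(drop=True)
        decision.index = data.index
        meta = None
        if self.metadata is not None:
            meta = self.metadata.iloc[idx].reset_index(drop=True)
            meta.index = data.index
        # rows of a validated table stay valid
        return self.replace(data=data, decision=decision, metadata=meta, validate=False)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out[self.decision_name] = self.decision
        out.to_csv(path, index_label="object")

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"DecisionTable({self.n_objects} objects, "
            f"{len(self.attributes)} condition attributes, "
            f"decision={self.decision_name!r})"
        )


# -- loading ---------------------------------------------------------------


def load_table(
    path,
    schema: Sequence[Attribute],
    decision: str,
    id_column: str | None = None,
) -> DecisionTable:
    """Read a decision table from CSV and validate it against a schema.

    The CSV must have a header row naming every schema attribute plus the
    decision column.  Unknown columns are rejected.  Row order is
    preserved; object identifiers default to 1-based row numbers unless
    ``id_column`` names an identifier column (a column literally named
    ``object``, as written by :meth:`DecisionTable.to_csv`, is picked up
    automatically).
    """
    df = pd.read_csv(path)
    if id_column is None and "object" in df.columns:
        id_column = "object"
    if len(df) == 0:
        raise ValueError("no objects: the CSV has no data rows")
    if decision not in df.columns:
        raise ValueError(f"missing decision column {decision!r}")
    known = {a.name for a in schema} | {decision}
    if id_column is not None:
        known.add(id_column)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ValueError(f"unknown columns {unknown}; declare them in the schema")
    absent = [a.name for a in schema if a.name not in df.columns]
    if absent:
        raise ValueError(f"schema attributes missing from CSV: {absent}")

    if id_column is not None:
        if df[id_column].duplicated().any():
            raise ValueError("duplicate object identifiers in id column")
        df = df.set_index(id_column)
    else:
        df.index = pd.RangeIndex(1, len(df) + 1)

    dec = pd.to_numeric(df[decision], errors="coerce")
    if dec.isna().any():
        raise ValueError(f"non-numeric value in decision column {decision!r}")
    data = df[[a.name for a in schema]]
    return DecisionTable(data, schema, dec, decision_name=decision)


def schema_from_yaml(path_or_stream) -> tuple[list[Attribute], str]:
    """Load ``(attributes, decision_name)`` from a YAML schema file.

    Expected layout::

        decision: f_2
        attributes:
          - {name: Coating, kind: nominal, values: [1, 2, 3]}
          - {name: "Tablet mass (mg)", kind: numeric, bounds: [516.0, 568.0]}
    """
    if hasattr(path_or_stream, "read"):
        spec = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            spec = yaml.safe_load(fh)
    attrs = []
    for entry in spec["attributes"]:
        attrs.append(
            Attribute(
                name=entry["name"],
                kind=entry.get("kind", NUMERIC),
                preference=entry.get("preference", NONE),
                values=frozenset(entry["values"]) if "values" in entry else None,
                bounds=tuple(entry["bounds"]) if "bounds" in entry else None,
            )
        )
    return attrs, spec["decision"]


def read_isf(path_or_stream) -> DecisionTable:
    """Read a jMAF/jRS-style ISF file (attribute-declaration header dialect).

    Supports the common subset: ``**ATTRIBUTES`` with ``+ name: (continuous)``
    or ``+ name: [v1, v2, ...]`` lines and a ``decision:`` pointer,
    ``**PREFERENCES`` with ``name: gain|cost|none``, and whitespace-separated
    ``**EXAMPLES`` rows.
    """
    if hasattr(path_or_stream, "read"):
        text = path_or_stream.read()
    else:
        with open(path_or_stream) as fh:
            text = fh.read()

    section = None
    names: list[str] = []
    kinds: dict[str, str] = {}
    domains: dict[str, frozenset] = {}
    prefs: dict[str, str] = {}
    decision_name = None
    rows: list[list[float]] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line.upper().startswith("**"):
            section = line[2:].strip().upper()
            continue
        if section == "ATTRIBUTES":
            if line.startswith("+"):
                m = re.match(r"\+\s*([^:]+):\s*(.+)", line)
                if not m:
                    raise ValueError(f"malformed attribute line: {line!r}")
                name, dom = m.group(1).strip(), m.group(2).strip()
                names.append(name)
                if dom.startswith("("):
                    kinds[name] = NUMERIC
                elif dom.startswith("["):
                    vals = [v.strip() for v in dom.strip("[]").split(",")]
                    try:
                        parsed = frozenset(float(v) for v in vals)
                    except ValueError:
                        parsed = frozenset(vals)
                    kinds[name] = NOMINAL
                    domains[name] = parsed
                else:
                    raise ValueError(f"unsupported domain {dom!r}")
            elif line.lower().startswith("decision"):
                decision_name = line.split(":", 1)[1].strip()
        elif section == "PREFERENCES":
            name, pref = (s.strip() for s in line.split(":", 1))
            prefs[name] = pref
        elif section == "EXAMPLES":
            rows.append(line.split())
        elif section == "END":
            break
    if decision_name is None:
        raise ValueError("missing decision column: no 'decision:' line in ISF header")
    if not rows:
        raise ValueError("no objects: ISF file has no examples")
    df = pd.DataFrame(rows, columns=names)
    for c in df.columns:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError):
            pass
    csv = io.StringIO()
    df.to_csv(csv, index=False)
    csv.seek(0)
    schema = [
        Attribute(
            name=n,
            kind=kinds.get(n, NUMERIC),
            preference={"gain": GAIN, "cost": COST}.get(prefs.get(n, ""), NONE),
            values=domains.get(n),
        )
        for n in names
        if n != decision_name
    ]
    return load_table(csv, schema, decision=decision_name)


# -- transformations -------------------------------------------------------


def binarize_nominal(table: DecisionTable, attribute: str) -> DecisionTable:
    """Replace one nominal attribute by one 0/1 attribute per domain value.

    New columns are named ``<attribute>_<value>`` (so coating value 1,
    Eudragit NE, becomes ``<attribute>_1``); exactly one of them is 1 for
    every object.  The original attribute is removed.
    """
    attr = table.attribute(attribute)
    if attr.kind != NOMINAL:
        raise ValueError(f"attribute {attribute!r} is not nominal")
    values = sorted(attr.values) if attr.values is not None else sorted(
        pd.unique(table.data[attr.base])
    )
    data = table.data.copy()
    new_attrs: list[Attribute] = []
    for a in table.attributes:
        if a.name != attribute:
            new_attrs.append(a)
            continue
        for v in values:
            label = f"{attribute}_{v:g}" if isinstance(v, (int, float)) else f"{attribute}_{v}"
            data[label] = (data[attr.base] == v).astype(int)
            new_attrs.append(
                Attribute(name=label, kind=NUMERIC, preference=NONE,
                          values=frozenset({0, 1}))
            )
    data = data.drop(columns=[attr.base])
    return table.replace(data=data, attributes=new_attrs)


def binarize_all_nominal(table: DecisionTable) -> DecisionTable:
    for a in list(table.attributes):
        if a.kind == NOMINAL:
            table = binarize_nominal(table, a.name)
    return table


def reconstruct_nominal(table: DecisionTable, attribute: str, values: Iterable):
    """Inverse of :func:`binarize_nominal` (argmax over the binary columns)."""
    cols = {}
    for v in values:
        label = f"{attribute}_{v:g}" if isinstance(v, (int, float)) else f"{attribute}_{v}"
        cols[v] = table.data[label]
    frame = pd.DataFrame(cols)
    return frame.idxmax(axis=1)


def clone_gain_cost(table: DecisionTable) -> DecisionTable:
    """Two-copy transformation for attributes of unknown preference.

    Every numeric condition attribute with ``preference="none"`` is
    declared twice: a ``_gain`` copy (rules may use >= / > on it) and a
    ``_cost`` copy (<= / <).  Both copies point at the same value column,
    so the object x value grid is untouched; the transformation only
    widens the attribute declarations and cannot bias which monotone
    relationships are discoverable.  Attributes already declared gain or
    cost are kept as single copies.  Nominal attributes must be binarized
    first.
    """
    new_attrs: list[Attribute] = []
    for a in table.attributes:
        if a.preference in (GAIN, COST):
            new_attrs.append(a)
        elif a.kind == NOMINAL:
            raise ValueError(
                f"nominal attribute {a.name!r} must be binarized before cloning"
            )
        else:
            new_attrs.append(replace(a, name=f"{a.name}_gain", preference=GAIN, base=a.base))
            new_attrs.append(replace(a, name=f"{a.name}_cost", preference=COST, base=a.base))
    return table.replace(attributes=new_attrs)


def discretize_decision(
    table: DecisionTable,
    f2_column: str | None = None,
    threshold: float = F2_THRESHOLD,
) -> DecisionTable:
    """Turn a numeric f2 decision into the two ordinal classes.

    Class 1 (release profile preserved) where f2 >= ``threshold``, class 2
    otherwise; the cut is a sharp >= with no tolerance band.  The raw f2
    values are retained in ``table.metadata`` and excluded from the
    condition attributes.
    """
    if f2_column is None or f2_column == table.decision_name:
        f2 = pd.to_numeric(table.decision, errors="coerce")
        name = table.decision_name
        data = table.data
        attrs = table.attributes
    else:
        attr = table.attribute(f2_column)
        f2 = pd.to_numeric(table.data[attr.base], errors="coerce")
        name = f2_column
        data = table.data.drop(columns=[attr.base])
        attrs = [a for a in table.attributes if a.name != f2_column]
    if f2.isna().any():
        raise ValueError(f"non-numeric f2 value in column {name!r}")
    labels = pd.Series(
        np.where(f2 >= threshold, CLASS_SIMILAR, CLASS_DIFFERENT),
        index=data.index,
        dtype=int,
    )
    meta = pd.DataFrame({name: f2}, index=data.index)
    if table.metadata is not None:
        meta = pd.concat([table.metadata, meta], axis=1)
    return DecisionTable(
        data, attrs, labels, decision_name="class", metadata=meta
    )
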