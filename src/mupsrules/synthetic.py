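"""Synthetic formulation tables and dissolution profiles with known truth.

The generator emulates the structure of the tableting study: ~180
formulations described by coating type, tablet press, compression force,
tablet mass/hardness/crushing strength/friability and a one-hot filler
pattern, with the ordinal class generated by planted monotone rules and a
tunable fraction of flipped labels standing in for the dominance
inconsistencies real process data exhibit.  Ground-truth labels are
returned separately so recovery can be measured at every pipeline stage.

What it does *not* emulate: real compaction physics (attributes are drawn
independently and uniformly within their domains, so the hardness/force
correlation of real tablets is absent) and dissolution kinetics beyond a
saturating release curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dissolution import DissolutionProfile
from .information_system import (
    COST,
    GAIN,
    NOMINAL,
    NONE,
    NUMERIC,
    Attribute,
    DecisionTable,
)

#: Fillers used at a single one-hot level (name -> level %).
FILLER_LEVELS = {
    "Mannitol": 34.3,
    "Tablettose_80": 34.3,
    "Ludipress_LCE": 34.3,
    "Arbocel_P290": 47.0,
    "Sorbitol": 34.3,
    "Povidone_K30": 34.3,
    "StarLac": 34.3,
    "Starch_1500": 43.8,
    "CaHPO4xH2O": 34.3,
    "CaHPO4": 34.3,
    "Vivapur_200": 34.3,
    "Avicel_CE015": 34.3,
    "Macrogol_6000": 34.3,
}

#: Default planted class-1 rules (any firing rule => true class 1):
#: an elastic Eudragit NE coating pressed above the lowest force into a
#: sufficiently hard tablet, or a non-brittle coating with a very robust
#: tablet body.
DEFAULT_PLANTED_RULES = [
    [("Coating", "==", 1), ("Compression_force", ">=", 12), ("Hardness", ">=", 42.4)],
    [("Coating", "!=", 2), ("Crushing_strength", ">=", 180.8)],
]


@dataclass
class GeneratorConfig:
    """Study-shaped generator settings.

    Defaults reproduce the study conditions: 180 formulations, attribute
    domains as in the published attribute table, and a 10% label-flip
    (inconsistency) rate representing the partial inconsistency of real
    process data.
    """

    n_objects: int = 180
    inconsistency: float = 0.10
    seed: int = 0
    force_levels: tuple = (6, 12, 18)
    mass_range: tuple = (516.0, 568.0)
    hardness_range: tuple = (11.0, 297.0)
    crushing_range: tuple = (11.0, 619.0)
    friability_range: tuple = (0.0, 10.1)
    kollidon_presence: float = 0.8
    avicel_probs: tuple = (0.55, 0.15, 0.20, 0.10)  # 102@12.7, 102@47, 101@12.7, none
    planted_rules: list = field(default_factory=lambda: [list(r) for r in DEFAULT_PLANTED_RULES])
    declare_preferences: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.inconsistency < 0.5:
            raise ValueError("inconsistency rate must lie in [0, 0.5)")
        if self.n_objects < 1:
            raise ValueError("n_objects must be positive")


def _schema(config: GeneratorConfig) -> list[Attribute]:
    pref = (
        {
            "Tablet_press": COST,
            "Compression_force": GAIN,
            "Tablet_mass": COST,
            "Hardness": GAIN,
            "Crushing_strength": GAIN,
            "Friability": COST,
            "Avicel_102": GAIN,
            "Avicel_101": COST,
        }
        if config.declare_preferences
        else {}
    )
    attrs = [
        Attribute("Coating", kind=NOMINAL, values=frozenset({1, 2, 3})),
        Attribute("Tablet_press", kind=NUMERIC, values=frozenset({1, 2}),
                  preference=pref.get("Tablet_press", NONE)),
        Attribute("Compression_force", kind=NUMERIC,
                  values=frozenset(config.force_levels),
                  preference=pref.get("Compression_force", NONE)),
        Attribute("Tablet_mass", kind=NUMERIC, bounds=config.mass_range,
                  preference=pref.get("Tablet_mass", NONE)),
        Attribute("Hardness", kind=NUMERIC, bounds=config.hardness_range,
                  preference=pref.get("Hardness", NONE)),
        Attribute("Crushing_strength", kind=NUMERIC, bounds=config.crushing_range,
                  preference=pref.get("Crushing_strength", NONE)),
        Attribute("Friability", kind=NUMERIC, bounds=config.friability_range,
                  preference=pref.get("Friability", NONE)),
        Attribute("Avicel_102", kind=NUMERIC, values=frozenset({0.0, 12.7, 47.0}),
                  preference=pref.get("Avicel_102", NONE)),
        Attribute("Avicel_101", kind=NUMERIC, values=frozenset({0.0, 12.7}),
                  preference=pref.get("Avicel_101", NONE)),
    ]
    for name, level in FILLER_LEVELS.items():
        attrs.append(Attribute(name, kind=NUMERIC, values=frozenset({0.0, level})))
    attrs.append(Attribute("Kollidon_CL", kind=NUMERIC, values=frozenset({0.0, 9.5})))
    return attrs


def _apply_planted(rules, data: pd.DataFrame) -> np.ndarray:
    """True class labels: 1 iff any planted class-1 rule fires."""
    fired = np.zeros(len(data), dtype=bool)
    for rule in rules:
        mask = np.ones(len(data), dtype=bool)
        for attr, op, value in rule:
            if attr not in data.columns:
                raise ValueError(f"planted rule references undeclared attribute {attr!r}")
            col = data[attr].to_numpy()
            if op == ">=":
                mask &= col >= value
            elif op == "<=":
                mask &= col <= value
            elif op == "==":
                mask &= col == value
            elif op == "!=":
                mask &= col != value
            else:
                raise ValueError(f"planted rules must be monotone; got op {op!r}")
        fired |= mask
    return np.where(fired, 1, 2)


def generate_table(config: GeneratorConfig) -> tuple[DecisionTable, pd.Series]:
    """Draw a formulation table; returns ``(table, ground_truth)``.

    The table's decision holds the observed (possibly flipped) class; the
    second element is the noise-free ground truth.  Exactly
    ``round(inconsistency * n_objects)`` labels are flipped, split as
    evenly as the class sizes allow between the two classes.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_objects
    data = pd.DataFrame(index=pd.RangeIndex(1, n + 1))
    data["Coating"] = rng.integers(1, 4, size=n)
    data["Tablet_press"] = rng.integers(1, 3, size=n)
    data["Compression_force"] = rng.choice(config.force_levels, size=n)
    data["Tablet_mass"] = np.round(rng.uniform(*config.mass_range, size=n), 0)
    data["Hardness"] = np.round(rng.uniform(*config.hardness_range, size=n), 0)
    data["Crushing_strength"] = np.round(rng.uniform(*config.crushing_range, size=n), 0)
    data["Friability"] = np.round(rng.uniform(*config.friability_range, size=n), 2)

    # Avicel grades: mutually exclusive draws mimicking the one-hot pattern
    avicel = rng.choice(4, size=n, p=config.avicel_probs)
    data["Avicel_102"] = np.select([avicel == 0, avicel == 1], [12.7, 47.0], 0.0)
    data["Avicel_101"] = np.where(avicel == 2, 12.7, 0.0)
    # exactly one filler per formulation
    fillers = list(FILLER_LEVELS)
    choice = rng.integers(0, len(fillers), size=n)
    for j, name in enumerate(fillers):
        data[name] = np.where(choice == j, FILLER_LEVELS[name], 0.0)
    data["Kollidon_CL"] = np.where(
        rng.random(n) < config.kollidon_presence, 9.5, 0.0
    )

    truth = _apply_planted(config.planted_rules, data)
    observed = truth.copy()
    n_flip = round(config.inconsistency * n)
    if n_flip:
        ones = np.flatnonzero(truth == 1)
        twos = np.flatnonzero(truth == 2)
        want1 = min(n_flip // 2, len(ones))
        want2 = min(n_flip - want1, len(twos))
        short = n_flip - want1 - want2
        want1 = min(want1 + short, len(ones))
        picks = np.concatenate(
            [
                rng.choice(ones, size=want1, replace=False),
                rng.choice(twos, size=want2, replace=False),
            ]
        )
        observed[picks] = 3 - observed[picks]

    table = DecisionTable(
        data,
        _schema(config),
        pd.Series(observed, index=data.index, dtype=int),
        decision_name="class",
    )
    return table, pd.Series(truth, index=data.index, name="true_class")


# -- dissolution profiles --------------------------------------------------


def offset_for_f2(target: float) -> float:
    """Constant per-point |R-T| offset giving exactly the target f2."""
    if not 0.0 < target <= 100.0:
        raise ValueError("f2 targets must lie in (0, 100]")
    return float(np.sqrt((100.0 / 10 ** (target / 50.0)) ** 2 - 1.0))


def generate_profiles(
    f2_targets, n_points: int = 6, seed: int = 0, jitter: float = 0.2
) -> list[tuple[DissolutionProfile, DissolutionProfile]]:
    """Reference/test profile pairs hitting each target f2.

    The reference is a saturating release curve over hourly sampling
    points 1..n; the test profile subtracts per-point offsets whose mean
    square is renormalized to the exact value solving the f2 equation, so
    the realized f2 matches each target to machine precision (well within
    the 0.5 construction tolerance).  Targets so low that the required
    offset cannot fit between 0 and 100% dissolved raise ``ValueError``.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(1.0, n_points + 1.0)
    out = []
    for target in f2_targets:
        d = offset_for_f2(target)
        lo = max(25.0, (1.0 + jitter) / max(1.0 - jitter, 1e-9) * d + 2.0)
        if lo > 99.0 - 1.0:
            raise ValueError(f"f2 target {target} unreachable within 0-100% dissolved")
        hi = min(99.0, lo + 60.0)
        k = rng.uniform(0.35, 0.6)
        shape = (1.0 - np.exp(-k * times)) / (1.0 - np.exp(-k * times[-1]))
        ref = lo + (hi - lo) * shape
        if d == 0.0:
            out.append((DissolutionProfile(times, ref), DissolutionProfile(times, ref.copy())))
            continue
        w = 1.0 + jitter * rng.uniform(-1.0, 1.0, size=n_points)
        w /= np.sqrt(np.mean(w**2))  # mean squared offset == d**2 exactly
        test = ref - d * w
        out.append((DissolutionProfile(times, ref), DissolutionProfile(times, test)))
    return out
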