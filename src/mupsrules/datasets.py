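"""Bundled study data: schema, reprinted excerpt and published rule tables.

The underlying study tableted verapamil-hydrochloride pellets into MUPS
under varying coating polymer (1 = Eudragit NE, 2 = ethyl cellulose,
3 = shellac), tablet press (1 = single punch, 2 = rotary), compression
force (6/12/18 kN) and tablet-mass composition, and classified each of 180
formulations by whether the dissolution profile survived compression
(f2 >= 50, class 1) or not (class 2).  Only a 20-formulation excerpt of
the full 180-row information system is publicly printed; it is bundled
here verbatim, together with the two published tables of the 20 strongest
decision rules per class (with their reported support, strength and
confirmation values), which serve as reference inputs for consistency
checks and worked examples.
"""

from __future__ import annotations

import io

import pandas as pd

from .information_system import (
    NOMINAL,
    NUMERIC,
    Attribute,
    DecisionTable,
    load_table,
)

#: One-hot excipient levels (%, of tablet mass) as used in the study design.
EXCIPIENT_LEVELS = {
    "Avicel_102": (0.0, 12.7, 47.0),
    "Avicel_101": (0.0, 12.7),
    "Mannitol": (0.0, 34.3),
    "Tablettose_80": (0.0, 34.3),
    "Ludipress_LCE": (0.0, 34.3),
    "Arbocel_P290": (0.0, 47.0),
    "Sorbitol": (0.0, 34.3),
    "Povidone_K30": (0.0, 34.3),
    "StarLac": (0.0, 34.3),
    "Starch_1500": (0.0, 43.8),
    "CaHPO4xH2O": (0.0, 34.3),
    "CaHPO4": (0.0, 34.3),
    "Vivapur_200": (0.0, 34.3),
    "Avicel_CE015": (0.0, 34.3),
    "Macrogol_6000": (0.0, 34.3),
    "Kollidon_CL": (0.0, 9.5),
}


def study_schema() -> tuple[list[Attribute], str]:
    """Attribute declarations mirroring the study's condition-attribute
    domains; decision column is the raw f2 value."""
    attrs = [
        Attribute("Coating", kind=NOMINAL, values=frozenset({1, 2, 3})),
        Attribute("Tablet_press", kind=NUMERIC, values=frozenset({1, 2})),
        Attribute("Compression_force", kind=NUMERIC, values=frozenset({6, 12, 18})),
        Attribute("Tablet_mass", kind=NUMERIC, bounds=(516.0, 568.0)),
        Attribute("Hardness", kind=NUMERIC, bounds=(11.0, 297.0)),
        Attribute("Crushing_strength", kind=NUMERIC, bounds=(11.0, 619.0)),
        Attribute("Friability", kind=NUMERIC, bounds=(0.0, 10.1)),
    ]
    for name, levels in EXCIPIENT_LEVELS.items():
        attrs.append(Attribute(name, kind=NUMERIC, values=frozenset(levels)))
    return attrs, "f2"


_EXCERPT_CSV = """\
Coating,Tablet_press,Compression_force,Tablet_mass,Hardness,Crushing_strength,Friability,Avicel_102,Avicel_101,Mannitol,Tablettose_80,Ludipress_LCE,Arbocel_P290,Sorbitol,Povidone_K30,StarLac,Starch_1500,CaHPO4xH2O,CaHPO4,Vivapur_200,Avicel_CE015,Macrogol_6000,Kollidon_CL,f2
1,1,6,559,63,92,2.30,12.7,0,34.3,0,0,0,0,0,0,0,0,0,0,0,0,9.5,59.4
1,1,6,548,66,96,3.10,0,12.7,34.3,0,0,0,0,0,0,0,0,0,0,0,0,9.5,56.3
1,1,6,557,111,163,4.20,0,12.7,0,0,0,0,0,0,0,0,0,0,0,34.3,0,9.5,35.7
1,1,6,558,96,140,0.50,47,0,0,0,0,0,0,0,0,0,0,0,0,0,0,9.5,37.5
1,1,6,562,41,58,0.00,12.7,0,0,34.3,0,0,0,0,0,0,0,0,0,0,0,9.5,38.7
1,1,6,557,45,67,2.40,12.7,0,0,0,34.3,0,0,0,0,0,0,0,0,0,0,9.5,35.9
1,1,6,562,105,153,0.60,0,0,0,0,0,47,0,0,0,0,0,0,0,0,0,9.5,40.9
1,1,6,559,76,111,0.40,12.7,0,0,0,0,0,34.3,0,0,0,0,0,0,0,0,9.5,59.4
1,1,6,555,55,80,0.70,12.7,0,0,0,0,0,0,34.3,0,0,0,0,0,0,0,9.5,56.3
1,1,6,565,36,52,2.30,12.7,0,0,0,0,0,0,0,34.3,0,0,0,0,0,0,9.5,35.7
1,1,6,566,26,38,3.40,12.7,0,0,0,0,0,0,0,0,43.8,0,0,0,0,0,0,37.5
1,1,6,559,40,58,1.20,12.7,0,0,0,0,0,0,0,0,0,34.3,0,0,0,0,9.5,38.7
1,1,6,560,39,57,0.90,12.7,0,0,0,0,0,0,0,0,0,0,34.3,0,0,0,9.5,35.9
1,1,6,562,40,59,0.70,12.7,0,0,0,0,0,0,0,0,0,0,0,34.3,0,0,9.5,40.9
1,1,6,550,40,58,0.40,12.7,0,0,0,0,0,0,0,0,0,0,0,0,34.3,0,9.5,59.4
1,1,6,555,40,58,0.60,12.7,0,0,0,0,0,0,0,0,0,0,0,0,0,34.3,9.5,55.9
1,1,12,549,91,134,1.10,12.7,0,34.3,0,0,0,0,0,0,0,0,0,0,0,0,9.5,50.7
1,1,12,545,79,115,0.90,0,12.7,34.3,0,0,0,0,0,0,0,0,0,0,0,0,9.5,63.5
1,1,12,554,248,363,0.90,0,12.7,0,0,0,0,0,0,0,0,0,0,0,34.3,0,9.5,48.3
1,1,12,566,229,335,0.40,47,0,0,0,0,0,0,0,0,0,0,0,0,0,0,9.5,58.7
"""


def load_study_excerpt() -> DecisionTable:
    """The 20 printed formulations as a raw decision table (f2 decision).

    Object identifiers are the 1-based formulation numbers of the printed
    excerpt.  Note this is an excerpt: quantities published for the full
    180-formulation system (rule supports, CV accuracy) are not
    recomputable from these rows alone.
    """
    attrs, decision = study_schema()
    return load_table(io.StringIO(_EXCERPT_CSV), attrs, decision=decision)


#: Study size: number of formulations in the full information system.
STUDY_N_FORMULATIONS = 180

# Published strongest-rule tables.  Conditions are (attribute, op, value)
# on the binarized representation (Coating_1 = Eudragit NE, Coating_2 =
# ethyl cellulose, Coating_3 = shellac); support / strength / confirmation
# are the published values on the full 180-formulation system.
PRINTED_RULES_CLASS1 = [
    {"conditions": [("Coating_2", "==", 0), ("Tablet_mass", "<=", 553.1),
                    ("Crushing_strength", ">=", 68.8), ("Avicel_102", ">=", 12.7)],
     "support": 32, "strength": 0.1777, "confirmation": 0.75},
    {"conditions": [("Coating_1", "==", 1), ("Compression_force", ">", 6),
                    ("Tablet_mass", "<=", 563.3), ("Hardness", ">=", 42.4),
                    ("Avicel_101", "==", 0)],
     "support": 46, "strength": 0.2555, "confirmation": 0.75},
    {"conditions": [("Coating_1", "==", 1), ("Compression_force", ">", 6),
                    ("Hardness", ">=", 49.2), ("Vivapur_200", "==", 0),
                    ("Avicel_101", "==", 0), ("Povidone_K30", "==", 0)],
     "support": 43, "strength": 0.2388, "confirmation": 0.73},
    {"conditions": [("Coating_1", "==", 1), ("Compression_force", ">", 6),
                    ("Hardness", ">=", 42.4), ("Povidone_K30", "==", 0),
                    ("Mannitol", "==", 0)],
     "support": 47, "strength": 0.2611, "confirmation": 0.73},
    {"conditions": [("Coating_1", "==", 1), ("Compression_force", ">", 6),
                    ("Crushing_strength", ">=", 102.5), ("Vivapur_200", "==", 0),
                    ("StarLac", "==", 0)],
     "support": 48, "strength": 0.2666, "confirmation": 0.73},
    {"conditions": [("Coating_1", "==", 1), ("Hardness", ">=", 105.8),
                    ("Avicel_101", "==", 0)],
     "support": 33, "strength": 0.1833, "confirmation": 0.72},
    {"conditions": [("Coating_1", "==", 1), ("Compression_force", ">", 6),
                    ("Hardness", ">=", 105)],
     "support": 36, "strength": 0.2000, "confirmation": 0.72},
    {"conditions": [("Hardness", ">", 111.9), ("Crushing_strength", ">", 163.6)],
     "support": 36, "strength": 0.2000, "confirmation": 0.72},
    {"conditions": [("Coating_2", "==", 0), ("Crushing_strength", ">=", 180.8)],
     "support": 39, "strength": 0.2166, "confirmation": 0.72},
    {"conditions": [("Coating_2", "==", 0), ("Hardness", ">=", 107)],
     "support": 41, "strength": 0.2277, "confirmation": 0.72},
    {"conditions": [("Coating_1", "==", 1), ("Tablet_mass", "<=", 556.4),
                    ("Friability", "<=", 1.6)],
     "support": 50, "strength": 0.2777, "confirmation": 0.72},
    {"conditions": [("Coating_1", "==", 1), ("Tablet_mass", "<=", 554.1),
                    ("Friability", "<=", 1.1)],
     "support": 34, "strength": 0.1888, "confirmation": 0.70},
    {"conditions": [("Coating_1", "==", 1), ("Tablet_press", "==", 2),
                    ("Hardness", ">=", 49.2)],
     "support": 37, "strength": 0.2055, "confirmation": 0.70},
    {"conditions": [("Coating_1", "==", 1), ("Compression_force", ">", 6),
                    ("Tablet_mass", "<=", 561.5), ("Hardness", ">=", 49.2),
                    ("Vivapur_200", "==", 0), ("Avicel_101", "==", 0)],
     "support": 41, "strength": 0.2277, "confirmation": 0.70},
    {"conditions": [("Coating_1", "==", 1), ("Compression_force", ">", 6),
                    ("Hardness", ">", 42.4), ("Povidone_K30", "==", 0)],
     "support": 53, "strength": 0.2944, "confirmation": 0.70},
    {"conditions": [("Hardness", ">=", 148.9), ("Vivapur_200", "==", 0)],
     "support": 21, "strength": 0.1166, "confirmation": 0.69},
    {"conditions": [("Coating_1", "==", 1), ("Tablet_mass", "<=", 554.1),
                    ("Avicel_102", ">=", 12.7)],
     "support": 32, "strength": 0.1777, "confirmation": 0.69},
    {"conditions": [("Coating_1", "==", 1), ("Compression_force", ">", 6),
                    ("Vivapur_200", "==", 0), ("Avicel_101", "==", 0),
                    ("Povidone_K30", "==", 0), ("StarLac", "==", 0)],
     "support": 43, "strength": 0.2388, "confirmation": 0.69},
    {"conditions": [("Coating_1", "==", 1), ("Compression_force", ">", 6),
                    ("Hardness", ">=", 49.2), ("Vivapur_200", "==", 0),
                    ("StarLac", "==", 0), ("Mannitol", "==", 0)],
     "support": 43, "strength": 0.2388, "confirmation": 0.69},
    {"conditions": [("Coating_2", "==", 0), ("Crushing_strength", ">=", 163.6)],
     "support": 47, "strength": 0.2611, "confirmation": 0.69},
]

PRINTED_RULES_CLASS2 = [
    {"conditions": [("Tablet_press", "==", 2), ("Crushing_strength", "<=", 97.8)],
     "support": 30, "strength": 0.1666, "confirmation": 0.70},
    {"conditions": [("Coating_1", "==", 0), ("Compression_force", "<", 18),
                    ("Crushing_strength", "<=", 158.3)],
     "support": 48, "strength": 0.2666, "confirmation": 0.70},
    {"conditions": [("Coating_1", "==", 0), ("Compression_force", "<", 18),
                    ("Tablettose_80", "==", 0)],
     "support": 42, "strength": 0.2333, "confirmation": 0.70},
    {"conditions": [("Coating_1", "==", 0), ("Compression_force", "<", 18),
                    ("Crushing_strength", "<=", 133.1)],
     "support": 43, "strength": 0.2388, "confirmation": 0.70},
    {"conditions": [("Coating_1", "==", 0), ("Tablet_press", "==", 2),
                    ("Arbocel_P290", "==", 0)],
     "support": 31, "strength": 0.1722, "confirmation": 0.70},
    {"conditions": [("Crushing_strength", "<=", 68.1), ("Kollidon_CL", ">=", 9.5)],
     "support": 37, "strength": 0.2055, "confirmation": 0.69},
    {"conditions": [("Coating_1", "==", 0), ("Compression_force", "<", 18),
                    ("Avicel_CE015", "==", 0)],
     "support": 42, "strength": 0.2333, "confirmation": 0.67},
    {"conditions": [("Compression_force", "==", 6), ("Crushing_strength", "<=", 72)],
     "support": 31, "strength": 0.1722, "confirmation": 0.67},
    {"conditions": [("Coating_1", "==", 0), ("Compression_force", "==", 12)],
     "support": 23, "strength": 0.1277, "confirmation": 0.67},
    {"conditions": [("Tablet_press", "==", 2), ("Hardness", "<=", 48.8)],
     "support": 23, "strength": 0.1277, "confirmation": 0.67},
    {"conditions": [("Tablet_press", "==", 2), ("Hardness", "<=", 60.1)],
     "support": 31, "strength": 0.1722, "confirmation": 0.67},
    {"conditions": [("Coating_1", "==", 0), ("Compression_force", "<", 18),
                    ("Tablet_mass", "<", 558)],
     "support": 41, "strength": 0.2277, "confirmation": 0.66},
    {"conditions": [("Coating_1", "==", 0), ("Tablet_press", "==", 2),
                    ("Hardness", "<=", 84.5)],
     "support": 30, "strength": 0.1666, "confirmation": 0.66},
    {"conditions": [("Coating_1", "==", 0), ("Compression_force", "<", 18),
                    ("Crushing_strength", "<=", 90.9)],
     "support": 37, "strength": 0.2055, "confirmation": 0.66},
    {"conditions": [("Compression_force", "<", 18), ("Crushing_strength", "<=", 67.3)],
     "support": 35, "strength": 0.1944, "confirmation": 0.66},
    {"conditions": [("Coating_2", "==", 1)],
     "support": 42, "strength": 0.2333, "confirmation": 0.65},
    {"conditions": [("Coating_1", "==", 0), ("Tablet_press", "==", 2),
                    ("Crushing_strength", "<=", 158.3)],
     "support": 36, "strength": 0.2000, "confirmation": 0.65},
    {"conditions": [("Coating_1", "==", 0), ("Tablet_press", "==", 2),
                    ("Crushing_strength", "<=", 138)],
     "support": 33, "strength": 0.1833, "confirmation": 0.65},
    {"conditions": [("Compression_force", "<", 18), ("Crushing_strength", "<=", 68.1)],
     "support": 36, "strength": 0.2000, "confirmation": 0.65},
    {"conditions": [("Coating_1", "==", 0), ("Tablet_press", "==", 2),
                    ("Crushing_strength", "<=", 148.5)],
     "support": 34, "strength": 0.1888, "confirmation": 0.65},
]

#: Published repeated-CV outcome of the VC-bagged rule classifier on the
#: full 180-formulation system (average over 100 repeats of 5-fold CV).
PUBLISHED_CV = {
    "correctly_classified_avg": 148.91,
    "incorrectly_classified_avg": 31.09,
    "accuracy_pct": 82.72,
    "precision_pct": 82.75,
}


def premise_mask(conditions, data: pd.DataFrame):
    """Boolean mask of objects satisfying a printed-rule premise."""
    import numpy as np

    from .rules import ElementaryCondition

    mask = np.ones(len(data), dtype=bool)
    for attr, op, value in conditions:
        mask &= np.asarray(ElementaryCondition(attr, op, value).evaluate(data[attr]))
    return mask
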