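"""Dissolution-profile similarity (f2) and tablet mechanics.

The f2 similarity factor compares the percentage of drug dissolved from a
reference and a test formulation at the same sampling times::

    f2 = 50 * log10( 100 / sqrt(1 + mean_t (R(t) - T(t))^2) )

Identical profiles give f2 = 100; a root-mean-square difference of
sqrt(99) percentage points gives exactly 50, the conventional similarity
threshold.  Values below 0 are possible for very different profiles and
are reported as-is.

By default every paired sampling point enters the mean (the study design
here samples both profiles at the same six hourly points); the EMA
convention of truncating the profile after the first point above 85%
dissolved is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .information_system import CLASS_DIFFERENT, CLASS_SIMILAR, F2_THRESHOLD


@dataclass(frozen=True)
class DissolutionProfile:
    """Cumulative % of label claim dissolved at ordered sampling times (h)."""

    times: np.ndarray
    dissolved: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.dissolved, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "dissolved", d)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("profile needs at least one sampling point")
        if t.size != d.size:
            raise ValueError("times and dissolved must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if np.any(d < 0) or np.any(d > 110):
            raise ValueError("dissolved values must lie in [0, 110] % of label claim")

    @property
    def n(self) -> int:
        return int(self.times.size)


def similarity_factor_f2(
    reference: DissolutionProfile,
    test: DissolutionProfile,
    truncate_at_85: bool = False,
) -> float:
    """f2 similarity factor between two profiles sampled at identical times.

    With ``truncate_at_85`` the comparison stops one point after the
    reference first exceeds 85% dissolved (regulatory convention); by
    default all paired points are used.
    """
    if reference.n != test.n or not np.allclose(reference.times, test.times):
        raise ValueError("profiles must share identical sampling times")
    r = reference.dissolved
    t = test.dissolved
    if truncate_at_85:
        above = np.nonzero(r > 85.0)[0]
        if above.size:
            stop = min(above[0] + 1, r.size - 1)
            r = r[: stop + 1]
            t = t[: stop + 1]
    msd = float(np.mean((r - t) ** 2))
    return 50.0 * np.log10(100.0 / np.sqrt(1.0 + msd))


def f2_class(f2: float, threshold: float = F2_THRESHOLD) -> int:
    """Ordinal class from an f2 value (class 1 iff f2 >= threshold)."""
    return CLASS_SIMILAR if f2 >= threshold else CLASS_DIFFERENT


@dataclass(frozen=True)
class TabletGeometry:
    """Crushing force (N) and tablet radius / thickness (m)."""

    crushing_force: float
    radius: float
    thickness: float

    def __post_init__(self) -> None:
        for field_name in ("crushing_force", "radius", "thickness"):
            if getattr(self, field_name) <= 0:
                raise ValueError(f"{field_name} must be strictly positive")


def crushing_strength(geometry: TabletGeometry) -> float:
    """Tablet crushing strength in 10^4 N/m^2.

    Force needed to crush the tablet divided by (radius x thickness),
    rescaled to the 10^4 N/m^2 units used for the crushing-strength
    condition attribute.
    """
    return geometry.crushing_force / (geometry.radius * geometry.thickness) / 1e4


def read_profiles(path) -> dict:
    """Read paired profiles from long-format CSV.

    Columns: ``formulation``, ``time``, ``dissolved``, ``role`` where role
    is ``reference`` (pellets before compression) or ``test`` (after).
    Returns ``{formulation: (reference, test)}``.
    """
    df = pd.read_csv(path)
    required = {"formulation", "time", "dissolved", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV missing columns {sorted(missing)}")
    out = {}
    for fid, grp in df.groupby("formulation", sort=False):
        pair = {}
        for role, sub in grp.groupby("role"):
            sub = sub.sort_values("time")
            pair[role] = DissolutionProfile(
                sub["time"].to_numpy(), sub["dissolved"].to_numpy()
            )
        if set(pair) != {"reference", "test"}:
            raise ValueError(f"formulation {fid!r} needs a reference and a test profile")
        out[fid] = (pair["reference"], pair["test"])
    return out


def f2_table(profiles: dict, threshold: float = F2_THRESHOLD) -> pd.DataFrame:
    """Per-formulation f2 and class for a dict of (reference, test) pairs."""
    rows = []
    for fid, (ref, test) in profiles.items():
        f2 = similarity_factor_f2(ref, test)
        rows.append({"formulation": fid, "f2": f2, "class": f2_class(f2, threshold)})
    return pd.DataFrame(rows)
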