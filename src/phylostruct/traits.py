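"""Leaf-trait and soil-variable formulas, plus trait aggregation.

All formulas are exact closed forms:

    SWC  = (fresh soil mass - dry soil mass) / dry soil mass
    SLA  = leaf area / leaf dry mass            [cm^2/g]
    LDMC = leaf dry mass / leaf fresh mass      [fraction]
    LWC  = (1 - LDMC) * 100                     [%]
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "soil_water_content",
    "specific_leaf_area",
    "leaf_dry_matter_content",
    "leaf_water_content",
    "aggregate_traits",
]


def soil_water_content(fresh_mass, dry_mass):
    """Gravimetric soil water content (fresh - dry) / dry."""
    fresh = np.asarray(fresh_mass, dtype=float)
    dry = np.asarray(dry_mass, dtype=float)
    if np.any(dry <= 0):
        raise ValueError("dry mass must be positive")
    if np.any(fresh < dry):
        raise ValueError("fresh mass below dry mass: weighing anomaly")
    out = (fresh - dry) / dry
    return float(out) if out.ndim == 0 else out


def specific_leaf_area(leaf_area, dry_mass):
    """Specific leaf area, area per unit dry mass (cm^2/g)."""
    area = np.asarray(leaf_area, dtype=float)
    mass = np.asarray(dry_mass, dtype=float)
    if np.any(mass <= 0):
        raise ValueError("leaf dry mass must be positive")
    if np.any(area <= 0):
        raise ValueError("leaf area must be positive")
    out = area / mass
    return float(out) if out.ndim == 0 else out


def leaf_dry_matter_content(dry_mass, fresh_mass):
    """Leaf dry matter content dry/fresh, a fraction in (0, 1]."""
    dry = np.asarray(dry_mass, dtype=float)
    fresh = np.asarray(fresh_mass, dtype=float)
    if np.any(fresh <= 0):
        raise ValueError("fresh mass must be positive")
    if np.any(dry > fresh):
        raise ValueError("dry mass exceeds fresh mass: weighing anomaly")
    out = dry / fresh
    return float(out) if out.ndim == 0 else out


def leaf_water_content(ldmc):
    """Leaf water content in percent, the complement of LDMC."""
    frac = np.asarray(ldmc, dtype=float)
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("LDMC must be a fraction in [0, 1]")
    out = (1.0 - frac) * 100.0
    return float(out) if out.ndim == 0 else out


def aggregate_traits(
    measurements: pd.DataFrame,
    by=("sample", "species"),
) -> pd.DataFrame:
    """Mean per-group trait table from long-format replicate measurements.

    ``measurements`` columns: the grouping keys, plus ``trait`` and
    ``value``. Returns a wide table (one row per group, one column per
    trait); groups without measurements are simply absent, and a warning
    reports any NaN measurements dropped.
    """
    required = set(by) | {"trait", "value"}
    if not required.issubset(measurements.columns):
        raise ValueError(f"measurement table needs columns {sorted(required)}")
    data = measurements.dropna(subset=["value"])
    if len(data) < len(measurements):
        warnings.warn(
            f"dropped {len(measurements) - len(data)} empty measurements",
            stacklevel=2,
        )
    if data.empty:
        raise ValueError("no measurements to aggregate")
    wide = data.pivot_table(
        index=list(by), columns="trait", values="value", aggfunc="mean"
    )
    wide.columns.name = None
    return wide
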