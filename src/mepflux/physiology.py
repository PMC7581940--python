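"""Drought-treatment bookkeeping: FTSW, RTR, stress staging, dry-weight basis.

Water availability in a drying pot is tracked by the fraction of
transpirable soil water, FTSW = (daily − final) / (initial − final) pot
weight; a tree's relative transpiration rate, RTR = 100 · TR / ATR, scales
its daily pot-weight loss against the mean transpiration of a well-watered
reference group.  Sampling triggers: RTR 50% = moderate stress, 20% =
severe stress, 10% = the FTSW endpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WateringSeries",
    "DryWeightFactor",
    "ftsw",
    "rtr",
    "classify_stage",
    "to_dry_weight",
    "transpiration",
    "average_transpiration",
    "staging_table",
    "STAGE_UNSTRESSED",
    "STAGE_MODERATE",
    "STAGE_SEVERE",
    "STAGE_ENDPOINT",
]

STAGE_UNSTRESSED = "unstressed"
STAGE_MODERATE = "moderate"
STAGE_SEVERE = "severe"
STAGE_ENDPOINT = "endpoint"

#: RTR (%) sampling triggers; a tree at exactly the trigger is classified
#: into the stressed stage ("<=" boundaries)
RTR_MODERATE = 50.0
RTR_SEVERE = 20.0
RTR_ENDPOINT = 10.0


@dataclass(frozen=True)
class WateringSeries:
    """Daily pot weights of one tree with the FTSW anchor weights."""

    days: np.ndarray
    daily_weights: np.ndarray
    initial_weight: float
    final_weight: float
    tree_id: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.days)
        w = np.asarray(self.daily_weights, dtype=float)
        if d.shape != w.shape or d.ndim != 1:
            raise ValueError("days and daily_weights must be 1-D and equal length")
        if not self.initial_weight > self.final_weight:
            raise ValueError("initial_weight must exceed final_weight")
        object.__setattr__(self, "days", d)
        object.__setattr__(self, "daily_weights", w)


@dataclass(frozen=True)
class DryWeightFactor:
    """Fresh-to-dry mass conversion from a weighed freeze-dried aliquot."""

    fresh_mass: float
    dry_mass: float

    def __post_init__(self) -> None:
        if self.fresh_mass <= 0 or self.dry_mass <= 0:
            raise ValueError("masses must be > 0")
        if self.dry_mass > self.fresh_mass:
            raise ValueError("dry mass cannot exceed fresh mass")

    @property
    def factor(self) -> float:
        return self.dry_mass / self.fresh_mass


def ftsw(daily_weight, initial_weight: float, final_weight: float):
    """Fraction of transpirable soil water from pot weights.

    Values marginally outside [0, 1] — possible at the 1 g weighing
    precision — are clamped with a warning.
    """
    if not initial_weight > final_weight:
        raise ValueError("initial_weight must exceed final_weight")
    w = np.asarray(daily_weight, dtype=float)
    value = (w - final_weight) / (initial_weight - final_weight)
    if np.any(value < 0) or np.any(value > 1):
        warnings.warn("FTSW outside [0, 1]; clamped (weighing precision)",
                      UserWarning, stacklevel=2)
        value = np.clip(value, 0.0, 1.0)
    return float(value) if np.ndim(value) == 0 else value


def rtr(tr, atr):
    """Relative transpiration rate, percent of the well-watered reference."""
    atr_arr = np.asarray(atr, dtype=float)
    if np.any(atr_arr <= 0):
        raise ValueError("atr must be > 0")
    value = 100.0 * np.asarray(tr, dtype=float) / atr_arr
    return float(value) if np.ndim(value) == 0 else value


def classify_stage(rtr_percent: float) -> str:
    """Stress stage from RTR (%): boundaries at 50 / 20 / 10 inclusive."""
    if rtr_percent < 0:
        raise ValueError("rtr must be >= 0")
    if rtr_percent <= RTR_ENDPOINT:
        return STAGE_ENDPOINT
    if rtr_percent <= RTR_SEVERE:
        return STAGE_SEVERE
    if rtr_percent <= RTR_MODERATE:
        return STAGE_MODERATE
    return STAGE_UNSTRESSED


def to_dry_weight(rate_per_fresh, factor: DryWeightFactor):
    """Convert a per-g-fresh-weight rate to a per-g-dry-weight basis."""
    f = factor.factor
    if f == 0:
        raise ValueError("dry-weight factor must be > 0")
    value = np.asarray(rate_per_fresh, dtype=float) / f
    return float(value) if np.ndim(value) == 0 else value


def transpiration(series: WateringSeries) -> pd.Series:
    """Daily transpiration (g water day⁻¹) as pot-weight loss per day.

    The pot is bagged, so weight loss is attributed to transpiration only.
    The first day has no previous weight and yields NaN.
    """
    w = pd.Series(series.daily_weights, index=series.days)
    return -w.diff() / pd.Series(series.days, index=series.days).diff()


def average_transpiration(
    reference: pd.DataFrame, per_day: bool = True
) -> pd.Series | float:
    """ATR of the well-watered reference group.

    ``reference`` is tidy with columns tree_id, day, weight_g.  Per-day
    mode (default) returns the across-tree mean transpiration for each
    day, linearly interpolating missing days; otherwise a single
    experiment-wide mean is returned.
    """
    req = {"tree_id", "day", "weight_g"}
    if not req.issubset(reference.columns):
        raise ValueError(f"reference table needs columns {sorted(req)}")
    per_tree = []
    for _, grp in reference.sort_values("day").groupby("tree_id"):
        tr = -grp["weight_g"].diff() / grp["day"].diff()
        per_tree.append(pd.Series(tr.values, index=grp["day"].values))
    daily = pd.concat(per_tree, axis=1).mean(axis=1)
    daily = daily.interpolate(limit_direction="both")
    if per_day:
        return daily
    return float(daily.mean())


def staging_table(
    weights: pd.DataFrame,
    anchors: pd.DataFrame,
    reference: pd.DataFrame,
    per_day_atr: bool = True,
) -> pd.DataFrame:
    """Per-tree, per-day FTSW, TR, RTR and stress stage.

    ``weights``: tidy (tree_id, day, weight_g); ``anchors``:
    (tree_id, initial_g, final_g); ``reference``: well-watered group
    weights for the ATR.
    """
    anchors_idx = anchors.set_index("tree_id")
    atr = average_transpiration(reference, per_day=per_day_atr)
    rows = []
    for tree, grp in weights.sort_values("day").groupby("tree_id"):
        if tree not in anchors_idx.index:
            raise ValueError(f"no anchor weights for tree {tree!r}")
        init = float(anchors_idx.loc[tree, "initial_g"])
        final = float(anchors_idx.loc[tree, "final_g"])
        tr = (-grp["weight_g"].diff() / grp["day"].diff()).values
        for (_, rec), tr_day in zip(grp.iterrows(), tr):
            day = rec["day"]
            atr_day = float(atr.reindex([day]).iloc[0]) if per_day_atr else float(atr)
            f = ftsw(rec["weight_g"], init, final)
            if np.isnan(tr_day) or np.isnan(atr_day):
                r, stage = np.nan, ""
            else:
                r = rtr(tr_day, atr_day)
                stage = classify_stage(r)
            rows.append({"tree_id": tree, "day": day, "ftsw": f,
                         "tr": tr_day, "rtr": r, "stage": stage})
    return pd.DataFrame(rows)
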