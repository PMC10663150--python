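"""Categorical classification of migration's demographic role.

Two classifiers, applicable at any zonal level (admin unit, urban/rural
stratum of a unit, socioclimatic bin):

* **impact** — how cumulative net migration over a window altered the
  population trajectory relative to natural change alone.  Inputs are the
  window population change ``popChange`` (end minus start population), the
  cumulative net migration ``netMgrSum`` and their difference
  ``popChange_woMgr = popChange − netMgrSum`` (the counterfactual change
  without migration, i.e. natural change).  Six sign-pattern criteria plus
  a boundary class:

  1. ``woMgr > 0 & mgr > 0``  → migration increases natural growth
  2. ``popChange < 0 & mgr > 0`` → migration slows decline
  3. ``woMgr < 0 & popChange > 0`` → migration turns decline to growth
  4. ``woMgr < 0 & mgr < 0`` → migration increases natural decline
  5. ``popChange > 0 & mgr < 0`` → migration slows growth
  6. ``woMgr > 0 & popChange < 0`` → migration turns growth to decline

  The criteria use strict inequalities only; any input with an exact zero
  in ``popChange``, ``netMgrSum`` or ``popChange_woMgr`` is classed
  ``negligible`` (the seventh category).

* **direction** — sign pattern of cumulative urban vs rural net migration
  within a unit: net-receiving (+,+), net-sending (−,−), rural pull–urban
  push (−urban, +rural), urban pull–rural push (+urban, −rural), and zero.
  Patterns with exactly one zero are reported as ``zero`` with the
  non-zero side recorded in an audit subclass.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd


class ImpactClass(str, Enum):
    INCREASES_GROWTH = "increases_growth"
    SLOWS_DECLINE = "slows_decline"
    TURNS_DECLINE_TO_GROWTH = "turns_decline_to_growth"
    INCREASES_DECLINE = "increases_decline"
    SLOWS_GROWTH = "slows_growth"
    TURNS_GROWTH_TO_DECLINE = "turns_growth_to_decline"
    NEGLIGIBLE = "negligible"


class DirectionClass(str, Enum):
    NET_RECEIVING = "net_receiving"
    NET_SENDING = "net_sending"
    RURAL_PULL_URBAN_PUSH = "rural_pull_urban_push"
    URBAN_PULL_RURAL_PUSH = "urban_pull_rural_push"
    ZERO = "zero"


@dataclass(frozen=True)
class ImpactInputs:
    """Window aggregates feeding the impact classifier.

    ``pop_change`` is end-of-window minus start-of-window population;
    ``net_mgr_sum`` the summed annual net migration over the window.  The
    counterfactual change without migration is their difference, so the
    identity ``pop_change_wo_mgr + net_mgr_sum == pop_change`` holds by
    construction.
    """

    pop_change: float
    net_mgr_sum: float

    @property
    def pop_change_wo_mgr(self) -> float:
        return self.pop_change - self.net_mgr_sum


def impact_class(inputs: ImpactInputs) -> ImpactClass:
    """Classify migration's impact on a unit's population trajectory.

    Total function: the "turns" criteria are evaluated before their
    sign-pattern companions (their conditions are strict subsets), and any
    exact zero among the three quantities yields ``negligible``.
    """
    pc = inputs.pop_change
    mgr = inputs.net_mgr_sum
    wo = inputs.pop_change_wo_mgr
    if pc == 0 or mgr == 0 or wo == 0:
        return ImpactClass.NEGLIGIBLE
    if wo < 0 and pc > 0:
        return ImpactClass.TURNS_DECLINE_TO_GROWTH
    if wo > 0 and pc < 0:
        return ImpactClass.TURNS_GROWTH_TO_DECLINE
    if pc < 0 and mgr > 0:
        return ImpactClass.SLOWS_DECLINE
    if pc > 0 and mgr < 0:
        return ImpactClass.SLOWS_GROWTH
    if wo > 0 and mgr > 0:
        return ImpactClass.INCREASES_GROWTH
    return ImpactClass.INCREASES_DECLINE


def direction_class(urban_mgr: float, rural_mgr: float) -> DirectionClass:
    """Sign-pattern direction of migration between urban and rural areas."""
    if urban_mgr > 0 and rural_mgr > 0:
        return DirectionClass.NET_RECEIVING
    if urban_mgr < 0 and rural_mgr < 0:
        return DirectionClass.NET_SENDING
    if urban_mgr < 0 and rural_mgr > 0:
        return DirectionClass.RURAL_PULL_URBAN_PUSH
    if urban_mgr > 0 and rural_mgr < 0:
        return DirectionClass.URBAN_PULL_RURAL_PUSH
    return DirectionClass.ZERO


def direction_audit(urban_mgr: float, rural_mgr: float) -> str:
    """Audit subclass for exactly-one-zero sign patterns.

    The main class for such patterns is ``zero`` (the criteria use strict
    inequalities); the audit column preserves which side moved.
    """
    if urban_mgr == 0 and rural_mgr != 0:
        return "urban_zero_rural_" + ("pos" if rural_mgr > 0 else "neg")
    if rural_mgr == 0 and urban_mgr != 0:
        return "rural_zero_urban_" + ("pos" if urban_mgr > 0 else "neg")
    return ""


def classify_all_units(
    window: pd.DataFrame,
    *,
    population_col: str = "population",
) -> pd.DataFrame:
    """Classify every unit's impact and direction over a window.

    Parameters
    ----------
    window:
        One row per unit with columns ``unit_id``, ``pop_change``,
        ``net_mgr_sum`` (total), ``urban_mgr``, ``rural_mgr``,
        ``urban_pop_change``, ``rural_pop_change`` and a population column
        used for share-of-population accounting.  Units with zero
        population are excluded (and counted in the function's log).

    Returns
    -------
    DataFrame with per-unit ``impact`` (total), ``impact_urban``,
    ``impact_rural``, ``direction``, ``direction_audit`` and
    ``pop_share_pct`` columns; shares sum to 100% over classified units.
    """
    df = window.copy()
    pop = df[population_col].to_numpy(dtype=float)
    keep = pop > 0
    df = df.loc[keep].copy()
    pop = pop[keep]

    df["impact"] = [
        impact_class(ImpactInputs(pc, mg)).value
        for pc, mg in zip(df["pop_change"], df["net_mgr_sum"])
    ]
    if {"urban_pop_change", "urban_mgr"} <= set(df.columns):
        df["impact_urban"] = [
            impact_class(ImpactInputs(pc, mg)).value
            for pc, mg in zip(df["urban_pop_change"], df["urban_mgr"])
        ]
    if {"rural_pop_change", "rural_mgr"} <= set(df.columns):
        df["impact_rural"] = [
            impact_class(ImpactInputs(pc, mg)).value
            for pc, mg in zip(df["rural_pop_change"], df["rural_mgr"])
        ]
    if {"urban_mgr", "rural_mgr"} <= set(df.columns):
        df["direction"] = [
            direction_class(u, r).value
            for u, r in zip(df["urban_mgr"], df["rural_mgr"])
        ]
        df["direction_audit"] = [
            direction_audit(u, r)
            for u, r in zip(df["urban_mgr"], df["rural_mgr"])
        ]
    df["pop_share_pct"] = 100.0 * pop / pop.sum() if pop.sum() > 0 else np.nan
    return df


def class_population_shares(classified: pd.DataFrame, class_col: str = "impact") -> pd.Series:
    """Percent of classified population in each class (sums to 100)."""
    return classified.groupby(class_col)["pop_share_pct"].sum()
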