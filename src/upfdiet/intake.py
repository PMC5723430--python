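"""Intake scoring: responses → grams/day → NOVA-group nutrient aggregates.

The central quantity is PEI-UPF, the percent of a subject's total energy
intake derived from NOVA group-4 (ultra-processed) foods.  Energy is never
taken from a composition database; it is recomputed from macronutrients as

    energy [MJ] = 0.017 MJ/g · (carbohydrate g + protein g) + 0.037 MJ/g · fat g

which makes total energy exactly the macronutrient formula by construction
and immunises the pipeline against database energy inconsistencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # imported lazily to avoid a cycle with instrument.py
    from .instrument import (FoodItem, InstrumentDefinition, ItemResponse,
                             ResponseSet)

__all__ = [
    "NUTRIENT_COLUMNS",
    "CARB_PROTEIN_MJ_PER_G",
    "FAT_MJ_PER_G",
    "recompute_energy",
    "item_grams_per_day",
    "build_profile",
    "group_share_table",
    "profiles_to_frame",
    "IntakeProfile",
    "ZeroIntakeError",
    "MissingResponseError",
]

#: Metabolisable-energy coefficients, megajoules per gram.
CARB_PROTEIN_MJ_PER_G = 0.017
FAT_MJ_PER_G = 0.037

#: Order of the seven tabulated quantities in every aggregate.
NUTRIENT_COLUMNS = ("energy_MJ", "carb_g", "protein_g", "fat_g", "sugars_g",
                    "fiber_g", "sodium_mg")


class ZeroIntakeError(ValueError):
    """A subject's responses imply zero total energy intake."""


class MissingResponseError(ValueError):
    """An item needed for scoring still has missing answers."""


def recompute_energy(carb_g: float, protein_g: float, fat_g: float) -> float:
    """Energy in MJ for the given gram amounts of macronutrients.

    Additive and positively homogeneous; works identically per 100 g of a
    food or per day of intake.
    """
    if carb_g < 0 or protein_g < 0 or fat_g < 0:
        raise ValueError("macronutrient amounts must be non-negative")
    return (CARB_PROTEIN_MJ_PER_G * (carb_g + protein_g)
            + FAT_MJ_PER_G * fat_g)


def item_grams_per_day(response: "ItemResponse", item: "FoodItem",
                       instrument: "InstrumentDefinition",
                       main_response: "ItemResponse | None" = None,
                       main_kind=None) -> float:
    """Grams per day implied by one item's categorical answers.

    Foods and beverages: frequency midpoint (times/month) × grams per
    serving ÷ days per month.  Condiments: the fraction-of-time option ×
    the *attached main item's* frequency × the condiment's grams per
    serving ÷ days per month; ``main_response`` must then be supplied.
    """
    from .instrument import FoodKind

    if response.amount_opt is None:
        raise MissingResponseError(f"{item.item_id}: missing amount option")
    grams = item.grams_per_serving(response.amount_opt)

    if item.kind is FoodKind.CONDIMENT:
        if response.cond_frac_opt is None:
            raise MissingResponseError(
                f"{item.item_id}: missing condiment fraction option")
        if main_response is None or main_response.freq_opt is None:
            raise MissingResponseError(
                f"{item.item_id}: attached main item {item.attached_to!r} "
                "has missing frequency")
        frac = instrument.condiment_fraction(response.cond_frac_opt)
        # the main item's kind governs which frequency scale applies; main
        # items are foods or beverages, never condiments themselves
        times = instrument.times_per_month(main_kind or FoodKind.FOOD,
                                           main_response.freq_opt)
        return frac * times * grams / instrument.days_per_month

    if response.freq_opt is None:
        raise MissingResponseError(f"{item.item_id}: missing frequency option")
    times = instrument.times_per_month(item.kind, response.freq_opt)
    return times * grams / instrument.days_per_month


@dataclass
class IntakeProfile:
    """Per-subject derived intake.

    ``by_group`` is a 4×7 frame (NOVA groups × nutrient columns) of daily
    amounts, ``by_subgroup`` the 33-row analogue; ``pei`` maps each NOVA
    group to its percent of total energy and ``pei_upf`` is the group-4
    entry.
    """

    subject_id: str
    grams_per_day: dict[str, float]
    by_group: pd.DataFrame
    by_subgroup: pd.DataFrame
    total_energy_MJ_per_day: float
    pei: dict[int, float]
    pei_upf: float


def _nutrients_per_gram(item: "FoodItem") -> np.ndarray:
    return np.array([
        item.energy_MJ_per_100g, item.carb_g_per_100g, item.protein_g_per_100g,
        item.fat_g_per_100g, item.sugars_g_per_100g, item.fiber_g_per_100g,
        item.sodium_mg_per_100g,
    ]) / 100.0


def build_profile(response_set: "ResponseSet",
                  food_items: "Sequence[FoodItem]",
                  instrument: "InstrumentDefinition") -> IntakeProfile:
    """Score one subject's complete (imputed) responses into an IntakeProfile.

    Raises :class:`ZeroIntakeError` if the implied total energy is zero and
    :class:`MissingResponseError` if any answered-for item is incomplete.
    """
    from .instrument import NOVA_SUBGROUPS

    by_id = {it.item_id: it for it in food_items}
    grams: dict[str, float] = {}
    for iid, ans in response_set.answers.items():
        if iid not in by_id:
            raise KeyError(f"response names unknown item {iid!r}")
        item = by_id[iid]
        main = (response_set.answers.get(item.attached_to)
                if item.attached_to is not None else None)
        main_kind = None
        if item.attached_to is not None:
            if main is None:
                raise MissingResponseError(
                    f"{iid}: no response for attached main item "
                    f"{item.attached_to!r}")
            main_kind = by_id[item.attached_to].kind
        grams[iid] = item_grams_per_day(ans, item, instrument,
                                        main_response=main,
                                        main_kind=main_kind)

    subgroups = list(NOVA_SUBGROUPS)
    sub_index = {s: i for i, s in enumerate(subgroups)}
    sub_mat = np.zeros((len(subgroups), len(NUTRIENT_COLUMNS)))
    for iid, g in grams.items():
        item = by_id[iid]
        sub_mat[sub_index[item.nova_subgroup]] += g * _nutrients_per_gram(item)

    by_subgroup = pd.DataFrame(sub_mat, index=subgroups,
                               columns=list(NUTRIENT_COLUMNS))
    group_of = pd.Series({s: g for s, g in NOVA_SUBGROUPS.items()})
    by_group = by_subgroup.groupby(group_of).sum()
    by_group = by_group.reindex([1, 2, 3, 4], fill_value=0.0)

    total_energy = float(by_group["energy_MJ"].sum())
    if total_energy <= 0:
        raise ZeroIntakeError(
            f"subject {response_set.subject_id}: zero total energy intake")
    pei = {g: 100.0 * float(by_group.at[g, "energy_MJ"]) / total_energy
           for g in (1, 2, 3, 4)}
    return IntakeProfile(
        subject_id=response_set.subject_id,
        grams_per_day=grams,
        by_group=by_group,
        by_subgroup=by_subgroup,
        total_energy_MJ_per_day=total_energy,
        pei=pei,
        pei_upf=pei[4],
    )


def group_share_table(profiles: Sequence[IntakeProfile],
                      method: str = "cohort_sum") -> pd.DataFrame:
    """Group-level nutrient share table across a cohort.

    Rows are NOVA groups 1–4 plus ``TOTAL``; columns are mean absolute
    energy (MJ/day) and, for energy plus the six nutrients, the percent of
    total intake obtained from each group.  ``method='cohort_sum'`` (the
    default reporting convention) forms shares of summed cohort intake;
    ``method='subject_mean'`` averages each subject's own shares.
    """
    if not profiles:
        raise ValueError("empty cohort")
    if method not in ("cohort_sum", "subject_mean"):
        raise ValueError(f"unknown method {method!r}")

    stacked = np.stack([p.by_group.to_numpy() for p in profiles])  # n×4×7
    mean_abs = stacked.mean(axis=0)  # 4×7 mean daily amounts
    if method == "cohort_sum":
        totals = stacked.sum(axis=0)          # 4×7 cohort totals
        shares = 100.0 * totals / totals.sum(axis=0, keepdims=True)
    else:
        per_subj = 100.0 * stacked / stacked.sum(axis=1, keepdims=True)
        shares = per_subj.mean(axis=0)

    out = pd.DataFrame(index=[1, 2, 3, 4])
    out["energy_MJ_per_day"] = mean_abs[:, 0]
    for j, col in enumerate(NUTRIENT_COLUMNS):
        out[col.rsplit("_", 1)[0] + "_pct"] = shares[:, j]
    total = out.sum(axis=0).to_frame().T
    total.index = ["TOTAL"]
    return pd.concat([out, total])


def profiles_to_frame(profiles: Sequence[IntakeProfile]) -> pd.DataFrame:
    """Per-subject summary: total energy, PEI per group, PEI-UPF."""
    rows = []
    for p in profiles:
        row = {"subject_id": p.subject_id,
               "total_energy_MJ_per_day": p.total_energy_MJ_per_day}
        for g in (1, 2, 3, 4):
            row[f"pei_group{g}"] = p.pei[g]
        row["pei_upf"] = p.pei_upf
        rows.append(row)
    return pd.DataFrame(rows)
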