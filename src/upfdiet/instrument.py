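"""Food-frequency instrument model: option lists, food table, responses.

The instrument mirrors a month-recall FFQ of the DHQ II shape: every food
line item carries a categorical consumption-frequency answer (8 options for
foods, "never" up to "2 or more times per day"; beverages run up to "6 or
more times per day"), one of three portion-size options, and — for
condiments — one of five options for the fraction of the time the condiment
is added to its main food.  All numeric midpoints live in an editable YAML
file, never in code.

Everything in this module is pure parsing and validation: no operation
alters a numeric value.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .intake import recompute_energy

__all__ = [
    "AMOUNT_OPTION_LABELS",
    "NOVA_SUBGROUPS",
    "FoodKind",
    "InstrumentDefinition",
    "FoodItem",
    "ItemResponse",
    "ResponseSet",
    "SchemaError",
    "ValidationError",
    "read_instrument",
    "write_instrument",
    "read_food_table",
    "read_responses",
    "write_responses",
    "read_cohort_table",
]


class SchemaError(ValueError):
    """A file does not conform to the documented schema."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


#: The three portion-size options; grams per serving are item-specific
#: columns of the composition table.
AMOUNT_OPTION_LABELS = ("small", "medium", "large")

#: The 33 food subgroups nested within the four NOVA groups.  Group 1 is
#: unprocessed/minimally processed food, group 2 processed culinary
#: ingredients, group 3 processed foods, group 4 ultra-processed foods.
NOVA_SUBGROUPS: Mapping[str, int] = {
    # group 1 (12)
    "fruits": 1,
    "vegetables": 1,
    "grains": 1,
    "legumes": 1,
    "red_meat": 1,
    "poultry": 1,
    "fish_seafood": 1,
    "eggs": 1,
    "milk_plain_yogurt": 1,
    "nuts_seeds": 1,
    "roots_tubers": 1,
    "coffee_tea": 1,
    # group 2 (5)
    "vegetable_oils": 2,
    "butter_cream": 2,
    "table_sugar": 2,
    "honey_syrups": 2,
    "salt": 2,
    # group 3 (5)
    "cheese": 3,
    "cured_meat_fish": 3,
    "canned_fruits_vegetables": 3,
    "beer_wine": 3,
    "salted_roasted_nuts": 3,
    # group 4 (11)
    "cakes_cookies_pies": 4,
    "breads": 4,
    "breakfast_cereals": 4,
    "soft_drinks": 4,
    "fruit_drinks": 4,
    "salty_snacks": 4,
    "candy_confectionery": 4,
    "ice_cream_desserts": 4,
    "sauces_dressings": 4,
    "reconstituted_meat": 4,
    "ready_meals": 4,
}


class FoodKind(str, Enum):
    FOOD = "food"
    BEVERAGE = "beverage"
    CONDIMENT = "condiment"


def _check_options(name: str, options: Sequence[tuple[str, float]],
                   *, expect_n: int | None = None,
                   upper: float | None = None) -> list[tuple[str, float]]:
    out = [(str(lab), float(v)) for lab, v in options]
    if expect_n is not None and len(out) != expect_n:
        raise ValidationError(
            f"{name}: expected exactly {expect_n} options, got {len(out)}")
    values = [v for _, v in out]
    if any(v < 0 for v in values):
        raise ValidationError(f"{name}: negative midpoint")
    if upper is not None and any(v > upper for v in values):
        raise ValidationError(f"{name}: value above {upper}")
    if any(b <= a for a, b in zip(values, values[1:])):
        raise ValidationError(f"{name}: midpoints must be strictly increasing")
    return out


@dataclass(frozen=True)
class InstrumentDefinition:
    """Numeric decoding of the questionnaire's categorical options.

    ``food_frequency_options`` and ``beverage_frequency_options`` map option
    labels to times-per-month midpoints; ``condiment_fraction_options`` map
    labels to the fraction of the time the condiment accompanies its main
    food.  ``days_per_month`` converts per-month frequencies to per-day
    intakes (365.25 / 12 by default).
    """

    food_frequency_options: list[tuple[str, float]]
    beverage_frequency_options: list[tuple[str, float]]
    condiment_fraction_options: list[tuple[str, float]]
    days_per_month: float = 30.4

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "food_frequency_options",
            _check_options("food_frequency_options",
                           self.food_frequency_options, expect_n=8))
        object.__setattr__(
            self, "beverage_frequency_options",
            _check_options("beverage_frequency_options",
                           self.beverage_frequency_options))
        object.__setattr__(
            self, "condiment_fraction_options",
            _check_options("condiment_fraction_options",
                           self.condiment_fraction_options,
                           expect_n=5, upper=1.0))
        if self.days_per_month <= 0:
            raise ValidationError("days_per_month must be positive")

    def frequency_options(self, kind: FoodKind) -> list[tuple[str, float]]:
        if kind is FoodKind.BEVERAGE:
            return self.beverage_frequency_options
        return self.food_frequency_options

    def times_per_month(self, kind: FoodKind, option_index: int) -> float:
        opts = self.frequency_options(kind)
        if not 0 <= option_index < len(opts):
            raise ValidationError(
                f"frequency option index {option_index} out of range "
                f"0..{len(opts) - 1} for kind {kind.value}")
        return opts[option_index][1]

    def condiment_fraction(self, option_index: int) -> float:
        if not 0 <= option_index < len(self.condiment_fraction_options):
            raise ValidationError(
                f"condiment fraction option index {option_index} out of range")
        return self.condiment_fraction_options[option_index][1]


_INSTRUMENT_KEYS = {
    "food_frequency_options", "beverage_frequency_options",
    "condiment_fraction_options", "days_per_month",
}


def read_instrument(path: str | Path) -> InstrumentDefinition:
    """Read an instrument YAML file, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: instrument file must be a YAML mapping")
    unknown = set(raw) - _INSTRUMENT_KEYS
    if unknown:
        raise SchemaError(f"{path}: unknown keys {sorted(unknown)}")
    missing = _INSTRUMENT_KEYS - {"days_per_month"} - set(raw)
    if missing:
        raise SchemaError(f"{path}: missing keys {sorted(missing)}")

    def pairs(key: str) -> list[tuple[str, float]]:
        entries = raw[key]
        if not isinstance(entries, list):
            raise SchemaError(f"{path}: {key} must be a list")
        out = []
        for e in entries:
            if not (isinstance(e, dict) and {"label", "value"} == set(e)):
                raise SchemaError(
                    f"{key}: each option needs exactly 'label' and 'value'")
            out.append((e["label"], float(e["value"])))
        return out

    return InstrumentDefinition(
        food_frequency_options=pairs("food_frequency_options"),
        beverage_frequency_options=pairs("beverage_frequency_options"),
        condiment_fraction_options=pairs("condiment_fraction_options"),
        days_per_month=float(raw.get("days_per_month", 30.4)),
    )


def write_instrument(instrument: InstrumentDefinition, path: str | Path) -> None:
    doc = {
        "food_frequency_options": [
            {"label": lab, "value": v}
            for lab, v in instrument.food_frequency_options],
        "beverage_frequency_options": [
            {"label": lab, "value": v}
            for lab, v in instrument.beverage_frequency_options],
        "condiment_fraction_options": [
            {"label": lab, "value": v}
            for lab, v in instrument.condiment_fraction_options],
        "days_per_month": instrument.days_per_month,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_instrument() -> InstrumentDefinition:
    """The packaged default instrument."""
    return read_instrument(Path(__file__).parent / "data" / "instrument.yaml")


@dataclass(frozen=True)
class FoodItem:
    """One FFQ line item: identity, serving sizes and per-100 g nutrients.

    ``energy_MJ_per_100g`` is always derived from the macronutrients via
    :func:`upfdiet.intake.recompute_energy`; energy columns in source files
    are ignored.
    """

    item_id: str
    name: str
    kind: FoodKind
    attached_to: str | None
    nova_group: int
    nova_subgroup: str
    serv_grams: tuple[float, float, float]  # small, medium, large
    carb_g_per_100g: float
    protein_g_per_100g: float
    fat_g_per_100g: float
    sugars_g_per_100g: float
    fiber_g_per_100g: float
    sodium_mg_per_100g: float
    energy_MJ_per_100g: float = field(init=False)

    def __post_init__(self) -> None:
        if self.nova_group not in (1, 2, 3, 4):
            raise ValidationError(
                f"{self.item_id}: nova_group must be 1-4, got {self.nova_group}")
        if self.nova_subgroup not in NOVA_SUBGROUPS:
            raise ValidationError(
                f"{self.item_id}: unknown NOVA subgroup {self.nova_subgroup!r}")
        if NOVA_SUBGROUPS[self.nova_subgroup] != self.nova_group:
            raise ValidationError(
                f"{self.item_id}: subgroup {self.nova_subgroup!r} belongs to "
                f"group {NOVA_SUBGROUPS[self.nova_subgroup]}, not "
                f"{self.nova_group}")
        if self.kind is FoodKind.CONDIMENT and self.attached_to is None:
            raise ValidationError(
                f"{self.item_id}: condiment must name its main item")
        if self.kind is not FoodKind.CONDIMENT and self.attached_to is not None:
            raise ValidationError(
                f"{self.item_id}: only condiments may set attached_to")
        nutrients = (self.carb_g_per_100g, self.protein_g_per_100g,
                     self.fat_g_per_100g, self.sugars_g_per_100g,
                     self.fiber_g_per_100g, self.sodium_mg_per_100g)
        if any(v < 0 for v in nutrients):
            raise ValidationError(f"{self.item_id}: negative nutrient value")
        macro = (self.carb_g_per_100g + self.protein_g_per_100g
                 + self.fat_g_per_100g)
        if macro > 100 + 1e-9:
            raise ValidationError(
                f"{self.item_id}: carb+protein+fat = {macro:.2f} g per 100 g")
        if any(v < 0 for v in self.serv_grams) or len(self.serv_grams) != 3:
            raise ValidationError(f"{self.item_id}: bad serving sizes")
        object.__setattr__(
            self, "energy_MJ_per_100g",
            recompute_energy(self.carb_g_per_100g, self.protein_g_per_100g,
                             self.fat_g_per_100g))

    def grams_per_serving(self, amount_index: int) -> float:
        if not 0 <= amount_index < 3:
            raise ValidationError(
                f"amount option index {amount_index} out of range 0..2")
        return self.serv_grams[amount_index]


_COMPOSITION_COLS = [
    "item_id", "name", "kind", "attached_to", "serv_small_g", "serv_med_g",
    "serv_large_g", "carb_g", "protein_g", "fat_g", "sugars_g", "fiber_g",
    "sodium_mg",
]
_NOVA_COLS = ["item_id", "nova_group", "nova_subgroup", "note"]


def _read_csv_rows(path: str | Path, required: list[str]) -> list[dict]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        cols = reader.fieldnames or []
        missing = [c for c in required if c not in cols]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}")
        return list(reader)


def read_food_table(composition_path: str | Path,
                    nova_map_path: str | Path) -> list[FoodItem]:
    """Join the composition table with the NOVA map into FoodItems.

    Every item must appear in both files; energy is recomputed from the
    macronutrient columns regardless of any energy column present.
    """
    comp_rows = _read_csv_rows(composition_path, _COMPOSITION_COLS)
    nova_rows = _read_csv_rows(nova_map_path, _NOVA_COLS[:3])
    nova = {}
    for row in nova_rows:
        iid = row["item_id"]
        if iid in nova:
            raise ValidationError(f"duplicate item_id {iid!r} in NOVA map")
        nova[iid] = row
    comp_ids = [r["item_id"] for r in comp_rows]
    if len(set(comp_ids)) != len(comp_ids):
        raise ValidationError("duplicate item_id in composition table")
    only_comp = sorted(set(comp_ids) - set(nova))
    only_nova = sorted(set(nova) - set(comp_ids))
    if only_comp or only_nova:
        raise ValidationError(
            f"composition/NOVA map mismatch: only in composition {only_comp}, "
            f"only in NOVA map {only_nova}")

    items = []
    for row in comp_rows:
        nrow = nova[row["item_id"]]
        try:
            kind = FoodKind(row["kind"])
        except ValueError:
            raise SchemaError(
                f"{row['item_id']}: unknown kind {row['kind']!r}") from None
        attached = row.get("attached_to") or None
        items.append(FoodItem(
            item_id=row["item_id"],
            name=row["name"],
            kind=kind,
            attached_to=attached,
            nova_group=int(nrow["nova_group"]),
            nova_subgroup=nrow["nova_subgroup"],
            serv_grams=(float(row["serv_small_g"]), float(row["serv_med_g"]),
                        float(row["serv_large_g"])),
            carb_g_per_100g=float(row["carb_g"]),
            protein_g_per_100g=float(row["protein_g"]),
            fat_g_per_100g=float(row["fat_g"]),
            sugars_g_per_100g=float(row["sugars_g"]),
            fiber_g_per_100g=float(row["fiber_g"]),
            sodium_mg_per_100g=float(row["sodium_mg"]),
        ))
    by_id = {it.item_id: it for it in items}
    for it in items:
        if it.attached_to is not None and it.attached_to not in by_id:
            raise ValidationError(
                f"{it.item_id}: attached_to {it.attached_to!r} not in table")
    return items


def default_food_table() -> list[FoodItem]:
    """The packaged synthetic food table (composition + NOVA map)."""
    d = Path(__file__).parent / "data"
    return read_food_table(d / "composition.csv", d / "nova_map.csv")


@dataclass(frozen=True)
class ItemResponse:
    """A subject's categorical answers for one item; ``None`` = missing."""

    freq_opt: int | None = None
    amount_opt: int | None = None
    cond_frac_opt: int | None = None


@dataclass
class ResponseSet:
    """All of one subject's answers, keyed by item id."""

    subject_id: str
    answers: dict[str, ItemResponse] = field(default_factory=dict)


def _parse_opt(cell: str, what: str, subject: str, item: str,
               n_max: int | None = None) -> int | None:
    if cell is None or cell.strip() == "":
        return None
    try:
        v = int(cell)
    except ValueError:
        raise SchemaError(
            f"subject {subject}, item {item}: non-integer {what} "
            f"{cell!r}") from None
    if v < 0 or (n_max is not None and v >= n_max):
        raise ValidationError(
            f"subject {subject}, item {item}: {what} index {v} out of range")
    return v


def read_responses(path: str | Path,
                   instrument: InstrumentDefinition | None = None,
                   food_items: Sequence[FoodItem] | None = None,
                   ) -> list[ResponseSet]:
    """Read a long-format response CSV.

    Blank cells become explicit ``None`` (never silently zero).  When an
    instrument and food table are supplied, option indices are range-checked
    per item kind.
    """
    rows = _read_csv_rows(
        path, ["subject_id", "item_id", "freq_opt", "amount_opt",
               "cond_frac_opt"])
    kinds = ({it.item_id: it.kind for it in food_items}
             if food_items is not None else None)
    out: dict[str, ResponseSet] = {}
    for row in rows:
        sid, iid = row["subject_id"], row["item_id"]
        rs = out.setdefault(sid, ResponseSet(subject_id=sid))
        if iid in rs.answers:
            raise ValidationError(
                f"duplicate response row for subject {sid}, item {iid}")
        n_freq = n_cond = None
        if instrument is not None and kinds is not None:
            if iid not in kinds:
                raise ValidationError(f"unknown item_id {iid!r} in responses")
            n_freq = len(instrument.frequency_options(kinds[iid]))
            n_cond = len(instrument.condiment_fraction_options)
        rs.answers[iid] = ItemResponse(
            freq_opt=_parse_opt(row["freq_opt"], "frequency option", sid, iid,
                                n_freq),
            amount_opt=_parse_opt(row["amount_opt"], "amount option", sid, iid,
                                  3),
            cond_frac_opt=_parse_opt(row["cond_frac_opt"],
                                     "condiment fraction option", sid, iid,
                                     n_cond),
        )
    return list(out.values())


def write_responses(responses: Sequence[ResponseSet], path: str | Path) -> None:
    def fmt(v: int | None) -> str:
        return "" if v is None else str(v)

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "item_id", "freq_opt", "amount_opt",
                    "cond_frac_opt"])
        for rs in responses:
            for iid, ans in rs.answers.items():
                w.writerow([rs.subject_id, iid, fmt(ans.freq_opt),
                            fmt(ans.amount_opt), fmt(ans.cond_frac_opt)])


#: Documented cohort-table schema: required column name -> (kind, levels/range)
COHORT_COLUMNS = {
    "subject_id": "id",
    "pei_upf": "percent",
    "hei2010": "percent",
    "age": "continuous",
    "race": ("Caucasian", "AfricanAmerican_other"),
    "clinic": ("low_income", "high_income"),
    "weight_status": ("lean", "obese"),
    "energy_kcal_per_day": "continuous",
    "fat_g_per_day": "continuous",
    "moderate_pa_pct": "continuous",
}

COHORT_OUTCOMES = ("gwg_kg", "thigh_skinfold_mm", "subscap_skinfold_mm",
                   "neonate_bodyfat_pct")


def read_cohort_table(path: str | Path,
                      column_map: Mapping[str, str] | None = None):
    """Read a subject covariate/outcome CSV into a validated DataFrame.

    ``column_map`` renames source columns to the documented schema (for
    externally deposited datasets whose headers differ); any renaming is
    recorded in the returned frame's ``attrs['column_map']``.
    """
    import pandas as pd

    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
        df.attrs["column_map"] = dict(column_map)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing cohort columns {missing}")
    for col in ("pei_upf", "hei2010"):
        bad = df[(df[col] < 0) | (df[col] > 100)]
        if len(bad):
            raise ValidationError(f"{col} outside [0,100] for "
                                  f"{bad['subject_id'].tolist()}")
    for col, spec in COHORT_COLUMNS.items():
        if isinstance(spec, tuple):
            levels = set(df[col].dropna().unique())
            if not levels <= set(spec):
                raise ValidationError(
                    f"{col}: unexpected levels {sorted(levels - set(spec))}")
    return df
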