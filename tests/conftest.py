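import numpy as np
import pytest

from upfdiet import instrument as inst_mod
from upfdiet.instrument import (FoodItem, FoodKind, ItemResponse, ResponseSet)


@pytest.fixture(scope="session")
def instrument():
    return inst_mod.default_instrument()


@pytest.fixture(scope="session")
def food_items():
    return inst_mod.default_food_table()


@pytest.fixture(scope="session")
def items_by_id(food_items):
    return {it.item_id: it for it in food_items}


def make_item(item_id="x", kind=FoodKind.FOOD, attached_to=None,
              nova_group=1, nova_subgroup="fruits",
              serv=(50.0, 100.0, 150.0), carb=10.0, protein=5.0, fat=4.0,
              sugars=1.0, fiber=1.0, sodium=10.0):
    return FoodItem(item_id=item_id, name=item_id, kind=kind,
                    attached_to=attached_to, nova_group=nova_group,
                    nova_subgroup=nova_subgroup, serv_grams=tuple(serv),
                    carb_g_per_100g=carb, protein_g_per_100g=protein,
                    fat_g_per_100g=fat, sugars_g_per_100g=sugars,
                    fiber_g_per_100g=fiber, sodium_mg_per_100g=sodium)


@pytest.fixture
def tiny_items():
    """One group-1 fruit and one group-4 snack, chosen so per-100g energy
    is identical (symmetry tests)."""
    return [
        make_item("fruit", nova_group=1, nova_subgroup="fruits",
                  carb=10, protein=5, fat=4),
        make_item("snack", nova_group=4, nova_subgroup="salty_snacks",
                  carb=10, protein=5, fat=4),
    ]


def response(subject_id, **answers):
    return ResponseSet(subject_id=subject_id,
                       answers={k: ItemResponse(**v)
                                for k, v in answers.items()})


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260918)
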