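"""Scoring engine: energy formula, grams/day, profiles, share tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_item, response
from upfdiet import intake
from upfdiet.instrument import (NOVA_SUBGROUPS, FoodKind, ItemResponse,
                                ResponseSet)
from upfdiet.intake import (MissingResponseError, ZeroIntakeError,
                            build_profile, group_share_table,
                            item_grams_per_day, recompute_energy)


class TestRecomputeEnergy:
    @pytest.mark.parametrize("carb,protein,fat,expected", [
        (0, 0, 0, 0.0),
        (100, 0, 0, 1.7),             # carbohydrate coefficient
        (0, 0, 100, 3.7),             # fat coefficient
        (10, 5, 4, 0.017 * 15 + 0.037 * 4),  # hand evaluation: 0.403
    ])
    def test_known_values(self, carb, protein, fat, expected):
        assert recompute_energy(carb, protein, fat) == pytest.approx(
            expected, abs=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            recompute_energy(-1, 0, 0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.tuples(*[st.floats(0, 1e3) for _ in range(6)]),
           st.floats(0, 10))
    def test_additive_and_homogeneous(self, args, scale):
        c1, p1, f1, c2, p2, f2 = args
        total = recompute_energy(c1 + c2, p1 + p2, f1 + f2)
        assert total == pytest.approx(
            recompute_energy(c1, p1, f1) + recompute_energy(c2, p2, f2),
            rel=1e-12, abs=1e-12)
        assert recompute_energy(scale * c1, scale * p1, scale * f1) == \
            pytest.approx(scale * recompute_energy(c1, p1, f1),
                          rel=1e-12, abs=1e-12)


class TestItemGramsPerDay:
    def test_never_is_zero(self, instrument):
        item = make_item()
        assert item_grams_per_day(ItemResponse(freq_opt=0, amount_opt=2),
                                  item, instrument) == 0.0

    def test_daily_consumption_equals_serving(self, instrument):
        # frequency midpoint 30.4/month at the 100 g serving -> 100 g/day
        item = make_item(serv=(50, 100, 150))
        daily_idx = [v for _, v in instrument.food_frequency_options
                     ].index(30.4)
        assert item_grams_per_day(
            ItemResponse(freq_opt=daily_idx, amount_opt=1), item,
            instrument) == pytest.approx(100.0)

    def test_condiment_fraction_scales_main_frequency(self, instrument):
        cond = make_item("marg", kind=FoodKind.CONDIMENT, attached_to="bread",
                         nova_group=4, nova_subgroup="sauces_dressings",
                         serv=(5, 10, 15))
        daily_idx = [v for _, v in instrument.food_frequency_options
                     ].index(30.4)
        half_idx = [v for _, v in instrument.condiment_fraction_options
                    ].index(0.5)
        g = item_grams_per_day(
            ItemResponse(amount_opt=1, cond_frac_opt=half_idx), cond,
            instrument,
            main_response=ItemResponse(freq_opt=daily_idx, amount_opt=1))
        assert g == pytest.approx(0.5 * 30.4 * 10 / 30.4)

    def test_condiment_without_main_frequency_propagates(self, instrument):
        cond = make_item("marg", kind=FoodKind.CONDIMENT, attached_to="bread",
                         nova_group=4, nova_subgroup="sauces_dressings")
        with pytest.raises(MissingResponseError, match="frequency"):
            item_grams_per_day(
                ItemResponse(amount_opt=1, cond_frac_opt=2), cond,
                instrument, main_response=ItemResponse(freq_opt=None))

    def test_missing_fields_rejected(self, instrument):
        with pytest.raises(MissingResponseError):
            item_grams_per_day(ItemResponse(freq_opt=None, amount_opt=1),
                               make_item(), instrument)


class TestBuildProfile:
    def test_single_group4_item_is_pure_upf(self, instrument):
        items = [make_item("snack", nova_group=4,
                           nova_subgroup="salty_snacks")]
        rs = response("s1", snack=dict(freq_opt=5, amount_opt=1))
        prof = build_profile(rs, items, instrument)
        assert prof.pei_upf == pytest.approx(100.0)

    def test_equal_energy_split_is_fifty_fifty(self, instrument, tiny_items):
        rs = response("s1", fruit=dict(freq_opt=4, amount_opt=1),
                      snack=dict(freq_opt=4, amount_opt=1))
        prof = build_profile(rs, tiny_items, instrument)
        assert prof.pei_upf == pytest.approx(50.0)

    def test_zero_intake_names_subject(self, instrument, tiny_items):
        rs = response("subjZ", fruit=dict(freq_opt=0, amount_opt=1),
                      snack=dict(freq_opt=0, amount_opt=1))
        with pytest.raises(ZeroIntakeError, match="subjZ"):
            build_profile(rs, tiny_items, instrument)

    def test_three_item_worked_fixture(self, instrument, items_by_id):
        """Golden spreadsheet-style hand computation, independent of the
        matrix path.

        apple daily at 140 g, cookies 3-4/wk at 28 g, white bread 1-2/wk
        at 50 g (packaged composition values).
        """
        rs = response("s1",
                      apple=dict(freq_opt=6, amount_opt=1),
                      cookies=dict(freq_opt=4, amount_opt=0),
                      white_bread=dict(freq_opt=3, amount_opt=1))
        prof = build_profile(
            rs, [items_by_id[i] for i in ("apple", "cookies", "white_bread")],
            instrument)

        # hand computation with plain arithmetic
        g_apple = 30.4 * 140 / 30.4          # 140 g/day
        g_cook = 15.2 * 28 / 30.4            # 14 g/day
        g_bread = 6.51 * 50 / 30.4
        e_apple = 0.017 * (g_apple * 0.14 + g_apple * 0.003) \
            + 0.037 * g_apple * 0.002
        e_cook = 0.017 * (g_cook * 0.68 + g_cook * 0.05) \
            + 0.037 * g_cook * 0.23
        e_bread = 0.017 * (g_bread * 0.49 + g_bread * 0.09) \
            + 0.037 * g_bread * 0.032
        expected_pei = 100 * (e_cook + e_bread) / (e_apple + e_cook + e_bread)

        assert prof.grams_per_day["cookies"] == pytest.approx(14.0)
        assert prof.total_energy_MJ_per_day == pytest.approx(
            e_apple + e_cook + e_bread, rel=1e-12)
        assert prof.pei_upf == pytest.approx(expected_pei, rel=1e-12)

    def test_brute_force_oracle_equivalence(self, instrument, food_items,
                                            rng):
        """Item-by-item accumulation written independently of build_profile
        agrees on small random cohorts."""
        items = [it for it in food_items
                 if it.kind is not FoodKind.CONDIMENT][:10]
        for _ in range(5):
            answers = {
                it.item_id: ItemResponse(
                    freq_opt=int(rng.integers(
                        1, len(instrument.frequency_options(it.kind)))),
                    amount_opt=int(rng.integers(0, 3)))
                for it in items}
            rs = ResponseSet("s", answers)
            prof = build_profile(rs, items, instrument)

            # oracle: per-item loop accumulating into plain dicts
            tot = {c: 0.0 for c in intake.NUTRIENT_COLUMNS}
            e_by_group = {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0}
            for it in items:
                a = answers[it.item_id]
                freq = instrument.frequency_options(it.kind)[a.freq_opt][1]
                g = freq * it.serv_grams[a.amount_opt] / 30.4
                e = (0.017 * (it.carb_g_per_100g + it.protein_g_per_100g)
                     + 0.037 * it.fat_g_per_100g) * g / 100
                e_by_group[it.nova_group] += e
                tot["energy_MJ"] += e
                tot["carb_g"] += g * it.carb_g_per_100g / 100
                tot["protein_g"] += g * it.protein_g_per_100g / 100
                tot["fat_g"] += g * it.fat_g_per_100g / 100
                tot["sugars_g"] += g * it.sugars_g_per_100g / 100
                tot["fiber_g"] += g * it.fiber_g_per_100g / 100
                tot["sodium_mg"] += g * it.sodium_mg_per_100g / 100

            for col in intake.NUTRIENT_COLUMNS:
                assert prof.by_group[col].sum() == pytest.approx(
                    tot[col], rel=1e-9, abs=1e-12)
            assert prof.pei_upf == pytest.approx(
                100 * e_by_group[4] / tot["energy_MJ"], rel=1e-9)

    def test_conservation_and_normalisation(self, instrument, food_items,
                                            rng):
        """Groups sum to totals, subgroups sum to parents, PEI sums to 100."""
        for _ in range(20):
            answers = {}
            for it in food_items:
                if it.kind is FoodKind.CONDIMENT:
                    answers[it.item_id] = ItemResponse(
                        amount_opt=int(rng.integers(0, 3)),
                        cond_frac_opt=int(rng.integers(0, 5)))
                else:
                    answers[it.item_id] = ItemResponse(
                        freq_opt=int(rng.integers(
                            0, len(instrument.frequency_options(it.kind)))),
                        amount_opt=int(rng.integers(0, 3)))
            rs = ResponseSet("s", answers)
            try:
                prof = build_profile(rs, food_items, instrument)
            except ZeroIntakeError:
                continue
            assert sum(prof.pei.values()) == pytest.approx(100.0, abs=1e-9)
            assert all(0 <= v <= 100 for v in prof.pei.values())
            group_of = {s: g for s, g in NOVA_SUBGROUPS.items()}
            parent = prof.by_subgroup.groupby(
                prof.by_subgroup.index.map(group_of)).sum()
            np.testing.assert_allclose(
                parent.to_numpy(), prof.by_group.to_numpy(), atol=1e-9)
            np.testing.assert_allclose(
                prof.by_subgroup.sum().to_numpy(),
                prof.by_group.sum().to_numpy(), atol=1e-9)

    def test_scale_equivariance(self, instrument, tiny_items):
        """Doubling frequency midpoints doubles intakes, fixes shares."""
        from upfdiet.instrument import InstrumentDefinition

        doubled = InstrumentDefinition(
            food_frequency_options=[(l, 2 * v) for l, v in
                                    instrument.food_frequency_options],
            beverage_frequency_options=[(l, 2 * v) for l, v in
                                        instrument.beverage_frequency_options],
            condiment_fraction_options=instrument.condiment_fraction_options,
            days_per_month=instrument.days_per_month)
        rs = response("s1", fruit=dict(freq_opt=3, amount_opt=2),
                      snack=dict(freq_opt=5, amount_opt=0))
        p1 = build_profile(rs, tiny_items, instrument)
        p2 = build_profile(rs, tiny_items, doubled)
        assert p2.total_energy_MJ_per_day == pytest.approx(
            2 * p1.total_energy_MJ_per_day, rel=1e-12)
        for iid in p1.grams_per_day:
            assert p2.grams_per_day[iid] == pytest.approx(
                2 * p1.grams_per_day[iid], rel=1e-12)
        assert p2.pei_upf == pytest.approx(p1.pei_upf, rel=1e-12)


class TestGroupShareTable:
    def test_single_group_cohort_is_100_percent(self, instrument):
        items = [make_item("ap", nova_group=1, nova_subgroup="fruits")]
        prof = build_profile(response("s1", ap=dict(freq_opt=3, amount_opt=1)),
                             items, instrument)
        tab = group_share_table([prof])
        assert tab.loc[1, "energy_pct"] == pytest.approx(100.0)
        assert tab.loc[4, "energy_pct"] == pytest.approx(0.0)

    def test_mirrored_cohort_splits_evenly(self, instrument, tiny_items):
        p1 = build_profile(response("s1", fruit=dict(freq_opt=5, amount_opt=1),
                                    snack=dict(freq_opt=2, amount_opt=1)),
                           tiny_items, instrument)
        p2 = build_profile(response("s2", fruit=dict(freq_opt=2, amount_opt=1),
                                    snack=dict(freq_opt=5, amount_opt=1)),
                           tiny_items, instrument)
        for method in ("cohort_sum", "subject_mean"):
            tab = group_share_table([p1, p2], method=method)
            assert tab.loc[1, "energy_pct"] == pytest.approx(50.0)
            assert tab.loc[4, "energy_pct"] == pytest.approx(50.0)

    def test_total_row_is_100(self, instrument, food_items, rng):
        from upfdiet.synthetic import GeneratorConfig, generate_responses
        cfg = GeneratorConfig(n_subjects=8, missing_rate=0.0)
        _, unmasked, _ = generate_responses(cfg, instrument, food_items,
                                            seed=3)
        profiles = [build_profile(r, food_items, instrument)
                    for r in unmasked]
        tab = group_share_table(profiles)
        for col in tab.columns:
            if col.endswith("_pct"):
                assert tab.loc["TOTAL", col] == pytest.approx(100.0,
                                                              abs=1e-9)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            group_share_table([])
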