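"""Default parameter tables for the demonstration landscape.

Everything here is an editable config default, not a constant of the method:
the valuation is driven entirely by :class:`esvscape.valuation.EconomicParams`
and :class:`esvscape.valuation.HabitatParams`, and real studies supply their
own yearbook prices and equivalent-factor tables.  The numbers below are
round, plausible magnitudes for a north-Chinese coastal prefecture (grain
6000 kg/ha at 2.5 CNY/kg, reservoir cost ~6 CNY/m3, social cost of carbon
~1170 CNY/t C) with equivalent factors in the style of the Chinese
unit-area equivalent tables (one equivalent = 1/7 of grain output value).
"""

from __future__ import annotations

from .valuation import EconomicParams, FoodItem, HabitatParams

__all__ = ["default_economic_params", "default_habitat_params"]


def default_economic_params() -> EconomicParams:
    return EconomicParams(
        food_items={
            "dry farm": [FoodItem(4.5, 2.4, 0.35)],
            "paddy field": [FoodItem(6.5, 2.8, 0.35)],
            "fish farming": [FoodItem(8.0, 12.0, 0.30)],
            "grassland": [FoodItem(0.8, 6.0, 0.30)],
        },
        carbon_cost=1170.0,
        oxygen_cost=400.0,
        reservoir_cost=6.11,
        sediment_deposit_ratio=0.24,
        soil_bulk_density=1.25,
        soil_thickness=0.5,
        forestry_income=3000.0,
        grain_yield=6000.0,
        grain_price=2.5,
        equivalent_A={
            "forest": 2.5, "grassland": 1.5, "wetland": 3.5, "water": 2.5,
            "ocean": 1.0, "mudflat": 1.0, "moor": 1.2, "shrubbery": 2.0,
            "paddy field": 0.4, "dry farm": 0.2, "fish farming": 0.6,
            "salt pan": 0.1, "other land use": 0.1, "building": 0.02,
        },
        equivalent_L={
            "forest": 1.2, "grassland": 0.7, "wetland": 2.0, "water": 2.0,
            "ocean": 1.0, "mudflat": 0.6, "moor": 0.8, "shrubbery": 1.0,
            "paddy field": 0.1, "dry farm": 0.1, "fish farming": 0.3,
            "salt pan": 0.05, "other land use": 0.05, "building": 0.01,
        },
        tourism_local=1.6,  # tourism-heavy coastal city: above national mean
        tourism_national=1.0,
    )


def default_habitat_params() -> HabitatParams:
    farm = {"dry farm", "paddy field"}
    return HabitatParams(
        suitability={
            "forest": 1.0, "shrubbery": 0.9, "wetland": 0.9, "grassland": 0.8,
            "water": 0.8, "ocean": 0.7, "mudflat": 0.6, "moor": 0.6,
            "paddy field": 0.4, "dry farm": 0.3, "fish farming": 0.3,
            "other land use": 0.3, "salt pan": 0.2, "building": 0.0,
        },
        threats={
            "building": {"classes": ["building"], "weight": 1.0, "max_distance": 5000.0},
            "farmland": {"classes": sorted(farm), "weight": 0.7, "max_distance": 3000.0},
            "aquaculture": {"classes": ["fish farming"], "weight": 0.5, "max_distance": 2000.0},
        },
        sensitivity={
            "forest": {"building": 0.9, "farmland": 0.6, "aquaculture": 0.2},
            "shrubbery": {"building": 0.8, "farmland": 0.5, "aquaculture": 0.2},
            "grassland": {"building": 0.7, "farmland": 0.6, "aquaculture": 0.2},
            "wetland": {"building": 0.9, "farmland": 0.7, "aquaculture": 0.5},
            "water": {"building": 0.7, "farmland": 0.5, "aquaculture": 0.5},
            "ocean": {"building": 0.5, "farmland": 0.2, "aquaculture": 0.6},
            "mudflat": {"building": 0.8, "farmland": 0.5, "aquaculture": 0.6},
            "moor": {"building": 0.7, "farmland": 0.5, "aquaculture": 0.3},
            "paddy field": {"building": 0.3, "farmland": 0.0, "aquaculture": 0.1},
            "dry farm": {"building": 0.3, "farmland": 0.0, "aquaculture": 0.1},
            "fish farming": {"building": 0.3, "farmland": 0.1, "aquaculture": 0.0},
            "salt pan": {"building": 0.2, "farmland": 0.1, "aquaculture": 0.1},
            "other land use": {"building": 0.2, "farmland": 0.1, "aquaculture": 0.1},
            "building": {"building": 0.0, "farmland": 0.0, "aquaculture": 0.0},
        },
        z=2.5,
    )
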