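"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from foodtax.mrio import CharacterizationTable, MRIOSystem, build_account
from foodtax.synthdata import (
    SyntheticConfig,
    gen_household_survey,
    gen_toy_mrio,
    gen_vat_table,
)


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    return SyntheticConfig(
        n_households=400, n_countries=2, n_categories=4, n_regions=4, n_sectors=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_survey(small_cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return gen_household_survey(small_cfg)


@pytest.fixture(scope="session")
def toy_system() -> MRIOSystem:
    return gen_toy_mrio(3, 6, seed=3)


@pytest.fixture(scope="session")
def char_table(toy_system) -> CharacterizationTable:
    return CharacterizationTable.default_for_regions(toy_system.region_labels, seed=5)


@pytest.fixture(scope="session")
def toy_account(toy_system, char_table):
    return build_account(toy_system, char_table)


@pytest.fixture(scope="session")
def toy_vat(toy_system):
    cats, meat = _toy_categories()
    return gen_vat_table(
        n_countries=len(toy_system.region_labels),
        share_with_reduction=2 / 3,
        seed=7,
        categories=cats,
        meat_categories=meat,
        countries=toy_system.region_labels,
    )


def _toy_categories():
    from foodtax.synthdata import default_categories

    return default_categories(10)


def make_system_1x1(a: float, s: float) -> MRIOSystem:
    """Minimal single-node system with one stressor row (CO2)."""
    idx = pd.MultiIndex.from_product([["R00"], ["S00"]], names=["region", "sector"])
    sat = pd.DataFrame([[s]], index=pd.Index(["CO2"], name="stressor"), columns=idx)
    return MRIOSystem(
        region_labels=["R00"],
        sector_labels=["S00"],
        tech_coefficients=np.array([[a]]),
        household_demand={"R00": np.array([1.0])},
        satellite=sat,
        food_concordance={"S00": "beef"},
    )
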