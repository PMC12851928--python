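"""Cleaning filters, nearest-neighbour imputation and unit-value adjustment."""

import numpy as np
import pandas as pd
import pytest

from foodtax.surveyprep import (
    _impute_from_pool,
    adjust_unit_values,
    aggregate_items,
    clean_households,
    impute_cross_country,
    impute_within_country,
    unit_values,
)
from foodtax.synthdata import DEMOGRAPHICS


def make_table(rows: list[dict]) -> pd.DataFrame:
    """Minimal household table; rows give per-item exp/qty overrides."""
    base = []
    for i, row in enumerate(rows):
        rec = {
            "household_id": f"X_{i:04d}",
            "country": row.get("country", "C00"),
            "subregion": 0,
            **{d: row.get(d, 0) for d in DEMOGRAPHICS},
            "weight": row.get("weight", 1.0),
            "total_expenditure": row.get("total_expenditure", 100.0),
            "exp_a": row.get("exp_a", 10.0),
            "qty_a": row.get("qty_a", 5.0),
            "exp_b": row.get("exp_b", 10.0),
            "qty_b": row.get("qty_b", 4.0),
        }
        rec["total_food_expenditure"] = row.get(
            "total_food_expenditure", rec["exp_a"] + rec["exp_b"]
        )
        base.append(rec)
    return pd.DataFrame(base)


class TestCleanHouseholds:
    @pytest.mark.parametrize(
        "row, rule",
        [
            ({"exp_a": -1.0}, 1),
            ({"exp_a": 0.0, "qty_a": 2.0}, 2),
            ({"total_food_expenditure": 80.0, "total_expenditure": 100.0}, 3),
            ({"exp_a": 0.0, "qty_a": 0.0, "exp_b": 0.0, "qty_b": 0.0}, 4),
        ],
    )
    def test_each_rule_fires_in_order(self, row, rule):
        table = make_table([{}, row])
        clean, log = clean_households(table)
        assert len(clean) == 1
        fired = {e["rule"]: e["excluded"] for e in log.entries}
        assert fired[rule] == 1
        assert sum(v for k, v in fired.items() if k != rule) == 0

    def test_clean_table_passes_through_with_empty_log(self):
        table = make_table([{}, {}, {}])
        clean, log = clean_households(table)
        pd.testing.assert_frame_equal(clean, table)
        assert log.total_excluded == 0

    def test_idempotent(self):
        table = make_table([{}, {"exp_a": -1.0}, {"total_food_expenditure": 90.0}])
        once, _ = clean_households(table)
        twice, log2 = clean_households(once)
        pd.testing.assert_frame_equal(once, twice)
        assert log2.total_excluded == 0

    def test_jsonl_log_roundtrip(self, tmp_path):
        _, log = clean_households(make_table([{}, {"exp_a": -2.0}]))
        path = tmp_path / "log.jsonl"
        log.to_jsonl(path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 4  # one record per rule


class TestImputation:
    def test_inverse_distance_weighting_hand_case(self):
        """Donors at distances (1, 2) with quantities (2, 4) and the target's
        expenditure: weighted mean (2*1 + 4*0.5) / 1.5 = 8/3."""
        target = make_table([{"exp_a": 10.0, "qty_a": 0.0}])
        # one covariate differs: place donors at relative distances 1 and 2
        donors = make_table(
            [
                {"exp_a": 10.0, "qty_a": 2.0, "weight": 1.0},
                {"exp_a": 10.0, "qty_a": 4.0, "weight": 1.0},
            ]
        )
        donors.loc[0, "age_gt45"] = 1
        donors.loc[1, "age_gt45"] = 2  # twice as far in the single
        # informative dimension (standardization preserves the ratio)
        out = _impute_from_pool(target, donors, "a", k=2)
        assert out[0] == pytest.approx(8.0 / 3.0)

    def test_equal_donors_reproduce_quantity(self):
        target = make_table([{"exp_a": 10.0, "qty_a": 0.0}])
        donors = make_table([{"exp_a": 10.0, "qty_a": 7.0}] * 5)
        out = _impute_from_pool(target, donors, "a", k=5)
        assert out[0] == pytest.approx(7.0)

    def test_expenditure_scaling_single_donor(self):
        target = make_table([{"exp_a": 30.0, "qty_a": 0.0}])
        donor = make_table([{"exp_a": 10.0, "qty_a": 2.0}])
        out = _impute_from_pool(target, donor, "a", k=1)
        assert out[0] == pytest.approx(6.0)  # 2 * (30 / 10)

    def test_small_pool_warns_and_uses_all(self):
        target = make_table([{"exp_a": 10.0, "qty_a": 0.0}])
        donors = make_table([{"exp_a": 10.0, "qty_a": 3.0}] * 2)
        with pytest.warns(UserWarning, match="donor pool"):
            out = _impute_from_pool(target, donors, "a", k=10)
        assert out[0] == pytest.approx(3.0)

    def test_empty_pool_raises(self):
        target = make_table([{"exp_a": 10.0, "qty_a": 0.0}])
        donors = make_table([]) if False else make_table([{}]).iloc[:0]
        with pytest.raises(ValueError, match="empty donor pool"):
            _impute_from_pool(target, donors, "a", k=3)

    def test_within_country_only_fills_zero_quantity_rows(self):
        table = make_table(
            [
                {"exp_a": 10.0, "qty_a": 5.0},
                {"exp_a": 10.0, "qty_a": 0.0},
                {"exp_a": 0.0, "qty_a": 0.0},
            ]
        )
        out = impute_within_country(table, k=1)
        assert out.loc[0, "qty_a"] == 5.0       # observed untouched
        assert out.loc[1, "qty_a"] > 0.0        # imputed
        assert out.loc[2, "qty_a"] == 0.0       # zero expenditure stays zero

    def test_within_country_noop_without_targets(self):
        table = make_table([{}, {}])
        out = impute_within_country(table)
        pd.testing.assert_frame_equal(out, table)

    def test_cross_country_unrecorded_item(self):
        rows = [{"country": "C00", "exp_a": 12.0} for _ in range(3)]
        rows += [{"country": "C01", "exp_a": 10.0, "qty_a": 2.0} for _ in range(4)]
        table = make_table(rows)
        table.loc[table.country == "C00", "qty_a"] = np.nan
        table.loc[table.index[1], "exp_a"] = 0.0  # zero-expenditure target
        regions = {"C00": "west", "C01": "west"}
        out = impute_cross_country(table, regions, k=4)
        c00 = out[out.country == "C00"]
        assert not c00["qty_a"].isna().any()
        assert c00.iloc[1]["qty_a"] == 0.0
        assert (c00[c00["exp_a"] > 0]["qty_a"] > 0).all()
        # scaling: donors all have qty 2 at exp 10, target exp 12 -> 2.4
        assert c00.iloc[0]["qty_a"] == pytest.approx(2.0 * 12.0 / 10.0)

    def test_cross_country_needs_region_map(self):
        table = make_table([{"country": "C00"}])
        table["qty_a"] = np.nan
        with pytest.raises(ValueError, match="macro-region"):
            impute_cross_country(table, {})

    def test_imputation_beats_country_mean_on_structured_data(self):
        """When quantities depend on covariates, nearest-neighbour matching
        has lower RMSE than imputing the country mean."""
        rng = np.random.default_rng(42)
        n = 400
        z = rng.integers(0, 2, size=(n, 2)).astype(float)
        latent_q = 2.0 + 3.0 * z[:, 0] + 1.5 * z[:, 1] + rng.normal(0, 0.2, n)
        exp_a = latent_q * (1.0 + rng.normal(0, 0.05, n))
        rows = []
        for i in range(n):
            rows.append(
                {
                    "exp_a": exp_a[i],
                    "qty_a": latent_q[i],
                    "age_gt45": z[i, 0],
                    "high_income": z[i, 1],
                }
            )
        table = make_table(rows)
        mask = rng.random(n) < 0.25
        table.loc[mask, "qty_a"] = 0.0
        out = impute_within_country(table, k=10)
        imputed = out.loc[mask, "qty_a"].to_numpy()
        truth = latent_q[mask]
        rmse_nn = np.sqrt(np.mean((imputed - truth) ** 2))
        rmse_mean = np.sqrt(np.mean((latent_q[~mask].mean() - truth) ** 2))
        assert rmse_nn < rmse_mean


class TestAggregateItems:
    def test_identity_map_keeps_values(self):
        table = make_table([{}, {}])
        out = aggregate_items(table, {"a": "a", "b": "b"})
        assert np.allclose(out["exp_a"], table["exp_a"])
        assert np.allclose(out["qty_b"], table["qty_b"])

    def test_two_items_merge(self):
        table = make_table([{"exp_a": 3.0, "exp_b": 2.0, "qty_a": 1.0, "qty_b": 2.0}])
        out = aggregate_items(table, {"a": "food", "b": "food"})
        assert out.loc[0, "exp_food"] == pytest.approx(5.0)
        assert out.loc[0, "qty_food"] == pytest.approx(3.0)

    def test_grand_total_invariance_random_map(self):
        rng = np.random.default_rng(1)
        table = make_table([{"exp_a": rng.uniform(1, 5), "exp_b": rng.uniform(1, 5)} for _ in range(10)])
        out = aggregate_items(table, {"a": "x", "b": "x"})
        exp_cols_in = table[["exp_a", "exp_b"]].sum(axis=1)
        assert np.allclose(out["exp_x"], exp_cols_in)

    def test_unmapped_item_raises(self):
        with pytest.raises(KeyError, match="not in concordance"):
            aggregate_items(make_table([{}]), {"a": "x"})


class TestUnitValues:
    def test_simple_ratio_and_missing(self):
        table = make_table([{"exp_a": 10.0, "qty_a": 4.0, "exp_b": 5.0, "qty_b": 0.0}])
        uv = unit_values(table)
        assert uv.loc[0, "a"] == pytest.approx(2.5)
        assert np.isnan(uv.loc[0, "b"])

    def test_scale_invariance(self):
        t1 = make_table([{"exp_a": 10.0, "qty_a": 4.0}])
        t2 = make_table([{"exp_a": 20.0, "qty_a": 8.0}])
        assert unit_values(t1).loc[0, "a"] == unit_values(t2).loc[0, "a"]


class TestAdjustUnitValues:
    @staticmethod
    def _uv_setup(n=60, seed=0, gamma=0.0):
        rng = np.random.default_rng(seed)
        income = rng.integers(0, 2, n).astype(float)
        supply = 2.0 + rng.normal(0, 0.3, n)
        uv = supply + gamma * income + rng.normal(0, 0.05, n)
        cov = pd.DataFrame({"high_income": income, "age_gt45": rng.integers(0, 2, n)})
        return pd.DataFrame({"a": uv}), cov, np.ones(n), supply

    def test_constant_covariates_passthrough_exactly(self):
        uv, cov, w, _ = self._uv_setup()
        cov["high_income"] = 1.0
        cov["age_gt45"] = 1.0
        with pytest.warns(UserWarning, match="collinear"):
            prices, model = adjust_unit_values(uv, cov, w)
        # alpha + resid == UV (up to the positivity floor on the low tail)
        assert np.allclose(prices["a"], np.maximum(uv["a"], model.floor["a"]))

    def test_below_min_obs_passes_raw_through(self):
        uv, cov, w, _ = self._uv_setup(n=29)
        prices, model = adjust_unit_values(uv, cov, w, min_obs=30)
        assert not model.fitted["a"]
        assert np.allclose(prices["a"], np.maximum(uv["a"], model.floor["a"]))

    def test_quality_purge_improves_supply_correlation(self):
        uv, cov, w, supply = self._uv_setup(n=500, seed=3, gamma=0.8)
        prices, model = adjust_unit_values(uv, cov, w)
        assert model.fitted["a"]
        r_adj = np.corrcoef(prices["a"], supply)[0, 1]
        r_raw = np.corrcoef(uv["a"], supply)[0, 1]
        assert r_adj > r_raw

    def test_invariant_to_covariate_shift(self):
        uv, cov, w, _ = self._uv_setup(n=200, seed=5, gamma=0.5)
        p1, _ = adjust_unit_values(uv, cov, w)
        cov2 = cov.copy()
        cov2["high_income"] = cov2["high_income"] + 7.0
        p2, _ = adjust_unit_values(uv, cov2, w)
        assert np.allclose(p1["a"], p2["a"])

    def test_missing_households_get_country_median(self):
        uv, cov, w, _ = self._uv_setup(n=100, seed=1)
        uv.loc[3, "a"] = np.nan
        prices, _ = adjust_unit_values(uv, cov, w)
        fitted = prices["a"].drop(3)
        assert prices.loc[3, "a"] == pytest.approx(np.median(fitted))

    def test_positivity_floor(self):
        uv, cov, w, _ = self._uv_setup(n=200, seed=2)
        uv.loc[0, "a"] = 0.001  # extreme low value pulled up by the floor
        prices, model = adjust_unit_values(uv, cov, w)
        assert (prices["a"] > 0).all()
        assert (prices["a"] >= model.floor["a"] - 1e-12).all()

    def test_adjust_false_returns_raw(self):
        uv, cov, w, _ = self._uv_setup(n=100, seed=4, gamma=0.9)
        prices, model = adjust_unit_values(uv, cov, w, adjust=False)
        assert not model.fitted["a"]
        assert np.allclose(prices["a"], np.maximum(uv["a"], model.floor["a"]))
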