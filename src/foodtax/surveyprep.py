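"""Survey cleaning, quantity imputation and quality-adjusted unit values.

Household budget surveys record expenditures and purchased quantities per
food item.  Before a demand system can be estimated the microdata need
(1) plausibility filters, (2) imputation of missing quantities by
nearest-neighbour matching, (3) aggregation of items into food categories,
and (4) price proxies: unit values (expenditure per unit purchased) purged
of quality variation by regressing them on household characteristics and
keeping only the constant plus the residual.

Exclusion rules, applied in order:

1. negative expenditure on any item;
2. zero expenditure combined with a positive quantity on any item;
3. food expenditure share of total expenditure above 75%;
4. zero total food expenditure.

Two imputation algorithms share one weighting rule (inverse-distance mean
of the k = 10 nearest neighbours, rescaled by the ratio of the target's
expenditure to the distance-weighted mean donor expenditure): the
cross-country variant fills items whose quantities were never recorded in a
country, drawing donors from other countries of the same macro-region; the
within-country variant fills implausible (positive expenditure, zero
quantity) records from domestic donors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.neighbors import NearestNeighbors

from .synthdata import DEMOGRAPHICS

__all__ = [
    "ExclusionLog",
    "UnitValueModel",
    "clean_households",
    "impute_cross_country",
    "impute_within_country",
    "aggregate_items",
    "unit_values",
    "adjust_unit_values",
    "prepare_country_prices",
]

DIST_FLOOR = 1e-9
MIN_OBS_FOR_ADJUSTMENT = 30
MATCH_COVARIATES = list(DEMOGRAPHICS)

RULES = [
    (1, "negative_expenditure"),
    (2, "zero_expenditure_positive_quantity"),
    (3, "food_share_above_75pct"),
    (4, "zero_total_food_expenditure"),
]


@dataclass
class ExclusionLog:
    """Structured audit trail of the cleaning filters."""

    entries: list[dict] = field(default_factory=list)

    def record(self, rule: int, name: str, excluded: int, remaining: int) -> None:
        self.entries.append(
            {"rule": rule, "name": name, "excluded": int(excluded), "remaining": int(remaining)}
        )

    @property
    def total_excluded(self) -> int:
        return sum(e["excluded"] for e in self.entries)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(json.dumps(e) + "\n")


def _item_columns(table: pd.DataFrame) -> list[str]:
    return [c[4:] for c in table.columns if c.startswith("exp_")]


def clean_households(raw: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the four exclusion rules in order; idempotent on clean data."""
    items = _item_columns(raw)
    exp = raw[[f"exp_{i}" for i in items]].to_numpy(dtype=float)
    qty = raw[[f"qty_{i}" for i in items]].to_numpy(dtype=float)
    log = ExclusionLog()
    keep = np.ones(len(raw), dtype=bool)

    rule1 = (exp < 0).any(axis=1)
    drop = keep & rule1
    keep &= ~rule1
    log.record(1, RULES[0][1], drop.sum(), keep.sum())

    with np.errstate(invalid="ignore"):
        rule2 = ((exp == 0) & (qty > 0)).any(axis=1)
    drop = keep & rule2
    keep &= ~rule2
    log.record(2, RULES[1][1], drop.sum(), keep.sum())

    food = raw["total_food_expenditure"].to_numpy(dtype=float)
    total = raw["total_expenditure"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rule3 = food / total > 0.75
    drop = keep & rule3
    keep &= ~rule3
    log.record(3, RULES[2][1], drop.sum(), keep.sum())

    rule4 = exp.sum(axis=1) == 0.0
    drop = keep & rule4
    keep &= ~rule4
    log.record(4, RULES[3][1], drop.sum(), keep.sum())

    return raw.loc[keep].reset_index(drop=True), log


def _match_features(table: pd.DataFrame, item: str) -> np.ndarray:
    cols = [c for c in MATCH_COVARIATES if c in table.columns]
    feats = table[cols].to_numpy(dtype=float)
    exp = table[f"exp_{item}"].to_numpy(dtype=float)
    return np.column_stack([feats, np.log1p(exp)])


def _standardize(pool: np.ndarray, targets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    both = np.vstack([pool, targets])
    mu = both.mean(axis=0)
    sd = both.std(axis=0)
    sd[sd == 0.0] = 1.0
    return (pool - mu) / sd, (targets - mu) / sd


def _impute_from_pool(
    targets: pd.DataFrame,
    pool: pd.DataFrame,
    item: str,
    k: int,
) -> np.ndarray:
    """Inverse-distance-weighted quantity imputation with expenditure scaling.

    Ties at the k-th neighbour are all included with renormalized weights;
    exact-duplicate donors get a distance floor instead of infinite weight.
    Donor ordering is made deterministic by sorting the pool by household id.
    """
    pool = pool.sort_values("household_id", kind="stable").reset_index(drop=True)
    if len(pool) == 0:
        raise ValueError(f"empty donor pool for item {item!r}")
    k_eff = min(k, len(pool))
    if k_eff < k:
        warnings.warn(
            f"donor pool for item {item!r} has only {len(pool)} households "
            f"(requested k={k}); using all of them",
            stacklevel=2,
        )
    xp, xt = _standardize(_match_features(pool, item), _match_features(targets, item))
    nn = NearestNeighbors(n_neighbors=k_eff).fit(xp)
    dist, idx = nn.kneighbors(xt)

    donor_q = pool[f"qty_{item}"].to_numpy(dtype=float)
    donor_e = pool[f"exp_{item}"].to_numpy(dtype=float)
    target_e = targets[f"exp_{item}"].to_numpy(dtype=float)

    out = np.zeros(len(targets))
    # pairwise distances for tie detection at the k-th neighbour
    from scipy.spatial.distance import cdist

    full = cdist(xt, xp)
    for t in range(len(targets)):
        kth = dist[t, -1]
        sel = np.flatnonzero(full[t] <= kth + 1e-12)
        wts = 1.0 / np.maximum(full[t, sel], DIST_FLOOR)
        wts = wts / wts.sum()
        mean_q = float(wts @ donor_q[sel])
        mean_e = float(wts @ donor_e[sel])
        out[t] = mean_q * (target_e[t] / mean_e) if mean_e > 0 else mean_q
    return out


def impute_cross_country(
    tables: pd.DataFrame,
    regions: Mapping[str, str],
    k: int = 10,
) -> pd.DataFrame:
    """Fill items whose quantities were never recorded in a country.

    An item is flagged as never-recorded in country c when its quantity
    column is entirely missing (NaN) there.  Donors are households with
    positive expenditures and recorded positive quantities from the other
    countries of the same macro-region.  Positive-expenditure target
    households get the weighted-neighbour imputation; zero-expenditure
    households get zero quantities.
    """
    table = tables.copy()
    items = _item_columns(table)
    for country, sub in table.groupby("country", sort=True):
        region = regions.get(str(country))
        if region is None:
            raise ValueError(f"no macro-region assigned to country {country!r}")
        for item in items:
            qcol = f"qty_{item}"
            if not sub[qcol].isna().all():
                continue
            siblings = [c for c, r in regions.items() if r == region and c != country]
            pool = table[
                table["country"].isin(siblings)
                & (table[f"exp_{item}"] > 0)
                & (table[qcol] > 0)
                & table[qcol].notna()
            ]
            pos = sub[sub[f"exp_{item}"] > 0]
            if len(pos):
                table.loc[pos.index, qcol] = _impute_from_pool(pos, pool, item, k)
            zero_idx = sub.index[sub[f"exp_{item}"] == 0]
            table.loc[zero_idx, qcol] = 0.0
    return table


def impute_within_country(table: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Fill implausible (positive expenditure, zero quantity) records from
    domestic donors with positive expenditures and quantities; observed
    quantities are never altered."""
    table = table.copy()
    items = _item_columns(table)
    for country, sub in table.groupby("country", sort=True):
        for item in items:
            qcol = f"qty_{item}"
            targets = sub[(sub[f"exp_{item}"] > 0) & (sub[qcol] == 0)]
            if len(targets) == 0:
                continue
            pool = sub[(sub[f"exp_{item}"] > 0) & (sub[qcol] > 0)]
            table.loc[targets.index, qcol] = _impute_from_pool(targets, pool, item, k)
    return table


def aggregate_items(
    table: pd.DataFrame, concordance: Mapping[str, str]
) -> pd.DataFrame:
    """Aggregate item expenditures and quantities into food categories.

    Every item must be mapped exactly once; per-household expenditure totals
    are preserved by construction.
    """
    items = _item_columns(table)
    unmapped = [i for i in items if i not in concordance]
    if unmapped:
        raise KeyError(f"items not in concordance: {unmapped}")
    cats: dict[str, list[str]] = {}
    for item in items:
        cats.setdefault(concordance[item], []).append(item)
    base = table[[c for c in table.columns if not c.startswith(("exp_", "qty_"))]].copy()
    for cat, members in cats.items():
        base[f"exp_{cat}"] = table[[f"exp_{m}" for m in members]].sum(axis=1)
        base[f"qty_{cat}"] = table[[f"qty_{m}" for m in members]].sum(axis=1, skipna=False)
    return base


def unit_values(table: pd.DataFrame) -> pd.DataFrame:
    """Unit values UV = expenditure / quantity; missing where quantity is 0."""
    items = _item_columns(table)
    out = {}
    for item in items:
        e = table[f"exp_{item}"].to_numpy(dtype=float)
        q = table[f"qty_{item}"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            uv = np.where(q > 0, e / q, np.nan)
        out[item] = uv
    return pd.DataFrame(out, index=table.index)


@dataclass
class UnitValueModel:
    """Per-category quality-adjustment regressions for one country."""

    alpha: dict[str, float] = field(default_factory=dict)
    beta: dict[str, np.ndarray] = field(default_factory=dict)
    fitted: dict[str, bool] = field(default_factory=dict)
    floor: dict[str, float] = field(default_factory=dict)
    n_positive: dict[str, int] = field(default_factory=dict)


def _drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank == X.shape[1]:
        return X, names
    keep = sorted(piv[:rank])
    dropped = [names[i] for i in sorted(piv[rank:])]
    warnings.warn(f"dropping collinear unit-value covariates: {dropped}", stacklevel=2)
    return X[:, keep], [names[i] for i in keep]


def adjust_unit_values(
    uv: pd.DataFrame,
    covariates: pd.DataFrame,
    weights: pd.Series | np.ndarray,
    min_obs: int = MIN_OBS_FOR_ADJUSTMENT,
    adjust: bool = True,
) -> tuple[pd.DataFrame, UnitValueModel]:
    """Quality-purged prices p = alpha_hat + residual per household/category.

    Covariates are centred (weighted) before the regression so the adjusted
    price level equals the weighted mean unit value and the result is
    invariant to adding constants to covariates.  Categories with fewer
    than ``min_obs`` positive observations keep their raw unit values.
    Households without a unit value get the country median of the adjusted
    values; a positivity floor at the 1st percentile of raw unit values
    guards the logs taken downstream.  ``adjust=False`` skips the quality
    regression entirely (raw-unit-value robustness variant).
    """
    w = np.asarray(weights, dtype=float)
    model = UnitValueModel()
    prices = pd.DataFrame(index=uv.index, columns=uv.columns, dtype=float)
    for cat in uv.columns:
        vals = uv[cat].to_numpy(dtype=float)
        pos = np.isfinite(vals)
        npos = int(pos.sum())
        model.n_positive[cat] = npos
        adj = vals.copy()
        if adjust and npos >= min_obs:
            Xr = covariates.to_numpy(dtype=float)[pos]
            wp = w[pos]
            Xc = Xr - np.average(Xr, axis=0, weights=wp)
            names = list(covariates.columns)
            Xc, names = _drop_collinear(Xc, names)
            X = sm.add_constant(Xc, has_constant="add")
            res = sm.WLS(vals[pos], X, weights=wp).fit()
            alpha = float(res.params[0])
            resid = vals[pos] - res.fittedvalues
            adj[pos] = alpha + resid
            model.alpha[cat] = alpha
            model.beta[cat] = np.asarray(res.params[1:])
            model.fitted[cat] = True
        else:
            model.fitted[cat] = False
        if npos == 0:
            raise ValueError(f"no positive unit values at all for category {cat!r}")
        median = float(np.nanmedian(adj[pos]))
        adj[~pos] = median
        floor = float(np.nanpercentile(vals[pos], 1.0))
        floor = max(floor, DIST_FLOOR)
        model.floor[cat] = floor
        prices[cat] = np.maximum(adj, floor)
    return prices, model


def prepare_country_prices(
    table: pd.DataFrame,
    covariate_names: Iterable[str] = MATCH_COVARIATES,
    min_obs: int = MIN_OBS_FOR_ADJUSTMENT,
    adjust: bool = True,
) -> tuple[pd.DataFrame, dict[str, UnitValueModel]]:
    """Adjusted unit-value prices per country for a multi-country table."""
    all_prices = []
    models: dict[str, UnitValueModel] = {}
    for country, sub in table.groupby("country", sort=True):
        uv = unit_values(sub)
        cov = sub[list(covariate_names)]
        prices, model = adjust_unit_values(
            uv, cov, sub["weight"], min_obs=min_obs, adjust=adjust
        )
        models[str(country)] = model
        all_prices.append(prices)
    return pd.concat(all_prices).loc[table.index], models
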