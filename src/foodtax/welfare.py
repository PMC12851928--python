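"""Household welfare costs, tax revenues and monetized environmental benefits.

Because the demand system derives from an expenditure function, policy
welfare costs have a closed form: the log cost-of-living index

    log COL_h = (p1 - p0)' w_h0 + 1/2 (p1 - p0)' (A + B y_h) (p1 - p0)

is the extra log expenditure needed to keep pre-policy utility at
post-policy (log) prices — a first-order Stone term (purchasing power) plus
a second-order quadratic form (substitution, which dampens the loss).
Multiplying by the household's nominal food expenditure gives the euro cost;
positive values are welfare losses.

Tax-revenue accounting works on post-policy expenditures derived from the
Hicksian budget-share semi-elasticities (nominal food budgets are held
constant under the partial-system assumption): the change in VAT paid per
household, and the GHG levy collected on net-of-VAT post-policy
expenditures, which aggregates to the post-policy emission base times the
carbon price.  Footprint changes are monetized with social costs: GHG gases
valued globally (F-gases via their CO2-equivalent), nitrogen and phosphorus
valued only where impacts arise inside the home-region set, since no robust
global cost estimates exist for them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from collections.abc import Iterable

import numpy as np
import pandas as pd

from .easi import DemandObservations, EASIFit
from .mrio import DEFAULT_GWP100

__all__ = [
    "SocialCostTable",
    "WelfareResult",
    "cost_of_living",
    "post_policy_expenditures",
    "vat_revenue_change",
    "ghg_revenue",
    "monetize",
    "aggregate",
]

FGAS = ("SF6", "HFC", "PFC")


@dataclass
class SocialCostTable:
    """Social costs per substance in euro per unit.

    Keys: ``CO2``, ``CH4``, ``N2O`` (per tonne), ``fgas_co2e`` (per tonne
    CO2e of SF6/HFC/PFC), ``nitrogen`` and ``phosphorus`` (per kg).  The
    ``sources`` mapping documents where each value comes from; synthetic
    placeholders are flagged there.
    """

    costs: dict[str, float]
    sources: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.costs.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"social cost {k!r} must be finite and >= 0")

    def scaled(self, factor: float) -> "SocialCostTable":
        return SocialCostTable(
            costs={k: v * factor for k, v in self.costs.items()},
            sources=dict(self.sources),
        )


def cost_of_living(
    fit: EASIFit,
    obs: DemandObservations,
    dp_log: np.ndarray | pd.Series,
) -> tuple[np.ndarray, np.ndarray]:
    """Log cost-of-living index and its euro equivalent per household.

    Parameters
    ----------
    dp_log:
        Log price changes per category, ``p1 - p0 = ln(1 + dp/p)``.

    Returns
    -------
    (log_col, delta_col):
        ``log_col`` per household; ``delta_col = log_col * X_h`` with
        ``X_h`` the nominal food expenditure (same monetary units as the
        survey).  Zero price changes give exactly zero.
    """
    dp = np.asarray(dp_log, dtype=float)
    if dp.shape != (fit.n,):
        raise ValueError(f"dp_log must have length {fit.n}")
    w0 = obs.w
    stone = w0 @ dp
    quad_core = dp @ fit.A @ dp + (dp @ fit.B @ dp) * obs.y
    log_col = stone + 0.5 * quad_core
    x_nominal = np.exp(obs.x)
    return log_col, log_col * x_nominal


def post_policy_expenditures(
    obs: DemandObservations,
    fit: EASIFit,
    dpp_rel: np.ndarray | pd.Series,
    semi_p: np.ndarray | None = None,
) -> np.ndarray:
    """Post-policy expenditures per household and category (Hicksian update).

    Budget shares shift by the compensated semi-elasticity response
    ``dw_i = sum_j (dw_i/dp_j) (dp_j/p_j)`` while the nominal food budget
    stays fixed (partial-system assumption):

        x1_i = x0_i + X_total * dw_i.

    With zero price changes, or with fixed shares (zero semi-elasticities),
    expenditures are unchanged.  Negative results are floored at zero with
    a warning.
    """
    dpp = np.asarray(dpp_rel, dtype=float)
    if dpp.shape != (fit.n,):
        raise ValueError(f"dpp_rel must have length {fit.n}")
    x_total = np.exp(obs.x)
    x0 = obs.w * x_total[:, None]
    if semi_p is None:
        Phi = fit.Phi if fit.Phi is not None else np.ones_like(obs.w)
        semi_p = Phi[:, :, None] * (
            fit.A[None, :, :] + fit.B[None, :, :] * obs.y[:, None, None]
        )
    dw = semi_p @ dpp
    x1 = x0 + x_total[:, None] * dw
    if (x1 < 0).any():
        warnings.warn("negative post-policy expenditures floored at 0", stacklevel=2)
        x1 = np.maximum(x1, 0.0)
    return x1


def vat_revenue_change(
    x0: np.ndarray,
    x1: np.ndarray,
    rates_pre: np.ndarray | pd.Series,
    rates_post: np.ndarray | pd.Series,
) -> np.ndarray:
    """Change in VAT paid per household (baseline minus post-policy).

    Computed as ``sum_i (x0_i r0/(1+r0) - x1_i r1/(1+r1))``: a positive
    value means the household pays *less* VAT after the policy (a revenue
    loss for the government); the aggregate revenue gain reported to the
    government's perspective is the negative of the mean of this quantity.
    """
    r0 = np.asarray(rates_pre, dtype=float)
    r1 = np.asarray(rates_post, dtype=float)
    if (r0 < 0).any() or (r1 < 0).any():
        raise ValueError("VAT rates must be >= 0")
    return (x0 * (r0 / (1.0 + r0))).sum(axis=1) - (x1 * (r1 / (1.0 + r1))).sum(axis=1)


def ghg_revenue(
    x1: np.ndarray,
    rates_pre: np.ndarray | pd.Series,
    mu: np.ndarray | pd.Series,
    tau: float,
) -> np.ndarray:
    """GHG levy paid per household on net-of-VAT post-policy expenditures,
    ``sum_i x1_i / (1 + r0_i) * mu_i * tau``."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    r0 = np.asarray(rates_pre, dtype=float)
    m = np.asarray(mu, dtype=float)
    return (x1 / (1.0 + r0) * m).sum(axis=1) * tau


def monetize(
    delta: pd.DataFrame,
    costs: SocialCostTable,
    home_regions: Iterable[str],
    gwp100: dict[str, float] | None = None,
) -> dict[str, float]:
    """Monetized benefits (euro) of footprint changes.

    ``delta`` holds origin-resolved changes with a (measure, origin_region)
    or (country, measure, origin_region) row MultiIndex; negative changes
    (reductions) yield positive benefits.  GHG gases are valued globally —
    CO2, CH4 and N2O at their own social cost, F-gases via their
    CO2-equivalent at the ``fgas_co2e`` cost; nitrogen and phosphorus only
    for impacts originating inside ``home_regions``.
    """
    gwp = gwp100 or DEFAULT_GWP100
    home = set(home_regions)
    required = ["CO2", "CH4", "N2O", "fgas_co2e", "nitrogen", "phosphorus"]
    missing = [k for k in required if k not in costs.costs]
    if missing:
        raise KeyError(f"social-cost table lacks entries: {missing}")

    levels = delta.index.names
    def measure_total(measure: str, only_home: bool = False) -> float:
        try:
            sub = delta.xs(measure, level="measure")
        except KeyError:
            return 0.0
        if only_home:
            lvl = "origin_region"
            mask = sub.index.get_level_values(lvl).isin(home) if lvl in (sub.index.names or []) else sub.index.isin(home)
            sub = sub[mask]
        return float(sub.to_numpy().sum())

    benefits: dict[str, float] = {}
    ghg_benefit = 0.0
    for gas in ("CO2", "CH4", "N2O"):
        ghg_benefit += -measure_total(f"gas:{gas}") * costs.costs[gas]
    fgas_co2e = sum(-measure_total(f"gas:{g}") * gwp[g] for g in FGAS)
    ghg_benefit += fgas_co2e * costs.costs["fgas_co2e"]
    benefits["ghg"] = ghg_benefit
    benefits["nitrogen"] = -measure_total("nitrogen", only_home=True) * costs.costs["nitrogen"]
    benefits["phosphorus"] = -measure_total("phosphorus", only_home=True) * costs.costs["phosphorus"]
    benefits["total"] = sum(benefits.values())
    return benefits


@dataclass
class WelfareResult:
    """Per-household welfare and revenue outcomes for one scenario."""

    scenario: str
    household_id: np.ndarray
    log_col: np.ndarray
    delta_col: np.ndarray
    delta_t_vat: np.ndarray
    delta_t_ghg: np.ndarray
    weights: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "household_id": self.household_id,
                "scenario": self.scenario,
                "log_col": self.log_col,
                "delta_col": self.delta_col,
                "delta_t_vat": self.delta_t_vat,
                "delta_t_ghg": self.delta_t_ghg,
                "weight": self.weights,
            }
        )


def aggregate(
    values: np.ndarray,
    weights: np.ndarray,
    mean_household_size: float = 2.3,
) -> dict[str, float]:
    """Weighted mean per household-equivalent and per capita.

    Weights are sample weights (population representativeness); the
    per-capita figure divides by the configured mean household size.
    Invariant to rescaling all weights by a constant.
    """
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    mean = float(np.average(np.asarray(values, dtype=float), weights=w))
    return {
        "per_household": mean,
        "per_capita": mean / mean_household_size,
    }
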