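"""Tax-policy simulation: price changes, demand responses, footprint changes.

Two consumption-tax scenarios are simulated under full pass-through:

* **VAT reform** — the reduced VAT rate on meat categories is replaced by
  the country's standard rate, so meat prices rise by
  ``(1 + r_standard) / (1 + r_reduced) - 1`` and non-meat prices are
  unchanged.
* **GHG price** — a uniform levy of ``tau`` euro per tCO2e on all food
  categories, translated into relative price changes through the monetary
  GHG emission intensity ``mu = E / X`` (emissions per euro of demand):
  ``dp/p = mu * tau``.  Because ``mu * tau * X = E * tau`` the levy equals
  the product's emissions times the carbon price — a Pigouvian tax on the
  demand footprint.  The levy itself is not subject to VAT.

Relative demand changes follow from the country-mean Marshallian price
elasticity matrix, ``dq/q = eta dp/p``, and footprint changes scale the
baseline account proportionally, ``dg = (dq/q) g``, per country, category
and indicator, with reductions allocated to producing regions in proportion
to where impacts arise in the status quo.  The GHG price achieving the same
total GHG reduction as the VAT reform is solved for; the mapping
``tau -> dGHG`` is linear in this model, which the solver verifies before
using the closed form (a bracketing root-finder is the fallback for
nonlinear configurations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mrio import NON_FOOD, FootprintAccount
from .synthdata import VATTable

__all__ = [
    "PolicyScenario",
    "SimulationResult",
    "vat_price_changes",
    "ghg_price_changes",
    "demand_changes",
    "footprint_changes",
    "solve_equivalent_ghg_price",
    "simulate_scenario",
]


@dataclass
class PolicyScenario:
    """A policy to simulate.

    ``kind`` is ``"vat_reform"`` or ``"ghg_price"``; the GHG scenario needs
    a price ``tau_ghg`` (euro per tCO2e) and the country x category GHG
    demand intensities ``mu`` (tCO2e per euro).  Pass-through to consumer
    prices is complete.
    """

    kind: str
    vat: VATTable
    tau_ghg: float | None = None
    mu: pd.DataFrame | None = None
    pass_through: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("vat_reform", "ghg_price"):
            raise ValueError("kind must be 'vat_reform' or 'ghg_price'")
        if self.kind == "ghg_price":
            if self.tau_ghg is None or self.mu is None:
                raise ValueError("ghg_price scenario needs tau_ghg and mu")
            if self.tau_ghg < 0:
                raise ValueError("tau_ghg must be >= 0")
        if self.pass_through != 1.0:
            raise ValueError("only complete pass-through is modelled")


def vat_price_changes(vat: VATTable) -> pd.DataFrame:
    """Relative consumer-price changes of removing reduced meat VAT rates.

    The same relative increase applies to every meat category of a country
    (it depends only on the standard and reduced rates); non-meat categories
    are unaffected.
    """
    out = pd.DataFrame(0.0, index=vat.countries, columns=vat.applied.columns)
    for cat in vat.meat_categories:
        out[cat] = (1.0 + vat.standard) / (1.0 + vat.applied[cat]) - 1.0
    return out


def ghg_price_changes(mu: pd.DataFrame, tau: float) -> pd.DataFrame:
    """Relative price changes dp/p = mu * tau of a uniform GHG price."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if (mu.to_numpy() < 0).any():
        raise ValueError("intensities must be >= 0")
    return mu * tau


def demand_changes(eta: pd.DataFrame, dpp: pd.Series) -> pd.Series:
    """Relative quantity changes dq/q = eta dp/p for one country.

    Cross-price terms mean that categories without a price change can still
    move (substitutes rise, complements fall); no sign constraint applies.
    Changes below -100% are floored (quantities cannot turn negative).
    """
    if list(eta.columns) != list(dpp.index):
        raise ValueError("elasticity matrix and price-change vector misaligned")
    dqq = pd.Series(eta.to_numpy() @ dpp.to_numpy(), index=eta.index)
    if (dqq < -1.0).any():
        warnings.warn("demand change below -100% floored", stacklevel=2)
        dqq = dqq.clip(lower=-1.0)
    return dqq


@dataclass
class SimulationResult:
    """Price, demand and footprint changes of one scenario."""

    kind: str
    price_changes: pd.DataFrame    # country x category (dp/p)
    demand_changes: pd.DataFrame   # country x category (dq/q)
    delta: pd.DataFrame            # (country, measure, origin_region) x category
    tau_ghg: float | None = None

    def total_change(self, measure: str) -> float:
        """Aggregate change over all countries, categories and origins."""
        sub = self.delta.xs(measure, level="measure")
        cols = [c for c in sub.columns if c != NON_FOOD]
        return float(sub[cols].to_numpy().sum())

    def reduction(self, measure: str) -> float:
        return -self.total_change(measure)

    def reductions(self, measures: list[str]) -> dict[str, float]:
        return {m: self.reduction(m) for m in measures}

    def to_tidy(self) -> pd.DataFrame:
        out = self.delta.stack()
        out.index.names = ["country", "measure", "origin_region", "category"]
        return out.rename("change").reset_index()


def footprint_changes(
    dqq: pd.DataFrame, baseline: FootprintAccount, kind: str = "",
    price_changes: pd.DataFrame | None = None, tau_ghg: float | None = None,
) -> SimulationResult:
    """Scale the baseline account by the relative demand changes.

    ``dqq`` is a country x category table; every (measure, origin) row of a
    country's account is scaled by the category's relative change, so the
    spatial allocation of reductions mirrors the status quo.
    """
    data = baseline.data
    countries = data.index.get_level_values("country")
    missing = [c for c in dqq.index if c not in set(countries)]
    if missing:
        raise KeyError(f"baseline account lacks countries: {missing}")
    cats = [c for c in data.columns if c != NON_FOOD]
    lacking = [c for c in cats if c not in dqq.columns]
    if lacking:
        raise KeyError(f"demand-change table lacks categories: {lacking}")

    factors = dqq.reindex(index=countries.unique(), columns=data.columns).fillna(0.0)
    scale = factors.loc[countries].to_numpy()
    delta = pd.DataFrame(
        data.to_numpy() * scale, index=data.index, columns=data.columns
    )
    return SimulationResult(
        kind=kind,
        price_changes=price_changes if price_changes is not None else dqq * 0.0,
        demand_changes=dqq,
        delta=delta,
        tau_ghg=tau_ghg,
    )


def simulate_scenario(
    scenario: PolicyScenario,
    etas: dict[str, pd.DataFrame],
    baseline: FootprintAccount,
) -> SimulationResult:
    """Run one scenario end to end at country-mean elasticities."""
    if scenario.kind == "vat_reform":
        dpp = vat_price_changes(scenario.vat)
    else:
        dpp = ghg_price_changes(scenario.mu, scenario.tau_ghg)
    dqq = pd.DataFrame(
        {c: demand_changes(etas[c], dpp.loc[c]) for c in dpp.index}
    ).T
    dqq.index.name = "country"
    return footprint_changes(
        dqq, baseline, kind=scenario.kind, price_changes=dpp,
        tau_ghg=scenario.tau_ghg,
    )


def solve_equivalent_ghg_price(
    target_ghg_change: float,
    mu: pd.DataFrame,
    etas: dict[str, pd.DataFrame],
    baseline: FootprintAccount,
    vat: VATTable,
    tau_max: float = 10_000.0,
    rtol: float = 1e-6,
) -> float:
    """GHG price achieving the same total GHG change as the VAT reform.

    ``dGHG(tau)`` is linear in tau under the model's composition of price
    rule, elasticity response and proportional footprint scaling; linearity
    is verified on two probe points (relative curvature below 1e-10) and the
    closed form ``tau* = target / slope`` is used, otherwise a Brent-style
    bracketing root search.  A VAT reform with no GHG reduction yields
    ``tau* = 0``.
    """
    if target_ghg_change == 0.0:
        return 0.0

    def ghg_change(tau: float) -> float:
        scn = PolicyScenario(kind="ghg_price", vat=vat, tau_ghg=tau, mu=mu)
        return simulate_scenario(scn, etas, baseline).total_change("ghg")

    g1 = ghg_change(1.0)
    g2 = ghg_change(2.0)
    if g1 == 0.0:
        raise ValueError("GHG price has no effect on emissions; target unreachable")
    if abs(g2 - 2.0 * g1) <= 1e-10 * abs(g1):
        tau_star = target_ghg_change / g1
    else:
        from scipy.optimize import brentq

        lo, hi = 0.0, tau_max
        f = lambda t: ghg_change(t) - target_ghg_change  # noqa: E731
        if f(lo) * f(hi) > 0:
            raise ValueError(f"target not reachable with tau <= {tau_max}")
        tau_star = brentq(f, lo, hi, xtol=1e-10, rtol=1e-12)
    if not (0.0 <= tau_star <= tau_max):
        raise ValueError(f"target not reachable with tau <= {tau_max}")
    achieved = ghg_change(tau_star)
    if abs(achieved - target_ghg_change) > rtol * abs(target_ghg_change):
        raise RuntimeError("equivalence solver failed to meet tolerance")
    return float(tau_star)
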