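"""Synthetic inputs with known ground truth for the whole pipeline.

The generator emulates, at desk scale, the statistical structure of the data
the analysis needs: a household budget survey with item expenditures and
quantities per food category (including selection-driven zeros and
quality-varying unit values), a toy multi-regional input-output system with
environmental satellite accounts, a VAT rate table, and a social-cost table.

The survey generator is the structural model the demand-system estimator is
meant to recover.  Latent budget shares follow the linear-approximated EASI
share system

    w_h = sum_r b_r y_h^r + A p_h + C z_h + B p_h y_h + D z_h y_h + eps_h

with implicit utility ``y_h = x_h - w_h' ln(ptilde_h)`` (log nominal food
expenditure deflated by the household's Stone price index) and normalized
log prices ``p_h = ln(ptilde_h) - x_h``.  Adding-up (shares sum to one) and
homogeneity hold by construction of the true parameters: ``1'b_0 = 1``,
``1'b_r = 0`` for r >= 1, A and B symmetric with zero row/column sums, and
C, D with zero column sums; the preference noise eps_h sums to zero across
categories.  Zeros arise through an independent per-category selection
probit, so the censoring mechanism is exactly the two-step model the
estimator assumes.

Units are scale-free: expenditures and prices are expressed relative to the
sample median annual food budget, which keeps the implicit-utility index
y_h of order one (well-conditioned 4th-order Engel-curve polynomials)
without loss of generality, since the demand system is homogeneous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from . import mrio as mrio_mod
from .mrio import (
    ALL_STRESSORS,
    GHG_GASES,
    LAND_STRESSORS,
    MRIOSystem,
    PHOSPHORUS_STRESSOR,
    WATER_STRESSOR,
)
from .welfare import SocialCostTable

__all__ = [
    "EASIParams",
    "SyntheticConfig",
    "SurveyTruth",
    "VATTable",
    "default_categories",
    "default_easi_params",
    "gen_toy_mrio",
    "gen_household_survey",
    "gen_vat_table",
    "gen_social_cost_table",
    "demand_shares",
]

DEMOGRAPHICS = ["age_gt45", "female_head", "children", "high_income", "urban"]

_MEAT_NAMES = ["beef", "pork", "poultry", "other_meat"]
_NONMEAT_NAMES = [
    "fish_seafood",
    "dairy_eggs",
    "bread_cereals",
    "fruits_vegetables",
    "oils_fats",
    "food_nec",
]


def default_categories(n: int) -> tuple[list[str], list[str]]:
    """Return (category names, meat categories) for an n-category system.

    Roughly the first four of ten categories are meat (mirroring the
    beef/pork/poultry/other-meat split); for small n at least one meat and
    one non-meat category are kept.
    """
    if n < 2:
        raise ValueError("need at least two food categories")
    n_meat = max(1, min(len(_MEAT_NAMES), round(0.4 * n)))
    if n - n_meat < 1:
        n_meat = n - 1
    meat = _MEAT_NAMES[:n_meat]
    nonmeat = list(_NONMEAT_NAMES)
    while len(nonmeat) < n - n_meat:
        nonmeat.append(f"food_extra_{len(nonmeat)}")
    return meat + nonmeat[: n - n_meat], meat


@dataclass
class EASIParams:
    """True parameters of the generator's share system (R = 4 polynomial)."""

    b: np.ndarray  # (5, n): b_0 .. b_4
    A: np.ndarray  # (n, n) symmetric, zero row/column sums
    B: np.ndarray  # (n, n) symmetric, zero row/column sums
    C: np.ndarray  # (n, L) zero column sums
    D: np.ndarray  # (n, L) zero column sums

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        n = self.A.shape[0]
        if self.b.shape != (5, n):
            raise ValueError("b must have shape (5, n)")
        for name, m in [("A", self.A), ("B", self.B)]:
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def L(self) -> int:
        return self.C.shape[1]


def _sym_centered(m: np.ndarray) -> np.ndarray:
    """Symmetrize and project onto zero row/column sums (stays symmetric)."""
    s = (m + m.T) / 2.0
    n = s.shape[0]
    row = s.mean(axis=1, keepdims=True)
    col = s.mean(axis=0, keepdims=True)
    return s - row - col + s.mean()


def default_easi_params(n: int, L: int = len(DEMOGRAPHICS), seed: int = 0) -> EASIParams:
    """Draw a well-behaved true parameter set for an n-category system.

    Price responses are mild (shares stay inside (0, 1)) with a negative
    diagonal on A so that compensated own-price effects are negative on top
    of the mechanical ``w_i - 1`` term.
    """
    rng = np.random.default_rng(seed)
    base = rng.dirichlet(np.full(n, 12.0))
    b0 = 0.5 * base + 0.5 / n          # interior baseline shares
    b = np.zeros((5, n))
    b[0] = b0
    # Perturbation magnitudes scale with the typical share 1/n so that
    # shares stay interior for any category count.
    k = min(1.0, 4.0 / n)
    scales = [0.030 * k, 0.012 * k, 0.005 * k, 0.002 * k]
    for r in range(1, 5):
        v = rng.normal(0.0, scales[r - 1], size=n)
        b[r] = v - v.mean()
    J = np.eye(n) - np.ones((n, n)) / n  # symmetric, zero row sums
    A = _sym_centered(rng.normal(0.0, 0.010 * k, size=(n, n))) - 0.030 * k * J
    B = _sym_centered(rng.normal(0.0, 0.004 * k, size=(n, n))) - 0.008 * k * J
    C = rng.normal(0.0, 0.015 * k, size=(n, L))
    C -= C.mean(axis=0, keepdims=True)
    D = rng.normal(0.0, 0.006 * k, size=(n, L))
    D -= D.mean(axis=0, keepdims=True)
    return EASIParams(b=b, A=A, B=B, C=C, D=D)


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic study.

    Defaults emulate the study conditions at desk scale: ten food categories
    with a four-category meat block, 20% selection-driven zeros, mild
    quality variation in unit values, and within-country price variation
    through sub-region and urbanity shifters plus a household-idiosyncratic
    (outlet/package) component — the supply-side unit-value dispersion that
    identifies the price responses in survey data without price surveys.
    """

    n_households: int = 1000
    n_countries: int = 5
    n_categories: int = 10
    n_regions: int = 8
    n_sectors: int = 12
    true_easi_params: EASIParams | None = None
    censoring_rate: float = 0.20
    quality_effect_scale: float = 0.05
    pref_noise_scale: float = 0.02
    zero_quantity_rate: float = 0.02
    unrecorded_items: dict[str, list[str]] = field(default_factory=dict)
    selection_slope_scale: float = 0.6
    region_price_sd: float = 0.12
    country_price_sd: float = 0.05
    urban_price_sd: float = 0.05
    idiosyncratic_price_sd: float = 0.20
    noise_truncation: float = 2.5  # noise draws truncated at this many sd
    expenditure_sd: float = 0.50
    eur_scale: float = 3000.0
    n_subregions: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ValueError("n_categories must be >= 2")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.n_households < 1 or self.n_countries < 1:
            raise ValueError("need at least one household and one country")
        if self.true_easi_params is None:
            self.true_easi_params = default_easi_params(
                self.n_categories, seed=self.seed
            )
        if self.true_easi_params.n != self.n_categories:
            raise ValueError("true_easi_params dimension mismatch")
        if abs(self.true_easi_params.b[0].sum() - 1.0) > 1e-10:
            raise ValueError("b_0 must sum to one (adding-up)")

    @property
    def categories(self) -> list[str]:
        return default_categories(self.n_categories)[0]

    @property
    def meat_categories(self) -> list[str]:
        return default_categories(self.n_categories)[1]

    @property
    def countries(self) -> list[str]:
        return [f"C{i:02d}" for i in range(self.n_countries)]


def demand_shares(
    params: EASIParams,
    p: np.ndarray,
    y: np.ndarray | float,
    z: np.ndarray,
) -> np.ndarray:
    """Evaluate the latent share system at normalized log prices p,
    implicit utility y and demographics z (vectorized over households)."""
    p = np.atleast_2d(np.asarray(p, dtype=float))
    z = np.atleast_2d(np.asarray(z, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))[:, None]
    engel = sum(params.b[r] * y**r for r in range(5))
    return engel + p @ params.A.T + z @ params.C.T + (p @ params.B.T + z @ params.D.T) * y


def _solve_latent_shares(
    params: EASIParams,
    log_prices: np.ndarray,
    x: np.ndarray,
    z: np.ndarray,
    eps: np.ndarray,
    tol: float = 1e-13,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed point of (w, y): y = x - w' ln(ptilde), w = f(p, y, z) + eps."""
    p = log_prices - x[:, None]
    y = x - log_prices.mean(axis=1)
    for _ in range(max_iter):
        w = demand_shares(params, p, y, z) + eps
        y_new = x - np.einsum("ij,ij->i", w, log_prices)
        if np.max(np.abs(y_new - y)) < tol:
            y = y_new
            break
        y = y_new
    w = demand_shares(params, p, y, z) + eps
    bad = (w < 0).any(axis=1) | (w > 1).any(axis=1)
    if bad.mean() > 0.005:
        raise ValueError(
            "generated budget shares leave [0, 1] for "
            f"{bad.mean():.2%} of households; the configured parameters, "
            "price dispersion or noise scale are too extreme"
        )
    if bad.any():
        # Rare tail households: clip into the simplex and renormalize so
        # adding-up still holds exactly.
        import warnings

        warnings.warn(
            f"clipped budget shares of {int(bad.sum())} tail household(s) "
            "into [0, 1]",
            stacklevel=2,
        )
        w[bad] = np.clip(w[bad], 1e-6, 1.0)
        w[bad] /= w[bad].sum(axis=1, keepdims=True)
        y[bad] = x[bad] - np.einsum("ij,ij->i", w[bad], log_prices[bad])
    return w, y


@dataclass
class CountryTruth:
    """Per-country ground truth returned alongside the survey."""

    gamma: np.ndarray          # (n, 1 + L + 1) selection coefficients
    latent_shares: np.ndarray  # (N, n) pre-censoring shares (sum to 1)
    y: np.ndarray              # (N,) implicit utility at the fixed point
    x: np.ndarray              # (N,) log nominal food expenditure
    log_prices: np.ndarray     # (N, n) raw log unit-value supply prices
    z: np.ndarray              # (N, L)
    weight: np.ndarray         # (N,)

    @property
    def mean_point(self) -> tuple[np.ndarray, float, np.ndarray]:
        """(p_mean, y_mean, z_mean) — normalized prices, utility, demographics."""
        p = self.log_prices - self.x[:, None]
        return p.mean(axis=0), float(self.y.mean()), self.z.mean(axis=0)


@dataclass
class SurveyTruth:
    """Ground truth of the generated survey, for validation and oracles."""

    params: EASIParams
    categories: list[str]
    meat_categories: list[str]
    by_country: dict[str, CountryTruth]

    def shares_at(self, p: np.ndarray, y: float, z: np.ndarray) -> np.ndarray:
        return demand_shares(self.params, p, y, z)[0]

    def analytic_elasticities(self, country: str):
        """Compensated price matrix, expenditure vector and Marshallian
        matrix at the country's mean covariates (no censoring at the truth).

        Standard share-to-quantity conversions of the semi-elasticities:
        eta^PE = diag(w)^-1 (A + B y) + w 1' - I on the price side and
        eta^EE = diag(w)^-1 (sum_r r b_r y^(r-1) + B p + D z) + 1; the
        Marshallian matrix follows from the Slutsky equation.
        """
        ct = self.by_country[country]
        p, y, z = ct.mean_point
        w = self.shares_at(p, y, z)
        par = self.params
        dp = par.A + par.B * y
        dy = sum(r * par.b[r] * y ** (r - 1) for r in range(1, 5)) + par.B @ p + par.D @ z
        eta_pe = dp / w[:, None] + np.tile(w, (par.n, 1)) - np.eye(par.n)
        eta_ee = dy / w + 1.0
        eta_m = eta_pe - np.outer(eta_ee, w)
        return eta_pe, eta_ee, eta_m

    def fd_elasticities(self, country: str, h: float = 1e-5):
        """Finite-difference oracle for the elasticities at mean covariates.

        Differentiates the generator's share function in its exogenous
        arguments (p, y) by central differences and applies the same
        share-to-quantity conversion; independent of the closed-form
        derivative matrices.
        """
        ct = self.by_country[country]
        p, y, z = ct.mean_point
        n = self.params.n
        w = self.shares_at(p, y, z)
        dwdp = np.zeros((n, n))
        for j in range(n):
            e = np.zeros(n)
            e[j] = h
            dwdp[:, j] = (self.shares_at(p + e, y, z) - self.shares_at(p - e, y, z)) / (2 * h)
        dwdy = (self.shares_at(p, y + h, z) - self.shares_at(p, y - h, z)) / (2 * h)
        eta_pe = dwdp / w[:, None] + np.tile(w, (n, 1)) - np.eye(n)
        eta_ee = dwdy / w + 1.0
        eta_m = eta_pe - np.outer(eta_ee, w)
        return eta_pe, eta_ee, eta_m


def _calibrate_probit_intercept(slope_term: np.ndarray, rate: float) -> float:
    """Intercept g0 such that mean_h Phi(g0 + slope_term_h) = 1 - rate."""
    target = 1.0 - rate

    def gap(g0: float) -> float:
        return float(norm.cdf(g0 + slope_term).mean() - target)

    bound = 12.0 + float(np.abs(slope_term).max())
    return brentq(gap, -bound, bound, xtol=1e-12)


def gen_household_survey(
    cfg: SyntheticConfig,
    prices: dict[str, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, SurveyTruth]:
    """Generate the household survey and its ground truth.

    Parameters
    ----------
    cfg:
        Study configuration; ``cfg.seed`` drives a single root seed with
        per-country child streams.
    prices:
        Optional per-country baseline log-price vectors (length
        ``n_categories``); drawn from N(0, country_price_sd) when omitted.
        Sub-region and urbanity shifters are added on top so that
        within-country price variation exists.

    Returns
    -------
    (survey, truth):
        ``survey`` is a tidy household table (one row per household) with
        demographics, weights, total and per-category expenditures and
        quantities; zeros in expenditures arise via the selection probit.
        ``truth`` carries the generating parameters, latent shares,
        selection coefficients and elasticity oracles.
    """
    params = cfg.true_easi_params
    cats = cfg.categories
    n, L = params.n, params.L
    root = np.random.SeedSequence(cfg.seed)
    country_seeds = root.spawn(cfg.n_countries)

    frames = []
    by_country: dict[str, CountryTruth] = {}
    z_probs = np.array([0.5, 0.45, 0.4, 0.5, 0.35])[:L]

    for ci, country in enumerate(cfg.countries):
        rng = np.random.default_rng(country_seeds[ci])
        N = cfg.n_households
        z = (rng.random((N, L)) < z_probs).astype(float)
        weight = rng.lognormal(0.0, 0.3, size=N)
        subregion = rng.integers(0, cfg.n_subregions, size=N)
        def tnorm(sd: float, size) -> np.ndarray:
            v = rng.normal(0.0, sd, size=size)
            bound = cfg.noise_truncation * sd
            return np.clip(v, -bound, bound)

        x = 0.35 * z[:, 3] + 0.10 * z[:, 2] + tnorm(cfg.expenditure_sd, N)
        x -= 0.35 * z_probs[3] + 0.10 * z_probs[2]  # keep mean ~ 0

        if prices is not None and country in prices:
            base = np.asarray(prices[country], dtype=float)
            if base.shape != (n,):
                raise ValueError(f"price vector for {country} must have length {n}")
        else:
            base = rng.normal(0.0, cfg.country_price_sd, size=n)
        region_shift = tnorm(cfg.region_price_sd, (cfg.n_subregions, n))
        urban_shift = tnorm(cfg.urban_price_sd, n)
        log_prices = (
            base[None, :]
            + region_shift[subregion]
            + urban_shift * z[:, 4:5]
            + tnorm(cfg.idiosyncratic_price_sd, (N, n))
        )

        # Express the monetary scale in euros (median annual food budget):
        # shifting prices and expenditures by the same log constant leaves
        # shares, normalized prices, implicit utility and elasticities
        # unchanged (homogeneity), so this is presentation only.
        log_scale = np.log(cfg.eur_scale)
        x = x + log_scale
        log_prices = log_prices + log_scale

        eps = tnorm(cfg.pref_noise_scale, (N, n))
        eps -= eps.mean(axis=1, keepdims=True)

        w_latent, y = _solve_latent_shares(params, log_prices, x, z, eps)

        # Selection probits: s_h = [1, z_h, x_h]; intercepts calibrated so
        # the expected zero-fraction per category equals censoring_rate.
        s = np.column_stack([np.ones(N), z, x])
        gamma = np.zeros((n, s.shape[1]))
        d = np.ones((N, n), dtype=bool)
        if cfg.censoring_rate > 0.0:
            slopes = rng.normal(0.0, cfg.selection_slope_scale, size=(n, s.shape[1] - 1))
            zeta = rng.normal(0.0, 1.0, size=(N, n))
            for i in range(n):
                term = s[:, 1:] @ slopes[i]
                g0 = _calibrate_probit_intercept(term, cfg.censoring_rate)
                gamma[i] = np.concatenate([[g0], slopes[i]])
                d[:, i] = (s @ gamma[i] + zeta[:, i]) > 0.0

        kappa = rng.normal(0.0, 1.0, size=(n, L))
        quality = cfg.quality_effect_scale * (
            z @ kappa.T + rng.normal(0.0, 0.3, size=(N, n))
        )
        unit_values = np.exp(log_prices + quality)

        X = np.exp(x)
        expend = d * w_latent * X[:, None]
        qty = np.where(expend > 0, expend / unit_values, 0.0)

        if cfg.zero_quantity_rate > 0.0:
            drop = (rng.random((N, n)) < cfg.zero_quantity_rate) & (expend > 0)
            qty = np.where(drop, 0.0, qty)
        for item in cfg.unrecorded_items.get(country, []):
            qty[:, cats.index(item)] = np.nan

        food_share = 1.0 / (1.0 + np.exp(-rng.normal(-1.7, 0.3, size=N)))
        total_expenditure = X / food_share

        df = pd.DataFrame(
            {
                "household_id": [f"{country}_{k:06d}" for k in range(N)],
                "country": country,
                "subregion": subregion,
                **{DEMOGRAPHICS[l]: z[:, l].astype(int) for l in range(L)},
                "weight": weight,
                "total_expenditure": total_expenditure,
                "total_food_expenditure": X,
            }
        )
        for j, cat in enumerate(cats):
            df[f"exp_{cat}"] = expend[:, j]
            df[f"qty_{cat}"] = qty[:, j]
        frames.append(df)

        by_country[country] = CountryTruth(
            gamma=gamma,
            latent_shares=w_latent,
            y=y,
            x=x,
            log_prices=log_prices,
            z=z,
            weight=weight,
        )

    survey = pd.concat(frames, ignore_index=True)
    truth = SurveyTruth(
        params=params,
        categories=cats,
        meat_categories=cfg.meat_categories,
        by_country=by_country,
    )
    return survey, truth


# ---------------------------------------------------------------------------
# Toy MRIO
# ---------------------------------------------------------------------------

def gen_toy_mrio(
    n_regions: int,
    n_sectors: int,
    seed: int,
    categories: list[str] | None = None,
) -> MRIOSystem:
    """Generate a productive toy MRIO system with environmental extensions.

    The technical-coefficient matrix is scaled so that every column sum is
    at most 0.6, which bounds the spectral radius below one.  Household
    demand vectors are generated per region (each region is a consuming
    country).  Food sectors are assigned round-robin to the food categories;
    roughly a quarter of sectors remain non-food.
    """
    if n_regions < 1 or n_sectors < 1:
        raise ValueError("need at least one region and one sector")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 730)))
    regions = [f"R{i:02d}" for i in range(n_regions)]
    sectors = [f"S{j:02d}" for j in range(n_sectors)]
    m = n_regions * n_sectors

    a = rng.uniform(0.0, 1.0, size=(m, m))
    home_bias = np.kron(np.eye(n_regions), np.ones((n_sectors, n_sectors)))
    a = a * (0.3 + 0.7 * home_bias)
    a *= 0.6 / a.sum(axis=0).max()

    demand = {}
    for r in range(n_regions):
        y = rng.uniform(0.2, 1.0, size=m)
        home = np.zeros(m)
        home[r * n_sectors : (r + 1) * n_sectors] = 1.0
        y = y * (0.4 + 0.6 * home)  # home bias in final consumption
        demand[regions[r]] = y

    sat = pd.DataFrame(
        0.0,
        index=pd.Index(ALL_STRESSORS, name="stressor"),
        columns=pd.MultiIndex.from_product([regions, sectors], names=["region", "sector"]),
    )
    # Intensity scales are set so that supply-chain totals per euro of food
    # demand land at realistic magnitudes (around 1 kgCO2e, 5 gN, 0.5 gP,
    # 0.05 m3 blue water and a few m2 of land occupation per euro).
    sat.loc["CO2"] = rng.lognormal(-8.1, 0.6, size=m)          # tCO2 per EUR
    sat.loc["CH4"] = rng.lognormal(-11.5, 0.8, size=m)         # t per EUR
    sat.loc["N2O"] = rng.lognormal(-14.0, 0.8, size=m)
    for gas in ("SF6", "HFC", "PFC"):
        sat.loc[gas] = rng.lognormal(-23.0, 1.0, size=m)
    for s_ in ["N_water", "NH3_air", "NOx_air"]:
        sat.loc[s_] = rng.lognormal(-5.8, 0.6, size=m)         # kg per EUR
    sat.loc[PHOSPHORUS_STRESSOR] = rng.lognormal(-7.9, 0.6, size=m)
    sat.loc[WATER_STRESSOR] = rng.lognormal(-3.0, 0.7, size=m)  # m3 per EUR
    for s_ in LAND_STRESSORS:
        sat.loc[s_] = rng.lognormal(-11.1, 0.9, size=m)        # ha per EUR

    if categories is None:
        categories = default_categories(10)[0]
    n_food = max(1, int(round(0.75 * n_sectors))) if n_sectors > 1 else 1
    concordance = {
        sectors[j]: categories[j % len(categories)] for j in range(n_food)
    }

    return MRIOSystem(
        region_labels=regions,
        sector_labels=sectors,
        tech_coefficients=a,
        household_demand=demand,
        satellite=sat,
        food_concordance=concordance,
    )


# ---------------------------------------------------------------------------
# VAT and social-cost tables
# ---------------------------------------------------------------------------

@dataclass
class VATTable:
    """Country VAT rates: the standard rate and the rate applied per food
    category in the status quo; meat categories are flagged explicitly."""

    standard: pd.Series              # per country
    applied: pd.DataFrame            # country x category (pre-policy rates)
    meat_categories: list[str]

    def __post_init__(self) -> None:
        if (self.applied.to_numpy() < 0).any() or (self.standard < 0).any():
            raise ValueError("VAT rates must be non-negative")
        exceeds = self.applied.gt(self.standard, axis=0)
        if exceeds.to_numpy().any():
            raise ValueError("applied rates must not exceed the standard rate")

    @property
    def countries(self) -> list[str]:
        return list(self.standard.index)

    def reform_rates(self) -> pd.DataFrame:
        """Post-reform rates: standard on meat, unchanged elsewhere."""
        post = self.applied.copy()
        for cat in self.meat_categories:
            post[cat] = self.standard
        return post


def gen_vat_table(
    n_countries: int,
    share_with_reduction: float = 22.0 / 27.0,
    seed: int = 0,
    categories: list[str] | None = None,
    meat_categories: list[str] | None = None,
    countries: list[str] | None = None,
) -> VATTable:
    """Generate a VAT table; by default 22 of 27 countries (the EU27
    institutional setting) apply a reduced rate to meat products."""
    if not (0.0 <= share_with_reduction <= 1.0):
        raise ValueError("share_with_reduction must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 947)))
    if categories is None:
        categories, meat_categories = default_categories(10)
    if meat_categories is None:
        raise ValueError("meat_categories required when categories are custom")
    if countries is None:
        countries = [f"C{i:02d}" for i in range(n_countries)]
    standard = pd.Series(
        np.round(rng.uniform(0.17, 0.27, size=n_countries), 3), index=countries
    )
    food_reduced = pd.Series(
        np.round(rng.uniform(0.04, 0.12, size=n_countries), 3), index=countries
    )
    n_reduced = int(round(share_with_reduction * n_countries))
    has_reduction = np.zeros(n_countries, dtype=bool)
    has_reduction[:n_reduced] = True

    applied = pd.DataFrame(index=countries, columns=categories, dtype=float)
    for cat in categories:
        if cat in meat_categories:
            applied[cat] = np.where(has_reduction, food_reduced, standard)
        else:
            applied[cat] = food_reduced
    return VATTable(standard=standard, applied=applied, meat_categories=list(meat_categories))


def gen_social_cost_table(
    phosphorus_eur_per_kg: float = 153.50,
    co2_eur_per_t: float = 193.0,
    ch4_eur_per_t: float = 5300.0,
    n2o_eur_per_t: float = 52000.0,
    nitrogen_eur_per_kg: float = 12.0,
    fgas_co2e_eur_per_t: float | None = None,
) -> SocialCostTable:
    """Social-cost table for monetizing footprint changes.

    The phosphorus entry defaults to the reported external cost of
    phosphorus emissions into surface waters (153.50 EUR per kg); the
    remaining defaults are synthetic placeholders of plausible magnitude and
    are flagged as such.  F-gases (SF6, HFCs, PFCs) are valued via their
    CO2-equivalent at the CO2 cost unless an explicit value is given.
    """
    if fgas_co2e_eur_per_t is None:
        fgas_co2e_eur_per_t = co2_eur_per_t
    costs = {
        "CO2": co2_eur_per_t,
        "CH4": ch4_eur_per_t,
        "N2O": n2o_eur_per_t,
        "fgas_co2e": fgas_co2e_eur_per_t,
        "nitrogen": nitrogen_eur_per_kg,
        "phosphorus": phosphorus_eur_per_kg,
    }
    sources = {
        "CO2": "synthetic placeholder (order of published SCC estimates)",
        "CH4": "synthetic placeholder",
        "N2O": "synthetic placeholder",
        "fgas_co2e": "CO2 cost applied to CO2e of SF6/HFC/PFC",
        "nitrogen": "synthetic placeholder (domestic cost per kg N)",
        "phosphorus": "reported external cost per kg P to surface waters",
    }
    return SocialCostTable(costs=costs, sources=sources)
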