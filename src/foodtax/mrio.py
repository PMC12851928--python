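"""Environmentally extended multi-regional input-output (MRIO) accounting.

The module implements consumption-based footprint accounting in the Leontief
tradition: an economy of ``R`` regions times ``S`` sectors is described by a
technical-coefficient matrix ``A`` (inputs per unit of output), household
final demand vectors ``y`` per consuming country, and a satellite matrix of
environmental stressor intensities per unit of sectoral output.  Total output
required to serve a demand vector is ``x = (I - A)^-1 y`` and the induced
stressor releases are ``g = S x``.

Raw stressors (six greenhouse gases, nitrogen species, phosphorus, blue
water, and twenty land-use stressors) are characterized into six indicators:
GHG emissions in CO2-equivalents (GWP100), water consumption, land use,
nitrogen, phosphorus, and land-use driven biodiversity loss expressed as the
global potentially disappeared fraction (PDF) of species.  Biodiversity
characterization is regionalized: land occupation is attributed to the
producing region before region-specific PDF factors per land-use type are
applied.

All operations are linear in demand, which downstream policy simulation
exploits (footprint changes scale with quantity changes, and reductions are
allocated proportionally to where impacts arise in the baseline).
"""

from __future__ import annotations

import io
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "INDICATORS",
    "GHG_GASES",
    "LAND_USE_TYPES",
    "MRIOSystem",
    "CharacterizationTable",
    "FootprintAccount",
    "leontief_inverse",
    "compute_footprints",
    "footprints_by_purchased_sector",
    "aggregate_to_categories",
    "characterize",
    "split_domestic_imported",
    "demand_intensity",
    "build_account",
    "write_mrio_csv",
    "read_mrio_csv",
]

INDICATORS = ["ghg", "water", "land", "nitrogen", "phosphorus", "biodiversity"]

GHG_GASES = ["CO2", "CH4", "N2O", "SF6", "HFC", "PFC"]

#: 100-year global warming potentials (kg CO2e per kg gas).  Configuration
#: data with a documented source; override via ``CharacterizationTable``.
DEFAULT_GWP100 = {
    "CO2": 1.0,
    "CH4": 27.0,      # non-fossil methane, 100-yr horizon
    "N2O": 273.0,
    "SF6": 24300.0,
    "HFC": 1526.0,    # HFC-134a as representative species
    "PFC": 7380.0,    # CF4 as representative species
}

#: Aggregation weights of nitrogen species into the nitrogen indicator
#: (kg N per kg emitted species; NH3 and NOx converted by molar N content).
DEFAULT_NITROGEN_FACTORS = {
    "N_water": 1.0,
    "NH3_air": 14.0 / 17.0,
    "NOx_air": 14.0 / 46.0,
}

WATER_STRESSOR = "water_blue"
PHOSPHORUS_STRESSOR = "P_water"

LAND_USE_TYPES = [
    "annual_crops",
    "permanent_crops",
    "pastures",
    "urban",
    "extensive_forestry",
    "intensive_forestry",
]

#: Twenty land-use stressors (13 cropland, 3 pasture, 2 forest, infrastructure
#: and other land) mapped onto the six land-use types used for biodiversity
#: characterization.  Every stressor maps to exactly one type.
DEFAULT_LANDUSE_MAP = {
    **{f"cropland_{i:02d}": "annual_crops" for i in range(1, 12)},
    "cropland_12": "permanent_crops",
    "cropland_13": "permanent_crops",
    "pasture_01": "pastures",
    "pasture_02": "pastures",
    "pasture_03": "pastures",
    "forest_extensive": "extensive_forestry",
    "forest_intensive": "intensive_forestry",
    "infrastructure_land": "urban",
    "other_land": "pastures",
}

LAND_STRESSORS = list(DEFAULT_LANDUSE_MAP)

#: Canonical stressor ordering of the satellite account.
ALL_STRESSORS = (
    GHG_GASES
    + list(DEFAULT_NITROGEN_FACTORS)
    + [PHOSPHORUS_STRESSOR, WATER_STRESSOR]
    + LAND_STRESSORS
)

NON_FOOD = "non_food"


def _gas_measure(gas: str) -> str:
    return f"gas:{gas}"


GAS_MEASURES = [_gas_measure(g) for g in GHG_GASES]
ALL_MEASURES = INDICATORS + GAS_MEASURES


@dataclass
class MRIOSystem:
    """A multi-regional input-output system with environmental extensions.

    Attributes
    ----------
    region_labels, sector_labels:
        Names of the ``R`` regions and ``S`` sectors; the economic core is
        indexed by the ``R*S`` region-sector pairs in row-major order.
    tech_coefficients:
        Square non-negative matrix ``A`` with spectral radius below one.
    household_demand:
        Final household consumption vector per consuming country, each of
        length ``R*S`` (imports are entries on foreign region-sector pairs).
    satellite:
        Stressor x region-sector intensity matrix (stressor units per unit
        of output), indexed by stressor name.
    food_concordance:
        Mapping of sector name to food category; sectors absent from the
        mapping are treated as ``non_food``.
    """

    region_labels: list[str]
    sector_labels: list[str]
    tech_coefficients: np.ndarray
    household_demand: dict[str, np.ndarray]
    satellite: pd.DataFrame
    food_concordance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rs = len(self.region_labels) * len(self.sector_labels)
        a = np.asarray(self.tech_coefficients, dtype=float)
        if a.shape != (rs, rs):
            raise ValueError(
                f"technical coefficients must be {rs}x{rs}, got {a.shape}"
            )
        if (a < 0).any():
            raise ValueError("technical coefficients must be non-negative")
        self.tech_coefficients = a
        for country, y in self.household_demand.items():
            y = np.asarray(y, dtype=float)
            if y.shape != (rs,):
                raise ValueError(f"demand vector for {country} has wrong length")
            if (y < 0).any():
                raise ValueError(f"negative final demand for {country}")
            self.household_demand[country] = y
        if (self.satellite.to_numpy() < 0).any():
            raise ValueError("satellite intensities must be non-negative")

    @property
    def node_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_product(
            [self.region_labels, self.sector_labels], names=["region", "sector"]
        )

    def sector_category(self, sector: str) -> str:
        return self.food_concordance.get(sector, NON_FOOD)

    @property
    def categories(self) -> list[str]:
        seen: list[str] = []
        for s in self.sector_labels:
            c = self.sector_category(s)
            if c not in seen:
                seen.append(c)
        if NON_FOOD not in seen:
            seen.append(NON_FOOD)
        return seen


@dataclass
class CharacterizationTable:
    """Factors translating raw stressors into the six indicators.

    ``biodiversity_factors`` is a region x land-use-type table of global PDF
    per unit of occupied area and year (matrix ``C``); it is applied to land
    occupation by the *producing* region, which is what makes the
    biodiversity indicator regionalized.
    """

    ghg_gwp100: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GWP100))
    nitrogen_factors: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NITROGEN_FACTORS)
    )
    landuse_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_LANDUSE_MAP))
    biodiversity_factors: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for name, table in [
            ("ghg_gwp100", self.ghg_gwp100),
            ("nitrogen_factors", self.nitrogen_factors),
        ]:
            for k, v in table.items():
                if not np.isfinite(v) or v < 0:
                    raise ValueError(f"{name}[{k}] must be finite and >= 0")
        bad = set(self.landuse_map.values()) - set(LAND_USE_TYPES)
        if bad:
            raise ValueError(f"unknown land-use types in landuse_map: {sorted(bad)}")

    @classmethod
    def default_for_regions(
        cls, regions: Iterable[str], seed: int | None = None
    ) -> "CharacterizationTable":
        """Characterization table with region-specific PDF factors.

        With ``seed=None`` all PDF factors are 1 (identity characterization);
        otherwise mildly heterogeneous positive factors are drawn so that
        regionalization is exercised.
        """
        regions = list(regions)
        if seed is None:
            bf = pd.DataFrame(1.0, index=regions, columns=LAND_USE_TYPES)
        else:
            rng = np.random.default_rng(seed)
            # global PDF per occupied ha and year; regionally heterogeneous
            bf = pd.DataFrame(
                rng.lognormal(mean=-13.8, sigma=0.5, size=(len(regions), len(LAND_USE_TYPES))),
                index=regions,
                columns=LAND_USE_TYPES,
            )
        return cls(biodiversity_factors=bf)


# ---------------------------------------------------------------------------
# Core Leontief accounting
# ---------------------------------------------------------------------------

def spectral_radius(a: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(np.asarray(a, dtype=float)))))


def leontief_inverse(tech_coefficients: np.ndarray) -> np.ndarray:
    """Return the total-requirements matrix ``L = (I - A)^-1``.

    Raises
    ------
    ValueError
        If ``A`` is not productive, i.e. its spectral radius is >= 1, in
        which case the Neumann series sum over supply-chain rounds diverges.
    """
    a = np.asarray(tech_coefficients, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("technical coefficients must be a square matrix")
    if (a < 0).any():
        raise ValueError("technical coefficients must be non-negative")
    rho = spectral_radius(a)
    if rho >= 1.0:
        raise ValueError(
            f"non-productive economy: spectral radius of A is {rho:.4f} >= 1"
        )
    return np.linalg.solve(np.eye(a.shape[0]) - a, np.eye(a.shape[0]))


def compute_footprints(system: MRIOSystem, demand: np.ndarray) -> pd.DataFrame:
    """Stressor releases by region-sector of origin for a demand vector.

    Uses the diagonalized-output formulation ``G = S diag((I-A)^-1 y)`` so
    that the attribution of every stressor to the producing region-sector is
    exact and sums to the aggregate footprint.
    """
    y = np.asarray(demand, dtype=float)
    rs = system.tech_coefficients.shape[0]
    if y.shape != (rs,):
        raise ValueError(f"demand vector must have length {rs}, got {y.shape}")
    x = leontief_inverse(system.tech_coefficients) @ y
    values = system.satellite.to_numpy() * x[np.newaxis, :]
    return pd.DataFrame(values, index=system.satellite.index, columns=system.node_index)


def footprints_by_purchased_sector(system: MRIOSystem, demand: np.ndarray) -> pd.DataFrame:
    """Origin-resolved stressor totals split by the sector purchased.

    For each of the ``S`` sector names the demand vector is masked to the
    entries of that sector (across all producing regions), propagated through
    the Leontief inverse, and the induced stressors are summed over origin
    sectors.  Rows are (stressor, origin region); columns are purchased
    sectors.  Column sums over purchased sectors reproduce the total
    footprint of ``demand`` because the accounting is linear.
    """
    y = np.asarray(demand, dtype=float)
    nr, ns = len(system.region_labels), len(system.sector_labels)
    if y.shape != (nr * ns,):
        raise ValueError("demand vector length mismatch")
    L = leontief_inverse(system.tech_coefficients)
    S = system.satellite.to_numpy()
    sector_of_node = np.tile(np.arange(ns), nr)
    region_of_node = np.repeat(np.arange(nr), ns)
    out = np.zeros((S.shape[0], nr, ns))
    for j in range(ns):
        yj = np.where(sector_of_node == j, y, 0.0)
        if not yj.any():
            continue
        x = L @ yj
        g = S * x[np.newaxis, :]              # stressor x origin node
        for r in range(nr):
            out[:, r, j] = g[:, region_of_node == r].sum(axis=1)
    idx = pd.MultiIndex.from_product(
        [system.satellite.index, system.region_labels],
        names=["stressor", "origin_region"],
    )
    return pd.DataFrame(
        out.reshape(S.shape[0] * nr, ns), index=idx, columns=system.sector_labels
    )


def aggregate_to_categories(
    account: pd.DataFrame,
    concordance: Mapping[str, str] | Iterable[tuple[str, str]],
) -> pd.DataFrame:
    """Aggregate purchased-sector columns into food categories.

    ``concordance`` maps sector -> category; sectors not mapped go to
    ``non_food``.  When given as (sector, category) pairs, a sector appearing
    twice raises.  Mass is conserved: the sum over category columns equals
    the sum over the original sector columns.
    """
    if not isinstance(concordance, Mapping):
        pairs = list(concordance)
        seen: dict[str, str] = {}
        for sector, cat in pairs:
            if sector in seen:
                raise ValueError(f"sector {sector!r} mapped twice in concordance")
            seen[sector] = cat
        concordance = seen
    cats: dict[str, list[str]] = {}
    for sector in account.columns:
        cat = concordance.get(sector, NON_FOOD)
        cats.setdefault(cat, []).append(sector)
    data = {cat: account[cols].sum(axis=1) for cat, cols in cats.items()}
    return pd.DataFrame(data)


def characterize(raw: pd.DataFrame, table: CharacterizationTable) -> pd.DataFrame:
    """Characterize raw stressors into the six indicators.

    ``raw`` must have a (stressor, origin_region) row MultiIndex; columns are
    arbitrary (purchased sectors or food categories).  The result has rows
    (measure, origin_region) where measure covers the six indicators plus the
    per-gas GHG rows ``gas:<G>`` retained for monetization.

    Raises
    ------
    KeyError
        If a stressor in ``raw`` is not recognized by the table.
    """
    stressors = raw.index.get_level_values("stressor").unique()
    known = (
        set(table.ghg_gwp100)
        | set(table.nitrogen_factors)
        | set(table.landuse_map)
        | {WATER_STRESSOR, PHOSPHORUS_STRESSOR}
    )
    unmapped = [s for s in stressors if s not in known]
    if unmapped:
        raise KeyError(f"unmapped stressors in characterization: {unmapped}")

    regions = raw.index.get_level_values("origin_region").unique()
    rows = {}
    by_stressor = {s: raw.xs(s, level="stressor") for s in stressors}
    zeros = pd.DataFrame(0.0, index=regions, columns=raw.columns)

    def get(s: str) -> pd.DataFrame:
        return by_stressor.get(s, zeros).reindex(regions).fillna(0.0)

    ghg = zeros.copy()
    for gas, gwp in table.ghg_gwp100.items():
        contrib = get(gas) * gwp
        ghg = ghg + contrib
        rows[_gas_measure(gas)] = get(gas)
    rows["ghg"] = ghg
    rows["water"] = get(WATER_STRESSOR)
    rows["phosphorus"] = get(PHOSPHORUS_STRESSOR)
    nitrogen = zeros.copy()
    for s, f in table.nitrogen_factors.items():
        nitrogen = nitrogen + get(s) * f
    rows["nitrogen"] = nitrogen

    land_by_type = {t: zeros.copy() for t in LAND_USE_TYPES}
    land_total = zeros.copy()
    for s, t in table.landuse_map.items():
        area = get(s)
        land_by_type[t] = land_by_type[t] + area
        land_total = land_total + area
    rows["land"] = land_total

    if table.biodiversity_factors is None:
        bf = pd.DataFrame(1.0, index=regions, columns=LAND_USE_TYPES)
    else:
        bf = table.biodiversity_factors.reindex(regions).fillna(0.0)
    bio = zeros.copy()
    for t in LAND_USE_TYPES:
        bio = bio + land_by_type[t].mul(bf[t], axis=0)
    rows["biodiversity"] = bio

    out = pd.concat(rows, names=["measure", "origin_region"])
    return out.loc[[m for m in ALL_MEASURES if m in out.index.get_level_values(0)]]


def split_domestic_imported(
    account: pd.DataFrame, home_regions: Iterable[str]
) -> pd.DataFrame:
    """Domestic vs imported share of each measure by origin region.

    Returns a DataFrame indexed by measure with columns ``domestic`` and
    ``imported`` that sum to one exactly (measures with zero total get a
    domestic share of one by convention).
    """
    home = set(home_regions)
    if not home:
        raise ValueError("home_regions must be a non-empty set of region labels")
    regions = set(account.index.get_level_values("origin_region"))
    unknown = home - regions
    if unknown:
        raise ValueError(f"home regions not in account: {sorted(unknown)}")
    totals = account.sum(axis=1)
    by_measure = totals.groupby(level="measure").sum()
    is_home = totals.index.get_level_values("origin_region").isin(home)
    home_tot = totals[is_home].groupby(level="measure").sum().reindex(by_measure.index).fillna(0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dom = (home_tot / by_measure).to_numpy()
    dom = np.where(by_measure.to_numpy() == 0.0, 1.0, dom)
    out = pd.DataFrame({"domestic": dom}, index=by_measure.index)
    out["imported"] = 1.0 - out["domestic"]
    return out


def demand_intensity(
    footprint_totals: pd.DataFrame, expenditures: pd.DataFrame
) -> pd.DataFrame:
    """Monetary impact intensity mu = E / X (impact per unit expenditure).

    ``footprint_totals`` and ``expenditures`` are country x category tables.
    A zero expenditure combined with a nonzero impact is undefined and
    raises; zero impact on zero expenditure yields mu = 0.
    """
    e = footprint_totals.reindex_like(expenditures).fillna(0.0)
    x = expenditures
    bad = (x.to_numpy() == 0.0) & (e.to_numpy() != 0.0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            "undefined intensity: zero expenditure with nonzero impact at "
            f"({x.index[i]}, {x.columns[j]})"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = e.to_numpy() / x.to_numpy()
    mu = np.where(x.to_numpy() == 0.0, 0.0, mu)
    return pd.DataFrame(mu, index=x.index, columns=x.columns)


@dataclass
class FootprintAccount:
    """Origin-resolved, characterized footprints per consuming country.

    ``data`` rows are a (country, measure, origin_region) MultiIndex; columns
    are food categories plus ``non_food``.  Measures cover the six indicators
    and the per-gas GHG rows.
    """

    data: pd.DataFrame

    @property
    def countries(self) -> list[str]:
        return list(self.data.index.get_level_values("country").unique())

    @property
    def categories(self) -> list[str]:
        return list(self.data.columns)

    def totals(self, measure: str, include_non_food: bool = False) -> pd.DataFrame:
        """Country x category totals for one measure (summed over origins)."""
        sub = self.data.xs(measure, level="measure")
        out = sub.groupby(level="country").sum()
        if not include_non_food and NON_FOOD in out.columns:
            out = out.drop(columns=NON_FOOD)
        return out

    def country_account(self, country: str) -> pd.DataFrame:
        return self.data.xs(country, level="country")


def build_account(
    system: MRIOSystem, table: CharacterizationTable
) -> FootprintAccount:
    """Compute the full footprint account for every consuming country."""
    pieces = {}
    for country, y in system.household_demand.items():
        by_sector = footprints_by_purchased_sector(system, y)
        by_cat = aggregate_to_categories(by_sector, system.food_concordance)
        pieces[country] = characterize(by_cat, table)
    data = pd.concat(pieces, names=["country", "measure", "origin_region"])
    return FootprintAccount(data=data)


# ---------------------------------------------------------------------------
# Labelled wide-CSV I/O (EXIOBASE-style region|sector multi-headers)
# ---------------------------------------------------------------------------

def write_mrio_csv(system: MRIOSystem, path) -> None:
    """Write the system as a single labelled text file.

    Layout mirrors the EXIOBASE IOT text convention: matrices in wide CSV
    with two header rows (region, sector); blocks are separated by marker
    lines so a single file round-trips the whole system.
    """
    idx = system.node_index
    with open(path, "w") as fh:
        fh.write("# foodtax MRIO system\n")
        fh.write(f"#REGIONS,{','.join(system.region_labels)}\n")
        fh.write(f"#SECTORS,{','.join(system.sector_labels)}\n")
        conc = ";".join(f"{s}={c}" for s, c in system.food_concordance.items())
        fh.write(f"#CONCORDANCE,{conc}\n")
        fh.write("#BLOCK A\n")
        pd.DataFrame(system.tech_coefficients, index=idx, columns=idx).to_csv(fh)
        fh.write("#BLOCK Y\n")
        ydf = pd.DataFrame(system.household_demand, index=idx)
        ydf.to_csv(fh)
        fh.write("#BLOCK S\n")
        sat = system.satellite.copy()
        sat.columns = idx
        sat.to_csv(fh)


def read_mrio_csv(path) -> MRIOSystem:
    """Read a system written by :func:`write_mrio_csv`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    regions = sectors = None
    concordance: dict[str, str] = {}
    blocks: dict[str, list[str]] = {}
    current: list[str] | None = None
    for line in lines:
        if line.startswith("#REGIONS,"):
            regions = line.split(",")[1:]
        elif line.startswith("#SECTORS,"):
            sectors = line.split(",")[1:]
        elif line.startswith("#CONCORDANCE,"):
            body = line.split(",", 1)[1]
            if body:
                concordance = dict(p.split("=") for p in body.split(";") if p)
        elif line.startswith("#BLOCK "):
            current = blocks.setdefault(line.split()[1], [])
        elif line.startswith("#"):
            continue
        elif current is not None:
            current.append(line)
    if regions is None or sectors is None:
        raise ValueError("malformed MRIO CSV: missing region/sector header")

    def parse(block: str, header: list[int], index_col: list[int]) -> pd.DataFrame:
        return pd.read_csv(
            io.StringIO("\n".join(blocks[block])), header=header, index_col=index_col
        )

    a = parse("A", [0, 1], [0, 1])
    y = parse("Y", [0], [0, 1])
    s = parse("S", [0, 1], [0])
    sat = s.copy()
    sat.columns = pd.MultiIndex.from_product([regions, sectors], names=["region", "sector"])
    return MRIOSystem(
        region_labels=regions,
        sector_labels=sectors,
        tech_coefficients=a.to_numpy(),
        household_demand={c: y[c].to_numpy() for c in y.columns},
        satellite=sat,
        food_concordance=concordance,
    )
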