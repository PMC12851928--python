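"""Configuration and the canonical end-to-end run.

The pipeline chains the package's stages — synthesize inputs, compute
baseline footprints and monetary GHG intensities, prepare the survey,
estimate the country demand systems, simulate the two tax policies, do the
welfare and revenue accounting, and bootstrap the uncertainty ranges — and
persists every stage's artifacts (plain CSV/JSON) together with a manifest
of seeds, versions and content checksums.  Reruns with the same
configuration are byte-identical; stage timings live in a separate file so
they do not break that contract.

Survey countries are mapped onto the first MRIO regions, and the MRIO food
demand of each country is calibrated so that per-category final demand
matches the weighted survey expenditures — this keeps the monetary GHG
intensities mu = E / X consistent between the footprint account and the
household-level tax accounting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .easi import (
    CountryElasticities,
    DemandObservations,
    EASIFit,
    EASISpec,
    build_observations,
    compute_elasticities,
    country_mean_elasticities,
    fit_censored_easi,
    fit_selection_probits,
)
from .mrio import (
    INDICATORS,
    NON_FOOD,
    CharacterizationTable,
    FootprintAccount,
    MRIOSystem,
    build_account,
    demand_intensity,
    split_domestic_imported,
    write_mrio_csv,
)
from .policy import (
    PolicyScenario,
    SimulationResult,
    simulate_scenario,
    solve_equivalent_ghg_price,
)
from .surveyprep import (
    clean_households,
    impute_cross_country,
    impute_within_country,
    prepare_country_prices,
)
from .synthdata import (
    SyntheticConfig,
    VATTable,
    gen_household_survey,
    gen_social_cost_table,
    gen_toy_mrio,
    gen_vat_table,
)
from .welfare import (
    WelfareResult,
    aggregate,
    cost_of_living,
    ghg_revenue,
    monetize,
    post_policy_expenditures,
    vat_revenue_change,
)

__all__ = [
    "RunConfig",
    "ROBUSTNESS_SPECS",
    "estimate_country",
    "estimate_all",
    "simulate_policies",
    "calibrate_demand",
    "run_pipeline",
]

#: The named robustness specifications of the demand-system estimation.
#: Each entry is a set of RunConfig/EASISpec overrides relative to the main
#: specification.
ROBUSTNESS_SPECS: dict[str, dict] = {
    "main": {},
    "uncensored_nmin1": {"spec": {"censored": False, "n_minus_1": True}},
    "ytilda": {"spec": {"deflator": "ytilda"}},
    "alt_price_regime": {"price_seed_offset": 1},
    "ycentered": {"spec": {"center_y": True}},
    "unweighted": {"spec": {"weighted": False}},
    "incomplete": {"spec": {"numeraire": True}},
    "pzint": {"spec": {"pz_interactions": True}},
    "uvnonadj": {"uv_adjust": False},
    "partial_drop_first": {"drop_countries_first": 1},
}


@dataclass
class RunConfig:
    """Configuration of one end-to-end experiment.

    The synthetic-study fields mirror :class:`~foodtax.synthdata.SyntheticConfig`;
    estimation switches mirror :class:`~foodtax.easi.EASISpec`.  Invalid
    combinations are rejected at construction time.
    """

    # synthetic study
    n_households: int = 1000
    n_countries: int = 5
    n_categories: int = 10
    n_regions: int = 8
    n_sectors: int = 16
    censoring_rate: float = 0.20
    quality_effect_scale: float = 0.05
    pref_noise_scale: float = 0.02
    zero_quantity_rate: float = 0.02
    price_seed_offset: int = 0
    # estimation
    spec: EASISpec = field(default_factory=EASISpec)
    uv_adjust: bool = True
    drop_countries_first: int = 0
    # policy / welfare
    tau_ghg: float | str = "solve"
    mean_household_size: float = 2.3
    # bootstrap
    bootstrap_b: int = 100
    run_bootstrap: bool = True
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.spec, dict):
            self.spec = EASISpec(**self.spec)
        if self.n_regions < self.n_countries:
            raise ValueError("need at least one MRIO region per survey country")
        n_food_sectors = max(1, int(round(0.75 * self.n_sectors)))
        if n_food_sectors < self.n_categories:
            raise ValueError(
                "not enough food sectors to cover every category: "
                f"{n_food_sectors} food sectors for {self.n_categories} categories"
            )
        if isinstance(self.tau_ghg, str) and self.tau_ghg != "solve":
            raise ValueError("tau_ghg must be a number or 'solve'")
        if self.bootstrap_b < 1:
            raise ValueError("bootstrap_b must be >= 1")
        if self.drop_countries_first >= self.n_countries:
            raise ValueError("cannot drop all countries")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def synthetic_config(self) -> SyntheticConfig:
        return SyntheticConfig(
            n_households=self.n_households,
            n_countries=self.n_countries,
            n_categories=self.n_categories,
            n_regions=self.n_regions,
            n_sectors=self.n_sectors,
            censoring_rate=self.censoring_rate,
            quality_effect_scale=self.quality_effect_scale,
            pref_noise_scale=self.pref_noise_scale,
            zero_quantity_rate=self.zero_quantity_rate,
            seed=self.seed,
        )

    def apply_robustness(self, name: str) -> "RunConfig":
        """Return a copy configured for one of the named robustness specs."""
        if name not in ROBUSTNESS_SPECS:
            raise KeyError(f"unknown robustness specification {name!r}")
        overrides = ROBUSTNESS_SPECS[name]
        d = self.to_dict()
        for k, v in overrides.items():
            if k == "spec":
                d["spec"] = {**d["spec"], **v}
            else:
                d[k] = v
        return RunConfig(**d)


# ---------------------------------------------------------------------------
# Pipeline building blocks (shared with the bootstrap)
# ---------------------------------------------------------------------------

def estimate_country(
    table_c: pd.DataFrame,
    spec: EASISpec | None = None,
    uv_adjust: bool = True,
) -> tuple[DemandObservations, EASIFit, CountryElasticities]:
    """Estimate one country's demand system from its cleaned survey table."""
    spec = spec or EASISpec()
    prices, _ = prepare_country_prices(table_c, adjust=uv_adjust)
    obs = build_observations(table_c, prices, spec=spec)
    if spec.censored:
        gamma, Phi, phi = fit_selection_probits(obs)
        fit = fit_censored_easi(obs, Phi, phi)
        fit.gamma = gamma
    else:
        fit = fit_censored_easi(obs)
    eset = compute_elasticities(fit, obs)
    ce = country_mean_elasticities(eset, country=obs.country)
    return obs, fit, ce


def estimate_all(
    survey: pd.DataFrame,
    spec: EASISpec | None = None,
    uv_adjust: bool = True,
) -> dict[str, tuple[DemandObservations, EASIFit, CountryElasticities]]:
    out = {}
    for country, sub in survey.groupby("country", sort=True):
        out[str(country)] = estimate_country(
            sub.reset_index(drop=True), spec=spec, uv_adjust=uv_adjust
        )
    return out


def _food_eta(ce_eta: pd.DataFrame, categories: list[str]) -> pd.DataFrame:
    """Restrict an elasticity matrix to the food categories (drops the
    numeraire row/column of the incomplete-system variant)."""
    return ce_eta.loc[categories, categories]


def simulate_policies(
    etas: dict[str, pd.DataFrame],
    vat: VATTable,
    mu: pd.DataFrame,
    baseline: FootprintAccount,
    tau_ghg: float | str = "solve",
) -> dict:
    """VAT reform, equivalent-GHG-price solve and GHG-price scenario."""
    cats = list(vat.applied.columns)
    etas = {c: _food_eta(m, cats) for c, m in etas.items()}
    vat_scn = PolicyScenario(kind="vat_reform", vat=vat)
    vat_res = simulate_scenario(vat_scn, etas, baseline)
    target = vat_res.total_change("ghg")
    if tau_ghg == "solve":
        tau_star = solve_equivalent_ghg_price(target, mu, etas, baseline, vat)
    else:
        tau_star = float(tau_ghg)
    ghg_scn = PolicyScenario(kind="ghg_price", vat=vat, tau_ghg=tau_star, mu=mu)
    ghg_res = simulate_scenario(ghg_scn, etas, baseline)
    return {"vat_reform": vat_res, "ghg_price": ghg_res, "tau_star": tau_star}


def calibrate_demand(
    system: MRIOSystem, expenditures: pd.DataFrame, country_region: dict[str, str]
) -> MRIOSystem:
    """Scale each country's MRIO food demand to match survey expenditures.

    For every (country, category) the final-demand entries on sectors of
    that category (across producing regions) are rescaled so their sum
    equals the weighted survey expenditure, keeping the import composition
    of the toy system.  Non-food entries are untouched.
    """
    nr, ns = len(system.region_labels), len(system.sector_labels)
    sector_cat = np.array([system.sector_category(s) for s in system.sector_labels])
    demand = {}
    for country, region in country_region.items():
        y = system.household_demand[region].copy()
        cat_of_node = np.tile(sector_cat, nr)
        for cat in expenditures.columns:
            mask = cat_of_node == cat
            cur = y[mask].sum()
            tgt = float(expenditures.loc[country, cat])
            if cur <= 0:
                raise ValueError(f"no MRIO demand to calibrate for category {cat!r}")
            y[mask] *= tgt / cur
        demand[country] = y
    return MRIOSystem(
        region_labels=system.region_labels,
        sector_labels=system.sector_labels,
        tech_coefficients=system.tech_coefficients,
        household_demand=demand,
        satellite=system.satellite,
        food_concordance=system.food_concordance,
    )


def weighted_expenditures(survey: pd.DataFrame, categories: list[str]) -> pd.DataFrame:
    """Country x category expenditure totals, sample-weighted."""
    rows = {}
    for country, sub in survey.groupby("country", sort=True):
        w = sub["weight"].to_numpy()
        rows[str(country)] = {
            c: float((sub[f"exp_{c}"].to_numpy() * w).sum()) for c in categories
        }
    return pd.DataFrame(rows).T.loc[:, categories]


# ---------------------------------------------------------------------------
# End-to-end run
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run every stage and persist artifacts plus a manifest.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    artifacts: list[Path] = []

    def run_stage(name, fn):
        t0 = time.perf_counter()
        result = fn()
        timings[name] = time.perf_counter() - t0
        return result

    # --- synth -------------------------------------------------------------
    def _synth():
        scfg = config.synthetic_config()
        if config.price_seed_offset:
            rng = np.random.default_rng(
                np.random.SeedSequence((config.seed + config.price_seed_offset, 101))
            )
            prices = {
                c: rng.normal(0.0, scfg.country_price_sd, size=scfg.n_categories)
                for c in scfg.countries
            }
        else:
            prices = None
        survey, truth = gen_household_survey(scfg, prices=prices)
        if config.drop_countries_first:
            dropped = scfg.countries[: config.drop_countries_first]
            survey = survey[~survey["country"].isin(dropped)].reset_index(drop=True)
        system = gen_toy_mrio(
            scfg.n_regions, scfg.n_sectors, config.seed, categories=scfg.categories
        )
        vat = gen_vat_table(
            n_countries=len(survey["country"].unique()),
            seed=config.seed,
            categories=scfg.categories,
            meat_categories=scfg.meat_categories,
            countries=sorted(survey["country"].unique()),
        )
        costs = gen_social_cost_table()
        survey.to_csv(out / "survey.csv", index=False)
        write_mrio_csv(system, out / "mrio.csv")
        vat_df = vat.applied.copy()
        vat_df.insert(0, "standard", vat.standard)
        vat_df.to_csv(out / "vat.csv", index_label="country")
        (out / "social_costs.json").write_text(
            json.dumps({"costs": costs.costs, "sources": costs.sources}, indent=1)
        )
        artifacts.extend(
            [out / "survey.csv", out / "mrio.csv", out / "vat.csv", out / "social_costs.json"]
        )
        return scfg, survey, truth, system, vat, costs

    scfg, survey, truth, system, vat, costs = run_stage("synth", _synth)
    categories = scfg.categories

    # --- prep --------------------------------------------------------------
    def _prep():
        clean, log = clean_households(survey)
        countries = sorted(clean["country"].unique())
        regions = {c: f"M{i % 4}" for i, c in enumerate(countries)}
        clean = impute_cross_country(clean, regions)
        clean = impute_within_country(clean)
        clean.to_csv(out / "survey_clean.csv", index=False)
        log.to_jsonl(out / "exclusion_log.jsonl")
        artifacts.extend([out / "survey_clean.csv", out / "exclusion_log.jsonl"])
        return clean

    clean = run_stage("prep", _prep)
    countries = sorted(clean["country"].unique())

    # --- footprint ---------------------------------------------------------
    def _footprint():
        country_region = {
            c: system.region_labels[i] for i, c in enumerate(countries)
        }
        expend = weighted_expenditures(clean, categories)
        calibrated = calibrate_demand(system, expend, country_region)
        char = CharacterizationTable.default_for_regions(
            system.region_labels, seed=config.seed + 17
        )
        account = build_account(calibrated, char)
        ghg_totals = account.totals("ghg")
        mu = demand_intensity(ghg_totals, expend)
        home = [country_region[c] for c in countries]
        shares = split_domestic_imported(account.data.droplevel("country"), home)
        account.data.stack().rename("value").reset_index().to_csv(
            out / "footprints.csv", index=False
        )
        mu.to_csv(out / "mu_ghg.csv", index_label="country")
        shares.to_csv(out / "origin_shares.csv", index_label="measure")
        artifacts.extend(
            [out / "footprints.csv", out / "mu_ghg.csv", out / "origin_shares.csv"]
        )
        return expend, account, mu, home

    expend, account, mu, home_regions = run_stage("footprint", _footprint)

    # --- estimate ----------------------------------------------------------
    def _estimate():
        ests = estimate_all(clean, spec=config.spec, uv_adjust=config.uv_adjust)
        rows = []
        for c, (obs, fit, ce) in ests.items():
            fit.to_json(out / f"fit_{c}.json")
            artifacts.append(out / f"fit_{c}.json")
            for i, ci in enumerate(ce.categories):
                for j, cj in enumerate(ce.categories):
                    rows.append(
                        {
                            "country": c,
                            "category_i": ci,
                            "category_j": cj,
                            "elas": ce.eta_m.iloc[i, j],
                            "sd": ce.eta_m_sd.iloc[i, j],
                        }
                    )
        pd.DataFrame(rows).to_csv(out / "elasticities.csv", index=False)
        artifacts.append(out / "elasticities.csv")
        return ests

    ests = run_stage("estimate", _estimate)
    etas = {c: ests[c][2].eta_m for c in ests}

    # --- simulate ----------------------------------------------------------
    def _simulate():
        sim = simulate_policies(etas, vat, mu, account, tau_ghg=config.tau_ghg)
        for scen in ("vat_reform", "ghg_price"):
            sim[scen].to_tidy().to_csv(out / f"sim_{scen}.csv", index=False)
            artifacts.append(out / f"sim_{scen}.csv")
        reductions = {
            scen: sim[scen].reductions(INDICATORS) for scen in ("vat_reform", "ghg_price")
        }
        payload = {"tau_star": sim["tau_star"], "reductions": reductions}
        (out / "tau_star.json").write_text(json.dumps(payload, indent=1))
        artifacts.append(out / "tau_star.json")
        return sim

    sim = run_stage("simulate", _simulate)

    # --- welfare -----------------------------------------------------------
    def _welfare():
        frames = []
        agg_rows = []
        benefits = {}
        for scen in ("vat_reform", "ghg_price"):
            res: SimulationResult = sim[scen]
            per_country = []
            for c, (obs, fit, _) in ests.items():
                dpp = res.price_changes.loc[c, categories].to_numpy()
                if fit.spec.numeraire:
                    dpp = np.append(dpp, 0.0)
                dp_log = np.log1p(dpp)
                log_col, delta_col = cost_of_living(fit, obs, dp_log)
                x1 = post_policy_expenditures(obs, fit, dpp)
                ncat = len(categories)
                x0 = (obs.w * np.exp(obs.x)[:, None])[:, :ncat]
                x1 = x1[:, :ncat]
                r0 = vat.applied.loc[c, categories].to_numpy()
                if scen == "vat_reform":
                    r1 = vat.reform_rates().loc[c, categories].to_numpy()
                    dt_ghg = np.zeros(len(x1))
                else:
                    r1 = r0
                    dt_ghg = ghg_revenue(
                        x1, r0, mu.loc[c, categories].to_numpy(), res.tau_ghg
                    )
                dt_vat = vat_revenue_change(x0, x1, r0, r1)
                wr = WelfareResult(
                    scenario=scen,
                    household_id=np.arange(len(x1)),
                    log_col=log_col,
                    delta_col=delta_col,
                    delta_t_vat=dt_vat,
                    delta_t_ghg=dt_ghg,
                    weights=obs.weight,
                )
                df = wr.to_frame()
                df["country"] = c
                per_country.append(df)
                rev_gain = -dt_vat + dt_ghg
                col_agg = aggregate(delta_col, obs.weight, config.mean_household_size)
                rev_agg = aggregate(rev_gain, obs.weight, config.mean_household_size)
                agg_rows.append(
                    {
                        "scenario": scen,
                        "country": c,
                        "mean_welfare_cost": col_agg["per_household"],
                        "mean_revenue_gain": rev_agg["per_household"],
                        "net_cost": col_agg["per_household"] - rev_agg["per_household"],
                        "net_cost_per_capita": (
                            col_agg["per_capita"] - rev_agg["per_capita"]
                        ),
                    }
                )
            frames.extend(per_country)
            benefits[scen] = monetize(res.delta, costs, home_regions)
        pd.concat(frames, ignore_index=True).to_csv(out / "welfare.csv", index=False)
        pd.DataFrame(agg_rows).to_csv(out / "welfare_aggregate.csv", index=False)
        (out / "monetized_benefits.json").write_text(json.dumps(benefits, indent=1))
        artifacts.extend(
            [
                out / "welfare.csv",
                out / "welfare_aggregate.csv",
                out / "monetized_benefits.json",
            ]
        )
        return agg_rows

    run_stage("welfare", _welfare)

    # --- bootstrap ---------------------------------------------------------
    if config.run_bootstrap:

        def _bootstrap():
            from .uncertainty import bootstrap_pipeline

            boot = bootstrap_pipeline(
                clean,
                vat,
                mu,
                account,
                b=config.bootstrap_b,
                seed=config.seed,
                spec=config.spec,
                uv_adjust=config.uv_adjust,
            )
            boot.to_csv(out / "bootstrap.csv")
            (out / "bootstrap_summary.json").write_text(
                json.dumps(boot.summary_json(), indent=1)
            )
            artifacts.extend([out / "bootstrap.csv", out / "bootstrap_summary.json"])
            return boot

        run_stage("bootstrap", _bootstrap)

    manifest = {
        "package_version": __version__,
        "config": _jsonable(config.to_dict()),
        "seed": config.seed,
        "stages": list(timings),
        "artifacts": {p.name: _sha256(p) for p in sorted(set(artifacts))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "timings.json").write_text(json.dumps(timings, indent=1))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
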