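"""Censored LA-EASI estimation: observations, probits, SUR fit, elasticities."""

import warnings

import numpy as np
import pandas as pd
import pytest

from foodtax.easi import (
    DemandObservations,
    EASIFit,
    EASISpec,
    build_observations,
    compute_elasticities,
    country_mean_elasticities,
    fit_censored_easi,
    fit_selection_probits,
)
from foodtax.orchestration import estimate_country
from foodtax.surveyprep import clean_households, impute_within_country
from foodtax.synthdata import (
    DEMOGRAPHICS,
    SyntheticConfig,
    gen_household_survey,
)


def gen_clean(seed=0, n=2000, n_cat=4, **kw):
    cfg = SyntheticConfig(
        n_households=n, n_countries=1, n_categories=n_cat, seed=seed, **kw
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        survey, truth = gen_household_survey(cfg)
        clean, _ = clean_households(survey)
        clean = impute_within_country(clean)
    return clean, truth


def two_category_table(log_prices, x_total, shares):
    """One household, two categories, for hand-checked Stone algebra."""
    exp_a = shares[0] * x_total
    exp_b = shares[1] * x_total
    table = pd.DataFrame(
        {
            "household_id": ["h0"],
            "country": ["C"],
            **{d: [0] for d in DEMOGRAPHICS},
            "weight": [1.0],
            "total_expenditure": [x_total * 5],
            "total_food_expenditure": [x_total],
            "exp_a": [exp_a],
            "qty_a": [1.0],
            "exp_b": [exp_b],
            "qty_b": [1.0],
        }
    )
    prices = pd.DataFrame({"a": [np.exp(log_prices[0])], "b": [np.exp(log_prices[1])]})
    return table, prices


class TestBuildObservations:
    def test_hand_computed_stone_deflation(self):
        lp = np.array([0.3, -0.2])
        w = np.array([0.6, 0.4])
        table, prices = two_category_table(lp, x_total=50.0, shares=w)
        obs = build_observations(table, prices)
        x = np.log(50.0)
        assert obs.w[0] == pytest.approx(w)
        assert obs.p[0] == pytest.approx(lp - x)
        assert obs.y[0] == pytest.approx(x - w @ lp)

    def test_unit_prices_give_y_equal_x(self):
        table, prices = two_category_table(np.zeros(2), x_total=20.0, shares=[0.5, 0.5])
        obs = build_observations(table, prices)
        assert obs.y[0] == pytest.approx(np.log(20.0))

    def test_ytilda_equals_stone_for_homogeneous_sample(self):
        lp = np.array([0.1, -0.1])
        tables = []
        for _ in range(3):
            t, prices = two_category_table(lp, x_total=30.0, shares=[0.7, 0.3])
            tables.append(t)
        table = pd.concat(tables, ignore_index=True)
        prices = pd.concat([prices] * 3, ignore_index=True)
        y_stone = build_observations(table, prices, EASISpec(deflator="stone")).y
        y_tilda = build_observations(table, prices, EASISpec(deflator="ytilda")).y
        assert np.allclose(y_stone, y_tilda)

    def test_centred_variant_subtracts_median(self, small_survey):
        survey, truth = small_survey
        sub = survey[survey.country == "C00"].reset_index(drop=True)
        uv = pd.DataFrame(
            {c: sub[f"exp_{c}"] / sub[f"qty_{c}"].replace(0, np.nan) for c in truth.categories}
        ).fillna(1.0)
        y0 = build_observations(sub, uv).y
        yc = build_observations(sub, uv, EASISpec(center_y=True)).y
        assert np.allclose(yc, y0 - np.median(y0))

    def test_non_positive_price_rejected(self):
        table, prices = two_category_table(np.zeros(2), 10.0, [0.5, 0.5])
        prices.iloc[0, 0] = 0.0
        with pytest.raises(ValueError, match="strictly positive"):
            build_observations(table, prices)

    def test_numeraire_variant_appends_composite_good(self):
        table, prices = two_category_table(np.zeros(2), 20.0, [0.5, 0.5])
        obs = build_observations(table, prices, EASISpec(numeraire=True))
        assert obs.categories[-1] == "numeraire"
        assert obs.w.shape[1] == 3
        assert obs.w[0].sum() == pytest.approx(1.0)  # shares of total spending


class TestSelectionProbits:
    def test_no_zeros_forces_degenerate_correction(self):
        clean, _ = gen_clean(seed=1, n=300, censoring_rate=0.0, zero_quantity_rate=0.0)
        obs, fit, _ = estimate_country(clean)
        assert np.allclose(fit.Phi, 1.0)
        assert np.allclose(fit.phi, 0.0)

    def test_intercept_only_fifty_percent_zeros(self):
        rng = np.random.default_rng(0)
        N, n = 2000, 1
        d = (rng.random((N, n)) < 0.5).astype(float)
        obs = DemandObservations(
            country="C",
            categories=["a"],
            w=d * 0.5,
            p=np.zeros((N, n)),
            log_prices=np.zeros((N, n)),
            x=np.zeros(N),
            y=np.zeros(N),
            z=np.zeros((N, 0)),
            s=np.ones((N, 1)),
            d=d,
            weight=np.ones(N),
            spec=EASISpec(),
        )
        gamma, Phi, phi = fit_selection_probits(obs)
        assert np.allclose(Phi, d.mean(), atol=0.03)
        assert np.isclose(Phi[0, 0], Phi[-1, 0])  # constant across households

    def test_gamma_recovery_within_three_standard_errors(self):
        clean, truth = gen_clean(seed=5, n=10_000, censoring_rate=0.25)
        obs, fit, _ = estimate_country(clean)
        import statsmodels.api as sm

        gamma_true = truth.by_country["C00"].gamma
        # oracle: direct statsmodels probit per category with its bse
        for i in range(len(obs.categories)):
            res = sm.GLM(
                obs.d[:, i],
                obs.s,
                family=sm.families.Binomial(link=sm.families.links.Probit()),
                var_weights=obs.weight,
            ).fit()
            assert np.all(
                np.abs(np.asarray(res.params) - gamma_true[i]) < 3 * np.asarray(res.bse) + 1e-6
            )
            assert np.allclose(fit.gamma[i], res.params, atol=1e-6)


class TestCensoredFit:
    def test_symmetry_imposed_exactly(self):
        clean, _ = gen_clean(seed=2, n=600)
        _, fit, _ = estimate_country(clean)
        assert (fit.A == fit.A.T).all()
        assert (fit.B == fit.B.T).all()

    def test_null_price_model_estimates_near_zero(self):
        from foodtax.synthdata import EASIParams, default_easi_params

        base = default_easi_params(4)
        params = EASIParams(
            b=base.b, A=np.zeros((4, 4)), B=np.zeros((4, 4)), C=base.C, D=base.D
        )
        clean, truth = gen_clean(
            seed=3, n=4000, censoring_rate=0.0, zero_quantity_rate=0.0,
            quality_effect_scale=0.0, true_easi_params=params,
        )
        _, fit, _ = estimate_country(clean)
        assert np.abs(fit.A).max() < 0.02
        assert np.abs(fit.B).max() < 0.02

    def test_censoring_free_collapse_matches_plain_sur(self):
        clean, _ = gen_clean(seed=4, n=1500, censoring_rate=0.0, zero_quantity_rate=0.0)
        obs1, fit_cens, _ = estimate_country(clean, spec=EASISpec(censored=True))
        obs2, fit_plain, _ = estimate_country(clean, spec=EASISpec(censored=False))
        assert np.abs(fit_cens.A - fit_plain.A).max() < 1e-8
        assert np.abs(fit_cens.B - fit_plain.B).max() < 1e-8
        assert np.abs(fit_cens.b - fit_plain.b).max() < 1e-8
        assert np.allclose(fit_cens.f, 0.0)

    def test_parameter_recovery_uncensored_large_sample(self):
        clean, truth = gen_clean(
            seed=6, n=20_000, censoring_rate=0.0, zero_quantity_rate=0.0
        )
        _, fit, _ = estimate_country(clean)
        for name in ("A", "B", "C", "D", "b"):
            err = np.abs(getattr(fit, name) - getattr(truth.params, name)).max()
            assert err < 0.05, f"{name} off by {err}"

    def test_rank_deficiency_names_offending_regressors(self):
        clean, _ = gen_clean(seed=7, n=400)
        clean["age_gt45"] = clean["female_head"]  # duplicate demographic
        with pytest.raises(np.linalg.LinAlgError, match="offending regressors"):
            estimate_country(clean)

    def test_homogeneity_end_to_end(self):
        """Rescaling all prices and expenditures by a common factor leaves
        shares, implicit utility and elasticities unchanged."""
        clean, _ = gen_clean(seed=8, n=800)
        lam = 7.3
        scaled = clean.copy()
        for c in scaled.columns:
            if c.startswith("exp_") or c.startswith("total_"):
                scaled[c] = scaled[c] * lam
            # quantities unchanged -> unit values scale by lam
        obs1, fit1, ce1 = estimate_country(clean)
        obs2, fit2, ce2 = estimate_country(scaled)
        assert np.allclose(obs1.w, obs2.w)
        assert np.allclose(obs1.y, obs2.y)
        assert np.allclose(ce1.eta_m.to_numpy(), ce2.eta_m.to_numpy(), atol=1e-6)

    def test_n_minus_1_variant_reconstructs_adding_up(self):
        clean, truth = gen_clean(
            seed=9, n=6000, censoring_rate=0.0, zero_quantity_rate=0.0
        )
        _, fit, _ = estimate_country(
            clean, spec=EASISpec(censored=False, n_minus_1=True)
        )
        assert fit.b[0].sum() == pytest.approx(1.0)
        for r in range(1, 5):
            assert fit.b[r].sum() == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fit.A.sum(axis=0), 0.0, atol=1e-12)
        assert np.allclose(fit.A, fit.A.T)
        assert np.abs(fit.A - truth.params.A).max() < 0.05

    @pytest.mark.parametrize(
        "spec",
        [
            EASISpec(deflator="ytilda"),
            EASISpec(center_y=True),
            EASISpec(weighted=False),
            EASISpec(pz_interactions=True),
            EASISpec(numeraire=True),
        ],
        ids=["ytilda", "ycentered", "unweighted", "pzint", "numeraire"],
    )
    def test_specification_variants_run_and_stay_symmetric(self, spec):
        clean, _ = gen_clean(seed=10, n=700)
        _, fit, ce = estimate_country(clean, spec=spec)
        assert (fit.A == fit.A.T).all()
        assert np.isfinite(ce.eta_m.to_numpy()).all()


def make_fit_and_obs(n=3, N=50, seed=0, A=None, B=None, b=None, shares=None):
    rng = np.random.default_rng(seed)
    A = np.zeros((n, n)) if A is None else A
    B = np.zeros((n, n)) if B is None else B
    b_arr = np.zeros((5, n))
    b_arr[0] = 1.0 / n
    if b is not None:
        b_arr = b
    if shares is None:
        w = rng.dirichlet(np.full(n, 8.0), size=N)
    else:
        w = np.tile(shares, (N, 1))
    spec = EASISpec()
    obs = DemandObservations(
        country="C",
        categories=[f"c{i}" for i in range(n)],
        w=w,
        p=rng.normal(0, 0.1, (N, n)),
        log_prices=rng.normal(0, 0.1, (N, n)),
        x=rng.normal(0, 0.2, N),
        y=rng.normal(0, 0.3, N),
        z=np.zeros((N, 2)),
        s=np.ones((N, 1)),
        d=np.ones((N, n)),
        weight=np.ones(N),
        spec=spec,
    )
    fit = EASIFit(
        categories=obs.categories,
        spec=spec,
        b=b_arr,
        A=A,
        B=B,
        C=np.zeros((n, 2)),
        D=np.zeros((n, 2)),
        f=np.zeros(n),
        Phi=np.ones((N, n)),
        phi=np.zeros((N, n)),
    )
    return fit, obs


class TestElasticityFormulas:
    def test_zero_price_terms_collapse(self):
        """With A + By = 0 and no censoring the compensated matrix is
        w_i - 1 on the diagonal and w_j off the diagonal."""
        shares = np.array([0.5, 0.3, 0.2])
        fit, obs = make_fit_and_obs(shares=shares)
        es = compute_elasticities(fit, obs)
        expected = np.tile(shares, (3, 1)) - np.eye(3)
        assert np.allclose(es.eta_pe[0], expected)

    def test_unitary_expenditure_elasticities(self):
        fit, obs = make_fit_and_obs()
        es = compute_elasticities(fit, obs)
        assert np.allclose(es.eta_ee, 1.0)

    def test_slutsky_back_transform_recovers_compensated(self):
        rng = np.random.default_rng(3)
        M = rng.normal(0, 0.02, (3, 3))
        A = (M + M.T) / 2
        A = A - A.mean(0) - A.mean(1)[:, None] + A.mean()
        fit, obs = make_fit_and_obs(A=A, seed=3)
        es = compute_elasticities(fit, obs)
        back = es.eta_m + es.eta_ee[:, :, None] * es.shares[:, None, :]
        assert np.allclose(back, es.eta_pe, equal_nan=True)

    def test_share_floor_marks_household_rows_undefined(self):
        shares = np.array([0.001, 0.499, 0.5])
        fit, obs = make_fit_and_obs(shares=shares)
        es = compute_elasticities(fit, obs)
        assert not es.valid[0, 0]
        assert np.isnan(es.eta_pe[0, 0, 0])
        assert es.valid[0, 1]

    def test_estimated_elasticities_match_fd_truth(self, small_survey):
        """End-to-end: country means from the estimated system stay close
        to the generator's finite-difference truth on a small sample."""
        survey, truth = small_survey
        sub = survey[survey.country == "C00"].reset_index(drop=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clean, _ = clean_households(sub)
            clean = impute_within_country(clean)
            _, _, ce = estimate_country(clean)
        _, _, m_truth = truth.fd_elasticities("C00")
        # n=400 is small; just require the right sign and rough magnitude
        assert np.all(np.diag(ce.eta_m.to_numpy()) < 0)
        assert np.abs(np.diag(ce.eta_m.to_numpy()) - np.diag(m_truth)).max() < 0.5


class TestCountryMeans:
    def test_identical_households_mean_is_each(self):
        shares = np.array([0.4, 0.6])
        fit, obs = make_fit_and_obs(n=2, N=10, shares=shares)
        obs.x = np.zeros(10)
        es = compute_elasticities(fit, obs)
        ce = country_mean_elasticities(es, "C")
        assert np.allclose(ce.eta_m.to_numpy(), es.eta_m[0])
        assert np.allclose(ce.eta_m_sd.to_numpy(), 0.0)

    def test_weighted_mean_hand_case(self):
        fit, obs = make_fit_and_obs(n=2, N=2, shares=np.array([0.5, 0.5]))
        es = compute_elasticities(fit, obs)
        es.eta_m[0] = np.array([[-1.0, 0.0], [0.0, -1.0]])
        es.eta_m[1] = np.array([[-0.6, 0.0], [0.0, -0.6]])
        es.weights = np.array([1.0, 3.0])
        ce = country_mean_elasticities(es, "C")
        assert ce.eta_m.iloc[0, 0] == pytest.approx(-0.7)

    def test_permutation_invariance(self):
        fit, obs = make_fit_and_obs(n=3, N=40, seed=9)
        es = compute_elasticities(fit, obs)
        ce1 = country_mean_elasticities(es, "C")
        perm = np.random.default_rng(0).permutation(40)
        for attr in ("eta_pe", "eta_ee", "eta_m", "semi_p", "semi_y", "shares", "valid"):
            setattr(es, attr, getattr(es, attr)[perm])
        es.weights = es.weights[perm]
        ce2 = country_mean_elasticities(es, "C")
        assert np.allclose(ce1.eta_m.to_numpy(), ce2.eta_m.to_numpy())

    def test_all_undefined_cell_raises(self):
        shares = np.array([0.001, 0.999])
        fit, obs = make_fit_and_obs(n=2, shares=shares)
        es = compute_elasticities(fit, obs)
        with pytest.raises(ValueError, match="undefined"):
            country_mean_elasticities(es, "C")

    def test_elasticity_csv_layout(self, tmp_path):
        fit, obs = make_fit_and_obs(n=2, N=5, shares=np.array([0.5, 0.5]))
        es = compute_elasticities(fit, obs)
        ce = country_mean_elasticities(es, "C")
        path = tmp_path / "elas.csv"
        ce.to_csv(path)
        df = pd.read_csv(path)
        assert set(df.columns) == {"country", "category_i", "category_j", "elas", "sd"}
        assert len(df) == 4


class TestSerialization:
    def test_fit_json_roundtrippable(self, tmp_path):
        clean, _ = gen_clean(seed=11, n=400)
        _, fit, _ = estimate_country(clean)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        import json

        payload = json.loads(path.read_text())
        assert np.allclose(np.array(payload["A"]), fit.A)
        assert payload["spec"]["censored"] is True
        assert "A symmetric" in payload["restrictions"]
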