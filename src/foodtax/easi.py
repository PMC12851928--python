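"""Censored linear-approximated EASI demand systems and elasticities.

The implicit-Marshallian budget-share system estimated here is

    w_h = sum_{r=0}^{4} b_r y_h^r + A p_h + C z_h + B p_h y_h + D z_h y_h + e_h

with budget shares ``w_h`` over ``n`` food categories, normalized log prices
``p_h = ln(ptilde_h) - x_h`` (log unit values minus log nominal food
expenditure, which imposes homogeneity), implicit utility
``y_h = x_h - w_h' ln(ptilde_h)`` (nominal expenditure deflated with the
household Stone index), demographics ``z_h`` and Slutsky symmetry imposed
through shared parameters (A = A', B = B').

Zero observed expenditures are treated as the outcome of an upstream binary
choice: a probit per category yields fitted cdf/pdf values that enter the
share equations in the usual two-step fashion — every regressor of equation
``i`` is multiplied by the fitted cdf ``Phi_hi`` and the fitted pdf
``phi_hi`` enters with a free coefficient ``f_i``.  Because adding-up cannot
be imposed on a censoring-corrected system, all ``n`` equations are
estimated jointly by (sample-weighted) seemingly unrelated regression with
cross-equation symmetry restrictions; an uncensored n-1-equation variant
with adding-up imposed is available as a specification switch, as are a
common Stone deflator, centred utility, unweighted estimation,
price-demographics interactions and an incomplete system with a composite
numeraire.

Compensated (Hicksian) price and expenditure elasticities follow from the
semi-elasticity matrices of the fitted system; Marshallian elasticities are
obtained through the Slutsky equation and are the ones used for policy
simulation (the compensated/uncompensated labelling of the simulation
matrix is ambiguous in parts of the literature; this package uses the
Slutsky-transformed Marshallian matrix).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "EASISpec",
    "DemandObservations",
    "EASIFit",
    "ElasticitySet",
    "CountryElasticities",
    "build_observations",
    "fit_selection_probits",
    "fit_censored_easi",
    "compute_elasticities",
    "country_mean_elasticities",
]

SHARE_FLOOR = 0.005
PHI_CLIP = 1e-10
NUMERAIRE = "numeraire"


@dataclass
class EASISpec:
    """Specification switches of the demand-system estimation.

    The defaults are the main specification: household-specific Stone
    deflator, uncentred utility, sample-weighted SUR over all n equations
    with the censoring correction.
    """

    deflator: str = "stone"          # "stone" | "ytilda"
    center_y: bool = False
    center_stat: str = "median"      # centring statistic when center_y
    weighted: bool = True
    censored: bool = True
    impose_homogeneity: bool = True  # zero row/column sums of A and B
    n_minus_1: bool = False          # uncensored n-1 system, adding-up imposed
    pz_interactions: bool = False    # sum_l z_l E_l p term
    numeraire: bool = False          # incomplete system with composite non-food good

    def __post_init__(self) -> None:
        if self.deflator not in ("stone", "ytilda"):
            raise ValueError("deflator must be 'stone' or 'ytilda'")
        if self.center_stat not in ("median", "mean"):
            raise ValueError("center_stat must be 'median' or 'mean'")
        if self.n_minus_1 and self.censored:
            raise ValueError(
                "the n-1 adding-up variant is only available uncensored"
            )


@dataclass
class DemandObservations:
    """Estimation-ready observations for one country."""

    country: str
    categories: list[str]
    w: np.ndarray            # (N, n) observed budget shares
    p: np.ndarray            # (N, n) normalized log prices ln(ptilde) - x
    log_prices: np.ndarray   # (N, n) raw log prices ln(ptilde)
    x: np.ndarray            # (N,) log nominal food expenditure
    y: np.ndarray            # (N,) implicit utility (per spec deflator)
    z: np.ndarray            # (N, L)
    s: np.ndarray            # (N, 2 + L) selection covariates [1, z, x]
    d: np.ndarray            # (N, n) 1 = positive expenditure observed
    weight: np.ndarray       # (N,) sample weights
    spec: EASISpec

    @property
    def n(self) -> int:
        return len(self.categories)

    @property
    def N(self) -> int:
        return self.w.shape[0]


def build_observations(
    table: pd.DataFrame,
    prices: pd.DataFrame,
    spec: EASISpec | None = None,
    demographics: list[str] | None = None,
) -> DemandObservations:
    """Assemble demand observations from a category-level household table.

    Parameters
    ----------
    table:
        Household table of one country with columns ``exp_<cat>``, the
        recorded ``total_food_expenditure``, a ``weight`` column and the
        demographic dummies.
    prices:
        Household x category table of (quality-adjusted) unit-value prices
        in levels, strictly positive, aligned with ``table``.
    spec:
        Specification switches; defaults to the main specification.

    Notes
    -----
    Implicit utility uses the household Stone index on raw log prices,
    ``y = x - sum_i w_i ln ptilde_i``, which is invariant to a common
    rescaling of all prices and expenditures; the regressor prices are the
    expenditure-normalized ``p = ln ptilde - x`` (homogeneity).  The
    ``ytilda`` variant deflates with the weighted sample-mean share vector;
    the centred variant subtracts the sample median (or mean) of y.
    """
    spec = spec or EASISpec()
    if demographics is None:
        from .synthdata import DEMOGRAPHICS as demographics  # noqa: PLC0415

    countries = table["country"].unique()
    if len(countries) != 1:
        raise ValueError("build_observations expects a single-country table")
    categories = [c[4:] for c in prices.columns] if all(
        str(c).startswith("exp_") for c in prices.columns
    ) else list(prices.columns)

    pv = prices.to_numpy(dtype=float)
    if (pv <= 0).any() or not np.isfinite(pv).all():
        raise ValueError("prices must be strictly positive and finite")

    exp_cols = [f"exp_{c}" for c in categories]
    expend = table[exp_cols].to_numpy(dtype=float)
    x_total = table["total_food_expenditure"].to_numpy(dtype=float)
    if (x_total <= 0).any():
        raise ValueError("total food expenditure must be positive")

    if spec.numeraire:
        if "total_expenditure" not in table.columns:
            raise ValueError("numeraire variant needs a total_expenditure column")
        grand = table["total_expenditure"].to_numpy(dtype=float)
        w_food = expend / grand[:, None]
        w = np.column_stack([w_food, 1.0 - w_food.sum(axis=1)])
        pv = np.column_stack([pv, np.ones(len(grand))])
        categories = categories + [NUMERAIRE]
        x = np.log(grand)
    else:
        w = expend / x_total[:, None]
        x = np.log(x_total)

    log_prices = np.log(pv)
    p = log_prices - x[:, None]
    weight = table["weight"].to_numpy(dtype=float)
    if (weight <= 0).any():
        raise ValueError("sample weights must be positive")

    if w.sum(axis=1).max() <= 0:
        raise ValueError("households with zero observed food shares; clean first")
    # Stone weights: a censored household's observed shares sum to less
    # than one, and which items are missing is selection-driven, so using
    # observed shares alone would correlate the deflator with the selection
    # process.  Zero-share items therefore enter the household Stone index
    # at the (weighted) sample-mean share of purchasing households, and the
    # completed weight vector is renormalized to sum to one — which also
    # keeps y invariant to the monetary scale.
    pos = expend > 0
    if spec.numeraire:
        pos = np.column_stack([pos, np.ones(len(x), dtype=bool)])
    wbar = np.zeros(w.shape[1])
    for j in range(w.shape[1]):
        if pos[:, j].any():
            wbar[j] = np.average(w[pos[:, j], j], weights=weight[pos[:, j]])
    if spec.deflator == "stone":
        w_stone = np.where(pos, w, wbar[None, :])
        w_stone = w_stone / w_stone.sum(axis=1, keepdims=True)
        y = x - np.einsum("ij,ij->i", w_stone, log_prices)
    else:
        wnorm = wbar / wbar.sum()
        y = x - log_prices @ wnorm
    if spec.center_y:
        c = np.median(y) if spec.center_stat == "median" else y.mean()
        y = y - c

    z = table[list(demographics)].to_numpy(dtype=float)
    s = np.column_stack([np.ones(len(x)), z, x])
    d = (expend > 0).astype(float)
    if spec.numeraire:
        d = np.column_stack([d, np.ones(len(x))])

    return DemandObservations(
        country=str(countries[0]),
        categories=categories,
        w=w,
        p=p,
        log_prices=log_prices,
        x=x,
        y=y,
        z=z,
        s=s,
        d=d,
        weight=weight,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Selection probits
# ---------------------------------------------------------------------------

def _ridge_probit(
    s: np.ndarray, d: np.ndarray, w: np.ndarray, lam: float = 1e-3
) -> np.ndarray:
    """Weighted probit MLE with a small L2 penalty on the slopes.

    Fallback for (quasi-)separated categories where the unpenalized fit
    diverges.
    """

    def negll(g: np.ndarray) -> float:
        eta = s @ g
        ll = d * norm.logcdf(eta) + (1.0 - d) * norm.logcdf(-eta)
        return -float(np.sum(w * ll)) + lam * float(np.sum(g[1:] ** 2))

    def grad(g: np.ndarray) -> np.ndarray:
        eta = s @ g
        pdf = norm.pdf(eta)
        cdf = np.clip(norm.cdf(eta), 1e-12, 1 - 1e-12)
        score = w * pdf * (d / cdf - (1.0 - d) / (1.0 - cdf))
        gr = -(s * score[:, None]).sum(axis=0)
        gr[1:] += 2.0 * lam * g[1:]
        return gr

    res = minimize(negll, np.zeros(s.shape[1]), jac=grad, method="BFGS")
    return res.x


def fit_selection_probits(
    obs: DemandObservations,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First-stage probits of the zero/positive outcome per category.

    Returns ``(gamma, Phi, phi)``: coefficient rows per category and the
    per-household fitted standard-normal cdf/pdf values.  Categories without
    any zero observation are degenerate and get ``Phi = 1`` and ``phi = 0``
    (the correction then collapses to the uncensored share system for that
    equation).  Probits are weighted with the same sample weights as the
    SUR stage when the specification is weighted.
    """
    N, n = obs.d.shape
    k = obs.s.shape[1]
    gamma = np.full((n, k), np.nan)
    Phi = np.ones((N, n))
    phi = np.zeros((N, n))
    w = obs.weight if obs.spec.weighted else np.ones(N)
    for i in range(n):
        di = obs.d[:, i]
        if di.min() == di.max():
            continue  # degenerate: no zeros (or no positives) observed
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GLM(
                    di,
                    obs.s,
                    family=sm.families.Binomial(link=sm.families.links.Probit()),
                    var_weights=w,
                )
                res = model.fit(maxiter=200)
            g = np.asarray(res.params)
            if not np.isfinite(g).all() or np.abs(g).max() > 20.0:
                raise ValueError("divergent probit fit")
        except Exception:
            warnings.warn(
                f"probit for category {obs.categories[i]!r} is (quasi-)separated; "
                "using ridge-penalized fit",
                stacklevel=2,
            )
            g = _ridge_probit(obs.s, di, w)
        gamma[i] = g
        eta = obs.s @ g
        Phi[:, i] = np.clip(norm.cdf(eta), PHI_CLIP, 1.0)
        phi[:, i] = norm.pdf(eta)
    return gamma, Phi, phi


# ---------------------------------------------------------------------------
# Stacked symmetric SUR with censoring correction
# ---------------------------------------------------------------------------

@dataclass
class EASIFit:
    """Estimated demand-system parameters and diagnostics."""

    categories: list[str]
    spec: EASISpec
    b: np.ndarray                 # (5, n)
    A: np.ndarray                 # (n, n) symmetric
    B: np.ndarray                 # (n, n) symmetric
    C: np.ndarray                 # (n, L)
    D: np.ndarray                 # (n, L)
    f: np.ndarray                 # (n,) pdf-term coefficients
    E: np.ndarray | None = None   # (L, n, n) price-demographics interactions
    gamma: np.ndarray | None = None
    Phi: np.ndarray | None = None
    phi: np.ndarray | None = None
    sigma: np.ndarray | None = None   # residual covariance across equations
    residuals: np.ndarray | None = None
    n_iter: int = 0
    converged: bool = True
    param_names: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def to_json(self, path) -> None:
        """Serialize parameters, restrictions and diagnostics to JSON."""
        payload = {
            "categories": self.categories,
            "spec": asdict(self.spec),
            "b": self.b.tolist(),
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "C": self.C.tolist(),
            "D": self.D.tolist(),
            "f": self.f.tolist(),
            "E": None if self.E is None else self.E.tolist(),
            "sigma": None if self.sigma is None else self.sigma.tolist(),
            "n_iter": self.n_iter,
            "converged": self.converged,
            "restrictions": ["A symmetric", "B symmetric"],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _pair_index(n: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n) for j in range(i, n)]


def _build_design(
    obs: DemandObservations, Phi: np.ndarray, phi: np.ndarray
) -> tuple[np.ndarray, list[str], dict]:
    """Stacked design tensor (N, n_eq, K) with shared symmetric parameters.

    Every regressor of equation i is multiplied by Phi[:, i]; symmetric A
    and B are parameterized by their upper triangles so the restriction
    holds exactly by construction.  The pdf term enters only for categories
    with censoring (all-zero phi columns would be void regressors).
    """
    spec = obs.spec
    N, n = obs.w.shape
    L = obs.z.shape[1]
    y = obs.y
    p = obs.p
    z = obs.z
    cats = obs.categories

    if spec.n_minus_1:
        n_eq = n - 1
        p_use = p[:, :-1] - p[:, -1:]
        pairs = _pair_index(n - 1)
        homog = False
    else:
        n_eq = n
        p_use = p
        homog = spec.impose_homogeneity
        # With homogeneity, A and B have zero row sums: only relative
        # prices matter, so the free parameters are the off-diagonal upper
        # triangles and each pair (i, j) loads p_j - p_i in equation i.
        # This also removes the common -x component of the normalized
        # prices from the price block, which would otherwise be nearly
        # collinear with the Engel-curve polynomial in y.
        pairs = (
            [(i, j) for i in range(n) for j in range(i + 1, n)]
            if homog
            else _pair_index(n)
        )

    cols: list[np.ndarray] = []
    names: list[str] = []
    layout: dict = {"n_eq": n_eq, "pairs": pairs}

    ypow = np.column_stack([y**r for r in range(5)])
    for r in range(5):
        for i in range(n_eq):
            col = np.zeros((N, n_eq))
            col[:, i] = Phi[:, i] * ypow[:, r]
            cols.append(col)
            names.append(f"b{r}[{cats[i]}]")
    layout["b"] = (0, 5 * n_eq)

    layout["homog"] = homog

    def price_block(scale: np.ndarray, label: str) -> None:
        start = len(cols)
        for (i, j) in pairs:
            col = np.zeros((N, n_eq))
            if homog:
                col[:, i] += Phi[:, i] * (p_use[:, j] - p_use[:, i]) * scale
                col[:, j] += Phi[:, j] * (p_use[:, i] - p_use[:, j]) * scale
            else:
                col[:, i] += Phi[:, i] * p_use[:, j] * scale
                if j != i:
                    col[:, j] += Phi[:, j] * p_use[:, i] * scale
            cols.append(col)
            names.append(f"{label}[{cats[i]},{cats[j]}]")
        layout[label] = (start, len(cols))

    price_block(np.ones(N), "A")
    price_block(y, "B")

    start = len(cols)
    for l in range(L):
        for i in range(n_eq):
            col = np.zeros((N, n_eq))
            col[:, i] = Phi[:, i] * z[:, l]
            cols.append(col)
            names.append(f"C[{cats[i]},z{l}]")
    layout["C"] = (start, len(cols))

    start = len(cols)
    for l in range(L):
        for i in range(n_eq):
            col = np.zeros((N, n_eq))
            col[:, i] = Phi[:, i] * z[:, l] * y
            cols.append(col)
            names.append(f"D[{cats[i]},z{l}]")
    layout["D"] = (start, len(cols))

    if spec.pz_interactions:
        start = len(cols)
        for l in range(L):
            for i in range(n_eq):
                for j in range(n_eq):
                    col = np.zeros((N, n_eq))
                    col[:, i] = Phi[:, i] * z[:, l] * p_use[:, j]
                    cols.append(col)
                    names.append(f"E{l}[{cats[i]},{cats[j]}]")
        layout["E"] = (start, len(cols))

    f_eqs = []
    if spec.censored:
        start = len(cols)
        for i in range(n_eq):
            if np.any(phi[:, i] > 0.0):
                col = np.zeros((N, n_eq))
                col[:, i] = phi[:, i]
                cols.append(col)
                names.append(f"f[{cats[i]}]")
                f_eqs.append(i)
        layout["f"] = (start, len(cols))
    layout["f_eqs"] = f_eqs

    X = np.stack(cols, axis=2)  # (N, n_eq, K)
    return X, names, layout


def _unpack(beta: np.ndarray, layout: dict, obs: DemandObservations) -> dict:
    """Map the stacked coefficient vector back onto named matrices,
    reconstructing the dropped equation of the n-1 variant from adding-up."""
    spec = obs.spec
    n = obs.n
    L = obs.z.shape[1]
    n_eq = layout["n_eq"]
    pairs = layout["pairs"]

    lo, hi = layout["b"]
    b_eq = beta[lo:hi].reshape(5, n_eq)
    homog = layout.get("homog", False)

    def price_unpack(label: str) -> np.ndarray:
        lo, hi = layout[label]
        M = np.zeros((n_eq, n_eq))
        for (i, j), v in zip(pairs, beta[lo:hi]):
            M[i, j] = M[j, i] = v
        if homog:
            np.fill_diagonal(M, 0.0)
            np.fill_diagonal(M, -M.sum(axis=1))
        return M

    A_eq = price_unpack("A")
    B_eq = price_unpack("B")
    lo, hi = layout["C"]
    C_eq = beta[lo:hi].reshape(L, n_eq).T
    lo, hi = layout["D"]
    D_eq = beta[lo:hi].reshape(L, n_eq).T
    E = None
    if spec.pz_interactions:
        lo, hi = layout["E"]
        E = beta[lo:hi].reshape(L, n_eq, n_eq)
    f = np.zeros(n)
    if spec.censored:
        lo, hi = layout["f"]
        for i, v in zip(layout["f_eqs"], beta[lo:hi]):
            f[i] = v

    if not spec.n_minus_1:
        return {"b": b_eq, "A": A_eq, "B": B_eq, "C": C_eq, "D": D_eq, "E": E, "f": f}

    # Adding-up reconstruction of the dropped nth equation: column sums of
    # A, B, C, D are zero; b_0 columns sum to one, higher b_r to zero.
    b = np.zeros((5, n))
    b[:, :-1] = b_eq
    b[0, -1] = 1.0 - b_eq[0].sum()
    for r in range(1, 5):
        b[r, -1] = -b_eq[r].sum()
    A = np.zeros((n, n))
    A[:-1, :-1] = A_eq
    A[:-1, -1] = -A_eq.sum(axis=1)
    A[-1, :-1] = A[:-1, -1]
    A[-1, -1] = -A[:-1, -1].sum()
    B = np.zeros((n, n))
    B[:-1, :-1] = B_eq
    B[:-1, -1] = -B_eq.sum(axis=1)
    B[-1, :-1] = B[:-1, -1]
    B[-1, -1] = -B[:-1, -1].sum()
    C = np.vstack([C_eq, -C_eq.sum(axis=0)])
    D = np.vstack([D_eq, -D_eq.sum(axis=0)])
    return {"b": b, "A": A, "B": B, "C": C, "D": D, "E": E, "f": f}


def _rank_check(Xf: np.ndarray, names: list[str]) -> None:
    from scipy.linalg import qr

    _, R, piv = qr(Xf, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xf.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < Xf.shape[1]:
        offending = [names[k] for k in piv[rank:]]
        raise np.linalg.LinAlgError(
            "rank-deficient demand-system design; offending regressors: "
            + ", ".join(offending)
        )


def fit_censored_easi(
    obs: DemandObservations,
    Phi: np.ndarray | None = None,
    phi: np.ndarray | None = None,
    spec: EASISpec | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> EASIFit:
    """Estimate the (censored) LA-EASI system by symmetric-restricted SUR.

    One-step feasible GLS on the restriction-reduced stacked system,
    iterating the cross-equation residual covariance to convergence.  The
    covariance is eigenvalue-floored before inversion because the residuals
    of an (uncensored) share system are linearly dependent across equations
    by adding-up.
    """
    spec = spec or obs.spec
    if spec is not obs.spec:
        obs.spec = spec
    N, n = obs.w.shape
    if not spec.censored or Phi is None:
        Phi_use = np.ones((N, n))
        phi_use = np.zeros((N, n))
        if spec.censored and Phi is None:
            raise ValueError("censored fit requires first-stage Phi and phi")
    else:
        Phi_use, phi_use = Phi, phi

    X, names, layout = _build_design(obs, Phi_use, phi_use)
    n_eq = layout["n_eq"]
    K = X.shape[2]
    target = obs.w[:, :n_eq]
    omega = obs.weight if spec.weighted else np.ones(N)
    sw = np.sqrt(omega)

    sigma = np.eye(n_eq)
    beta = None
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        evals, evecs = np.linalg.eigh(sigma)
        floor = max(evals.max(), 1e-300) * 1e-8
        P = (evecs / np.sqrt(np.clip(evals, floor, None))) @ evecs.T  # Sigma^-1/2
        Xt = np.einsum("ab,hbk->hak", P, X) * sw[:, None, None]
        wt = (target @ P.T) * sw[:, None]
        Xf = Xt.reshape(N * n_eq, K)
        wf = wt.reshape(N * n_eq)
        sol, _, rank, _ = np.linalg.lstsq(Xf, wf, rcond=None)
        if rank < K:
            _rank_check(Xf, names)
        resid = target - np.einsum("hak,k->ha", X, sol)
        sigma = (omega[:, None] * resid).T @ resid / omega.sum()
        if beta is not None and np.max(np.abs(sol - beta)) < tol:
            beta = sol
            converged = True
            break
        beta = sol

    parts = _unpack(beta, layout, obs)
    return EASIFit(
        categories=obs.categories,
        spec=spec,
        b=parts["b"],
        A=parts["A"],
        B=parts["B"],
        C=parts["C"],
        D=parts["D"],
        E=parts["E"],
        f=parts["f"],
        Phi=Phi_use,
        phi=phi_use,
        sigma=sigma,
        residuals=resid,
        n_iter=n_iter,
        converged=converged,
        param_names=names,
    )


# ---------------------------------------------------------------------------
# Elasticities
# ---------------------------------------------------------------------------

@dataclass
class ElasticitySet:
    """Household-level elasticities with validity masks and weights.

    The weight used for country means is sample weight times nominal food
    expenditure, so means are representative of aggregate expenditures.
    Households whose budget share for a category falls below the floor have
    that category's elasticity row marked undefined (the compensated formula
    divides by the share).
    """

    categories: list[str]
    semi_p: np.ndarray   # (N, n, n) Hicksian price semi-elasticities
    semi_y: np.ndarray   # (N, n) Hicksian expenditure semi-elasticities
    eta_pe: np.ndarray   # (N, n, n) compensated price elasticities
    eta_ee: np.ndarray   # (N, n) expenditure elasticities
    eta_m: np.ndarray    # (N, n, n) Marshallian price elasticities
    shares: np.ndarray   # (N, n)
    valid: np.ndarray    # (N, n) boolean
    weights: np.ndarray  # (N,)


def compute_elasticities(
    fit: EASIFit, obs: DemandObservations, share_floor: float = SHARE_FLOOR
) -> ElasticitySet:
    """Household elasticities from the fitted system.

    Compensated:  eta^PE = diag(w)^-1 Phi (A + B y) + 1 w' - I
    Expenditure:  eta^EE = diag(w)^-1 Phi (sum_r r b_r y^(r-1) + B p + D z) + 1
    Marshallian:  eta^M_ij = eta^PE_ij - eta^EE_i w_j   (Slutsky)
    """
    n = fit.n
    N = obs.N
    y = obs.y
    w = obs.w
    Phi = fit.Phi if fit.Phi is not None else np.ones((N, n))

    semi_p = Phi[:, :, None] * (fit.A[None, :, :] + fit.B[None, :, :] * y[:, None, None])
    if fit.E is not None:
        semi_p = semi_p + Phi[:, :, None] * np.einsum("hl,lij->hij", obs.z, fit.E)
    grad_y = (
        sum(r * fit.b[r] * y[:, None] ** (r - 1) for r in range(1, 5))
        + obs.p @ fit.B.T
        + obs.z @ fit.D.T
    )
    semi_y = Phi * grad_y

    valid = w >= share_floor
    w_safe = np.where(valid, w, np.nan)
    eta_pe = semi_p / w_safe[:, :, None] + w[:, None, :] - np.eye(n)[None, :, :]
    eta_ee = semi_y / w_safe + 1.0
    eta_m = eta_pe - eta_ee[:, :, None] * w[:, None, :]

    weights = obs.weight * np.exp(obs.x)
    return ElasticitySet(
        categories=obs.categories,
        semi_p=semi_p,
        semi_y=semi_y,
        eta_pe=eta_pe,
        eta_ee=eta_ee,
        eta_m=eta_m,
        shares=w,
        valid=valid,
        weights=weights,
    )


@dataclass
class CountryElasticities:
    """Weighted country-mean elasticity matrices (and dispersions)."""

    country: str
    categories: list[str]
    eta_pe: pd.DataFrame
    eta_ee: pd.Series
    eta_m: pd.DataFrame
    eta_m_sd: pd.DataFrame

    def to_csv(self, path) -> None:
        """Tidy layout: country, category_i, category_j, mean, sd."""
        rows = []
        for i, ci in enumerate(self.categories):
            for j, cj in enumerate(self.categories):
                rows.append(
                    {
                        "country": self.country,
                        "category_i": ci,
                        "category_j": cj,
                        "elas": self.eta_m.iloc[i, j],
                        "sd": self.eta_m_sd.iloc[i, j],
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)


def _masked_mean(values: np.ndarray, valid: np.ndarray, weights: np.ndarray):
    """Weighted mean and s.d. over valid entries, weights renormalized."""
    vw = np.where(valid, weights, 0.0)
    tot = vw.sum(axis=0)
    if np.any(tot == 0.0):
        raise ValueError("elasticity cell undefined for every household")
    mean = np.nansum(np.where(valid, values, 0.0) * vw, axis=0) / tot
    dev = np.where(valid, values - mean, 0.0)
    var = np.nansum(dev**2 * vw, axis=0) / tot
    return mean, np.sqrt(var)


def country_mean_elasticities(
    eset: ElasticitySet, country: str = ""
) -> CountryElasticities:
    """Expenditure-and-sample-weight weighted country means.

    Entries of row i are averaged over households whose share for category
    i is above the floor; weights are renormalized over that subset.
    """
    n = len(eset.categories)
    wts = eset.weights[:, None, None] * np.ones((1, n, n))
    valid_m = eset.valid[:, :, None] & np.ones((1, 1, n), dtype=bool)
    pe_mean, _ = _masked_mean(eset.eta_pe, valid_m, wts)
    m_mean, m_sd = _masked_mean(eset.eta_m, valid_m, wts)
    ee_mean, _ = _masked_mean(eset.eta_ee, eset.valid, eset.weights[:, None] * np.ones((1, n)))
    cats = eset.categories
    return CountryElasticities(
        country=country,
        categories=cats,
        eta_pe=pd.DataFrame(pe_mean, index=cats, columns=cats),
        eta_ee=pd.Series(ee_mean, index=cats),
        eta_m=pd.DataFrame(m_mean, index=cats, columns=cats),
        eta_m_sd=pd.DataFrame(m_sd, index=cats, columns=cats),
    )
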