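"""Linear mixed models for turbine-proximity analyses.

The response in every model is the 3-D distance (metres) of a tag fix or
flight line to its nearest turbine hub.  Fixed-effect candidates are drawn
from the habitat score at the turbine (``GETturb``), the score at the
bird/pass location (``GETtag``), the operational phase indicator
(``Postop``), hub wind speed (``Wind``, m/s) and the blade-motion
indicator (``Turn``).  GET scores enter as numeric covariates (single
slopes), Postop and Turn as 0/1 indicators.  Every model carries three
crossed random intercepts — wind-farm, turbine and bird identity — which
absorb the repeated-measures structure of telemetry data.

Fits are Gaussian maximum likelihood (not REML) so that AIC/BIC are
comparable across fixed-effect structures; estimation is delegated to
:class:`statsmodels.regression.mixed_linear_model.MixedLM` with variance
components, and the information criteria are recomputed here from the
log-likelihood with ``df = n_fixed + n_variance_components + 1``.

Variance is decomposed following Nakagawa & Schielzeth: the marginal R²
is the fixed-effects share sigma_f^2 / (sigma_f^2 + sum tau + sigma^2)
with sigma_f^2 the variance of the fixed-effects linear predictor over
the data, and the conditional R² additionally credits the random
intercept variances tau.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)

#: model-term symbol -> data column
VARIABLES = {
    "GETturb": "get_turbine",
    "GETtag": "get_location",
    "Postop": "postop",
    "Wind": "wind_speed",
    "Turn": "turning",
}

RANDOM_FACTORS = {"farm": "farm_id", "turbine": "turbine_id", "bird": "bird_id"}

Z95 = 1.959963984540054


@dataclass(frozen=True)
class CandidateModel:
    """One candidate fixed-effects structure.

    ``terms`` is a tuple of terms; each term is a tuple of variable
    symbols (length 1: main effect, length >= 2: interaction).  Every
    interaction's constituent mains are present by construction.
    """

    label: str
    terms: tuple[tuple[str, ...], ...]

    def formula_rhs(self) -> str:
        if not self.terms:
            return "1"
        return " + ".join(":".join(VARIABLES[v] for v in t) for t in self.terms)

    def columns(self) -> list[str]:
        return sorted({VARIABLES[v] for t in self.terms for v in t})

    @property
    def n_fixed(self) -> int:
        return 1 + len(self.terms)  # intercept + one parameter per term


def _factorial(mains: tuple[str, ...]) -> tuple[tuple[str, ...], ...]:
    """All main effects and interactions up to the full order."""
    from itertools import combinations

    out = []
    for k in range(1, len(mains) + 1):
        out.extend(combinations(mains, k))
    return tuple(out)


def enumerate_before_after_candidates() -> list[CandidateModel]:
    """The 12 before/after candidates (null .. saturated three-way)."""
    M = CandidateModel
    return [
        M("M0", ()),
        M("M1", (("GETturb",),)),
        M("M2", (("Postop",),)),
        M("M3", (("GETtag",),)),
        M("M4", (("GETturb",), ("Postop",))),
        M("M5", (("GETturb",), ("Postop",), ("GETturb", "Postop"))),
        M("M6", (("GETturb",), ("GETtag",))),
        M("M7", (("GETturb",), ("GETtag",), ("GETturb", "GETtag"))),
        M("M8", (("Postop",), ("GETtag",))),
        M("M9", (("Postop",), ("GETtag",), ("Postop", "GETtag"))),
        M("M10", (("GETturb",), ("Postop",), ("GETtag",))),
        M("M11", _factorial(("GETturb", "Postop", "GETtag"))),
    ]


def enumerate_after_candidates() -> list[CandidateModel]:
    """The 27 after-operation candidates over GETtag, GETturb, Turn, Wind."""
    M = CandidateModel
    return [
        M("M0", ()),
        M("M1", (("GETtag",),)),
        M("M2", (("GETturb",),)),
        M("M3", (("Turn",),)),
        M("M4", (("Wind",),)),
        M("M5", (("GETturb",), ("GETtag",))),
        M("M6", (("GETturb",), ("GETtag",), ("GETturb", "GETtag"))),
        M("M7", (("GETturb",), ("Turn",))),
        M("M8", (("GETturb",), ("Turn",), ("GETturb", "Turn"))),
        M("M9", (("Turn",), ("GETtag",))),
        M("M10", (("Turn",), ("GETtag",), ("Turn", "GETtag"))),
        M("M11", (("Wind",), ("GETtag",))),
        M("M12", (("Wind",), ("GETtag",), ("Wind", "GETtag"))),
        M("M13", (("Wind",), ("GETturb",))),
        M("M14", (("Wind",), ("GETturb",), ("Wind", "GETturb"))),
        M("M15", (("Wind",), ("Turn",))),
        M("M16", (("Wind",), ("Turn",), ("Wind", "Turn"))),
        M("M17", (("GETturb",), ("Turn",), ("GETtag",))),
        M("M18", _factorial(("GETturb", "Turn", "GETtag"))),
        M("M19", (("Wind",), ("GETtag",), ("Turn",))),
        M("M20", _factorial(("Wind", "GETtag", "Turn"))),
        M("M21", (("Wind",), ("GETturb",), ("GETtag",))),
        M("M22", _factorial(("Wind", "GETturb", "GETtag"))),
        M("M23", (("Wind",), ("GETturb",), ("Turn",))),
        M("M24", _factorial(("Wind", "GETturb", "Turn"))),
        M("M25", (("Wind",), ("GETtag",), ("GETturb",), ("Turn",))),
        M("M26", _factorial(("Wind", "GETtag", "GETturb", "Turn"))),
    ]


@dataclass
class FitResult:
    """Summary of one maximum-likelihood mixed-model fit."""

    label: str
    params: pd.Series
    conf_int: pd.DataFrame  # columns lo, hi
    pvalues: pd.Series
    llf: float
    df: int
    nobs: int
    aic: float
    bic: float
    sigma2: float
    tau: dict[str, float]
    n_groups: dict[str, int]
    converged: bool
    boundary: list[str] = field(default_factory=list)
    dropped_factors: list[str] = field(default_factory=list)
    p_value_method: str = "wald-normal"
    fixed_predictor: np.ndarray | None = None
    cov_fe: pd.DataFrame | None = None
    design_info: object | None = None
    column_means: pd.Series | None = None
    model_spec: CandidateModel | None = None

    def criteria_consistent(self, tol: float = 1e-8) -> bool:
        return (
            abs(self.aic - (-2 * self.llf + 2 * self.df)) < tol
            and abs(self.bic - (-2 * self.llf + self.df * np.log(self.nobs))) < tol
        )


def fit_lmm(
    model: CandidateModel,
    data: pd.DataFrame,
    response: str = "d3d",
    random_factors: dict[str, str] | None = None,
    min_levels: int = 2,
) -> FitResult:
    """Fit one candidate by Gaussian maximum likelihood.

    Random factors with fewer than ``min_levels`` levels in the
    complete-case data are dropped with a warning (a single-farm fixture
    cannot identify a farm variance) and recorded on the result.
    Optimisation is deterministic: L-BFGS with fixed tolerances, with a
    Powell fallback only if the first attempt fails to converge.
    """
    random_factors = random_factors or RANDOM_FACTORS
    cols = [response] + model.columns() + list(random_factors.values())
    d = data[cols].dropna().copy()
    if len(d) == 0:
        raise ValueError("no complete-case rows for model " + model.label)

    vc, dropped, n_groups = {}, [], {}
    for name, col in random_factors.items():
        k = d[col].nunique()
        if k < min_levels:
            dropped.append(name)
            log.warning("random factor %r has %d level(s); dropped from %s", name, k, model.label)
        else:
            vc[name] = f"0 + C({col})"
            n_groups[name] = k

    formula = f"{response} ~ {model.formula_rhs()}"
    md = smf.mixedlm(
        formula, d, groups=np.ones(len(d)), vc_formula=vc, re_formula="0"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = md.fit(reml=False, method="lbfgs", maxiter=1000, disp=False)
        converged = bool(res.converged)
        if not converged:
            res = md.fit(reml=False, method="powell", maxiter=2000, disp=False)
            converged = bool(res.converged)

    fe = res.fe_params
    k_fe = len(fe)
    df = k_fe + len(vc) + 1
    llf = float(res.llf)
    nobs = len(d)
    aic = -2 * llf + 2 * df
    bic = -2 * llf + df * np.log(nobs)

    vc_names = list(md.exog_vc.names) if vc else []
    tau = {name: float(max(v, 0.0)) for name, v in zip(vc_names, np.atleast_1d(res.vcomp))}
    sigma2 = float(res.scale)
    boundary = [nm for nm, v in tau.items() if v < 1e-8 * max(sigma2, 1.0)]

    cov = res.cov_params()
    cov_fe = pd.DataFrame(
        np.asarray(cov)[:k_fe, :k_fe], index=fe.index, columns=fe.index
    )
    # near-boundary variance components can leave a non-PD Hessian; such
    # fits keep their estimates but get NaN standard errors
    diag = np.diag(cov_fe)
    with np.errstate(invalid="ignore"):
        se = np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)
    ci = pd.DataFrame(
        {"lo": fe - Z95 * se, "hi": fe + Z95 * se}, index=fe.index
    )
    from scipy import stats

    z = fe / se
    pvals = pd.Series(2 * stats.norm.sf(np.abs(z)), index=fe.index)

    return FitResult(
        label=model.label,
        params=fe,
        conf_int=ci,
        pvalues=pvals,
        llf=llf,
        df=df,
        nobs=nobs,
        aic=aic,
        bic=bic,
        sigma2=sigma2,
        tau=tau,
        n_groups=n_groups,
        converged=converged,
        boundary=boundary,
        dropped_factors=dropped,
        fixed_predictor=np.asarray(md.exog @ fe.values),
        cov_fe=cov_fe,
        design_info=md.data.design_info,
        column_means=d[model.columns()].mean() if model.columns() else pd.Series(dtype=float),
        model_spec=model,
    )


# -- model selection ------------------------------------------------------

def delta_table(fits: list[FitResult]) -> pd.DataFrame:
    """AIC/BIC table with deltas relative to the best (lowest) of each."""
    if not fits:
        raise ValueError("delta_table needs at least one fit")
    t = pd.DataFrame(
        {
            "label": [f.label for f in fits],
            "df": [f.df for f in fits],
            "AIC": [f.aic for f in fits],
            "BIC": [f.bic for f in fits],
        }
    )
    t["dAIC"] = t["AIC"] - t["AIC"].min()
    t["dBIC"] = t["BIC"] - t["BIC"].min()
    return t


def select_best(fits: list[FitResult], rule: str = "bic_on_discord") -> str:
    """Pick the best candidate by information criteria.

    If one model minimises both AIC and BIC it wins.  When the two
    criteria disagree, the BIC winner is chosen (``bic_on_discord``,
    the parsimony rule; pass ``rule="aic"`` to prefer AIC instead).
    Remaining ties break toward fewer parameters.
    """
    def argmin(key):
        best = min(key(f) for f in fits)
        tied = [f for f in fits if key(f) == best]
        return min(tied, key=lambda f: f.df).label

    a, b = argmin(lambda f: f.aic), argmin(lambda f: f.bic)
    if a == b:
        return a
    if rule == "aic":
        return a
    return b


# -- variance decomposition ----------------------------------------------

def nakagawa_r2_from_components(
    sigma_f2: float, taus, sigma2: float
) -> tuple[float, float]:
    """Marginal and conditional R² from variance components."""
    taus = list(taus.values()) if isinstance(taus, dict) else list(taus)
    total = sigma_f2 + sum(taus) + sigma2
    if total <= 0:
        return 0.0, 0.0
    return sigma_f2 / total, (sigma_f2 + sum(taus)) / total


def r2_nakagawa(fit: FitResult) -> tuple[float, float]:
    """Nakagawa marginal/conditional R² of a fit.

    sigma_f^2 is the variance (ddof=1, matching R's ``var``) of the
    fixed-effects linear predictor over the modelled observations.
    """
    pred = fit.fixed_predictor
    if (
        pred is None
        or len(pred) < 2
        or (fit.model_spec is not None and not fit.model_spec.terms)
    ):
        sigma_f2 = 0.0  # intercept-only predictor is constant by construction
    else:
        sigma_f2 = float(np.var(pred, ddof=1))
    return nakagawa_r2_from_components(sigma_f2, fit.tau, fit.sigma2)


def fixed_variance_from_r2(marginal: float, conditional: float, sum_tau: float) -> float:
    """Invert the Nakagawa identities for the fixed-effects variance.

    From marginal = f/(f+T+s) and conditional = (f+T)/(f+T+s) it follows
    that f = marginal * T / (conditional - marginal).  Useful for
    reconstructing sigma_f^2 from a published table that prints both R²
    values and the random-intercept variances.
    """
    if marginal < 0 or conditional <= marginal:
        if marginal == 0:
            return 0.0
        raise ValueError("need conditional > marginal >= 0")
    if marginal == 0:
        return 0.0
    return marginal * sum_tau / (conditional - marginal)


def variance_shares(sigma_f2: float, tau: dict[str, float]) -> dict[str, float]:
    """Share of the *explained* variance captured by the fixed effects and
    by each random factor: share_g = tau_g / (sigma_f^2 + sum tau)."""
    denom = sigma_f2 + sum(tau.values())
    if denom <= 0:
        raise ValueError("no explained variance to decompose")
    shares = {name: v / denom for name, v in tau.items()}
    shares["fixed"] = sigma_f2 / denom
    return shares


# -- effect grids ---------------------------------------------------------

def effect_grid(
    fit: FitResult,
    focal: str,
    grid,
    conditions: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Fitted distance ± 95% CI over a grid of one focal predictor.

    ``focal`` and ``conditions`` use data column names (e.g.
    ``wind_speed``, ``turning``).  Non-focal predictors sit at their
    observed means unless pinned in ``conditions``; random effects at 0.
    CIs are delta-method from the fixed-effect covariance.
    """
    import patsy

    if fit.design_info is None or fit.model_spec is None:
        raise ValueError("fit does not carry design information")
    cols = fit.model_spec.columns()
    if focal not in cols:
        raise KeyError(f"{focal!r} is not a predictor of model {fit.label}")
    conditions = conditions or {}
    grid = np.asarray(grid, dtype=float)
    new = pd.DataFrame({c: np.full(len(grid), fit.column_means[c]) for c in cols})
    for k, v in conditions.items():
        new[k] = v
    new[focal] = grid

    X = np.asarray(patsy.build_design_matrices([fit.design_info], new)[0])
    beta = fit.params.values
    pred = X @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov_fe.values, X))
    return pd.DataFrame(
        {focal: grid, "fitted": pred, "lo": pred - Z95 * se, "hi": pred + Z95 * se}
    )
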