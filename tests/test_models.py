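"""Mixed-model layer: candidate enumerations, ML oracle, criteria identities,
selection rules, R² decomposition, effect grids."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from windshy.models import (
    CandidateModel,
    delta_table,
    effect_grid,
    enumerate_after_candidates,
    enumerate_before_after_candidates,
    fit_lmm,
    fixed_variance_from_r2,
    nakagawa_r2_from_components,
    r2_nakagawa,
    select_best,
    variance_shares,
)

# -- candidate enumerations ----------------------------------------------

def test_before_after_set_has_twelve_models():
    cands = enumerate_before_after_candidates()
    assert len(cands) == 12
    assert cands[0].terms == ()  # null: random effects only
    # saturated: 3 mains, 3 two-way, 1 three-way
    lens = sorted(len(t) for t in cands[11].terms)
    assert lens == [1, 1, 1, 2, 2, 2, 3]
    # interactions only ever accompany their main effects
    for m in cands:
        mains = {t[0] for t in m.terms if len(t) == 1}
        for t in m.terms:
            assert set(t) <= mains


def test_before_after_specific_rows():
    cands = {m.label: m for m in enumerate_before_after_candidates()}
    assert cands["M2"].terms == (("Postop",),)
    assert cands["M5"].terms == (("GETturb",), ("Postop",), ("GETturb", "Postop"))
    assert cands["M10"].terms == (("GETturb",), ("Postop",), ("GETtag",))


def test_after_set_has_twenty_seven_models():
    cands = enumerate_after_candidates()
    assert len(cands) == 27
    labels = [m.label for m in cands]
    assert labels == [f"M{i}" for i in range(27)]
    for m in cands:
        mains = {t[0] for t in m.terms if len(t) == 1}
        for t in m.terms:
            assert set(t) <= mains


def test_after_specific_rows():
    cands = {m.label: m for m in enumerate_after_candidates()}
    assert cands["M16"].terms == (("Wind",), ("Turn",), ("Wind", "Turn"))
    # M24: Wind, GETturb, Turn with all two-way and the three-way
    lens = sorted(len(t) for t in cands["M24"].terms)
    assert lens == [1, 1, 1, 2, 2, 2, 3]
    assert {t[0] for t in cands["M24"].terms if len(t) == 1} == {"Wind", "GETturb", "Turn"}
    # M26: four mains, all interactions up to four-way -> 15 terms
    assert len(cands["M26"].terms) == 15
    assert sorted(len(t) for t in cands["M26"].terms) == [1] * 4 + [2] * 6 + [3] * 4 + [4]
    # expected df (n_fixed + 3 variance components + residual)
    assert cands["M26"].n_fixed + 4 == 20
    assert cands["M24"].n_fixed + 4 == 12


# -- fitting --------------------------------------------------------------

def _one_way_data(k=8, m=12, mu=500.0, sa=60.0, se=40.0, seed=4):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, sa, k)
    rows = []
    for i in range(k):
        for _ in range(m):
            rows.append((f"G{i}", mu + a[i] + rng.normal(0, se)))
    df = pd.DataFrame(rows, columns=["bird_id", "d3d"])
    df["farm_id"] = "F"
    df["turbine_id"] = "T"
    return df


def _ml_one_way_oracle(df):
    """Directly maximise the exact Gaussian loglik of the one-way random
    intercept model (block-diagonal covariance) — independent of MixedLM."""
    groups = df.groupby("bird_id")["d3d"]
    ybar = groups.mean().to_numpy()
    counts = groups.size().to_numpy()
    sse_within = float(((df["d3d"] - df.groupby("bird_id")["d3d"].transform("mean")) ** 2).sum())
    n = len(df)
    k = len(ybar)
    m = counts[0]
    assert (counts == m).all()

    def nll(params):
        mu, log_sa2, log_se2 = params
        sa2, se2 = np.exp(log_sa2), np.exp(log_se2)
        # balanced one-way: eigenvalues se2 (n-k fold) and se2 + m*sa2 (k fold)
        lam = se2 + m * sa2
        ll = -0.5 * (
            n * np.log(2 * np.pi)
            + (n - k) * np.log(se2)
            + k * np.log(lam)
            + sse_within / se2
            + m * np.sum((ybar - mu) ** 2) / lam
        )
        return -ll

    res = optimize.minimize(nll, x0=[df["d3d"].mean(), np.log(1000), np.log(1000)],
                            method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    mu, sa2, se2 = res.x[0], np.exp(res.x[1]), np.exp(res.x[2])
    return mu, sa2, se2, -res.fun


def test_ml_variance_components_match_closed_form_oracle():
    df = _one_way_data()
    fit = fit_lmm(CandidateModel("null", ()), df)
    mu, sa2, se2, llf = _ml_one_way_oracle(df)
    assert fit.dropped_factors == ["farm", "turbine"]  # single-level factors dropped
    assert fit.params["Intercept"] == pytest.approx(mu, abs=1e-3)
    assert fit.tau["bird"] == pytest.approx(sa2, rel=1e-4, abs=1e-4)
    assert fit.sigma2 == pytest.approx(se2, rel=1e-4)
    assert fit.llf == pytest.approx(llf, abs=1e-5)


def test_degenerate_random_effects_match_ols():
    rng = np.random.default_rng(8)
    n = 600
    x = rng.uniform(1, 10, n)
    y = 300 + 25 * x + rng.normal(0, 50, n)
    df = pd.DataFrame(
        {
            "d3d": y,
            "get_turbine": x,
            "farm_id": rng.choice(["A", "B"], n),
            "turbine_id": rng.choice([f"T{i}" for i in range(10)], n),
            "bird_id": rng.choice([f"B{i}" for i in range(6)], n),
        }
    )
    fit = fit_lmm(CandidateModel("M1", (("GETturb",),)), df)
    import statsmodels.api as sm

    ols = sm.OLS(y, sm.add_constant(x)).fit()
    se = ols.bse
    assert abs(fit.params["Intercept"] - ols.params[0]) < 2 * se[0]
    assert abs(fit.params["get_turbine"] - ols.params[1]) < 2 * se[1]
    assert sum(fit.tau.values()) < 0.15 * fit.sigma2  # near-zero random variance


def test_parameter_recovery_from_known_truth():
    """Data simulated from the model itself: slopes recovered within CI."""
    rng = np.random.default_rng(15)
    hits = 0
    for rep in range(5):
        n = 2500
        turb = rng.choice([f"T{i}" for i in range(25)], n)
        bird = rng.choice([f"B{i}" for i in range(10)], n)
        farm = np.where(pd.Series(turb).str[1:].astype(int) < 12, "F1", "F2")
        tur_eff = dict(zip([f"T{i}" for i in range(25)], rng.normal(0, 120, 25)))
        bir_eff = dict(zip([f"B{i}" for i in range(10)], rng.normal(0, 60, 10)))
        postop = rng.integers(0, 2, n)
        beta = 75.0
        y = 500 + beta * postop + np.array([tur_eff[t] for t in turb]) \
            + np.array([bir_eff[b] for b in bird]) + rng.normal(0, 170, n)
        df = pd.DataFrame(
            {"d3d": y, "postop": postop, "farm_id": farm, "turbine_id": turb, "bird_id": bird}
        )
        fit = fit_lmm(CandidateModel("M2", (("Postop",),)), df)
        lo, hi = fit.conf_int.loc["postop"]
        hits += lo <= beta <= hi
    assert hits >= 4


def test_aic_bic_identities_and_determinism(ba_records):
    m = enumerate_before_after_candidates()[11]
    f1 = fit_lmm(m, ba_records)
    f2 = fit_lmm(m, ba_records.sample(frac=1.0, random_state=0))  # permuted rows
    assert f1.criteria_consistent()
    assert f1.aic == pytest.approx(-2 * f1.llf + 2 * f1.df)
    assert f1.bic == pytest.approx(-2 * f1.llf + f1.df * np.log(f1.nobs))
    assert f1.params.values == pytest.approx(f2.params.values, rel=1e-6)
    assert f1.llf == pytest.approx(f2.llf, abs=1e-6)


# -- selection ------------------------------------------------------------

def _fake_fit(label, aic, bic, df):
    from windshy.models import FitResult

    return FitResult(
        label=label, params=pd.Series(dtype=float), conf_int=pd.DataFrame(),
        pvalues=pd.Series(dtype=float), llf=0.0, df=df, nobs=100,
        aic=aic, bic=bic, sigma2=1.0, tau={}, n_groups={}, converged=True,
    )


def test_delta_table_minima_are_zero():
    fits = [_fake_fit("A", 100.0, 130.0, 5), _fake_fit("B", 110.0, 120.0, 7)]
    t = delta_table(fits)
    assert t["dAIC"].min() == 0.0 and t["dBIC"].min() == 0.0
    assert t.loc[t.label == "B", "dAIC"].iloc[0] == 10.0
    single = delta_table([_fake_fit("A", 50.0, 60.0, 4)])
    assert single["dAIC"].iloc[0] == 0.0 == single["dBIC"].iloc[0]


def test_select_best_rules():
    # one model minimises both -> chosen
    fits = [_fake_fit("A", 100, 110, 5), _fake_fit("B", 120, 130, 6)]
    assert select_best(fits) == "A"
    # discord: AIC prefers complex, BIC prefers simple -> BIC winner
    fits = [_fake_fit("cplx", 100, 140, 20), _fake_fit("parsim", 105, 120, 8)]
    assert select_best(fits) == "parsim"
    assert select_best(fits, rule="aic") == "cplx"
    # all equal -> fewest parameters
    fits = [_fake_fit("A", 100, 100, 9), _fake_fit("B", 100, 100, 5)]
    assert select_best(fits) == "B"


# -- variance decomposition ----------------------------------------------

def test_r2_identities_and_bounds(ba_records):
    for m in enumerate_before_after_candidates()[:4]:
        f = fit_lmm(m, ba_records)
        marg, cond = r2_nakagawa(f)
        assert 0.0 <= marg <= cond <= 1.0


def test_null_model_marginal_is_zero(ba_records):
    f = fit_lmm(enumerate_before_after_candidates()[0], ba_records)
    marg, cond = r2_nakagawa(f)
    assert marg == 0.0
    assert cond > 0.0


def test_r2_from_components_degenerate():
    assert nakagawa_r2_from_components(0.0, {}, 100.0) == (0.0, 0.0)
    m, c = nakagawa_r2_from_components(50.0, {"a": 0.0}, 50.0)
    assert m == pytest.approx(0.5) and c == pytest.approx(0.5)


def test_fixed_variance_round_trip():
    sigma_f2, taus, sigma2 = 4424.0, {"t": 30898.9, "b": 5244.8, "f": 2481.9}, 27247.2
    marg, cond = nakagawa_r2_from_components(sigma_f2, taus, sigma2)
    back = fixed_variance_from_r2(marg, cond, sum(taus.values()))
    assert back == pytest.approx(sigma_f2, rel=1e-9)
    assert fixed_variance_from_r2(0.0, 0.5, 1000.0) == 0.0
    with pytest.raises(ValueError):
        fixed_variance_from_r2(0.6, 0.5, 1000.0)


def test_variance_shares_sum_to_one():
    shares = variance_shares(4424.0, {"t": 30898.9, "b": 5244.8, "f": 2481.9})
    assert sum(shares.values()) == pytest.approx(1.0, abs=1e-9)
    assert shares["t"] > shares["b"] > shares["f"]
    only = variance_shares(0.0, {"t": 10.0})
    assert only["t"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        variance_shares(0.0, {"t": 0.0})


# -- effect grids ----------------------------------------------------------

def test_effect_grid_linear_identity(ba_records):
    f = fit_lmm(CandidateModel("M1", (("GETturb",),)), ba_records)
    grid = np.arange(1.0, 11.0)
    eg = effect_grid(f, "get_turbine", grid)
    a, b = f.params["Intercept"], f.params["get_turbine"]
    assert eg["fitted"].to_numpy() == pytest.approx(a + b * grid)
    assert (eg["hi"] > eg["fitted"]).all() and (eg["lo"] < eg["fitted"]).all()


def test_effect_grid_interaction_matches_hand_computation(ba_records):
    m = CandidateModel("M5", (("GETturb",), ("Postop",), ("GETturb", "Postop")))
    f = fit_lmm(m, ba_records)
    grid = np.array([2.0, 5.0, 8.0])
    eg = effect_grid(f, "get_turbine", grid, conditions={"postop": 1})
    p = f.params
    hand = p["Intercept"] + p["get_turbine"] * grid + p["postop"] + p["get_turbine:postop"] * grid
    assert eg["fitted"].to_numpy() == pytest.approx(hand)


def test_effect_grid_unknown_focal_rejected(ba_records):
    f = fit_lmm(CandidateModel("M1", (("GETturb",),)), ba_records)
    with pytest.raises(KeyError):
        effect_grid(f, "wind_speed", [1, 2])
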