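"""Cox screening, LASSO selection, risk scoring, KM and time-dependent ROC."""

import numpy as np
import pandas as pd
import pytest

from hmrisk import survival
from hmrisk.survival import CoxResult, RiskModel


def _cohort(expr_rows, genes=None):
    arr = np.asarray(expr_rows, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = [f"s{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=samples)


def _sim_survival(eta, censor_frac=0.2, seed=0, scale=5.0):
    """Exponential survival with hazard proportional to exp(eta)."""
    rng = np.random.default_rng(seed)
    lam0 = np.log(2) / scale
    t = rng.exponential(1.0 / (lam0 * np.exp(eta - np.mean(eta))))
    if censor_frac > 0:
        c = rng.exponential(t.mean() / censor_frac * 0.5, size=len(t))
        event = (t <= c).astype(int)
        time = np.minimum(t, c)
    else:
        time, event = t, np.ones(len(t), dtype=int)
    return pd.DataFrame({"time": np.maximum(time, 1e-6), "event": event},
                        index=[f"s{i}" for i in range(len(t))])


# ---------------------------------------------------------------------------
# Candidate funnel
# ---------------------------------------------------------------------------

def _degs_all(genes, klass="up"):
    return pd.DataFrame({"klass": [klass] * len(genes)}, index=genes)


def test_build_candidates_expression_filter():
    rng = np.random.default_rng(1)
    expr = _cohort(rng.lognormal(1, 0.3, size=(5, 20)))
    expr.iloc[1, :5] = 0.0   # g1 expressed in 75% only
    expr.iloc[3, :4] = 0.0   # g3 expressed in 80% only
    genes = expr.index.tolist()
    got = survival.build_candidates(genes, _degs_all(genes), expr,
                                    expr.columns.tolist(), expressed_frac=0.9)
    assert got == ["g0", "g2", "g4"]
    # vacuous filter returns the full intersection
    assert survival.build_candidates(genes, _degs_all(genes), expr,
                                     expr.columns.tolist(), expressed_frac=0.0) == genes


def test_build_candidates_disjoint_sets_error():
    expr = _cohort(np.ones((2, 4)))
    with pytest.raises(ValueError, match="intersect"):
        survival.build_candidates(["gX"], _degs_all(["g0", "g1"]), expr,
                                  expr.columns.tolist())


# ---------------------------------------------------------------------------
# Univariate screen
# ---------------------------------------------------------------------------

def test_univariate_screen_null_retention_is_rare():
    rng = np.random.default_rng(4)
    n = 300
    expr = _cohort(rng.normal(5, 1, size=(20, n)))
    surv = _sim_survival(np.zeros(n), seed=4)
    seeds, results = survival.univariate_screen(expr.index.tolist(), expr, surv)
    assert len(results) == 20
    assert len(seeds) <= 4  # ~5% of 20 pure-noise genes


def test_univariate_screen_recovers_planted_coefficient():
    rng = np.random.default_rng(7)
    n = 500
    x = rng.normal(0, 1, n)
    surv = _sim_survival(0.5 * x, seed=7)
    expr = _cohort([x + 5.0], genes=["driver"])  # shift keeps values positive
    seeds, results = survival.univariate_screen(["driver"], expr, surv)
    assert seeds == ["driver"]
    assert 0.3 <= results.loc["driver", "coef"] <= 0.7


def test_univariate_screen_pcut_one_keeps_everything():
    rng = np.random.default_rng(9)
    expr = _cohort(rng.normal(5, 1, size=(5, 100)))
    surv = _sim_survival(np.zeros(100), seed=9)
    seeds, _ = survival.univariate_screen(expr.index.tolist(), expr, surv,
                                          p_cut=1.0)
    assert len(seeds) == 5


# ---------------------------------------------------------------------------
# LASSO selection
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", [1, 2, 3])
def test_lasso_keeps_predictive_gene_among_noise(seed):
    rng = np.random.default_rng(seed)
    n = 500
    x = rng.normal(0, 1, size=(6, n))
    surv = _sim_survival(1.0 * x[0], seed=seed)
    expr = _cohort(x + 5.0, genes=[f"g{i}" for i in range(6)])
    kept, info = survival.lasso_select(expr.index.tolist(), expr, surv, seed=seed)
    assert "g0" in kept
    assert info["alpha"] > 0


def test_lasso_penalty_extremes():
    rng = np.random.default_rng(12)
    n = 200
    x = rng.normal(0, 1, size=(4, n))
    surv = _sim_survival(0.8 * x[0], seed=12)
    expr = _cohort(x + 5.0)
    with pytest.raises(ValueError, match="alpha"):
        survival.lasso_select(expr.index.tolist(), expr, surv, alpha=1e6)
    kept, info = survival.lasso_select(expr.index.tolist(), expr, surv, alpha=0)
    assert kept == expr.index.tolist()


# ---------------------------------------------------------------------------
# Multivariate fit and risk model
# ---------------------------------------------------------------------------

def test_hazard_ratio_is_exp_coef_to_full_precision():
    r = CoxResult("g", coef=-0.288, se_coef=0.095, p=0.002)
    assert r.hazard_ratio == pytest.approx(np.exp(-0.288), rel=1e-12)
    assert r.z == pytest.approx(-0.288 / 0.095, rel=1e-12)


def test_multivariate_fit_recovers_planted_coefficients():
    rng = np.random.default_rng(21)
    n = 1000
    coefs = np.array([0.5, -0.4])
    x = rng.normal(0, 1, size=(2, n))
    surv = _sim_survival(coefs @ x, seed=21)
    expr = _cohort(x + 5.0, genes=["gA", "gB"])
    model, fit = survival.multivariate_fit(["gA", "gB"], expr, surv)
    assert fit.loc["gA", "coef"] == pytest.approx(0.5, abs=0.15)
    assert fit.loc["gB", "coef"] == pytest.approx(-0.4, abs=0.15)
    np.testing.assert_allclose(fit["hazard_ratio"], np.exp(fit["coef"]),
                               rtol=1e-12)


def test_multivariate_fit_rejects_collinear_design():
    rng = np.random.default_rng(22)
    x = rng.normal(5, 1, size=100)
    expr = _cohort([x, x], genes=["gA", "gB"])  # identical columns
    surv = _sim_survival(np.zeros(100), seed=22)
    with pytest.raises(ValueError, match="gA.*gB|collinear"):
        survival.multivariate_fit(["gA", "gB"], expr, surv)


def test_risk_score_linearity_and_order_invariance():
    model = RiskModel(["gA", "gB"], np.array([0.5, -1.0]))
    expr = _cohort([[1.0, 2.0, 0.0], [3.0, 0.0, 0.0]], genes=["gA", "gB"])
    rs = model.score(expr)
    assert rs.tolist() == pytest.approx([0.5 * 1 - 1 * 3, 1.0, 0.0])
    doubled = model.score(expr * 2)
    np.testing.assert_allclose(doubled, 2 * rs)
    flipped = RiskModel(["gB", "gA"], np.array([-1.0, 0.5])).score(expr)
    np.testing.assert_allclose(flipped, rs)
    with pytest.raises(KeyError, match="gC"):
        RiskModel(["gC"], np.array([1.0])).score(expr)


def test_risk_score_median_split_balance_and_tie_rule():
    model = RiskModel(["g"], np.array([1.0]))
    expr = _cohort([np.arange(10, dtype=float)], genes=["g"])
    table = survival.risk_score(model, expr)
    counts = table["group"].value_counts()
    assert abs(counts["high"] - counts["low"]) <= 1
    # the median sample itself lands in the low group
    med = table["risk_score"].median()
    assert (table.loc[table["risk_score"] == med, "group"] == "low").all()


# ---------------------------------------------------------------------------
# KM curves and log-rank
# ---------------------------------------------------------------------------

def _scores_frame(groups):
    return pd.DataFrame({
        "risk_score": np.linspace(0, 1, len(groups)),
        "group": groups,
    }, index=[f"s{i}" for i in range(len(groups))])


def test_km_identical_groups_logrank_null():
    times = np.tile(np.arange(1.0, 11.0), 2)
    events = np.ones(20, dtype=int)
    surv = pd.DataFrame({"time": times, "event": events},
                        index=[f"s{i}" for i in range(20)])
    scores = _scores_frame(["high"] * 10 + ["low"] * 10)
    out = survival.km_curves(scores, surv)
    assert out["logrank_p"] == pytest.approx(1.0, abs=1e-9)
    assert out["reliable"]


def test_km_detects_planted_hazard_difference():
    rng = np.random.default_rng(30)
    n = 400
    groups = np.array(["high"] * (n // 2) + ["low"] * (n // 2))
    eta = np.where(groups == "high", np.log(3.0), 0.0)
    surv = _sim_survival(eta, seed=30)
    scores = _scores_frame(list(groups))
    out = survival.km_curves(scores, surv)
    assert out["logrank_p"] < 0.01
    # the high-risk curve sits below the low-risk curve at its median time
    hi, lo = out["curves"]["high"], out["curves"]["low"]
    t_mid = surv["time"].median()
    hi_val = hi[hi.index <= t_mid]["survival"].iloc[-1]
    lo_val = lo[lo.index <= t_mid]["survival"].iloc[-1]
    assert hi_val < lo_val


def test_km_all_censored_flat_and_flagged():
    surv = pd.DataFrame({"time": np.arange(1.0, 21.0), "event": 0},
                        index=[f"s{i}" for i in range(20)])
    scores = _scores_frame(["high"] * 10 + ["low"] * 10)
    out = survival.km_curves(scores, surv)
    assert not out["reliable"]
    for curve in out["curves"].values():
        np.testing.assert_allclose(curve["survival"], 1.0)


# ---------------------------------------------------------------------------
# Time-dependent ROC
# ---------------------------------------------------------------------------

def test_td_roc_null_score_near_half():
    rng = np.random.default_rng(40)
    n = 500
    surv = _sim_survival(np.zeros(n), seed=40)
    scores = pd.Series(rng.normal(size=n), index=surv.index)
    auc = survival.time_dependent_roc(scores, surv, horizons=[3.0])[3.0]
    assert 0.45 <= auc <= 0.55


def test_td_roc_strong_score_and_sign_symmetry():
    rng = np.random.default_rng(41)
    n = 400
    eta = rng.normal(0, 2.0, n)
    surv = _sim_survival(eta, seed=41)
    scores = pd.Series(eta, index=surv.index)
    aucs = survival.time_dependent_roc(scores, surv, horizons=[3.0, 5.0])
    assert aucs[3.0] > 0.85
    flipped = survival.time_dependent_roc(-scores, surv, horizons=[3.0])
    assert flipped[3.0] == pytest.approx(1.0 - aucs[3.0], abs=1e-10)


def test_td_roc_matches_independent_ipcw_implementation():
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    rng = np.random.default_rng(42)
    n = 300
    eta = rng.normal(0, 1.0, n)
    surv = _sim_survival(eta, seed=42)
    scores = pd.Series(eta + rng.normal(0, 0.5, n), index=surv.index)
    mine = survival.time_dependent_roc(scores, surv, horizons=[3.0])[3.0]
    y = Surv.from_arrays(event=surv["event"].astype(bool), time=surv["time"])
    ref = cumulative_dynamic_auc(y, y, scores.to_numpy(), times=[3.0])[0][0]
    assert mine == pytest.approx(ref, abs=1e-6)


def test_td_roc_nn_mode_agrees_roughly_with_ipcw():
    rng = np.random.default_rng(43)
    n = 300
    eta = rng.normal(0, 1.5, n)
    surv = _sim_survival(eta, seed=43)
    scores = pd.Series(eta, index=surv.index)
    ipcw = survival.time_dependent_roc(scores, surv, horizons=[3.0])[3.0]
    nn = survival.time_dependent_roc(scores, surv, horizons=[3.0],
                                     method="nn")[3.0]
    assert nn == pytest.approx(ipcw, abs=0.1)


def test_td_roc_error_paths():
    surv = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [0, 0, 1]},
                        index=["a", "b", "c"])
    scores = pd.Series([0.1, 0.2, 0.3], index=["a", "b", "c"])
    with pytest.raises(ValueError, match="follow-up"):
        survival.time_dependent_roc(scores, surv, horizons=[10.0])
    with pytest.raises(ValueError, match="no events"):
        survival.time_dependent_roc(scores, surv, horizons=[0.5])
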