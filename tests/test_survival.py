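"""Survival-distribution formulas, censored likelihood, MLE, model selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from psmcea import (
    ParametricSurvival,
    fit_mle,
    log_likelihood,
    restricted_mean_survival,
    select_best,
    survival_probability,
)
from psmcea.survival import FAMILIES, SurvivalInputError

# ---------------------------------------------------------------------------
# survivor-function values and shape
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "family, params, t, expected",
    [
        ("loglogistic", (9.06, 2.15), 0.0, 1.0),
        ("loglogistic", (9.06, 2.15), 9.06, 0.5),       # scale = median
        ("exponential", (0.1,), 10.0, np.exp(-1)),
        ("lognormal", (1.80, 0.72), np.exp(1.80), 0.5),  # median = exp(meanlog)
        ("weibull", (0.01, 1.32), 0.0, 1.0),
        ("gompertz", (0.1, 0.05), 0.0, 1.0),
    ],
)
def test_survival_probability_known_values(family, params, t, expected):
    model = ParametricSurvival(family, params)
    assert survival_probability(model, t) == pytest.approx(expected, abs=1e-12)


_param_strategies = {
    "exponential": st.tuples(st.floats(0.01, 2)),
    "weibull": st.tuples(st.floats(0.005, 1), st.floats(0.3, 3)),
    "loglogistic": st.tuples(st.floats(0.5, 40), st.floats(0.3, 4)),
    "lognormal": st.tuples(st.floats(-1, 4), st.floats(0.1, 2)),
    "gompertz": st.tuples(st.floats(-0.2, 0.5), st.floats(0.005, 1)),
    "gengamma": st.tuples(st.floats(-1, 3), st.floats(0.2, 2), st.floats(-1.5, 1.5)),
}


@pytest.mark.parametrize("family", FAMILIES)
def test_survivor_function_is_proper(family):
    """S(0)=1, S in [0,1], and S nonincreasing on a grid, for every family."""

    @given(params=_param_strategies[family])
    def check(params):
        model = ParametricSurvival(family, params)
        grid = np.linspace(0, 200, 401)
        s = model.sf(grid)
        assert s[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(s >= -1e-15) and np.all(s <= 1 + 1e-15)
        assert np.all(np.diff(s) <= 1e-12)

    check()


def test_invalid_inputs_raise():
    with pytest.raises(SurvivalInputError):
        ParametricSurvival("loglogistic", (-1.0, 2.0))
    with pytest.raises(SurvivalInputError):
        ParametricSurvival("loglogistic", (1.0,))
    with pytest.raises(SurvivalInputError):
        ParametricSurvival("exponential", (0.1,)).sf(-1.0)


# ---------------------------------------------------------------------------
# censored log-likelihood
# ---------------------------------------------------------------------------


def test_loglik_exponential_closed_form():
    lam = 0.37
    ipd = pd.DataFrame({"time": [2.0, 3.0], "event": [1, 0]})
    got = log_likelihood(ParametricSurvival("exponential", (lam,)), ipd)
    assert got == pytest.approx(np.log(lam) - 2 * lam - 3 * lam, rel=1e-12)


def test_loglik_empty_data_is_zero():
    assert log_likelihood(ParametricSurvival("weibull", (0.1, 1.2)), pd.DataFrame({"time": [], "event": []})) == 0.0


def test_loglik_matches_numerical_density_oracle():
    """Per-record summation with the density from -dS/dt reproduces the loglik."""
    rng = np.random.default_rng(7)
    model = ParametricSurvival("loglogistic", (9.06, 2.15))
    t = model.ppf(rng.uniform(size=200))
    event = rng.integers(0, 2, size=200)
    ipd = pd.DataFrame({"time": t, "event": event})
    h = 1e-6
    dens = (model.sf(np.maximum(t - h, 0)) - model.sf(t + h)) / (2 * h)
    oracle = float(np.sum(np.where(event == 1, np.log(dens), np.log(model.sf(t)))))
    assert log_likelihood(model, ipd) == pytest.approx(oracle, rel=1e-6)


# ---------------------------------------------------------------------------
# maximum likelihood
# ---------------------------------------------------------------------------


def test_exponential_mle_matches_closed_form():
    """The fitted rate equals events / time-at-risk on censored data."""
    rng = np.random.default_rng(3)
    t = rng.exponential(8.0, size=400)
    cens = rng.uniform(2, 15, size=400)
    time = np.minimum(t, cens)
    event = (t <= cens).astype(int)
    res = fit_mle(pd.DataFrame({"time": time, "event": event}), "exponential")
    closed = event.sum() / time.sum()
    assert res.converged
    assert res.params[0] == pytest.approx(closed, rel=1e-6)
    # information-criteria identities
    assert res.aic == pytest.approx(2 * 1 - 2 * res.loglik, rel=1e-12)
    assert res.bic == pytest.approx(np.log(400) - 2 * res.loglik, rel=1e-12)


def test_weibull_profile_at_unit_shape_matches_exponential_mle():
    """With the Weibull shape pinned to 1 the optimal rate is the exponential MLE."""
    from scipy.optimize import minimize_scalar

    rng = np.random.default_rng(5)
    t = rng.exponential(5.0, size=300)
    cens = np.full(300, 12.0)
    time, event = np.minimum(t, cens), (t <= cens).astype(int)
    ipd = pd.DataFrame({"time": time, "event": event})

    res = minimize_scalar(
        lambda lam: -log_likelihood(ParametricSurvival("weibull", (lam, 1.0)), ipd),
        bounds=(1e-4, 2.0), method="bounded", options={"xatol": 1e-10},
    )
    assert res.x == pytest.approx(event.sum() / time.sum(), rel=1e-5)


@pytest.mark.parametrize("family", FAMILIES)
def test_parameter_recovery_within_5pct(family, recovery_fits):
    """n=5000 uncensored draws recover every parameter within 5%."""
    truth, res = recovery_fits[family]
    assert res.converged, res.message
    scale = np.where(np.abs(truth) > 0, np.abs(truth), 1.0)
    rel = np.abs(res.params - truth) / scale
    assert np.all(rel < 0.05), f"{family}: truth {truth}, got {res.params}"


def test_fit_requires_events():
    ipd = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [0, 0, 1]})
    with pytest.raises(SurvivalInputError):
        fit_mle(ipd, "weibull")


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------


def test_select_best_prefers_parsimony_under_nesting():
    """On large exponential data the exponential outranks generalized gamma."""
    rng = np.random.default_rng(11)
    ipd = pd.DataFrame({"time": rng.exponential(10.0, size=2000), "event": 1})
    ranked = select_best(ipd, ["gengamma", "exponential"])
    order = [r.model.family for r in ranked]
    assert order.index("exponential") < order.index("gengamma")
    by_bic = sorted(ranked, key=lambda r: r.bic)
    assert by_bic[0].model.family == "exponential"


def test_select_best_identifies_strong_loglogistic_shape():
    rng = np.random.default_rng(13)
    truth = ParametricSurvival("loglogistic", (9.0, 2.5))
    ipd = pd.DataFrame({"time": truth.ppf(rng.uniform(size=2000)), "event": 1})
    ranked = select_best(ipd, ["exponential", "weibull", "loglogistic", "lognormal"])
    assert ranked[0].model.family == "loglogistic"


def test_select_best_single_family_passthrough():
    rng = np.random.default_rng(17)
    ipd = pd.DataFrame({"time": rng.exponential(5.0, size=100), "event": 1})
    ranked = select_best(ipd, ["weibull"])
    assert len(ranked) == 1 and ranked[0].model.family == "weibull"


def test_summary_renders(recovery_fits):
    _, res = recovery_fits["loglogistic"]
    text = res.summary()
    assert "loglogistic" in text and "AIC" in text


# ---------------------------------------------------------------------------
# restricted mean survival
# ---------------------------------------------------------------------------


def test_rmst_exponential_closed_form():
    model = ParametricSurvival("exponential", (0.05,))
    got = restricted_mean_survival(model, 174, step=0.1)
    assert got == pytest.approx((1 - np.exp(-8.7)) / 0.05, abs=1e-3)


def test_rmst_loglogistic_arctan_closed_form():
    # for shape k=2 the integral of S is theta * arctan(t / theta)
    theta = 16.12
    model = ParametricSurvival("loglogistic", (theta, 2.0))
    got = restricted_mean_survival(model, 174, step=0.1)
    assert got == pytest.approx(theta * np.arctan(174 / theta), abs=1e-3)


def test_rmst_zero_horizon():
    assert restricted_mean_survival(ParametricSurvival("exponential", (0.1,)), 0.0) == 0.0
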