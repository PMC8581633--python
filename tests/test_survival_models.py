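"""Survival laws: evaluation, medians, censored MLE and AIC/BIC ranking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncocea import (
    FitError,
    ParametricSurvival,
    fit_parametric,
    inverse_survival,
    median_survival,
    rank_models,
    survival_at,
)
from oncocea.survival_models import FAMILIES, _median_numeric

EXAMPLES = {
    "exponential": {"rate": math.log(2)},
    "weibull": {"shape": 1.447, "scale": 17.034},
    "weibullPH": {"shape": 1.3, "rate": 0.05},
    "gompertz": {"shape": 0.05, "rate": 0.04},
    "gamma": {"shape": 1.6, "rate": 0.12},
    "gengamma": {"mu": 2.2, "sigma": 0.8, "q": 0.7},
    "genf": {"mu": 2.2, "sigma": 0.8, "q": 0.5, "p": 0.4},
    "loglogistic": {"shape": 1.783, "scale": 6.675},
    "lognormal": {"meanlog": 2.0, "sdlog": 0.7},
}


@pytest.mark.parametrize("family", sorted(FAMILIES))
def test_survival_function_shape(family):
    """S(0)=1, S in [0,1], non-increasing, vanishing on a 0-600 month grid."""
    model = ParametricSurvival(family, EXAMPLES[family])
    t = np.linspace(0, 600, 1201)
    s = survival_at(model, t)
    assert s[0] == pytest.approx(1.0)
    assert np.all((s >= 0) & (s <= 1))
    assert np.all(np.diff(s) <= 1e-12)
    assert s[-1] < 0.01


def test_survival_point_values():
    """Log-logistic S(scale)=1/2; Weibull tail from direct evaluation."""
    ll = ParametricSurvival("loglogistic", {"shape": 1.783, "scale": 6.675})
    assert survival_at(ll, 6.675) == pytest.approx(0.5, abs=1e-12)
    wb = ParametricSurvival("weibull", {"shape": 1.447, "scale": 17.034})
    assert survival_at(wb, 0.0) == pytest.approx(1.0)
    assert survival_at(wb, 60.0) == pytest.approx(0.00206215692626, rel=1e-10)


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        ParametricSurvival("weibull", {"shape": -1.0, "scale": 17.0})
    with pytest.raises(ValueError):
        ParametricSurvival("weibull", {"shape": 1.0})
    with pytest.raises(ValueError):
        ParametricSurvival("nosuch", {"rate": 1.0})
    wb = ParametricSurvival("weibull", {"shape": 1.447, "scale": 17.034})
    with pytest.raises(ValueError):
        survival_at(wb, -1.0)


@pytest.mark.parametrize("family", sorted(FAMILIES))
def test_median_matches_numeric_bisection(family):
    """Closed-form medians agree with the numeric root of S(t)=1/2 to 1e-9."""
    model = ParametricSurvival(family, EXAMPLES[family])
    assert median_survival(model) == pytest.approx(_median_numeric(model), abs=1e-9)


def test_median_known_values():
    assert median_survival(
        ParametricSurvival("loglogistic", {"shape": 2.499, "scale": 2.076})
    ) == pytest.approx(2.076)
    assert median_survival(
        ParametricSurvival("weibull", {"shape": 1.447, "scale": 17.034})
    ) == pytest.approx(13.22249788, rel=1e-8)
    assert median_survival(
        ParametricSurvival("exponential", {"rate": math.log(2)})
    ) == pytest.approx(1.0)


@given(u=st.floats(0.01, 0.99))
@settings(max_examples=25, deadline=None)
def test_inverse_survival_roundtrip(u):
    model = ParametricSurvival("loglogistic", {"shape": 1.741, "scale": 5.133})
    t = inverse_survival(model, u)
    assert survival_at(model, t) == pytest.approx(u, abs=1e-9)


@pytest.mark.parametrize(
    "family,params",
    [
        ("weibull", {"shape": 1.447, "scale": 17.034}),
        ("loglogistic", {"shape": 1.741, "scale": 5.133}),
        ("exponential", {"rate": 0.1}),
        ("lognormal", {"meanlog": 2.0, "sdlog": 0.7}),
    ],
)
def test_fit_recovers_simulation_truth(family, params):
    """MLE on 500 uncensored draws lands within 10% of the true parameters."""
    model = ParametricSurvival(family, params)
    rng = np.random.default_rng(42)
    times = np.asarray(inverse_survival(model, rng.uniform(size=500)))
    fit = fit_parametric(times, np.ones_like(times), family)
    assert fit.converged
    for name, true in params.items():
        assert fit.model[name] == pytest.approx(true, rel=0.10)


def test_fit_agrees_with_lifelines():
    """Independent MLE cross-check: lifelines' Weibull fitter on the same data."""
    from lifelines import WeibullFitter

    model = ParametricSurvival("weibull", {"shape": 1.447, "scale": 17.034})
    rng = np.random.default_rng(7)
    raw = np.asarray(inverse_survival(model, rng.uniform(size=400)))
    censor = 24.0
    times = np.minimum(raw, censor)
    events = (raw <= censor).astype(int)
    ours = fit_parametric(times, events, "weibull")
    wf = WeibullFitter().fit(times, events)
    assert ours.model["scale"] == pytest.approx(wf.lambda_, rel=1e-3)
    assert ours.model["shape"] == pytest.approx(wf.rho_, rel=1e-3)
    assert ours.loglik == pytest.approx(wf.log_likelihood_, rel=1e-6)


def test_weibull_fit_nests_exponential():
    """Data simulated from an exponential gives a Weibull shape near 1."""
    rng = np.random.default_rng(3)
    times = rng.exponential(10.0, size=500)
    fit = fit_parametric(times, np.ones_like(times), "weibull")
    assert fit.model["shape"] == pytest.approx(1.0, rel=0.15)


def test_fit_bias_shrinks_with_n():
    model = ParametricSurvival("weibull", {"shape": 1.447, "scale": 17.034})
    errs = []
    for n in (100, 500, 2000):
        rng = np.random.default_rng(11)
        times = np.asarray(inverse_survival(model, rng.uniform(size=n)))
        fit = fit_parametric(times, np.ones_like(times), "weibull")
        errs.append(abs(fit.model["shape"] - 1.447) / 1.447)
    assert errs[-1] < errs[0]
    assert errs[-1] < 0.05


def test_fit_degenerate_inputs():
    with pytest.raises(FitError):
        fit_parametric([1.0, 2.0, 3.0], [0, 0, 0], "weibull")
    # a single distinct event time cannot identify two parameters
    fit = fit_parametric([5.0] * 20, [1] * 20, "weibull")
    assert not fit.converged
    with pytest.raises(FitError):
        fit_parametric([5.0] * 20, [1] * 20, "weibull", return_flagged=False)


def test_information_criteria_definition():
    """AIC/BIC recomputed independently from loglik, k and n."""
    rng = np.random.default_rng(5)
    times = rng.weibull(1.4, 200) * 15
    fit = fit_parametric(times, np.ones_like(times), "loglogistic")
    k, n = 2, 200
    assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k, abs=1e-9)
    assert fit.bic == pytest.approx(-2 * fit.loglik + k * math.log(n), abs=1e-9)


def test_rank_models_ordering_and_ties():
    rng = np.random.default_rng(9)
    model = ParametricSurvival("loglogistic", {"shape": 1.741, "scale": 5.133})
    times = np.asarray(inverse_survival(model, rng.uniform(size=500)))
    events = np.ones_like(times)
    fits = [fit_parametric(times, events, f) for f in ("exponential", "loglogistic", "weibull")]
    ranked = rank_models(fits)
    # the generating family must beat exponential by direct likelihood comparison
    assert ranked[0].model.family == "loglogistic"
    assert ranked[0].loglik > [f for f in fits if f.model.family == "exponential"][0].loglik
    # tie-break: equal AIC -> lower BIC first
    a, b = fits[0], fits[1]
    a.aic = b.aic = 100.0
    a.bic, b.bic = 102.0, 101.0
    assert rank_models([a, b])[0] is b
    with pytest.raises(ValueError):
        rank_models([])
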