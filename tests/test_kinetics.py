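"""Chase quantification, first-order decay fitting, curve comparison, Holm."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

import degronscreen as ds
from degronscreen.kinetics import FirstOrderDecay, fit_chase_table
from degronscreen.sequences import ValidationError

from conftest import make_truth


def _series(t, sub, load):
    return pd.DataFrame(
        {"time_min": t, "substrate_signal": sub, "loading_signal": load}
    )


# --- percent remaining --------------------------------------------------

@pytest.mark.parametrize(
    "sub,load,expected",
    [
        ((100, 50), (100, 100), (100, 50)),
        ((100, 80), (100, 160), (100, 50)),
        ((250, 95), (80, 130), (100, None)),  # t=0 always self-normalizes to 100
    ],
)
def test_percent_remaining_values(sub, load, expected):
    pr = ds.percent_remaining(_series([0, 10], sub, load))
    assert pr["percent"].iloc[0] == pytest.approx(100.0)
    if expected[1] is not None:
        assert pr["percent"].iloc[1] == pytest.approx(expected[1])


def test_percent_remaining_invariant_to_common_rescale():
    base = _series([0, 5, 10], [100, 70, 40], [90, 95, 88])
    scaled = base.assign(
        substrate_signal=base.substrate_signal * 7.3,
        loading_signal=base.loading_signal * 7.3,
    )
    np.testing.assert_allclose(
        ds.percent_remaining(base)["percent"],
        ds.percent_remaining(scaled)["percent"],
    )


def test_percent_remaining_error_modes():
    with pytest.raises(ValidationError, match="loading"):
        ds.percent_remaining(_series([0, 5], [100, 50], [100, 0]))
    with pytest.raises(ValidationError, match="t=0"):
        ds.percent_remaining(_series([0, 5], [0, 50], [100, 100]))
    with pytest.raises(ValidationError, match="0-min"):
        ds.percent_remaining(_series([5, 10], [100, 50], [100, 100]))


# --- decay fitting ------------------------------------------------------

def test_fit_recovers_noiseless_rate_exactly():
    t = np.array([0.0, 5.0, 10.0, 20.0])
    fit = ds.fit_decay(t, 100 * np.exp(-0.1 * t))
    assert fit.lambda_ == pytest.approx(0.1, abs=1e-8)
    assert fit.ssr == pytest.approx(0.0, abs=1e-12)


def test_fit_two_points_closed_form():
    fit = ds.fit_decay([0.0, 10.0], [100.0, 50.0])
    assert fit.lambda_ == pytest.approx(math.log(2) / 10, rel=1e-6)
    assert fit.t_half == pytest.approx(10.0, rel=1e-6)


def test_fit_free_amplitude_recovers_scaled_curve():
    t = np.array([0.0, 2.0, 5.0, 10.0, 20.0])
    p = 140.0 * np.exp(-0.2 * t)
    fit = ds.fit_decay(t, p, free_amplitude=True)
    assert fit.amplitude == pytest.approx(140.0, rel=1e-5)
    assert fit.lambda_ == pytest.approx(0.2, rel=1e-5)


def test_half_life_values_and_stable_sentinel():
    assert ds.half_life(math.log(2)) == pytest.approx(1.0)
    assert ds.half_life(0.0693147) == pytest.approx(10.0, rel=1e-4)
    assert ds.half_life(0.0) == math.inf
    t = np.array([0.0, 5.0, 10.0])
    fit = ds.fit_decay(t, [100.0, 100.0, 100.0])
    assert fit.stable
    assert fit.format_t_half().startswith(">")


def test_t_half_strictly_decreasing_in_rate():
    t = np.linspace(0, 30, 7)
    halves = [
        ds.fit_decay(t, 100 * np.exp(-lam * t)).t_half
        for lam in (0.05, 0.1, 0.2, 0.4)
    ]
    assert all(a > b for a, b in zip(halves, halves[1:]))


def test_fit_rejects_degenerate_input():
    with pytest.raises(ValidationError):
        ds.fit_decay([0.0], [100.0])
    with pytest.raises(ValidationError):
        ds.fit_decay([0.0, 5.0], [100.0, -3.0])


def test_fit_chase_table_groups(small_screen):
    params = small_screen.params
    chase = ds.simulate_chases(
        small_screen.truth,
        params,
        np.random.default_rng(2),
        degron_ids=[small_screen.records[0].id],
    )
    fits = fit_chase_table(chase)
    assert set(fits.strain) == {"WT", "doa10"}
    assert (fits.n_reps == params.chase_replicates).all()
    assert (fits["lambda"] >= 0).all()


def test_pooled_fit_recovers_simulated_rate_with_replicate_sd(small_screen):
    rng = np.random.default_rng(6)
    chase = ds.simulate_chase(0.2, ds.SimParams(), rng)
    fit = FirstOrderDecay.from_chase(chase).fit()
    assert fit.lambda_ == pytest.approx(0.2, rel=0.25)
    assert len(fit.replicate_lambdas) == 3
    assert np.isfinite(fit.t_half_sd)


# --- curve comparison ---------------------------------------------------

def _f_sf_oracle(f_obs, d1, d2):
    """Numerical upper-tail F probability from the density, written from scratch."""

    def beta(a, b):
        return math.gamma(a) * math.gamma(b) / math.gamma(a + b)

    def pdf(x):
        num = (d1 * x) ** d1 * d2**d2 / (d1 * x + d2) ** (d1 + d2)
        return math.sqrt(num) / (x * beta(d1 / 2, d2 / 2))

    val, _ = quad(pdf, f_obs, np.inf)
    return val


def test_compare_identical_curves_gives_null_result():
    t = np.array([0.0, 2.0, 5.0, 10.0])
    p = 100 * np.exp(-0.15 * t)
    cmp_res = ds.compare_decay(t, p, t, p)
    assert cmp_res.f_stat == pytest.approx(0.0, abs=1e-9)
    assert cmp_res.p_value == pytest.approx(1.0)


def test_compare_detects_distinct_rates():
    t = np.tile(np.array([0.0, 2.0, 5.0, 10.0, 20.0]), 3)
    rng = np.random.default_rng(13)
    pa = 100 * np.exp(-0.1 * t) * rng.lognormal(0, 0.05, t.size)
    pb = 100 * np.exp(-0.4 * t) * rng.lognormal(0, 0.05, t.size)
    cmp_res = ds.compare_decay(t, pa, t, pb)
    assert cmp_res.p_value < 0.01
    assert cmp_res.lambda_b > cmp_res.lambda_a


def test_compare_p_matches_f_distribution_oracle():
    t = np.array([0.0, 2.0, 5.0, 10.0, 20.0])
    rng = np.random.default_rng(21)
    pa = 100 * np.exp(-0.1 * t) + rng.normal(0, 4, t.size)
    pb = 100 * np.exp(-0.13 * t) + rng.normal(0, 4, t.size)
    pa[0] = pb[0] = 100.0
    pa, pb = np.clip(pa, 0, None), np.clip(pb, 0, None)
    cmp_res = ds.compare_decay(t, pa, t, pb)
    assert cmp_res.p_value == pytest.approx(
        _f_sf_oracle(cmp_res.f_stat, cmp_res.df_num, cmp_res.df_den), rel=1e-6
    )


# --- multiple-comparison adjustment ------------------------------------

def _holm_oracle(pvals):
    order = np.argsort(pvals)
    m = len(pvals)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


@pytest.mark.parametrize(
    "pvals,expected",
    [
        ((0.01, 0.04), (0.02, 0.04)),
        ((0.3,), (0.3,)),
        ((0.01, 0.01), (0.02, 0.02)),
    ],
)
def test_holm_known_values(pvals, expected):
    assert ds.adjust_pvalues(pvals) == pytest.approx(expected)


def test_holm_matches_definition_for_all_small_permutations():
    base_sets = [
        [0.001, 0.02, 0.04, 0.2, 0.9],
        [0.05, 0.05, 0.049, 0.5],
        [0.3, 0.1, 0.7],
    ]
    for base in base_sets:
        for perm in permutations(base):
            p = np.array(perm)
            np.testing.assert_allclose(ds.adjust_pvalues(p), _holm_oracle(p))


def test_adjust_pvalues_validates_range():
    with pytest.raises(ValidationError):
        ds.adjust_pvalues([0.5, 1.2])


# --- steady-state ratios ------------------------------------------------

def test_steady_state_ratio_reference_and_doubling():
    blot = pd.DataFrame(
        {
            "strain": ["WT"] * 4,
            "degron_id": ["none", "none", "d1", "d2"],
            "replicate": [1, 2, 1, 1],
            "substrate_signal": [100.0, 100.0, 200.0, 50.0],
            "loading_signal": [100.0, 100.0, 100.0, 100.0],
        }
    )
    out = ds.steady_state_ratio(blot).set_index("degron_id")
    assert out.loc["none", "ratio"] == pytest.approx(1.0)
    assert out.loc["d1", "ratio"] == pytest.approx(2.0)
    assert out.loc["d2", "ratio"] == pytest.approx(0.5)
    with pytest.raises(ValidationError, match="reference"):
        ds.steady_state_ratio(blot[blot.degron_id != "none"])


def test_steady_state_ratio_recovers_stabilization_factor():
    """A 4x rate drop in the mutant shows up as the predicted level increase."""
    lam, factor = 2.0, 4.0
    truth = make_truth(
        [("d1", "WT", False, lam), ("d1", "uba1", True, lam / factor)]
    )
    params = ds.SimParams()
    blot = ds.simulate_steady_state(
        truth, params, np.random.default_rng(3), replicates=40
    )
    out = ds.steady_state_ratio(blot).set_index(["strain", "degron_id"])
    observed = out.loc[("uba1", "d1"), "ratio"] / out.loc[("WT", "d1"), "ratio"]
    mu = params.dilution_rate
    expected = (lam + mu) / (lam / factor + mu)
    assert observed == pytest.approx(expected, rel=0.15)
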