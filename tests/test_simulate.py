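"""Synthetic-screen generator: determinism, marginal structure, noise models."""

import math

import numpy as np
import pandas as pd
import pytest

import degronscreen as ds
from degronscreen.sequences import ValidationError

from conftest import make_truth


def test_full_determinism_and_seed_sensitivity():
    params = ds.SimParams(n_fragments=25, genome_length=20_000)
    a = ds.simulate_screen(params, seed=5)
    b = ds.simulate_screen(params, seed=5)
    c = ds.simulate_screen(params, seed=6)
    assert a.genome == b.genome
    assert a.records == b.records
    pd.testing.assert_frame_equal(a.plates, b.plates)
    assert a.genome != c.genome
    assert not a.plates["area"].equals(c.plates["area"])


def test_fragment_sizes_orientation_and_empty_library():
    params = ds.SimParams(n_fragments=150, genome_length=50_000)
    _, records = ds.simulate_library(params, np.random.default_rng(3))
    sizes = [r.source.end - r.source.start for r in records]
    assert all(50 <= s <= 400 for s in sizes)
    assert any(r.source.reverse for r in records)
    assert any(not r.source.reverse for r in records)
    assert all(r.length >= 1 for r in records)
    _, empty = ds.simulate_library(params.with_(n_fragments=0), np.random.default_rng(3))
    assert empty == []


def test_genome_too_short_rejected():
    with pytest.raises(ValidationError):
        ds.SimParams(genome_length=100, fragment_size_range=(50, 400))


def test_assign_kinetics_degenerate_and_null_cases():
    records = [
        ds.DegronRecord.from_peptide(f"d{i}", "MKVLF" * 3) for i in range(10)
    ]
    params = ds.SimParams(
        gravy_coef=0.0,
        hydrophobic_run_coef=0.0,
        rate_sigma=0.0,
        log_rate_intercept=math.log(0.2),
        strains=(ds.StrainEffect("doa10", 0.0, 8.0),),
    )
    truth = ds.assign_kinetics(records, params, np.random.default_rng(0))
    assert np.allclose(truth.table["lambda_"], 0.2)
    # pi = 0: mutant rates identical to WT
    wt = truth.table[truth.table.strain == "WT"].set_index("degron_id")["lambda_"]
    mut = truth.table[truth.table.strain == "doa10"].set_index("degron_id")["lambda_"]
    assert np.allclose(wt, mut)
    assert truth.dependent_ids("doa10") == set()


def test_dependent_fraction_converges_to_pi():
    records = [ds.DegronRecord.from_peptide(f"d{i}", "MKVLF") for i in range(2000)]
    truth = ds.assign_kinetics(records, ds.SimParams(), np.random.default_rng(8))
    frac = len(truth.dependent_ids("doa10")) / 2000
    se = math.sqrt(0.5 * 0.5 / 2000)
    assert abs(frac - 0.5) <= 3 * se


def test_plates_noiseless_means_and_saturation_limit():
    truth = make_truth(
        [("d1", "WT", False, 1e9), ("d1", "doa10", True, 1e9 / 8)]
    )
    layout = ds.default_layout(["d1"])
    params = ds.SimParams(plate_noise_cv=0.0, plate_effect_sigma=0.0)
    plates = ds.simulate_plates(truth, layout, params, np.random.default_rng(0))
    ref = plates[plates.role == "URA3_HA_REF"]["area"]
    floor = plates[plates.role == "NO_URA3"]["area"]
    deg = plates[(plates.role == "DEGRON") & (plates.strain == "WT")]["area"]
    b0, K = params.baseline_area_frac, params.michaelis_k
    assert np.allclose(ref, params.a_max * (b0 + (1 - b0) / (1 + K)))
    assert np.allclose(floor, params.a_max * b0)
    # an enormous decay rate drives the expected area to the no-Ura3 baseline
    assert np.allclose(deg, floor.iloc[0], rtol=1e-4)


def test_plates_reject_unknown_degrons():
    truth = make_truth([("d1", "WT", False, 0.1)])
    layout = ds.default_layout(["d1", "mystery"])
    with pytest.raises(ValidationError, match="mystery"):
        ds.simulate_plates(truth, layout, ds.SimParams(), np.random.default_rng(0))


def test_dependent_degron_grows_more_in_mutant():
    """Monte Carlo sign check over 500 simulated plate pairs."""
    truth = make_truth([("d1", "WT", False, 0.2), ("d1", "doa10", True, 0.2 / 8)])
    layout = ds.default_layout(["d1"])
    params = ds.SimParams()
    rng = np.random.default_rng(17)
    mut_means, wt_means = [], []
    for _ in range(500):
        plates = ds.simulate_plates(truth, layout, params, rng)
        deg = plates[plates.role == "DEGRON"]
        wt_means.append(deg[deg.strain == "WT"]["area"].mean())
        mut_means.append(deg[deg.strain == "doa10"]["area"].mean())
    assert np.mean(mut_means) > np.mean(wt_means)


def test_chase_noiseless_and_deterministic():
    params = ds.SimParams(blot_sigma=0.0)
    flat = ds.simulate_chase(0.0, params, np.random.default_rng(0))
    assert np.allclose(flat["substrate_signal"], params.substrate_signal0)
    a = ds.simulate_chase(0.1, ds.SimParams(), np.random.default_rng(4))
    b = ds.simulate_chase(0.1, ds.SimParams(), np.random.default_rng(4))
    pd.testing.assert_frame_equal(a, b)
    with pytest.raises(ValidationError):
        ds.simulate_chase(0.1, ds.SimParams(), timepoints=[-1.0, 0.0])


def test_chase_expectation_at_reciprocal_rate():
    """E[I(1/lambda)/I(0)] ~ exp(-1) over 10^4 replicates (up to lognormal bias)."""
    lam = 0.2
    chase = ds.simulate_chase(
        lam,
        ds.SimParams(),
        np.random.default_rng(9),
        timepoints=[0.0, 1.0 / lam],
        replicates=10_000,
    )
    wide = chase.pivot(index="replicate", columns="time_min", values="substrate_signal")
    ratio = (wide[1.0 / lam] / wide[0.0]).mean()
    assert ratio == pytest.approx(math.exp(-1), rel=0.03)


def test_steady_state_monotone_in_rate():
    truth = make_truth(
        [("d1", "WT", False, 0.05), ("d2", "WT", False, 0.5)]
    )
    tab = truth.table.set_index("degron_id")
    assert tab.loc["d1", "steady_state"] > tab.loc["d2", "steady_state"]
    blot = ds.simulate_steady_state(truth, ds.SimParams(), np.random.default_rng(1))
    assert set(blot.degron_id) == {"none", "d1", "d2"}
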