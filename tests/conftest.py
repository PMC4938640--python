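import numpy as np
import pandas as pd
import pytest

import degronscreen as ds

# Printed properties of the 14-member degron tester set (id, length, GRAVY).
TESTER_TABLE = [
    ("CL1", 16, 0.569),
    ("10-1", 28, 0.268),
    ("10-6", 39, 0.010),
    ("10-13", 17, 0.212),
    ("10-15", 7, 0.429),
    ("10-21", 26, 0.288),
    ("10-31", 33, 0.533),
    ("10-34", 7, 3.943),
    ("10-40", 21, 0.829),
    ("10-43", 22, -0.586),
    ("12-32", 18, 0.650),
    ("12-33", 34, 0.241),
    ("12-86", 19, 1.126),
    ("12-98", 33, 0.664),
]


@pytest.fixture(scope="session")
def tester_records():
    return ds.load_tester_set()


def make_plate(areas_by_role, plate="p1", strain="WT"):
    """Build a one-plate colony table from {(role, degron_id): [areas]}."""
    rows = []
    wells = iter(
        (r, c) for r in "ABCDEFGH" for c in range(1, 13)
    )
    for (role, deg), areas in areas_by_role.items():
        well = next(wells)
        for rep, area in enumerate(areas, start=1):
            rows.append(
                {
                    "plate": plate,
                    "strain": strain,
                    "well_row": well[0],
                    "well_col": well[1],
                    "role": role,
                    "degron_id": deg,
                    "replicate": rep,
                    "area": float(area),
                }
            )
    return pd.DataFrame(rows)


def make_truth(rows):
    """GroundTruth from (degron_id, strain, dependent, lambda_) tuples."""
    table = pd.DataFrame(rows, columns=["degron_id", "strain", "dependent", "lambda_"])
    mu = ds.SimParams().dilution_rate
    table["steady_state"] = mu / (table["lambda_"] + mu)
    return ds.GroundTruth(table=table)


@pytest.fixture(scope="session")
def small_screen():
    """A small but complete simulated screen shared across tests."""
    params = ds.SimParams(n_fragments=40, genome_length=30_000)
    return ds.simulate_screen(params, seed=123, with_chase=False, with_blot=True)
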