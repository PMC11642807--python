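import numpy as np
import pandas as pd
import pytest

from tauspread import (Connectome, RegionAtlas, make_ground_truth,
                       simulate_cohort)


@pytest.fixture(scope="session")
def gt_small():
    """Ground truth on a 40-region synthetic connectome."""
    return make_ground_truth(n_regions=40, rng_seed=11)


@pytest.fixture(scope="session")
def cohort_small(gt_small):
    return simulate_cohort(gt_small, 8, rng_seed=12)


@pytest.fixture()
def toy_atlas():
    """HIP with two leaf children plus a separate 3-deep chain."""
    rows = [
        ("HIP", "HIP", "ipsi", None, 0.0, 0.0, 0.0),
        ("DG", "DG", "ipsi", "HIP", 1.0, 0.0, 0.0),
        ("CA1", "CA1", "ipsi", "HIP", 0.0, 1.0, 0.0),
        ("A", "A", "contra", None, 5.0, 5.0, 5.0),
        ("B", "B", "contra", "A", 6.0, 5.0, 5.0),
        ("C", "C", "contra", "B", 7.0, 5.0, 5.0),
    ]
    df = pd.DataFrame(rows, columns=["region_id", "acronym", "hemisphere",
                                     "parent_id", "x", "y", "z"])
    return RegionAtlas.from_frame(df)


@pytest.fixture()
def tiny_conn():
    A = np.array([[0.0, 1.0], [0.0, 0.0]])
    return Connectome(regions=("r1", "r2"), A=A)


def make_group_cohort(sizes, regions=("R1", "R2"), value=1.0):
    """Cohort with the given number of mice per (genotype, treatment)."""
    rows = []
    for (g, t), n in sizes.items():
        for k in range(n):
            for r in regions:
                rows.append({"mouse_id": f"{g}-{t}-{k}", "genotype": g,
                             "treatment": t, "region_id": r,
                             "pathology": value, "tdt": np.nan})
    return pd.DataFrame(rows)
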