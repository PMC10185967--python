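import itertools

import numpy as np
import pandas as pd
import pytest

from mmnet.cohort import Cohort
from mmnet.panel import DISEASES
from mmnet.synthetic import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def demo_cohort() -> Cohort:
    """Moderate synthetic cohort shared by read-only tests."""
    return generate_cohort(SimulationConfig(n_per_stratum=800, seed=42))


@pytest.fixture(scope="session")
def big_cohort() -> Cohort:
    """Large cohort for asymptotic checks (≈30k records)."""
    return generate_cohort(SimulationConfig(n_per_stratum=5000, seed=7))


def random_cohort_frame(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Small random cohort table for oracle-equivalence tests."""
    prev = rng.uniform(0.05, 0.6, size=len(DISEASES))
    flags = (rng.random((n, len(DISEASES))) < prev).astype(int)
    index = rng.choice([1.0, 0.9, 0.6], size=n, p=[0.4, 0.4, 0.2])
    df = pd.DataFrame(flags, columns=list(DISEASES))
    df.insert(0, "id", [f"r{i}" for i in range(n)])
    df.insert(1, "sex", rng.choice(["male", "female"], size=n))
    df.insert(2, "age_group", "65-69")
    df.insert(3, "weight", 1.0)
    df["eq5d_index"] = index
    df["hrqol"] = np.where(index <= 0.721, "poor", np.where(index == 1.0, "good", "normal"))
    return df


def brute_force_rules(flags: np.ndarray) -> dict[tuple[int, int], tuple[float, float, float]]:
    """Independent oracle: double loop over records for every disease pair.

    Returns {(i, j): (support, confidence_i_to_j, lift)} for i != j.
    """
    flags = [[int(v) for v in row] for row in flags]
    n, k = len(flags), len(flags[0])
    out = {}
    for i, j in itertools.permutations(range(k), 2):
        n_i = n_j = n_ij = 0
        for row in flags:
            n_i += row[i]
            n_j += row[j]
            n_ij += row[i] and row[j]
        support = n_ij / n
        conf = np.nan if n_i == 0 else n_ij / n_i
        lift = np.nan if n_i == 0 or n_j == 0 else (n_ij * n) / (n_i * n_j)
        out[(i, j)] = (support, conf, lift)
    return out
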