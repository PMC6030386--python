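import numpy as np
import pytest

import phyloglmm as pg

# ((A:1,B:2):0.5,C:3); hand-computed patristic distances:
#   d(A,B) = 3.0, d(A,C) = 4.5, d(B,C) = 5.5
HAND_NEWICK = "((A:1,B:2):0.5,C:3);"
HAND_D = {
    ("A", "B"): 3.0,
    ("A", "C"): 4.5,
    ("B", "C"): 5.5,
}


@pytest.fixture
def hand_tree():
    return pg.PhyloDistances.from_newick(HAND_NEWICK)


@pytest.fixture(scope="session")
def small_tree():
    dist, _ = pg.random_tree(20, seed=7)
    return dist


@pytest.fixture(scope="session")
def medium_dataset():
    """One continuous-outcome dataset reused by read-only tests."""
    design = pg.SimulationDesign(
        m=10,
        signal_density_pct=10,
        abundance_level="high",
        outcome_type="continuous",
        seed=42,
    )
    return pg.simulate_dataset(design, n=120, p=60)


def random_instance(rng, n=8, p=6):
    """Small random (Z, dist, y) triple for oracle checks."""
    dist, _ = pg.random_tree(p, seed=int(rng.integers(2**31 - 1)))
    dm = pg.DmParams.default(p)
    _, z = pg.simulate_counts(dm, n, seed=int(rng.integers(2**31 - 1)))
    y = rng.normal(size=n)
    return z, dist, y
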