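import numpy as np
import pytest

from snowmatch.allele_db import AlignmentGrid, AlleleDatabase, AlleleProfile
from snowmatch.synthetic_cohorts import SimulationConfig, make_allele_pool


@pytest.fixture(scope="session")
def pool():
    """Default synthetic allele pool, shared read-only across tests."""
    return make_allele_pool(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def pool_config():
    return SimulationConfig(seed=0)


def make_toy_db(profiles: dict[str, tuple[str, set[int]]],
                consensus: str | None = None) -> AlleleDatabase:
    """Tiny hand-specified database: allele -> (sequence, surface positions).

    Surface positions (1-based) get RSA 0.6, the rest 0.1, so the default
    0.3717 threshold separates them exactly.
    """
    n = len(next(iter(profiles.values()))[0])
    if consensus is None:
        consensus = next(iter(profiles.values()))[0]
    grid = AlignmentGrid(locus_group="toy", consensus=consensus)
    db = AlleleDatabase(grid)
    for name, (seq, surface) in profiles.items():
        rsa = np.full(n, 0.1)
        for p in surface:
            rsa[p - 1] = 0.6
        rsa[[c == "-" for c in seq]] = np.nan
        db.add(AlleleProfile(allele=name, aligned_sequence=seq, rsa=rsa))
    return db
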