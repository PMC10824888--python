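import numpy as np
import pandas as pd
import pytest

from adrsignal.tabulate import ADR_PREFIX, DRUG_PREFIX


def random_reports(rng, n_reports=200, drugs=("D", "E"), adrs=("A", "B", "C")):
    """Report-level frame with random binary flags; every report has >=1 ADR."""
    frame = pd.DataFrame({"report_id": [f"r{i}" for i in range(n_reports)]})
    for d in drugs:
        frame[DRUG_PREFIX + d] = (rng.random(n_reports) < 0.3).astype(int)
    amat = rng.random((n_reports, len(adrs))) < 0.4
    none = ~amat.any(axis=1)
    amat[none, rng.integers(0, len(adrs), none.sum())] = True
    for j, a in enumerate(adrs):
        frame[ADR_PREFIX + a] = amat[:, j].astype(int)
    return frame


@pytest.fixture
def rng():
    return np.random.default_rng(20240116)


@pytest.fixture
def reports(rng):
    return random_reports(rng)


@pytest.fixture
def four_reports():
    """{D,A}, {D,B}, {E,A}, {E,B}."""
    return pd.DataFrame({
        "report_id": ["r1", "r2", "r3", "r4"],
        DRUG_PREFIX + "D": [1, 1, 0, 0],
        DRUG_PREFIX + "E": [0, 0, 1, 1],
        ADR_PREFIX + "A": [1, 0, 1, 0],
        ADR_PREFIX + "B": [0, 1, 0, 1],
    })
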