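import logging

import numpy as np
import pandas as pd
import pytest

from rumiherit import synthio
from rumiherit.tables import AsvTable

logging.getLogger("rumiherit").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_population():
    """A compact simulated flock shared by read-only tests."""
    params = synthio.SynthParams(n_dams=30, n_asvs=40, n_trait_asvs=3, seed=11)
    return synthio.simulate_population(params), params


@pytest.fixture()
def toy_table():
    counts = pd.DataFrame(
        [[2, 2, 4, 0], [0, 2, 2, 4], [1, 0, 3, 6]],
        index=["s1", "s2", "s3"],
        columns=["a1", "a2", "a3", "a4"],
    )
    tax = {
        "a1": "Bacteria;B1;C1;O1;F1;G1;sp1",
        "a2": "Bacteria;B1;C1;O1;F1;G1;sp2",
        "a3": "Bacteria;B1;C1;O1;F2;G2;sp3",
        "a4": "Bacteria;B2;C2;O2;F3;G3;sp4",
    }
    return AsvTable(counts, tax)


def random_pedigree_records(n_founders, n_descendants, rng):
    """Random valid pedigree: founders then descendants with parents drawn
    from earlier animals, sires and dams kept disjoint."""
    sires = [f"S{i}" for i in range(n_founders // 2)]
    dams = [f"D{i}" for i in range(n_founders - n_founders // 2)]
    records = [(a, None, None) for a in sires + dams]
    males, females = list(sires), list(dams)
    for k in range(n_descendants):
        s = males[rng.integers(0, len(males))]
        d = females[rng.integers(0, len(females))]
        name = f"X{k}"
        records.append((name, s, d))
        (males if rng.random() < 0.5 else females).append(name)
    return records
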