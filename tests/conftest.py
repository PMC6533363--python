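import numpy as np
import pandas as pd
import pytest

from aurox.db import load_database
from aurox.ecology import OtuTable


@pytest.fixture(scope="session")
def db():
    return load_database()


@pytest.fixture()
def tiny_otu_table():
    """6-OTU, 8-site table with two co-varying and one anti-varying OTU.

    OTU1/OTU2 scale together across sites, OTU3 runs against them, OTU4-6
    provide background; used for the network brute-force oracle.
    """
    rng = np.random.default_rng(42)
    n_sites = 8
    base = np.linspace(1, 4, n_sites)
    counts = pd.DataFrame(
        {
            "OTU1": (100 * base).astype(int),
            "OTU2": (200 * base).astype(int),
            "OTU3": (500 / base).astype(int),
            "OTU4": rng.integers(50, 150, n_sites),
            "OTU5": rng.integers(50, 150, n_sites),
            "OTU6": np.full(n_sites, 80),
        },
        index=[f"s{i}" for i in range(n_sites)],
    )
    counts.index.name = "site"
    tax = pd.DataFrame(
        {
            "otu": counts.columns,
            "order": [f"Order{i}" for i in range(6)],
            "phylum": ["Ascomycota"] * 6,
        }
    ).set_index("otu")
    meta = pd.DataFrame(
        {
            "site": counts.index,
            "area": ["anomaly"] * 4 + ["reference"] * 4,
            "au": rng.lognormal(1.0, 0.5, n_sites),
            "ph": rng.normal(5.6, 0.2, n_sites),
        }
    ).set_index("site")
    return OtuTable(counts, tax, meta)
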