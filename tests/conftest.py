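import numpy as np
import pandas as pd
import pytest

from kinact import networks, synthetic
from kinact.reference import Phosphoproteome


@pytest.fixture(scope="session")
def small_spec():
    """A small but non-trivial synthetic system shared by unit tests."""
    return synthetic.SynthSpec(
        n_sites=600,
        n_kinases=5,
        substrates_per_kinase=40,
        candidate_fraction=0.6,
        planted=("KIN02", 0.4),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_proteome(small_spec):
    return synthetic.gen_phosphoproteome(small_spec)


@pytest.fixture(scope="session")
def small_network(small_spec, small_proteome):
    return synthetic.gen_weighted_network(small_spec, small_proteome)


@pytest.fixture(scope="session")
def small_config(small_proteome):
    return networks.PruneConfig.default_for(
        "Y", small_proteome, substrates_per_kinase=40,
        max_kinases_per_substrate=5, n_networks=5, seed=3,
    )


@pytest.fixture(scope="session")
def small_ensemble(small_network, small_proteome, small_config):
    return networks.build_ensemble(small_network, small_proteome, small_config)


@pytest.fixture()
def toy_proteome():
    """A hand-written 12-site proteome covering all bias classes."""
    rows = []
    for i, count in enumerate([0, 0, 0, 0, 1, 1, 2, 2, 3, 4, 5, 5]):
        rows.append((f"P{i:03d}", "Y", 10 + i, count))
    return Phosphoproteome(
        pd.DataFrame(rows, columns=["accession", "residue", "position", "compendia_count"])
    )
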