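import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from hybridcre.synthetic import MotifSpec, SyntheticConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """A deterministic 80-locus fixture with AP-1 and TEAD plantings."""
    config = SyntheticConfig(
        n_loci=80,
        locus_length=1000,
        motif_specs=(
            MotifSpec("AP1", "VTGACTCAB", 0.6),
            MotifSpec("TEAD", "GGAATK", 0.6),
        ),
        disruption_prob=0.5,
        depth_mean=100.0,
        dispersion=1e9,  # Poisson-limit counts: exact binomial conditional
        n_replicates=2,
        seed=11,
    )
    return simulate_bundle(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
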