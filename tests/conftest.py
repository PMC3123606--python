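import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

# optimizer convergence warnings are expected under the loose tolerances
# used for small test problems
logging.getLogger("stemloop.likelihood").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20110527)


@pytest.fixture(scope="session")
def toy_alignment():
    """Six-taxon structured alignment with stems, loops and ground truth."""
    from stemloop.simulate import SimulationConfig, simulate
    from stemloop.trees import PhyloTree

    tree = PhyloTree.from_newick(
        "(((A:0.1,B:0.1):0.08,C:0.15):0.06,(D:0.12,E:0.1):0.07,O:0.3);")
    aln, truth = simulate(SimulationConfig(
        tree=tree, n_stem_pairs=60, n_loop_sites=120, seed=3))
    return aln, truth, tree
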