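import numpy as np
import pytest

import rnabd as rb


@pytest.fixture(scope="session")
def params():
    return rb.DEFAULT_PARAMS


@pytest.fixture(scope="session")
def hairpin_ff():
    """Small 12-bead hairpin force field with ideal-geometry rest lengths."""
    ss = rb.parse_dot_bracket("((((....))))")
    net = rb.build_spring_network(ss)
    conf = rb.assemble_initial_conformation(ss, seed=0)
    net = rb.assign_equilibrium_lengths(net, conf.coords)
    return rb.ForceField(net), conf


@pytest.fixture(scope="session")
def trna():
    """tRNA-phe topology, initial conformation and force field."""
    ss, arms = rb.load_fixture("trna_phe")
    net = rb.build_spring_network(ss)
    conf = rb.assemble_initial_conformation(ss, seed=1)
    net = rb.assign_equilibrium_lengths(net, conf.coords)
    return ss, arms, rb.ForceField(net), conf


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
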