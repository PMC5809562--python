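import numpy as np
import pytest

import hmpt

TOY_EQN = """example: one-tree old/new detection model
t1 h D
t1 h (1-D)*g
t1 m (1-D)*(1-g)
"""

# identifiable two-tree model: detection D plus guessing g
TWO_TREE_EQN = """example: old/new detection with new-item tree
old hit D
old hit (1-D)*g
old miss (1-D)*(1-g)
new fa g
new cr (1-g)
"""


@pytest.fixture(scope="session")
def toy_model():
    return hmpt.parse_eqn(TOY_EQN)


@pytest.fixture(scope="session")
def two_tree_model():
    return hmpt.parse_eqn(TWO_TREE_EQN)


@pytest.fixture(scope="session")
def htsm():
    return hmpt.parse_eqn(hmpt.two_htsm_eqn())


@pytest.fixture(scope="session")
def htsm_restricted():
    model = hmpt.parse_eqn(hmpt.two_htsm_eqn())
    r = hmpt.parse_restrictions(hmpt.two_htsm_restrictions(), model)
    return hmpt.apply_restrictions(model, r)


@pytest.fixture(scope="session")
def htsm_table(htsm_restricted):
    """Small heterogeneous 2HTSM data set (trait population)."""
    from hmpt.datagen import TraitPopulationSpec, gen_trait_mpt

    spec = TraitPopulationSpec(
        mu_probit=np.array([0.3, 0.3, -0.1, 0.6]),  # D, a, b, d
        sigma_probit=np.array([0.3, 0.5, 0.4, 0.6]),
    )
    table, theta, _ = gen_trait_mpt(
        24, {"E": 20, "U": 20, "N": 40}, spec, htsm_restricted, seed=101
    )
    return table, theta
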