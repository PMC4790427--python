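"""Shared fixtures: the canonical network, reference fluxes, and a small
TCA-like toy network used for brute-force isotopomer cross-checks."""

import numpy as np
import pytest

from cumoflux.cumomer import build_rhs, enumerate_bonded_cumomers
from cumoflux.network import Network, Pool, Product, Reaction, build_default_network
from cumoflux.synth import AcquisitionSpec, default_truth_fluxes, input_function


@pytest.fixture(scope="session")
def net():
    return build_default_network()


@pytest.fixture(scope="session")
def truth():
    return default_truth_fluxes()


@pytest.fixture(scope="session")
def sys3(net):
    return build_rhs(net, enumerate_bonded_cumomers(net, max_order=3))


@pytest.fixture(scope="session")
def sys1(net):
    return build_rhs(net, enumerate_bonded_cumomers(net, max_order=1))


@pytest.fixture(scope="session")
def plasma_fe():
    return input_function(AcquisitionSpec())


@pytest.fixture(scope="session")
def t_grid():
    return np.linspace(0.0, 180.0, 19)


def _identity(pool, n):
    return {i: (pool, i) for i in range(1, n + 1)}


@pytest.fixture(scope="session")
def toy_net():
    """Four-pool TCA-like loop: driven acetate-like input, condensation,
    symmetric scrambling and an unlabeled anaplerotic inflow."""
    pools = {
        "src": Pool("src", "input", 2, 0.0, is_input=True,
                    input_labeled_positions=(1, 2)),
        "ac": Pool("ac", "shared", 2, 0.3),
        "oaa": Pool("oaa", "shared", 4, 0.4),
        "og": Pool("og", "shared", 5, 0.6),
    }
    reactions = (
        Reaction("uptake", "v_tca", ("src",),
                 (Product("ac", (_identity("src", 2),)),)),
        Reaction("cs", "v_tca", ("oaa", "ac"),
                 (Product("og", ({1: ("oaa", 4), 2: ("oaa", 3), 3: ("oaa", 2),
                                  4: ("ac", 2), 5: ("ac", 1)},)),)),
        Reaction("ogdh", "v_tca", ("og",),
                 (Product("oaa", ({1: ("og", 2), 2: ("og", 3),
                                   3: ("og", 4), 4: ("og", 5)},
                                  {1: ("og", 5), 2: ("og", 4),
                                   3: ("og", 3), 4: ("og", 2)})),)),
        Reaction("anaplerosis", "v_anap", (),
                 (Product("oaa", ({1: None, 2: None, 3: None, 4: None},)),)),
        Reaction("oaa_drain", "v_anap", ("oaa",), ()),
    )
    return Network(pools, reactions, measured_pools={"og": ("og",)})


@pytest.fixture(scope="session")
def toy_fluxes():
    return {"v_tca": 0.5, "v_anap": 0.2}


@pytest.fixture(scope="session")
def toy_input():
    def fe(t):
        return 0.8 * min(max(t / 2.0, 0.0), 1.0)

    return fe
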