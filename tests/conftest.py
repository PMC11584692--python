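import numpy as np
import pytest

from bmecsim import (
    ModelNetwork,
    ParameterSet,
    RateLaw,
    Reaction,
    Regulator,
    SpeciesDef,
    default_model,
    find_quiescent_state,
    make_ogdr_protocol,
    run_protocol,
)


@pytest.fixture(scope="session")
def model():
    net, params = default_model()
    return net, params


@pytest.fixture(scope="session")
def quiescent(model):
    net, params = model
    state, report = find_quiescent_state(net, params)
    assert report.success, report.worst_species()
    return state


@pytest.fixture(scope="session")
def ogdr_trajectory(model, quiescent):
    """The canonical OGD 6 h / reox 24 h run, shared across tests."""
    net, params = model
    return run_protocol(net, params, quiescent, make_ogdr_protocol(6.0, 24.0))


def make_decay_network(kd: float = np.log(2), initial: float = 100.0):
    """One species, first-order decay: closed-form exponential."""
    net = ModelNetwork(
        species=[SpeciesDef("A", "cytosol", initial)],
        reactions=[
            Reaction(
                id="deg_A",
                reactants=[("A", 1)],
                rate_law=RateLaw(kind="first_order_decay"),
                parameter_id="kd_A",
                module="metabolism",
            )
        ],
    )
    return net, ParameterSet.with_default_bounds({"kd_A": kd})


def make_synthesis_decay_network(k_syn: float = 2.0, k_deg: float = 0.5):
    """Production/degradation pair with analytic steady state k_syn/k_deg."""
    net = ModelNetwork(
        species=[SpeciesDef("P", "cytosol", 1.0), SpeciesDef("Q", "cytosol", 1.0)],
        reactions=[
            Reaction(id="syn_P", products=[("P", 1)],
                     rate_law=RateLaw(kind="zeroth_order_synthesis"),
                     parameter_id="kt_P", module="metabolism"),
            Reaction(id="deg_P", reactants=[("P", 1)],
                     rate_law=RateLaw(kind="first_order_decay"),
                     parameter_id="kd_P", module="metabolism"),
            Reaction(id="syn_Q", products=[("Q", 1)],
                     rate_law=RateLaw(kind="zeroth_order_synthesis"),
                     parameter_id="kt_Q", module="metabolism"),
            Reaction(id="deg_Q", reactants=[("Q", 1)],
                     rate_law=RateLaw(kind="first_order_decay"),
                     parameter_id="kd_Q", module="metabolism"),
        ],
    )
    params = ParameterSet.with_default_bounds(
        {"kt_P": k_syn, "kd_P": k_deg, "kt_Q": 1.0, "kd_Q": 1.0}
    )
    return net, params


def make_hill_network(K: float = 2.0, n: float = 2.0, k: float = 1.0):
    """Hill-activated synthesis of P by X (X constant)."""
    net = ModelNetwork(
        species=[SpeciesDef("X", "cytosol", K, frozenset({"environment"})),
                 SpeciesDef("P", "cytosol", 0.0)],
        reactions=[
            Reaction(id="syn_P", products=[("P", 1)],
                     regulators=[Regulator("X", "activate", K, n)],
                     rate_law=RateLaw(kind="hill_activation", hill_K=K, hill_n=n),
                     parameter_id="k_syn", module="metabolism"),
        ],
    )
    return net, ParameterSet.with_default_bounds({"k_syn": k})
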