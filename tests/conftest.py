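"""Shared fixtures: the synthetic mini-methanotroph model and small toy
networks used across the suite."""

import numpy as np
import pytest

from redoxflux.conditions import build_condition
from redoxflux.curation import MaintenanceSpec
from redoxflux.minimodel import MiniModelConfig, build_minimodel, default_fixtures
from redoxflux.model import MetabolicModel, Metabolite, Reaction


@pytest.fixture(scope="session")
def mini_model():
    return build_minimodel()


@pytest.fixture(scope="session")
def maintenance():
    return MaintenanceSpec()  # gam 10.86, ngam 3.5, P/O 2.5


@pytest.fixture(scope="session")
def ch4_condition(maintenance):
    return build_condition("CH4", 3.5, maintenance)


@pytest.fixture(scope="session")
def fixtures():
    return default_fixtures()


def make_chain_model(input_flux: float = 1.0) -> MetabolicModel:
    """EX_a -> a -> b -> EX_b linear chain with pinned input."""
    mets = [Metabolite("a", compartment="c", formula="C"),
            Metabolite("b", compartment="c", formula="C")]
    rxns = [
        Reaction("EX_a", {"a": -1.0}, -input_flux, -input_flux),
        Reaction("AB", {"a": -1.0, "b": 1.0}, 0.0, 1000.0),
        Reaction("EX_b", {"b": -1.0}, 0.0, 1000.0),
    ]
    return MetabolicModel(mets, rxns, "EX_b", id="chain")


def make_branch_model(source: float = 10.0) -> MetabolicModel:
    """Source metabolite split over two parallel branches F and T."""
    mets = [Metabolite("s", compartment="c"), Metabolite("p", compartment="c")]
    rxns = [
        Reaction("EX_s", {"s": -1.0}, -source, -source),
        Reaction("F", {"s": -1.0, "p": 1.0}, 0.0, 1000.0),
        Reaction("T", {"s": -1.0, "p": 1.0}, 0.0, 1000.0),
        Reaction("EX_p", {"p": -1.0}, 0.0, 1000.0),
    ]
    return MetabolicModel(mets, rxns, "EX_p", id="branch")


@pytest.fixture()
def chain_model():
    return make_chain_model()


@pytest.fixture()
def branch_model():
    return make_branch_model()


@pytest.fixture(scope="session")
def jittered_models():
    """Ten structurally identical mini-models with perturbed bounds, for
    randomized implementation-vs-oracle comparisons."""
    return [build_minimodel(MiniModelConfig(bound_jitter=0.3, seed=s)) for s in range(10)]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
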