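import dataclasses

import numpy as np
import pytest

from lemnaflux.fitting import LabelingModel
from lemnaflux.fixtures import load_fixture
from lemnaflux.network import steady_state_basis
from lemnaflux.panel import panel_default
from lemnaflux.synth import (
    fitting_network,
    generate_measurements,
    preset,
    preset_labels,
    truth_flux,
)


@pytest.fixture(scope="session")
def toy():
    return load_fixture


@pytest.fixture(scope="session")
def midsize_network():
    return load_fixture("toy_midsize")


@pytest.fixture(scope="session")
def midsize_flux(midsize_network):
    """A strictly positive steady-state flux on the mid-size toy."""
    basis = steady_state_basis(midsize_network)
    q = _feasible_q(midsize_network, basis, np.random.default_rng(0), min_slack=1.5)
    xch = np.zeros(len(midsize_network.reactions))
    for rid in basis.free_exchange_ids:
        xch[midsize_network.rxn_index(rid)] = 2.0
    return basis.flux_state(q, xch)


def _feasible_q(network, basis, rng, min_slack=0.5, sigma=3.0):
    """Rejection-sample free fluxes giving strictly positive irreversible
    fluxes on a small network (Gaussian around a feasible center)."""
    from lemnaflux.fitting import _feasible_center

    center = _feasible_center(basis)
    lo = np.array([r.lb for r in network.reactions])
    for _ in range(5000):
        q = center + rng.normal(0.0, sigma, size=basis.n_free_net)
        v = basis.expand(q)
        slack = np.where(np.isfinite(lo), v - lo, np.inf)
        if np.min(slack) > min_slack:
            return q
    raise RuntimeError("no feasible random flux found")


@pytest.fixture(scope="session")
def ins_preset():
    return preset("INS")


@pytest.fixture(scope="session")
def ins_truth(ins_preset):
    return truth_flux(ins_preset)


@pytest.fixture(scope="session")
def ins_noisefree():
    """Noise- and inoculum-free INS scenario: preset, truth, raw data."""
    p = dataclasses.replace(preset("INS"), noise_sd=0.0, inoculum_fraction=0.0)
    truth = truth_flux(p)
    raw = generate_measurements(truth, p=p)
    return p, truth, raw


@pytest.fixture(scope="session")
def ins_noisy(ins_preset, ins_truth):
    """Noisy INS dataset at the default study conditions (seed fixed)."""
    return generate_measurements(ins_truth, p=ins_preset, seed=20230913)


@pytest.fixture(scope="session")
def ins_fit_model(ins_preset):
    net = fitting_network(ins_preset)
    model = LabelingModel(
        net,
        panel_default(),
        preset_labels(ins_preset),
        derivatized=True,
        inoculum_fraction=ins_preset.inoculum_fraction,
    )
    return net, model
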