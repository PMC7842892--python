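"""Shared fixtures and the independent dense solver oracle.

The oracle assembles the nodal equations the brute-force way — one stamp per
element over every node of the network, no series-chain merging — and solves
the dense system directly.  It shares only the network data structure and
the source-substitution frame with the production solver, so agreement of
the two is a genuine cross-check of the reduction logic.
"""

from __future__ import annotations

import numpy as np
import pytest

from plasmawell import (
    build_network,
    default_parameters,
    volume_derived_parameters,
)
from plasmawell.solver import element_admittance


def dense_oracle_potentials(network):
    """Node potentials from a plain dense full-node assembly (ground = 0,
    source = v_rms; solved in the source-referenced frame)."""
    v_rms = network.params.drive.v_rms
    omega = network.params.drive.omega
    fixed = {network.source_node: 0.0 + 0.0j, network.ground: -v_rms + 0.0j}
    unknowns = [n for n in network.nodes if n not in fixed]
    index = {n: i for i, n in enumerate(unknowns)}
    A = np.zeros((len(unknowns), len(unknowns)), dtype=complex)
    b = np.zeros(len(unknowns), dtype=complex)
    for e in network.elements:
        y = element_admittance(e, omega)
        for p, q in ((e.node_a, e.node_b), (e.node_b, e.node_a)):
            if p in index:
                A[index[p], index[p]] += y
                if q in index:
                    A[index[p], index[q]] -= y
                else:
                    b[index[p]] += y * fixed[q]
    x = np.linalg.solve(A, b)
    phi = {n: fixed[n] + v_rms for n in fixed}
    phi.update({n: x[index[n]] + v_rms for n in unknowns})
    return phi


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def params_volume():
    return volume_derived_parameters()


@pytest.fixture(scope="session")
def network(params):
    return build_network(params)


@pytest.fixture(scope="session")
def network_volume(params_volume):
    return build_network(params_volume)


@pytest.fixture(scope="session")
def solution(network):
    from plasmawell import solve_phasor

    return solve_phasor(network)


@pytest.fixture(scope="session")
def solution_volume(network_volume):
    from plasmawell import solve_phasor

    return solve_phasor(network_volume)
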