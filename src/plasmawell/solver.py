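"""Complex-phasor nodal analysis of the well network at the drive frequency.

The network is linear (resistors + capacitors + one ideal sinusoidal
source), so the steady state at angular frequency ω is a single complex
linear solve.  Phasors carry RMS magnitude throughout: the source phasor is
v_pp/(2√2) + 0j, and "effective values" downstream are plain phasor
magnitudes.

Two numerical choices matter here:

* The ideal source is handled by substitution (the constrained node is
  eliminated from the unknowns), never by a large-conductance penalty.
* The solve runs in a *source-referenced* frame: the source node is held at
  0 and ground at −v_rms, and the result is shifted back afterwards.  Every
  interior node of this network sits within a few volts of the source (the
  plate capacitance dominates the vertical impedance), so solving with
  ground as reference represents kilovolt-scale potentials whose µV-scale
  differences drive the radial currents — a catastrophic-cancellation trap
  that leaves Kirchhoff-current-law residuals near 1e-8 of the source
  current.  The shifted frame keeps interior potentials small and brings the
  residual to round-off (~1e-13).

Maximal series chains (the four-element cell-radial branches, and the runs
of the vertical stacks between junctions) are merged into single branch
impedances before assembly; per-element voltages are recovered afterwards by
impedance division.  This reduces the unknowns to the true junction nodes
and is algebraically identical to the full system.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .network import CircuitElement, CircuitNetwork


class SingularNetworkError(ValueError):
    """The nodal system is singular (disconnected or floating node)."""


@dataclass
class PhasorSolution:
    """Complex node potentials and per-element branch quantities (RMS).

    ``branch_voltages[e]`` is V(node_a) − V(node_b) of element *e* and
    ``branch_currents[e]`` the current flowing node_a → node_b, both
    computed in the well-conditioned source-referenced frame (they agree
    with potential differences of ``node_potentials`` to round-off of the
    source voltage).  ``source_current`` is the current the ideal source
    injects into the source node.
    """

    node_potentials: dict
    branch_voltages: dict
    branch_currents: dict
    omega: float
    source_current: complex


def element_admittance(element: CircuitElement, omega: float) -> complex:
    """Admittance in S: 1/R for resistors, jωC for capacitors."""
    if omega <= 0:
        raise ValueError("omega must be > 0")
    if element.kind == "R":
        return 1.0 / element.value + 0.0j
    if element.kind == "C":
        return 1j * omega * element.value
    raise ValueError(f"unknown element kind {element.kind!r}")


def element_impedance(element: CircuitElement, omega: float) -> complex:
    return 1.0 / element_admittance(element, omega)


def _check_connected(network: CircuitNetwork) -> None:
    adj = defaultdict(list)
    for e in network.elements:
        adj[e.node_a].append(e.node_b)
        adj[e.node_b].append(e.node_a)
    seen = {network.ground}
    stack = [network.ground]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    missing = set(network.nodes) - seen
    if missing:
        raise SingularNetworkError(
            f"node(s) disconnected from ground: {sorted(missing)}"
        )


def _series_chains(network: CircuitNetwork):
    """Split the element multigraph into maximal series chains.

    A chain is an ordered list of (element, flip) pairs running between two
    junction nodes, where interior nodes have exactly two incident elements
    and are neither ground nor the source node.  ``flip`` records whether
    the element's (node_a, node_b) orientation opposes the walk direction.
    """
    incident = defaultdict(list)
    for e in network.elements:
        incident[e.node_a].append(e)
        incident[e.node_b].append(e)
    junctions = {
        n
        for n in network.nodes
        if len(incident[n]) != 2 or n in (network.ground, network.source_node)
    }
    chains = []
    visited = set()
    for start in sorted(junctions):
        for e0 in incident[start]:
            if e0.id in visited:
                continue
            chain = []
            node, el = start, e0
            while True:
                visited.add(el.id)
                flip = el.node_b == node
                chain.append((el, flip))
                node = el.node_a if flip else el.node_b
                if node in junctions:
                    break
                nxt = [e for e in incident[node] if e.id != el.id]
                el = nxt[0]
            chains.append((start, node, chain))
    if len(visited) != len(network.elements):
        # pure cycle of degree-2 nodes: floating loop, cannot carry the solve
        leftover = [e.id for e in network.elements if e.id not in visited]
        raise SingularNetworkError(f"floating series loop: {leftover}")
    return junctions, chains


def solve_phasor(network: CircuitNetwork) -> PhasorSolution:
    """Solve the network at its drive frequency.

    Returns a :class:`PhasorSolution` with ground at exactly 0 and the
    source node at exactly v_rms.  Raises :class:`SingularNetworkError` for
    disconnected topologies, naming an offending node.
    """
    _check_connected(network)
    omega = network.params.drive.omega
    v_rms = network.params.drive.v_rms
    junctions, chains = _series_chains(network)

    chain_z = [
        sum(element_impedance(e, omega) for e, _ in chain)
        for _, _, chain in chains
    ]

    # source-referenced frame: fixed potentials
    fixed = {network.source_node: 0.0 + 0.0j, network.ground: -v_rms + 0.0j}
    unknowns = sorted(junctions - set(fixed))
    index = {n: i for i, n in enumerate(unknowns)}
    dim = len(unknowns)
    A = np.zeros((dim, dim), dtype=complex)
    b = np.zeros(dim, dtype=complex)
    for (na, nb, _), z in zip(chains, chain_z):
        y = 1.0 / z
        for p, q in ((na, nb), (nb, na)):
            if p in index:
                A[index[p], index[p]] += y
                if q in index:
                    A[index[p], index[q]] -= y
                else:
                    b[index[p]] += y * fixed[q]
    if dim:
        zero_rows = np.where(~A.any(axis=1))[0]
        if zero_rows.size:
            raise SingularNetworkError(
                f"node {unknowns[zero_rows[0]]} has no conducting path"
            )
        try:
            x = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise SingularNetworkError(f"singular nodal system: {exc}") from exc
    else:
        x = np.zeros(0, dtype=complex)

    phi = dict(fixed)
    phi.update({n: x[index[n]] for n in unknowns})

    branch_v = {}
    branch_i = {}
    for (na, nb, chain), z in zip(chains, chain_z):
        i_chain = (phi[na] - phi[nb]) / z
        node_phi = phi[na]
        for e, flip in chain:
            dv = i_chain * element_impedance(e, omega)
            # dv is the drop along the walk direction; store in (a→b) sense
            sign = -1.0 if flip else 1.0
            branch_v[e.id] = sign * dv
            branch_i[e.id] = sign * i_chain
            next_phi = node_phi - dv
            interior = e.node_a if flip else e.node_b
            if interior not in phi:
                phi[interior] = next_phi
            node_phi = next_phi

    # shift back so ground is exactly 0 and the source exactly v_rms
    potentials = {n: v + v_rms for n, v in phi.items()}

    inflow = 0.0 + 0.0j
    for e in network.elements:
        if e.node_a == network.source_node:
            inflow += branch_i[e.id]
        if e.node_b == network.source_node:
            inflow -= branch_i[e.id]
    return PhasorSolution(
        node_potentials=potentials,
        branch_voltages=branch_v,
        branch_currents=branch_i,
        omega=omega,
        source_current=inflow,
    )


def kcl_residual(sol: PhasorSolution, network: CircuitNetwork) -> float:
    """Max over internal nodes of |Σ incident currents| / |source current|."""
    net_in = defaultdict(complex)
    for e in network.elements:
        i = sol.branch_currents[e.id]
        net_in[e.node_a] -= i
        net_in[e.node_b] += i
    i_src = abs(sol.source_current)
    internal = [
        n for n in network.nodes if n not in (network.ground, network.source_node)
    ]
    return max(abs(net_in[n]) for n in internal) / i_src


def power_balance(sol: PhasorSolution, network: CircuitNetwork):
    """(source complex power, Σ element complex powers), both in VA.

    With RMS phasors, S = V·conj(I) directly.  Tellegen's theorem makes the
    two equal up to round-off; resistors absorb non-negative real power and
    capacitors none.
    """
    v_src = sol.node_potentials[network.source_node]
    s_source = v_src * np.conj(sol.source_current)
    s_elements = sum(
        sol.branch_voltages[e.id] * np.conj(sol.branch_currents[e.id])
        for e in network.elements
    )
    return s_source, s_elements


def nodal_admittance_matrix(network: CircuitNetwork, omega: float | None = None):
    """(node labels, dense complex admittance matrix) with ground eliminated.

    The plain element-wise stamp over all non-ground nodes — useful for
    inspecting reciprocity (the matrix is symmetric) and conditioning; not
    used by :func:`solve_phasor`.
    """
    omega = network.params.drive.omega if omega is None else omega
    labels = [n for n in network.nodes if n != network.ground]
    index = {n: i for i, n in enumerate(labels)}
    Y = np.zeros((len(labels), len(labels)), dtype=complex)
    for e in network.elements:
        y = element_admittance(e, omega)
        for p, q in ((e.node_a, e.node_b), (e.node_b, e.node_a)):
            if p in index:
                Y[index[p], index[p]] += y
                if q in index:
                    Y[index[p], index[q]] -= y
    return labels, Y
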