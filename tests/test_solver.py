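"""Phasor solver: Ohm/divider sanity, conservation, oracle equivalence,
linearity, reciprocity, and the closed-form degenerate limit."""

import dataclasses
import math

import numpy as np
import pytest

from conftest import dense_oracle_potentials
from plasmawell import (
    CircuitElement,
    CircuitNetwork,
    SingularNetworkError,
    build_network,
    default_parameters,
    element_admittance,
    kcl_residual,
    power_balance,
    solve_phasor,
)
from plasmawell.network import element_values
from plasmawell.solver import nodal_admittance_matrix


def el(eid, kind, value, na, nb, seg=1):
    return CircuitElement(
        id=eid, kind=kind, value=value, node_a=na, node_b=nb,
        layer="buffer", orientation="vertical", segment=seg,
        geom_length=1.0, geom_area=1.0,
    )


def tiny_network(elements, v_rms=1.0, frequency=20e3, source="S"):
    p = default_parameters()
    drive = dataclasses.replace(
        p.drive, v_pp=v_rms * 2 * math.sqrt(2), frequency=frequency
    )
    p = dataclasses.replace(p, drive=drive)
    nodes = sorted({x for e in elements for x in (e.node_a, e.node_b)})
    return CircuitNetwork(
        nodes=tuple(nodes), elements=tuple(elements),
        source_node=source, ground="G", params=p,
    )


class TestElementAdmittance:
    def test_resistor_and_capacitor(self):
        r = el("R1", "R", 2.0, "a", "b")
        assert element_admittance(r, 1.0) == 0.5 + 0j
        c = el("C1", "C", 1e-6, "a", "b")
        y = element_admittance(c, 1e6)
        assert y == pytest.approx(1j)

    def test_membrane_capacitor_at_drive_frequency(self):
        c = el("C1", "C", 6.67582e-11, "a", "b")
        y = element_admittance(c, 2 * math.pi * 20e3)
        assert abs(y) == pytest.approx(8.39e-6, rel=1e-3)

    def test_nonpositive_omega_rejected(self):
        with pytest.raises(ValueError):
            element_admittance(el("R1", "R", 1.0, "a", "b"), 0.0)


class TestSmallNetworks:
    def test_single_resistor_ohms_law(self):
        net = tiny_network([el("R1", "R", 1.0, "S", "G")])
        sol = solve_phasor(net)
        assert sol.branch_currents["R1"] == pytest.approx(1.0)
        assert sol.source_current == pytest.approx(1.0)

    def test_two_resistor_divider(self):
        net = tiny_network(
            [el("R1", "R", 1.0, "S", "mid"), el("R2", "R", 1.0, "mid", "G")]
        )
        sol = solve_phasor(net)
        assert sol.node_potentials["mid"] == pytest.approx(0.5)
        assert sol.node_potentials["G"] == 0.0
        assert sol.node_potentials["S"] == pytest.approx(net.params.drive.v_rms)

    def test_disconnected_node_reported(self):
        net = tiny_network(
            [el("R1", "R", 1.0, "S", "G"), el("R2", "R", 1.0, "x", "y")]
        )
        with pytest.raises(SingularNetworkError, match="x"):
            solve_phasor(net)

    def test_capacitor_load_power_is_reactive(self):
        net = tiny_network([el("C1", "C", 1e-9, "S", "G")])
        sol = solve_phasor(net)
        s_src, s_sum = power_balance(sol, net)
        assert s_src.real == pytest.approx(0.0, abs=1e-18)
        assert s_src == pytest.approx(s_sum)

    def test_resistor_power_balance(self):
        net = tiny_network([el("R1", "R", 1.0, "S", "G")])
        sol = solve_phasor(net)
        s_src, s_sum = power_balance(sol, net)
        assert s_src == pytest.approx(1.0 + 0.0j)
        assert s_sum == pytest.approx(1.0 + 0.0j)


class TestFullNetwork:
    def test_solution_invariants(self, network, solution):
        p = network.params
        assert solution.node_potentials[network.ground] == 0.0
        assert solution.node_potentials[network.source_node] == p.drive.v_rms
        # branch voltage consistent with node potentials (up to round-off of
        # the kV-scale potentials) and exactly with Y·V
        for e in network.elements:
            va = solution.node_potentials[e.node_a]
            vb = solution.node_potentials[e.node_b]
            dv = solution.branch_voltages[e.id]
            assert dv == pytest.approx(va - vb, abs=1e-9 * p.drive.v_rms)
            y = element_admittance(e, p.drive.omega)
            assert solution.branch_currents[e.id] == pytest.approx(dv * y, rel=1e-12)

    def test_kcl_residual_default_network(self, network, solution):
        assert kcl_residual(solution, network) < 1e-9

    def test_kcl_residual_detects_perturbation(self, network, solution):
        # R1n1 carries nearly the whole source current, so a 1% error in it
        # must show up as a large relative KCL violation
        broken = dataclasses.replace(
            solution,
            branch_currents={
                k: (v * 1.01 if k == "R1n1" else v)
                for k, v in solution.branch_currents.items()
            },
        )
        assert kcl_residual(broken, network) >= 1e-3

    def test_power_balance_default_network(self, network, solution):
        s_src, s_sum = power_balance(solution, network)
        assert abs(s_src - s_sum) / abs(s_src) < 1e-9
        # per-element physicality
        omega = network.params.drive.omega
        for e in network.elements:
            s = solution.branch_voltages[e.id] * np.conj(
                solution.branch_currents[e.id]
            )
            if e.kind == "R":
                assert s.real >= 0
            else:
                assert abs(s.real) <= 1e-12 * abs(s)

    @pytest.mark.parametrize("n", [2, 4, 16])
    def test_oracle_equivalence(self, n):
        p = default_parameters()
        p = dataclasses.replace(p, disc=dataclasses.replace(p.disc, n_segments=n))
        net = build_network(p)
        sol = solve_phasor(net)
        oracle = dense_oracle_potentials(net)
        worst = max(
            abs(sol.node_potentials[nd] - oracle[nd]) / max(abs(oracle[nd]), 1e-30)
            for nd in net.nodes
            if nd != net.ground
        )
        assert worst < 1e-10

    def test_linearity_in_drive_voltage(self, network, solution):
        p = network.params
        for k, tol in ((2.0, 0.0), (3.0, 1e-12)):
            drive = dataclasses.replace(p.drive, v_pp=k * p.drive.v_pp)
            scaled = build_network(dataclasses.replace(p, drive=drive))
            sol_k = solve_phasor(scaled)
            for eid in ("R0n1", "C0n16", "Cron7", "R1n3"):
                a = sol_k.branch_currents[eid]
                b = k * solution.branch_currents[eid]
                if tol == 0.0:
                    assert a == b  # scaling by 2 is exact in binary floats
                else:
                    assert a == pytest.approx(b, rel=tol)

    def test_reciprocity(self, network):
        _, Y = nodal_admittance_matrix(network)
        assert np.allclose(Y, Y.T, rtol=0, atol=0)


class TestDegenerateLimit:
    def test_single_stack_matches_closed_form(self):
        """Membrane shorted and σ_c = σ_b: one vertical stack equals the
        hand-computed buffer-column + cytoplasm-column + plate-capacitor
        series divider."""
        p = default_parameters()
        p = dataclasses.replace(
            p, materials=dataclasses.replace(p.materials, sigma_c=p.materials.sigma_b)
        )
        v = element_values(1, p)
        net = tiny_network(
            [
                el("R0n1", "R", v.r0, "S", "t"),
                el("Rzin1", "R", v.rzi, "t", "m"),
                el("Rzon1", "R", v.rzo, "m", "d"),
                el("C0n1", "C", v.c0, "d", "G"),
            ],
            v_rms=p.drive.v_rms,
            frequency=p.drive.frequency,
        )
        sol = solve_phasor(net)
        z = v.r0 + v.rzi + v.rzo + 1.0 / (1j * p.drive.omega * v.c0)
        expected = p.drive.v_rms / z
        assert sol.source_current == pytest.approx(expected, rel=1e-9)
        # divider potential at the plate top
        v_d = p.drive.v_rms * (1.0 / (1j * p.drive.omega * v.c0)) / z
        assert sol.node_potentials["d"] == pytest.approx(v_d, rel=1e-9)
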