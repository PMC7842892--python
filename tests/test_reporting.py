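"""Overlay scaling, the synthetic efficiency fixture, CSV round-trips,
and SPICE netlist export/import."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasmawell import (
    EfficiencyProfile,
    build_network,
    default_parameters,
    export_netlist,
    overlay_scale,
    read_efficiency,
    read_netlist,
    synth_efficiency,
)
from plasmawell.reporting import (
    TableFormatError,
    write_efficiency,
    write_profiles,
)


class TestOverlayScale:
    def test_constant_curves(self):
        eff = EfficiencyProfile(r_mm=np.linspace(0, 2, 21), eta=np.ones(21))
        res = overlay_scale(np.linspace(0, 2, 21), 2 * np.ones(21), eff, (0.0, 2.0))
        assert res.scale == pytest.approx(0.5)
        assert res.residual == pytest.approx(0.0, abs=1e-12)

    def test_identity(self):
        eff = synth_efficiency(3.2, noise_sd=0.0, seed=0)
        res = overlay_scale(eff.r_mm, eff.eta, eff, (0.0, 1.6))
        assert res.scale == pytest.approx(1.0)
        assert res.residual == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_matches_brute_force_scan(self):
        """The closed-form Σyη/Σy² must sit at the minimum of an explicit
        1-D scan over candidate scales."""
        rng = np.random.default_rng(7)
        r = np.linspace(0.1, 3.0, 40)
        y = np.exp(-r) + 0.2
        eta = 2.0 * y + rng.normal(0, 0.01, r.size)
        eff = EfficiencyProfile(r_mm=r, eta=np.clip(eta, 0, None))
        res = overlay_scale(r, y, eff, (0.1, 3.0))

        def ssr(s):
            return float(np.sum((s * y - eff.eta) ** 2))

        scan = np.linspace(1.0, 3.0, 20001)
        best = scan[np.argmin([ssr(s) for s in scan])]
        assert res.scale == pytest.approx(best, abs=2e-4)
        assert ssr(res.scale) <= min(ssr(s) for s in scan) + 1e-12

    def test_noise_free_factor_recovery(self):
        eff = synth_efficiency(3.2, noise_sd=0.0, seed=1)
        res = overlay_scale(eff.r_mm, 2.0 * eff.eta, eff, (0.0, 1.6))
        assert res.scale == pytest.approx(0.5, abs=1e-6)

    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    @settings(derandomize=True, max_examples=30)
    def test_scale_invariance(self, c):
        eff = synth_efficiency(3.2, noise_sd=0.05, seed=3)
        y = np.exp(-eff.r_mm)
        base = overlay_scale(eff.r_mm, y, eff, (0.2, 1.6))
        scaled = overlay_scale(eff.r_mm, c * y, eff, (0.2, 1.6))
        assert scaled.scale * c == pytest.approx(base.scale, rel=1e-9)

    def test_error_cases(self):
        eff = EfficiencyProfile(r_mm=np.linspace(0, 1, 11), eta=np.ones(11))
        with pytest.raises(ValueError, match="window"):
            overlay_scale(eff.r_mm, eff.eta, eff, (2.0, 3.0))
        with pytest.raises(ValueError, match="zero"):
            overlay_scale(eff.r_mm, np.zeros(11), eff, (0.0, 1.0))


class TestSynthEfficiency:
    def test_plateau_and_drop(self):
        eff = synth_efficiency(3.2, noise_sd=0.0, seed=0)
        assert eff.eta[eff.r_mm < 1.2].min() >= 0.97  # flat top
        assert eff.eta[eff.r_mm > 2.5].max() <= 1e-3  # near zero outside

    def test_deterministic_for_seed(self):
        a = synth_efficiency(3.2, noise_sd=0.1, seed=42)
        b = synth_efficiency(3.2, noise_sd=0.1, seed=42)
        np.testing.assert_array_equal(a.eta, b.eta)
        c = synth_efficiency(3.2, noise_sd=0.1, seed=43)
        assert not np.array_equal(a.eta, c.eta)

    def test_noise_free_monotone_beyond_plateau(self):
        eff = synth_efficiency(3.2, noise_sd=0.0, seed=0)
        tail = eff.eta[eff.r_mm >= 1.0]
        assert np.all(np.diff(tail) <= 0)

    def test_truncation_at_zero(self):
        eff = synth_efficiency(3.2, noise_sd=0.5, seed=5)
        assert np.all(eff.eta >= 0)

    def test_invalid_drop_radius(self):
        with pytest.raises(ValueError):
            synth_efficiency(1.0, drop_radius_mm=1.6)


class TestCsvRoundTrips:
    def test_efficiency_round_trip(self, tmp_path):
        eff = synth_efficiency(3.2, noise_sd=0.05, seed=9)
        path = tmp_path / "eff.csv"
        write_efficiency(eff, path)
        back = read_efficiency(path)
        np.testing.assert_allclose(back.r_mm, eff.r_mm, rtol=1e-12)
        np.testing.assert_allclose(back.eta, eff.eta, rtol=1e-12)

    def test_profile_round_trip(self, tmp_path, network, solution):
        import pandas as pd

        from plasmawell import layer_profiles

        prof = layer_profiles(solution, network)
        path = tmp_path / "profiles.csv"
        write_profiles(prof, path)
        df = pd.read_csv(path)
        mem = df[df["layer"] == "membrane"]
        np.testing.assert_allclose(
            mem["J_mean"].to_numpy(), prof.layers["membrane"].J_mean, rtol=1e-12
        )

    @pytest.mark.parametrize(
        "content, message",
        [
            ("", "missing header"),
            ("r_mm,eta\n0.5,1.0\n0.2,0.9\n", "non-increasing"),
            ("r_mm,eta\n0.1,ok\n", ":2:"),
            ("r_mm,eta\n0.1\n", ":2:"),
            ("radius,eff\n0.1,1.0\n", "missing header"),
        ],
    )
    def test_malformed_efficiency_rejected(self, tmp_path, content, message):
        path = tmp_path / "bad.csv"
        path.write_text(content)
        with pytest.raises(TableFormatError, match=message):
            read_efficiency(path)


class TestNetlist:
    def test_default_netlist_shape(self, network):
        text = export_netlist(network)
        lines = [
            l for l in text.splitlines() if l and not l.startswith(("*", "."))
        ]
        element_lines = [l for l in lines if not l.startswith("V")]
        source_lines = [l for l in lines if l.startswith("V")]
        assert len(element_lines) == 171
        assert len(source_lines) == 1
        # SIN source carries peak amplitude v_pp/2 and the drive frequency
        assert "SIN(0 7.5" in source_lines[0]
        for l in element_lines:
            assert len(l.split()) == 4

    def test_round_trip_identity(self, network):
        back = read_netlist(export_netlist(network))
        assert back.source_node == network.source_node
        assert len(back.elements) == len(network.elements)
        orig = {e.id: e for e in network.elements}
        for e in back.elements:
            o = orig[e.id]
            assert (e.node_a, e.node_b) == (o.node_a, o.node_b)
            assert e.value == pytest.approx(o.value, rel=1e-12)
            assert (e.layer, e.orientation, e.segment) == (
                o.layer, o.orientation, o.segment,
            )
        assert back.params == network.params

    def test_two_segment_netlist(self):
        p = default_parameters()
        p = dataclasses.replace(p, disc=dataclasses.replace(p.disc, n_segments=2))
        net = build_network(p)
        text = export_netlist(net)
        element_lines = [
            l
            for l in text.splitlines()
            if l and not l.startswith(("*", ".", "V"))
        ]
        assert len(element_lines) == 17  # 12 vertical + 1 buffer + 4 cell radial
        back = read_netlist(text)
        assert len(back.elements) == 17
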