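"""Tabular/netlist I/O, overlay normalization, and the efficiency fixture.

Three jobs live here:

* **SPICE netlist export** of the built network, one line per element plus
  the sinusoidal source, so the realized topology is auditable and the
  solve can be cross-validated in any external circuit simulator.  The
  package's own reader round-trips the netlist to an identical network.
* **Overlay scaling**: transfection-efficiency profiles are normalized
  (dimensionless), model current densities are A/m²; overlaying the two
  requires a vertical-axis scale.  The visual "adjust the axis until they
  overlap" procedure is formalized as the least-squares ratio
  s* = Σ y·η / Σ y² over a stated radial window.
* **Synthetic efficiency fixture**: a generator emulating the measured
  transfection-efficiency shape — flat plateau inside the drop radius
  (≈1.6 mm), a steep sigmoid fall to near zero beyond, additive Gaussian
  noise truncated at zero.  Real measured profiles enter through the same
  two-column CSV interface (r_mm, eta).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network import GROUND, CircuitElement, CircuitNetwork, element_geometry
from .params import (
    Discretization,
    DriveSignal,
    MaterialSet,
    ModelParameters,
    WellGeometry,
)
from .postprocess import ExposureProfile, RadialProfile


class TableFormatError(ValueError):
    """A tabular input violates the expected schema."""


# ---------------------------------------------------------------------------
# Efficiency profiles and overlay scaling
# ---------------------------------------------------------------------------

#: Radial overlay windows (mm) used for the three standard curve pairs.
DEFAULT_WINDOWS = {
    "cell": (0.0, 1.6),
    "buffer_circuit": (0.2, 0.5),
    "buffer_reference": (0.4, 1.6),
}


@dataclass
class EfficiencyProfile:
    """Normalized transfection efficiency η vs radius (mm)."""

    r_mm: np.ndarray
    eta: np.ndarray

    def __post_init__(self):
        self.r_mm = np.asarray(self.r_mm, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        if self.r_mm.ndim != 1 or self.r_mm.shape != self.eta.shape:
            raise TableFormatError("r and eta must be 1-D arrays of equal length")
        if np.any(np.diff(self.r_mm) <= 0):
            raise TableFormatError("non-increasing radii")
        if np.any(self.eta < 0):
            raise TableFormatError("eta must be >= 0")


@dataclass
class OverlayResult:
    """Least-squares vertical scale of a model curve onto an efficiency
    profile over ``window`` (mm), with the RMS misfit in η units."""

    scale: float
    window: tuple
    residual: float


def overlay_scale(
    model_r_mm: np.ndarray,
    model_y: np.ndarray,
    eff: EfficiencyProfile,
    window: tuple,
) -> OverlayResult:
    """Best s minimizing Σ (s·y(r) − η(r))² over the window.

    The model series is interpolated linearly onto the efficiency radii;
    closed form s* = Σyη / Σy².
    """
    model_r_mm = np.asarray(model_r_mm, dtype=float)
    model_y = np.asarray(model_y, dtype=float)
    lo, hi = window
    if lo >= hi:
        raise ValueError(f"empty window {window}")
    mask = (
        (eff.r_mm >= lo)
        & (eff.r_mm <= hi)
        & (eff.r_mm >= model_r_mm.min())
        & (eff.r_mm <= model_r_mm.max())
    )
    if not mask.any():
        raise ValueError(f"no efficiency samples inside window {window}")
    r_w = eff.r_mm[mask]
    eta_w = eff.eta[mask]
    y_w = np.interp(r_w, model_r_mm, model_y)
    denom = float(np.sum(y_w**2))
    if denom == 0.0:
        raise ValueError("model series is identically zero inside the window")
    s = float(np.sum(y_w * eta_w)) / denom
    resid = float(np.sqrt(np.mean((s * y_w - eta_w) ** 2)))
    return OverlayResult(scale=s, window=(lo, hi), residual=resid)


def synth_efficiency(
    r_max_mm: float,
    drop_radius_mm: float = 1.6,
    noise_sd: float = 0.05,
    seed: int = 0,
    n_points: int = 64,
    plateau: float = 1.0,
    width_mm: float = 0.1,
) -> EfficiencyProfile:
    """Synthetic transfection-efficiency fixture.

    η(r) = plateau / (1 + exp((r − drop_radius)/width)) + noise, truncated
    at zero: a flat top inside the drop radius falling steeply ("drastically")
    to near zero outside it.  Deterministic for a fixed seed.
    """
    if drop_radius_mm >= r_max_mm:
        raise ValueError("drop_radius must be < r_max")
    rng = np.random.default_rng(seed)
    r = np.linspace(0.05, r_max_mm, n_points)
    eta = plateau / (1.0 + np.exp((r - drop_radius_mm) / width_mm))
    if noise_sd > 0:
        eta = eta + rng.normal(0.0, noise_sd, size=r.shape)
    return EfficiencyProfile(r_mm=r, eta=np.clip(eta, 0.0, None))


# ---------------------------------------------------------------------------
# CSV round-trips
# ---------------------------------------------------------------------------

def write_profiles(profile: RadialProfile, path) -> None:
    profile.to_frame().to_csv(path, index=False)


def write_exposure(exposure: ExposureProfile, path) -> None:
    exposure.to_frame().to_csv(path, index=False)


def read_efficiency(path) -> EfficiencyProfile:
    """Read a two-column efficiency CSV (header ``r_mm,eta``).

    Malformed rows are rejected with their line numbers.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    if not text:
        raise TableFormatError(f"{path}: missing header")
    header = [h.strip() for h in text[0].split(",")]
    if header[:2] != ["r_mm", "eta"]:
        raise TableFormatError(f"{path}: missing header 'r_mm,eta' (got {text[0]!r})")
    radii, etas = [], []
    for lineno, line in enumerate(text[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) < 2:
            raise TableFormatError(f"{path}:{lineno}: expected 2 columns")
        try:
            radii.append(float(cells[0]))
            etas.append(float(cells[1]))
        except ValueError:
            raise TableFormatError(
                f"{path}:{lineno}: non-numeric cell in {line!r}"
            ) from None
    try:
        return EfficiencyProfile(r_mm=np.array(radii), eta=np.array(etas))
    except TableFormatError as exc:
        raise TableFormatError(f"{path}: {exc}") from None


def write_efficiency(eff: EfficiencyProfile, path) -> None:
    pd.DataFrame({"r_mm": eff.r_mm, "eta": eff.eta}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# SPICE netlist export / import
# ---------------------------------------------------------------------------

_NETLIST_ID = re.compile(
    r"^(?P<sym>R0|R1|Czi|Czo|Cri|Cro|Rzi|Rzo|Rri|Rro|C0)n(?P<seg>\d+)$"
)

_LAYER_OF_SYMBOL = {
    "R0": ("buffer", "vertical"),
    "R1": ("buffer", "radial"),
    "Czi": ("membrane", "vertical"),
    "Czo": ("membrane", "vertical"),
    "Cri": ("membrane", "radial"),
    "Cro": ("membrane", "radial"),
    "Rzi": ("cytoplasm", "vertical"),
    "Rzo": ("cytoplasm", "vertical"),
    "Rri": ("cytoplasm", "radial"),
    "Rro": ("cytoplasm", "radial"),
    "C0": ("plate", "vertical"),
}


def export_netlist(network: CircuitNetwork) -> str:
    """SPICE netlist text of the network.

    Ground is node ``0``; one ``Rxxx``/``Cxxx`` line per element; the
    source line uses v_pp/2 as sine amplitude (SPICE SIN sources take peak
    amplitude — the solver's RMS phasor is v_pp/(2√2)).  Parameter header
    comments make the netlist self-describing so the reader can rebuild an
    identical network.
    """
    p = network.params
    lines = [
        "* plasmawell equivalent-circuit network",
        "* phasor convention: solver carries RMS amplitude v_pp/(2*sqrt(2))",
        f"*PARAM sigma_b {p.materials.sigma_b!r}",
        f"*PARAM eps_m_rel {p.materials.eps_m_rel!r}",
        f"*PARAM sigma_c {p.materials.sigma_c!r}",
        f"*PARAM eps_w_rel {p.materials.eps_w_rel!r}",
        f"*PARAM H_w {p.geometry.H_w!r}",
        f"*PARAM H_c {p.geometry.H_c!r}",
        f"*PARAM H_m {p.geometry.H_m!r}",
        f"*PARAM H_b {p.geometry.H_b!r}",
        f"*PARAM n_segments {p.disc.n_segments!r}",
        f"*PARAM delta_r {p.disc.delta_r!r}",
        f"*PARAM v_pp {p.drive.v_pp!r}",
        f"*PARAM frequency {p.drive.frequency!r}",
    ]

    def node(n):
        return "0" if n == network.ground else n

    for e in network.elements:
        lines.append(f"{e.id} {node(e.node_a)} {node(e.node_b)} {e.value:.15e}")
    lines.append(
        f"V1 {node(network.source_node)} 0 "
        f"SIN(0 {p.drive.v_pp / 2.0:.15e} {p.drive.frequency:.15e})"
    )
    lines.append(".end")
    return "\n".join(lines) + "\n"


def read_netlist(text: str) -> CircuitNetwork:
    """Rebuild a :class:`CircuitNetwork` from :func:`export_netlist` output."""
    raw_params = {}
    elements = []
    source_node = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line == ".end":
            continue
        if line.startswith("*"):
            if line.startswith("*PARAM "):
                _, key, value = line.split(maxsplit=2)
                raw_params[key] = float(value)
            continue
        parts = line.split()
        if parts[0].startswith("V"):
            source_node = parts[1]
            continue
        if len(parts) != 4:
            raise TableFormatError(f"netlist line {lineno}: expected 4 fields")
        eid, na, nb, val = parts
        m = _NETLIST_ID.match(eid)
        if m is None:
            raise TableFormatError(f"netlist line {lineno}: unknown element id {eid!r}")
        elements.append((eid, m["sym"], int(m["seg"]), na, nb, float(val)))

    needed = {
        "sigma_b", "eps_m_rel", "sigma_c", "eps_w_rel",
        "H_w", "H_c", "H_m", "H_b", "n_segments", "delta_r",
        "v_pp", "frequency",
    }
    missing = needed - set(raw_params)
    if missing:
        raise TableFormatError(f"netlist missing *PARAM lines: {sorted(missing)}")
    params = ModelParameters(
        materials=MaterialSet(
            sigma_b=raw_params["sigma_b"],
            eps_m_rel=raw_params["eps_m_rel"],
            sigma_c=raw_params["sigma_c"],
            eps_w_rel=raw_params["eps_w_rel"],
        ),
        geometry=WellGeometry(
            H_w=raw_params["H_w"], H_c=raw_params["H_c"],
            H_m=raw_params["H_m"], H_b=raw_params["H_b"],
        ),
        disc=Discretization(
            n_segments=int(raw_params["n_segments"]),
            delta_r=raw_params["delta_r"],
        ),
        drive=DriveSignal(
            v_pp=raw_params["v_pp"], frequency=raw_params["frequency"]
        ),
    )
    if source_node is None:
        raise TableFormatError("netlist has no source line")

    els = []
    for eid, sym, seg, na, nb, val in elements:
        layer, orient = _LAYER_OF_SYMBOL[sym]
        length, area = element_geometry(layer, orient, seg, params)
        kind = "R" if sym.startswith("R") else "C"
        els.append(
            CircuitElement(
                id=eid, kind=kind, value=val,
                node_a=GROUND if na == "0" else na,
                node_b=GROUND if nb == "0" else nb,
                layer=layer, orientation=orient, segment=seg,
                geom_length=length, geom_area=area,
            )
        )
    nodes = sorted({x for e in els for x in (e.node_a, e.node_b)})
    return CircuitNetwork(
        nodes=tuple(nodes),
        elements=tuple(els),
        source_node=source_node,
        ground=GROUND,
        params=params,
    )


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------

def plot_field_profiles(profile: RadialProfile):
    """Two-panel figure: E(r) and J(r) per layer (vertical, radial, mean)."""
    import matplotlib.pyplot as plt

    fig, (ax_e, ax_j) = plt.subplots(1, 2, figsize=(10, 4))
    r_mm = profile.r * 1e3
    for layer, lp in profile.layers.items():
        ax_e.semilogy(r_mm, lp.E_mean, label=f"{layer} mean")
        ax_e.semilogy(r_mm, lp.E_vertical, ":", label=f"{layer} vertical")
        ax_e.semilogy(r_mm, lp.E_radial, "-.", label=f"{layer} radial")
        ax_j.semilogy(r_mm, lp.J_mean, label=f"{layer} mean")
        ax_j.semilogy(r_mm, lp.J_vertical, ":")
        ax_j.semilogy(r_mm, lp.J_radial, "-.")
    ax_e.set_xlabel("r (mm)")
    ax_e.set_ylabel("E (V/m, RMS)")
    ax_j.set_xlabel("r (mm)")
    ax_j.set_ylabel("J (A/m², RMS)")
    ax_e.legend(fontsize=7)
    fig.tight_layout()
    return fig


def plot_overlay(model_r_mm, model_y, eff: EfficiencyProfile, result: OverlayResult,
                 label="model current density"):
    """Model curve scaled onto the efficiency profile, window shaded."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(eff.r_mm, eff.eta, "o", ms=3, label="efficiency η")
    ax.plot(model_r_mm, result.scale * np.asarray(model_y), "-",
            label=f"{label} × {result.scale:.3g}")
    ax.axvspan(*result.window, alpha=0.15, label="overlay window")
    ax.set_xlabel("r (mm)")
    ax.set_ylabel("normalized efficiency")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_exposure(exposure: ExposureProfile):
    """V_m(r) and I_cell(r) with the physiological reference bands shaded."""
    import matplotlib.pyplot as plt

    fig, (ax_v, ax_i) = plt.subplots(1, 2, figsize=(10, 4))
    r_mm = exposure.r * 1e3
    b = exposure.bands
    ax_v.semilogy(r_mm, exposure.V_m, "o-")
    ax_v.axhspan(b["damage_min_V"], b["damage_max_V"], color="red", alpha=0.2,
                 label="membrane damage")
    ax_v.axhspan(ax_v.get_ylim()[0], b["action_potential_V"], color="blue",
                 alpha=0.15, label="action potential")
    ax_v.set_xlabel("r (mm)")
    ax_v.set_ylabel("V_m (V, RMS)")
    ax_v.legend(fontsize=8)
    ax_i.semilogy(r_mm, exposure.I_cell, "o-")
    ax_i.axhspan(ax_i.get_ylim()[0], b["ion_transport_A"], color="blue",
                 alpha=0.15, label="ion transport")
    ax_i.set_xlabel("r (mm)")
    ax_i.set_ylabel("I_cell (A, RMS)")
    ax_i.legend(fontsize=8)
    fig.tight_layout()
    return fig
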