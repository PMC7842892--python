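"""Assembly of the three-layer, axisymmetric ladder network.

The well is discretized into ``n_segments`` concentric ring segments.  Each
segment *n* contributes a vertical stack of lumped elements from the buffer
surface down to the grounded plate backing::

    B_n --R0n-- T_n --Czin-- U_n --Rzin-- M_n --Rzon-- L_n --Czon-- D_n --C0n-- G

i.e. buffer column resistance, upper membrane capacitance, upper/lower
cytoplasm half-resistances (meeting at the mid-cytoplasm node M_n), lower
membrane capacitance, and the polystyrene plate capacitance to ground.
Adjacent segments are linked radially in two places:

* at the buffer surface by the buffer radial resistor ``R1n`` (B_n—B_{n+1});
* through the cell layer by the four-element series branch
  M_n —Rron(n)— —Cron(n)— —Crin(n+1)— —Rrin(n+1)— M_{n+1}: current leaves
  cytoplasm *n* through its outer half-resistance and outer radial membrane
  capacitance, and enters segment *n+1* through the inner radial membrane
  and inner half-resistance.

The outermost segment has no outward radial link (insulating well wall), and
the plate layer carries vertical capacitors only (the ground plane is
equipotential).  An ideal sinusoidal source sits between ground and B_1 —
the plasma filament is a zero-resistance conductor touching the buffer
surface at the centre.

Element values follow from each element's geometry (length ℓ, cross-section
A) and its layer's material constant: R = ℓ/(σA), C = εA/ℓ.  The radial
cell-layer cross-sections maintain the H_m:H_c height ratio, so a ring of
many individual cells is represented by one lumped component per segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .params import ModelParameters, validate

GROUND = "G"

Layer = str  # "buffer" | "membrane" | "cytoplasm" | "plate"
Orientation = str  # "vertical" | "radial"


@dataclass(frozen=True)
class CircuitElement:
    """A lumped resistor or capacitor with geometric provenance.

    ``value`` is Ω for resistors, F for capacitors.  ``geom_length`` and
    ``geom_area`` are the (ℓ, A) pair of the constitutive law the value was
    computed from, so fields can later be recovered as |V|/ℓ and |I|/A.
    """

    id: str
    kind: str  # "R" | "C"
    value: float
    node_a: str
    node_b: str
    layer: Layer
    orientation: Orientation
    segment: int  # 1-based
    geom_length: float
    geom_area: float


@dataclass(frozen=True)
class SegmentValues:
    """Element values of segment *n* (Ω / F)."""

    r0: float  # buffer, vertical
    r1: float  # buffer, radial
    czi: float  # membrane, vertical (upper); czo equal by symmetry
    czo: float
    cri: float  # membrane, radial (inner); cro equal
    cro: float
    rzi: float  # cytoplasm, vertical half (upper); rzo equal
    rzo: float
    rri: float  # cytoplasm, radial half (inner); rro equal
    rro: float
    c0: float  # plate, vertical


@dataclass
class CircuitNetwork:
    """Node set plus annotated elements; the object the solver consumes."""

    nodes: tuple
    elements: tuple
    source_node: str
    ground: str
    params: ModelParameters
    _by_id: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._by_id:
            self._by_id = {e.id: e for e in self.elements}

    def element(self, element_id: str) -> CircuitElement:
        return self._by_id[element_id]

    def elements_where(self, **attrs):
        """All elements matching the given attribute values."""
        out = []
        for e in self.elements:
            if all(getattr(e, k) == v for k, v in attrs.items()):
                out.append(e)
        return out


def element_geometry(
    layer: Layer, orientation: Orientation, segment: int, params: ModelParameters
) -> tuple:
    """(length ℓ, cross-section A) in SI for one element class at segment n.

    These are exactly the geometric factors of the element-value formulas;
    the radial cell-layer entries carry the Δr/H_c aspect factor that keeps
    the membrane:cell height ratio inside a ring of lumped cells.
    """
    g = params.geometry
    dr = params.disc.delta_r
    rn = (segment - 0.5) * dr
    circ = 2.0 * math.pi * rn
    aspect = dr / g.H_c  # radial run expressed in cell-layer heights
    table = {
        ("buffer", "vertical"): (g.H_b, circ * dr),
        ("buffer", "radial"): (dr, circ * g.H_b),
        ("membrane", "vertical"): (g.H_m, circ * dr),
        ("membrane", "radial"): (aspect * g.H_m, circ * g.H_c),
        ("cytoplasm", "vertical"): (
            (g.H_c - 2 * g.H_m) / 2.0,
            circ * aspect * (g.H_c - 2 * g.H_m),
        ),
        ("cytoplasm", "radial"): (
            aspect * (g.H_c - 2 * g.H_m) / 2.0,
            circ * (g.H_c - 2 * g.H_m),
        ),
        ("plate", "vertical"): (g.H_w, circ * dr),
    }
    try:
        return table[(layer, orientation)]
    except KeyError:
        raise ValueError(f"unknown layer/orientation: {layer}/{orientation}") from None


def _resistance(layer, orientation, n, params, sigma):
    length, area = element_geometry(layer, orientation, n, params)
    return length / (sigma * area)

def _capacitance(layer, orientation, n, params, eps):
    length, area = element_geometry(layer, orientation, n, params)
    return eps * area / length


def element_values(n: int, params: ModelParameters) -> SegmentValues:
    """All element values of segment ``n`` (1-based) from the constitutive
    laws; inner/outer pairs are equal by construction."""
    if not 1 <= n <= params.disc.n_segments:
        raise ValueError(f"segment {n} outside 1..{params.disc.n_segments}")
    m = params.materials
    r0 = _resistance("buffer", "vertical", n, params, m.sigma_b)
    r1 = _resistance("buffer", "radial", n, params, m.sigma_b)
    cz = _capacitance("membrane", "vertical", n, params, m.eps_m)
    cr = _capacitance("membrane", "radial", n, params, m.eps_m)
    rz = _resistance("cytoplasm", "vertical", n, params, m.sigma_c)
    rr = _resistance("cytoplasm", "radial", n, params, m.sigma_c)
    c0 = _capacitance("plate", "vertical", n, params, m.eps_w)
    return SegmentValues(
        r0=r0, r1=r1, czi=cz, czo=cz, cri=cr, cro=cr,
        rzi=rz, rzo=rz, rri=rr, rro=rr, c0=c0,
    )


def build_network(params: ModelParameters) -> CircuitNetwork:
    """Assemble the full ladder network for ``params``.

    Node naming: B/T/U/M/L/D + segment index for the six vertical rails,
    ``X{n}a/b/c`` for the three interior nodes of the cell-layer radial
    branch between segments n and n+1, ground ``"G"``.  Element ids carry
    the conventional symbol plus segment (``R0n1``, ``Czin3``, ``Cron7``…).
    """
    validate(params)
    N = params.disc.n_segments
    els = []

    def add(eid, kind, value, na, nb, layer, orient, seg):
        length, area = element_geometry(layer, orient, seg, params)
        els.append(
            CircuitElement(
                id=eid, kind=kind, value=value, node_a=na, node_b=nb,
                layer=layer, orientation=orient, segment=seg,
                geom_length=length, geom_area=area,
            )
        )

    for n in range(1, N + 1):
        v = element_values(n, params)
        add(f"R0n{n}", "R", v.r0, f"B{n}", f"T{n}", "buffer", "vertical", n)
        add(f"Czin{n}", "C", v.czi, f"T{n}", f"U{n}", "membrane", "vertical", n)
        add(f"Rzin{n}", "R", v.rzi, f"U{n}", f"M{n}", "cytoplasm", "vertical", n)
        add(f"Rzon{n}", "R", v.rzo, f"M{n}", f"L{n}", "cytoplasm", "vertical", n)
        add(f"Czon{n}", "C", v.czo, f"L{n}", f"D{n}", "membrane", "vertical", n)
        add(f"C0n{n}", "C", v.c0, f"D{n}", GROUND, "plate", "vertical", n)

    for n in range(1, N):
        v_n = element_values(n, params)
        v_next = element_values(n + 1, params)
        add(f"R1n{n}", "R", v_n.r1, f"B{n}", f"B{n+1}", "buffer", "radial", n)
        add(f"Rron{n}", "R", v_n.rro, f"M{n}", f"X{n}a", "cytoplasm", "radial", n)
        add(f"Cron{n}", "C", v_n.cro, f"X{n}a", f"X{n}b", "membrane", "radial", n)
        add(f"Crin{n+1}", "C", v_next.cri, f"X{n}b", f"X{n}c", "membrane", "radial", n + 1)
        add(f"Rrin{n+1}", "R", v_next.rri, f"X{n}c", f"M{n+1}", "cytoplasm", "radial", n + 1)

    nodes = sorted({x for e in els for x in (e.node_a, e.node_b)})
    return CircuitNetwork(
        nodes=tuple(nodes),
        elements=tuple(els),
        source_node="B1",
        ground=GROUND,
        params=params,
    )
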