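"""Model parameters for the plasma-exposed well, with explicit SI units.

The model describes a single well of a 96-well plate during microdischarge
plasma exposure: a polystyrene plate bottom, a monolayer of adherent
fibroblasts (membrane + cytoplasm), and a conductive TE/PBS buffer column,
driven by a 20 kHz high-voltage sinusoid delivered by the plasma filament at
the well centre.  Everything downstream of this module (network assembly, AC
solve, post-processing) consumes a validated :class:`ModelParameters`.

All quantities are SI internally.  Configuration files may carry unit-tagged
strings (``"0.2 mm"``, ``"15 kV"``) which are converted on load; bare numbers
are taken as SI.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

#: Vacuum permittivity, F/m (4 significant figures).
EPSILON_0 = 8.854e-12


class ParameterError(ValueError):
    """A model-parameter invariant is violated or a config entry is malformed."""


@dataclass(frozen=True)
class MaterialSet:
    """Electrical material constants of the four media.

    sigma_b
        Buffer (TE/PBS) conductivity, S/m.
    eps_m_rel
        Cell-membrane relative permittivity (multiples of ε₀).
    sigma_c
        Cytoplasm conductivity, S/m.
    eps_w_rel
        Polystyrene plate relative permittivity (multiples of ε₀).
    """

    sigma_b: float = 0.376
    eps_m_rel: float = 30.0
    sigma_c: float = 1.0
    eps_w_rel: float = 2.4

    @property
    def eps_m(self) -> float:
        """Membrane permittivity, F/m."""
        return self.eps_m_rel * EPSILON_0

    @property
    def eps_w(self) -> float:
        """Plate permittivity, F/m."""
        return self.eps_w_rel * EPSILON_0


@dataclass(frozen=True)
class WellGeometry:
    """Layer heights of the axisymmetric well stack, metres.

    ``H_w`` plate thickness, ``H_c`` cell-layer height (fibroblast diameter),
    ``H_m`` membrane-layer height (1/100 of the cell layer), ``H_b`` buffer
    column height.  The buffer height is deliberately a plain field: the
    nominal value is 50 mm, but the 6 µL fill spread over the well bottom
    gives ≈0.19 mm (:func:`volume_derived_buffer_height`); both are
    physically meaningful configurations and both can be run.
    """

    H_w: float = 1.5e-3
    H_c: float = 50e-6
    H_m: float = 0.5e-6
    H_b: float = 50e-3


@dataclass(frozen=True)
class Discretization:
    """Radial discretization: ``n_segments`` concentric ring segments of
    width ``delta_r`` (m)."""

    n_segments: int = 16
    delta_r: float = 0.2e-3

    @property
    def r_max(self) -> float:
        """Outer radius of the discretized region, m."""
        return self.n_segments * self.delta_r


@dataclass(frozen=True)
class DriveSignal:
    """Sinusoidal drive delivered by the plasma filament.

    ``v_pp`` is the source peak-to-peak voltage (V) and ``frequency`` the
    drive frequency (Hz).  Derived: ``omega`` = 2πf and the RMS amplitude
    ``v_rms`` = v_pp / (2√2), which is the phasor magnitude carried through
    the solver (so reported "effective values" need no further factor).
    """

    v_pp: float = 15e3
    frequency: float = 20e3

    @property
    def omega(self) -> float:
        """Angular frequency, rad/s."""
        return 2.0 * math.pi * self.frequency

    @property
    def v_rms(self) -> float:
        """RMS source voltage, V."""
        return self.v_pp / (2.0 * math.sqrt(2.0))


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter set: materials, geometry, discretization, drive."""

    materials: MaterialSet = field(default_factory=MaterialSet)
    geometry: WellGeometry = field(default_factory=WellGeometry)
    disc: Discretization = field(default_factory=Discretization)
    drive: DriveSignal = field(default_factory=DriveSignal)


def default_parameters() -> ModelParameters:
    """Return the nominal parameter set.

    σ_b = 0.376 S/m, ε_m = 30ε₀, σ_c = 1 S/m, ε_w = 2.4ε₀;
    H_w = 1.5 mm, H_c = 50 µm, H_m = 0.5 µm, H_b = 50 mm;
    16 segments of Δr = 0.2 mm; 15 kV peak-to-peak at 20 kHz.
    """
    return ModelParameters()


def volume_derived_buffer_height(
    volume: float = 6e-9, well_radius: float = 3.2e-3
) -> float:
    """Buffer height implied by spreading ``volume`` (m³, default 6 µL) over
    the well bottom of radius ``well_radius`` (m, default 3.2 mm).

    ≈ 0.187 mm for the defaults — the alternative to the nominal 50 mm.
    """
    if volume <= 0 or well_radius <= 0:
        raise ParameterError("volume and well_radius must be > 0")
    return volume / (math.pi * well_radius**2)


def volume_derived_parameters(base: ModelParameters | None = None) -> ModelParameters:
    """``base`` (default: nominal parameters) with H_b replaced by the
    volume-derived buffer height."""
    base = base if base is not None else default_parameters()
    geom = replace(base.geometry, H_b=volume_derived_buffer_height())
    return replace(base, geometry=geom)


def validate(params: ModelParameters) -> ModelParameters:
    """Check every invariant; return ``params`` unchanged if all hold.

    Raises :class:`ParameterError` naming the first violated invariant.
    """
    m, g, d, s = params.materials, params.geometry, params.disc, params.drive
    checks = [
        (m.sigma_b > 0, "sigma_b > 0"),
        (m.sigma_c > 0, "sigma_c > 0"),
        (m.eps_m_rel >= 1, "eps_m_rel >= 1"),
        (m.eps_w_rel >= 1, "eps_w_rel >= 1"),
        (g.H_w > 0, "H_w > 0"),
        (g.H_b > 0, "H_b > 0"),
        (g.H_m > 0, "H_m > 0"),
        (g.H_c > 2 * g.H_m, "H_c > 2·H_m"),
        (d.n_segments >= 2, "n_segments >= 2"),
        (float(d.n_segments).is_integer(), "n_segments integral"),
        (d.delta_r > 0, "delta_r > 0"),
        (s.v_pp > 0, "v_pp > 0"),
        (s.frequency > 0, "frequency > 0"),
    ]
    for ok, name in checks:
        if not ok:
            raise ParameterError(f"{name} violated")
    return params


def radial_positions(disc: Discretization) -> np.ndarray:
    """Segment-centre radii r_n = (n − ½)Δr for n = 1..n_segments, in m."""
    n = np.arange(1, disc.n_segments + 1)
    return (n - 0.5) * disc.delta_r


# ---------------------------------------------------------------------------
# Configuration loading
# ---------------------------------------------------------------------------

# unit-tag → SI factor, grouped by the dimension each config field carries
_UNIT_FACTORS = {
    "length": {"m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9},
    "voltage": {"V": 1.0, "kV": 1e3},
    "frequency": {"Hz": 1.0, "kHz": 1e3, "MHz": 1e6},
    "conductivity": {"S/m": 1.0, "mS/m": 1e-3, "uS/m": 1e-6, "µS/m": 1e-6},
    "dimensionless": {"": 1.0},
}

# section → {key: (attribute, dimension)}
_CONFIG_SCHEMA = {
    "materials": {
        "sigma_b": ("sigma_b", "conductivity"),
        "eps_m_rel": ("eps_m_rel", "dimensionless"),
        "sigma_c": ("sigma_c", "conductivity"),
        "eps_w_rel": ("eps_w_rel", "dimensionless"),
    },
    "geometry": {
        "H_w": ("H_w", "length"),
        "H_c": ("H_c", "length"),
        "H_m": ("H_m", "length"),
        "H_b": ("H_b", "length"),
    },
    "discretization": {
        "n_segments": ("n_segments", "dimensionless"),
        "delta_r": ("delta_r", "length"),
    },
    "drive": {
        "v_pp": ("v_pp", "voltage"),
        "frequency": ("frequency", "frequency"),
    },
}


def _parse_quantity(raw, dimension: str, where: str) -> float:
    """Convert a config value (number = SI, or "``<number> <unit>``") to SI."""
    if isinstance(raw, bool):
        raise ParameterError(f"{where}: boolean is not a quantity")
    if isinstance(raw, (int, float)):
        return float(raw)
    if isinstance(raw, str):
        parts = raw.split()
        if len(parts) != 2:
            raise ParameterError(
                f"{where}: expected '<number> <unit>', got {raw!r}"
            )
        num, unit = parts
        factors = _UNIT_FACTORS[dimension]
        if unit not in factors:
            raise ParameterError(
                f"{where}: unknown unit {unit!r} for {dimension} "
                f"(accepted: {sorted(factors)})"
            )
        try:
            return float(num) * factors[unit]
        except ValueError as exc:
            raise ParameterError(f"{where}: non-numeric value {num!r}") from exc
    raise ParameterError(f"{where}: unsupported value type {type(raw).__name__}")


def load_config(path: str | Path) -> ModelParameters:
    """Load a TOML configuration, defaulting every absent field.

    Sections ``[materials]``, ``[geometry]``, ``[discretization]``,
    ``[drive]``; unknown sections or keys are rejected.  The result is
    validated before being returned.
    """
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return parameters_from_dict(data)


def parameters_from_dict(data: dict) -> ModelParameters:
    """Build validated :class:`ModelParameters` from a nested config dict."""
    unknown = set(data) - set(_CONFIG_SCHEMA)
    if unknown:
        raise ParameterError(f"unknown config section(s): {sorted(unknown)}")
    params = default_parameters()
    section_objs = {
        "materials": params.materials,
        "geometry": params.geometry,
        "disc": params.disc,
        "drive": params.drive,
    }
    attr_of_section = {
        "materials": "materials",
        "geometry": "geometry",
        "discretization": "disc",
        "drive": "drive",
    }
    for section, entries in data.items():
        schema = _CONFIG_SCHEMA[section]
        if not isinstance(entries, dict):
            raise ParameterError(f"[{section}] must be a table")
        bad = set(entries) - set(schema)
        if bad:
            raise ParameterError(f"[{section}]: unknown key(s) {sorted(bad)}")
        attr = attr_of_section[section]
        updates = {}
        for key, raw in entries.items():
            field_name, dim = schema[key]
            value = _parse_quantity(raw, dim, f"[{section}].{key}")
            if field_name == "n_segments":
                if value != int(value):
                    raise ParameterError("[discretization].n_segments must be integral")
                value = int(value)
            updates[field_name] = value
        section_objs[attr] = replace(section_objs[attr], **updates)
    params = ModelParameters(
        materials=section_objs["materials"],
        geometry=section_objs["geometry"],
        disc=section_objs["disc"],
        drive=section_objs["drive"],
    )
    return validate(params)
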