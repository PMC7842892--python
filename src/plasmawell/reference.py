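"""Axisymmetric electro-quasistatic solver for the uniform-medium model.

This is the cross-check against the *prior* way of modelling the exposure:
no cells, just a buffer column over the polystyrene plate, with the plasma
treated as a conducting disc (σ = 1 S/m) covering r < 0.4 mm at the buffer
surface, through which the discharge current enters uniformly.  The complex
potential obeys ∇·(κ∇φ) = 0 with κ = σ + jωε, discretized by a conservative
finite-volume scheme on a cell-centred tensor grid (harmonic-mean face
conductivities, exact annular face areas).  Boundary conditions: the
discharge current enters *uniformly* over the top of the plasma disc (an
equipotential disc would instead crowd the current at the disc rim), φ = 0
on the grounded plane under the plate, zero normal current on the axis, the
outer wall, and the remaining top surface.  The total injected current is
determined first by an auxiliary solve with the disc held at v_rms, so the
drive amplitude stays tied to the source voltage and scales linearly with
it.

The point of the module is qualitative: in the uniform medium the buffer
current density is near-flat inside the disc radius and decays beyond,
whereas the circuit network (current injected into the innermost segment)
gives a buffer current that is maximal at the centre and strictly decaying.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .params import ModelParameters, validate

REGION_PLATE = 0
REGION_BUFFER = 1
REGION_PLASMA = 2

#: Radius of the conducting plasma disc at the buffer surface, m.
PLASMA_RADIUS = 0.4e-3

#: Conductivity assigned to the plasma disc, S/m.
PLASMA_SIGMA = 1.0


@dataclass
class AxisymGrid:
    """Cell-centred axisymmetric grid with per-cell complex conductivity.

    Axes: index ``i`` runs over radius (nr cells), ``j`` over height
    (nz cells, plate first, then buffer).  ``kappa[i, j]`` = σ + jωε of the
    cell.  Dirichlet conditions live on the bottom faces (ground, φ=0) and
    on the top faces of plasma columns (φ = ``v_top``).
    """

    params: ModelParameters
    r_faces: np.ndarray
    z_faces: np.ndarray
    region: np.ndarray
    kappa: np.ndarray
    nz_plate: int
    plasma_radius: float
    v_top: float
    #: per-column complex current injected through the top faces; set by
    #: :func:`solve_potential` so the conservation checks can replay the
    #: boundary fluxes that were actually applied.
    top_flux: np.ndarray | None = None

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_faces[:-1] + self.r_faces[1:])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_faces[:-1] + self.z_faces[1:])

    @property
    def nr(self) -> int:
        return self.r_faces.size - 1

    @property
    def nz(self) -> int:
        return self.z_faces.size - 1

    @property
    def plasma_columns(self) -> np.ndarray:
        """Boolean mask over radial cells whose top face is driven."""
        return self.region[:, -1] == REGION_PLASMA


def build_grid(
    params: ModelParameters,
    nr: int = 64,
    nz: int = 64,
    plasma_radius: float = PLASMA_RADIUS,
) -> AxisymGrid:
    """Layered κ map for the plate + buffer stack with a plasma disc on top.

    ``nz`` cells are split between the plate and the buffer in proportion to
    their thickness, with at least four cells each.
    """
    validate(params)
    if nr < 8 or nz < 8:
        raise ValueError("nr and nz must both be >= 8")
    g = params.geometry
    m = params.materials
    omega = params.drive.omega

    # split cells by thickness, but guarantee each layer a quarter of the
    # column so a thin buffer (0.19 mm under a 1.5 mm plate) stays resolved
    floor = max(4, nz // 4)
    nz_plate = int(round(nz * g.H_w / (g.H_w + g.H_b)))
    nz_plate = min(max(nz_plate, floor), nz - floor)
    nz_buffer = nz - nz_plate
    if nz_plate < 4 or nz_buffer < 4:
        raise ValueError("grid too coarse to resolve both layers")

    r_max = params.disc.r_max
    r_faces = np.linspace(0.0, r_max, nr + 1)
    z_faces = np.concatenate(
        [
            np.linspace(0.0, g.H_w, nz_plate + 1),
            np.linspace(g.H_w, g.H_w + g.H_b, nz_buffer + 1)[1:],
        ]
    )

    region = np.full((nr, nz), REGION_BUFFER, dtype=int)
    region[:, :nz_plate] = REGION_PLATE
    r_centers = 0.5 * (r_faces[:-1] + r_faces[1:])
    region[r_centers < plasma_radius, -1] = REGION_PLASMA
    if not (region[:, -1] == REGION_PLASMA).any():
        raise ValueError("plasma disc thinner than one radial cell")

    kappa = np.empty((nr, nz), dtype=complex)
    kappa[region == REGION_PLATE] = 1j * omega * m.eps_w
    kappa[region == REGION_BUFFER] = m.sigma_b
    kappa[region == REGION_PLASMA] = PLASMA_SIGMA

    return AxisymGrid(
        params=params,
        r_faces=r_faces,
        z_faces=z_faces,
        region=region,
        kappa=kappa,
        nz_plate=nz_plate,
        plasma_radius=plasma_radius,
        v_top=params.drive.v_rms,
    )


def _face_conductances(grid: AxisymGrid):
    """Radial and vertical inter-cell conductances plus boundary conductances.

    Returns (Gr, Gz, Gbot, Gtop): Gr[i, j] couples cells (i, j)-(i+1, j),
    Gz[i, j] couples (i, j)-(i, j+1); Gbot/Gtop couple the bottom/top cells
    to their Dirichlet faces (Gtop is zero outside the plasma disc).
    """
    rf, zf = grid.r_faces, grid.z_faces
    dr = np.diff(rf)
    dz = np.diff(zf)
    k = grid.kappa
    nr, nz = grid.nr, grid.nz

    # radial faces: area 2π r_face Δz; series half-cells
    area_r = 2.0 * np.pi * rf[1:-1, None] * dz[None, :]
    half = dr / 2.0
    Gr = area_r / (half[:-1, None] / k[:-1, :] + half[1:, None] / k[1:, :])

    # vertical faces: annulus area π(r_out² − r_in²)
    ann = np.pi * (rf[1:] ** 2 - rf[:-1] ** 2)
    hz = dz / 2.0
    Gz = ann[:, None] / (hz[None, :-1] / k[:, :-1] + hz[None, 1:] / k[:, 1:])

    Gbot = ann / (hz[0] / k[:, 0])
    Gtop = np.where(grid.plasma_columns, ann / (hz[-1] / k[:, -1]), 0.0)
    return Gr, Gz, Gbot, Gtop


def _assemble_and_solve(grid: AxisymGrid, dirichlet_top: bool,
                        top_flux: np.ndarray | None = None) -> np.ndarray:
    """One sparse solve; top boundary either held at v_top over the plasma
    columns (``dirichlet_top``) or fed the given per-column current."""
    nr, nz = grid.nr, grid.nz
    Gr, Gz, Gbot, Gtop = _face_conductances(grid)

    def idx(i, j):
        return i * nz + j

    n_cells = nr * nz
    rows, cols, vals = [], [], []
    b = np.zeros(n_cells, dtype=complex)

    def stamp(p, q, g):
        rows.extend((p, p, q, q))
        cols.extend((p, q, q, p))
        vals.extend((g, -g, g, -g))

    for i in range(nr - 1):
        for j in range(nz):
            stamp(idx(i, j), idx(i + 1, j), Gr[i, j])
    for i in range(nr):
        for j in range(nz - 1):
            stamp(idx(i, j), idx(i, j + 1), Gz[i, j])
    diag_extra = np.zeros(n_cells, dtype=complex)
    for i in range(nr):
        p = idx(i, 0)
        diag_extra[p] += Gbot[i]  # ground at φ=0: rhs contribution is zero
        q = idx(i, nz - 1)
        if dirichlet_top:
            if Gtop[i] != 0.0:
                diag_extra[q] += Gtop[i]
                b[q] += Gtop[i] * grid.v_top
        elif top_flux is not None and top_flux[i] != 0.0:
            b[q] += top_flux[i]
    rows.extend(range(n_cells))
    cols.extend(range(n_cells))
    vals.extend(diag_extra)

    A = sp.csr_matrix((vals, (rows, cols)), shape=(n_cells, n_cells))
    if not np.any(np.abs(b)):
        raise ValueError("no drive present; system is singular")
    phi = spla.spsolve(A, b)
    return phi.reshape(nr, nz)


def solve_potential(grid: AxisymGrid) -> np.ndarray:
    """Complex potential φ[i, j] at cell centres.

    Two-stage drive: an auxiliary solve with the plasma disc held at v_rms
    fixes the total discharge current; the returned solution then injects
    that current *uniformly* over the disc (current ∝ annular face area),
    matching how the discharge feeds the buffer surface.  The per-column
    injected currents are recorded on ``grid.top_flux``.
    """
    _, _, _, Gtop = _face_conductances(grid)
    phi_aux = _assemble_and_solve(grid, dirichlet_top=True)
    i_total = np.sum(Gtop * (grid.v_top - phi_aux[:, -1]))

    rf = grid.r_faces
    ann = np.pi * (rf[1:] ** 2 - rf[:-1] ** 2)
    mask = grid.plasma_columns
    disc_area = np.sum(ann[mask])
    top_flux = np.where(mask, ann, 0.0) * (i_total / disc_area)

    phi = _assemble_and_solve(grid, dirichlet_top=False, top_flux=top_flux)
    grid.top_flux = top_flux
    return phi


def divergence_residual(phi: np.ndarray, grid: AxisymGrid) -> float:
    """Max cell-wise net current imbalance / total injected current.

    Recomputed from face fluxes (not from the assembled matrix), so it is a
    genuine conservation check on the returned potential.
    """
    Gr, Gz, Gbot, Gtop = _face_conductances(grid)
    nr, nz = grid.nr, grid.nz
    net = np.zeros((nr, nz), dtype=complex)
    fr = Gr * (phi[:-1, :] - phi[1:, :])  # current i -> i+1
    net[:-1, :] -= fr
    net[1:, :] += fr
    fz = Gz * (phi[:, :-1] - phi[:, 1:])
    net[:, :-1] -= fz
    net[:, 1:] += fz
    net[:, 0] -= Gbot * phi[:, 0]
    top = _top_currents(phi, grid, Gtop)
    net[:, -1] += top
    i_total = np.abs(np.sum(top))
    return float(np.max(np.abs(net)) / i_total)


def _top_currents(phi, grid, Gtop):
    """Per-column current entering through the top boundary, replaying the
    drive that was applied (recorded flux, else the Dirichlet disc)."""
    if grid.top_flux is not None:
        return grid.top_flux
    return Gtop * (grid.v_top - phi[:, -1])


def boundary_current_balance(phi: np.ndarray, grid: AxisymGrid):
    """(current in through the plasma disc, current out through ground)."""
    _, _, Gbot, Gtop = _face_conductances(grid)
    i_in = np.sum(_top_currents(phi, grid, Gtop))
    i_out = np.sum(Gbot * phi[:, 0])
    return i_in, i_out


def buffer_current_profile(
    phi: np.ndarray, grid: AxisymGrid, z_sample: float | None = None
):
    """(radii m, |J| A/m²) along a horizontal mid-buffer line.

    Default sampling depth is the middle of the buffer layer; the magnitude
    combines both components, |J| = σ_b·√(|E_r|² + |E_z|²).
    """
    g = grid.params.geometry
    z = grid.z_centers
    if z_sample is None:
        z_sample = g.H_w + g.H_b / 2.0
    j = int(np.argmin(np.abs(z - z_sample)))
    j = min(max(j, 1), grid.nz - 2)

    r = grid.r_centers
    row = phi[:, j]
    er = np.empty(grid.nr, dtype=complex)
    er[1:-1] = -(phi[2:, j] - phi[:-2, j]) / (r[2:] - r[:-2])
    er[0] = -(phi[1, j] - phi[0, j]) / (r[1] - r[0])
    er[-1] = -(phi[-1, j] - phi[-2, j]) / (r[-1] - r[-2])
    ez = -(phi[:, j + 1] - phi[:, j - 1]) / (z[j + 1] - z[j - 1])

    sigma = grid.params.materials.sigma_b
    jmag = sigma * np.sqrt(np.abs(er) ** 2 + np.abs(ez) ** 2)
    return r, jmag
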