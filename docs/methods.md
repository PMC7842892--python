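# Methods

## Physical model and assumptions

The system is a single well of a 96-well plate during microdischarge-plasma
exposure: a grounded copper plate under the polystyrene well bottom
(thickness H_w = 1.5 mm, ε_w = 2.4ε₀), a confluent monolayer of adherent
fibroblasts (cell-layer height H_c = 50 µm, membrane layer H_m = 0.5 µm =
H_c/100, membrane ε_m = 30ε₀, cytoplasm σ_c = 1 S/m), and a TE/PBS buffer
column (σ_b = 0.376 S/m) on top.  The plasma filament is treated as an
ideal conductor delivering a 15 kV peak-to-peak, 20 kHz sinusoid to the
buffer surface at the well centre.

Assumptions:

* **Electro-quasistatics.** At 20 kHz the wavelength vastly exceeds the
  well, so the field obeys ∇·((σ + jωε)∇φ) = 0 and a lumped-element
  network is a faithful discretization.
* **Axial symmetry.** Voltage and current depend on radius only, so the
  2-D cell lattice collapses to a 1-D radial ladder of ring segments.
* **Monolayer.** Local cell stacking is ignored; one membrane–cytoplasm–
  membrane sandwich spans the cell layer.
* **Linear, dispersion-free materials.** Conductivities and permittivities
  are constant; no membrane breakdown or electroporation nonlinearity, no
  temperature or electrochemistry.  Single-frequency steady state only.

## Network construction

Sixteen segments at radii r_n = (n − ½)Δr, Δr = 0.2 mm.  Each element's
value comes from its constitutive law, R = ℓ/(σA) or C = εA/ℓ, with the
(ℓ, A) pairs stored on the element so fields can be recovered later:

| element | layer | ℓ | A |
|---|---|---|---|
| R0n (vert) | buffer | H_b | 2πr_nΔr |
| R1n (rad) | buffer | Δr | 2πr_nH_b |
| Czin/Czon (vert) | membrane | H_m | 2πr_nΔr |
| Crin/Cron (rad) | membrane | (Δr/H_c)·H_m | 2πr_nH_c |
| Rzin/Rzon (vert) | cytoplasm | (H_c−2H_m)/2 | 2πr_n(Δr/H_c)(H_c−2H_m) |
| Rrin/Rron (rad) | cytoplasm | (Δr/H_c)(H_c−2H_m)/2 | 2πr_n(H_c−2H_m) |
| C0n (vert) | plate | H_w | 2πr_nΔr |

The Δr/H_c factor in the radial cell-layer entries preserves the membrane:
cell height ratio when a ring of many physical cells is lumped into one
component.

Topology decisions (the figure the layout follows is schematic, so these
are explicit package choices, all auditable in the netlist export):

* Buffer radial resistors connect adjacent surface nodes B_n—B_{n+1}.
* The cell-layer radial path between segments is the four-element series
  branch M_n—Rron(n)—Cron(n)—Crin(n+1)—Rrin(n+1)—M_{n+1}, giving the
  inner/outer element pairs distinct roles consistent with the half-length
  cytoplasm resistances.
* Segment 16 has no outward link (insulating wall); the plate layer is
  vertical-only (equipotential ground plane); the source is ideal (zero
  internal impedance) between ground and B_1.

## AC solve

Complex nodal analysis at ω = 2πf with RMS phasors (source phasor
v_pp/(2√2) ≈ 5303 V, so plotted "effective values" are plain magnitudes).
The constrained source node is eliminated by substitution, never by a
penalty conductance.  Maximal series chains are merged into single branch
impedances (junction-node unknowns only); per-element voltages are
recovered by impedance division.

**Reference-frame conditioning.**  The plate capacitance dominates the
vertical impedance, so every interior node sits within a few volts of the
source.  Solving with ground as the reference represents ~5.3 kV potentials
whose µV-scale differences drive the radial currents; the cancellation
leaves Kirchhoff-current-law residuals near 10⁻⁸ of the source current.
The solver therefore works in a source-referenced frame (source at 0,
ground at −v_rms) and shifts back afterwards, which brings the residual to
~10⁻¹³.  Branch voltages/currents are computed in the shifted frame; they
agree with differences of the reported node potentials to round-off of the
kV scale.

Verification is by conservation laws (KCL residual, complex power balance
via Tellegen's theorem), linearity and reciprocity properties, agreement
with an independent dense full-node assembly (tests), and a closed-form
series-divider limit (membrane shorted, σ_c = σ_b).

## Post-processing

E = |V|/ℓ and J = |I|/A per element.  Per segment and layer the vertical
component averages the upper/lower vertical elements; the radial component
averages the incident inner/outer radial branches (boundary segments use
their single incident branch).  The scalar profile is (radial + vertical)/2
— the surface average of the flux over a spherical cell of diameter H_c,
whose r- and z-projected areas are equal.  Constitutive consistency
(J = σE in conducting layers, J = ωε_m·E in the membrane) is exact by
construction and asserted to 10⁻⁹ in tests.

The "cell" current density is taken from the membrane elements (the
vertical stack is a series path, so membrane and cytoplasm carry the same
vertical current; both layers' profiles are exported).  Exposure:
V_m = E_mean(membrane)·H_m, I_cell = J_mean·πH_c², with reference bands
0.1 V (action potential), 0.5–1 V (membrane damage), 1 nA (ion-channel
transport) attached as constants.

## The buffer-height question

The nominal buffer height is H_b = 50 mm, but the stated origin of the
value — the 6 µL fill divided by the well-bottom area π(3.2 mm)² — gives
H_b ≈ 0.187 mm.  The two are inconsistent, so the package refuses to pick
silently: `default_parameters()` carries the nominal 50 mm,
`volume_derived_parameters()` the 0.187 mm fill, and everything runs under
both.  The choice matters quantitatively:

* Under H_b = 50 mm the buffer radial resistance is negligible, the
  surface is nearly equipotential, and all profiles are almost flat; the
  peak per-cell current is ≈37 nA.
* Under H_b ≈ 0.19 mm the radial spreading resistance concentrates current
  at the centre: peak I_cell ≈ 103 nA (two orders above the ~1 nA
  ion-transport scale), peak V_m ≈ 0.20 V, and the cell-layer current
  declines monotonically from the centre — the shape that overlaps the
  measured transfection-efficiency plateau inside r < 1.6 mm.

Conservation, oracle-agreement and linearity guarantees hold identically
under both.  The physical-claim tests (per-cell current two orders above
ion transport, centre-peaked cell current) are asserted under the
volume-derived height, which is the configuration consistent with the
fill volume actually dispensed; the numbers above document the nominal
configuration's outcome.

## Uniform-medium reference solver

The contrast case — the well modelled *without* cells, as buffer over
plate with the plasma as a conducting disc (σ = 1 S/m, radius 0.4 mm) at
the buffer surface — is solved by a conservative finite-volume
discretization of ∇·(κ∇φ) = 0, κ = σ + jωε, on a cell-centred axisymmetric
grid: harmonic-mean face conductivities, exact annular face areas, ground
plane Dirichlet below the plate, zero normal current on the axis, outer
wall and undriven top surface.

The discharge current enters **uniformly** over the disc.  An equipotential
(Dirichlet) disc would instead crowd the current at the disc rim (a ~6×
rise in mid-buffer |J| toward r = 0.4 mm); physically the filament feeds
the surface region roughly evenly, and the uniform-supply condition is
what produces the near-flat profile inside the disc.  Implementation: an
auxiliary solve with the disc held at v_rms fixes the total current, which
is then injected area-proportionally (keeping the drive tied to the source
voltage and exactly linear in v_pp).

The mid-buffer sampling line sits at z = H_w + H_b/2 (configurable; no
canonical depth exists for this comparison).  "Near-flat inside the disc"
is defined here as max/min ≤ 2.5 over r < 0.4 mm: the converged solution
carries a genuine factor-≈2 rim contribution from the radial spreading
component, which is small against the >50× decay outside the disc and the
circuit model's strictly centre-peaked buffer profile.  Grid-refinement
stability of the profile is < 5% between 64² and 128² cells.  The
comparison is qualitative by design — no attempt is made to reproduce any
particular finite-element mesh or its numbers.

## Synthetic efficiency fixture

Measured transfection-efficiency profiles enter as two-column CSV
(r_mm, η).  For testing, `synth_efficiency` emulates the characteristic
shape: a flat plateau (height 1.0) inside the drop radius (default
1.6 mm), a steep sigmoid fall (width 0.1 mm) to near zero beyond, plus
optional truncated Gaussian noise (default SD 0.05, a typical
pixel-fraction uncertainty), deterministic per seed.  What the fixture does
**not** emulate: well-to-well variability, the imaging chain, or any radial
asymmetry — tests passing on it show the overlay machinery is correct, not
that the model fits any particular measured dataset.

The overlay itself formalizes "adjust the vertical axis until the curves
overlap" as the closed-form least-squares ratio s* = Σyη/Σy² over a stated
radial window (defaults: cell r < 1.6 mm, circuit-buffer 0.2–0.5 mm,
reference-buffer 0.4–1.6 mm), with the RMS misfit reported.

## Numerical choices and problem sizes

* Dense complex direct solves throughout the circuit path (≤ 46 junction
  unknowns at n = 16); sparse LU for the finite-volume grids (128² cells
  in the standard runs, 64²/128² for the refinement study).
* ε₀ = 8.854×10⁻¹² F/m (4 significant figures, matching the precision of
  the derived constants 33.4 µS/m and 374 kΩ·m).
* Degenerate inputs fail loudly: parameter invariants are checked by name,
  disconnected nodes are reported by label, malformed CSV rows by line
  number.
* Ties/boundaries: segment 1 and segment 16 use their single incident
  radial branch; the netlist writes values to 15 decimal digits so the
  round trip is the identity to 12 significant digits.

## Known limitations

* Steady-state single-tone only; the transient response (filament rise
  time, burst envelopes) is out of scope.
* No membrane electroporation nonlinearity: exposure above the damage band
  is reported, not fed back into the conductances.
* The uniform-medium solver is a qualitative cross-check, not a
  reproduction of any published finite-element computation.
* Chemical/reactive-species transport — the other half of the transfection
  mechanism — is deliberately outside the model.
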