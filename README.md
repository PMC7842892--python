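# plasmawell

Equivalent-circuit network model of a 96-well culture well during
microdischarge-plasma (MDP) gene transfection: it computes the radial
distributions of electric field, current density, membrane voltage and
per-cell current that decide whether the **electric field** or the
**electrical current** is the dominant electrical factor acting on the
cells.

## Who this is for

Plasma-medicine and bioelectromagnetics researchers who want cell-level
exposure estimates for a plasma-treated adherent culture without running a
full finite-element model.  The well (conductive TE/PBS buffer over a
fibroblast monolayer on a polystyrene plate, driven by a 15 kV peak-to-peak
20 kHz sinusoid delivered by the plasma filament at the centre) is reduced
to a lumped ladder network that solves in milliseconds and whose every
element is physically auditable.

## The model

The well is discretized into 16 axisymmetric ring segments of width
Δr = 0.2 mm, each contributing a vertical stack (top to bottom)

    B_n —R0n— T_n —Czin— U_n —Rzin— M_n —Rzon— L_n —Czon— D_n —C0n— GND

buffer-column resistance R0n, membrane capacitances Czin/Czon, cytoplasm
half-resistances Rzin/Rzon, plate capacitance C0n.  Segments are linked
radially by buffer resistors R1n at the surface and by four-element
membrane/cytoplasm branches (Rron–Cron–Crin–Rrin) between mid-cytoplasm
nodes.  Every value follows from R = ℓ/(σA), C = εA/ℓ with σ_b = 0.376 S/m,
ε_m = 30ε₀, σ_c = 1 S/m, ε_w = 2.4ε₀ and layer heights H_b (buffer),
H_c = 50 µm, H_m = 0.5 µm, H_w = 1.5 mm, at radii r_n = (n − ½)Δr.

The network is solved by complex-phasor nodal analysis at 20 kHz (RMS
phasor convention).  Branch phasors become fields via E = |V|/ℓ,
J = |I|/A; per segment, the reported scalar is the mean of the radial and
vertical components (the surface average over a spherical cell of diameter
H_c).  Exposure conversion: V_m = E_mean(membrane)·H_m and
I_cell = J_mean·πH_c², compared against physiological bands (≈0.1 V action
potential, 0.5–1 V membrane damage, ~1 nA ion-channel transport).

A companion axisymmetric finite-difference solver reproduces the older
*uniform-medium* picture (no cells, plasma as a conducting disc of radius
0.4 mm feeding current uniformly into the buffer surface) for qualitative
contrast, and a SPICE netlist export makes the circuit auditable in any
external simulator.

## Worked example

```python
import plasmawell as pw

params = pw.volume_derived_parameters()   # 6 µL fill: H_b ≈ 0.19 mm
net = pw.build_network(params)            # 171 elements, 16 segments
sol = pw.solve_phasor(net)
prof = pw.layer_profiles(sol, net)
exp = pw.membrane_exposure(prof, params)

summ = pw.admittance_summary(params)
print(f"omega*eps_m      = {summ.omega_eps_m_uS_per_m:.3g} uS/m")
print(f"1/(omega*eps_w)  = {summ.plate_impedance_kohm_m:.3g} kOhm*m")
print(f"KCL residual     = {pw.kcl_residual(sol, net):.2e}")
print(f"max V_m          = {exp.V_m.max():.3g} V")
print(f"max I_cell       = {exp.I_cell.max()*1e9:.3g} nA")
```

prints

```
omega*eps_m      = 33.4 uS/m
1/(omega*eps_w)  = 374 kOhm*m
KCL residual     = 2.18e-14
max V_m          = 0.197 V
max I_cell       = 103 nA
```

Reading: the buffer conducts ~10⁴× better than the membrane displaces
(0.376 S/m vs 33.4 µS/m), so most of the discharge current spreads through
the buffer; the plate impedance (374 kΩ·m) dominates the vertical path, so
the vertical current density through the cells is nearly uniform in radius.
The membrane voltage stays below the 0.5–1 V damage band away from the
centre, while the per-cell current (~100 nA at the centre) is two orders of
magnitude above the ~1 nA ion-transport scale — current, not field, is the
electrically active factor.

The same pipeline is available from the shell:

```sh
plasmawell simulate  --buffer-height volume --out-dir out/
plasmawell reference --buffer-height volume --out-dir out/
plasmawell compare   --buffer-height volume out/efficiency.csv --out-dir out/
plasmawell netlist   --out-dir out/
```

`simulate` writes `profiles.csv`, `exposure.csv` and `summary.json`;
`compare` overlays model current densities on a measured (or synthetic)
transfection-efficiency profile via least-squares vertical scaling.

Note on the buffer height: the nominal configuration uses H_b = 50 mm; the
volume-derived configuration spreads the actual 6 µL fill over the well
bottom (H_b ≈ 0.19 mm).  Both are supported (`--buffer-height
printed|volume|<metres>`); see `docs/methods.md` for how the choice affects
the profiles.

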