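# bilayerlab

Analysis toolkit for molecular-dynamics studies of small molecules at lipid
bilayer interfaces, together with a self-contained well-tempered
metadynamics (WTM) engine for free-energy surfaces over collective
variables.  Everything runs desk-scale on synthetic systems with known
ground truth, so every estimator in the package is validated against a
closed form or an independent brute-force oracle.

It is intended for people who analyse membrane/probe trajectories — the
kind of workflow built around GROMACS output and PLUMED bias files — and
for teaching or prototyping enhanced-sampling analyses where an exactly
solvable stand-in for the expensive all-atom system is invaluable.

## What it computes

**Bilayer structure.** Area per lipid `A = Lx·Ly / (Nl + Nchol)` using the
lipid-plus-cholesterol count of one leaflet, and bilayer thickness `Δz` as
the distance between the mean phosphate z of the two leaflets; per frame,
with block-averaged errors.

**Pair structure and reversible work.** The radial distribution function

    g12(r) = V ⟨n2(r)⟩ / (4π r² Δr N2)

with minimum-image distances under the per-frame periodic box, and the
reversible-work profile (potential of mean force)

    W(r) = −kB·T · ln g12(r)

with coordination-shell location and free-energy barrier extraction
(`ΔF = W(first maximum) − W(preceding minimum)`).

**Lateral diffusion.** Multiple-time-origin mean-square displacement
(computed by an FFT identity, exact to roundoff) and the Einstein relation
`D = lim MSD(τ) / (2·d·τ)` with `d = 2` for in-plane motion, fitted over a
configurable lag window with block-refit errors.

**Torsional conformers.** Signed four-point dihedrals on (−180°, 180°] and
a folded/extended classification on |Ψ| (windows [56°, 106°] and
[124°, 180°]), plus interface residence-episode statistics.

**Well-tempered metadynamics.** Overdamped Langevin dynamics on an analytic
CV potential plus a history-dependent bias of Gaussian hills whose heights
decay as `w = w₀·exp(−V(s)/kB·ΔT)` with `ΔT = (γ−1)·T`; the free-energy
surface is recovered as `F(s) = −γ/(γ−1)·V(s) + C`.  Basins are local
minima of the reconstructed surface and the barrier between basins is the
minimax-path saddle on the grid graph (8-connected, periodic in Ψ).

**Synthetic ground truth.** A pseudo-bilayer generator with exact lattice
arithmetic, an overdamped Langevin sampler whose stationary law is the
Boltzmann distribution of the chosen analytic potential, Brownian walkers
with prescribed `D`, and a shipped four-basin membrane-insertion landscape
over (z, Ψ) mimicking folded/extended states on both membrane sides.

## Worked example

```bash
bilayerlab demo --seed 1 --out-dir demo_out
```

runs the full pipeline on generated data and writes `demo_out/summary.json`:

```json
"membrane":  { "area_per_lipid_nm2": 0.60822509, "thickness_nm": 4.0003571 },
"diffusion": { "true_D_1e-7_cm2_s": 3.9, "fitted_D_1e-7_cm2_s": 3.9169641 },
"wtm":       { "first_hill_kJ_mol": 1.0, "first_barrier_kJ_mol": 15.176909,
               "true_barrier_kJ_mol": 15.0, "fes_basin_error_kJ_mol": 1.1627684 }
```

Reading: the jittered 100-lipid bilayer (0.78 nm lattice, 4 nm leaflet
separation) averages to A ≈ 0.608 nm² and Δz ≈ 4.00 nm; the Einstein fit
recovers the generator's lateral diffusion constant 3.9×10⁻⁷ cm²/s to 0.4%;
and a 2 ns tempered run on the 15 kJ/mol double well reproduces the barrier
to ~0.2 kJ/mol with a free-energy error over the wells around 1 kJ/mol
(less than 1 kBT ≈ 2.5 kJ/mol at 303 K).  The same workflow is available as
individual subcommands (`generate`, `membrane`, `rdf`, `pmf`, `diffusion`,
`wtm run`, `wtm fes`), all reading a YAML config whose defaults
`bilayerlab config show-defaults` prints.

## File formats

Internal units are nm / ps / kJ/mol / degrees everywhere; readers convert
on ingest, writers on output.

* **Multi-frame XYZ** with a comment-line micro-format
  `t=<val> ps box=<Lx> <Ly> <Lz>` (XYZ has no standard for time or box).
* **GRO** (GROMACS fixed-column coordinates, nm), single- or multi-frame,
  orthorhombic boxes only.
* **COLVAR / HILLS** in the PLUMED `#! FIELDS …` dialect, with
  `#! SET period_<cv>` / `#! SET unit_<cv>` lines for CV metadata.

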