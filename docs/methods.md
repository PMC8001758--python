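# Methods

This note records the models behind each module, the defaults that matter,
what the synthetic generators do and do not emulate, and the numerical
choices a maintainer would want to know.

## Unit system

All in-memory quantities are nm, ps, kJ/mol, degrees and Kelvin; `kB` is
the molar gas constant 8.31446×10⁻³ kJ/(mol·K).  Readers convert on ingest
and writers on output, so Å and other presentation units appear only at
format boundaries.  Diffusion coefficients are reported in cm²/s (the unit
such tables are conventionally printed in); 1 nm²/ps = 10⁻² cm²/s.

## Membrane observables

*Area per lipid* divides the lateral box area by the lipid + cholesterol
count of **one** leaflet; cholesterol counts identically to lipids.
*Thickness* is |⟨z⟩_upper − ⟨z⟩_lower| over the phosphate marker groups —
an ensemble-level reading of "distance between the phosphate planes" that
is robust to positional jitter, rather than any per-lipid pairing.
Windowed means carry block-averaged standard errors (5 contiguous blocks;
fewer frames than blocks falls back to the plain SE).

The probe position is its centre-of-mass z (unit masses unless a mass
table is supplied — toy probes are single particles) minus the bilayer
midplane, defined per frame as the mean of the two leaflet means; the
series is therefore invariant under rigid z translations.

*Conformer windows.*  The folded/extended torsional states are assigned on
|Ψ| with windows mean ± 2.5 sd of the observed conformer distributions
(81 ± 10° → [56°, 106°]; 170 ± 23° → [124°, 180°], capped at 180°).  The
2.5-sd width is a package choice: it covers ~99% of each distribution
while leaving a deliberate unassigned gap between the states so that the
labels never overlap.

*Residence episodes* are maximal runs of frames with z inside the slab;
excursions strictly shorter than `min_gap` merge the adjacent runs
(brief recrossings count as one adsorption event).  Episode durations
count one frame spacing per resident frame, so a fully-resident series has
occupancy exactly 1.

## Pair structure

The RDF estimator is the standard shell count
`g12(r) = V⟨n2(r)⟩/(4π r² Δr N2)` with per-frame volume (correct for a
fluctuating NPT box), minimum-image distances, and self-pair exclusion for
overlapping groups.  The default Δr = 0.002 nm resolves hydrogen-bond-scale
first peaks (0.17–0.20 nm); coarser bins are advisable for sparse data.

`W(r) = −kB·T·ln g(r)` is computed only where g > 0; empty bins are masked
rather than mapped to ±∞, and `exp(−W/kBT)` reproduces g on unmasked bins
to machine precision (a tested invariant).  Extremum location optionally
applies a centred 3-bin moving average (off by default) because noisy
tails otherwise spawn spurious extrema.  The barrier convention is
*first interior minimum → next maximum at larger r*; profiles referenced
to the bulk plateau would give different absolute numbers, so the
convention is stated here and in the docstrings.

## Diffusion

MSD uses every time origin; the implementation evaluates the identical sum
via an FFT autocorrelation identity in O(n log n) and is tested to agree
with the O(n²) double loop at machine precision.  Coordinates must be
unwrapped; a minimum-image step-correction helper is provided and wrapped
jumps (single-frame steps beyond half the box) raise with advice.

The Einstein fit uses lags in [10%, 50%] of the trajectory length by
default — early lags are noise/ballistic-contaminated in real data, late
lags origin-starved.  The standard error is the **spread (std) of 5
block refits, not spread/√5**: with a fit window that scales with series
length, the fitted-D sampling variance does not decay as 1/T, so the block
spread estimates the full-series fit's own standard deviation.  Empirical
coverage of ±2 SE on Brownian fixtures is ~88% (the 5-block spread is
t-distributed), which the coverage tests account for with a binomial
floor (≥ 14 of 20 seeds).  The estimator itself is unbiased (verified over
100 seeds).

## Synthetic generators

`generate_bilayer` places phosphate markers of each leaflet on a jittered
square lattice at ±separation/2, with independent per-frame jitter and
lateral box fluctuation; all structural expectations (A, Δz) are exact by
construction at zero jitter.  Defaults (100 lipids/leaflet, 0.78 nm
spacing, 4.0 nm separation, 0.05 nm jitter) give a DMPC-like liquid-phase
bilayer: A ≈ 0.61 nm², Δz ≈ 4 nm.  What it does **not** emulate: lipid
tails, undulations, leaflet asymmetry, area–thickness anticorrelation, or
any chemistry — so passing tests validate the estimators' arithmetic and
statistics, not force-field realism.

`simulate_langevin` integrates overdamped (Euler–Maruyama) dynamics
`x ← x − ∇U·dt/γ + √(2 kB T dt/γ)·ξ`, whose stationary law is
∝ exp(−U/kBT).  Inertia, thermostats and solvent memory are deliberately
absent: for CV-space sampling the exact stationary law is worth far more
than kinetic realism.  A declared stability bound rejects
`dt·max|U″|/γ > 0.5` (estimated on a coarse domain grid); beyond ≈1 the
discrete harmonic update becomes badly biased and at 2 it diverges.
Non-periodic CVs reflect at the domain edges; periodic CVs wrap onto
(−half, half].

`simulate_brownian2d` draws i.i.d. Gaussian increments of variance 2·D·dt
per axis — the exact discrete-time law, so recovery tests close the
generator/estimator loop with no discretisation error.  Multiple walkers
shrink estimator variance honestly.

All generators are pure functions of (spec, seed); there is no global
random state.

## Well-tempered metadynamics

Hills of widths σ are deposited every `stride` ps with heights
`w = w₀·exp(−V(s)/kB ΔT)`, `ΔT = (γ−1)T`; the surface is estimated as
`F = −γ/(γ−1)·V` (exact in the long-time WTM limit) rather than by
histogram reweighting — simpler, and sufficient for the convergence levels
targeted here.  The zero convention is min-zero by default; max-zero
(surface referenced to its highest value, i.e. to the bulk) is available.

Engine internals: the bias **and its analytic gradient** are accumulated
on a regular CV grid (default spacing 0.05 nm / 2°, several times finer
than the hill widths) as each hill is added, so a propagation step costs
two multilinear interpolations regardless of the hill count; the static
potential gradient is tabulated on the same grid once.  Interpolation
error is second order in the grid spacing and negligible against the
statistical error at these settings.  FES reconstruction from a hill log
exploits the separability of the Gaussians over axes (outer products of
per-axis factor vectors), identical to the naive sum at roundoff.

Periodic CVs use minimum-image displacements in hill evaluation, grid
accumulation and path analysis, so surfaces are invariant under shifting
all Ψ values by a period (tested).

*Basins and barriers.*  Basins are local minima (8-connected, wrapping
over periodic axes) below a depth threshold — by default within 25% of the
surface range above the global minimum, deepest `n_basins_max` kept,
labelled A, B, … by depth.  The barrier from basin i to j is the
minimax-path saddle: grid points are activated in ascending F with
union–find merging, and the first value at which the two basins' components
join is the lowest possible "highest point along a path".  `ΔF(i→j) =
F_saddle − F(basin i)`, measured from the departing basin and therefore
asymmetric.  Tests compare against an independent bisection-over-threshold
BFS oracle.

*Shipped benchmarks and problem sizes.*  Two study presets are shipped and
used by the tests and the acceptance script: a 1D quartic double well
(barrier 15 kJ/mol, 3 ns of toy time, dt 5 fs, hill width 0.1 nm) and a 2D
four-basin membrane-insertion landscape over (z, Ψ) (wells of 20 kJ/mol at
z = ±1.5 nm, Ψ = ±70°/180°, a 45 kJ/mol ridge at z = 0; 20 ns, dt 10 fs,
hill widths 0.30 nm / 20°, stride 1 ps, w₀ = 1 kJ/mol, γ = 10 at
303.15 K).  Run lengths were sized so the tempered bias revisits every
basin many times; both recover the ground-truth surface over the basin
regions (F within 5 kJ/mol of each well bottom) to better than 1 kBT
(≈2.5 kJ/mol), after aligning the arbitrary additive constant over that
region.  The folded↔extended torsion barrier (same membrane side)
converges to within 1 kBT of the exact minimax value; the much larger
cross-membrane barrier over the central ridge converges more slowly —
its top is exponentially rarely visited — and is reported but not held to
the 1 kBT bar at these run lengths.

Friction defaults (10 /ps on z, 0.05 /ps on Ψ) put the per-CV diffusion
constants at 0.25 nm²/ps and ≈50 deg²/ps, i.e. both CVs traverse their
domains many times per nanosecond; they are sampler settings, not physical
constants.

## Design choices that were genuinely open

* **Eq-style area denominator**: one leaflet's counts, made unambiguous by
  the generator's leaflet groups.
* **Barrier conventions**: PMF barriers are min→next-max differences; FES
  barriers are minimax-path saddles.  Both stated above because neither is
  universal in the literature.
* **Ψ stored signed** with period 360°; |Ψ| is a presentation fold applied
  only in the conformer classification.
* **CV dialect**: COLVAR/HILLS metadata (`period_`, `unit_` SET lines) is
  this package's extension of the PLUMED header style, needed because the
  files must round-trip periodicity and units.
* **FES from the bias relation**, not reweighting; reweighting is a
  non-goal.

## Known limitations

* Orthorhombic boxes only; binary trajectory formats (XTC/TRR/DCD) are out
  of scope — XYZ/GRO/COLVAR/HILLS text dialects cover the toy studies.
* The Langevin sampler is first-order; observables that depend on kinetic
  correlations (velocity autocorrelation, inertial recrossing) are outside
  its reach.
* The WTM engine supports one or two CVs (the grid-accumulated bias is
  dimension-general in principle, but only 1D/2D paths are implemented and
  tested).
* `find_basins_barriers` has no prominence-based basin merging; very noisy
  surfaces can yield spurious shallow basins unless the depth threshold is
  tightened.
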