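# Methods

## The model

`gonad-cpm` simulates the compaction of the *Drosophila* embryonic gonad —
an elongated primordium of 7 primordial germ cells (PGCs) ensheathed by 14
somatic gonadal precursors (SGPs) that rounds up into a sphere — as a 2D
Cellular Potts model (CPM) on a square lattice. Each cell occupies many
pixels; the perigonadal environment is a single reserved "medium" label.
A configuration's potential energy is

    U = Σ_cells (K_i/2)(V_i − V_i0)²        volume elasticity
      + Σ_interfaces E_j · l_j              linear interfacial energy
      + Σ_cells (C_i/2) L_i²                quadratic cortical tension

with V_i the pixel count of cell i, L_i its boundary length, and l_j the
shared edge length of interface class j. E_j balances cortical contraction
(positive) against adhesion (negative): cadherin enrichment at SGP–SGP
boundaries corresponds to lowering E_SGP-SGP. The medium has no volume or
perimeter terms and enters only through the cell–medium ("out")
coefficients.

Dynamics are Metropolis Monte Carlo: one Monte Carlo step (MCS) is
height×width flip attempts; each attempt draws a boundary pixel uniformly
(rejection sampling), proposes the label of a uniformly chosen differing
4-neighbour, and accepts with probability 1 for ΔU ≤ 0 and exp(−βΔU)
otherwise. ΔU is computed incrementally from the 4-neighbourhood and is
exactly equal to the full energy difference (property-tested to 1e-6
relative on 10⁴ random flips). Geometry (volumes, perimeters, interface
lengths) is maintained in exact integers; energies in double precision.
A cell whose volume reaches zero is logged as an extinction; its elastic
energy (K/2)V0² remains in the total so that incremental differences stay
exact across annihilation events. Fragmentation is permitted (no
connectivity constraint) and is rare at the default β.

### Conventions

- 4-neighbour adjacency defines interfaces, perimeters and the flip-source
  boundary; an 8-connected *proposal* pool is available
  (`proposal_connectivity=8`) but does not change energy bookkeeping.
- Pixels outside the grid read as medium (fixed-medium frame); there is no
  periodic wrap. The gonad is an isolated cluster in effectively infinite
  medium.
- One seeded `numpy` generator drives a whole run; sweep trials use
  seed + trial index, with identical seeds across grid points so that
  comparisons between points are paired.

## Parameters

Defaults (dimensionless coefficients converted at construction):

| symbol | value | meaning |
|---|---|---|
| K_G, K_S | 80, 200 | volume elasticity, germ / somatic |
| V_G0, V_S0 | 1600, 400 px | favoured volumes |
| C_G, C_S | 6.8e-3, 7.4e-3 × K_G·V_G0 | cortical spring constants |
| E_PGC-PGC | 4.0e-2 × K_G·V_G0^{3/2} | germ–germ tension |
| E_PGC-SGP | −2.0e-2 × K_G·V_G0^{3/2} | germ–somatic adhesion |
| E_PGC-out | 2.2e-1 × K_G·V_G0^{3/2} | germ–medium tension |
| E_SGP-SGP | −0.01 (axis) | somatic–somatic balance |
| E_SGP-out | 0.16 (axis) | somatic–medium tension |
| β | 1.2e-5 | inverse temperature |

E_SGP-SGP and E_SGP-out are the two free axes of the phase sweep. By
default they are converted with the same K_G·V_G0^{3/2} unit as the other
interfacial coefficients. Because that unit is a convention choice rather
than a measurement, `sgp_energy_unit="sgp"` converts them with the somatic
cells' own elastic unit K_S·V_S0^{3/2} instead (3.2× smaller), which moves
the tissue surface from ~10 kT to ~3 kT per edge and qualitatively changes
the kinetics (below).

### Reduced-scale runs

The full system needs a ≈265×151 lattice and ~20,000 MCS. For routine runs
and the test suite the model is shrunk by a linear factor s
(`scale=0.375`): favoured volumes ×s² (V_G0→225, V_S0→56), C and E rebuilt
from the same dimensionless coefficients with the scaled units, and β×s⁻³,
which leaves every acceptance-controlling β·E product at its full-scale
value. The reduced system (120×72 lattice, 8,000 MCS, averaging window
5,000–8,000 MCS) reproduces the full-scale behaviour in all checks we run;
the problem sizes were chosen so a complete sweep finishes on a laptop
core in minutes.

## Initial configuration

The starting primordium is a three-lobed band: a superellipse-capped rod
with shallow waists at its thirds, echoing the three parasegment SGP
clusters that merge to form the gonad. Waist depth and cap sharpness fade
smoothly to a disc as the aspect ratio approaches 1, so the contour
circularity of the default aspect-3 band is ≈0.57 (elongated) while an
aspect-1 start is ≈0.99 (round). Cells are laid into three horizontal
bands — SGPs above, the PGC row in the middle, SGPs below — by exact
pixel-count chunking in column-major order, so every cell begins within a
few percent of its favoured volume and all 21 cells are contiguous.

## Readouts

- **Gonad circularity** 4πA/P² of the union of all cell pixels (largest
  connected component if the gonad has split, with a split flag). The
  default perimeter is the length of the marching-squares contour polygon
  smoothed with a 5-vertex circular moving average: raw marching-squares
  contours of binary masks overestimate perimeter (a rasterized r=40 disc
  would score 0.89), while the smoothed contour scores it 0.994 and tracks
  the Ramanujan closed form of a 5:1 ellipse within 1%. Exact lattice edge
  counts (`method="edge"`) and the 4-direction Crofton estimate
  (`method="crofton"`) remain available; the energy terms always use edge
  counts.
- **Cell circularity**: same formula per cell, clipped to 1.0; regions
  under 10 px are flagged degenerate.
- **Orientation**: acute angle between the principal axis of the pixel
  second moments and the anterior–posterior (AP) axis, in [0°, 90°];
  regions with principal-eigenvalue ratio < 1.05 have no meaningful long
  axis and return None. Image-moment axes are rotation-stable, unlike the
  longest chord.
- **AP regions**: cell centroids projected on the AP axis; the projected
  extent of the gonad is split into three equal bins (boundaries to the
  lower bin). When no axis is supplied the principal axis of the gonad
  mask is used.
- **Membrane intensity ratio**: SGP membrane pixels (within 1 px of a
  differing label) are classed OUTER if they touch medium, else INNER if
  they touch another SGP; SGP–PGC boundary pixels are excluded. The ratio
  is the pooled outer mean over the pooled inner mean. Optional background
  subtraction removes the additive floor that biases raw ratios toward 1,
  and optional junction exclusion drops vertices where a finite PSF mixes
  the two classes; both default off.
- **Group summaries**: per-group mean and SE plus Welch (unequal-variance)
  two-sample p-values, matching how stage and genotype contrasts are
  typically annotated.

## Synthetic sections

The generator emulates a stained 2D gonad section: n_pgc + n_sgp seeds
inside an ellipse of controllable aspect ratio (germ-cell seeds fill the
centre in a sunflower pattern, somatic seeds sit on a peripheral ring),
tessellated by nearest seed. A matched intensity image paints inner_level
on SGP–SGP boundaries and outer_level on both pixel layers of the
SGP–medium outline (so both membrane classes are two pixels wide and blur
erodes them symmetrically), on top of a uniform background, then applies a
Gaussian PSF and seeded Gaussian noise. Ground truth (areas, measured
clean-image circularities and orientations, seed-based region bins, the
true intensity ratio) is emitted alongside. The gonad area is held fixed
across aspect ratios, so a series of decreasing ratios emulates
progressive compaction with strictly increasing circularity.

What the generator does *not* emulate: irregular cell outlines, nuclei,
3D structure, Poisson photon statistics, protrusions. Passing recovery
tests therefore validate the estimators' geometry and noise behaviour,
not segmentation of real micrographs.

## Known limitations

- **Kinetic arrest at the default couplings.** With interfacial
  coefficients on the K_G·V_G0^{3/2} unit and β = 1.2e-5, surface moves
  cost ~10–13 kT per lattice edge. The tissue surface facets and freezes:
  from the elongated start the gonad rounds only to circularity ≈0.62 and
  then arrests (verified out to 30,000 MCS), with at most weak,
  correctly-signed trends along both phase-diagram axes (≈0.02 over the
  default grid). Under the alternative `sgp_energy_unit="sgp"` reading the
  surface is thermally active and the tension axis resolves strongly, but
  the adhesion axis remains within Monte Carlo noise at these system
  sizes. Distinguishing adhesion-driven from tension-driven compaction at
  this cell count therefore requires either longer runs at intermediate
  couplings or additional conventions (e.g. a connectivity constraint)
  that this implementation deliberately omits.
- Surface tension compresses cells below their favoured volumes
  (Laplace pressure): time-averaged volumes sit 10–25% low at the default
  couplings. This is a real property of the potential, not a bookkeeping
  error (the same runs satisfy the exact ΔU and geometry invariants).
- Circularity of lattice shapes depends on the perimeter estimator;
  results quote the smoothed-contour convention unless stated.
- The Metropolis proposal (uniform over boundary pixels, then uniform over
  differing neighbour labels) is one of several standard CPM choices;
  absolute MCS time scales are convention-dependent and only comparisons
  at matched conventions are meaningful.

## File formats

- `series.csv` (simulate; also `results/time_course*.csv`): `mcs`,
  `energy`, `gonad_circularity`, `accepted_flips` — one row per recorded
  MCS.
- `trials.csv` (sweep): `e_sgp_sgp`, `e_sgp_out`, `trial`, `seed`,
  `mean_circularity` (windowed), `final_circularity`, `surviving_cells`,
  `split_final`, `n_extinctions`; `means.csv` aggregates
  `mean_circularity` per grid point.
- `cells.csv` (measure): `cell_id`, `kind`, `area`, `circularity`,
  `orientation_deg` (NaN when undefined), `region`.
- `gonad.json` (measure): gonad circularity, cell count and — when an
  intensity image is given — `outer_mean`, `inner_mean`, `ratio`,
  `n_outer`, `n_inner`.
- `truth.csv` (synth): `cell_id`, `kind`, `seed_x`, `seed_y`, `area`,
  `circularity`, `orientation_deg`, `region`.
- `kinds.csv`: `cell_id`, `kind` — maps label ids to PGC/SGP.
- Label images are 16-bit TIFF (or PNG); intensity images float32 TIFF;
  snapshot stacks multi-page TIFF. Every CLI run writes `manifest.json`
  (subcommand, full config, seed, outputs, version, wall clock).
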