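# Methods

This note documents the models and procedures implemented in `chromofold`,
the parameters that matter, and the design decisions taken where the
methodology left choices open.

## Scope and data flow

The package studies local chromatin fiber folding — the hypothesis that
quiescent cells compact their chromatin through an increase in the range
of inter-nucleosomal contacts — with three independent measurement arms
plus a simulation arm:

1. **Contact analytics** (`contact_pipeline`): proximity-ligation pair
   records at nucleosome resolution are filtered, binned, and summarized
   as contact-probability decay curves, long/short odds ratios,
   anchor-centred pileups, and stratum-adjusted correlations (SCC).
2. **Mesoscale simulation** (`fiber_model`, `mc_engine`): a
   nucleosome-resolution coarse-grained fiber sampled by Metropolis /
   configurational-bias Monte Carlo.
3. **Fiber statistics** (`fiber_analysis`): sedimentation coefficient,
   radius of gyration, packing ratio, alpha-shape volume, DBSCAN
   clustering, internucleosome contact maps and I(k) profiles, and
   tail–element interaction matrices.
4. **Erosion analysis** (`erosion_analysis`): average fiber diameter from
   serial morphological erosion of segmented binary volumes.

Every input is produced by `synthetic_data`, so the full pipeline runs
and is tested without external data.

## Synthetic data

**Nucleosome tracks.** Dyads are laid down sequentially with spacing
`max(147, N(repeat, jitter))`; the 147 bp floor is the nucleosome
footprint, so dyads can never overlap. Defaults use a 165 bp repeat
(~18 bp linkers, typical of yeast). Nucleosome-free regions are realized
as dyad-free gaps. Acetylation and linker-histone (LH) flags are
independent Bernoulli draws. The two study presets are: *log-like* —
acetylation density 61/222, LH density 0.05/nucleosome; *quiescent-like*
— acetylation 3/228, LH 0.29/nucleosome.

**Contact pairs.** The genomic-distance law is an explicit mixture:
nucleosome-neighbour components at `k × repeat ± jitter` (k in nucleosome
steps, so tests can dial n+1-dominated versus long-range-enriched regimes
directly), a uniform long-range band (default 500–1000 bp), uniform
background, and optional anchor-loop / stripe components for pileup
analysis. In-facing pairs are emitted at a configurable fraction; the
remaining orientation mass is split evenly among out-facing and the two
tandem classes so every orientation class is populated. Positions are
0-based internally and written 1-based in the pairs text. The *log-like*
preset concentrates neighbour mass at k=1 (weight 0.55); the
*quiescent-like* preset flattens k=1..3 and moves mass (0.38) into the
500–1000 bp band. Beyond 1 kb the distance law of real samples is not
characterized here; the background and long-range knobs are free
parameters, not calibrated to data.

**Tube volumes.** Solid cylinders on a voxel grid spanning the full z
extent (like a fiber crossing a sub-tomogram), with optional
salt-and-pepper noise. Only lateral padding is added, so erosion with
out-of-volume voxels treated as foreground measures the radial geometry
alone.

All generators are pure functions of (spec, seed); reruns are
bit-identical.

## The coarse-grained fiber model

Elements per nucleosome:

* **Core**: a geometric centre (the backbone node used for the chain
  terms, Rg and sedimentation) plus surface charge beads distributed by
  golden angle on the lateral surface of a cylinder. The default surface
  layout uses a 4.0 nm radius × 4.0 nm height cylinder: with ~165 bp
  repeats the inter-core contour is only ~9 nm and the model has no
  independent core rotation moves, so wider (disc-sized) rigid shells of
  neighbouring cores would permanently interpenetrate and freeze the
  backbone under the excluded-volume wall. The 5.5 nm nucleosome radius
  is retained where it is a physical constant (the sedimentation
  formula). Total core charge (−72 e by default) is spread uniformly
  over the charge beads, so reducing the bead count (the desk preset
  uses 16 instead of 48) preserves the monopole.
* **Linker DNA**: one bead per 9 bp (3.0 nm segments), harmonic
  stretching (100 kT/nm²), harmonic bending with g = Lp/l₀ per interior
  node (Lp = 50 nm, reduced to 30 nm in magnesium mode), and a harmonic
  twist register per segment (torsional persistence 75 nm). The initial
  twist is set by the B-twist argument (−12°, 0°, or +12°).
* **Histone tails**: five residues per bead — H3 and H4 5 beads, H2B 5,
  H2A N-tail 3, H2A C-tail 2, two copies each (10 tails/core), grafted to
  designated charge beads. Tail bonds are fixed-length in practice: the
  regrowth move places beads at the equilibrium bond length, so the
  stretch term is identically zero for tails and the k=1 limit of the
  Rosenbluth acceptance reduces *exactly* to Metropolis. Acetylated
  nucleosomes carry their H3 and H4 tails in the *folded* state: a
  compact template with force constants multiplied by 100, excluded from
  every nonbonded pair list and from regrowth (the non-interaction rule
  is exact, which the tests exploit).
* **Linker histones**: on flagged nucleosomes, 6 globular beads plus a
  22-bead (H1e) or 21-bead (H1c) C-terminal domain, built as a compact
  helix near the core (a straight 40 nm spike would take most of a
  desk-scale run just to relax).

**Nonbonded terms.** Screened Coulomb (Debye–Hückel, ε_r = 80,
κ = 1.27 nm⁻¹ at 150 mM) plus 12-6 Lennard-Jones within a 7 nm cutoff.
Pairs within the same exclusion group (one nucleosome's core + tails +
LH, or one linker segment) do not interact. Magnesium mode raises the
DNA–DNA inverse screening length to κ_dd = 2.5 nm⁻¹ and reduces the DNA
persistence length to 30 nm; default conditions are 293 K, 150 mM
monovalent salt, magnesium mode on.

**Charges are stand-ins.** The per-bead charge magnitudes (DNA −4 e,
tails +1.1…+2.1 e per bead by kind, LH globular/CTD positive) are not
derived from atomistic structures; they were chosen once for physical
plausibility — tails and LH must bridge DNA and cores strongly enough
that LH-rich, deacetylated fibers condense within desk-scale runs
(hundreds of thousands of steps), while LH-poor, acetylated fibers stay
extended — and are flagged as stand-ins in the force-field metadata.
Absolute energies and absolute compaction magnitudes are therefore not
meaningful; *directional* comparisons between parameter sets are the
supported use.

**Initial configuration.** Cores on an ideal two-start zigzag with
inter-core separation equal to the linker contour; linker beads
interpolated; tails grafted perpendicular to the local fiber axis with a
parity-alternating tilt, then swept deterministically over a fan of graft
directions to remove residual steric clashes (the zigzag at ~165 bp
repeats is genuinely crowded). The build is a pure function of the track
and force field.

## Monte Carlo sampling

Five tailored moves: global pivot (shorter side of the bisected chain,
tie toward the lower-index side, rotated about a random axis through the
pivot node), single-bead translation (uniform in the amplitude ball),
single-bead frame rotation — realized as a twist-register perturbation
for DNA beads and a crankshaft rotation about the bonded-neighbour axis
for LH beads — configurational-bias tail regrowth (k trial directions
per bead, fixed bond length, weights `exp(-u)` with u the bend plus
nonbonded energy; acceptance `min(1, W_new/W_old)`), and fold-swap
(Metropolis on the energy difference between the folded and unfolded
templates; the template coordinates are regenerated deterministically
from the current anchor geometry, so a double swap restores the state
exactly).

Default mixture 0.2/0.3/0.2/0.2/0.1
(pivot/translate/rotate/regrow/fold-swap) with amplitudes (15°, 0.35 nm,
60°) tuned to the conventional 30–50% acceptance window; the fold-swap
probability is redistributed when no tails are acetylated. Energies are
in kT so the Metropolis exponent is unit-free. One `numpy` Generator per
trajectory, keyed by the schedule seed; trajectories are bit-reproducible
and all randomness flows from explicit seeds.

Desk-scale defaults are 12–24 nucleosomes and 10⁵–10⁶ steps with
configurations saved every 10⁴ steps; the production scale of the
modelled system (50 trajectories × ≥6×10⁷ steps) is a configuration
choice, not a code path difference. Scalar statistics (energy, Rg,
sedimentation) use the final sixth of each run (the proportional
last-10M-of-60M analysis window); contact maps and tail statistics use
the full run, mirroring the stated analysis protocol for those
quantities. Convergence is monitored by windowed means with a relative
drift statistic and an explicit "insufficient" status for too-short
runs.

## Fiber statistics

* **Sedimentation** S_w,20 = [S₁ + (S₀−S₁)·LH_conc] · (1 + (R₁/N_C)
  Σ_{i≠j} 1/R_ij), with S₀ = 12 S (mononucleosome with LH), S₁ = 11.1 S
  (without), R₁ = 5.5 nm. This grouping is the unique reading consistent
  with both mononucleosome limits; the ordered pair sum counts each
  unordered pair twice. LH_conc defaults to the flagged fraction of the
  topology.
* **Radius of gyration** over core centres.
* **Fiber axis length**: arc length of a cubic smoothing spline through
  the core centres ordered by fiber index; packing ratio = 11·N_C /
  length. Interpolation (smoothing 0) is exact for straight fibers; for
  compaction comparisons a smoothing budget of 30·N_C nm² (≈5.5 nm rms
  slack per core) lets the axis cut through a condensed blob rather than
  thread every core, which is what makes the packing ratio sensitive to
  condensation.
* **Alpha-shape volume**: Delaunay tetrahedra with circumradius ≤ alpha;
  alpha = ∞ is the convex hull; volume is monotone in alpha.
* **Clustering**: DBSCAN on core centres, 20 nm neighbourhood, minimum
  three neighbours. `min_neighbors` counts neighbours *excluding* the
  point itself (sklearn `min_samples = min_neighbors + 1`); both
  conventions agree on the documented worked examples.
* **Contact maps**: nucleosomes i, j are in contact in a configuration if
  any tail or charge bead of i is within 2 nm of any of j (binary per
  configuration). Per-trajectory count maps are normalized by their
  maximal entry — a scalar, not per-element, since per-element
  normalization would destroy the relative intensities that I(k)
  measures — then summed across trajectories.
  I(k) = Σᵢ I′(i, i±k) / ΣI′, so Σₖ I(k) = 1 for any nonzero map.
* **Tail interactions**: per configuration, each unfolded tail is
  assigned to at most one element class — separate core, separate DNA,
  or separate tails — by the nearest separate-nucleosome bead, provided
  that distance is under 2 nm. "Separate DNA" excludes the tail's own
  nucleosome's entering and exiting linkers. T′ is the occurrence
  fraction per (kind, class); T row-normalizes T′ so nonzero rows sum to
  one (zero rows are reported as NaN, never 0/0); dispersion is across
  trajectories.

## Erosion diameter estimation

The binary volume is eroded with discrete ball structuring elements of
increasing whole-voxel radius; the residual volume fraction (relative to
the unoperated mask) is recorded. The diameter estimate is the x-axis
intercept of an OLS line through the first five data points counted from
the smallest nonzero radius (radius zero carries no slope information).
For an ideal cylinder of diameter D the residual fraction is
((D/2−r)/(D/2))² ≈ 1 − 4r/D near r = 0, so the raw intercept sits at
D/4; the estimator therefore reports the raw intercept together with a
calibrated diameter (× 4.0 for cylindrical geometry). Absolute estimates
retain a positive bias of roughly half the mean fit radius (the fit
window is not infinitesimal) plus a discretization offset; relative
comparisons between volumes measured with the same voxel size and radii
are the supported use, and on synthetic 20/30/40 nm cylinders at 0.5 nm
voxels the estimate ratios track the true ratios within 10%. By default
out-of-volume voxels count as foreground during erosion (fibers cross
sub-tomogram boundaries); disable `border_foreground` for objects fully
contained in the volume.

## What the synthetic data do and do not show

The generators emulate the *statistical structure* of the real inputs —
nucleosome spacing with footprint exclusion, Bernoulli modification
flags at measured densities, an explicit contact-distance mixture,
clean cylindrical fibers. They do not emulate read-level noise, mapping
artifacts, chromatin heterogeneity along the genome, sequence-dependent
nucleosome positioning, irregular fiber cross-sections, or segmentation
errors. Passing tests therefore demonstrate that the *analytics* are
correct (oracle equivalence, normalization contracts, directional
recovery of configured signals), not that the biological conclusions
would reproduce from raw data.

## Numerical choices and degenerate inputs

Half-open distance bands ([50, 500) and [500, 1000) bp) avoid double
counting the 500 bp stratum. Genomic distance is |pos2−pos1| on raw
positions; binned diagonals use bin-index distance. The pileup median
over an even number of submatrices is the mean of the two central order
statistics (numpy's convention). SCC smoothing is a mean filter with
edge truncation, half-width 1 bin by default. Zero-variance strata carry
zero SCC weight; an all-zero matrix yields NaN rather than a number.
Undefined odds ratios (zero short-range mass), zero-slope erosion fits
and all-zero contact maps are flagged explicitly instead of returning
infinities. Coincident beads (r = 0) and NaN coordinates are rejected
with diagnostics. Inter-anchor pileups use same-chromosome anchor pairs
only.

## Known limitations

Cores carry no independent orientation moves, so orientation-dependent
stacking (the driver of regular two-start geometry) is not represented;
the model supports directional compaction comparisons, not absolute
fiber geometry. The fold-swap move maps the many unfolded conformations
onto one canonical template, a mild detailed-balance approximation that
regrowth moves dominate in practice (the two-state occupancy test
bounds the residual error). Desk-scale runs of the quiescent-like preset
condense by a nucleation-like event; individual seeds differ in when it
happens, which is why compaction comparisons pool several seeds and use
the late analysis window.
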