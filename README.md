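# chromofold

Local chromatin fiber folding, simulated and measured.

Quiescent cells repress transcription genome-wide, and one proposed
mechanism is a change in how the 10 nm chromatin fiber folds locally:
instead of the next-neighbour (n+1) contacts that dominate in cycling
cells, quiescent fibers gain inter-nucleosomal contacts in the 500–1000 bp
range, compacting without forming regular 30 nm structures. `chromofold`
implements the computational machinery needed to study this hypothesis
end to end:

* **a nucleosome-resolution mesoscale Monte Carlo simulator** — cores
  with surface charge beads, worm-like-chain linker DNA, flexible histone
  tails (five residues per bead) with an acetylation fold state, and
  linker histones, sampled with five tailored moves (pivot, bead
  translation/rotation, Rosenbluth tail regrowth, fold swap);
* **a fiber compaction analysis suite** — sedimentation coefficient
  S_w,20, radius of gyration, smoothing-spline packing ratio, alpha-shape
  volume, DBSCAN nucleosome clustering, internucleosome contact maps with
  k-neighbour profiles I(k), and tail–element interaction matrices;
* **nucleosome-resolution contact analytics** — pair orientation
  classification and in-facing filtering, multi-resolution binning
  (10/200/5000 bp), contact-probability decay curves, the long/short
  (500–1000 over 50–500 bp) odds ratio, anchor-centred median pileups,
  and the stratum-adjusted correlation coefficient (SCC);
* **an erosion-based fiber diameter estimator** for segmented binary
  volumes;
* **synthetic-data generators** for every input — nucleosome tracks with
  acetylation/linker-histone flags, contact-pair files with controllable
  local-folding structure, anchor sets, and binary tube volumes — so the
  whole pipeline runs and is tested without external data.

## The statistics at the core

The compaction proxy is the sedimentation coefficient

    S_w,20 = [S1 + (S0 − S1)·LH_conc] · (1 + (R1/N_C) Σ_{i≠j} 1/R_ij)

with the mononucleosome limits S0 = 12 S (linker histone bound) and
S1 = 11.1 S (without), R1 = 5.5 nm, and the sum over ordered core pairs.
The contact-probability decay P(d) divides each 10 bp diagonal sum of the
contact matrix by the diagonal's element count and normalizes the curve
to unit total; the odds ratio is the cumulative probability over
[500, 1000) bp divided by that over [50, 500) bp. The SCC between two
matrices is the variance-weighted combination Σ w_d r_d / Σ w_d of
per-distance-stratum Pearson correlations with w_d = N_d √(var_d(x)
var_d(y)), computed per chromosome up to 100 kb at 5 kb bins, median
reported. See `docs/methods.md` for the full model description.

## Worked example

```python
from chromofold import (classify_and_filter_pairs, bin_pairs, decay_curve,
                        odds_ratio, generate_contact_pairs)
from chromofold.presets import log_contact_spec, quiescent_contact_spec

for name, spec in [("log-like", log_contact_spec(n_pairs=100_000, seed=1)),
                   ("quiescent-like", quiescent_contact_spec(n_pairs=100_000, seed=2))]:
    pairs = classify_and_filter_pairs(generate_contact_pairs(spec))
    mats = bin_pairs(pairs, spec.chrom_sizes, 10)
    orr = odds_ratio(decay_curve(mats))
    print(f"{name}: kept {len(pairs)} pairs, odds ratio {orr.value:.3f}")
```

prints

```
log-like: kept 75099 pairs, odds ratio 0.174
quiescent-like: kept 75133 pairs, odds ratio 1.041
```

— about 75% of pairs survive the in-facing filter (the generator emits
25% in-facing pairs, which are removed as likely undigested
di-nucleosome contamination), and the quiescent-like distance mixture
(elevated 500–1000 bp mass) produces a roughly six-fold higher
long/short contact odds ratio than the n+1-dominated log-like mixture —
the directional signature that distinguishes folded from extended
fibers.

A desk-scale fiber simulation:

```python
from chromofold import build_initial_fiber, run_trajectory, MoveSchedule
from chromofold import sedimentation_coefficient, generate_nucleosome_track
from chromofold.presets import quiescent_fiber_spec, desk_force_field
from dataclasses import replace

track = generate_nucleosome_track(replace(quiescent_fiber_spec(seed=12),
                                          n_nucleosomes=12))
ff = desk_force_field()
config = build_initial_fiber(track, ff)
traj = run_trajectory(config, ff,
                      schedule=MoveSchedule(total_steps=100_000, seed=7))
print(f"S_w,20 = {sedimentation_coefficient(config):.1f} S, "
      f"acceptance: { {k: round(v, 2) for k, v in traj.acceptance_rates().items()} }")
```

The command-line interface mirrors the library:
`chromofold simulate-pairs`, `simulate-track`, `simulate-volume`,
`simulate-fiber`, `analyze-fiber`, `pairs-filter`, `decay`, `pileup`,
`scc`, `erosion` (each with `--help`).

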