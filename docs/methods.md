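# Methods

## Model

A gene-sized chromatin region is a 1D lattice of `n` nucleosomes (default
50, ≈10 kb at 200 bp per nucleosome).  Each lattice site carries one
modification state — unmodified U, acetylated A or methylated M — and at most
one bound enzyme (methyltransferase Mt; in the dual-enzyme model also an
acetyltransferase At).  The system evolves as a continuous-time Markov chain
whose reaction channels are:

| channel | condition | rate |
|---|---|---|
| initiate | enzyme's initiation site unoccupied | k_on |
| unbind | any bound enzyme | k_off |
| catalyze_site | bound enzyme on a U nucleosome | k_transferase |
| catalyze_neighbor | bound enzyme, U neighbour (recruitment/combined) | k_neighbor |
| slide | bound enzyme, empty neighbour (diffusion/combined) | k_slide/2 per direction |
| recruit | empty nucleosome carrying the enzyme's own mark (recruitment/combined) | k_recruitment per site |
| background_acetylate | U nucleosome (single-enzyme model) | k_background_acetylation |
| demodify | A or M nucleosome | k_demodification |
| connect | connectivity-site pair with ≥1 bound enzyme | k_interaction per pair |

Boundaries are reflective (no slide channel off the array) and enzymes
exclude one another, so without connectivity they can never pass each other.
Enzymes may bind nucleosomes in any modification state but only convert
U → M (Mt) or U → A (At); demodification and background acetylation are
enzyme-independent and are *not* blocked by a bound transferase.
Connectivity fires per unordered site pair: a lone enzyme hops across, two
enzymes exchange positions; pairs with both sites empty are not scheduled
(the corresponding firing would be a no-op and leaves every observable
distribution unchanged).

Three movement mechanisms are exposed: `diffusion` (sliding only — no
neighbour catalysis, no recruitment), `recruitment` (neighbour catalysis and
recruitment, no sliding) and `combined` (all of the above).

## Parameters

All rates are s⁻¹ and derive from physical constants
(`nucspread.physical`):

- `k_on = 4π(D_E+D_S)(r_E+r_S) n_E / V_nucleus ≈ 2.4` — Smoluchowski
  association of ~5000 nuclear enzymes (D_E ≈ 3.8 µm²/s, 2.5 nm radii) with
  a 5 nm site in a 500 µm³ nucleus.  The same value is used for
  `k_demodification` and `k_background_acetylation` (the background
  reactions are themselves diffusion-limited enzymatic events).  The
  dual-enzyme model lowers `k_on` to 0.01 so recruitment, not initiation,
  dominates and either mark can take over the array.
- `k_off = 1/residence = 0.1` — 10 s mean chromatin residence (FRAP).
- `k_slide = 2 D_1d / d² ≈ 0.6` with D_1d = 2×10⁻⁴ µm²/s and d = 25 nm.
  This is the **total** hop rate of a symmetric random walk whose MSD is
  2·D_1d·t; the simulator therefore assigns k_slide/2 to each direction.
  (Quoting 0.6 per direction would double the effective diffusivity; with
  that convention the seeding experiment nucleates in ~90% instead of ~80%
  of replicates and the stationary state overshoots to ~45 methylated
  nucleosomes.)
- `k_transferase = 1000` — on-site catalysis is effectively instantaneous
  once an enzyme is bound; `k_neighbor = 0.2` — neighbour catalysis is slow
  (DNA persistence length).
- `k_recruitment ∈ [0.24, 4.8]`, summarised by the recruitment efficiency
  RE = k_recruitment/k_demodification (mark lifetime over mean time to a
  recruitment event); `k_interaction ∈ [0.01, 1]` per connectivity pair.

Configurations are YAML files keyed by these symbols; bundled presets
(`fig2` … `fig7e_ii`, `figS1…S5` connectivity grids with the equidistant
2/3/5/10-site layouts) cover the reference experiments.

## Simulation

`simulate` samples the chain exactly.  The default solver is a
next-reaction method: every channel of a fixed, configuration-wide indexing
holds a tentative absolute firing time; after an event, channels whose
propensity is unchanged keep their time, while the fired channel and any
channel whose propensity changed draw a fresh exponential.  Redrawing on
change (rather than Gibson–Bruck rescaling) is exact by the memoryless
property and keeps the inner loop branch-free.  The classic direct method is
implemented independently and retained as a cross-validation oracle; both
live in numba-compiled kernels operating on integer-coded state arrays.
Tie-breaking of equal tentative times (measure-zero, but possible in
floating point) resolves to the smallest channel index.

Reproducibility: one RNG stream per trajectory, seeded from
`SeedSequence([master_seed, replicate_index])`; identical
(config, seed, method) triples give byte-identical event logs, and run
manifests record every replicate seed so experiments replay exactly.

Exactness is verified two ways: (i) for n ∈ {2,3} the time-weighted SSA
state distribution matches the stationary vector of the explicitly
assembled generator matrix to total variation < 0.02 (the generator is built
from an independent clause-by-clause rule oracle in the test suite); (ii)
the two solvers are statistically indistinguishable on two-sample KS tests
over 200 paired-seed ensembles.

## Estimators

All estimators are time-weighted (a state counts in proportion to the time
spent in it) and accept either exact event logs or fixed-step kymograph
rasters; the two agree as the raster step approaches the event resolution.

- *Positional profile*: per-position probabilities of each mark and of
  occupancy by each enzyme, over the final 60% (configurable) of each
  trajectory, ensemble-averaged.
- *Count distribution*: time-weighted distribution of a total count
  (M, A, U or enzymes) over the same steady window.
- *Binned dynamics*: per 1-s bin, each trajectory contributes its
  time-weighted bin mean; the ensemble min, quartiles (linear interpolation
  between order statistics) and median are reported per bin.
- *Relaxation experiment*: k_on forced to 0, start fully methylated and
  fully occupied, follow the total-M order statistics.
- *Seeding experiment*: start from k equidistant methylated+occupied
  nucleosomes (positions round(n(2i−1)/2k), the symmetric placement) in an
  otherwise unmodified, enzyme-free array, with no initiation influx; a
  replicate ends "high" if its time-averaged total M over the final 10% of
  the run exceeds n/2.  The two modes sit near 0 and ≈40, so any mid-gap
  threshold gives the same classification; n/2 is the symmetric choice.
  The fraction is reported with a 95% Clopper–Pearson interval.
  Initiation influx is off in this experiment because a no-methylation end
  state is only stationary without it: with k_on = 2.4 the initiation site
  is occupied ~96% of the time and every arrival is a fresh nucleation
  attempt, so all replicates eventually end high.  The influx variant
  remains available via `config.with_rates(k_on=2.4)`.
- *Boundary statistic*: per 10-s window, the replicate distribution of the
  time-averaged (total M − total A), rounded to integer bins.
- *Switching summary*: whether a replicate's (total M − total A) ever
  exceeds +n/2 (majority-M) or falls below −n/2 (majority-A).

## Establishment times

Establishment is measured on the ensemble median of total M from the fully
acetylated, enzyme-free start: the first 1-s bin whose median reaches 90% of
the stationary plateau, with the plateau taken as the mean of the median
over the final quarter of the standard 400-s horizon.  The combined
mechanism's plateau is insensitive to the horizon (identical at 800 s).  The
RE = 2 recruitment system, by contrast, is still slowly coarsening beyond
400 s (its apparent plateau keeps rising out to at least 1200 s), so its
establishment time is only meaningful relative to the standard horizon; we
report it on that protocol.  Under these conditions the combined mechanism
reaches 90% of its plateau in ≈1.7 min — somewhat above the often-quoted
one-minute scale, which our parameterisation does not reproduce while
simultaneously matching the seeding-bistability fractions and the ≈40
nucleosome stationary level; we prioritise the latter, sharper statistics.

## Scale of the shipped experiments

Reference ensembles are 400 replicates (seeding), 450 (boundary windows)
and 1000 (characteristics); the acceptance script runs the 400- and
100-replicate experiments in full, while the test suite and the
`--scale` CLI flag run proportionally smaller ensembles (e.g. 100
replicates) with correspondingly widened statistical intervals.

## What the simulator does and does not capture

The model treats each nucleosome as a single three-state unit: no
multivalent marks, no nucleosome turnover or eviction, no explicit
demodification enzymes, no transcriptional output, and no 3D polymer
geometry beyond the designated interaction sites.  Enzyme complexes and
multi-step binding are collapsed into single first-order events, so the
simulated timescales are the fast end of what the biology allows.  Passing
tests therefore certify the stochastic model and its estimators, not
quantitative agreement with any particular locus in vivo.
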