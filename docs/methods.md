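# Methods

## The expansion model

The simulator is a deterministic (optionally stochastic) two-dimensional
stepping-stone model. The arena is a north-up raster of demes; each deme
carries an absolute carrying capacity `K` (individuals) and a friction
`f ∈ [0, 1]`. Both derive from rasters: land-cover classes map to a
relative capacity `k_rel` and a vegetation friction through a
reclassification table, and altitude above 600 m a.s.l. contributes a hard
barrier (friction 1). The two friction sources combine by elementwise
maximum, since a deme either source declares impassable must stay
impassable. Absolute capacity is `K = k_rel · k_max`; `k_max` (default
10 000 individuals/deme) is a free scale because, under deterministic
dynamics, arrival times and front speeds are invariant to jointly scaling
`k_max`, founder counts and the colonisation threshold (asserted as a
test).

Each generation applies, in order:

1. **growth** — clamped logistic `N' = min(K, N(1 + g(1 − N/K)))` or
   Beverton–Holt `N' = N·Rc₀/(1 + N(Rc₀ − 1)/K)`, with
   `g = ln Rc₀`, `Rc₀ = R₀ × survival`;
2. **migration** — each deme emits `E = mN` migrants split over its four
   cardinal neighbours with weight `w_dir (1 − f_target)`, renormalised
   over admissible targets (in-bounds, unmasked, `f < 1`); with no
   admissible neighbour the emigrants stay. The step conserves total
   population exactly (to float round-off deterministically; exactly per
   draw in the integer stochastic mode);
3. **crowding cap** — densities are clipped at `K`.

The cap is this package's density-regulation choice: migration out of a
friction-renormalised neighbourhood can transiently push a saturated deme
a few percent above `K`, and we treat that excess as crowding mortality so
recorded densities always satisfy `0 ≤ N ≤ K`. The cap acts far behind the
front (leading-edge densities are far below `K`), so it does not affect
spread dynamics.

The generation is the time step; `r_day = g/25` is retained for reporting
only. The order growth-then-migration is a convention fixed for
reproducibility.

### Growth forms and the leading edge

The two growth forms share `Rc₀` and the equilibrium `K` but differ at
vanishing density: the clamped logistic linearises to a per-generation
factor `1 + g`, Beverton–Holt to `Rc₀` itself. With the average scenario
(`Rc₀ ≈ 9.61`, `g ≈ 2.26`) the naive unclamped discrete logistic would be
deep in its unstable regime; the clamp keeps it physical, and
Beverton–Holt provides the monotone alternative whose front speed reflects
`Rc₀` directly. Front-speed cross-checks therefore pair each form with its
own edge factor: `λ = Rc₀` (Beverton–Holt) or `λ = 1 + g` (clamped
logistic).

### Linear-determinacy cross-check

On homogeneous terrain the expansion is a pulled wave whose speed is fixed
by the linearised edge dynamics:

    c* = min_{s>0} [ln λ + ln M(s)] / s   (demes/generation)

where `M(s)` is the moment generating function of the single-generation
displacement along the travel direction. On a one-row lattice the off-axis
weights renormalise onto the axis, giving (westward, defaults)
`M(s) = 0.94 + 0.045 e^s + 0.015 e^{−s}`. The minimiser is found by a
brute-force grid on `(0, 60]` refined by bounded scalar minimisation —
a computation entirely independent of the lattice iteration it predicts.
For strong growth the infimum approaches the kernel's reach (1
deme/generation), where the speed saturates; the implementation caps `c*`
there. Simulated speeds (least-squares slope of the maximum front distance
vs generation, after a 20-generation burn-in on a 1×300 lattice run for
320 generations) agree with `c*` to well under 10% for both growth forms.

### Units and defaults

| parameter | default | meaning |
|---|---|---|
| `m` | 0.06 | emigrant fraction per generation (migratory flight morph) |
| `w_W, w_N, w_E, w_S` | 1/2, 1/6, 1/6, 1/6 | directional split, westward-biased |
| survival | 0.177 | field survival correcting laboratory `R₀` |
| `R₀` presets | 19.75 / 54.30 / 158.24 | min / avg / max host-plant scenarios |
| generation time | 25 d | hence 365/25 = 14.6 generations/year |
| altitude threshold | 600 m | hard dispersal barrier above this |
| cell edge | √72 ≈ 8.485 km | deme of ~72 km² |
| `k_max` | 10 000 | individuals/deme at `k_rel = 1` (scale-free) |
| founders / threshold | 100 / 1 | per-origin seed and colonisation threshold |
| generations / snapshots | 30 / every 5 | run length and raster output cadence |

The reclassification table fixes intensive agriculture and the two
agricultural mosaics at `k_rel = 1` (friction 0) and water bodies,
mangroves, flooded forest, barren soil and permanent snow/ice at
`k_rel = 0` (friction 1). Intermediate classes are not dictated by the
habitat-quality rules, so the shipped table applies the documented default
`friction = 1 − k_rel`, with shrub/grass/savanna habitat at 0.5 and dense
humid forest — the habitat least likely to sustain this whitefly — at 0.1.
Users override any of this with their own table file.

An optional rare long-distance-dispersal kernel exists (per-generation
probability of one individual jumping a geometric cardinal distance) but
is off by default: nearest-neighbour migration bounds the front at 1
deme/generation (~124 km/year), and realistic faster spread requires such
jumps, whose parameters we do not attempt to calibrate.

## Sequence divergence

Alignments are handled as integer-coded matrices (FASTA in/out via
Biopython). Trimming cuts to a centred window (1022 nt for mtCOI, 754 nt
for RP-15 by convention) and converts each sequence's terminal gap runs to
missing data; internal gaps stay gaps. All pairwise statistics use
pairwise deletion: only sites where both sequences carry a plain base
count.

**K2P** uses the closed form `d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)`; arguments
at or below zero raise a saturation error, which the matrix builder
records as NaN with an inapplicability flag.

**HKY+Γ** maximises the pairwise likelihood over the branch length `t`:
the HKY85 generator (normalised to one expected substitution per unit
time) is diagonalised through the `π^{1/2}` similarity transform, the
gamma rate mixture uses 4 discrete categories by mean-of-quantile
discretisation (the standard choice; finer categories change distances
negligibly at these divergences), and `t` is optimised by bounded scalar
search (tolerance 1e-8). κ is profiled on a log grid when not supplied;
base frequencies default to the pair's empirical frequencies floored away
from zero. Identical sequences short-circuit to `t = 0`.

Nearest-reference classification returns the minimum-distance reference
label, the distance and the margin to the runner-up; margins within 1e-9
are flagged ambiguous. Percent-divergence reporting rounds `100·d` to one
decimal, the granularity used in mitotype work.

## Synthetic data

The landscape generator emits land-cover and altitude rasters keyed to the
shipped table: corridor rows/columns of intensive agriculture, barrier
rows/columns realised either as a >600 m ridge (altitude raster) or as
water (cover raster), and a background class chosen by nearest `k_rel`
with a seeded fraction of mosaic noise. It shares one code path with
real-map runs by construction.

The sequence generator evolves a star-of-stars topology — root, group
ancestors, tips — under the package's own substitution machinery, with
tip branches `within/2` and group branches `(between − within)/2` so
expected pairwise divergences hit the recipe targets (e.g. the ~0.5–1.9%
within-mitotype mtCOI spread, or two nuclear allele clades 1.5% apart).
Per-site rate categories are drawn once per panel and shared across
branches, matching the among-site-rate-variation assumption the
estimators make. Group ancestors can be emitted as labelled reference
sequences; classification experiments use them as the reference panel,
mirroring how field queries are compared against canonical haplotype
references. A star-of-stars is deliberately not a coalescent: only the
pairwise divergence structure matters to the stages under test, so
conclusions about real panels extend only to that structure (no
recombination, no rate heterogeneity among lineages).

The two-origin simulation fixture is a fixed-seed ~100×100 grid that is
water except for two habitable coastal blobs (radius 15 demes) around the
origins, textured with savanna and an agricultural corridor through each
origin, run for 30 generations under average rates with Beverton–Holt
growth. Blob radii are chosen inside the 30-generation reach of the
front — with a 4-neighbour kernel the front cannot exceed 1
deme/generation (the average-scenario westward speed is ≈0.86, off-axis
≈0.68), so habitable demes farther than ~20 demes from an origin could
never be colonised in 30 generations regardless of parameters. Within
that geometry the merged two-origin run colonises every habitable deme,
and each single-origin run covers exactly its own blob.

## Numerical choices and degenerate inputs

* Esri ASCII parsing is case-insensitive, converts `*llcenter` origins to
  the corner convention, ignores unknown header lines (hand-edited
  exports), and defaults NODATA to −9999; round-trips are exact to 1e-9.
* Migration renormalisation: a deme with no admissible neighbour keeps
  its emigrants; out-of-bounds neighbours are inadmissible (no-flux
  boundary), preserving conservation.
* Origins must lie on unmasked demes with friction < 1; founder counts
  are capped at the local `K`.
* Arrival grids store the first generation density ≥ threshold; demes
  never colonised are masked (NODATA on export).
* Speed fits drop a 2-generation burn-in by default (20 in the long
  homogeneous benchmark runs) to suppress the founder transient.
* Stochastic migration moves `round(mN)` individuals multinomially; it is
  seeded and exactly conservative per draw.

## Problem sizes

Benchmarks and tests run at desk scale by design: 1×300 lattices over a
few hundred generations for speed cross-checks, ~100×100 landscapes over
30 generations for end-to-end runs, 200 replicate pairs at 1022 nt per
divergence level for estimator recovery, and 200 simulated queries for
classifier accuracy. The full test suite and the acceptance script each
complete in seconds.

## Known limitations

* Desk-scale runs use synthetic landscapes; reproducing map-specific
  figures (e.g. arrival generations at named Brazilian cities, or the
  200–500 km/year front measured with long-distance dispersal enabled)
  requires the real GIS layers and a calibrated jump kernel, neither of
  which ships with the package.
* The HKY+Γ distance profiles κ per pair when unset; published distance
  tables computed with a single model-wide κ/α may differ in the third
  decimal.
* Friction semantics are immigration-side only (emigration from
  high-friction demes is unimpeded), matching the attractiveness
  interpretation of friction maps.
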