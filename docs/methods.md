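# Methods

## The model

`gdasim` simulates the origin of high-copy tandem gene amplifications in a
bacterial population under nutrient selection, in the setting of the
*Acinetobacter baylyi* Ben-reversion system: a parent strain whose *cat*
genes are too weakly expressed to permit growth on benzoate, so that
colonies on selective plates arise exclusively through amplification of the
*cat* chromosomal region.

Amplification is modelled as a two-step process:

1. **Duplication formation.** During nonselective growth, each newborn
   haploid cell acquires a tandem duplication spanning the *cat* region
   with probability `k_dup` (default 1e-6 per cell per division).  The
   duplicated unit — the amplicon — is assigned a length drawn log-uniformly
   from 12–290 kb and a `permissive` flag (probability
   `permissive_fraction`) recording whether its endpoints permit selectable
   amplification; one amplicon end is biologically restricted to a small
   region near the *cat* cluster, so not every duplication can amplify
   usefully.

2. **Copy-number steps.** A cell with `n >= 2` tandem copies carries
   `n - 1` repeat junctions.  At each division an unequal
   sister-chromosome exchange occurs with probability `k_rec * (n - 1)`
   (default `k_rec` = 1e-2 per junction per division), producing daughters
   with `n + d` and `n - d` copies, `d` uniform on `1..n-1`.  The same
   event class therefore amplifies (the selected daughter) and collapses
   the array.  In addition, each daughter cell undergoes an
   intrachromosomal deletion (`n -> n - d`) with probability
   `intra_collapse_weight * k_rec * (n - 1)`; with the default weight 0.5
   the total per-division loss rate of the duplicated state is ~`k_rec`,
   which is the convention behind the analytic balance below.
   Deterministically keeping the higher daughter of maximal exchanges
   produces the canonical trajectory 2, 3, 5, 9, 17.

**Selective growth.** On a benzoate plate, growth rate depends on copy
number through a Hill-saturating law

    g(n) = g_max * (n-1)^h / ((n-1)^h + k_half^h)   divisions/day,

with `g(1) = 0` (haploids form the static lawn).  `h = 1` recovers the
simple saturating form `g_max (n-1)/(n-1+k_half)`; the extra shape
parameter is needed because the observed colony-formation delays of 2-, 3-,
8- and 15-copy founders are not consistent with any two-parameter
saturating curve (see Calibration).  A clone becomes a visible colony when
its cumulative size reaches `n_vis` cells (default 1e6, about 20
generations from a single founder).  Non-permissive amplicons confer no
selective growth at all.

**Nonselective fitness.** Extra copies carry a cost
`1 - dup_cost_per_copy * (n-1) * L/28` (floored at 0), normalized to a
28 kb amplicon.  The default cost is 0: the default steady state is the
pure formation/collapse balance, matching the analytic constants below; a
nonzero cost is a supported configuration.

**Analytic balance.** With formation `k_dup` and effective loss
`k_loss = k_rec` (collapse weight 1) the duplication frequency balances at

    f* = k_dup / (k_loss + cost) = 1e-6 / 1e-2 = 1e-4  (0.01%),

i.e. ~50,000 duplication-bearing cells among the 5e8 cells spread on one
plate.  Important caveat, stated here because it shapes several tests: the
relaxation time towards f* is `1/k_loss` = 100 generations, so a simulated
overnight culture (~29 generations from a single colony cell) is still in
the transient regime; its expected frequency is
`f* (1 - (1-k_loss)^t) ≈ k_dup * t ≈ 3e-5`, and the replicate-culture
*mean* is dominated by rare early-event jackpots.  The steady-state
recovery test therefore runs at fast-relaxing parameter settings (where
`log2(final size) * k_loss >> 1`), and the default-rate culture is checked
against the deterministic transient expectation instead.

## Simulators

**Culture (`simulate_culture`).** Discrete non-overlapping generations from
one haploid founder to saturation (default 5e8 cells, one plate load —
plating samples class frequencies, so the culture need not be larger than
the aliquot).  The haploid bulk is advanced deterministically; every
duplication event founds an explicitly tracked lineage with its own
amplicon.  Lineage classes below `stochastic_threshold` (1e4) cells are
advanced by exact integer sampling (binomial divisions, exchanges,
collapses, per-event uniform offsets); larger classes deterministically in
expectation.  This hybrid keeps 5e8-cell cultures tractable while
preserving the between-culture Luria-Delbrück structure, which lives
entirely in the stochastic early phase.

**Plate (`simulate_plate` / `CloneBatch`).** Every permissive
duplication-bearing cell in the inoculum founds an independent clone,
advanced in sub-day steps (`dt_days` = 0.05): per step each class divides
with probability `2^(g(n) dt) - 1`, exchanges and intra-collapses as above.
The same hybrid integer/expectation scheme applies per (clone, class)
entry; in addition, when more than 64 exchange or collapse events hit one
entry in one step, their uniform offsets are spread deterministically
rather than sampled per event (at that multiplicity the sampled and
averaged updates are statistically indistinguishable, and the per-event
path dominates runtime).  The early, fate-deciding phase of every clone —
a single founder cell waiting for its first amplification steps — is
always exactly stochastic.  Copy numbers are capped at `max_copy_number`
(64); growth has saturated far below the cap, so the clip only affects
bookkeeping of extreme jumps.

The lawn follows the measured deterministic trajectory: 5e8 cells at
plating, 10-fold geometric decline to day 12, geometric recovery to the
starting size by day 21, constant thereafter.  Under the default
(pre-existence) model the lawn produces no new duplications; setting
`plate_induction_rate > 0` enables the explicit "adaptive" contrast model
in which duplications are induced on the plate at a constant per-cell
per-day rate — used only as a negative-control model, never silently.

**Experiment harnesses.** `run_fluctuation_experiment` composes
culture -> aliquot -> plate into a plates-by-days count table (parallel
design: many cultures, one plate each; single-culture design: one culture,
many plates).  `run_reconstruction` seeds a known number (default 300) of
mutant cells of a given copy number (28 kb permissive amplicon) into a
full parental lawn; one parental culture feeds all plates of a trial (as
on the bench), and the parent-only background plate's counts are
subtracted day by day (negative differences clamp to 0; per-plate percent
curves are made non-decreasing by running maximum).  `run_replica_plating`
models each master microcolony's precursor content as a Luria-Delbrück
draw (duplications arising during ~23 generations of colony growth,
thinned by collapse and the permissive fraction), prints diminishing
fractions (0.25, halving per successive replica — prints get more
diffuse), and requires a transferred precursor cell to reach visibility
within the observation window (cached Monte-Carlo estimate of that
probability); the induction contrast assigns each plate position an
independent hit at the matched marginal rate, so same-position triples
collapse to the coincidence rate.

## Calibration

Four parameters are not printed anywhere and are fixed by
`scripts/calibrate.py` against the system's observed dynamics:

| parameter | value | pinned by |
|---|---|---|
| `g_max` | 16 /day | wild-type-like colony formation in 1–3 days |
| `k_half` | 25 | reconstruction delays (with `hill`) |
| `hill` | 1.3 | reconstruction delays (with `k_half`) |
| `permissive_fraction` | 0.5 | day-19 revertant frequency ~1e-7 |

The delay targets are: most 15-copy founders visible by day 4, 8-copy not
before day 5, 3-copy not before day 17, 2-copy not before day 27, and no
colonies at all on days 1–2.  With the chosen values the simulated medians
are ~4, ~6, ~20 and ~45–49 days respectively, and the reversion assay gives
frequencies of ~5e-9 / ~2.7e-8 / ~1e-7 at days 9 / 14 / 19 with first
colonies appearing from about day 6.  The permissive fraction is higher
than a literal endpoint-geometry argument would suggest because the
simulated transient culture carries fewer precursors than the measured
0.01%; the observable that pins it is the product (precursor frequency x
permissive fraction x per-precursor visibility).

## What the synthetic generators emulate — and what they do not

`gen_poisson_plates` and `gen_ld_plates` exist to exercise the statistics
suite against known distributional structure: i.i.d. Poisson counts
(within-culture, post-plating sampling noise) versus the heavy-tailed
jackpot distribution of a classic doubling-population,
binomial-new-mutants, no-loss lineage model.  The LD generator is
deliberately simpler than the mechanistic simulator — no collapse, no
fitness cost, no copy-number structure — because it is a test instrument
for statistics, not biology.  Consequently, tests that pass on these
generators certify the statistics, not the simulator; the simulator's own
distributional signatures are tested separately through the harnesses.
Neither generator (nor the mechanistic pipeline) models plate-to-plate
procedural variation, cell death in liquid culture, or plate drying, and
simulated day-10 parallel-culture means can exceed the fixture's because
jackpot cultures are included, not trimmed.

## Statistics

All statistics are computed from their defining formulas: sample
mean/variance/median; cumulative points `(x, P(X >= x))` for `x >= 1` with
positive proportion and their OLS slope in log10-log10 coordinates (no
binning — only observed x values enter); the exact Poisson tail; the
Brown-Forsythe test (median-centred absolute deviations, one-way F on
`F(p-1, N-p)`, with a label-permutation alternative, >= 1e4 permutations
recommended); Spearman rho (Pearson correlation of mid-ranks, two-sided
t-approximation p on n-2 df) and Kendall tau-b (tie-corrected, normal
approximation p).  scipy supplies only the reference distributions for
p-values; scipy's own implementations serve as independent oracles in the
test suite.  "Jackpot" has no printed numeric definition; the implemented
rule flags counts exceeding `median + 5 * max(1, IQR)` and is
configurable.  Fluctuation statistics always operate on cumulative counts
at an explicit day (day 10 for the embedded fixture).

## Numerical choices and degenerate inputs

- Day indexing is 1-based everywhere; appearance days are the ceiling of
  the continuous crossing time and never below 1.  Plate files store
  cumulative counts.
- Seed handling: every public entry point takes a seed (or Generator); the
  replicate harnesses spawn independent child streams via `SeedSequence`,
  so runs are reproducible bit for bit and recorded in run manifests.
- One-observation variance is undefined and returned as NaN; empty inputs
  raise.  A Brown-Forsythe with identical deviation patterns returns
  (0, 1); zero within-group spread with nonzero between-group spread
  returns (inf, 0).  All-zero count vectors have no cumulative points and
  no slope.  `variance_ratio` refuses a zero within-variance.
- The copy-number kernel caps probabilities at 1 and clips jumps at the
  tracked maximum; daughters always sum to `2n` before clipping.

## Known limitations

- The growth law is a phenomenological interpolation of four ordinal delay
  observations; only its ordering and rough scale are data-driven.
- Amplicon length affects nothing on the selective plate by default (the
  observed length/appearance-day correlation is weak and of no practical
  significance); it matters only through the optional nonselective cost
  and the digestion patterns.
- The replica-plating harness scores positions, not plate geometry; a
  "triple" is positional identity across the three replicas, and
  within-position colony counts are not resolved.
- The in-silico digestion model reports ideal fragment sizes and
  intensities (flank junction fragments ignored; `copies - 1` internal
  repeats); gel migration, smearing and detection thresholds are out of
  scope.
- Cultures are modelled from a single founder cell; any duplication
  structure inherited from the colony that seeded the culture is ignored,
  which understates between-culture fluctuation somewhat.
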