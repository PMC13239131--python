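# Methods

## Model

`floodsim` is a forward-time, individual-based model of a single diploid
autosomal locus with four alleles in a density-regulated population.
Residents are founded carrying W1/W2 at Hardy–Weinberg proportions
(`resident_W2_freq`, default 0.5); migrants carry L1/L2
(`migrant_L2_freq`, default 0.5). L2 is a recessive deleterious allele:
all penalties attach to the L2/L2 homozygote.

One generation applies five events in a fixed order:

1. **Migration pulse.** `round(m·K)` migrants join the population
   (`pulse_basis="capacity"`, the default). With pulses proportional to the
   carrying capacity, migrants make up an expected fraction `m/(1+m)` of a
   population standing at K. The alternative `pulse_basis="current"` scales
   the pulse to the standing population size instead; it is exposed because
   whether release schedules should track capacity or census size is a real
   design question for release programs, but the fixed-size pulse is the
   default since a constant release schedule is the natural reading of a
   fixed per-generation migration fraction.
2. **Viability survival.** Every individual survives independently with
   probability `base_survival × survival_mult_L2L2^[genotype is L2/L2]`.
   Survivors age by one generation. Adults persisting this way is the whole
   content of "overlapping generations" here: there are no age-specific
   fecundity schedules.
3. **Breeding-pool formation.** Each survivor enters independently with
   probability `(1 − mating_penalty)` if it was itself introduced (the
   penalty is never inherited) times `repro_mult_L2L2` if it is L2/L2.
   The latter multiplier is the model's "reduced reproductive success" of
   L2/L2 individuals, distinct from both the survival and the pair-fecundity
   penalties.
4. **Reproduction.** `multiple_paternity_factor` rounds; in each round every
   pooled female is paired with one pooled male drawn uniformly with
   replacement (males can sire several litters; females redraw mates each
   round, which is how multiple paternity enters). Each pairing produces a
   Poisson litter with mean `mean_litter / rounds × f(pair)`, where `f` is
   1, `fecundity_mult_one_homo` (0.7) or `fecundity_mult_both_homo` (0.2)
   according to how many parents are L2/L2. Dividing the per-round mean by
   the round count makes expected per-female fecundity invariant to mating
   structure, so the paternity factor isolates the effect of paternal
   diversity rather than inflating reproduction. Offspring inherit one
   allele from each parent uniformly (Mendelian segregation) and join the
   surviving adults.
5. **Density regulation.** If the population exceeds K, exactly K
   individuals are retained uniformly at random — blind to genotype, sex,
   age and origin, hence frequency-neutral in expectation.

**Collapse** is defined as both W1 and W2 absent from the final census.
Because W alleles have no re-entry route, loss is absorbing and this
coincides with "both lost at any generation"; the first such generation is
recorded. An emptied population (possible only without migration, or at
tiny K) keeps emitting zero censuses to the horizon; its W counts are zero,
so it counts as collapsed, and a separate `extinct` flag plus the sweep's
`n_extinct` column keep collapse-by-replacement and collapse-by-extinction
distinguishable.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `K` | 1000 | carrying capacity (individuals) |
| `m` | grid 0.05–0.40 | migration fraction per generation |
| `generations` | 100 | simulation horizon |
| `base_survival` | 0.5 | per-generation adult survival |
| `survival_mult_L2L2` | 0.5 | L2/L2 survival multiplier |
| `repro_mult_L2L2` | 0.5 | L2/L2 breeding-entry multiplier |
| `fecundity_mult_one_homo` | 0.7 | one L2/L2 parent |
| `fecundity_mult_both_homo` | 0.2 | both parents L2/L2 |
| `mean_litter` | 2.0 | mean offspring per pairing per generation |
| `mating_penalty` | grid {0, 0.25, 0.5, 0.75} | introduced-individual entry reduction |
| `multiple_paternity_factor` | grid {1, 2, 3} | mating rounds |
| `migrant_L2_freq` | 0.5 | L2 frequency among migrant gametes |
| `resident_W2_freq` | 0.5 | W2 frequency among founder gametes |

With `base_survival = 0.5` and `mean_litter = 2.0` the expected growth
factor of a closed population is exactly 1 (half the adults survive; a
quarter of the population are breeding females contributing two offspring
each), so demography is maintained by the capacity ceiling rather than by
intrinsic growth. This makes the population a near-critical branching
process below K: at realistic K (hundreds and up) sizes stay near K on the
100-generation horizon, while very small toy populations (K of order tens)
can drift to extinction — which is why the "no migration means zero collapse
probability" identity should be read at realistic K.

The survival (0.5) and pair-fecundity (0.7/0.2) multipliers are fixed model
constants of the penalty scheme; `repro_mult_L2L2 = 0.5` and the founder and
migrant gamete frequencies of 0.5 are documented defaults for quantities the
penalty scheme leaves open, all exposed as parameters.

## Sweep and seeding

The default design crosses 15 migration fractions (0.05–0.40, step 0.025),
4 mating penalties and 3 paternity factors, with 50 replicates per cell.
Every replicate's RNG is a `numpy` PCG64 generator seeded from a
`SeedSequence` over `(base_seed, round(m·1e6), round(penalty·1e6),
paternity, replicate_index)`. Keying on parameter *values* rather than grid
indices means enlarging, reordering or re-slicing the grid never changes an
existing cell, and serial and concurrent evaluation are identical.

## Threshold estimation

Per (penalty, paternity) condition the collapse probabilities as a function
of m form a dose–response curve. The critical migration fraction `m_c` is
the 0.5-crossing of a two-parameter logistic fitted by binomial maximum
likelihood to the per-cell `(n_collapsed, n_reps)` tallies — the standard
dose–response convention. Numerical details:

- the optimizer works in `(m_c, log slope)` with `m_c` bounded to the fitted
  m range and the slope capped at 2000; fits are restarted from three slope
  initializations and the best likelihood kept;
- a slope at the cap, an optimizer failure, or a boundary `m_c` is treated
  as "no interior optimum" (the typical cause is a perfectly separated 0/1
  curve, where the MLE diverges) and the estimator falls back to linear
  interpolation of the first 0.5-crossing — for a clean 0-to-1 step this is
  the midpoint of the bracketing interval; the reported slope is then the
  logistic slope matching the local secant;
- a curve that never crosses 0.5 within the fitted range raises a
  "no threshold in range" error rather than extrapolating;
- fitting is restricted to `m ≤ m_max_fit` (default 0.30) so that any
  non-monotone high-m behavior cannot distort the logistic fit;
- confidence intervals are percentile bootstrap (default 1000 resamples) on
  per-replicate collapse indicators within each cell, i.e. binomial
  resampling of each cell's tally; resamples whose curve does not cross 0.5
  are dropped.

The condition-level estimates are summarized by their sample mean and
sample standard deviation (SD of a single estimate is reported as 0). The
"±" on the reported cluster is interpreted as this across-condition SD;
that interpretation is recorded in `summary.json`.

**Regime detection.** A point at `m` above the estimated `m_c` is flagged
as *migrant failure to establish* when its collapse probability falls below
the maximum attained at any smaller m by more than twice the pooled
binomial standard error. Comparing against the running (not global) maximum
keeps rising-limb points of a monotone curve from being flagged. Unflagged
points are labelled *resident persistence* below `m_c` and *resident
collapse* above it. Note the 2×SE rule is a per-comparison test with a
~2.5% false-positive rate; on a 180-cell sweep occasional noise flags are
expected.

## Mean-field oracle

The oracle iterates expected genotype masses (4×4 symmetric matrices over
ordered allele pairs, in units of K) through the same five events,
split into a native and an introduced compartment so the mating penalty
applies exactly to pulse-derived individuals. The mating step collapses the
pairing machinery to expected pair-class weights: pooled females (half the
pool mass) each contribute `mean_litter × f(pair)` expected offspring with
pair classes weighted by the pooled genotype distribution, split into
L2/L2 and non-L2/L2 parental classes (fecundity depends only on that
dichotomy). Offspring add to surviving adult masses; masses above 1 are
rescaled (the cull is frequency-neutral). The reduction to expectations is
exact for means, not higher moments — the oracle validates the engine, it
does not generate results. With viability selection only, the recursion
reproduces the textbook one-locus formula `p' = p(p·w + q)/(1 − p²(1 − w))`
to machine precision, and the replicate-mean resident-allele frequency of
the stochastic engine at K = 20 000 tracks it within 0.004 (budget 0.03)
over 50 generations at m = 0.1.

## What the simulations do and do not show

All inputs are synthetic: the generator *is* the study system, emulating a
managed release program into an idealized closed population. Real systems
have age structure, spatial structure, environmental stochasticity,
multi-locus genetics and linkage — none of which are modeled, so passing
tests demonstrate internal consistency of this single-locus caricature, not
quantitative predictions for any actual species.

Two model-level findings from the default conditions deserve emphasis:

- The collapse threshold scales approximately as `m_c(0)/(1 − penalty)`,
  because a per-generation entry penalty multiplies a migrant's lifetime
  breeding opportunities by `(1 − penalty)` and therefore scales effective
  gene flow by the same factor. A penalty of 0.75 consequently shifts the
  threshold by roughly 4×, from ≈0.087 to ≈0.27 — a strong, not modest,
  displacement — which spreads the per-condition thresholds (SD ≈ 0.07)
  more than a narrow cluster.
- Under this penalty scheme the mean response is monotone in m everywhere
  probed (penalties to 0.75, fully inbred migrants, m to 0.9): because L2
  is recessive and most migrant-derived genotypes in a mixed population are
  unpenalized heterozygotes, dilution always outpaces the selection uplift
  on residents, and no deterministic high-migration persistence regime
  emerges. The regime detector is therefore exercised on synthetic curves
  in the tests, and on real sweeps it reports whatever the 2×SE rule finds.

## Numerical and testing choices

- The engine stores the population as flat numpy arrays (allele codes,
  sex, introduced flag, age), so a 100-generation replicate at K = 1000
  costs ~30 ms; the full default design (~9000 replicates) runs in about
  6 minutes on one CPU. Acceptance-style tests run the same design at 20
  replicates per cell (~2.5 minutes), a scale at which every checked
  aggregate is well inside its Monte-Carlo tolerance.
- Expected counts are always realized by integer sampling (Bernoulli,
  Poisson, uniform culling), never by rounding expectations — except the
  migrant pulse size `round(m·K)`, which is deterministic by design.
- Statistical tests use 3-standard-error bands (binomial, hypergeometric or
  Poisson as appropriate) or chi-square at α = 0.001; property tests are
  seeded/derandomized.
- The logistic fit is cross-checked in the test suite against an
  independent binomial GLM (statsmodels) on non-separated curves, and the
  whole estimator against synthetic curves with known thresholds
  (recovery within 0.015 of truth in >95% of 200 curves at n = 50).

## Known limitations

- Single locus, no linkage, no spatial or age structure, no environmental
  stochasticity; sex ratio fixed at 1:1 in expectation.
- The breeding-entry penalty compounds over an introduced individual's
  lifetime; release programs whose handicap applies only on arrival would
  need a different penalty scope.
- The mean-field oracle treats the introduced compartment's penalty exactly
  but collapses all higher moments; it is not valid for small-K behavior
  such as extinction.
- Bootstrap CIs condition on the fitted grid; they do not propagate
  grid-resolution uncertainty in `m_c`.
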