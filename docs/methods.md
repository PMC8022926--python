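# Methods

This note records the models implemented in `breedsim`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
data used by the test suite does and does not establish.

## Founder haplotypes

Founders are simulated per chromosome under a neutral, constant-size
Markovian coalescent with recombination.  Time is measured in units of 2Ne
generations.  The first local genealogy is a standard coalescent tree; the
genealogy then changes along the sequence at recombination breakpoints
(exponential distance with rate = total branch length × 2Ne × r per bp).
At a breakpoint a point is drawn uniformly on the branches, the lineage
above it is detached, and it re-coalesces with the pruned tree at pairwise
rate 1; the detached edge itself remains a candidate, in which case the
tree is unchanged (the "invisible" transition of the SMC' family).  This is
an approximation to the full ancestral recombination graph: long-range LD
is slightly underestimated relative to the exact coalescent, which is
irrelevant for breeding-program founders but worth knowing for
population-genetic inference uses.

Mutations are Poisson on total branch length (rate 2Ne·μ per bp) within
each non-recombining segment, each creating one biallelic site carried by
the leaves under its branch.  If more segregating sites arise than
requested, a uniform random subsample (order preserved) is kept; too few is
an error naming the shortfall.  Map positions of retained sites are
physical position × r; the chromosome map length is r × bp, and the
centromere defaults to the midpoint (both choices are conventions, not
biology; import paths can override them).

Defaults — Ne = 100, bp = 1e8, μ = 2.5e-8, r = 1e-8 per base per
generation — describe a generic livestock/crop-like population with
1-Morgan chromosomes and enough diversity that 50 inbred founders carry
well over 1000 segregating sites per chromosome.  They are the single
generic preset shipped; no species-specific presets are reproduced.

`quick_haplo` instead draws alleles i.i.d. at frequency 0.5 on an
equally-spaced 1-Morgan map — founders with maximal diversity and **no
LD**.  Tests built on it exercise the machinery but do not probe
LD-sensitive behavior; the coalescent path covers that (LD decay with map
distance is itself a test).

## Meiosis

Chiasmata on the four-strand bundle form a **stationary gamma renewal
process** with shape ν and rate 2ν per Morgan.  Stationarity is obtained by
drawing the first event as U·T with T from the length-biased interarrival
distribution Gamma(ν+1, rate 2ν) — the forward recurrence time — so the
crossover density is position-homogeneous.  Each chiasma involves a given
chromatid with probability ½ independently (no chromatid interference),
giving a crossover rate of 1 per Morgan; at ν = 1 crossover counts on an
L-Morgan chromosome are Poisson(L).  No obligate chiasma is enforced: the
zero-crossover probability per gamete at ν = 1 is e^(−L).  The default
ν = 2.6 is in the range commonly fitted to experimental crossover data in
plants and mammals; ν = 1 turns interference off for the closed-form checks
(Haldane's map function, Poisson dispersion).

A crossover at map position q switches all loci with position ≥ q
(half-open convention; ties are measure-zero).  Gametes carry a tract
record (source haplotype, start, end) that reconstructs the allele vector
exactly and exports as BED-like text.

**Autotetraploids.**  Each homologue group pairs as a cross-type
quadrivalent with probability `p_quad`, else as two random bivalents.  The
quadrivalent has a single exchange point uniform on the map: left of it the
pairing arms are (A,B) and (C,D), right of it (A,C) and (B,D), with the
four homologues randomly assigned.  Chiasmata are drawn per arm from the
same stationary gamma process.  Two centromeres are sampled without
replacement; each gamete chromatid is resolved from its centromere outward,
switching to the pairing partner at each chiasma of its current arm with
probability ½.  This yields chromatids combining up to three parental
chromosomes, and double reduction at loci separated from the centromere by
a crossover — zero at the centromere and rising with distance, both tested.
`p_quad` defaults to 0 (bivalent-only), since quadrivalent frequency is
species-specific; ploidies above 4 are out of scope.

## ADEG traits

Genetic values use centered additive coding (x − p/2), so the intercept is
the value of the "midpoint" genotype and rescaling effects never moves the
founder mean through the additive term.  Digenic dominance is h(x) =
x(p − x): for diploids the heterozygote indicator, for tetraploids the
count of heterozygous pairs among the six chromosome pairs — symmetric,
h(0) = h(p) = 0; any constant offset is absorbed by the intercept at
scaling.  Epistasis is additive-by-additive on the product of centered
dosages of randomly formed **disjoint** QTL pairs (an odd QTL leaves one
locus without an epistatic term, logged).  GxE effects are additive slopes
multiplied by one environmental covariate w ~ N(0, var_w) drawn per
phenotyping event and shared across replicates of that event (replicates
model locations within one evaluation; a fresh w per rep would conflate
GxE with residual error).

Raw effects come from a standard normal, or gamma(shape) magnitudes with
random signs for additive effects; dominance effects are dᵢ = δᵢ|aᵢ| with
dominance degree δᵢ ~ N(mean_dd, var_dd).  Because every term of the
genetic value is linear in its effect vector, multiplying all effects by
c = sqrt(target/observed variance) scales the founder variance exactly, and
setting the intercept afterwards fixes the mean exactly; the operation is
idempotent to floating point.  "Observed" is either the total genetic
variance or the additive component from the decomposition below.
Correlated traits are pleiotropic, same-type, built by applying the
Cholesky factor of the correlation matrix to i.i.d. normal draws before
scaling; gamma draws are not supported for correlated traits.

## Variance decomposition

For each QTL the average effect α is the least-squares slope of the
locus's own genotypic value (its additive + dominance terms) on dosage
under the **observed** genotype frequencies.  Breeding values are
Σ α(x − x̄); V_A is their population variance, so between-locus dosage
covariances (LD) enter automatically.  The partition

    V_A = Σ p·p_l·q_l·α² (genic) + Σ (var(x_l) − p·p_l·q_l)α² (HWE departure)
          + [V_A − Σ var(x_l)α²] (LD)

is an exact identity by construction and is asserted at machine precision.
Dominance deviations are the per-locus regression residuals; for epistatic
pairs, the pair term is regressed on the two dosages, the linear parts are
credited to the average effects (as average-effect theory prescribes) and
the residual variance is V_AA — any epistasis-by-LD covariance is folded
into V_AA.  All variances are population variances (divide by n).  GxE
terms are excluded from genetic values (w at its mean, 0).  A monomorphic
trait returns all-zero components rather than an error.

## Phenotyping, selection, mating

Phenotype = gv + GxE + ε with ε ~ N(0, var_e/reps).  An H² given to
`set_var_e` is converted against the **founder** total genetic variance
(var_e = V_G(1−H²)/H²) and stored, so later, selected populations keep the
same error variance — their realized heritability properly drifts as
genetic variance erodes.  An H² passed to a single `set_pheno` call applies
to that event only (modeling, e.g., low-accuracy visual selection) without
overwriting the stored value.

Selection (whole-population, within-family, or via a user hook) is stable:
ties break by original population order, and selected cohorts keep that
order.  Families smaller than the within-family quota are returned whole
with a log line.  Random crossing draws each pair uniformly (father
distinct from mother within a pair; parents may repeat across crosses) and
founds one family per cross.  Doubled haploids (diploids only) duplicate
one meiotic gamete; selfing, cloning, open pollination with a selfing rate,
and explicit mating plans round out the operators.  All operators draw from
a passed RNG or the SimParams stream, making runs reproducible by seed.

## RR-BLUP

y = 1b + Zu with Z the column-centered marker dosage matrix and
u ~ iid N(0, σ²_u).  The ratio λ = σ²_e/σ²_u maximizes the restricted
likelihood on the spectrum of the intercept-projected ZZ' (bounded search
on log λ in [−18, 18], tolerance 1e-8; the projected null direction along
1 is removed).  At the optimum, u = Z'(ZZ'+λI)⁻¹(y−1b) — identical to the
mixed-model-equation solution (Z'Z+λI)⁻¹Z'(y−1b), which the tests assert
at fixed λ.  The reported model heritability is σ²_u·tr(ZZ')/n over itself
plus σ²_e.  Fixed effects are limited to the intercept; marker sets default
to random genome-wide subsets excluding QTL ("SNP chip").  Multi-kernel
and Bayesian models are out of scope — the export/import hooks exist
precisely so external predictors can be swapped in.

## Scenario runner

Scenarios are declarative YAML/JSON (founder, sim, stages) rather than an
embedded language: the Python API remains the full-power interface, and a
declarative stage list is schema-checkable before any execution.  Each
stage draws from a named substream seeded by (run seed, stage label,
occurrence), so inserting a stage does not perturb the draws of other
stages.  Runs are bit-identical given (config, seed).  The runner emits a
long-format per-stage genetic-value table (the data behind the per-stage
boxplot) and a structured run log; plotting itself is left to the user.

## Problem sizes used in the checks

The bundled wheat-example config runs at full scale (50 coalescent inbred
founders × 21 chromosomes × 1000 sites, 20,000 DH lines; ~45 s on one
core).  The recurrent-selection benchmark config keeps the full population
flow (1000 parents, 10,000 progeny, 100 generations = 1,001,000
individuals; ~30 s) on a deliberately reduced genome, since the
individual-count bookkeeping it checks is genome-independent.  Statistical
checks use 10⁴–10⁵ meioses and founder cohorts of 10³–10⁴ with
Monte-Carlo tolerances stated per test (typically 3–4 standard errors).

## Known limitations

- SMC'-style founder LD is approximate at long range; demographic
  histories beyond constant Ne are not modeled.
- No mutation or gene conversion during forward simulation (pure gene
  drop).
- Dominance-related covariance components under inbreeding (D1, D2 style
  terms) are not separated; epistasis-by-LD covariance sits inside V_AA.
- Sexes are optional and minimal (opposite-sex crossing when recorded);
  no age-structured overlapping generations.
- Higher even ploidies (6, 8) and sex chromosomes are unsupported.
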