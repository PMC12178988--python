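# Methods

This note documents the models, conventions and design choices behind
`ucross`, in the order a user meets them: the genetic model, the
analytical progeny variance, the usefulness criterion and its scaling,
the stochastic simulator, the breeding-program scenarios, the
synthetic-data generator, heritability estimation, and numerical
details.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Genetic model

Genomes are diploid with L biallelic markers on a genetic map (cM).
Alleles are coded 0 (the allele of the common parent shared by all
populations) and 1 (the alternative parent's allele).  Every allele
copy carries an immutable **origin label** naming the biparental
population it descends from; meiosis copies allele and label together.

The genotypic value of individual *i* for trait *m* is additive and
origin-aware:

    u_im = sum over both haplotypes and loci of
           beta[origin(l)][m][l] * allele(l),

with `beta[p][m][l]` the effect of one alternative-allele copy of
population-*p* origin.  The baseline (0) allele contributes nothing,
which is what makes effects estimated separately per population
commensurable: each population's effects are deviations from the same
common-parent genome.  Dominance is excluded by design — the programs
end in essentially fixed (inbred) material, where dominance cannot
contribute to gain.

The selection index of an individual is the sum over traits of
genotypic values standardized by per-trait mean and standard deviation
of the **pooled initial (F4) generation**.  Which reference set to
standardize by is a genuinely open choice; pooling both F4 populations
uses a single, fixed scale for the whole program and is consistent with
the scaling used inside the usefulness criterion.  Selection always
acts on genotypic values (heritability 1 at the selection step).

## Progeny-variance decomposition

For a cross between parents P1 (haplotypes 1, 2) and P2 (haplotypes
3, 4), define for each parental haplotype *a* the effect-weighted
vector

    v_a[l] = allele_a[l] * beta[origin_a(l)][m][l].

The genetic variance among progeny at reference generation *g* is

    sigma^2 = sum over the six unordered haplotype pairs (a, b) of
              (v_a - v_b)' D^(ab) (v_a - v_b),

with D^(12) = D^(34) = D_w (within-parent) and
D^(13) = D^(14) = D^(23) = D^(24) = D_b (between-parent).  The D
matrices depend only on the map and *g*, never on the parents, so they
are built once per reference generation and shared by all candidate
crosses; ranking 10^5 pairs costs two matrix products plus O(1) work
per pair.

**Generation convention.**  g = 1 is the F1 of the cross (0 selfings);
each increment is one selfing generation (single-seed descent).  A
program generation G_t reached t steps after a cross therefore
corresponds to g = t.

**Closed forms.**  Let C1 be the matrix of single-meiosis recombination
fractions (Haldane transform of cM distances within chromosomes, 0.5
across chromosomes, 0 diagonal) and

    C^g = 2 C1 (1 - 0.5^g (1 - 2 C1)^g) / (1 + 2 C1)

the accumulated recombination matrix (C^1 = C1).  The package uses

    D_w(g) = 0.25 (1 - 2 C^g)
    D_b(g) = 0.25 (1 - 2 C^g - 2 (0.5 (1 - 2 C1))^g)

elementwise.  These are exact, and derived as follows.  Track one locus
pair (recombination fraction c) through selfing.  For haplotype-origin
pair (a, b) let h_g(a,b) be the probability that one homolog of a
generation-g individual carries origin *a* at the first locus and *b*
at the second, and k_g(a,b) the cross-homolog analogue.  One selfing
gives the linear recursion

    h_{g+1} = (1 - c) h_g + c k_g          (gamete formation)
    k_{g+1} = (h_g + k_g) / 2              (two independent gametes)

with eigenvalues 1 and (0.5 - c).  Writing the variance in terms of the
origin-count covariances Cov(n_a(l), n_b(l')) = 2h + 2k - 1/4 and
matching coefficients against the six-component quadratic form yields
D_w = -Cov(n_1, n_2) and D_b = -Cov(n_1, n_3); solving the recursion
from the F1 initial condition gives the closed forms above.  Checks:

* g = 1: D_w has diagonal 0.25 and off-diagonal 0.25(1 - 2c); D_b is
  identically **zero** — the four between-parent components vanish, as
  they must (an F1 of two inbreds is uniform).  No special-casing is
  needed; the closed form evaluates to zero.
* g -> infinity: both tend to the classic recombinant-inbred-line limit
  0.25 (1 - 2c) / (1 + 2c).
* Unlinked loci (c = 0.5): both are zero at every g.

Two independent validations are part of the test suite: an exact
256-state transfer-matrix computation of the two-locus origin chain
(`tests/_oracles.py`), agreeing to machine precision for g = 1..6 over
a grid of c; and a Monte-Carlo oracle (`ucross.uc.mc_oracle`) that
simulates 10^5 progeny through the meiosis engine — a fully separate
code path — agreeing within 3 SE for g = 1..5.

A widely used published form of the within-parent matrix,
0.25 (1 - C^g)(1 - 2 C1), equals D_w one generation later — the
algebraic identity (1 - C^g)(1 - 2 C1) = 1 - 2 C^{g+1} — i.e. it is
exact when its exponent counts *selfings* rather than
generations-after-cross.  The closed forms above are stated directly in
the F1-based convention to avoid that off-by-one trap; the oracle tests
pin the convention down.

**Cross mean.**  mu_k is the mid-parent genotypic value.  Under the
additive model this is the exact expected progeny value at every
generation (allele transmission is unbiased), so no progeny simulation
is needed for the mean either.

## Usefulness criterion and ranking

    UC_km = mu~_km + i * sqrt(sigma~^2_km),

where mu~ is the mid-parent value standardized by the pooled-F4 mean
and standard deviation of the trait and sigma~^2 = sigma^2 / sd^2 is
scaled by the standard deviation only (a variance divides by sd^2; the
mean offset cancels in differences).  The default selection intensity
i = 1.96 corresponds to keeping roughly the top 5% and reflects a
small program's realistic selected fraction; the ranking is insensitive
to moderate changes in *i* because the mean term usually dominates (a
property test checks top-10 overlap between i = 1.64 and i = 1.96).

Crosses are ranked by the summed UC over traits.  Ties break
lexicographically on (-index, parent1 id, parent2 id) so rankings are
reproducible across runs and platforms.

## Stochastic genome simulator

Meiosis follows the Haldane model (no crossover interference): along
each chromosome the transmitted haplotype is a Markov chain whose
switch probability between adjacent markers is the Haldane transform of
their cM distance; chromosomes assort independently.  This is exactly
the recombination model underlying the C^g algebra, so the analytical
and simulated halves of the package agree by construction, not by
calibration.  Crossing takes one gamete from each parent; single-seed
descent replaces each individual by one selfed offspring per
generation, conserving population size.

## Breeding-program scenarios

Both scenarios start from two F4 populations (300 each by default,
pooled where selection requires one pool), run 15 generations after the
first cross and maintain 36 x 25 = 10 x 90 = 900 individuals.

* **Scenario 1** (individual-based): first round selects the top 5 of
  population 1 and top 4 of population 2 by index; the 9 parents are
  crossed in all 36 non-self combinations, 25 progeny each.  At G_t the
  top 9 of all 900 are selected with no per-population quota (the
  populations are mixed by then) and crossed the same way.
* **Scenario 2** (cross-pair-based): first round ranks all non-self
  pairs among the pooled 600 F4 individuals by summed UC — 
  intra-population pairs are eligible and sometimes chosen — and takes
  the top 10, 90 progeny each.  At G_t, to bound the candidate count,
  the 450 individuals with the highest index are shortlisted and all
  their pairs ranked.  The variance term uses g = t (reference G_t) or
  g = 15 (reference G_15) at the first round, and always the final
  generation (g = 15 - t) at the second round.

Two readings of the design were genuinely open and are both exposed:

* "10 cross pairs including nine individuals": the link between 10
  pairs and 9 distinct parents is not operationalizable uniquely.  The
  default is the unconstrained top 10 pairs; `max_distinct_parents`
  applies a greedy distinct-parent cap for users who read it as a hard
  constraint.
* Under the G_15 reference the second crossing round is skipped by
  default (the first-round UC already targets the final generation);
  `second_cross_when_g15=True` restores it.  Neither behaviour is
  canonical.

Replicates are seeded per (t, replicate) from one base seed, and
scenario 1 and scenario 2 of the same replicate share a seed stream, so
the binomial scenario comparison is a matched-pairs test.  The
comparison is one-sided by default (directional claim of scenario-2
superiority); a two-sided option exists, and the p-value is the exact
binomial tail.

## Synthetic-data generator

The generator emulates the study conditions the analysis assumes, and
its defaults are fixed study conditions, not tuning knobs:

* map: 20 chromosomes x 20 uniformly spaced markers (L = 400),
  100 cM each — scaled down from ~2,000 real markers for desk-scale
  runtime while keeping realistic marker spacing (~5 cM);
* founders fully inbred; the common parent carries the 0 allele and
  each alternative parent the 1 allele at every marker, so every marker
  segregates within its own population (shared-polymorphism structure
  between populations is not modelled — the UC machinery only needs
  origin-labelled effects);
* populations: two F4 families of 300 (the real populations are ~298
  and ~297), each produced as F1 -> three generations of single-seed
  descent, giving expected per-locus heterozygosity 1/8;
* trait A (major-gene): 5 major QTL per population of magnitude 1.0,
  90% favorable — an oligogenic trait whose favorable alleles are
  quickly accumulated;
* trait B (polygenic): 40% of markers causal with half-normal(0.15)
  magnitudes, sign bias 0.2 in population 1 vs 0.8 in population 2 —
  opposite-signed small effects, so each population holds favorable
  alleles the other lacks and combining them raises the attainable
  ceiling;
* phenotypes: genotypic value plus iid normal noise with variance set
  so the realized genetic fraction equals the requested heritability.

What the generator does **not** emulate: genotyping error and missing
data, shared segregating markers between populations, estimation error
in marker effects (effects are treated as true, exactly as the
simulation design assumes), linkage-disequilibrium structure inherited
from breeding history, and more than two populations or traits
(the API accepts arbitrary numbers; the defaults use two).  Passing
tests therefore demonstrate correctness of the machinery under the
stated model, not robustness to these real-data complications.

## Genomic heritability

`estimate_heritability` fits y = mu + u + e with u ~ N(0, sigma_u^2 K)
by REML, using the spectral decomposition of the intercept-projected
kernel so the restricted likelihood is a one-dimensional function of
the variance ratio (optimized on log scale, bounded [-12, 12]).  K is a
VanRaden marker kernel **normalized to mean diagonal 1**: in partially
inbred material the usual 2*sum(p q) denominator leaves the diagonal
near 1 + F, which would deflate sigma_u^2 relative to the
per-individual genetic variance and bias h^2 = sigma_u^2 / (sigma_u^2 +
sigma_e^2) downward by a factor ~(1 + F).  With the normalization the
estimand matches the realized variance fraction the phenotype simulator
controls; a 20-replicate recovery test at n = 300, target 0.5, is part
of the acceptance suite.  Different kernel conventions in other
software mean h^2 values are comparable only within one convention.

## Numerical choices and edge cases

* Progeny variances are quadratic forms and mathematically
  non-negative; floating-point totals in [-1e-9, 0) are clamped to 0,
  anything more negative raises.
* Unlinked chromosomes use recombination fraction exactly 0.5, making
  their D entries exactly 0.
* `generation_recombination` requires integer g >= 1.
* Zero genetic variance in a population makes both the phenotype error
  variance (for h^2 < 1) and the index scaling undefined; both raise
  rather than guess.
* Heterozygosity comes in two flavours: gene diversity
  1 - (1/L) sum_l sum_i p_li^2 (`heterozygosity`) and the fraction of
  heterozygous genotype calls (`observed_heterozygosity`).  Only the
  latter halves per selfing; the former is frequency-based and decays
  only by drift.
* The top 1% of a population of n is max(1, round(0.01 n)) individuals
  (9 of 900).

## Known limitations

* Two-parent crosses only; three- and four-way generalizations of the
  variance algebra are not implemented.
* Real unphased genotype data would require phasing before the
  haplotype-level variance decomposition applies; the simulator always
  knows true haplotypes.
* The scenario engine models neither model updating across cycles nor
  cost constraints on generation advance.
* Reported per-generation variances use the sample variance of the
  realized population; with 900 individuals the Monte-Carlo error of a
  single replicate is visible, which is why all comparisons aggregate
  over paired replicates.
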