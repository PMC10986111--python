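# Methods

## Data model

A haplotype is one male donor's allele vector over an ordered locus
panel. The built-in panel is the 17-column Yfiler set: 16 loci, with the
duplicated locus DYS385 contributing two unordered calls per donor that
are always stored — and compared — as an ascending pair, so haplotype
identity is invariant to input order. Allele values are repeat counts;
microvariant alleles (13.2 and the like) are carried as exact decimals
and compared exactly, never with a tolerance: allele identity is
categorical in forensics. DYS389II is stored as reported by the kit (no
subtraction of DYS389I). Donors with a missing call are excluded from
haplotype-level statistics but their remaining loci still contribute to
per-locus gene diversity; out-of-range alleles are kept but flagged, so
no value passes silently.

## Diversity estimators

All diversity quantities use Nei's unbiased estimator
`GD = n/(n−1)·(1 − Σp²)`, computed in the rearranged integer form
`(n² − Σc²)/(n(n−1))` so that the all-distinct case yields exactly 1.0
and the monomorphic case exactly 0.0 in floating point. The sample-size
correction is always applied — this is the form standard in Y-STR
population reports. Haplotype diversity applies the estimator to
whole-haplotype frequencies; discrimination capacity is `h/n` over
complete haplotypes; match probability is the exact complement of HD.
Estimators refuse `n < 2` rather than returning 0, since an undefined
diversity and an absent diversity are different findings.

DYS385a/b enter per-locus gene diversity as two separate columns ('a'
the smaller allele after sorting), matching how duplicated-locus
diversity is conventionally reported; a `combine_dys385` flag pools the
two gene copies into one 2n-copy frequency spectrum instead. Report
precision follows the field's convention (HD 5 d.p., DC and GD 3 d.p.,
HMP 4 d.p.); full precision is retained internally.

## AMOVA and pairwise FST

Differentiation uses the standard two-level variance decomposition on
squared pairwise haplotype distances: `SS_total = (1/N)Σ_{i<j} d²`,
within-group sums analogously per population, `σ²_w = SS_w/(N−k)`,
`σ²_a = (SS_a/(k−1) − σ²_w)/n̄` with the usual unequal-size coefficient
`n̄ = (N − Σn²/N)/(k−1)`, and `Φ = σ²_a/(σ²_a+σ²_w)`. Two distance
models are offered: identity (d ∈ {0,1}; Φ is then a
haplotype-frequency FST, the convention used by the YHRD database) and
stepwise (sum of absolute repeat differences; the unordered DYS385 pair
contributes its minimum-assignment difference, which the ascending sort
realises automatically). Identity is the default. If the total variance
is zero the result is flagged degenerate and Φ defined as 0.

Permutation significance reassigns donors at random to the two labels
with sizes fixed; because `SS_total` is permutation-invariant, Φ is a
monotone decreasing function of `SS_within`, and the test counts
permuted `SS_within ≤` observed — algebraically identical to counting
`Φ* ≥ Φ` but allowing all B quadratic forms to be evaluated with one
matrix product. The p-value uses the `(1+x)/(B+1)` correction (never
exactly zero); B defaults to 10,000 and a seed is mandatory. No
multiple-testing correction is applied to the p-value matrix itself —
raw p-values are what comparable survey reports print — but a
Bonferroni-adjusted companion table is always emitted. Negative Φ
estimates are reported as computed in tables and clamped to zero only
where a dissimilarity is required (MDS).

## Classical MDS

Torgerson scaling: double-centre the squared dissimilarities,
eigendecompose, scale the top-m eigenvectors by the square roots of
their (positive) eigenvalues. Axis signs are fixed by making the
largest-magnitude coordinate of each axis positive, so plots are
deterministic. The goodness figure is the share of positive-eigenvalue
mass captured by the retained axes. An all-zero matrix embeds at the
origin; asymmetric input is an error. The implementation is ~20 lines
of numpy and is cross-checked in the tests against scikit-bio's
principal-coordinates analysis.

## The simulator

The generator is a forward-time Wright–Fisher model of `Ne` patrilines
per population — the Y chromosome is haploid and paternally inherited,
so the natural unit is the male lineage. Each generation every lineage
draws a father uniformly (multinomial offspring), optionally from
another deme under a symmetric island model (migrant source uniform
over the other d−1 demes); a "split" topology instead mixes all demes
fully for a burn-in and then isolates them. Each locus copy mutates
with probability `mu` per generation by ±1 repeat (stepwise mutation
model), reflecting at the panel bounds so microvariant fractional parts
are preserved. DYS385 is simulated as two independently mutating copies
and sorted only on output. The default `mu = 2×10⁻³` per locus per
generation is the order of magnitude typical of Y-STR loci;
per-locus overrides are supported. Everything is reproducible from a
single integer seed, and a truth log records realized allele counts and
surviving founder-lineage counts per population.

For the haploid finite island model the package also provides the
analytic quasi-equilibrium FST, obtained by solving the exact
one-generation identity-by-descent recursion
`F = (a + bF)(F(1−1/Ne) + 1/Ne)`; to first order in m this is the
familiar `1/(1 + 2Ne·m·d/(d−1))` (the diploid-convention composite
"4Nm"). Parameter-recovery tests calibrate m through this exact form
and pool variance components across replicates (the ratio-of-means
combination standard for FST) before comparing with the target.

### Recent-expansion phase

A small-Ne equilibrium population cannot show the hallmark of real
national Y-STR surveys — essentially every 17-locus haplotype unique
while per-locus gene diversity stays moderate — because whole-haplotype
homozygosity at equilibrium is of order `1/(1+2Ne·μ_total)`. Real
surveys achieve it through recent population growth, which makes
genealogies star-like. The simulator models this with
`expansion_generations`: after sampling, each sampled lineage accrues
that many generations of private mutation with no shared ancestry —
the exact coalescent limit of rapid terminal growth. This is a
demographic modelling choice, not a claim about any real population.

### Fixture profiles

`make_fixture("tiny")` gives 3 populations × 10 donors for oracle-scale
tests. `make_fixture("iran-like")` emulates the study design of a
16-province national survey (sizes 27–256, N = 1353): Ne = 300
patrilines per province, 800 generations of structured drift at
migration rate 0.04, per-locus mutation rates spread over an order of
magnitude (DYS385 highest, DYS391 lowest), per-locus initial dispersal
seeding realistic standing variation, and a 450-generation expansion
phase. With the default seed this yields ≥99% unique haplotypes,
HD ≥ 0.999, and per-locus gene diversity in roughly [0.3, 0.9] with a
pooled mean near 0.7. These parameters are tuning choices recorded in
the truth log; the profile reproduces the statistical *structure* of a
national survey, not the history of any population. What passing tests
on this fixture show is that the estimators behave correctly on data
with survey-like structure — they say nothing about mutation rates,
migration, or demography of real populations, and the generator omits
real-data features such as genotyping error, population substructure
below the province level, and locus-specific mutation directionality.

## Numerical and design notes

- Haplotype keys are canonical strings over the fixed panel order with
  DYS385 ascending; two donors share a key iff all 17 reported values
  are equal.
- Table I/O accepts DYS385 either combined ("14,11") or split into
  DYS385a/DYS385b and always writes the split form; read∘write is
  bit-exact, including microvariant decimals.
- Problem sizes in the validation experiments (6 demes × Ne 100,
  samples of 50, 200 replicates; permutation B = 999 under the null)
  were chosen so each experiment has enough Monte-Carlo resolution to
  detect estimator bias at the few-percent level while remaining
  desk-scale.
- The survey this package's structure follows reports both an
  all-unique haplotype count and DC = 0.997, which are mutually
  inconsistent; the package computes h and DC from the data and
  hard-codes neither.
- Known limitations: no three-level (region/province/donor) AMOVA; no
  haplogroup prediction; the stepwise model generates no new
  microvariants (they are carried through, never created); p-values are
  exchangeability-based and assume donors are unrelated.
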