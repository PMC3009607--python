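# Methods

## The inference problem

A recessive lethal mutation kept over a balancer cannot be made homozygous
in a live animal, so its position is inferred by exclusion rather than by
direct genotype–phenotype association.  Two evidence sources are combined
on a single chromosome:

**Deletion complementation.**  Each deficiency is modelled with two nested
extents: `min` (DNA demonstrated absent) and `max` (outer bounds of the
breakpoint-uncertainty zones).  If the deficiency fails to complement the
mutation, the mutation lies in DNA the deletion could remove, and the
candidate region is intersected with `max`.  If it complements, the
mutation cannot lie in DNA certainly removed, and `min` is subtracted.
Using `max` for retention and `min` for exclusion is conservative in both
directions: whatever the true breakpoints, the true position is never
discarded.

**Recessive-lethal recombination exclusion.**  In a B6 × Cast F2 panel
segregating the lethal (carried on the B6 haplotype), live animals prove
that B6/B6 homozygosity at their B6/B6-typed markers is compatible with
survival.  For each live animal, each maximal run of B6/B6 calls excludes
the closed span from the run's first to last marker.  Two deliberate
design choices keep this rule sound rather than powerful:

- The span is **not** extended toward flanking heterozygous markers.  The
  crossover lies somewhere in the flanking interval; extending the
  exclusion into it could discard the true position.
- Missing calls break runs, and a single-marker run excludes only the 1 bp
  of the marker itself — the only DNA proven B6/B6.

Exclusions from all live animals are unioned and subtracted from the
region.  Because every step is an intersection with, or subtraction of, a
fixed set, the final region is monotone (more evidence never enlarges it)
and invariant to evidence order.  The full step list is kept as a
replayable evidence log; an empty final region raises an
inconsistent-evidence error carrying that log.

*Caveat.*  The marker-span rule is sound up to double crossovers: a live
animal B6/B6 at both markers bracketing the mutation but heterozygous at
the mutation itself requires two crossovers inside one marker bracket in a
single gamete.  Under the no-interference meiosis model below, at 1.5 Mb
marker spacing and 0.5 cM/Mb this has probability ~1e-5 per animal; the
containment property is therefore expected, not absolute, at simulation
scale.

## Interval algebra

All mapping logic reduces to exact set algebra on integer base-pair
intervals.  Intervals are 0-based half-open internally; marker tables,
deletion TSVs and logs use the field's 1-based inclusive convention and
convert at the boundary (`[s, e]` 1-based ↔ `[s−1, e)` 0-based), which
keeps BED3 I/O native while reproducing printed coordinates.  Interval
sets are held in canonical form (sorted, disjoint, touching intervals
merged) so equality is structural; union, intersection and subtraction are
linear sweeps verified in tests against a per-basepair bitmap oracle.
Widths in kb round half away from zero — a 288,969 bp span between marker
positions 60,593,878 and 60,882,847 (1-based) prints as 289 kb.

## Complementation planning and allelism

With one critical region per mutation, every unordered pair is classified:
disjoint regions ⇒ complementation inferred without breeding; overlapping
regions carry their recorded cross outcome or are flagged untested.  A
recorded *failure* between disjoint regions is raised as a contradiction
(bad mapping, bad test, or a gene spanning adjacent intervals) rather than
silently resolved.  The potential-test count defaults to ordered
accounting, n(n−1), matching how reciprocal crosses are tallied in
screen-wide summaries; unordered n(n−1)/2 is available by flag.

Allelic groups are connected components over failure-to-complement edges
(allelism treated as transitive), computed by union-find and cross-checked
in tests against an independent graph-library implementation.

## Balancer-cross viability statistics

In an m₁/Bal × m₂/Bal intercross the balancer homozygote dies around
gastrulation, so the classes present at birth are 1/3 trans-heterozygote :
2/3 balancer carrier.  The complementation null is tested on **weaned**
counts — pups dying before weaning are typically ungenotyped and excluded —
with expectations (T/3, 2T/3) for T weanlings, kept as exact rationals
until the test.  The statistic is the uncorrected Pearson χ² with df = 1
(Yates' correction is deliberately not applied; with it, 0/21 gives 9.04
rather than 10.5).  Upper-tail probabilities come from the χ² survival
function, checked in tests against numerical integration of the df = 1
density.  At T = 60 the exact type-I error of the nominal 5% test is 3.9%
(binomial enumeration); the simulation calibration test asserts the
empirical rate within 5% ± 2%.

## Candidate-variant filtering

Four predicates, applied in order with per-record rejection logging:
zygosity (HET by default — carrier DNA; a flag admits HOM_ALT for DNA from
homozygous mutant embryos), position inside the critical region, absence
(or HOM_REF) at the same (chrom, pos, alt) in every control sample, and
absence from the known-variant catalog.  Matching is by exact
(chrom, pos, alt); multi-allelic VCF records are decomposed per alt before
filtering.  Quality thresholds are upstream concerns and pass through
untouched.  The filter is idempotent and invariant to record and control
order.  Re-sequenced sites are triaged by a rule table: presence in any
non-mutagenized strain sample ⇒ strain SNP; failure to replicate within
repeat sequencings of the same DNA ⇒ suspected artifact; otherwise ⇒
mutation.

## The screen simulator

The generator emulates the study design end to end with stored ground
truth.  Meiosis is Haldane: crossover count Poisson in the region's
genetic length, breakpoints uniform, no interference, starting phase a
fair coin — the simplest standard model, chosen because it gives the
closed-form recombinant fraction r = (1 − e^(−2d))/2 used as a test
oracle (Kosambi interference deliberately omitted).  F2 conceptuses draw
two F1 gametes; those homozygous for the mutation-bearing B6 haplotype at
the mutation position die before genotyping and never reach the live
table.  True deletion breakpoints are sampled uniformly within their
uncertainty zones; a deletion fails to complement exactly when the
mutation lies in its sampled true extent.  Intercross weanlings are
binomial 1/3 trans-heterozygote among births, with trans-heterozygotes
dying pre-wean when the pair does not complement.  Variant tables plant
one heterozygous causative change at the true position plus three
confounder classes: strain SNPs (shared with the partner-strain control),
background variants (shared by all samples) and known-catalog sites
(emitted with a matching catalog).

Defaults define the simulated study conditions: a 60.9 Mb region
(the proximal-Chr 5 footprint; the true inversion endpoints are not
printed anywhere, so the initial search region is configuration, not a
constant), markers every 1.5 Mb (realistic microsatellite fine-mapping
density), recombination 0.5 cM/Mb (order of the mouse genome average; the
study reports no rate), 100 F2 conceptuses per screen (panel sizes per
mutation are unreported; this value is an explicit, documented choice), a
six-deficiency panel in three nested complexes with ~1%-of-region
breakpoint-uncertainty zones, and variant noise of 20 strain SNPs, 30
shared background variants and 15 catalogued sites.  Genotyping error and
missingness default to 0 so soundness tests are deterministic; both are
config knobs.  Every output is a pure function of the configuration,
including its seed.

What the simulator does **not** emulate — and hence what passing tests do
not establish about real data: genotyping error in the default tests,
crossover interference, segregation distortion and litter structure,
variable marker informativeness, dose-dependent ENU mutation load, indels
or structural variants, and alignment/calling artifacts upstream of the
variant tables.

## Numerical and degenerate-input conventions

kb rounding is half-away-from-zero; empty interval sets are the single
canonical empty value; an empty genotype table yields an empty exclusion
set with a warning; a failed-complementation test whose maximal extent
misses the candidate region, a mapping whose evidence excludes everything,
and a χ² with zero weanlings all raise typed errors rather than returning
sentinels.  Pair keys are unordered; group and classification outputs are
sorted for determinism.

## Problem sizes used in checks

The automated checks run, per invocation: 1,000 randomized interval-set
instances against the bitmap oracle; 200 simulated screens (seeds 0–199)
for ground-truth containment; 100 seeds each at 20 and 200 conceptuses for
the width-shrinkage comparison (Welch one-sided test at α = 0.01); 50,000
gametes per distance for the Haldane check (±0.01); 100 seeded variant
tables for planted-variant recovery; and 10,000 null weanling replicates
at 60 weaned for χ² calibration.
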