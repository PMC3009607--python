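# rwmapkit

Mapping and cloning toolkit for **balancer-chromosome screens of recessive
lethal mouse mutations** — the forward-genetics setting in which ENU-induced
lethals on proximal Chr 5 are maintained in trans to the *Rw* (rump-white)
inversion and localized without ever observing a live homozygote.

It is written for mouse geneticists running (or simulating) regional
saturation screens, and implements the four inference stages such screens
chain together:

1. **Interval-exclusion mapping** (`rwmapkit.mapping`).  A mutation's
   *critical region* is whatever survives two kinds of exclusion applied to
   an initial search region *R₀*:

   - *Deletion complementation.* For a deficiency *Df* with known-absent
     DNA `min(Df)` and outermost possible extent `max(Df)`:
     failure to complement ⇒ region ∩ `max(Df)`;
     complementation ⇒ region − `min(Df)`.
   - *Recessive-lethal recombination exclusion.* In a B6 × Cast F2
     intercross no live animal can be homozygous for the mutagenized (B6)
     haplotype at the lethal, so for every live animal each maximal run of
     B6/B6 marker calls excludes the closed marker-to-marker span it covers
     (single-marker runs exclude 1 bp; missing calls break runs).

   Both rules are conservative, so evidence only ever shrinks the region
   and the result is order-independent; every step is kept in a replayable
   evidence log.

2. **Complementation planning and allelism** (`rwmapkit.allelism`).
   Mutations with disjoint critical regions cannot be alleles, which
   collapses the n(n−1) potential pairwise crosses to the co-localizing
   pairs; failure-to-complement edges are grouped into allelic classes by
   transitive closure.  Viability of a trans-heterozygote cross
   m₁/Bal × m₂/Bal is tested on weaned counts against the 1 : 2
   (non-balancer : balancer) null with a Pearson χ² (df = 1, no continuity
   correction).

3. **Candidate-variant filtering** (`rwmapkit.variants`).  Capture-seq
   calls are reduced to candidates that are heterozygous, unique to the
   mutant sample, inside the critical region, and absent from a
   known-variant catalog; every rejection is logged with its failing
   criterion.

4. **Screen simulation** (`rwmapkit.simulate`).  A generative model of the
   whole screen — Haldane (no-interference) meiosis, recessive lethality,
   deletion panels with breakpoint-uncertainty zones, balancer-intercross
   weanling counts, and variant tables with one planted causative change —
   with full ground truth, so every downstream stage can be scored exactly.

## Worked example

Simulate a screen, map the lethal, and filter variants down to the cause:

```bash
$ rwmapkit simulate --seed 3 --out screen/
wrote screen (seed=3, 74 live F2s of 100 conceptuses) to screen/

$ rwmapkit map --region screen/initial_region.bed \
    --deletions screen/deletions.tsv --tests screen/deletion_tests.tsv \
    --genotypes screen/genotypes.tsv --markers screen/markers.tsv \
    --mutation-id simL1 --out-bed screen/critical.bed
simL1	5	31059001	34499999
# total width: 3441 kb in 1 interval(s)

$ rwmapkit filter --mutant screen/variants_mutant.vcf \
    --control screen/variants_control_strain.tsv \
    --control screen/variants_control_b6.tsv \
    --region screen/critical.bed --known screen/known_variants.tsv
5	33250000	A	C	HET
# retained 1, rejected 65
```

Of 100 conceptuses, 74 survive (mutant homozygotes die in utero).  Two
deletions fail to complement, pinning the lethal inside their maximal
extents; recombination exclusions trim further, leaving a single 3.4 Mb
critical interval (printed 1-based).  The variant filter then discards all
65 confounders and keeps exactly one heterozygous candidate — at
33,250,000, which is indeed the simulated mutation position.

Viability statistics for a real cross — 21 weanlings, all balancer
carriers:

```bash
$ rwmapkit stats cross --weaned-bal 21 --weaned-nonbal 0
observed: 0 non-balancer, 21 balancer
expected under complementation: 7 non-balancer, 14 balancer
chi2 = 10.5 (df=1), p = 0.001194
```

The absence of trans-heterozygotes is significant: the two mutations fail
to complement, i.e. they disrupt the same gene.

All of this is equally available as a library (`rwmapkit.map_mutation`,
`rwmapkit.plan_tests`, `rwmapkit.complementation_chisq`,
`rwmapkit.filter_candidates`, `rwmapkit.simulate_screen`, ...); see the
docstrings and `docs/methods.md` for the model details.

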