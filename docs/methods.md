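# Methods

## The linkage-block model of non-crossover recombination

`ncohap` treats a phased cohort as a mosaic of two founder haplotypes per
region: the *derived* (archaic) haplotype, defined by the alleles an archaic
genome carries homozygously, and the *ancestral* haplotype, defined by an
outgroup. Crossover recombination — concentrated in hotspots — breaks the
region into discrete linkage blocks; non-crossover (NCO) gene conversion
moves individual alleles between the two haplotype backgrounds within a
block. Under this idealisation:

- SNPs never touched by conversion remain perfectly linked (their derived
  alleles sit on exactly the same haplotypes): r = +1 between any pair.
  They are the *block SNPs*, and their shared derived alleles form the
  *core haplotype*.
- A SNP hit by conversion on some haplotypes is no longer perfectly linked
  to the core: it becomes a *singleton*, and the degree of shuffling is
  summarised by the LD of its derived allele against the core.

The per-SNP NCO rate is defined as 1 − D′²_{a,hap}. D′ rather than r² is
used because r² is frequency-sensitive: a single conversion event already
drives r² below 1 by an amount that depends on f_a and f_hap, whereas
|D′| stays exactly 1 until at least two distinct event configurations have
occurred (all four haplotype classes present). 1 − D′² therefore counts
*haplotype-class diversity* created by recombination, not allele-frequency
drift.

### Assumptions

- The cohort is fully phased and the archaic/outgroup polarization is
  correct (homozygosity in the archaic genome is required to limit
  ancient-DNA damage artefacts; sites failing it are dropped and counted).
- Two founder states per block; back-mutation and recurrent mutation are
  ignored.
- Within a 200 kb window, perfect linkage is informative of common descent;
  beyond it, pairs are not evaluated (window inclusive: a pair exactly
  200,000 bp apart is considered).

## Analysis pipeline

1. **Polarization** (`archaic_snps`). A cohort SNP is retained iff the
   archaic genotype is homozygous for one of its alleles (that allele is
   *derived*, whether REF or ALT) and the outgroup carries the other
   (*ancestral*). The haplotype matrix is recoded to 1 = derived.
2. **Cores** (`linkage_blocks`). Connected components of the within-window
   r = +1 graph. Between binary columns r = +1 is equivalent to column
   identity, so components are found by grouping identical columns and
   splitting chains at gaps > 200 kb — O(n) instead of O(n²), and exactly
   equivalent (verified against the explicit pairwise route in tests).
   Components need ≥ 2 SNPs to be a core (`min_core_size`); the procedure
   defines singletons as the SNPs *left over* after perfect-linkage sets are
   identified, so a lone column is a singleton candidate, not a one-SNP
   core.
3. **Singleton assignment.** Each leftover polymorphic SNP is scored
   against the indicator column "haplotype carries *all* core members'
   derived alleles" for every core whose span lies within 200 kb, and
   assigned to the core with maximal exact r². Ties break by bp distance to
   the span, then by block id (the argmax alone is underdetermined; the
   tie-break makes output order-independent). SNPs with no candidate core
   are *omitted*.
4. **LD bundle** (`ld_stats`). All count-derived statistics are
   `fractions.Fraction` over 2N. r itself carries a square root and is
   float; its square and sign are exact. D = 0 maps to D′ = 0 by
   convention. Monomorphic margins leave r/D′/NCO rate undefined (`None`),
   and undefinedness propagates — never silently 0. Note that the piecewise
   D_max makes D′ ≥ 0 in both branches (for D < 0 numerator and denominator
   are both negative), so the sign information used by the Δf phasing rule
   is taken from r.
5. **GC bias** (`gc_bias`). Singletons with exact D′² = 1, exact r² < 1,
   maf > 0.2 and a G/C-vs-A/T allele pair are single-event SNPs; Δf > 0
   means the derived allele expanded (was transmitted), Δf < 0 means the
   ancestral allele replaced it. Bias = #GC-transmitted / total. The maf
   floor suppresses drift-dominated configurations; Δf = 0 events carry no
   direction and are dropped.
6. **Annotation profiles** (`annotation_profiles`). Binary overlap per
   merged track (a SNP at 1-based p overlaps (s, e) iff s ≤ p−1 < e);
   distances to interval boundaries with an inside/outside flag; GC content
   in a 200 bp window (100 bp flanks, N bases excluded, truncated at
   chromosome ends); an 11-way genic sub-region label with priority
   splice_site > UTR5 > UTR3 > exonic > intronic inside genes (splice sites
   are the first 2 bp of intron) and strand-aware distance bins (0–5, 5–50,
   > 50 kb) outside, collapsed to a 7-way scheme for mark-vs-region testing
   (splice sites merge into intronic — their positions are intronic and the
   coarse scheme has no splice category). Mark effects are tested per
   sub-region with a two-sided Mann-Whitney U (exact for tie-free samples
   ≤ 50 per group, else normal approximation with tie and continuity
   correction); hotspot-overlapping SNPs are excluded first so crossover
   machinery does not contaminate the NCO signal. Fold-change-vs-rate
   slopes use ordinary least squares over NCO-rate bins (default 10
   equal-width bins over [0, 1]; the bin count is configurable). State
   summaries average the rate per (epigenome × state) cell and rank-correlate
   against per-mark overlap frequencies (Spearman). Raw p-values are
   reported per cell without multiple-testing correction, matching the
   per-cell testing design; a Benjamini–Hochberg column can be added by the
   caller.

## The synthetic-data generator

`synthetic_data.simulate(config)` draws, from a single seed: a reference
sequence with background GC 0.40 and CpG-island segments at GC 0.65; gene
models with exons, CDS and both UTRs; hotspot, histone-mark, CpG-island and
15-state chromatin tracks; and a phased cohort built by

1. assigning each of the 2N haplotypes the derived founder state with
   probability `founder_derived_freq` (default 0.5), independently per
   crossover segment (crossovers are placed at hotspot centres and re-found
   the downstream segment — an idealisation of reciprocal exchange that
   keeps the truth exactly decodable);
2. initiating conversion events per haplotype and SNP site with hazard
   λ × multiplier(annotation at the site), multipliers composing
   multiplicatively across overlapping tracks; tract lengths are geometric
   with mean `tract_length_mean_bp` = 1000 bp (the field's standard tract
   scale), the initiating site placed uniformly within the tract;
3. resolving each heteroduplex site: strong/weak (G/C vs A/T) sites
   transmit the strong allele with probability `gc_transmission_bias`
   (default 0.68; recovery tests set it explicitly), all other sites copy
   the donor (opposite-founder) allele;
4. optional Wright–Fisher resampling of whole haplotypes
   (`drift_generations`) to spread allele frequencies.

Defaults mirror the studied cohort geometry: 99 diploid samples
(198 haplotypes), a 200 kb linkage window, maf floor 0.2, 200 bp GC window.

Every event is recorded (haplotype, tract, covered sites, per-site
old/new/transmitted class), so the suite can assert that each
derived↔ancestral discordance against the founder assignment is explained
by a recorded event, and that realized initiation counts match their
analytic expectation λ × multiplier × sites × 2N within Poisson error.

**What the generator does not emulate** — and what passing tests therefore
do not demonstrate about real data: coalescent ancestry and LD decay within
founder classes, mutation-rate heterogeneity and recurrent mutation,
genotyping and phasing error, selection, and realistic annotation geometry
(tracks are placed uniformly at random). Recovery results show the
*estimators* are correct under the model's own assumptions, not that the
assumptions hold in any particular cohort.

## Numerical choices

- Exact rational arithmetic for every count-derived LD quantity; the
  equalities r² = 1 and D′² = 1 that define block membership and the
  single-event filter are integer identities.
- Haplotype-composition bins over the derived fraction use (i/10, (i+1)/10]
  with the lower edge inclusive at bin boundaries (a fraction of exactly
  0.1 falls in the first mixed bin), computed in integer arithmetic.
- Distance and profile bins are caller-supplied edges ((a, b], lowest edge
  included); empty bins report count 0 with undefined mean, and weighted
  bin means recombine exactly to the global mean.
- Degenerate inputs: empty tracks yield all-false overlaps; chromosomes
  without intervals yield undefined distances; all-N windows yield
  undefined GC; chromosomes without genes label as far intergenic.

## Problem sizes

The test and acceptance runs use, as the package's own choices: 1000 random
small matrices (2N ≤ 40) for the LD oracle; cohorts of 99 samples with
20,000–50,000 SNPs at ~1 SNP/kb for landscape recovery (hazard multipliers
{1, 2, 4, 8} over disjoint class tiles, λ ≈ 0.5 initiations per site per
cohort at the mean multiplier, 5 seeds); 10⁵ events for estimator-level
GC-bias recovery and ~8,000-SNP cohorts for pipeline-level recovery.

## Known limitations

- Singletons inside another core's span may be assigned across it (pure
  argmax); no hierarchical block structure is modelled.
- The donor of a conversion event is not reconstructed; Δf only classifies
  expansion vs retraction of the derived allele.
- Unphased or missing genotypes drop the whole site; no imputation.
- Cohort-monomorphic archaic SNPs are retained in the table but flagged and
  excluded from blocks, singleton assignment and all averages.
- The CLI's `gc-bias` stage filters on float columns re-read from TSV; this
  is sound because D′² = 1 survives the float round-trip exactly and r² < 1
  gaps are far above float resolution at cohort sizes (denominators
  ≤ (2N)⁴), but the library path with exact Fractions is the reference.
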