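# Methods

This note records the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical conventions that make results
reproducible.

## Synthetic panel model

The generator emulates a multi-breed resequencing panel at desk scale.
Per site, an ancestral allele frequency *p* is drawn uniformly from a
configurable range (default 0.05–0.95; the range is a direct handle on
how much of the raw MAF spectrum falls below a filtering threshold).
Each breed's frequency is drawn from the Balding–Nichols distribution

    p_breed ~ Beta( p(1−F)/F , (1−p)(1−F)/F ),

where the per-breed drift parameter F ∈ (0,1) equals the expected
Weir–Cockerham F<sub>ST</sub> between breeds.  Haplotypes are sampled
i.i.d. Bernoulli(p_breed); positions are distinct sorted uniform draws.

Planted features, applied in this order so truth records always refer
to the pre-mask state:

1. **Sweep** — a designated haplotype overwrites both chromosomes of
   every sample of the swept breeds over the sweep interval, emulating
   a haplotype driven to fixation.
2. **Autozygosity tracts** — one haplotype is copied onto the other
   within each planted interval, producing genuine ROH.
3. **Missingness** — genotypes (dosage and both haplotype alleles) are
   masked i.i.d.

What the generator deliberately does *not* emulate: recombination maps
and background LD (sites are exchangeable given breed frequencies),
mutation-rate heterogeneity, sequencing error, and demographic events
beyond star-shaped drift.  Consequences for interpreting green tests:
EHH decays through haplotype diversity alone (fast in neutral regions,
flat across a planted sweep), which is exactly the contrast the scan
statistics need, but absolute EHH decay rates and LD-block structure on
real data will differ.  Gabriel-rule block tests therefore use
constructed haplotype genealogies (mutation-only diversity) rather than
the i.i.d. background, where the rule correctly finds no blocks.

Determinism: one `numpy` Generator seeded from the config drives all
draws; identical configs give byte-identical panels.  Pipeline stages
derive their seeds from the master seed by stable hashing
(SeedSequence over a CRC of the stage name), so single stages can be
reproduced in isolation.

## Site filtering

Sites are retained when MAF > 0.05 **and** call rate > 0.9, both
strict, computed over non-missing alleles/genotypes.  MAF is computed
from integer allele counts, not `1 − p` floating arithmetic, so a site
whose minor allele count is exactly 5% of called alleles is excluded
regardless of which allele is minor.  Windowed scans run on autosomes
only (X/Y/MT are excluded by default).  Coordinates are stored 1-based
as read from VCF; every exported interval is 0-based half-open, with
conversion only at I/O boundaries.

## Heterozygosity and ROH

Ho per site within a breed is het/called genotypes; He is the plug-in
2p̂(1−p̂) without the n/(n−1) small-sample correction (an optional flag
adds it), keeping He ≤ 0.5 exact for biallelic sites.  Breed values are
means over sites with at least one called genotype.

ROH detection follows PLINK's algorithm: 50-SNP windows sliding one SNP
at a time; a window is homozygous if it has ≤1 heterozygote and ≤5
missing calls; each SNP's hit rate is the homozygous fraction of the
windows covering it; SNPs with hit rate ≥ 0.05 (PLINK's
`--homozyg-window-threshold` semantics) form candidate runs, split at
physical gaps > 1 Mb; runs are emitted when they hold ≥100 SNPs, span
≥1 Mb and satisfy the 50 kb/SNP density rule.  All seven knobs are
configurable (`ROHParams`).  Hets are capped per window only, not per
final segment, matching PLINK.  F<sub>ROH</sub> divides summed ROH
length by the covered autosomal length (per chromosome, last minus
first SNP position).

## Structure

IBS distance is 1 − shared alleles / (2 × co-called sites).  The breed
F<sub>ST</sub> matrix uses the genome-wide Weir–Cockerham ratio of sums
per pair; negative genome-wide estimates are floored at 0 for distance
use with the raw value retained.  The NJ tree is Saitou–Nei with the
Studier–Keppler Q-criterion; ties in Q are broken by the
lexicographically smallest label pair, negative branch lengths are
clamped to zero (logged).  Raw pairwise F<sub>ST</sub> is the default
tree input; linearized Fst/(1−Fst) is available by flag.  PCA follows
the GCTA convention — center at 2p, scale by √(2p(1−p)), mean-impute
missing, drop monomorphic sites — with component signs fixed so each
component's largest-magnitude coordinate is positive.  No LD pruning is
applied by default.

## Selection scans

* **Per-site Fst terms** — Weir–Cockerham (1984) two-population
  components from sample sizes, allele frequencies and observed
  heterozygote fractions; sites uncalled in either population are NA,
  sites monomorphic across both contribute (0, 0) and are flagged.
  Windows combine terms as Σa / Σ(a+b+c) (the vcftools "weighted"
  convention); windows without usable sites are NA and excluded from
  quantiles.
* **Windows** are anchored at position 0 per chromosome, 40 kb wide at
  a 20 kb step; trailing partial windows are kept if they contain a
  SNP.
* **EHH** is unconditional homozygosity of extended haplotypes: groups
  are defined by the alleles at sites strictly beyond the core through
  the flanking site, so EHH(core) = 1 by definition.  Missing alleles
  never merge (a chromosome with a missing call becomes its own group
  from that site on) — a conservative choice that can only shrink EHH.
  Curves truncate after the first value below the cutoff (default
  0.05), at 1 Mb extension, or at the chromosome end.
* **XP-EHH** integrates EHH over physical distance by the trapezoid
  rule.  Both populations are truncated at a *shared* boundary per
  side — where the pooled-sample EHH drops below the cutoff — so the
  two iHH integrals cover the same span and the log-ratio is well
  defined (selscan's convention).  Cores monomorphic in the pooled
  sample, or with zero iHH in either population, are NA.  Per-SNP
  scores are z-standardized genome-wide before window-averaging;
  signed means are the default (an absolute-value flag exists).
* **LSBL** is computed per window from three matched Fst tracks; NA
  propagates; mismatched grids are an error.
* **Candidate calling** takes the empirical (1 − tail) quantile with
  the "higher" interpolation, so with all-distinct values exactly
  ⌈tail·N⌉ windows are flagged; the rule is closed above (≥ threshold),
  so ties can push the count higher (reported).  Degenerate all-equal
  tracks flag everything with a warning.
* **Intersection and merging** keeps windows flagged by both scans and
  merges overlapping or abutting windows into maximal regions (with a
  step smaller than the window, neighbors overlap by construction).

## Haplotype analysis

Samples with any missing call in the region are dropped (logged), not
imputed.  LD uses phased two-locus haplotype counts: D, D′ = D/D_max,
r² = D²/(p_A q_A p_B q_B).  Blocks follow the Gabriel
confidence-interval rule with Haploview's defaults: a 90% likelihood
interval on |D′| (multinomial likelihood on a 200-point grid with
allele frequencies fixed at observed values); strong LD when the CI is
[≥0.70, ≥0.98], strong recombination when the upper bound is <0.90;
a candidate span needs a strong-LD outermost pair and ≥95% strong-LD
informative pairs; candidates are accepted greedily by decreasing bp
span.  The haplotype network is a minimum spanning network over
Hamming distances — every MST edge plus each tie-equal alternative
(an edge joins iff its weight equals the bottleneck weight between its
endpoints) — chosen over median-joining because it is deterministic
and oracle-testable at this scale; median vectors are a possible
extension.  The frequency table keeps haplotypes with total count
strictly greater than the cutoff (default 2), labels them `hap_1…` by
descending count (ties by string), and reports per-breed homozygous
carriers.

## Annotation

Gene hits are any-overlap between a region and the gene span (a flag
adds ±k bp flanks); each gene is counted once genome-wide in totals.
SNP classes have precedence exonic > intronic > intergenic across
overlapping transcripts, and nonsynonymous > synonymous > non-coding
within exonic; codons are translated strand-aware with the standard
code; transcripts whose CDS length is not divisible by 3 are skipped
with a warning; a reference-base mismatch against the FASTA is an
error.  Peak overlap reports intersection bp, fraction and peak ids
per region.

## Problem sizes and tolerances

The test suite uses instance sizes chosen to make every oracle
comparison exhaustive (≤500-SNP brute-force checks), every closed-form
comparison exact (1e-9 to 1e-12), and every stochastic recovery test
well-powered at desk scale: Balding–Nichols F recovery uses 20,000
sites (tolerance 0.02, several Monte-Carlo standard errors); planted
sweep recovery uses 20 seeded replicates of a 2 Mb, 3-breed design and
requires ≥19 successes on both the merged-region overlap and the LSBL
argmax.  The bundled demo (4 breeds × 8, 2 Mb, ~2,000 SNPs) runs
end-to-end in seconds and is byte-identical across reruns.

## Known limitations

No statistical phasing or imputation (unphased input is rejected by
haplotype operations); no recombination-map support beyond physical
distance; no iHS/nSL/CLR statistics; admixture-style ancestry
estimation and GO/KEGG enrichment are out of scope.  Because the
generator lacks background LD, empirical tail thresholds on synthetic
tracks are not comparable in magnitude to thresholds on real data.
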