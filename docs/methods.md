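# Methods

## Scope and model

The package operates strictly downstream of variant calling: its unit
of input is a multi-sample VCF (FORMAT GT/AD/DP/GQ, site annotations
QUAL/FS/SOR/MQ/MQRankSum/ReadPosRankSum) plus the reference FASTA the
calls were made against. Read QC, mapping and calling are upstream
concerns. Cultured cell lines are modelled as clonal diploids: a
variant that distinguishes two lines is expected to be *fixed*
(homozygous) within each line, so a site enters a line's signature only
when both focal samples are homozygous. Heterozygous calls — residual
within-line segregation or caller noise — are set aside as NOT_FIXED
rather than forced into either category.

## Filtering cascade

Three stages, applied in order; each stage reports
input/passed/removed per variant class and per rule, and the cascade is
idempotent on its own output.

1. **Site hard filters.** SNPs are judged on QUAL < 30, SOR > 3.0,
   FS > 60, MQ < 40, MQRankSum < −12.5, ReadPosRankSum < −8; indels on
   QUAL < 30, FS > 200, ReadPosRankSum < −20. These are the standard
   hard-filter recommendations for germline short variants; all are
   configurable, and a site is only failed on annotations actually
   present — callers do not emit every annotation at every site, and
   absence is not evidence of failure.
2. **Genotype filters.** A site is dropped if any sample is missing
   ("." anywhere in GT), if it is multiallelic, if any sample has
   DP < 10 or GQ < 20, or if any heterozygote has minor-allele read
   fraction below 0.2 (computed from the AD of the two called alleles).
   Homozygotes are exempt from the allele-balance rule — the statistic
   is meaningful only for hets. A het lacking AD fails conservatively.
   Site dropping (rather than genotype masking) is used for DP/GQ
   failures, consistent with the subsequent no-missing-data rule.
3. **Depth cap.** Per variant class, per-site mean depth (mean of
   FORMAT/DP over samples) must not exceed 2 × the class's mode mean
   depth; the cap screens collapsed repeats and CNV artefacts that
   accumulate excess coverage. The mode is taken over half-up-rounded
   site means with ties broken toward the smaller value, and the cap
   boundary is inclusive — both choices are arbitrary conventions fixed
   for determinism.

## Two-line comparison and distribution

Biallelic post-filter sites are classified by the two focal samples'
genotypes into SHARED_ALT ("Same GT"), UNIQUE_A / UNIQUE_B
(together "Distinct GT"), NOT_FIXED and REF_BOTH. Venn percentages are
of SHARED+UNIQUE_A+UNIQUE_B and use half-away-from-zero integer
rounding throughout the reports.

Arm-level placement is tested with a Pearson χ² (scipy) against
expected counts proportional to contig sequence length — the null that
variants land uniformly along the genome. Window scans use 10 kb
windows advancing by 2.5 kb; full windows are emitted while
start ≤ L − w + 1, plus one flagged truncated window at the next step
position if the tail is uncovered, so with step < window an interior
variant is counted in window/step windows.

Cluster calls mark windows whose Distinct-GT count reaches
median + 3 × 1.4826 MAD of all window counts (floored at median + 3),
merge enriched windows within 2 × step of each other, assign the
dominant line by majority of UNIQUE_A vs UNIQUE_B in the merged span,
and drop clusters with fewer than 20 Distinct-GT variants. A robust
threshold is used deliberately instead of mean + 3 SD: fixed inversions
put enriched windows over several percent of the genome, which inflates
the plain SD until the cut exceeds the enriched level itself (for block
fraction f and block density c the mean+3SD cut is ≈ c·(f+3√(f(1−f))),
which is > c whenever f ≳ 1%). The MAD-based cut tracks the background
instead. Both the threshold and the merge/size parameters are
config-driven, since cluster calling has no canonical rule.

Per-feature counts locate every variant (indels by left-most reference
base, matching the `<arm>.<pos>` marker naming) in 0-based half-open
intervals; coding SNPs are classified synonymous/nonsynonymous by
translating the ref and alt codon of the containing CDS.

## Typing from diagnostic panels

A panel SNP contributes two allele observations per typed diploid
genotype; alleles matching neither state allele contribute nothing.
Karyotype calls: homozygous when one state holds ≥ 90% of counted
alleles, heterozygous when both hold ≥ 25%, undetermined when panel
coverage (typed SNPs / published panel size) is below 25%. The 90/25
thresholds are conventions — published in-silico karyotyping reports
near-unanimous tallies without a decision rule — and the 25% coverage
floor sits between coverages reported as reliable (≈ 55%) and as
unreliable (≈ 4–5%). Ancestry scoring averages 1 / 0.5 / 0 per typed
SNP (hom first state / het / hom second state); untyped SNPs are
excluded from the mean, and labels come from configurable bins
(≥ 0.8 / ≤ 0.2 by default). Gel-band interpretation matches observed
product sizes to genotype-label band sets within ± 20 bp by default —
agarose resolution; single-base differences are not resolvable.

## Marker selection and fingerprinting

Candidates are Distinct-GT fixed indels; six criteria are flagged per
candidate:

1. distinct fixed genotype between the two lines (re-checked);
2. indel length strictly > 79 bp (minimum gel-resolvable allele
   difference; configurable);
3. unique mapping: the deleted segment plus 20 bp flanks occurs exactly
   once in the reference, an inserted sequence occurs zero times, by
   exact two-strand substring search — a deterministic stand-in for a
   single-hit BLAST requirement;
4. complexity: dinucleotide Shannon entropy ≥ 1.5 bits/base and no 1–2-mer
   tandem run longer than 10 bases (excludes microsatellites);
5. isolation: no other called indel within 200 bp;
6. spacing: greedy max-min-distance selection, at most 2 markers per
   contig, so the panel spans the genome.

Criteria 3–6 operationalise qualitative requirements; each threshold is
a config field. In-silico PCR requires exact primer matches (forward on
the plus strand, reverse-complement of the reverse primer downstream);
the amplicon runs from forward 5′ start to reverse 5′ start inclusive,
products ≤ 3 kb are reported and > 10 products raise an ambiguity
error. Sample templates are the reference with the sample's variants
applied; homozygous edits go to both haplotypes, heterozygous edits to
one (phase across distant amplicons does not affect fragment sizes).
Bands within 5 bp collapse to one. Distinguishability reports whether
all line fingerprints are pairwise distinct at gel tolerance, all
minimal marker subsets achieving full discrimination (exhaustive over
subsets — panels are small), and redundant markers. Contamination is
flagged when any marker shows a band absent from the expected
fingerprint — in fraction mode only when the band's template fraction
reaches the 10% detection limit; mixtures of lines with identical
fingerprints are reported as non-informative rather than clean.

## Synthetic scenario

The default scenario is a 3.6 Mb genome of five arms (2R 1 Mb, 2L 0.6,
3R 0.8, 3L 0.7, X 0.5) with four lines. Per-bp rates: shared
homozygous divergence 3×10⁻³ (≈ 11 k variants), background
line-specific variants 10⁻⁴, and four inversion-mimicking blocks
(200/50/60/50 kb) at 2×10⁻³ — a 20-fold enrichment, comparable to a
fixed inversion's footprint. 15% of variants are indels (geometric
lengths, 3% heavy tail at 80–250 bp so some clear the marker size
criterion). Depth is Poisson(40) per sample; het noise 1% and
per-rule filter-failure rates of 0.2–0.4% plant labelled failing
sites, so filter reports can be audited against ground truth exactly.
A 300-SNP inversion panel (published size 349) sits inside the largest
block; the 20-SNP species panel is spread over X/2L/3L with per-line
compositions (1,6,13), (1,6,13), (3,0,17), (0,0,20). Five markers with
361 bp reference amplicons are planted with genotypes chosen to give
the four lines pairwise-distinct fingerprints, including one
heterozygous (two-band) cell and one redundant marker pair. All
randomness flows from one seeded generator; runs are byte-reproducible.

What the generator does *not* emulate: read-level error (noise enters
as genotype/annotation perturbations, not simulated reads), realistic
mutation spectra, linkage beyond the planted blocks, and genome-scale
variant counts. Passing tests therefore demonstrate the correctness of
the algorithms and their calibration on inversion-like structure, not
performance on any particular organism's data. Scenario sizes (≤ 5 Mb,
≈ 11 k variants) were chosen so the full pipeline completes in well
under a minute; noise is kept off the designed assay loci because the
panels and markers define the study conditions being tested.

## Known limitations

- In-silico PCR tolerates no primer mismatches; a mismatch budget is a
  natural extension for degraded or divergent templates.
- Contamination detection models band visibility as a sharp threshold
  on template fraction; real gels lose minor bands gradually.
- The depth-cap mode is recomputed on whatever call set it is given,
  so cascade idempotence holds in practice (removed sites are far from
  the mode) but is not a mathematical guarantee under adversarial
  depth distributions.
- Cluster boundaries are window-resolution (± one step) and are not
  inversion breakpoint estimates.
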