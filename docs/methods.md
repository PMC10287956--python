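# Methods

This note documents the models, conventions and numerical choices behind
`atacedit`, in the order data flows through the package.

## Generative picture of the assay

A pool of edited cells carries alleles a ∈ {WT, HDR…, DEL(start,len)…}
at frequencies f_a.  Genomic-DNA amplicon reads sample alleles at f_a
and span the full amplicon (primer to primer).  Targeted-ATAC reads
sample alleles at probabilities proportional to f_a·m_a, where m_a is
the allele's accessibility multiplier (m_WT ≡ 1): Tn5 tagments an
allele's locus in proportion to how open it is, and every tagmentation
event yields one sequenceable fragment.  Each ATAC read runs from the
fixed nested-primer end of the amplicon to a variable Tn5 insertion
site.  Under this model the expected per-replicate ratio r = count(a)/
count(WT) is f_a·m_a/f_WT in ATAC and f_a/f_WT in gDNA, so the ratio of
means r̄_A/r̄_G estimates exactly m_a.  This is the minimal generative
model consistent with the assay readout; it deliberately ignores PCR
amplification bias, duplicates/UMIs and the biotin-enrichment step.

## Read merging

Amplicons are designed shorter than 295 bp so that 2×150 bp pairs
overlap.  `merge_pair` scans all relative placements of the
reverse-complemented mate against read 1 (shifts below zero are the
dovetail "outie" geometry) and scores each candidate by mismatch
density over the doubly covered interval.  Defaults: minimum overlap
10 bp, maximum mismatch density 10%, outies allowed, fragment SD 40 bp.
Conventions where the upstream tools leave room:

* ties between equally clean overlaps break toward the placement whose
  implied fragment length is closest to `expected_fragment` (set it to
  the amplicon length), then toward the longer overlap;
* N bases count as half a mismatch — uninformative, not contradictory;
* at overlap disagreements the higher-quality base wins; where bases
  agree the maximum quality is kept;
* outie merges are trimmed to the doubly covered interval, because the
  single-covered tails in that geometry are adapter read-through.

No adapter or quality trimming is performed; pre-merged single-end
input bypasses the stage (`premerged: true`).

## Alignment

Reads are aligned to the amplicon reference (not the genome: every
informative read derives from one amplicon, and per-region alignment is
equivalent for classification while keeping the package self-contained).
The mode is glocal — read global, reference local — so an ATAC read
truncated at the Tn5 insertion site pays nothing for the uncovered
reference tail.  Scoring is affine-gap with match +4, mismatch −16, gap
open 24, gap extend 1 per base, a deliberately indel-lenient ratio under
which a 100-bp Cas9 deletion (cost 124) is cheaper than 8 mismatches
(160).  Reads scoring below `min_score` (default 70) are unmapped.  The
optimizer is Biopython's `PairwiseAligner`; the test suite checks its
scores against an independently written affine-gap dynamic program.

Indels are left-normalized within repeats (the variant-normalization
convention), giving every deletion a single canonical (start, length)
identity regardless of where the optimizer placed it.  Both read
orientations are tried and the better one kept, making classification
orientation-invariant.  Externally aligned SAM/BAM is ingested instead
via `load_alignments` (secondary/supplementary dropped, genome
coordinates shifted by `genome_offset`).

## Allele classification

The *analysis span* is the union of the deletion window (snp ± 6 bp by
default) and every HDR edit locus.  A read must fully cover the span to
be classified; otherwise it is excluded as `short_span` (applied
identically to ATAC and gDNA).  The call is decided by:

* substitutions overlapping the span, plus insertions and deletions
  anywhere on the read (indels are genuine repair outcomes wherever
  they fall);
* off-span substitutions never affect the call.  At a realistic 0.1%
  per-base error essentially every fifth read carries a high-quality
  off-span miscall; treating those as real edits would wholesale
  misclassify reads and bias editing rates, so they are regarded as
  sequencing/PCR noise.

Priority of rules: an exact match to an HDR allele's edit set wins first
(this is also how an *insertion* HDR allele is recognized, equivalent to
classifying against an insertion-containing alternate reference); any
other read containing an insertion is excluded (`insertion`); a single
remaining deletion is a DEL allele; no remaining edits is WT; everything
else (multiple deletions, deletion+substitution combinations, unexpected
in-span substitutions) is OTHER.  Every read gets exactly one
disposition, so classified + dropped = total per replicate.

The deletion-window filter retains DEL(start,len) iff all deleted bases
lie in [snp−w, snp+w] inclusive.  "Top deletions" are ranked by summed
gDNA counts — gDNA reflects pool frequency, whereas ranking by the ATAC
readout would bias selection toward accessible alleles.

## Statistics

* Replicates with zero WT reads have no ratio denominator and are
  excluded with a warning; replicates where the *allele* has zero reads
  contribute r = 0 (dropping them would bias toward no effect).
* Welch test: t = (r̄_A − r̄_G)/√(s²_A/n_A + s²_G/n_G) with
  Welch–Satterthwaite df, two-tailed.  Degenerate convention: both
  samples constant and equal → (t=0, df=n_A+n_B−2, p=1); constant and
  unequal → p→0, flagged by a warning.
* 95% CI: Welch interval on the difference of mean log-ratios,
  exponentiated — positive and symmetric on the ratio scale.  When a
  zero count occurs, a pseudocount of 0.5 reads replaces it for the
  log-CI only; point estimates are untouched.
* Editing rates from summed gDNA counts: hdr = HDR/(classified +
  insertion-dropped); indel = (DEL + insertion-dropped + OTHER)/(same).
  Unmapped/short-span drops are not editing outcomes and are excluded
  from the denominator.
* Technical PCR replicates of one tagmentation are pooled (counts
  summed) into their parent replicate before testing, so they cannot
  inflate the degrees of freedom.
* p-values are reported raw; a Benjamini–Hochberg q column is emitted
  alongside for screen-style experiments.

### Sensitivity

`min_detectable_change(sd, n, α)` returns t_{1−α/2, 2n−2} · sd: the
smallest shift in the mean WT-normalised ratio that reaches the
two-tailed critical value when the between-replicate SD of r is taken
as the noise scale of the group comparison, with the pooled equal-n df
2n−2 (the equal-variance reduction of the Welch test).  Other df/SE
conventions (e.g. multiplying by √(2/n)) are defensible and differ by a
constant factor; this package fixes the convention above.  With
sd = 0.0477 and n = 3 it yields 22.0% at α = 0.01 and 13.2% at α = 0.05.

## Saturation-mutagenesis profiles

Single-substitution HDR alleles are arranged into a position ×
nucleotide effect matrix with the WT base fixed at 1.  Logo letter
heights are the *squared* effect size (masked cells 0); an importance
score 1/effect is reported alongside (a base whose mutation collapses
accessibility is an important base).  Motif proportions divide each
effect by the per-position sum over the four bases; positions with any
unmeasured cell are excluded, and CI bounds on the proportion scale are
divided by the point-estimate sum (the sum's own uncertainty is not
propagated).  Comparison to a JASPAR PFM normalizes the PFM per
position and computes the Pearson correlation over all cells; the
offset/strand mapping between amplicon coordinates and PFM columns is
explicit configuration, never inferred.  Logo rendering is plain text;
no plotting dependency is used.

## Simulator

`SimConfig` defaults define the study conditions: 3 ATAC + 3 gDNA
replicates, 10⁴ reads per replicate, 150-bp reads, 0.1% per-base error
(Illumina-like), and a triangular Tn5 insertion-propensity profile
peaking mid-amplicon (reads shorten toward the peak flanks).  The
default deletion repertoire draws lengths geometrically (mean 4 bp) with
intervals straddling or abutting the blunt cut, and Dirichlet-distributed
frequencies.  Sampling is two-stage: per-replicate multinomial allele
draws (the count-level core, usable directly for statistical
calibration), then read synthesis — gDNA reads span the full allele
sequence; ATAC reads run from the fixed primer end to an insertion site
drawn from the profile restricted beyond the analysis span, so every
error-free ATAC read is classifiable.  Everything is deterministic under
the seed.

What the simulator does *not* emulate — PCR bias, duplicates, chimeras,
quality-score heterogeneity, the extra variance of tagmented-gDNA
controls — bounds what passing recovery tests show: they validate the
statistical chain under multinomial sampling noise, not robustness to
library-preparation artifacts.

## Problem sizes used in validation

Calibration checks run the count-level simulator at 10⁴ reads ×
3+3 replicates: 200 pools across multipliers {0.25, 0.5, 1, 2} for CI
coverage (observed ≈ 0.95) and 1000 null pools for the false-positive
rate (observed ≈ 0.04 at p < 0.05).  The end-to-end saturation check
simulates 9 positions × 3 substitutions at 3000 reads per replicate
through the full read-level path.  These sizes give stable pass/fail
behaviour at desk scale; the statistics themselves are depth-agnostic.

## Known limitations

* No UMI deduplication or chimera detection; PCR duplicates inflate
  effective depth.
* Base qualities inform merging but not alignment scoring.
* One amplicon per region; unmerged paired-end alignment is not
  supported (merge first, or supply SAM/BAM).
* The CI is t-based on log ratios; with very few replicates and many
  zero counts the pseudocount convention dominates its width.
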