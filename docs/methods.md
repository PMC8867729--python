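# Methods

This note documents the models implemented by `svjoint`, the parameter
defaults and why they were chosen, the numerical conventions, and what the
synthetic-data generator does and does not emulate.

## Scope and coordinate conventions

The package analyzes deletions, insertions, duplications and inversions of
50 bp–500 kb whose alleles are sequence-explicit (literal REF/ALT
nucleotides), because only such alleles can be genotyped by mapping short
reads to their breakpoints. `SVRecord` and all VCF-facing code are 1-based
inclusive with a padded anchor base; all internal interval arithmetic
(N-gap, repeat and genic overlap) is 0-based half-open, converted only at
the I/O boundary. Allele representations are left-normalized
(vt/bcftools-norm style: right-trim equal allele ends, rotating leftward
through the reference when an allele would empty, then trim the shared
prefix to one padding base). Normalization is applied on VCF input, by the
generator when it emits truth records, and to refined records — so
"same breakpoint" always means "same normalized representation".

## Call-set normalization

Filters applied to every raw call set: span in [50 bp, 500 kb]; chromosome
in a whitelist (organellar genomes and unanchored scaffolds excluded); type
in {DEL, INS, DUP, INV}; no overlap with any reference N run; insertions at
least 20 bp from any N; optionally (genotyping preparation) at least 1 kb
from both chromosome ends, measured from both `pos` and `end` — the
conservative reading, since either endpoint near an end breaks genotyping.
Heterozygous source calls are dropped from long-read call sets only:
residual heterozygosity in inbred lines is almost surely artifactual.
Breakend pairs are classified by join orientation (left breakend joining
rightward onto the mate's left side → DEL; the outward-facing reciprocal →
DUP; two same-sided joins → INV) and verified by a round-trip property
against the simulator's breakend emitter. The 500 kb cap is applied to the
SV *length* (also for insertions).

## Merging

Two normalized calls are *compatible* when they share type and chromosome
and either (a) |Δpos| ≤ 15 bp and |Δlength| ≤ 15 bp, or (b) relative shift,
relative size difference and relative sequence edit distance are all within
thresholds (defaults 0.1 / 0.1 / 0.2 of the mean length). The disjunction
of an absolute and an all-relative rule is this package's definition of
"slightly differing representations of the same allele"; the widely used
merging tools do not publish a closed-form rule, and this one merges
breakpoint-shifted representations while preserving true allele diversity.
The edit distance compares REF alleles for deletions and ALT alleles
otherwise, computed banded with cutoff `reldist × mean length`; sequences
above 10 kb skip the check (size agreement has already been established,
and the check would dominate runtime). Clusters are connected components of
the compatibility graph (single linkage, verified against a brute-force
transitive-closure oracle), and output order is deterministic by
(chromosome, position, length, id). Representative selection is uniform at
random under a seeded generator, optionally restricted to refined alleles
(long-read merging) or to short-read alleles (mixed-technology merging,
where short-read basecalls are more accurate).

## Breakpoint refinement

Long-read callers report breakpoints and insertion sequences derived from
reads with roughly 8–10% base error. Refinement rebuilds each DEL/INS call:

1. **Window reads.** Reads mapped within ±200 bp (`flank`) of the call are
   collected; fewer than 3 reads (`min_reads`, mirroring the caller's
   minimum support) forces fallback.
2. **Consensus.** The read with the smallest total edit distance to all
   others is the backbone; every read is globally aligned to it (edlib) and
   each backbone column is polished by majority vote, with insertions
   applied when more than half the reads support the same inserted sequence
   at the same position. This replaces an external assembler + polisher
   with a dependency-free consensus whose accuracy is asserted directly by
   the recovery tests (≥ 99% identity at 20× / 5% read error).
3. **Split alignment with gap excision.** The consensus is aligned to the
   local reference window by maximizing, over all ways to split query and
   reference into a prefix and a suffix, the sum of the two flank
   local-alignment scores (Gotoh affine scoring, defaults +1 match, −1
   mismatch, −2 gap open, −1 gap extend; the scores are package choices and
   config-exposed). The optimum over all split points is computed with one
   forward and one reverse DP plus 2-D running prefix maxima, so it costs
   the same as two ordinary alignments (numba kernels; instances capped at
   30 M DP cells). The skipped middle portions are the excised reference
   interval and the inserted query interval. Ties are broken toward the
   leftmost excision start and then the shortest excision, via
   lexicographically smallest block end cells. Equivalence with an
   exhaustive split-point search is asserted on random instances.
4. **Update-or-fallback.** The call is updated iff the alignment shows
   exactly one event of the call's type (the other side's residual ≤ 10 bp
   of slop), both flank blocks cover ≥ 20 reference bp with identity ≥ 0.9,
   and the refined length is within 25% of the original. These acceptance
   thresholds are package definitions standing in for decision logic that
   the upstream tools do not publish; all are config-exposed. Any other
   outcome returns the input record unchanged, with a reason code.
   Duplications and inversions are not refined — their internal structure
   is not a single excision/insertion event.

## Genotype benchmarking

Only homozygous-ALT calls are scored; heterozygous calls are ignored
entirely (neither TP nor FP), since truth sets from inbred lines contain
only homozygous records. Matching rules — pinned here as the package's
documented defaults, config-exposed — are: DEL/DUP/INV match a truth record
of the same type at ≥ 50% reciprocal overlap (duplications are deliberately
assessed under the same overlap conditions as deletions/inversions);
insertions match within 20 bp of the anchor with global-alignment identity
≥ 0.8 of the inserted sequences (computed as 1 − edit distance / max
length). Matching is greedy one-to-one by descending overlap/identity, so
nothing is double-counted, and per-stratum counts obey tp + fn = |truth
stratum| and tp + fp = |calls in stratum|. Sensitivity = tp/(tp+fn),
precision = tp/(tp+fp); empty strata report NaN. PR curves re-evaluate
after setting calls with fewer than t supporting reads to missing, for
ascending t. A record belongs to the repeat stratum when ≥ 20% of its span
overlaps the repeat annotation (insertions: anchor containment).
Population-level record filters: homozygous-ALT count ≥ 4 and
distinct-caller support ≥ k.

## Genic annotation and statistics

Labels are mutually exclusive with precedence cds > gene (non-coding genic)
> upstream5kb > intergenic. Upstream windows are strand-aware 5 kb blocks
5′ of the gene start; overlapping windows are unioned. Feature tracks are
merged into flat boundary arrays per chromosome so annotation is a pair of
`searchsorted` calls per record — this makes the randomization test cheap.

*Overlap randomization test*: each iteration re-draws every SV start
uniformly within the 100-kb genome-tiling bin containing it (length
preserved; an SV longer than its bin is pinned to the bin start and
logged), re-annotates, and records the four label proportions per SV type.
The one-sided p per (type, label) counts null proportions at least as
extreme as the observed one in the direction of the observed departure from
the null mean. *Frequency-difference test*: SVs with population frequency
exactly 1 are excluded (likely reference errors); for each type and each of
the six label pairs the null permutes labels across SVs; significance is
declared at α = 0.05/6 ≈ 0.0083. All permutation p-values use
(count + 1)/(iterations + 1), so the floors are 1/5001, 1/10001 and (for
the Mantel test at 999 permutations) 0.001. Because the direction is chosen
from the data, a calibrated two-sided decision doubles the one-sided p;
the calibration tests verify nominal size under that rule. Term enrichment
is a plain hypergeometric tail test (terms under the minimum gene count —
20 for broad ontologies, 10 for domain sets — are skipped; Bonferroni by
the number of terms tested, capped at 1); a conditional, graph-aware
ontology test is deliberately out of scope, so p-values for nested terms
are correlated.

## Transposable elements

Variant sequences of DEL/INS ≥ 100 bp are matched against a TE library by
local alignment; a hit must cover ≥ 80% of the query *and* ≥ 80% of the TE
sequence (aligned-length coverage), and the best-scoring passing hit's
classification is assigned. The strict subject coverage is what keeps
truncated or partial matches unannotated. The internal aligner (biotite,
BLAST-like scoring, edlib infix pre-screen) serves desk-scale libraries; a
12-column tabular alignment report can be imported instead, so external
alignment output drops in unchanged.

TIR/TSD detection operates on the inserted sequence plus ≥ 30 bp flanks.
For end offsets a, b ≤ 5 bp it compares `ins[a+k]` with the complement of
`ins[n−1−b−k]`, and selects the repeat length maximizing a changepoint
score (+1 per match, −2 per mismatch — the likelihood-ratio weighting for
~5% within-TIR divergence against 75% background mismatch), subject to
length ≥ 10 and ≤ 20% mismatches; exact score ties prefer the longer
repeat (terminal repeats are maximal by definition) and end offsets are
mildly penalized so the repeat stays anchored at the insertion boundaries.
The TSD is the longest 2–10 bp direct repeat shared by the two flanks.
TIR match proportion = 1 − edit distance / max length of the left TIR vs
the reverse complement of the right TIR — exactly symmetric and equal to
matches/columns for substitution-only divergence. The excision analysis
partitions samples by their homozygous allele at a three-allele site
(reference / TE insertion / short footprint insertion beginning with the
TSD), computes per-group SNV alternate-allele frequencies in a surrounding
linkage block, and counts SNVs with |Δ frequency| > 0.5 per group pair.

## Population genetics

Variant filters: SNV mode keeps minor allele frequency ≥ 0.05, missingness
≤ 0.4, heterozygosity ≤ 0.1; SV mode drops duplications/inversions and
records with homozygous-ALT count < 4 or missingness ≥ 0.4 (note the
strict boundary). The distance is allele-sharing 1 − IBS, i.e.
mean(|g_i − g_j|)/2 over shared non-missing 0/1/2 genotypes — pinned as
the package's definition since "pairwise distance" tools offer several
flavors. Neighbor joining follows Saitou–Nei with ties broken toward the
smallest sample-index pair; branch lengths may be negative and are left as
computed; topology identity with a brute-force 5-taxon minimum-evolution
search is asserted on additive matrices. Bootstrap support resamples
variant columns with replacement, rebuilds the tree, and counts replicate
trees containing each internal edge of the reference tree as an unrooted
bipartition. The Mantel statistic is the cross-product
Z = Σ_{i<j} d1·d2 with the null obtained by jointly permuting rows and
columns of d2; the two-sided p compares |Z − mean(Z_perm)| against the
permuted values.

## The synthetic-data generator

Defaults encode the study design the package targets: 102 inbred samples
(heterozygosity 0), 17 of them with ~12× long-read data, weak structure
from k = 5 subpopulations (Balding–Nichols per-variant subpopulation
frequencies at Fst 0.15, Dirichlet(0.3) admixture), an SV spectrum
dominated by small deletions/insertions (~290 events across four size
classes), long-read calls with Gaussian breakpoint jitter (sd 5 bp,
truncated at ±50) and 8% insertion-sequence error, short-read caller
profiles with per-type sensitivities in the 0.05–0.65 range, 2 bp jitter
and zero sensitivity for insertions > 1 kb, and a genotyper model with
per-type sensitivity/precision (DEL 0.60/0.85, INS 0.45/0.75, DUP and INV
deliberately poor) and Poisson read support (mean 10 for confident calls,
2 for false calls; a genotyping failure is emitted as a near-zero-support
hom-ref call, so the standard two-read filter converts it to missing).
The genome itself is desk-scale: 4 chromosomes × 500 kb with 55 genes/Mb,
40% repeat tracts and embedded N gaps — a deliberately small arena chosen
so the full pipeline runs in seconds; counts scale linearly with
`chrom_len`/`n_chrom`. MITE-scale insertions (~50% of 198–681 bp
insertions) are built from per-family canonical elements
(TIR + core + reverse-complement TIR, TSD TA or TAA) with a few
substitutions per copy; the element lands immediately after a TSD
occurrence in the reference, duplicating it, and the TIR–core junction is
forced to break the inverted repeat so the declared TIR length is the
sequence-level truth. One TE site carries a third allele: a 6 bp insertion
of TSD + 4 repair bases, the excision footprint, with sample groups of
roughly 70/10/20%.

What the generator does **not** emulate: sequence composition of a real
genome (GC structure, tandem repeats, segmental duplications), mapping
artifacts and systematic per-locus genotyping bias (errors are independent
given the record), linked variation outside the constructed excision block,
read length/quality distributions, and genome-scale variant counts.
Passing tests therefore demonstrate the correctness and calibration of the
algorithms under controlled error models, not performance on real data.

## Problem sizes and known limitations

The test suite and the acceptance script run the full pipeline at the
desk-scale genome above (seconds per simulated study; the whole suite in
under two minutes). Two consequences are worth stating plainly. First,
with only ~150–180 SVs surviving the population filters, SNV-vs-SV
structure comparisons carry limited information under deliberately weak
structure: the Mantel test between truth genotype distances and an
independent SNV set is usually at its permutation floor, but on unlucky
seeds the genotyped (error-bearing) SV matrix yields a non-significant p,
and tree-level bipartition sharing stays low — a power limitation of the
small variant count, not an algorithmic defect (supports and shared-split
fractions rise directly with variant numbers). Second, TIR boundary calls
are ambiguous when both allowed mismatches fall within the last few bases
of the repeat; the changepoint scoring resolves all other configurations,
and recovery is ~98–99% over the generator's MITE distribution. Other
limitations: the split aligner models exactly one event per call
(two-gap/multi-event alignments fall back); duplications and inversions
are handled through normalization, merging and benchmarking but are
excluded from refinement and population analyses by design; and the
enrichment test ignores ontology structure.
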