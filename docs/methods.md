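# Methods

## Scientific setting

A stress-activated transcription factor such as p53 binds thousands of
genomic sites, yet different stresses (a growth-arrest-biased drug versus an
apoptosis-biased one) activate different target-gene programs.  One candidate
explanation is that post-translational modification of the chromatin-bound
factor — here phosphorylation of serine 46 versus serine 15 — differs between
treatments even where total binding does not.  The pipeline quantifies this
from ChIP-seq: it compares total-antibody binding between two conditions,
asks how much of that binding carries each phospho-mark, relates the
phospho-marked fraction to binding strength, and intersects
condition-preferential phospho-binding with treatment-specific expression
changes.

## Pipeline model and assumptions

**Tags and coverage.**  The unit of evidence is a uniquely mapped read's 5'
position plus strand.  Tags are directionally extended to the sequencing
fragment length (default 133 bp, a library-prep property, configurable) and
coverage is the per-base count of overlapping extended fragments, averaged
over 10 bp windows for export.  Duplicate tags are retained; no
deduplication is applied.  The final partial window of a chromosome
averages over the bases that exist rather than zero-padding.

**Normalization.**  Libraries are compared only after downsampling every
library, uniformly at random without replacement, to the depth of the
smallest one.  Normalization happens before artifact filtering, matching
the processing order of the study design the pipeline follows.

**Peak calling.**  The caller is a deliberately small local-Poisson scanner,
not a re-implementation of a production caller: windows of twice the
extension length slide in steps of the coverage window; the observed count
k of extended fragments overlapping a window is tested against
P(X >= k; lambda_local) with lambda_local the maximum of the genome-wide
rate and rates from 5 kb and 10 kb windows centred on the candidate, all
estimated from the treatment library itself (the design uses no input
chromatin control).  Expected counts scale with (window + ext - 1), the
span of fragment start positions that can touch a window.  Significant
windows (default p < 1e-7) within one extension length merge into a peak;
the summit is the leftmost position of maximal fragment depth (a
deterministic tie-break), the height is that depth, and the peak p-value is
the smallest member-window p.  A `min_height` post-filter is exposed
(default 1) because the emergent minimum height depends on depth.
Phospho-specific peak sets are restricted to sites bound by the total
antibody in either condition before any downstream comparison.

**Occupancy.**  Reads-per-peak (RPP) is the count of extended normalized
tags overlapping a peak by >= 1 bp.  Between-condition agreement is the
square of the Pearson correlation of RPP over the site-level union of
peaks, computed on raw counts (no log transform; a transform can be applied
by the caller).  Peaks are *common* when they overlap (>= 1 bp) a peak of
the other condition and *preferential* otherwise; common-versus-preferential
and peak-versus-background contrasts use the two-sample Kolmogorov–Smirnov
test with the asymptotic null.  Background occupancy comes from uniformly
placed random regions of peak-core size.  For the binding-strength versus
modification relationship, union sites are ranked by the mean total-RPP of
the two conditions (the ranking condition is not dictated by the design;
the mean is symmetric and deterministic), split into five near-equal bins
(remainder to the lowest bins, RPP ties broken by coordinate), and each
bin's value is the fraction of its sites overlapping a phospho-specific
peak.

**Region annotation.**  The genome is partitioned into five categories —
TSS-flank (5 kb upstream of the TSS plus first exon and first intron,
strand-aware), intragenic (remaining exons and introns), 5 kb downstream,
5–25 kb flank, and intergenic (everything else) — with the fixed precedence
TSS-flank > intragenic > downstream > flank > intergenic applied across all
transcripts, so the partition is exact and promoter-like labels win where
isoforms or neighbouring genes collide.  Peaks take the single category of
their summit.  Enrichment over the genomic nucleotide distribution is a
one-sided binomial tail per category, Bonferroni-corrected across the five
categories; the test behind the original figure's asterisk is not
documented, so the binomial choice is this package's and is flagged in the
report.  Peak-to-gene assignment is summit-in-[tx_start - 25 kb,
tx_end + 25 kb), inclusive on the left, exclusive on the right,
many-to-many.

**Motif scanning.**  The response element is two RRRCWWGYYY decamer
half-sites sharing one 4x10 log2-odds matrix (allowed bases uniform within
each degenerate class, 0.01 probability for disallowed bases, uniform
background), with a configurable spacer (default 0, the modern consensus).
Scanning a 200 bp peak core (summit +/- 100 bp) evaluates every position,
strand and spacer and keeps the best hit at or above threshold; ties prefer
the leftmost position then the + strand.  Because the published scanner's
default matrix and threshold are defined only in earlier work, the default
threshold here is calibrated, not copied: the frozen value 10.16 is the
0.995 quantile of best scores over 10,000 seeded random uniform 200-mers
(`calibrate_threshold`), giving a per-region false-positive rate of ~0.005,
under the 0.01 design bound.  N bases score the column minimum; other
ambiguity codes are rejected.  The published 86%/88% motif fractions belong
to the deposited data and are not parity targets; the mechanism is.

**Expression integration.**  The pipeline consumes an already-normalized
log2 gene-level matrix with a (condition, timepoint, replicate) design.
Replicates are averaged per timepoint and the change is mean(24 h) -
mean(0 h) on the log2 scale.  Bound genes changing at least 1.7-fold
(inclusive, per treatment) are counted; bound genes' (change_A, change_B)
profiles are clustered by Lloyd k-means (k = 10) under the
1 - uncentered-correlation distance with L2-normalized mean centroids
(spherical k-means, so the objective is non-increasing), seeded k-distinct
point initialization, 10 restarts keeping the best objective, and empty
clusters re-seeded from the worst-fit point.  Differential-PTM candidates
are peaks with (pS46 RPP_B + 1)/(pS46 RPP_A + 1) >= 2 (the pseudo-count
guards zeros; the 2-fold default follows the validated examples) whose
assigned gene satisfies |change_B - change_A| >= log2(1.2); the original
report does not print its exact selection formula, so both thresholds are
configuration keys and the interpretation of "differs 1.2-fold between
treatments" as a difference of log2 changes is this package's.

## Synthetic study generator

The generator emulates the study design at desk scale: 2 chromosomes x
500 kb, 60 gene models, 120 shared binding sites, three antibodies x two
conditions, and a duplicated two-timepoint expression matrix.

* **Site strengths** (expected fragments per total library) follow a
  shifted log-normal, 30·(1 + LogNormal(0, 0.8)), so every site carries at
  least ~30 expected fragments at >= ~20x enrichment over background — the
  regime in which the caller is designed to be essentially lossless, which
  makes downstream comparisons interpretable rather than caller-limited.
* **Fragments** center uniformly within +/- 66 bp of the site; the recorded
  tag is the 133 bp fragment's 5' end on a random strand, so directional
  extension reconstructs the fragment.
* **Phosphorylation is thinning**: a site-bound protein is phosphorylated
  with probability f, so each phospho library keeps each site fragment
  independently with f (pS15: 0.5 in both conditions; pS46: 0.1 at baseline
  and 0.5 in condition B at the *responsive* sites).  This is the simplest
  process consistent with a fixed per-site modified fraction of bound
  protein.
* **Responsive sites** are the strongest 25% of sites; each sits inside a
  distinct host gene, and those genes receive a true +1 log2 expression
  change in condition B.  Tying responsiveness to strength is what produces
  the top-quintile contrast between conditions that the analysis is built
  to detect.
* **Background** is homogeneous Poisson at 0.01 tags/bp for the total
  libraries, topped up per phospho library so expected depths match across
  antibodies (library preps are sequenced to similar depth; the nonspecific
  fraction is larger where specific material is scarcer).
* **Expression noise** is Gaussian with sd 0.05 per replicate on the log2
  scale, the technical-duplicate regime of RMA-summarized arrays.  At the
  miniature's gene density (10x the human genome's, so each peak has
  several 25 kb neighbours) this keeps the 1.2-fold between-treatment
  selection threshold at ~3.7 sd of a null gene's measured difference,
  so the candidate list reflects design, not replicate noise.
* A consensus response element is implanted at every site center (can be
  disabled), and every draw flows from a single seed: one config + seed
  pair yields a byte-identical bundle.

**What the generator does not model** — and what passing tests therefore do
not show about real data: mappability and repeat structure, GC and
fragment-size biases, PCR duplicates, sequencing error, chromatin input
structure, biological replicate variance in expression, and real gene
architecture.  Recovery results certify the pipeline's inference logic
under its own assumptions, not performance on deposited reads.

## Numerical and reporting choices

* Coordinates are 0-based half-open throughout; overlap means >= 1 shared
  base; minus-strand 5' position is BED end - 1.
* Percentages derived from count pairs are rounded to the nearest integer.
* Peak p-values are clipped into (0, 1] at the smallest positive float.
* Correlations on constant vectors, medians of empty classes, and windows
  shorter than a motif site are reported as errors or missing values, never
  silently coerced.
* The sizes used by the shipped analysis and acceptance runs are the
  generator defaults above; they complete in seconds per seed.

## Known limitations

The caller is not a MACS substitute-in-kind: no fragment-shift model, no
control library, no FDR by sample swap, and peak counts on the original
deposited sequencing data are expressly out of scope.  The five-category map materializes
per-base label arrays, which is exact and fast at megabase scale but
memory-hungry at full-genome scale.  The motif model is consensus-derived
rather than data-derived.  Functional annotation clustering of candidate
genes depends on an external service and is out of scope.
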