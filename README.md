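# phosphobind

Genome-wide comparison of **total** and **phospho-specific** transcription-
factor chromatin binding between two treatments, integrated with expression
changes — a desk-scale ChIP-seq analysis pipeline built around the p53
serine-46/serine-15 phosphorylation question: when two stresses produce the
same binding landscape but different transcriptional programs, is the
*modification state* of the bound factor what differs?

The pipeline runs from aligned tags (BED6) to candidate genes:

1. **Normalization** — every library uniformly downsampled to the smallest
   depth.
2. **Peak calling** — tags extended to the fragment length (133 bp);
   sliding windows tested against a local Poisson background,
   `P(X >= k; lambda_local) < 1e-7` with
   `lambda_local = max(lambda_genome, lambda_5kb, lambda_10kb)`.
3. **Occupancy comparison** — reads-per-peak (RPP) per site,
   between-condition `R^2`, common/preferential classification with
   Kolmogorov–Smirnov contrasts, and quintile-binned phospho fractions
   (fraction of total-binding sites carrying a pS15/pS46 peak, by binding
   strength).
4. **Region annotation** — exact five-category genome partition
   (TSS-flank / intragenic / 5 kb downstream / 5–25 kb flank / intergenic),
   binomial enrichment, peak-to-gene assignment within the transcript or
   25 kb.
5. **Motif scanning** — bipartite RRRCWWGYYY x2 position-weight-matrix
   scanner over 200 bp peak cores, threshold calibrated to a 0.5% false
   positive rate per region.
6. **Expression integration** — log2(24 h / 0 h) changes per condition,
   1.7-fold bound-and-changed counts, k-means clustering under uncentered
   correlation (k = 10), and differential-pS46 candidates: peaks with a
   >= 2-fold pS46 RPP ratio between conditions whose genes differ
   >= 1.2-fold in expression change.

A fully truth-annotated **synthetic study generator**
(`phosphobind.simulate`) stands in for the deposited sequencing data: two
conditions x three antibodies over shared binding sites, phospho libraries
as thinned subsets of the total-binding fragment process, and an expression
matrix in which the strongest sites' host genes respond to one condition
only.  See `docs/methods.md` for the model and its limits.

## Worked example

The numbered drivers under `analysis/` run the whole study on a generated
miniature dataset (2 x 500 kb genome, 60 genes, 120 sites, six libraries of
~18,500 tags):

```sh
cd analysis
python 01_simulate.py --seed 0
python 02_call_peaks.py --seed 0
python 03_compare_occupancy.py --seed 0
python 04_annotate_and_scan.py
python 05_integrate_expression.py --seed 0
python 06_evaluate_recovery.py
```

Output of the seed-0 run (abridged):

```
normalized all libraries to 18353 tags
total p53, condition A: 119 peaks
total p53, condition B: 119 peaks
pS46, condition A: 3 peaks at total-p53 sites
pS46, condition B: 30 peaks at total-p53 sites
119/119 condition-A peaks common (100%)
R^2 total A vs B: 0.89
R^2 pS15 A vs B: 0.81
R^2 pS46 A vs B: 0.38
top-quintile pS46 fraction: A=0.13  B=1.00
100% of binding sites contain a consensus response element
condition B: 30/60 bound genes changed >= 1.7-fold (50%)
53 binding sites close to 29 unique genes show B-preferential pS46 binding
sensitivity 0.992, FDR 0.000
Spearman(RPP, true strength) = 0.95
candidate precision 1.00, recall 0.97
```

Reading this: total binding is nearly identical between conditions (every
condition-A peak recovered in B, `R^2 = 0.89`), pS15 tracks total binding in
both conditions, but pS46 binding is condition-B-enriched — ten times more
pS46 peaks in B, a much lower between-condition `R^2` (0.38), and the
strongest quintile of binding sites is pS46-marked in condition B (100%)
far more than in A (13%).  The candidate selector recovers 29 of the 30
designated responsive genes with no false positives — the miniature
analogue of a "98 sites near 94 genes" candidate list.  Tables land under
`results/`.

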