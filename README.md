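# epikit

Differential methylation, chromatin accessibility, expression, and
regulatory-network analysis for two-condition epigenomic designs, together
with a fully seeded multi-omics simulator that plants ground-truth signal
for end-to-end recovery testing.

The toolkit covers:

* **methylome** — windowed smoothing of per-CpG levels, beta-binomial
  dispersion estimation, per-CpG Wald tests, DMR assembly
  (`delta=0, minlen=200, minCG=5, dis.merge=50, pct.sig=0.5` style
  parameters), effect-size and coverage filters, and **empirical
  replicate-null calibration**: DMR counts between biological replicates
  provide the false-positive baseline for between-condition counts.
* **accessibility** — Tn5 insertion-site correction (+4 bp on the + strand,
  −5 bp on the − strand), a sliding-window Poisson peak caller,
  reciprocal-overlap + rank-concordance replicate reproducibility,
  insertion counting, and NB Wald differential accessibility
  (fold > 2, FDR < 0.01).
* **transcriptome** — median-of-ratios size factors, a shared NB Wald
  engine (also used by the accessibility module), differential expression
  (fold > 2, FDR < 0.05), TPM, and distal-element-to-gene assignment
  (nearest peak beyond 10 kb from the TSS).
* **enhancer_integration** — cross-assay classification of candidate
  regeneration enhancers (gained accessibility, distal > 2 kb, baseline
  methylation < 0.6, methylation change < 0.25) and the bundled
  reporter-assay validation table with its tally.
* **regulatory_network** — PWM scanning with *exact* p-values (dynamic
  programming over the discretized background score distribution, 0.01-bit
  bins), binomial motif enrichment with length-matched background, a
  two-component EM footprint mixture over 200-bp insertion windows
  (bound sites at posterior > 0.95), GRN assembly (bound site ∩ gained
  element → nearest upregulated gene), Wilcoxon mutant-response
  comparison, and the gRNA score
  `60·GC + 10·transcripts − 30·rel_pos + 2[pos20=G] − 3[pos20=A]`.
* **synthetic_data** — a deterministic generator for methylC tables,
  insertion BEDs, NB count matrices, a genome FASTA with planted motif
  instances, GTF annotation, MEME-style PWMs, and a `truth.json` ledger of
  every planted DMR/DAR/DE gene/footprint/edge.

## Command line

All functionality is exposed through one entry point:

```bash
epikit simulate --seed 7 --outdir sim/           # synthetic inputs + truth.json
epikit dmr --group1 a1.methylc,a2.methylc --group2 b1.methylc,b2.methylc --out dmrs.bed
epikit dmr-null --replicates a1.methylc,a2.methylc \
       --conditions "a1.methylc,a2.methylc|b1.methylc,b2.methylc" \
       --thresholds 1e-3,1e-5,1e-7 --out null.tsv
epikit atac-shift reads.bed --out insertions.bed
epikit peaks --track insertions.bed --chrom-sizes sizes.tsv --out peaks.bed
epikit dar --counts counts.tsv --design design.tsv --out dars.tsv
epikit de  --counts rna.tsv   --design design.tsv --out de.tsv
epikit enhancers --dars dars.tsv --meth0 t0.methylc --meth4 t4.methylc \
       --gtf genes.gtf --out candidates.tsv
epikit grn --dars gained.bed --genome genome.fa --pwms motifs.meme \
       --insertions t4.bed --expr rna.tsv --gtf genes.gtf \
       --design design.tsv --motif-map map.tsv --upregulated up.txt --out edges.tsv
epikit grna-score --seq ACGT... --prop 0.8 --relpos 0.2
epikit run --seed 7 --outdir out/                # full pipeline on simulated data
epikit validate-config config.json
```

`epikit run` simulates a complete input set, runs every stage, and writes
`report.json` with the replicate-null DMR table, stability fractions, the
hypomethylated-fraction of gained elements, DAR/DE concordance, the GRN
edge list, and truth-recovery precision/recall for every stage.

## Format dialects

* **methylC text**: tab-separated
  `chrom start end context ratio strand coverage`, 0-based half-open, one
  cytosine per line.  Only `CG` context is used; symmetric-strand records
  of a CpG dyad are collapsed into one record anchored at the + strand
  cytosine (summed counts).
* **BED/bedGraph** 0-based half-open; **GTF** 1-based closed on disk,
  converted at the I/O boundary — all in-memory coordinates are 0-based
  half-open.  GTF parsing is restricted to `gene` features and the
  `gene_id`/`gene_name` attributes.
* **PWMs**: MEME-like letter-probability blocks; rows are renormalized
  after pseudocount addition.
* **Count matrices**: TSV, features × samples, header row of sample names.

## Determinism

Every stochastic component draws from `numpy.random.default_rng` seeded
from the run seed; the same seed yields byte-identical output files, and
the `--threads` option never changes results.
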