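# genedist

Gene-unit definitions by **genetic distance** for gene- and pathway-based
association analysis.

## The problem

Gene-based association tests (VEGAS-style statistics, pathway enrichment,
SNP-to-gene annotation of GWAS hits) need a rule for deciding which SNPs
belong to a gene. The common practice is a fixed physical window — the gene
body ± 50 Kb is the most frequent choice — but physical distance is a poor
proxy for what actually matters: linkage disequilibrium, which decays with
*genetic* distance. Recombination is extremely uneven along the genome, so a
fixed window reaches across recombination hotspots at some genes (pulling in
unrelated neighbours) and stops short inside long LD blocks at others
(dropping truly linked variation).

`genedist` builds gene units whose flanks are defined in units of
recombination instead. For a genome-wide map of fixed 10 Kb bins carrying
sex-averaged recombination rates *r<sub>i</sub>* (cM/Mb), the
**standardized recombination rate** of bin *i* is

```
SRR_i = r_i / r̄          (r̄ = genome-wide mean rate, so mean SRR = 1)
```

Starting at each gene boundary, the flank grows outward bin by bin,
accumulating SRR, and stops at the first bin where the running sum reaches a
threshold *T* (default **SRR ≥ 2**, which yields flanks whose median
physical length is close to the familiar 50 Kb). Bins lying entirely inside
the gene body are never counted; the first counted bin is the one containing
the first base beyond the boundary, so a flank can be shorter than one bin
when that bin is recombination-rich. Genes near telomeres and centromeres,
where the map has no coverage, receive the median flank length of the
completed extensions on their chromosome instead. The result is one unit per
gene — short flanks through hotspots, long flanks through LD deserts — and a
±50 Kb comparator built by the same machinery.

The package also ships the evaluation toolkit used to compare the two
definitions: SRR-distribution and flank-length summaries, boundary
concordance, gene lists per association region (any-overlap rule) and per
top SNP (containment rule), scorecards against expert gene lists, and exact
one-tailed Fisher tests computed in rational arithmetic; plus a synthetic
generator (zero-inflated-gamma maps, random gene bodies) so the entire
pipeline is testable without external downloads.

## Worked example

Simulate a small two-chromosome genome, build both definitions, and compare
them:

```sh
genedist simulate --preset small --seed 7 --n-genes 60 --out-dir sim
genedist extend --map sim/map.tsv --genes sim/genes.bed --method srr   --out units_srr.tsv
genedist extend --genes sim/genes.bed --method fixed --out units_fixed.tsv
genedist srr --map sim/map.tsv --out hist.tsv
genedist stats --units units_srr.tsv --genes sim/genes.bed
genedist compare --units-a units_srr.tsv --units-b units_fixed.tsv
genedist fisher --table 17,1,6,12 --direction row1_higher
```

which prints

```
wrote 860 map bins and 60 genes to sim
wrote 60 gene units to units_srr.tsv
wrote 60 gene units to units_fixed.tsv
bins=860 zero=0.405 below_one=0.778 ge_threshold=0.152
n=120 median=43.6 Kb IQR=[17.6, 67.4] Kb
  < 10 Kb: 0.133   > 10 Kb: 0.867
  < 500 Kb: 1.000   > 500 Kb: 0.000
concordance(+/-10000 bp): per-extension=0.225 per-gene=0.017 over 60 genes
P = 0.000148313
```

Reading the numbers: 40.5% of the simulated map bins carry no recombination
at all and 15.2% have SRR ≥ 2 — the zero-inflated, long-tailed shape of a
real bin map. The 120 SRR-defined flanks (two per gene) have a median of
43.6 Kb, close to the 50 Kb convention, but spread from under 10 Kb (13.3%
of flanks) upward — which is exactly why only 22.5% of boundaries agree with
the fixed-window definition to within ±10 Kb, and only 1.7% of genes agree
on both sides at once. The Fisher line is the exact one-tailed p-value for a
17/18-vs-6/18 concordance table. The definition file itself is plain text,
one gene per row:

```
# coordinates: 0-based half-open; columns: chrom, left, right, name
chr1	110000	150000	SIM00001
chr1	320000	460000	SIM00002
```

The same operations are available as a library (`genedist.standardize`,
`genedist.build_gene_units`, `genedist.fisher_exact_one_tailed`, ...); see
the docstrings and `docs/methods.md`.

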