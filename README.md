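# qtlgsa — pathway-based QTL/microarray gene set analysis

`qtlgsa` identifies biological pathways associated with a quantitative
trait by combining three data sources: a strain-comparison expression
matrix, pathway gene sets (GMT), and the genomic intervals of the trait's
quantitative trait loci (QTL). Instead of hunting for individual
differentially expressed genes inside QTL regions — which misses genes
with moderate but coordinated changes — it scores each pathway *and* the
sub-pathway formed by intersecting the pathway with the QTL gene set, and
calls a pathway trait-associated only when its QTL-restricted sub-set is
both significant at a controlled false discovery rate and more significant
than the pathway as a whole.

It is aimed at quantitative geneticists working with inbred strain panels
(or any two-class design) who have QTL intervals from linkage or
association studies and want pathway-level candidates rather than single
genes.

## Method

For a two-group comparison (high- vs low-phenotype strains), the
gene-level statistic is the log2 fold change of group means. For a gene
set with measured members `x̄` (mean statistic) and size `n`, against the
background of all measured genes with mean `μ` and population standard
deviation `σ`, the set statistic is

```
z = (x̄ − μ) / sqrt(σ² / n)
```

with p-values from the standard normal. Three direction variants are run:
**U** (signed statistics, upper tail — coordinated up-regulation), **D**
(signed, lower tail), and **B** (absolute statistics, upper tail —
bi-directional change).

Let `Q` be the union of genes overlapping any of the trait's QTL
intervals (flanking markers when known, otherwise peak ± 20 Mb; closed
1-based coordinates). For the `m` retained pathways `G_i`, the sub-set
p-values `P(G_i ∩ Q)` are sorted ascending and the pathway at rank `i` is
significant iff

```
P(G_i ∩ Q) < min{ P(G_i), i·α/m }
```

i.e. it must clear the Benjamini–Hochberg critical value *and* beat its
own whole-pathway p-value. Evidence from multiple strain comparisons is
combined by the per-pathway maximum p-value, and overall significance
additionally requires the pathway to be flagged in every single
comparison. Discoveries are always a subset of the plain BH step-up
discoveries at the same α.

## Worked example

Generate a synthetic bundle (2,000 genes, 20 pathways, QTL regions
covering 30% of the genome, one pathway spiked with a +1.0 log2 shift in
its 20 QTL-intersection genes) and analyze it:

```
$ qtlgsa simulate -o demo7 --seed 7 --n-genes 2000 --n-pathways 20
bundle written to demo7; run with: qtlgsa run -c demo7/config.yaml
$ qtlgsa run -c demo7/config.yaml
INFO qtlgsa.preprocess: retained 20 of 20 gene set(s)
INFO qtlgsa.intersect_test: dropped 5 pathway(s) with QTL intersection < 10
INFO qtlgsa.intersect_test: m=15 retained pathway(s), 1 significant
INFO qtlgsa.pipeline: wrote results for 15 pathway(s) to demo7/results
15 pathway(s) tested, 1 significant (alpha=0.05); results in demo7/results
```

The top of `demo7/results/results.tsv` (first ten columns):

```
set_name  category   n_genes  n_in_qtl  direction  max_sub_p               max_whole_p             rank  critical_value         significant
pw001     Simulated  40       20        U          1.3115865763480227e-07  1.6216637554240997e-05  1     0.0033333333333333335  True
pw012     Simulated  40       14        U          0.01886974365542265     0.10631786095056134     2     0.006666666666666667   False
```

The spiked pathway `pw001` is recovered: its 20-gene QTL sub-set scores
z ≈ 5.2 (p ≈ 1.3e-7), far below both the rank-1 critical value
0.05/15 ≈ 0.0033 and the whole-pathway p-value 1.6e-5, and is labelled
**U** (up-regulated in the high-phenotype group). `pw012` is the
next-ranked pathway but clears neither threshold. `rank` and
`critical_value` refer to the reported direction variant's combined
ranking. `qtlgsa plot -r demo/results/results.tsv -o demo/sorted_p.png`
draws the sorted maximum p-values, red where the sub-pathway beats the
whole pathway and blue otherwise.

Real analyses replace the simulated files with: an expression TSV plus a
sample→group map, a GMT file, a 4-column gene annotation TSV, and a QTL
table (`qtl_name trait chromosome peak_bp flank_start_bp flank_end_bp`);
optional probe→gene and replicate maps enable control-probe filtering,
triplicate averaging and max-expression probe collapsing. See
`docs/methods.md` for formats and parameter details.

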