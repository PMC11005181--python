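# chromlink

Separating developmental from housekeeping gene regulation in
three-lineage multi-omic data: dominance-index classification of genes
and chromatin windows, genome/TAD architecture statistics, distal
enhancer-gene linking through the chromatin abundance coefficient, and
TF motif-repertoire comparison — with a synthetic-data generator that
plants all of the structure, so every stage is testable end to end.

## The problem

At gastrulation, pseudo-bulk profiles of the three germ layers
(ectoderm, endoderm, mesoderm) jointly measure the transcriptome, GpC
chromatin accessibility and CpG methylation. Two regulatory programs
coexist: *developmental* genes are expressed in one lineage, sit
isolated in the genome, and are driven by distal lineage-specific open,
hypomethylated regions (putative enhancers); *housekeeping* genes are
expressed evenly, cluster densely, and are regulated proximally. This
package implements the statistics that make that separation
quantitative, for analysts working with per-lineage expression tables,
window-level accessibility/methylation counts, TAD annotations and
enriched-motif lists.

## The core statistic

Everything rests on the Berger-Parker dominance index of a per-lineage
triple on the linear scale,

```
Dom = max(GE_i) / (GE_1 + GE_2 + GE_3),   Dom in [1/3, 1]
```

with Dom >= 0.6 defining lineage dominance (DEG; DAR/DhMR for windows)
and Dom <= 0.34 near-evenness (SEG; SAR/ShMR), both validated by
permutation tests. Distal linking uses the chromatin abundance
coefficient: for vicinity half-width `V`, each gene's open-region count
near its TSS is normalised by the expressed genes there,
`f_i = N(V_i)/Ng(V_i)`, and `CAC(V)` is the Pearson correlation of
grouped `f` against mean expression. The zone of influence `Z*` is the
grid `V` maximising the correlation while region density stays high, and
the link catalogue pairs genes with regions within `Z*` *in the same
TAD* — no chromatin-contact data required.

## Worked example

```
python examples/04_link_enhancers.py
```

prints (seed 1):

```
CAC r by vicinity (kB): {20: 0.35, 40: 0.63, 80: 0.67, 120: 0.85, 160: 0.84, 200: 0.69, 300: 0.68, 400: 0.75}
zone of influence Z* = 120 kB (r = 0.85, p = 3.7e-16)
catalogue: 431 ectoderm gene-DAR links for 30 genes, median |distance| 49,650 bp, 0% beyond 100 kB
```

The benchmark plants open regions uniformly within ±100 kB of dominant
genes at counts proportional to expression; the scan's correlation peaks
at the 120-kB grid point flanking that scale, and the TAD-constrained
catalogue keeps the links inside the planted zone. The other examples
cover gene classification (`01`), genome/TAD architecture (`02`), region
calling and DAR-DhMR clustering (`03`) and motif repertoires (`05`);
each prints the numbers it computes and one line on what they mean.

A thin CLI wraps the same stages for shell use:

```
chromlink --out-dir run simulate
chromlink --out-dir run classify-genes --expression run/expression.tsv
chromlink --out-dir run call-regions --acc run/acc_windows.tsv --meth run/meth_windows.tsv
chromlink --out-dir run link --classes run/classes.tsv --annotation run/annotation.tsv \
    --expression run/expression.tsv --dars run/dars.bed --tads run/tads.bed --lineage ect
```

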