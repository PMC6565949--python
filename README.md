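# lncnet

Downstream analysis for small-replicate bulk RNA-seq profiling of long
non-coding RNAs: from a transcript × sample count matrix to differential
expression tables, an lncRNA–mRNA co-expression network with
permutation-tested Pearson edges, cis-target annotation, and
enrichment/overlap reports.

The package targets the common design in which two conditions (for example
control and disease-model animals) are sequenced with very few biological
replicates — three per group — and the goal is to nominate lncRNAs that may
regulate protein-coding genes, either through strong co-expression or
through genomic proximity.

## Method

**Normalisation.** Counts become RPKM:
`RPKM[g,s] = counts[g,s] · 10⁹ / (L_g · N_s)` with `L_g` the exonic length
and `N_s` the per-sample mapped-read total.

**lncRNA candidates.** A transcript is a candidate lncRNA iff its exonic
length exceeds 200 nt, it has more than two exons, and all three
coding-potential verdicts (CPC-like, CNCI-like, Pfam-like) call it
non-coding.

**Differential expression.** Per transcript, a Welch two-sample t-test on
log₂(RPKM + 1) with Benjamini–Hochberg adjustment across all transcripts.
A transcript is differentially expressed when its group-mean ratio
(max/min) is ≥ 2 and the adjusted p < 0.05; fold changes are reported
signed (negative = down in the case group).

**Co-expression network.** For every DE-lncRNA × DE-mRNA pair, the Pearson
correlation r across all samples. With n < 8 samples an asymptotic p-value
for r is unreliable, so significance comes from a shuffling null: all n!
rearrangements of one profile are enumerated (720 at n = 6) and
`p = #{|r_perm| ≥ |r_obs|} / n!`; above the exact regime a seeded
Monte-Carlo estimator `p = (1 + #hits) / (B + 1)` is used. An edge is
retained when `|r| ≥ 0.95` and `p < 0.05`. Retained edges form a bipartite
graph; node degree identifies hub lncRNAs.

**Annotation layers.** Genes whose locus lies within 10 kb of a lncRNA
locus (either flank, boundary inclusive) are candidate cis-regulated
targets. Gene-set over-representation uses the upper-tail hypergeometric
test against a stated universe, and 2–3-way set-overlap (Venn) tables
compare DE genes with external disease-gene lists.

Because real sequencing data are not required, a seeded synthetic-data
generator (`lncnet.simulate`) produces negative-binomial count matrices
with planted DE transcripts and planted near-perfectly-correlated
lncRNA–mRNA pairs, together with the ground truth, so every stage of the
pipeline is testable offline.

## Worked example

A default run simulates a 3-vs-3 fixture (120 transcripts: 20 lncRNAs,
100 mRNAs, 20% planted DE at 4-fold, five planted pairs at |r| ≥ 0.99) and
pushes it through every stage:

```python
import lncnet as L

config = L.PipelineConfig(outdir="demo_run", seed=1)
summary = L.run_pipeline(config)
for key, value in sorted(summary.to_dict().items()):
    print(f"{key}: {value}")
```

prints

```
cis_calls: 1
config_hash: a65500f4354f8aa8
de_lncrna_down: 6
de_lncrna_up: 2
de_mrna_down: 7
de_mrna_up: 13
edges_retained: 65
enriched_sets: 0
lncrna_candidates: 20
pairs_evaluated: 160
seed: 1
transcripts_in: 120
```

Reading the summary: all 20 lncRNAs pass the candidate filter; 8 lncRNAs
and 20 mRNAs pass the DE filter, giving 8 × 20 = 160 candidate pairs; 65
survive the correlation cutoff with a significant exact permutation p
(the five planted pairs among them — the rest are edges among planted DE
transcripts that share the two-group mean structure). `demo_run/` then
contains the DE tables, volcano/heatmap tables, the network as SIF +
GraphML + node/edge TSVs (Cytoscape-ready), hub ranking (`hubs.tsv`),
cis-target calls and the run summary. The same pipeline runs from the
shell:

```
lncnet run --config config.yaml
lncnet simulate --outdir fixture --seed 4
lncnet de --counts fixture/counts.tsv --annotation fixture/annotation.gtf \
          --manifest fixture/manifest.yaml --out de.tsv
```

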