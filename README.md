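# budmine

Mining early-flowering regulator genes from multi-genotype, multi-stage
flower-bud expression counts of two closely related woody species.

Temperate fruit and ornamental trees set their flower buds before winter and
bloom only after dormancy is released by accumulated chilling. Sibling
genotypes from a segregating cross can differ sharply in flowering time, and
so can closely related species (an early-blooming mei-like species vs a
later peach-like one). `budmine` implements, as a tested and reusable
pipeline, the comparative strategy for extracting the genes behind that
difference from bulk RNA-seq counts of flower buds sampled along the
dormancy-to-pre-flowering trajectory:

1. **Replicate-free differential expression.** Each genotype contributes one
   count library per bud stage, so DEGs are called with the exact
   conditional test for two count libraries: given `x` reads in a reference
   library of size `N1`, the count `y` in a library of size `N2` follows,
   under equal relative expression,

   ```
   p(y|x) = (N2/N1)^y (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )
   ```

   Two-sided p-values double the smaller tail; significance defaults to
   Benjamini–Hochberg adjusted `p <= 0.01` with `|log2FC| >= 1`, where
   `log2FC = log2(((y+1)/N2)/((x+1)/N1))`.
2. **Cross-genotype set logic.** Candidate early-flowering regulators are
   the genes upregulated from dormancy to pre-flowering in *every*
   early-flowering genotype while *non-upregulated* (down, non-significant,
   or undetected) in every late-flowering genotype; shared-DEG
   intersections, UpSet-style membership tables and fold-change
   correlations support the contrast.
3. **Cross-species corroboration.** Candidates are projected through an
   orthologue table (one-to-one and one-to-many) and rank-based collinear
   (syntenic) blocks into the partner species, recording for each candidate
   its orthology class, collinearity status and whether an orthologue is
   itself upregulated toward bloom.
4. **Interpretation layers.** FPKM conversion and Ward clustering of
   standardized expression patterns; rule-based transcription-factor family
   classification from protein-domain signatures; hypergeometric term
   enrichment; and degree-based hub selection in a scored protein
   interaction network.

A synthetic-data generator plants ground truth for every stage — gene
classes (shared-up, early-only-up, late-only-up, down, null), orthologue
maps with constructed collinear blocks, negative-binomial counts, and
networks with planted hubs — so the whole pipeline is testable end to end
without any downloads.

## Worked example

Run the full pipeline on a small synthetic study (2,000 genes, four
genotypes of the focal species — two early-, two late-flowering — plus one
early-blooming partner-species cultivar, five bud stages S1–S4 and P, 60
genes planted per class):

```python
from budmine.pipeline import PipelineConfig, run_pipeline
from budmine.synthetic_data import SimulationConfig, BlockSpec, HubSpec

config = PipelineConfig(
    outdir="demo",
    simulation=SimulationConfig(
        n_genes_per_species=2000, n_chromosomes=4,
        block_spec=(BlockSpec("chr1", "chr1", 51, 51, 30),
                    BlockSpec("chr2", "chr3", 11, 101, 20, "reverse")),
        class_sizes={"SHARED_UP": 60, "EARLY_ONLY": 60,
                     "LATE_ONLY": 60, "DOWN": 60},
        hub_spec=HubSpec(n_hubs=2, hub_degree=13, background_edges=60),
        seed=11),
)
run_pipeline(config)
print(open("demo/report.txt").read())
```

The report starts:

```
# Early-flowering gene mining report
seed: 11

## Differentially expressed genes per genotype
  A209: 157 up, 69 down, 2000 detected
  A318: 173 up, 72 down, 2000 detected
  A323: 150 up, 79 down, 2000 detected
  A340: 166 up, 76 down, 2000 detected
  ZaoLve: 144 up, 78 down, 2000 detected

## Cross-genotype sets
  shared upregulated: 115
  early-specific candidates: 57
```

115 genes are upregulated in both early genotypes (the planted shared-up
and early-only classes less statistical misses), and the early-vs-late
filter narrows them to 57 candidates — 57 of the 60 planted early-only
genes. The projection section then reports how many candidates have
orthologues, lie in collinear blocks, and are upregulated in the partner
species (48 of 57 here); later sections give expression-pattern cluster
sizes, the TF family table of the candidates, enriched terms (the planted
term T0001 at `p_adj = 8.5e-29`), and the two planted degree-13 network
hubs. `demo/manifest.json` records per-stage output digests; re-running
with the same seed reproduces them bit for bit.

The same flow is available from the shell:

```bash
budmine simulate --seed 11 --out bundle/
budmine deg --counts bundle/counts_pper.tsv --design bundle/design.tsv \
        --genotype A340 --ref-stage S1 --test-stage P --out deg_A340.tsv
budmine run --seed 11 --out demo/
```

## Layout

| module | contents |
| --- | --- |
| `budmine.deg_stats` | exact conditional two-library test, BH adjustment, DEG calling |
| `budmine.expression` | count/FPKM/z-score matrices, Ward pattern clustering |
| `budmine.mining` | cross-genotype set logic, membership tables, fold-change correlation |
| `budmine.comparative_genomics` | orthologue tables, tandem duplicates, collinear block chaining, candidate projection |
| `budmine.network_hubs` | scored interaction graphs, degrees, hub selection, subnetworks |
| `budmine.annotation_tf` | TF family rules and summaries, hypergeometric enrichment |
| `budmine.synthetic_data` | planted-truth fixture generator and bundle I/O |
| `budmine.pipeline` / `budmine.cli` | orchestration, manifests, report, `budmine` command |
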