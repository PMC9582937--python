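# Methods

This note documents the statistical model, the synthetic study design, the
numerical choices, and the known limitations of the package.

## The replicate-free differential-expression test

The study design provides one sequencing library per genotype × bud stage,
so replicate-aware models (negative-binomial GLMs with estimated
dispersions) are not applicable. DEGs are called with the exact conditional
test for digital expression data: conditioning on the total `x + y`, the
count `y` in the second library follows

    p(y | x) = (N2/N1)^y (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) ),

a negative binomial in `y` with `x + 1` successes and success probability
`N1/(N1+N2)`. The test depends on the library sizes only through their
ratio, and is exact for Poisson-distributed counts.

Numerics. Tail probabilities are accumulated in log space from log-gamma
terms. The numerically smaller tail is always the one summed directly: the
lower tail as a finite sum over `k = 0..y`, the upper tail by adaptive
summation upward from `y` in chunks of 256 terms until the newest term
falls 60 nats below the running total (past the mode the term ratio is at
most `rho/(1+rho)`, so the truncated remainder is bounded far below 1e-12
of the sum for `N2/N1 <= 2`). The larger tail is recovered from the
total-probability identity `1 − (smaller-side sum)`, which never cancels
because the subtracted quantity is then at most ~0.6. Both tails agree
with exact rational-arithmetic summation to better than 1e-12 relative
over the `x, y <= 50` grid at library ratios 0.5–2 (measured ~7e-14).

Conventions, each configurable:

* **Two-sided p** = `min(1, 2 × min(lower, upper))`, the standard
  construction for discrete one-parameter tests. Note this construction is
  *not* symmetric under swapping `(x, N1) ↔ (y, N2)`: the two conditional
  pmfs differ by a factor `N1/N2`, and even at equal library sizes the two
  inclusive tails contain the observed point differently (x=0, y=1 gives
  p=1 while x=1, y=0 gives p=1/2). The suite therefore asserts the
  construction and its oracle agreement, not a swap identity.
* **Fold change** uses a +1 pseudocount on both counts —
  `log2(((y+1)/N2) / ((x+1)/N1))` — in the fold change only, never in the
  test statistic, keeping the test exact while making log-ratios finite at
  zero counts.
* **Calling thresholds** default to BH-adjusted `p <= 0.01` and
  `|log2FC| >= 1`, common digital-expression practice; the gene universe
  per contrast is the detected set (`x + y > 0`).
* Multiple-testing adjustment is Benjamini–Hochberg step-up
  (statsmodels' `fdr_bh` behind a validating wrapper).

Under an all-null Poisson study the discreteness of the test makes it
conservative: the measured fraction of raw `p <= 0.01` at 20,000 genes and
equal 5×10⁶ libraries is ≈ 0.009. Under negative-binomial overdispersion
the Poisson-based test is *anti*-conservative; see the recovery discussion
below.

## Cross-genotype candidate mining

Per genotype, a dormancy-reference stage is contrasted against the
pre-flowering stage. The candidate set is

    (⋂ early genotypes: upregulated) ∩ (⋂ late genotypes: non-upregulated)

where the non-upregulated set of a late genotype is its detected universe
minus its up-calls, *plus* anything it never detected — down-called,
non-significant and absent genes all count as non-up, which matches the
near-genome-scale non-up complements this contrast produces in practice.
The matched stage pair per genotype is analyst metadata
(chilling-requirement matching is a property of the sampling calendar, not
of the counts) and is carried explicitly in `MiningDesign`.

## FPKM, standardization, clustering

`FPKM(g, s) = counts(g, s) × 10⁹ / (length_bp(g) × library_size(s))` with
the gene length taken as the longest-transcript length in the catalogue
and library sizes defaulting to count-column totals unless supplied.
Pattern clustering standardizes each gene over the selected samples
(sample variance, ddof = 1; constant rows map to zero and are flagged) and
cuts a Ward/Euclidean agglomerative tree at `k` clusters (default 5).
Cluster labels are renumbered 1..k by descending size with ties broken by
the smallest member gene id, making the labelling deterministic; a small
exhaustive within-cluster-sum-of-squares oracle defines correctness for
planted two-group instances.

## Orthology, tandem duplicates, collinearity

Orthologue tables use the species-pair TSV dialect (header
`Orthogroup<TAB>A<TAB>B`, ", "-joined gene lists) preserving one-to-many
structure; a gene may belong to at most one orthogroup. Tandem duplicates
are same-chromosome homolog pairs with rank distance in `1..max_tandem_gap`
(default 5). Collinear blocks chain cross-species match points
`(rank_a, rank_b)` per chromosome pair: strictly increasing in species A,
strictly monotone per orientation in species B, per-step rank gaps at most
`max_gap` (default 25) on both sides, minimum block size 5 — the published
defaults of the standard rank-based synteny tool. Extraction is greedy
longest-chain-first (dynamic programming per orientation), removing anchors
after each extraction and repeating; ties break by smaller start ranks,
then forward before reverse, and among equal-length chains the
lexicographically smallest anchor sequence is taken. This is a deliberate
simplification of alignment-score chaining; an exhaustive chain-enumeration
oracle with the identical criterion defines correctness and agrees on 200
random instances per run. Overlapping blocks are permitted when they share
no anchors, matching the anchor-removal semantics.

Projection reports, per candidate: orthologue list and class
(one-to-one / one-to-many / none), whether some block anchor joins the
candidate to one of its orthologues, and whether any orthologue is called
up in the partner-species contrast.

## TF families and enrichment

Family classification applies domain-signature rules (required domains all
present, forbidden domains absent, highest priority wins; remaining ties
break by family name). The shipped table covers MADS-box (SRF-TF),
AP2/ERF (AP2), RAV (AP2+B3, higher priority), MYB, WRKY, bZIP, HSF, TALE
(Homeobox+ELK), Dof, ARF and FAR1, and can be replaced wholesale from a
TSV file; equal-priority rules whose required sets nest are rejected as
ill-defined. Domain assignment itself (HMM scanning) is an input, not
computed. A curated 25-entry catalogue of early-flowering-associated TFs
of the peach/mei pair ships with the package; its family summary (6
MADS-box; 24% AP2/ERF, 12% MYB, 4% WRKY) is one of the package's frozen
verification quantities. Enrichment is the upper-tail hypergeometric
`P(X >= k)` per term (scipy), BH-adjusted across tested terms, with
zero-overlap terms skipped and the universe defaulting to all annotated
genes.

## Network hubs

Interaction edges carry integer combined scores 0–1000; the default
retention threshold is 400 (medium confidence), symmetric duplicates keep
the maximum score, self-loops are dropped and counted. Degree is the
unweighted edge count. Hub selection is either every node with degree at
least `d` or the `k` highest-degree nodes with lexicographic tie-breaks;
subnetworks are induced subgraphs within a chosen radius of a hub.

## The synthetic study design

The generator emulates the targeted study: a focal species with four
genotypes from a segregating cross (two early-, two late-flowering), a
partner species with one early-blooming cultivar, five bud stages
(S1–S4 dormancy, P pre-flowering), one library per genotype × stage.
Defaults: 10,000 genes per species on 8 chromosomes; 200 genes per planted
class (shared-up, early-only, late-only, down; the rest null); planted
log2 effect 2; baseline mean 100 expected counts at the reference depth of
5×10⁶ fragments (per-sample means scale proportionally with the configured
library size); negative-binomial counts with variance `m + α m²` at
α = 0.05 (Poisson at α = 0), the standard RNA-seq overdispersion model.
Where the emulated study does not report a value (sequencing depth,
replicate structure, class sizes), defaults were chosen once as typical of
bulk RNA-seq bud experiments and are not tuned.

Planted effects reach their full log2 value at the pre-flowering stage and
interpolate linearly on the log2 scale across intermediate stages,
reproducing gradual-rise expression patterns; the default mining contrast
therefore uses the first stage (deep dormancy) as reference so that the
planted contrast equals the configured effect exactly. Down-class genes
halve toward pre-flowering. Orthology is mostly one-to-one with a
configurable one-to-many fraction; collinear blocks are constructed
exactly as specified (matching rank windows, reversed for reverse
orientation) and the remaining orthologues are paired by random
permutation, so planted blocks are recoverable against an order-free
background. The interaction network spans the planted early-only genes:
each of `n_hubs` hubs receives exactly `hub_degree` neighbours among
non-hub nodes, and background edges are added uniformly at random subject
to a per-node background degree cap (default 5), so planted hubs are
unique degree maxima by construction. All randomness flows from the single
configuration seed through per-stage generators; equal seeds give
byte-identical bundles.

What the generator does **not** emulate: read-level artefacts, splicing,
batch effects, library-composition biases, gene-length/GC effects,
correlated expression modules, or biological replicates. Passing the
planted-truth tests therefore demonstrates the correctness of the set
logic, statistics and chaining under the stated noise model — not
robustness to every artefact of real libraries.

### Recovery at the default design

At the default conditions the candidate miner's precision is ~0.96–1.0 and
its recall sits almost exactly at 0.9 (seed-to-seed range roughly
0.87–0.93). Two effects bound recall: the fold-change estimator's sd is
≈ 0.5 at these means under α = 0.05, so ~2% of planted genes per early
genotype miss the `|log2FC| >= 1` filter; and because the exact test is
anti-conservative under overdispersion, each late genotype falsely calls
~2–5% of flat genes "up", excluding those planted genes from the
candidate set. Both are properties of the stated study conditions, which
are reported as measured.

## Verification problem sizes

The acceptance script and test suite use: the full 51 × 51 count grid at
three library ratios (7,803 cases) for oracle equivalence; 20,000 genes
for type-I control; the full 10,000-gene design over three seeds for
recovery; 200 random instances of up to 15 match points for collinearity;
ten seeds for hub recovery. These sizes make the whole verification run in
a few minutes on one CPU while keeping every estimate's Monte-Carlo error
well inside the asserted margins.

## Known limitations

* The conditional test assumes Poisson sampling; with real biological
  replication a dispersion-estimating model should replace it.
* Greedy longest-first chaining is not score-optimal chaining; blocks from
  highly duplicated regions may split differently than an e-value-scoring
  tool would split them.
* TF classification is only as good as the supplied domain table and rule
  set; the shipped rules cover common plant families, not all of them.
* One-to-many orthology is projected permissively (any orthologue
  upregulated counts as corroboration).
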