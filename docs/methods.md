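# Methods

## Scope and model

`tissuespec` analyses a transcript-level FPKM matrix over a tissue panel
sequenced as technical replicates. The statistical situation it is built
for is the weakest common one in human multi-tissue profiling: no
biological replicates, hence no variance estimate per tissue, hence no
formal test of differential or specific expression. The package therefore
implements a fold-change criterion for specificity and relies on
technical-replicate concordance, pseudocount soft-thresholding and a
low-expression filter to keep that criterion stable.

## Pseudocount and filtering

Every log-scale or ratio computation uses FPKM + c with c = 0.1. The
choice of a relatively large pseudocount is deliberate: for a transcript
with tissue values a and b, the measured fold (a + c)/(b + c) is
attenuated toward 1 as a, b → 0, so weak expressors cannot produce large,
unstable fold changes. Smaller pseudocounts (0.01 and below) make
fold-change rankings of low expressors erratic; larger ones (1.0) discard
real signal. The attenuation is exact and computable: a planted FPKM-scale
fold f at baseline b is measured as (f·b + c)/(b + c).

The low-expression filter retains a transcript iff the geometric mean of
(FPKM + c) across tissues is ≥ 1. The comparison is inclusive on the
retain side (a transcript at exactly 1 is kept). On the pseudocounted
scale the geometric mean across tissues equals the arithmetic mean of the
log2 values, so the filter is a mean-log2 ≥ 0 rule. A consequence worth
knowing: a transcript expressed in a single tissue of 14 and silent
elsewhere needs (x + 0.1) ≥ 10¹³ there to survive — single-tissue
expressors must be extremely strong, or they are filtered. This matches
the filter's purpose (stabilising fold changes), not a claim about
biology.

## Replicate aggregation

The paper-style analyses need one column per tissue; libraries are
collapsed by the geometric mean of (FPKM + c), minus c, floored at 0.
This equals averaging replicates on the log2(FPKM + c) scale on which all
downstream statistics run, so aggregation and log transform commute.
Arithmetic-mean aggregation on the FPKM scale is available
(`method="arithmetic"`) for users who prefer averaging before the
transform. Expressed-transcript detection (FPKM ≥ 1 in a library) is
deliberately per-library and pseudocount-free, because it asks a
different question (was the transcript seen at all?) than the filter.

## Specificity calls

With v_t = FPKM_t + c on the aggregated tissue matrix, a transcript is
specific to its argmax tissue t\* iff v_{t\*} / max_{t≠t\*} v_t ≥ F with
F = 2. Decisions embedded in this definition:

* the scale is pseudocounted FPKM, equivalently a log2 difference ≥ 1 —
  consistent with the fold-compression rationale above;
* the boundary is inclusive ("at least two times");
* ties for the maximum give FC = 1 and are never specific, which makes
  the call order-independent and conservative;
* at most one tissue per transcript is structural (the criterion compares
  against the max of all others), and is asserted at run time.

No FDR or specificity index (tau, TSI) is computed: without biological
replicates a test would be decorative.

## Co-expression network

The network is built on the union of TSCT/TSNT calls, using all libraries
(tissue × site) rather than aggregated columns to maximise degrees of
freedom for the correlation. Adjacency is unsigned soft-thresholding,
a_ij = |cor|^β with β = 20 (β is taken as given, not scanned for
scale-free fit). Similarity is the standard unsigned topological overlap

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

with k_i = Σ_{u≠i} a_iu and TOM_ii = 1, computed vectorised as
(A·A)_ij − 2a_ij for the shared-neighbour sum and verified in the test
suite against a brute-force triple loop at 1e−12 on random instances.

Module detection is average-linkage hierarchical clustering of 1 − TOM
followed by a **static** tree cut: connected branches below `cut_height`
(default 0.995) with at least `min_module_size` (default 60) leaves become
modules; everything else is "gray" (label 0). The full dynamic-hybrid
tree-cut algorithm is a deliberate simplification target we did not
implement; the static cut is transparent, deterministic, and sufficient
for block-structured dissimilarities. The cut height default is close to
1 because TOM dissimilarities between unrelated transcript groups
concentrate near 1 once β is large; panels with few tissues produce less
extreme dissimilarities and may need a lower cut.

Hubs are defined as a module's top `n_hubs` (default 30) members by
intramodular connectivity (sum of within-module adjacency), with ties
broken by transcript id; the hub-hub edge list is written in VisANT's
import layout (node1, node2, direction flag 0, method tag M1000, weight),
weighted by TOM when supplied and adjacency otherwise.

## Enrichment

Over-representation uses the exact hypergeometric upper tail
P(X ≥ overlap) with N = |universe|, K = |set ∩ universe|, n = |query|,
and Benjamini–Hochberg adjustment across sets. The universe defaults to
all retained (post-filter) transcripts. This is an exact, reproducible
replacement for web-service enrichment tools built on the EASE-adjusted
Fisher statistic; those report slightly more conservative p-values for
identical overlaps, so p-values are comparable in rank but not in value.
All results are reported; no significance cut is imposed.

## Sample-level summaries

PCA runs on transcript-centered (not z-scored) log2(FPKM + 0.1) values;
component signs are fixed by making each component's largest-magnitude
loading positive, so coordinates are fully deterministic. Sample
clustering uses 1 − Pearson distance and average linkage, with samples
pre-sorted lexicographically so merge ties resolve deterministically.
Both choices (centering only; distance and linkage) are our defaults
where the analysis convention is genuinely open.

## Synthetic-data generator

The generator emulates the study design the pipeline targets, with
defaults forming the reference configuration used by the acceptance
checks: 14 tissues × 2 sites, 4,500 coding + 500 noncoding transcripts,
40 planted specifics per tissue at fold 8, per-tissue co-expression
blocks of 80, replicate noise 0.1 log2 units, dropout fraction 0.16,
baseline log2-normal with mean 3 and s.d. 2 (FPKM median ≈ 8). Sample
sizes mirror the target design (tissue count, replicate structure,
roughly one transcript in six never observed). The replicate noise
default (0.1 log2 units) is a low-noise regime yielding Spearman
concordance ≈ 0.998 — cleaner than real technical replicates, whose
concordance in deeply sequenced panels is typically 0.8–0.96 — so
recovery results characterise the method, not measurement error; effect
sizes (fold 8, factor s.d. 0.5) are what we consider a clearly
detectable but not degenerate planted signal.

Construction, per transcript:

* baseline log2 FPKM μ ~ N(3, 2), shared across tissues;
* planted specifics (disjoint per tissue): baseline truncated below at
  FPKM 1, elevated by log2(fold) in the target tissue. The truncation
  makes the planted fold identifiable after pseudocount attenuation and
  the filter — consistent with the pseudocount's stated purpose of
  restricting fold-change analysis to clearly expressed transcripts;
* planted co-expression blocks (disjoint from specifics): members add
  loading · f_m(t), loading ~ U(0.8, 1.0), where block m's latent tissue
  profile f_m is one value per tissue (shared by that tissue's
  replicates). The block profiles are mutually orthogonal directions in
  tissue space, scaled so entries have RMS `module_factor_sd` (0.5):
  i.i.d. profiles over as few as 14 tissues can correlate substantially
  by chance, in which case two nominally distinct blocks would share one
  program and the planted module labels would misdescribe the data the
  generator emitted. Orthogonalisation makes the generator realise the
  structure its truth object claims. Blocks carry no mean shift, so
  members are co-expressed but not tissue-specific;
* dropouts: a `dropout_fraction` of the remaining transcripts is set to
  FPKM 0 in every library;
* libraries: tissue-level log2 truth + N(0, replicate_noise_sd) per cell;
  at zero noise replicate columns are identical and replicate aggregation
  recovers the tissue-level truth exactly.

What the generator does **not** emulate: library-size differences (FPKM
is treated as already normalised), site-specific bias (noise is
exchangeable across sites), isoform-level quantification uncertainty,
correlated baseline expression between transcripts outside planted
blocks, and any read-level process. Passing recovery tests on this
generator therefore demonstrates that the pipeline's statistics do what
they claim on data with the assumed structure — not that the assumed
structure captures everything in real tissue panels.

`simulate_gene_sets` builds one set per tissue from that tissue's planted
specifics plus ~30% random decoys, padded with random sets; it requires
`n_sets` ≥ the number of tissues so its guarantee (one enriched set per
tissue) is satisfiable, and raises otherwise.

## Recovery evaluation

Specificity sensitivity/precision score calls against the planted
specific map (a true positive is a call to the planted tissue). Module
recovery runs the network on the planted block members' log2 expression
and computes the adjusted Rand index between detected labels and planted
block membership on transcripts that carry a planted label; under the
reference configuration the called specific set per tissue (40) is below
the minimum module size (60), so the end-to-end pipeline's module stage
on called transcripts is legitimately gray there, and block recovery is
evaluated on the planted members.

## Problem sizes and numerics

The test suite and the acceptance script run the reference configuration
(5,000 transcripts, 28 libraries; network on 1,120 block members), which
completes in seconds on one CPU; unit tests use 4–8 tissue configurations
with a few hundred transcripts. Numerical choices: Spearman uses average
ranks for ties (ties are common at FPKM 0); z-scoring uses the sample
s.d. (ddof = 1) and drops zero-variance rows with a warning; adjacency
enforces exact symmetry and clips correlations to [−1, 1] before
exponentiation; TOM is clipped to [0, 1]; module labels are assigned in
decreasing size order with ties broken by cluster id; hub ties break by
transcript id.

## Known limitations

* The static tree cut under-splits nested module structure that the
  dynamic-hybrid algorithm would separate.
* Fold-change specificity has no error control; calls near the threshold
  are sensitive to the pseudocount at low expression (by design).
* The hypergeometric test treats transcripts as exchangeable; no
  transcript-length or expression-level bias correction is applied.
* With fewer than ~6 tissues the default network cut height is too high
  (dissimilarities do not concentrate near 1) and should be lowered.
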