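# tissuespec

Tissue-specific transcript calling and weighted co-expression network
analysis for multi-tissue RNA-seq FPKM compendia.

Many diseases and adverse drug reactions are tissue-specific, and so are
the transcripts — coding and noncoding — that underlie them. Given a
transcript-level FPKM matrix across a panel of tissues (each sequenced as
technical replicates, without biological replicates), `tissuespec`
identifies the transcripts each tissue expresses far above all others,
separates them into tissue-specific coding transcripts (TSCTs) and
noncoding transcripts (TSNTs) by Ensembl biotype, groups them into
co-expression modules, extracts each module's hub transcripts, and tests
the tissue-specific sets for gene-set over-representation. A synthetic-data
generator with planted ground truth makes every stage testable end to end
without any external download.

The package targets analysts working with small multi-tissue bulk RNA-seq
panels where fold change — not a replicate-based statistical test — is the
only available specificity criterion.

## Method

All analyses run on pseudocounted log-scale expression, log2(FPKM + 0.1).
The relatively large pseudocount compresses fold changes of weak
expressors, acting as a soft threshold that focuses the analysis on
clearly expressed transcripts.

1. **Replicate aggregation.** Technical replicates of a tissue are
   collapsed by the geometric mean of (FPKM + 0.1) (equivalently, the
   arithmetic mean on the log2 scale), giving one column per tissue.
2. **Low-expression filter.** A transcript is retained iff its geometric
   mean of (FPKM + 0.1) over tissues is ≥ 1; the boundary case of exactly
   1 is retained.
3. **Biotype classes.** Everything that is not `protein_coding` is
   noncoding. Raw Ensembl biotypes are consolidated by ordered rules —
   all pseudogene flavours → `pseudogene`, `TR_*` → `TR_gene`, `IG_*` →
   `IG_gene` (pseudogene rule first, so `IG_pseudogene` is a pseudogene);
   anything unmatched maps to itself.
4. **Specificity calls.** With v_t = FPKM_t + 0.1, a transcript is
   specific to tissue t\* iff

       FC = v_{t*} / max_{t ≠ t*} v_t ≥ 2

   (inclusive; ties for the maximum are never specific). Calls are
   labelled TSCT or TSNT by merged class.
5. **Co-expression network** on the called transcripts: unsigned
   soft-threshold adjacency a_ij = |cor(x_i, x_j)|^β with β = 20 across
   all libraries, topological overlap

       TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

   average-linkage clustering of 1 − TOM, and a static tree cut: branches
   below the cut height (default 0.995) with ≥ 60 members become modules,
   the rest stay "gray". Hubs are a module's top-30 members by
   intramodular connectivity, exported as a VisANT-style edge list.
6. **Enrichment.** Each tissue's TSCT set is tested against GMT gene sets
   by the exact hypergeometric upper tail with Benjamini–Hochberg
   correction, over the universe of retained transcripts.

## Worked example

```python
from tissuespec import (
    SimulationConfig, simulate_expression, classify, TransformParams,
    aggregate_replicates, filter_low_expression, SpecificityParams,
    call_specific, count_specific, replicate_concordance,
)

config = SimulationConfig(n_tissues=6, n_coding=1500, n_noncoding=150,
                          n_specific_per_tissue=25, module_size_per_tissue=0,
                          seed=7)
expr, samples, annot, truth = simulate_expression(config)
annot = classify(annot)

params = TransformParams()          # pseudocount 0.1, filter threshold 1.0
tm = aggregate_replicates(expr, samples, params)
filtered, removed = filter_low_expression(tm, params)
print(f"retained {filtered.shape[0]} of {tm.shape[0]} transcripts "
      f"({len(removed)} lowly expressed)")

conc = replicate_concordance(expr, samples, annot)
print(conc.round(3).head(3))

calls = call_specific(filtered, SpecificityParams(), annot)
print(count_specific(calls))
```

prints

```
retained 1323 of 1650 transcripts (327 lowly expressed)
          coding  noncoding
tissue
tissue01   0.998      0.998
tissue02   0.998      0.998
tissue03   0.998      0.998
cls       TSCT  TSNT  total
tissue
tissue01    20     5     25
tissue02    24     1     25
tissue03    24     1     25
tissue04    25     0     25
tissue05    20     5     25
tissue06    23     2     25
```

The filter removed the 264 transcripts simulated as unexpressed plus 63
genuinely weak expressors; replicate Spearman concordance is near 1 at the
simulated noise level; and every tissue's 25 planted specific transcripts
are recovered, split into TSCTs and TSNTs according to their planted
biotypes.

The same stages are available from the shell:

```
tissuespec simulate --out-dir data --seed 7 --gene-sets 12
tissuespec filter --matrix data/expression_fpkm.tsv --samples data/samples.tsv --out-dir out
tissuespec specific --tissue-matrix out/tissue_matrix_filtered.tsv \
    --annotation data/annotation.tsv --out-dir out
tissuespec run --config pipeline.yaml      # end-to-end with a manifest
```

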