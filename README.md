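# regtarget

Calling transcription-factor **direct targets** by integrating ChIP-seq
binding with knockdown RNA-seq differential expression.

A transcription factor (TF) that drives a disease program — e.g. a
constitutively active oncogenic TF in an aggressive tumour subtype — leaves
two measurable footprints: where it binds (ChIP-seq peaks) and what changes
when it is depleted (differential expression after siRNA knockdown).
Neither alone identifies *direct* regulation: binding without an expression
response may be non-functional, and expression changes without nearby
binding are likely indirect. `regtarget` is the integration layer between
the two, for computational biologists who already have peak calls and a DE
table and want a reproducible, calibrated path from those to a
direction-split direct-target list and its pathway enrichments.

## The analysis

Given replicate peak sets, a TSS annotation, and a knockdown-vs-control DE
table, the pipeline:

1. **Replicate concordance & high-confidence peaks** — peaks are paired
   one-to-one across replicates by ≥1-bp overlap; concordance is
   `n_shared / min(n_a, n_b)` (QC threshold 0.8), and paired peaks merge
   into high-confidence sites (union interval, higher-scoring summit).
2. **DE filtering** — retain transcripts with `|log2FC| > log2(2.0)`
   (strict), after removing chrX/chrY transcripts; classify by direction
   (down upon knockdown ⇒ activated by the TF, up ⇒ repressed).
3. **Distance enrichment** — for every annotated autosomal transcript,
   compute the distance from its TSS to the nearest high-confidence peak
   summit; compare the DE transcripts' distance ECDF with the annotated
   background by a two-sample Kolmogorov–Smirnov test
   (`D = sup|F₁ − F₂|`; asymptotic `Q((√nₑ + 0.12 + 0.11/√nₑ)·D)` or exact
   permutation p),
   per direction.
4. **Direct-target calling** — a filtered DE transcript with a peak within
   **50 kb** of its TSS (inclusive) is a direct target; report
   activated/repressed sets, the fraction of DE transcripts within the
   cutoff, and the cross-sample intersection.
5. **Gene-set enrichment** — hypergeometric upper-tail overlap
   (`P(X ≥ k)` for X ~ Hypergeom(N, K, n)) of each direction's targets
   against GMT collections, with Benjamini–Hochberg FDR q-values.

Peak signal utilities (summit-window RPM quantification, pairwise Spearman
correlation, Ward/average hierarchical clustering, consensus-motif
enrichment against a shuffled null) and a seeded synthetic-data generator
with planted ground truth round out the package. See `docs/methods.md` for
the full model description and design rationale.

## Worked example

Generate a synthetic study with planted ground truth (two samples, 50
planted direct targets each within 50 kb of their TSS, background peaks
≥ 100 kb from every TSS, 50 DE-but-not-target decoys) and run the full
pipeline on it:

```console
$ regtarget simulate --scenario separated --seed 1 --outdir demo
wrote scenario 'separated' (seed 1) to demo
run it with: regtarget run --config demo/run.yaml --outdir demo/results

$ regtarget run --config demo/run.yaml --outdir demo/results
sampleA: concordance=0.921 highconf=293 de=100 targets=50 fraction_within=0.500
sampleB: concordance=0.930 highconf=294 de=100 targets=50 fraction_within=0.500
summary written to demo/results/summary.json
```

Reading the output: each sample's replicates reproduce ~92–93% of the
smaller replicate's peaks (passing the 0.8 QC gate), 293–294 peaks survive
as high-confidence sites, 100 transcripts pass the 2-fold filter, and
exactly the 50 planted targets are recovered — half of the retained DE
transcripts, because the other 50 are planted far-from-peak decoys. The
per-direction KS p-values in `summary.json` are ≈ 3.6×10⁻¹¹ (activated) and
1.1×10⁻⁸ (repressed): DE transcripts sit far closer to binding sites than
the annotated background. The enrichment table ranks the planted set first
by a wide margin:

```console
$ head -3 demo/results/sampleA.enrichment_down_upon_kd.tsv
set_name            k   K   n   N     p_value       q_value
PLANTED_ACTIVATED   23  50  25  1001  1.00e-30      2.20e-29
DECOY_14            4   50  25  1001  3.20e-02      3.52e-01
```

Every stage's table (distances, ECDFs, targets, enrichments, correlation
matrix) is persisted next to `summary.json`, and a rerun with the same
config and seed reproduces the summary byte for byte.

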