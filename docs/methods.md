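# Methods

`regtarget` implements the binding–expression integration analysis used to
call transcription-factor (TF) direct targets: it combines replicated
ChIP-seq peak calls with a knockdown-vs-control differential-expression (DE)
table and asks which DE transcripts have a reproducible binding site close
enough to their transcription start site (TSS) to plausibly be regulated
directly. This note records the model, the conventions, the tunable
parameters, and the design choices made where the procedure was genuinely
open.

## Coordinate conventions

All coordinates are 0-based, half-open `[start, end)`. A narrowPeak summit
offset of −1 (summit unknown) falls back to the interval midpoint with floor
division so every peak remains usable by summit-centred operations. The TSS
of a "−"-strand transcript is `txEnd − 1`, the last covered base in 0-based
coordinates.

## Replicate concordance and high-confidence peaks

Two replicate peak sets are compared by sweeping both in genomic order and
pairing peaks one-to-one whenever their intervals overlap by ≥ 1 bp; a peak
can participate in at most one pair, which keeps Venn-style counts free of
double counting. Concordance is `n_shared / min(n_a, n_b)` by default (the
fraction of the smaller replicate that is reproduced); the mean of the two
per-replicate fractions is available as an option. The greedy sweep is
verified against an exact maximum bipartite matching in the test suite.

High-confidence peaks are the merged pairs: the interval is the union of the
two members, and the summit and score come from the higher-scoring member
(ties favour replicate A). Unpaired peaks are dropped. A replicate pair
below the concordance threshold (default 0.8) produces a warning rather
than an abort — the threshold is a QC justification for combining
replicates, not an automated gate; `strict` mode upgrades it to an error.

## Signal quantification and correlation

Per-window read counts are normalized to reads per million
(`count × 10⁶ / library_size`), with windows taken as fixed-width (default
100 bp) intervals centred on peak summits, clipped to chromosome bounds, and
merged when they overlap. Cross-sample similarity is pairwise Spearman rank
correlation (average ranks on ties; undefined — returned as NaN with a
warning — when either vector has zero rank variance). Hierarchical
clustering supports Ward on euclidean distance (the expression-heatmap
setting) and average linkage on `1 − rho` (the binding-pattern setting);
Ward is restricted to the euclidean metric.

## Consensus-motif enrichment

The canonical GAS-family consensus `TTCNNNGAA` (9 bp, fixed spacer) is
scanned on both strands of each sequence as an IUPAC pattern. The null is a
per-sequence mononucleotide shuffle, repeated `n_shuffles` times with a
seeded generator; the background rate is the mean per-sequence match
frequency over shuffles, and the p-value is the upper binomial tail at the
observed number of matching sequences. This is a consensus-level enrichment
check, not motif discovery; no position-weight-matrix scoring is attempted.

## DE filtering

The DE table (transcript, chromosome, log2 fold change knockdown − control,
adjusted p) is an upstream contract: the count model that produced it is out
of scope. Filtering retains transcripts with `|log2fc| > log2(fold)` —
strictly, so a transcript at exactly a 2-fold change is excluded and counted
separately. Sex-chromosome (chrX/chrY) transcripts are removed before
filtering and before any downstream counting. No adjusted-p filter is
applied by default because the retention rule is fold-change-only; a
`padj_threshold` option exists for users who want one. Direction semantics:
log2fc < 0 (down upon knockdown) means the TF *activates* the transcript;
log2fc > 0 means the TF *represses* it.

## Distances, ECDFs and the KS test

The distance of a transcript is `min |tss − summit|` over same-chromosome
high-confidence peaks, unstranded; transcripts on peak-free chromosomes get
an infinite sentinel. Sentinels count in ECDF denominators (a transcript
with no nearby peak anywhere is evidence against proximity) but contribute
no support point, so an ECDF with sentinels never reaches 1.

Enrichment of binding near DE transcripts is a two-sample
Kolmogorov–Smirnov test of the DE transcripts' distances against the
background of all annotated autosomal transcripts (DE transcripts are not
removed from the background; at realistic DE fractions of ~1–2% the effect
on the statistic is negligible, and the null-calibration test exercises
exactly this configuration). The statistic is the supremum of |F1 − F2|
evaluated at every finite observed value. P-values:

- **asymptotic** — `Q(λ)` with `λ = (√nₑ + 0.12 + 0.11/√nₑ)·D`,
  `nₑ = n1·n2/(n1+n2)`, `Q(λ) = 2·Σ_{j≥1} (−1)^{j−1} e^{−2j²λ²}` truncated
  when terms drop below 1e−10 and clamped to (0, 1]. This is the standard
  small-sample-corrected series. Its accuracy against the exact permutation
  distribution is limited by the discreteness of that distribution: at
  n1 = n2 = 10 the exact distribution has steps of 0.1 in D and mid-range
  p-values can differ from exact by up to ~0.11, while tail p-values (the
  regime the pipeline operates in) agree to ~0.02.
- **exact permutation** — full enumeration of all C(n1+n2, n1) label
  assignments when that count is at most 2×10⁵ (which covers n1 = n2 = 10,
  where the enumeration is verified against an independent lattice-path
  counting oracle), otherwise a seeded Monte-Carlo permutation test with
  10⁴ permutations and add-one smoothing. Ties and infinite sentinels are
  handled by evaluating ECDF differences at tie-group boundaries of finite
  values only.
- **auto** — exact when enumeration is feasible, asymptotic otherwise.

Both regulation directions are tested against the same background,
producing the two per-direction p-values the pipeline reports.

## Direct targets

A filtered DE transcript is a direct target when its nearest-peak distance
is ≤ 50 kb (inclusive boundary — "within 50 kb"); the cutoff reflects the
observation that the coupling between TF binding and expression decays
beyond ~100 kb. Targets keep their DE direction: down upon knockdown →
activated by the TF. `fraction_within` is targets over retained DE
transcripts. Cross-sample intersection reports transcripts targeted in both
samples with a per-set direction and a concordance flag.

## Gene-set enrichment

Direction-split target sets are tested against GMT collections by
hypergeometric overlap: `k` = query∩set overlap, `n` = query size, `K` = set
size, `N` = universe size, p = upper tail P(X ≥ k) computed in log space
(log-gamma binomials with a log-sum-exp reduction). The universe is all
autosomal genes in the annotation, consistent with the sex-chromosome
omission upstream. Transcripts map to genes before counting, so a gene
contributes at most once to any overlap. Benjamini–Hochberg step-up
q-values are computed within each direction's run across all tested sets;
sets with no member in the universe are skipped. A ranked-list
(weighted-KS) enrichment variant is deliberately out of scope: no ranking
metric is defined for an unordered target set.

## Synthetic data

The generators produce every input the pipeline consumes, with planted
ground truth; they emulate the statistical structure the analysis assumes —
not reads, fragment lengths, GC bias, or peak-caller artifacts. Passing
tests therefore demonstrate the correctness and calibration of the
integration machinery, not robustness to upstream noise in real data.

- **Annotation** — TSSs placed per chromosome proportional to length,
  uniformly or on a jittered grid with a guaranteed minimum inter-TSS
  spacing; a configurable fraction of transcripts sits on chrX to exercise
  the sex-chromosome filter. One gene per transcript.
- **Peaks (separated layout)** — each planted target (autosomal, directions
  alternating) gets one peak with summit at `tss ± U(0, 50 kb)`, rejected
  within 100 kb of any *other* TSS; background peaks are rejection-sampled
  at least 100 kb from *every* TSS. The stronger decoy rule (spec-level
  descriptions often only exclude non-target TSSs) is what makes the
  recorded planted distance exactly the transcript's nearest-peak distance.
  The separated scenario uses large synthetic chromosomes (160 + 140 Mb
  autosomes, 30 Mb chrX) with 200-kb-spaced TSSs: with ≥ 1,000 transcripts
  a tens-of-megabases genome cannot satisfy the 100-kb separation
  constraint, so the genome is scaled to the constraint rather than the
  other way around. A small 2×10 Mb + 5 Mb toy genome is the default for
  unit-scale work without separation constraints.
- **Replicates** — each replicate keeps each truth peak independently with
  probability equal to the target concordance `c`; under the
  `shared/min(n_a, n_b)` definition the expected measured concordance is
  then `c` itself (shared ≈ c²N over min ≈ cN). Boundaries are jittered by
  a rounded Normal(0, jitter_sd = 5 bp) preserving summit containment. The
  separated scenario pins its planted target peaks in both replicates
  (`always_keep`) so that the planted truth survives replicate combination
  and end-to-end recovery is exact by construction; dropout applies to
  background peaks only. The concordance-calibration tests use the
  generator without pinning.
- **Signal** — Gamma–Poisson counts (dispersion 0.1) around a shared
  per-peak lognormal baseline, with a 4-fold group effect on a designated
  30% of peaks for non-reference groups; this plants within-group >
  between-group Spearman correlation.
- **DE table** — planted targets get `log2fc = ±(2.0 + N(0, noise_sd))`
  with sign fixed by direction; `n_null_de` additional far-from-peak
  transcripts get supra-threshold fold changes (DE-but-not-target decoys);
  everything else gets `N(0, noise_sd)`. The separated scenario uses
  noise_sd = 0 and n_null_de = n_targets = 50, so exactly 100 transcripts
  survive the 2-fold filter and the fraction of DE transcripts within
  50 kb is exactly 0.5 — mirroring the ~50% seen in real TF knockdown
  integrations of this kind.
- **Gene sets** — one planted set per direction containing 90% of that
  direction's target genes plus filler to 50 members, and 20 uniform decoy
  sets of 50.
- **Null scenario** — 2,000 transcripts, 300 peaks placed independently of
  the annotation, 40 DE transcripts drawn uniformly. The 2% DE fraction
  keeps the DE-in-background overlap negligible so the KS p-value is
  calibrated: across 200 seeds the p-distribution is statistically
  indistinguishable from uniform (slightly conservative in the mean, as
  expected from the asymptotic approximation at n₁ = 40).

All generators are bit-reproducible given (parameters, seed); scenario
child stages derive fixed offsets from the scenario seed.

## Pipeline determinism and audit

A run is a pure function of (input files, parameters, seed). Every stage
persists its table (high-confidence BED, concordance JSON, filtered DE,
distances, per-group ECDFs, target lists, enrichment tables, correlation
matrix), and every number in the summary JSON is recomputable from those
artifacts — the test suite re-derives the KS p-value and target counts from
the persisted files. The summary is written with sorted keys and contains
no paths or timestamps, so reruns are byte-identical.

## Problem sizes

Default scenario sizes (1,100 transcripts, ~350 peaks/sample, 2 samples;
null calibration at 200 seeds; concordance calibration at 10,000 peaks ×
20 seeds) were chosen so the full analysis and its calibration studies run
in seconds to a few minutes on one core while keeping every statistical
check well-powered (KS p < 10⁻⁶ at 25 planted targets per direction against
a 1,001-transcript background; binomial SE of measured concordance ≈ 0.004
at 10,000 peaks).

## Known limitations

- The consensus-motif stage scans a fixed IUPAC pattern; degenerate
  spacer-length variants and PWM-level affinities are out of scope.
- Distance is TSS-to-summit only; peak-edge distance is available as an
  option, but no regulatory-potential decay weighting or multi-peak
  aggregation is attempted.
- The hypergeometric/BH enrichment reproduces overlap-style FDR q-values;
  it is not a ranked-list GSEA and q-values on real collections depend
  strongly on the chosen universe.
- The asymptotic KS p-value inherits the discreteness limitation described
  above; for small samples the exact permutation method should be (and by
  default is) used.
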