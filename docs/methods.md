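# Methods

`zga` re-implements, as a tested library, the promoter-classification and
quantitative-chromatin workflow used to show that the histone variant
H2A.Z marks most pioneer-factor-independent promoters activated at
zygotic genome activation (ZGA). This note documents the models, the
numerical choices, the synthetic-data generator that stands in for real
embryo data, and the known limitations.

## 1. Promoter activity from nascent transcription

Fragments' 5' ends are extended 100 bp in their strand direction and
piled into per-strand coverage tracks (replicates pooled). Peak calling
is a self-contained Poisson scan rather than a wrapper around an
external caller: candidate regions are maximal runs of coverage that is
implausible (p < 1e-3) under the genome-wide Poisson rate, merged across
gaps up to the extension size; each region is scored by the Poisson tail
of its summit height against a local rate
`lambda_local = max(lambda_genome, lambda_1kb, lambda_10kb)` computed
with the region itself excluded. Benjamini–Hochberg correction uses
`track_length / extsize` as the number of tests — candidates that never
reached the prefilter count implicitly as p = 1. Correcting only over
detected candidates is selection-biased and calls false peaks on flat
background; with the pseudo-test count, a flat Poisson track yields no
peaks and, on null synthetic data, under 1% of promoters come up active.
Summit ties break leftmost for determinism.

A promoter is active iff a same-strand summit lies within 150 nt
(inclusive) of its TSS. "Within 150 nt" is measured to the summit, not
the peak edge, because summits are what the scan reports; the choice is
logged. Transcripts whose promoter windows (TSS ± 150 nt, same strand)
overlap are collapsed to one representative (smallest differential FDR
when available, else the most upstream TSS); windows overlapping a
different gene's window on the same strand are discarded as non-unique.
Hyper-accessible artefact regions are blacklisted by merging
accessibility peaks up to 1 kb apart and discarding merged spans
strictly longer than 12 kb.

## 2. Nucleosome dyads and the +1/−1 H2A.Z rules

Dyads are local maxima of a Gaussian-smoothed (sd 30 bp) histogram of
fragment midpoints, kept greedily in decreasing height subject to a
120 bp minimum separation (`scipy.signal.find_peaks` with `distance`
implements exactly this greedy suppression). Two thresholds apply: the
relative rule (2× the chromosome median density) and an absolute support
floor of 5 effective fragments (peak height × bandwidth × √2π). The
floor is needed because on sparse background the median of a smoothed
Poisson density is close to its mean, and a single isolated fragment
already forms a local maximum above twice that level; without the floor
the caller reports thousands of single-read dyads and the downstream
classification collapses. MNase fragments are length-filtered to
130–200 bp (inclusive) before dyad calling.

Flanking nucleosomes are assigned strand-aware (downstream offset ≥ 0
for the +1, upstream offset < 0 for the −1):

* rule 1 — nearest dyad with |offset| ≤ 350 nt in *either* replicate;
* rule 2 — nearest dyads with |offset| ≤ 600 nt in *both* replicates
  whose centers differ by < 80 nt; the assigned position is their
  midpoint (symmetric in the replicates).

Rule 1 is evaluated first; ties on |offset| break leftmost. A promoter
is H2A.Z-positive iff a +1 assignment exists; otherwise H2A.Z-negative
with or without a −1. Pioneer-factor-dependent promoters are excluded
from this partition (their flank calls are retained for reporting), so
the three labels partition the independent active promoters exactly.

## 3. Expression origin

TPM is computed at gene level with the annotated span as effective
length (no fragment-length correction; the workflow never states an
isoform model, and the toy annotation is single-isoform). A gene is
maternal if TPM > 5 (strict) in at least 3 unfertilized-egg replicates.
Origin classes are the set partition zygotic / maternal /
maternal-zygotic / silent. Zelda-zygotic targets are the conjunction:
Zld-dependent, zygotic-only, ZGA-active, and embryo TPM > 5 — the
embryo filter uses the replicate mean by default because, unlike the
unfertilized rule, no per-replicate rule is stated; a per-replicate mode
is available via a flag.

## 4. Differential statistics and quantitative scaling

One negative-binomial engine serves the Pol II (Zld dependence) and
nascent-transcription (knockdown) comparisons: features with mean count
below 10 are removed; per-feature dispersion is method-of-moments on
normalized counts (Poisson part subtracted, floor 1e-8); the NB GLM
(log link, log size factors as offset) is fitted by IRLS
(`statsmodels` NegativeBinomial family); the Wald statistic on the
condition coefficient is referred to a **t distribution with residual
degrees of freedom** rather than a normal. At 2–3 replicates per group
the moment dispersions are noisy and a normal reference is badly
anti-conservative (≈11% of null features at p < 0.05); with the t
reference the simulated null lands at ≈4% and is KS-uniform. Exact
tests, likelihood-ratio variants, and fold-change shrinkage are out of
scope. Zld dependence uses the strict rule logFC < −1 and FDR < 0.01.

Per-transcript occupancy counting multi-counts fragments across
overlapping transcripts (strand-agnostic by default, stranded mode for
nascent transcription), drops transcripts spanning < 125 nt or with
total counts ≤ 10, and reports FPKM against per-sample totals.

Normalization sources:

* **reference-set size factors** — median-of-ratios computed only on a
  reference feature set (the Zelda-zygotic targets, which carry no
  planted knockdown effect), so a global depletion is not absorbed into
  the normalization. Note the estimator is equivariant on factor
  *ratios*: scaling one sample by c scales its factor ratio to every
  other sample by exactly c (the per-feature geometric mean moves with
  the scaled sample, so the factor itself scales by c^(1−1/m)).
* **spike-in factors** — proportional to 1 / spike-contig count,
  normalized to geometric mean 1.
* **input-only factors** — library totals, for quantitative-ChIP
  transforms.

The quantitative-ChIP (RELACS-style) scaling factor is the
library-size-corrected double ratio of IP and input counts summed over
active promoters ± 400 nt, pooled across replicates (factor < 1 ⇔
depletion in the knockdown). The stabilized-log transform is
log2(count/size_factor + 1) with replicate averaging — a shifted-log
stand-in for a regularized-log transform. Genome-bin counting assigns
each fragment once, by midpoint, to 500 nt bins and discards bins with
mean count ≤ 25.

## 5. Hi-C insulation and TAD boundaries

Contacts are binned at 2 kb and balanced by iterative correction to
equal row sums (same fixed-point family as KR balancing; bins with zero
marginal are masked; convergence requires row-sum CV < 1e-5, and the
balanced matrices in the tests reach CV < 1e-4). The insulation score
of bin i averages, over window sizes 20–100 kb in 2 kb steps, the mean
balanced count of the diamond `[i−w, i−1] × [i+1, i+w]`; each window
track is log2-normalized to its chromosome mean (0 = average, negative
= insulated). A diamond with measured zero crossing contacts gives
−inf — a real extreme, distinct from NaN (no coverage: bins within the
maximum window of a chromosome edge, or masked bins). Boundaries are
covered local minima whose score drops below both flanking local maxima
by ≥ 0.01; this prominence rule is a documented simplification of the
published tool's rank-test-plus-correction procedure. Multi-window
aggregation is an unweighted mean (the published aggregation is not
described). Group profiles are strand-oriented pointwise medians with
standard errors (NaN for single-member groups); condition differences
subtract per bin where both tracks are covered and propagate NaN
elsewhere.

## 6. IP-MS enrichment

From a log2 intensity table: flagged rows (contaminant / decoy /
identified-by-site) are removed; rows need ≥ 2 observed values in bait
*or* control. Per-sample median centering stands in for
variance-stabilizing normalization (the arcsinh fit is out of scope).
Missing values are imputed per sample from
Normal(μ_s − 1.8 σ_s, (0.5 σ_s)²) — the standard width/downshift
treatment of missing-not-at-random dropout; observed values are never
altered. The moderated t-test shrinks per-protein pooled variances
toward a prior: d0 and s0² are estimated by matching the first two
moments of log s² to the scaled-F model (trigamma inversion by Newton
iteration; d0 = ∞ when the residual variances show no excess spread,
in which case every protein uses s0²). P-values use t with d0 + d df;
correction is Benjamini–Yekutieli (which dominates BH pointwise);
enrichment requires padj ≤ 0.05 and |log2FC| ≥ log2 1.5 (both
inclusive).

## 7. The synthetic embryo

The generator plants a fully labelled truth and emulates every input
the pipeline consumes. Defaults (one seed, one config — the study
conditions for all tests):

* **genome** — 2 chromosomes × 1 Mb plus a 48 kb spike contig;
  400 genes on a jittered grid (TSS spacing ≥ 3 kb, 110 kb edge margin
  so every TSS has full insulation-window coverage); gene bodies
  0.8–1.5 kb so neighbouring transcripts never overlap at this spacing.
* **classes** — 60% active; of active, 10% Zld-dependent and 62%
  H2A.Z-positive; 26% of the H2A.Z-negative remainder carry a −1-only
  nucleosome; 40% of genes maternal (drawn independently, giving a
  maternal-zygotic overlap). Counts are deterministic rounds of the
  fractions; membership is random.
* **chromatin geometry** — +1 dyads at +120 nt, −1 at −180 nt
  (strand-aware), phasing sd 20 bp; both inside the 350 nt rule-1
  window by construction, so the planted labels are recoverable by the
  classification's own thresholds.
* **nascent transcription** — 3 replicates; active genes emit ~600
  sense-strand fragments per replicate with exponentially decaying
  5'-end offsets (scale 300 bp) over a uniform background
  (0.005/bp/strand); knockdown scales each gene by its planted log2FC
  (−1.5 for H2A.Z-positive, −0.6 for −1-only, 0 elsewhere).
* **H2A.Z ChIP** — 2 replicates; ~35 fragments per planted nucleosome
  (147 bp, dyad-centred), multiplied by the depletion factor (default
  0.5) in the knockdown; plus a dominant *dispersed* H2A.Z component
  (0.07/bp outside TSS ± 1 kb) that is **not** depleted, and a small
  uniform background. The dispersed pool mirrors real IP libraries,
  where most fragments are not TSS-proximal; it is what makes the
  double ratio identifiable — if the whole library were depleted
  promoter signal, library-size correction would cancel the depletion
  exactly. Each sample adds spike-contig fragments at 5% of its
  library.
* **Pol II** — ~2500 fragments per active gene per replicate (2
  replicates); Zld-dependent genes drop 4-fold in the pioneer-factor
  knockdown. The depth is set so the strict logFC/FDR rule is decidable
  from two replicates under the deliberately conservative t(2) Wald
  reference.
* **RNA counts** — negative binomial (dispersion 0.05), length-scaled;
  maternal genes high in unfertilized eggs (4 replicates), active and
  maternal genes expressed in embryos (3 replicates).
* **contacts** — expected counts 3000·d^(−1) at 2 kb bins, Poisson
  sampled; boundaries planted at Zld-dependent TSS bins (thinned to
  ≥ 30 bins separation, ≥ 120 bins from chromosome ends so each
  boundary's full window neighbourhood is covered); pairs crossing a
  boundary are attenuated 5-fold (weakened in the knockdown). The depth
  corresponds to a deeply sequenced merged library; at ~10× less depth
  Poisson noise in the track exceeds the 0.01 boundary prominence and
  the delta rule alone cannot separate noise minima from structure.
* **proteomics** — 1000 proteins, 3 vs 3, log2 intensities N(25, 2²)
  with sd 0.3 replicate noise; 5% of proteins bait-enriched 4-fold;
  global left-censoring at the 12% quantile (missing-not-at-random);
  flagged contaminant/decoy/site-only rows injected.

Every assay draws from its own RNG stream derived from the master seed
(`SeedSequence([seed, crc32(name)])`), so adding an assay never changes
another's data and identical configs give identical output.

**What the generator does not emulate:** sequence content and
mappability/GC bias, fragment-length biology beyond simple ranges,
isoform structure, inter-chromosomal contacts, distance-dependent
boundary strength, batch effects, or any real-data peculiarity of the
deposited datasets. Passing the recovery tests therefore demonstrates
that the *rules and estimators* are implemented correctly and are
identifiable under clean conditions — not that the pipeline would
reproduce the published numbers from raw reads.

## 8. Problem sizes and determinism

Default test/acceptance scale: 400 genes on 2 Mb, ~0.4–1.2 M fragments
per assay, 500-bin contact matrices — a full pipeline run takes ~25 s
on one CPU, the whole suite under two minutes. End-to-end runs are
deterministic given the config (including seed); every threshold of the
classification lives in one `Thresholds` dataclass (the
`paper_defaults` YAML section) and is overridable without code changes.

## 9. Known limitations

* The peak scan, dyad caller, boundary rule and shifted-log transform
  are documented simplifications of the external tools used in the
  original workflow; they share the statistical idea, not the bits.
* The t-referenced Wald NB test is conservative at 2 replicates; the
  generator compensates with depth, as a real design would with more
  replicates.
* The double ratio is biased toward 1 by the promoter share of the IP
  library (~10% under defaults, worth ≲ +0.05 at strong depletion);
  shrinking that share further would cost dyad-calling signal.
* Balancing uses plain iterative correction; matrices with pathological
  sparsity patterns may need more iterations than the default cap.
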