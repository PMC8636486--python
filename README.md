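# zga — promoter classification and quantitative chromatin analysis at zygotic genome activation

At the major wave of zygotic genome activation (ZGA) in *Drosophila*,
thousands of promoters fire for the first time, but the pioneer factor
Zelda accounts for only a small subset of them. This package implements
the analysis that classifies the remaining, Zelda-independent promoters
by their chromatin state — specifically by whether the histone variant
H2A.Z occupies their +1/−1 nucleosomes — and quantifies what happens to
transcription, H2A.Z occupancy and 3D genome structure when the H2A.Z
chaperone Domino is depleted.

It is a library for people who work with embryo chromatin genomics and
want the published classification rules as reusable, tested code:

* **activity** — strand-specific Poisson-scan peak calling on nascent
  transcription (GRO-seq-like) coverage; a promoter is active iff a
  same-strand summit lies within 150 nt of its TSS; unique-promoter
  selection and hyper-accessible blacklisting.
* **nucleosome** — dyad calling from fragment midpoints and the
  replicate-consistency rules for +1/−1 nucleosomes: a dyad within
  350 nt in one replicate, or within 600 nt in both with centers < 80 nt
  apart. H2A.Z-positive ⇔ a +1 exists.
* **expression** — TPM, the maternal rule (TPM > 5 in ≥ 3 unfertilized
  replicates), maternal/zygotic origin classes, Zelda-zygotic targets.
* **differential** — negative-binomial GLM Wald tests with
  method-of-moments dispersions; reference-set, spike-in and input-only
  size factors; the Zld-dependence rule (logFC < −1, FDR < 0.01);
  quantitative-ChIP double-ratio scaling; binned counting.
* **insulation** — contact binning, iterative-correction balancing,
  the multi-window diamond insulation score, prominence-based TAD
  boundary calls, strand-oriented TSS group profiles.
* **proteomics** — IP-MS enrichment statistics: filtering, median
  centering, shifted-normal imputation (width 0.5, downshift 1.8),
  moderated t-test, Benjamini–Yekutieli, the ±50% fold-change call.
* **synthetic** — a generator that emulates all of these data types on
  a toy genome with planted ground truth, so the whole pipeline is
  testable end to end without the deposited datasets.

The model at the core is a partition of active promoters

```
active = Zld-dependent ⊎ H2A.Z-positive ⊎ H2A.Z-negative(−1) ⊎ H2A.Z-negative(none)
```

with per-class quantitative readouts: differential nascent
transcription under chaperone knockdown (NB GLM, log2 fold changes
anchored on a zero-change reference set), the promoter H2A.Z depletion
factor (IP/input double ratio), and TSS insulation
`IS(i) = mean_w log2( diamond_w(i) / chrom_mean_w )`.

## Worked example

`examples/01_classify_promoters.py` simulates a 120-gene embryo,
classifies its promoters and prints the confusion table against the
planted truth:

```
72 of 120 promoters active (76 peaks)

H2A.Z class vs planted truth (active promoters):
called           h2az_neg_minus1  h2az_neg_none  h2az_pos
planted
h2az_neg_minus1                5              0         0
h2az_neg_none                  0             15         0
h2az_pos                       0              0        45
zld_dep                        0              7         0
```

Every H2A.Z label is recovered from the fragment data alone (the
`zld_dep` row appears under `h2az_neg_none` here because this example
skips the Pol II differential that identifies Zelda dependence — the
full pipeline routes those promoters into their own class).
`examples/02_knockdown_quantification.py` recovers a planted 50% H2A.Z
depletion as a double ratio of 0.490 and per-planted-effect median
log2FC of −1.49 / −0.65 / 0.00 against planted −1.5 / −0.6 / 0;
`examples/03_tad_insulation.py` recovers 8/8 planted TAD boundaries
within one 2 kb bin; `examples/04_ipms_enrichment.py` recovers a
planted 4-fold bait enrichment with sensitivity 0.94 at zero observed
false discoveries.

The same workflow is scriptable from the shell:

```
zga run --seed 1                 # simulate -> classify -> quantify -> report
zga simulate --seed 1 --outdir sim
zga activity --fragments sim/groseq_Ctrl.tsv --gtf sim/annotation.gtf --truth sim/truth.tsv
zga hic --triplets sim/contacts_Ctrl.txt
zga ipms --table lfq.tsv --seed 7
```

`zga run` writes the per-promoter classification table (with the rule
provenance of every label), a JSON summary and a text digest.

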