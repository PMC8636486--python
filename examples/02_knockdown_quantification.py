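"""Quantify a chaperone-knockdown effect on H2A.Z and transcription.

Plants a 50% H2A.Z depletion at promoter nucleosomes, recovers it with
the library-size-corrected IP/input double ratio, and measures the
planted transcriptional knockdown effects with the negative-binomial
differential engine normalized on unaffected reference genes.
"""

import numpy as np
import pandas as pd

from zga import differential as D
from zga.genome import transcripts_frame
from zga.synthetic import SimConfig, simulate_chip, simulate_groseq, \
    simulate_truth_genome

cfg = SimConfig(seed=4, n_genes=120, chrom_length=500_000)
build, transcripts, truth = simulate_truth_genome(cfg)
tdf = transcripts_frame(transcripts)

# quantitative ChIP: double ratio over active promoters +/- 400 nt
act = truth[truth["active"]]
regions = pd.DataFrame({"chrom": act["chrom"],
                        "start": np.maximum(act["tss"] - 400, 0),
                        "end": act["tss"] + 400})
ip = simulate_chip(truth, cfg, build, "H2A.Z", "Ctrl").concat([
    simulate_chip(truth, cfg, build, "H2A.Z", "Ctrl"),
    simulate_chip(truth, cfg, build, "H2A.Z", "DomKD")])
inp = simulate_chip(truth, cfg, build, "input", "Ctrl").concat([
    simulate_chip(truth, cfg, build, "input", "Ctrl"),
    simulate_chip(truth, cfg, build, "input", "DomKD")])
factor = D.relacs_from_fragments(ip, inp, regions)
print(f"double-ratio scaling factor: {factor:.3f} "
      f"(planted depletion {cfg.depletion_factor})")

# spike-in size factors from the exogenous contig
spike = ip.frame[ip.frame["chrom"] == "spike"].groupby(
    ["condition", "replicate"]).size()
print("spike-in size factors:")
print(D.spikein_size_factors(spike).round(3).to_string())

# differential nascent transcription, normalized on zero-change genes
gro = simulate_groseq(truth, cfg, build, "Ctrl").concat([
    simulate_groseq(truth, cfg, build, "Ctrl"),
    simulate_groseq(truth, cfg, build, "DomKD")])
cm, _ = D.transcript_counts_fpkm(gro, tdf, stranded=True)
reference = [t for t in cm.counts.index
             if truth.loc[tdf.loc[t, "gene_id"], "planted_logFC_kd"] == 0.0]
sf = D.reference_size_factors(cm, reference)
diff = D.nb_differential(cm, sf, condition_ref="Ctrl")
diff["planted"] = truth.loc[tdf.loc[diff.index, "gene_id"],
                            "planted_logFC_kd"].to_numpy()
print("\nmedian estimated log2FC by planted effect:")
print(diff.groupby("planted")["logFC"].median().round(2).to_string())
# Each median should sit near its planted value: the reference-set size
# factors keep unaffected genes at zero instead of absorbing the global
# depletion into the normalization.
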