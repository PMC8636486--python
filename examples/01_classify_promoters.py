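"""Classify promoters of a small synthetic embryo.

Simulates nascent transcription and H2A.Z chromatin profiling on a toy
genome, calls peaks and nucleosome dyads, and partitions the active
promoters into pioneer-factor-dependent and H2A.Z-positive/-negative
classes.  Prints the class table against the planted truth.
"""

import pandas as pd

from zga import activity, nucleosome
from zga.genome import transcripts_frame
from zga.synthetic import SimConfig, simulate_chip, simulate_groseq, \
    simulate_truth_genome

cfg = SimConfig(seed=11, n_genes=120, chrom_length=500_000)
build, transcripts, truth = simulate_truth_genome(cfg)
tdf = transcripts_frame(transcripts)

# promoter activity from pooled nascent-transcription coverage
gro = simulate_groseq(truth, cfg, build, "Ctrl")
peaks = activity.call_peaks(activity.strand_coverage(gro))
promoters = activity.select_unique_promoters(tdf)
act = activity.assign_activity(promoters, peaks)

# H2A.Z classes from two replicate dyad calls
chip = simulate_chip(truth, cfg, build, "H2A.Z", "Ctrl")
d1 = nucleosome.call_dyads(chip.subset(replicate="1"))
d2 = nucleosome.call_dyads(chip.subset(replicate="2"))
flanks = nucleosome.assign_all_flanks(promoters, d1, d2)
classes = nucleosome.classify_h2az(promoters, flanks)

table = promoters.join(act).join(classes)
called = table.loc[table["active"], "h2az_class"]
planted = truth.loc[table.loc[table["active"], "gene_id"], "truth_class"]

print(f"{int(act['active'].sum())} of {len(table)} promoters active "
      f"({len(peaks)} peaks)")
print("\nH2A.Z class vs planted truth (active promoters):")
print(pd.crosstab(planted.to_numpy(), called.to_numpy(),
                  rownames=["planted"], colnames=["called"]))
# A diagonal table means every promoter's +1/-1 nucleosome content was
# recovered from the fragment data by the replicate-consistency rules.
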