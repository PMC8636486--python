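"""TPM quantification and maternal / zygotic origin classification.

Maternal transcripts are those detected in unfertilized eggs (TPM > 5
in at least 3 replicates); zygotic genes are transcribed in the embryo
(active by nascent transcription) but absent from unfertilized eggs;
genes present in both are maternal-zygotic.  Zelda-zygotic targets are
the Zld-dependent, zygotic-only, ZGA-active genes with TPM > 5 in
control embryos.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import CountMatrix

ORIGIN_LABELS = ("zygotic", "maternal", "maternal_zygotic", "silent")


def compute_tpm(cm: CountMatrix) -> pd.DataFrame:
    """Transcripts-per-million from counts and effective lengths.

    rate_g = count_g / length_g;  TPM_g = 1e6 * rate_g / sum(rate).
    Columns with no counts stay all-zero.
    """
    if cm.lengths is None:
        raise ValueError("count matrix lacks feature lengths")
    lengths = cm.lengths.to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValueError("non-positive feature length")
    rate = cm.counts.to_numpy(dtype=float) / lengths[:, None]
    total = rate.sum(axis=0)
    scale = np.divide(1e6, total, out=np.zeros_like(total), where=total > 0)
    return pd.DataFrame(rate * scale, index=cm.counts.index, columns=cm.counts.columns)


def maternal_set(
    tpm_unfertilized: pd.DataFrame, threshold: float = 5.0, min_reps: int = 3
) -> set[str]:
    """Genes with TPM strictly above ``threshold`` in >= ``min_reps`` samples."""
    n_pass = (tpm_unfertilized > threshold).sum(axis=1)
    return set(tpm_unfertilized.index[n_pass >= min_reps])


def origin_classify(maternal: set[str], zygotically_active: set[str],
                    universe: pd.Index) -> pd.Series:
    """Partition the gene universe into origin classes."""
    labels = pd.Series("silent", index=universe, dtype="object")
    mat = universe.isin(maternal)
    act = universe.isin(zygotically_active)
    labels[act & ~mat] = "zygotic"
    labels[mat & ~act] = "maternal"
    labels[mat & act] = "maternal_zygotic"
    return labels


def zelda_zygotic_targets(
    tpm_ctrl_embryos: pd.DataFrame,
    zld_dependent: set[str],
    origin: pd.Series,
    active: set[str],
    threshold: float = 5.0,
    per_replicate: bool = False,
    min_reps: int = 3,
) -> set[str]:
    """Zld-dependent, zygotic-only, ZGA-active genes expressed in embryos.

    The embryo expression filter uses the mean TPM across replicates by
    default; set ``per_replicate`` to require TPM > threshold in
    ``min_reps`` individual replicates instead.
    """
    if per_replicate:
        expressed = set(
            tpm_ctrl_embryos.index[(tpm_ctrl_embryos > threshold).sum(axis=1) >= min_reps]
        )
    else:
        expressed = set(
            tpm_ctrl_embryos.index[tpm_ctrl_embryos.mean(axis=1) > threshold]
        )
    zygotic_only = set(origin.index[origin == "zygotic"])
    return expressed & set(zld_dependent) & zygotic_only & set(active)
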