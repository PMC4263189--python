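"""Per-gene occupancy metrics and qPCR/NRO arithmetic.

The two window-ratio metrics at the core of the analysis:

* pausing index  = (TSS±250 signal + ε) / (body +500..+1000 signal + ε)
* processivity index = log2((body + ε) / (TES−500..0 + ε))  — orientation
  ``body/tes`` by default; ``tes/body`` is available via the orientation flag
  (the mirrored convention used for RNA coverage), and the orientation in
  force is recorded in the output metadata.

ε is a symmetric pseudocount, by default the r.p.m. equivalent of one read,
keeping ratios finite and rank-preserving on zero-count windows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome_io import (ANTISENSE_WINDOW, BODY_WINDOW, TES_WINDOW, TSS_WINDOW,
                        GeneModel, GenomeAnnotation, SignalTrack)
from .window_counter import RPM, count_exonic, count_window

#: genes shorter than this are excluded from index computations: the TSS,
#: body and terminal windows would overlap.
MIN_GENE_LENGTH = 1500

BODY_OVER_TES = "body/tes"
TES_OVER_BODY = "tes/body"


def rpm_pseudocount(track: SignalTrack) -> float:
    """The r.p.m. value of a single read in this track's library."""
    return 1e6 / track.total_reads


def pausing_index(tss_rpm, body_rpm, epsilon: float = 0.0):
    """Ratio of normalized TSS-window to body-window signal (elementwise)."""
    tss = np.asarray(tss_rpm, dtype=float)
    body = np.asarray(body_rpm, dtype=float)
    out = (tss + epsilon) / (body + epsilon)
    return out if out.ndim else float(out)


def chip_processivity_index(body_rpm, tes_rpm, epsilon: float = 0.0,
                            orientation: str = BODY_OVER_TES):
    """log2 ratio of body-window to terminal-window signal (elementwise)."""
    body = np.asarray(body_rpm, dtype=float)
    tes = np.asarray(tes_rpm, dtype=float)
    if orientation == BODY_OVER_TES:
        out = np.log2((body + epsilon) / (tes + epsilon))
    elif orientation == TES_OVER_BODY:
        out = np.log2((tes + epsilon) / (body + epsilon))
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return out if out.ndim else float(out)


def rna_processivity_index(body_exonic, tes_region, epsilon: float = 0.0,
                           orientation: str = BODY_OVER_TES):
    """RNA-coverage processivity: same arithmetic, exon-restricted body input."""
    return chip_processivity_index(body_exonic, tes_region, epsilon, orientation)


def occupancy_log_ratio(rpm_condition, rpm_control, epsilon: float = 0.0):
    """Per-gene log2 change of normalized signal, condition over control."""
    kd = np.asarray(rpm_condition, dtype=float)
    ctrl = np.asarray(rpm_control, dtype=float)
    out = np.log2((kd + epsilon) / (ctrl + epsilon))
    return out if out.ndim else float(out)


def index_table(track: SignalTrack, annotation: GenomeAnnotation, *,
                strand_mode: str = "both", exonic_body: bool = False,
                orientation: str = BODY_OVER_TES,
                epsilon: float | None = None,
                min_gene_length: int = MIN_GENE_LENGTH) -> pd.DataFrame:
    """Pausing and processivity indices for every eligible gene in one track.

    Returns a gene-indexed frame with the three window r.p.m. values and the
    derived ``pausing_index`` and ``processivity_index`` columns; genes
    shorter than ``min_gene_length`` get NaN metrics.  ``exonic_body``
    restricts the body window to exons (RNA coverage convention).
    """
    if epsilon is None:
        epsilon = rpm_pseudocount(track)
    rows = {}
    for g in annotation:
        size = annotation.chrom_sizes[g.chrom]
        if g.length < min_gene_length:
            rows[g.gene_id] = (np.nan, np.nan, np.nan)
            continue
        tss = count_window(track, g, TSS_WINDOW, strand_mode=strand_mode,
                           norm=RPM, chrom_size=size)
        if exonic_body:
            body = count_exonic(track, g, BODY_WINDOW, strand_mode=strand_mode,
                                norm=RPM, chrom_size=size)
            tes = count_exonic(track, g, TES_WINDOW, strand_mode=strand_mode,
                               norm=RPM, chrom_size=size)
        else:
            body = count_window(track, g, BODY_WINDOW, strand_mode=strand_mode,
                                norm=RPM, chrom_size=size)
            tes = count_window(track, g, TES_WINDOW, strand_mode=strand_mode,
                               norm=RPM, chrom_size=size)
        rows[g.gene_id] = (tss, body, tes)
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["tss_rpm", "body_rpm", "tes_rpm"])
    df.index.name = "gene_id"
    df["pausing_index"] = pausing_index(df.tss_rpm, df.body_rpm, epsilon)
    df["processivity_index"] = chip_processivity_index(
        df.body_rpm, df.tes_rpm, epsilon, orientation)
    df.attrs.update(orientation=orientation, epsilon=epsilon,
                    strand_mode=strand_mode, sample_id=track.sample_id,
                    condition=track.condition, replicate=track.replicate)
    return df


def antisense_score(track: SignalTrack, gene: GeneModel,
                    chrom_size: int | None = None) -> float:
    """Antisense fraction of reads in the −2000..0 window upstream of the TSS.

    score = antisense-strand reads / total reads in the window; NaN when the
    window holds no reads.  Callers should pre-filter to lone genes so the
    window is not contaminated by a neighbouring gene's sense reads.
    """
    anti = count_window(track, gene, ANTISENSE_WINDOW, strand_mode="antisense",
                        norm="raw", chrom_size=chrom_size)
    sense = count_window(track, gene, ANTISENSE_WINDOW, strand_mode="sense",
                         norm="raw", chrom_size=chrom_size)
    total = anti + sense
    if not np.isfinite(total) or total == 0:
        return np.nan
    return anti / total


def antisense_variation(kd_tracks: list[SignalTrack], ctrl_tracks: list[SignalTrack],
                        annotation: GenomeAnnotation,
                        genes: list[str] | None = None) -> pd.Series:
    """Mean over replicate pairs of log2(score_KD / score_ctrl) per gene."""
    if len(kd_tracks) != len(ctrl_tracks):
        raise ValueError("replicate pairing requires equal track counts")
    ids = annotation.gene_ids if genes is None else list(genes)
    out = {}
    for gid in ids:
        g = annotation[gid]
        size = annotation.chrom_sizes[g.chrom]
        ratios = []
        for kd, ctrl in zip(kd_tracks, ctrl_tracks):
            s_kd = antisense_score(kd, g, size)
            s_ct = antisense_score(ctrl, g, size)
            if np.isfinite(s_kd) and np.isfinite(s_ct) and s_kd > 0 and s_ct > 0:
                ratios.append(np.log2(s_kd / s_ct))
        out[gid] = float(np.mean(ratios)) if ratios else np.nan
    return pd.Series(out, name="antisense_variation")


# ---------------------------------------------------------------------------
# qPCR / NRO arithmetic
# ---------------------------------------------------------------------------

def percent_input(ct_ip: float, ct_input: float, vol_ratio: float) -> float:
    """ChIP enrichment as percent of input: 2^−ΔCT × 100 / (Vol IP / Vol input)."""
    if vol_ratio <= 0:
        raise ValueError("volume ratio must be > 0")
    if ct_ip <= 0 or ct_input <= 0:
        raise ValueError("CT values must be positive")
    return 2.0 ** -(ct_ip - ct_input) * 100.0 / vol_ratio


def ddct_fold_change(ct_target_a: float, ct_ref_a: float,
                     ct_target_b: float, ct_ref_b: float) -> float:
    """Comparative-CT (2^−ΔΔCT) fold change of condition a over condition b."""
    for ct in (ct_target_a, ct_ref_a, ct_target_b, ct_ref_b):
        if ct <= 0:
            raise ValueError("CT values must be positive")
    ddct = (ct_target_a - ct_ref_a) - (ct_target_b - ct_ref_b)
    return 2.0 ** -ddct


NRO_CONTROLS = ("RPS14", "7SK", "KDSR", "PIGB")


def nro_normalize(ct_table: pd.DataFrame, target: str,
                  condition: str, reference_condition: str,
                  controls: tuple[str, ...] = NRO_CONTROLS,
                  mode: str = "averaged") -> dict[str, float] | float:
    """Nuclear-run-on fold change of a target, normalized to control RNAs.

    ``ct_table`` holds mean CT values (technical replicates already averaged)
    indexed by amplicon with one column per condition.  ``mode='individual'``
    returns one ΔΔCT fold change per control; ``mode='averaged'`` uses the
    mean control CT within each condition.
    """
    missing = [c for c in controls if c not in ct_table.index]
    if missing:
        raise ValueError(f"missing control amplicons: {missing}")
    ct_t_a = float(ct_table.loc[target, condition])
    ct_t_b = float(ct_table.loc[target, reference_condition])
    if mode == "individual":
        return {
            c: ddct_fold_change(ct_t_a, float(ct_table.loc[c, condition]),
                                ct_t_b, float(ct_table.loc[c, reference_condition]))
            for c in controls
        }
    if mode == "averaged":
        ref_a = float(np.mean([ct_table.loc[c, condition] for c in controls]))
        ref_b = float(np.mean([ct_table.loc[c, reference_condition] for c in controls]))
        return ddct_fold_change(ct_t_a, ref_a, ct_t_b, ref_b)
    raise ValueError(f"unknown mode {mode!r}")


def nro_processivity_index(fold_change_3prime: float, fold_change_mid: float) -> float:
    """Run-on processivity: fold change at the 3′ amplicon over the mid amplicon."""
    if fold_change_mid <= 0 or fold_change_3prime <= 0:
        raise ValueError("fold changes must be > 0")
    return fold_change_3prime / fold_change_mid
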