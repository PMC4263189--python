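"""Normalized, strand-aware window counting and metagene profiles.

Counts are normalized to r.p.m. (reads per million; the default for ChIP
windows) or RPKM (additionally per kilobase of counted window; the default
for RNA coverage).  Reads are assigned to a window when their 5′ end falls
inside it, so counts over a partition of a window add up exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import (TES, TSS, AnchorWindow, GeneModel, GenomeAnnotation,
                        SignalTrack, resolve_window, strands_for)

RPM = "rpm"
RPKM = "rpkm"
RAW = "raw"


def _normalize(raw: float, length_bp: int, total_reads: float, norm: str) -> float:
    if norm == RAW:
        return raw
    if total_reads <= 0:
        raise ValueError("normalization requires total_reads > 0")
    rpm = raw * 1e6 / total_reads
    if norm == RPM:
        return rpm
    if norm == RPKM:
        return rpm / (length_bp / 1e3)
    raise ValueError(f"unknown normalization {norm!r}")


def count_window(track: SignalTrack, gene: GeneModel, window: AnchorWindow,
                 *, strand_mode: str = "both", norm: str = RPM,
                 chrom_size: int | None = None) -> float:
    """Normalized signal in an anchor window; NaN when the window is empty."""
    chrom, start, end = resolve_window(gene, window, chrom_size)
    if end <= start:
        return np.nan
    raw = track.count(chrom, start, end, strands_for(gene.strand, strand_mode))
    return _normalize(raw, end - start, track.total_reads, norm)


def count_exonic(track: SignalTrack, gene: GeneModel, window: AnchorWindow,
                 *, strand_mode: str = "sense", norm: str = RPKM,
                 chrom_size: int | None = None) -> float:
    """Normalized signal in window ∩ exons; RPKM length is the exonic bp."""
    chrom, start, end = resolve_window(gene, window, chrom_size)
    if end <= start:
        return np.nan
    strands = strands_for(gene.strand, strand_mode)
    raw, exonic_bp = 0.0, 0
    for es, ee in gene.exons:
        s, e = max(es, start), min(ee, end)
        if e > s:
            raw += track.count(chrom, s, e, strands)
            exonic_bp += e - s
    if exonic_bp == 0:
        return np.nan
    return _normalize(raw, exonic_bp, track.total_reads, norm)


def body_window(gene: GeneModel, mode: str = "fixed") -> AnchorWindow | None:
    """The gene-body window: TSS(+500,+1000) or +500 → TES, None if too short."""
    if mode == "fixed":
        if gene.length <= 1000:
            return None
        return AnchorWindow(TSS, 500, 1000)
    if mode == "to_end":
        if gene.length <= 500:
            return None
        return AnchorWindow(TSS, 500, gene.length)
    raise ValueError(f"unknown body mode {mode!r}")


def count_matrix(tracks: list[SignalTrack], annotation: GenomeAnnotation,
                 windows: dict[str, AnchorWindow], *, strand_mode: str = "both",
                 norm: str = RPM) -> pd.DataFrame:
    """Gene × (sample, window) matrix of normalized counts.

    Columns are a MultiIndex of (sample_id, window name); clipped-to-empty
    windows are NaN, not 0.
    """
    cols = {}
    for track in tracks:
        for wname, window in windows.items():
            cols[(track.sample_id, wname)] = [
                count_window(track, g, window, strand_mode=strand_mode, norm=norm,
                             chrom_size=annotation.chrom_sizes[g.chrom])
                for g in annotation
            ]
    out = pd.DataFrame(cols, index=pd.Index(annotation.gene_ids, name="gene_id"))
    out.attrs["norm"] = norm
    out.attrs["strand_mode"] = strand_mode
    return out


@dataclass
class MetageneProfile:
    """Mean normalized coverage in fixed bins around an anchor, 5′→3′ oriented."""

    anchor: str
    bin_edges: np.ndarray  # bp relative to anchor, len n_bins + 1
    values: np.ndarray     # per-bin mean normalized signal
    n_genes: int

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2


def metagene(track: SignalTrack, annotation: GenomeAnnotation,
             genes: list[str] | None = None, *, anchor: str = TES,
             span: int = 2000, bin_width: int = 25,
             strand_mode: str = "both", norm: str = RPM) -> MetageneProfile:
    """Average oriented per-gene coverage in ±span around the anchor.

    Per-gene coverage is normalized first and then averaged across genes, so
    deeply covered genes do not dominate the profile.  Genes whose span would
    be clipped at a chromosome edge are excluded.
    """
    if span % bin_width:
        raise ValueError("span must be a multiple of bin_width")
    ids = annotation.gene_ids if genes is None else list(genes)
    window = AnchorWindow(anchor, -span, span)
    n_bins = 2 * span // bin_width
    acc = np.zeros(n_bins)
    n_used = 0
    for gid in ids:
        g = annotation[gid]
        size = annotation.chrom_sizes[g.chrom]
        chrom, start, end = resolve_window(g, window, size)
        if end - start != 2 * span:
            continue  # clipped at a chromosome edge
        cov = track.coverage_array(chrom, start, end, strands_for(g.strand, strand_mode))
        if g.strand == "-":
            cov = cov[::-1]
        if norm == RPM:
            cov = cov * 1e6 / track.total_reads
        elif norm != RAW:
            raise ValueError(f"metagene supports norm in (rpm, raw), got {norm!r}")
        acc += cov.reshape(n_bins, bin_width).mean(axis=1)
        n_used += 1
    if n_used == 0:
        raise ValueError("no eligible genes for metagene profile")
    edges = np.arange(-span, span + bin_width, bin_width)
    return MetageneProfile(anchor=anchor, bin_edges=edges, values=acc / n_used,
                           n_genes=n_used)
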