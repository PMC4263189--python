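"""IUPAC motif scanning around TSS/TES anchors and motif–gene-set association.

Two elements recur throughout: the NELF-binding element hNBE (RNA hexamer
CUGGGA, scanned as DNA CTGGGA) searched in the promoter window TSS(−250,+250),
and the snRNA 3′ box (AAAAACAGACC) searched upstream of the termination site,
default window TES(−1500,0) with TES(−1000,0) available as the alternative
published window.  Both are scanned on the sense (transcribed) strand by
default, since they act as RNA elements in the nascent transcript.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .genome_io import (TES, TSS, AnchorWindow, GenomeAnnotation, resolve_window)
from .occupancy import fisher_intersection

logger = logging.getLogger("pauseproc")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass(frozen=True)
class MotifSpec:
    """A named IUPAC pattern searched in an anchor window."""

    name: str
    pattern: str
    window: AnchorWindow
    strand_policy: str = "sense"  # or "both"

    def __post_init__(self):
        if not self.pattern:
            raise ValueError("empty motif pattern")
        object.__setattr__(self, "pattern", self.pattern.upper().replace("U", "T"))
        bad = set(self.pattern) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC symbols in {self.name}: {bad}")
        if self.strand_policy not in ("sense", "both"):
            raise ValueError("strand_policy must be 'sense' or 'both'")


HNBE = MotifSpec("hNBE", "CTGGGA", AnchorWindow(TSS, -250, 250))
THREE_PRIME_BOX = MotifSpec("3box", "AAAAACAGACC", AnchorWindow(TES, -1500, 0))
THREE_PRIME_BOX_NARROW = MotifSpec("3box", "AAAAACAGACC", AnchorWindow(TES, -1000, 0))


def _iupac_regex(pattern: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported
    return re.compile("(?=" + "".join(IUPAC[c] for c in pattern) + ")")


def scan_motif(sequence: str, pattern: str,
               strand_policy: str = "sense") -> list[tuple[int, str]]:
    """All exact IUPAC match start positions (0-based) in a DNA sequence.

    ``strand_policy='both'`` also scans the reverse complement, reporting the
    position of the match footprint in sense coordinates; a palindromic hit
    (same footprint both strands) is reported once, on the + strand.
    """
    pattern = pattern.upper().replace("U", "T")
    bad = set(pattern) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC symbols: {bad}")
    sequence = sequence.upper()
    rx = _iupac_regex(pattern)
    hits = [(m.start(), "+") for m in rx.finditer(sequence)]
    if strand_policy == "both":
        rc = str(Seq(sequence).reverse_complement())
        k, L = len(pattern), len(sequence)
        fwd = {p for p, _ in hits}
        for m in rx.finditer(rc):
            pos = L - m.start() - k
            if pos not in fwd:
                hits.append((pos, "-"))
    elif strand_policy != "sense":
        raise ValueError("strand_policy must be 'sense' or 'both'")
    return sorted(hits)


def annotate_genes(annotation: GenomeAnnotation, sequences: dict[str, str],
                   motifs: list[MotifSpec]) -> pd.DataFrame:
    """Per-gene motif presence and hit positions, windows resolved strand-aware.

    For − strand genes the window sequence is reverse-complemented before
    scanning, so positions are reported in transcription coordinates relative
    to the window's upstream edge (add ``window.a`` for the anchor offset).
    Genes whose locus is missing from the sequence set get NA.
    """
    records = {}
    for g in annotation:
        chrom_seq = sequences.get(g.chrom)
        row = {}
        for spec in motifs:
            if chrom_seq is None:
                logger.warning("gene %s: chromosome %s missing from FASTA", g.gene_id, g.chrom)
                row[spec.name] = pd.NA
                row[f"{spec.name}_positions"] = None
                continue
            chrom, s, e = resolve_window(g, spec.window, len(chrom_seq))
            if e <= s:
                row[spec.name] = pd.NA
                row[f"{spec.name}_positions"] = None
                continue
            window_seq = chrom_seq[s:e]
            if g.strand == "-":
                window_seq = str(Seq(window_seq).reverse_complement())
            hits = scan_motif(window_seq, spec.pattern, spec.strand_policy)
            row[spec.name] = len(hits) > 0
            row[f"{spec.name}_positions"] = tuple(spec.window.a + p for p, _ in hits)
        records[g.gene_id] = row
    out = pd.DataFrame.from_dict(records, orient="index")
    out.index.name = "gene_id"
    return out.sort_index()


def motif_enrichment(motif_annotation: pd.DataFrame, gene_sets: dict[str, set[str]],
                     universe: set[str] | None = None,
                     motifs: list[str] | None = None) -> pd.DataFrame:
    """Fisher association of each motif with each gene set (motif vs no motif).

    One row per (motif, set) with the 2×2 table, odds ratio, raw/adjusted p
    and log2 p for scatter-style output.
    """
    import numpy as np

    from .occupancy import bh_adjust

    motifs = motifs or [c for c in motif_annotation.columns if not c.endswith("_positions")]
    known = motif_annotation.dropna(subset=motifs)
    universe = set(known.index) if universe is None else universe & set(known.index)
    rows = []
    for motif in motifs:
        bearing = set(known.index[known[motif].astype(bool)]) & universe
        for label, gene_set in gene_sets.items():
            res = fisher_intersection(gene_set, bearing, universe,
                                      label_a=label, label_b=motif)
            a, b, c, d = res.table
            rows.append({"motif": motif, "gene_set": label, "a": a, "b": b,
                         "c": c, "d": d, "odds_ratio": res.odds_ratio,
                         "p_value": res.p_value})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
        out["log2_p"] = np.log2(out["p_value"])
    return out
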