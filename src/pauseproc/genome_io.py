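"""Genome annotation, signal and peak IO with a strand-aware coordinate engine.

All coordinates are 0-based half-open (BED convention) internally; GTF input
(1-based closed) is converted on read.  Window offsets are expressed in
*transcription* coordinates: negative values lie upstream of the anchor in the
direction of transcription, so the same ``AnchorWindow`` resolves to mirrored
genomic intervals on the two strands.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("pauseproc")

TSS = "TSS"
TES = "TES"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene-level model with one representative TSS/TES.

    ``start``/``end`` are genomic (0-based half-open); the TSS is ``start`` on
    the + strand and ``end`` on the − strand, and vice versa for the TES.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        exons = tuple(sorted(tuple(e) for e in self.exons)) or ((self.start, self.end),)
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError(f"{self.gene_id}: overlapping exons {(s0, e0)} and {(s1, e1)}")
        for s, e in exons:
            if s < self.start or e > self.end or s >= e:
                raise ValueError(f"{self.gene_id}: exon {(s, e)} outside gene span")
        object.__setattr__(self, "exons", exons)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """Strand-aware gene models on named chromosomes."""

    genes: list[GeneModel]
    chrom_sizes: dict[str, int]

    def __post_init__(self):
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise ValueError(f"duplicate gene ids: {list(dup[dup > 1].index)[:5]}")
        for g in self.genes:
            size = self.chrom_sizes.get(g.chrom)
            if size is None:
                raise ValueError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            if g.start < 0 or g.end > size:
                raise ValueError(f"{g.gene_id}: outside chromosome bounds")
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "chrom": [g.chrom for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "tss": [g.tss for g in self.genes],
                "tes": [g.tes for g in self.genes],
                "n_exons": [len(g.exons) for g in self.genes],
            }
        ).set_index("gene_id")


@dataclass(frozen=True)
class AnchorWindow:
    """Window ``(a, b)`` in bp relative to the TSS or TES, transcription-oriented."""

    anchor: str
    a: int
    b: int

    def __post_init__(self):
        if self.anchor not in (TSS, TES):
            raise ValueError(f"anchor must be {TSS!r} or {TES!r}")
        if not self.a < self.b:
            raise ValueError("window requires a < b")

    @property
    def width(self) -> int:
        return self.b - self.a

    def __str__(self) -> str:
        return f"{self.anchor}({self.a:+d},{self.b:+d})"


# Windows used throughout: promoter/pausing TSS±250, body +500..+1000,
# terminal −500..0 from the TES, divergent/antisense −2000..0 from the TSS.
TSS_WINDOW = AnchorWindow(TSS, -250, 250)
BODY_WINDOW = AnchorWindow(TSS, 500, 1000)
TES_WINDOW = AnchorWindow(TES, -500, 0)
ANTISENSE_WINDOW = AnchorWindow(TSS, -2000, 0)


def resolve_window(gene: GeneModel, window: AnchorWindow,
                   chrom_size: int | None = None) -> tuple[str, int, int]:
    """Map a transcription-coordinate window onto the genome.

    On the + strand ``(a, b)`` anchored at position ``A`` maps to
    ``[A+a, A+b)``; on the − strand to ``[A-b, A-a)`` so that positive offsets
    always lie downstream in the direction of transcription.  The result is
    clipped to ``[0, chrom_size)``; a window falling entirely outside is
    returned as an empty interval (start == end).
    """
    anchor_pos = gene.tss if window.anchor == TSS else gene.tes
    if gene.strand == "+":
        start, end = anchor_pos + window.a, anchor_pos + window.b
    else:
        start, end = anchor_pos - window.b, anchor_pos - window.a
    start = max(start, 0)
    if chrom_size is not None:
        end = min(end, chrom_size)
    if end <= start:
        return gene.chrom, start, start
    return gene.chrom, start, end


@dataclass
class PeakSet:
    """Peak calls for one factor, as (chrom, start, end, score) intervals."""

    factor: str
    intervals: pd.DataFrame  # columns chrom, start, end, score

    def __post_init__(self):
        need = {"chrom", "start", "end"}
        if not need.issubset(self.intervals.columns):
            raise ValueError(f"peak table needs columns {need}")
        if "score" not in self.intervals.columns:
            self.intervals = self.intervals.assign(score=0.0)
        if len(self.intervals) and (self.intervals.start >= self.intervals.end).any():
            raise ValueError("peak intervals must satisfy start < end")

    def __len__(self) -> int:
        return len(self.intervals)


class SignalTrack:
    """Strand-resolved signal: read intervals or per-base coverage.

    Reads mode stores the interval table plus sorted 5′-end positions per
    (chrom, strand); window counts assign a read to a window iff its 5′ end
    falls inside (so counts over a partition of a window are additive).
    Coverage mode stores per-base arrays per (chrom, strand).
    """

    def __init__(self, *, reads: pd.DataFrame | None = None,
                 coverage: dict[tuple[str, str], np.ndarray] | None = None,
                 total_reads: float | None = None,
                 sample_id: str = "", condition: str = "", replicate: int = 0):
        if (reads is None) == (coverage is None):
            raise ValueError("provide exactly one of reads or coverage")
        self.sample_id, self.condition, self.replicate = sample_id, condition, replicate
        if reads is not None:
            self.source_kind = "reads"
            reads = reads.reset_index(drop=True)
            self._reads = reads
            self.total_reads = float(len(reads)) if total_reads is None else float(total_reads)
            five = np.where(reads["strand"].to_numpy() == "+",
                            reads["start"].to_numpy(), reads["end"].to_numpy() - 1)
            self._five_prime: dict[tuple[str, str], np.ndarray] = {}
            self._intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
            for (chrom, strand), idx in reads.groupby(["chrom", "strand"], sort=False).groups.items():
                self._five_prime[(chrom, strand)] = np.sort(five[np.asarray(idx)])
            self._max_span = 0
            for chrom, sub in reads.groupby("chrom", sort=False):
                starts = sub["start"].to_numpy()
                ends = sub["end"].to_numpy()
                order = np.argsort(starts, kind="stable")
                self._intervals[chrom] = (starts[order], ends[order],
                                          sub["strand"].to_numpy()[order])
                if len(starts):
                    self._max_span = max(self._max_span, int((ends - starts).max()))
        else:
            self.source_kind = "coverage"
            if total_reads is None:
                raise ValueError("coverage mode requires an explicit library size")
            self._coverage = {k: np.asarray(v, dtype=float) for k, v in coverage.items()}
            for key, arr in self._coverage.items():
                if (arr < 0).any():
                    raise ValueError(f"negative coverage on {key}")
            self.total_reads = float(total_reads)
        if self.total_reads < 0:
            raise ValueError("total_reads must be >= 0")

    # -- raw counting ------------------------------------------------------
    def count(self, chrom: str, start: int, end: int, strands: tuple[str, ...]) -> float:
        """Signal in [start, end) summed over the given absolute strands."""
        if end <= start:
            return np.nan
        total = 0.0
        if self.source_kind == "reads":
            for strand in strands:
                pos = self._five_prime.get((chrom, strand))
                if pos is not None:
                    total += np.searchsorted(pos, end, "left") - np.searchsorted(pos, start, "left")
        else:
            for strand in strands:
                arr = self._coverage.get((chrom, strand))
                if arr is not None:
                    total += float(arr[start:min(end, len(arr))].sum())
        return total

    def coverage_array(self, chrom: str, start: int, end: int,
                       strands: tuple[str, ...]) -> np.ndarray:
        """Per-base pileup over [start, end); reads contribute their full span."""
        n = end - start
        out = np.zeros(n, dtype=float)
        if self.source_kind == "reads":
            entry = self._intervals.get(chrom)
            if entry is None:
                return out
            starts, ends, strand_arr = entry
            hi = np.searchsorted(starts, end, "left")
            lo = np.searchsorted(starts, start - self._max_span, "left")
            sel = slice(lo, hi)
            mask = (ends[sel] > start) & np.isin(strand_arr[sel], strands)
            s = np.clip(starts[sel][mask] - start, 0, n)
            e = np.clip(ends[sel][mask] - start, 0, n)
            # difference-array pileup; ends clipped to n need no subtraction
            np.add.at(out, s[s < n], 1.0)
            np.subtract.at(out, e[e < n], 1.0)
            out = np.cumsum(out)
        else:
            for strand in strands:
                arr = self._coverage.get((chrom, strand))
                if arr is not None:
                    lo, hi = start, min(end, len(arr))
                    if hi > lo:
                        out[: hi - lo] += arr[lo:hi]
        return out


def strands_for(gene_strand: str, strand_mode: str) -> tuple[str, ...]:
    """Absolute strands selected by a gene-relative strand mode."""
    if strand_mode == "both":
        return ("+", "-")
    if strand_mode == "sense":
        return (gene_strand,)
    if strand_mode == "antisense":
        return ("-",) if gene_strand == "+" else ("+",)
    raise ValueError(f"unknown strand_mode {strand_mode!r}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_BED12_COLS = ["chrom", "start", "end", "name", "score", "strand",
               "thickStart", "thickEnd", "itemRgb", "blockCount",
               "blockSizes", "blockStarts"]


def read_annotation(path: str, chrom_sizes: dict[str, int] | None = None) -> GenomeAnnotation:
    """Read gene models from GTF or BED12/BED6.

    Records without a usable strand are rejected with a logged warning.  When
    ``chrom_sizes`` is not given, each chromosome's size is taken as the
    maximum annotated end (sufficient for window clipping on synthetic data).
    """
    path = os.fspath(path)
    if path.endswith((".gtf", ".gff", ".gtf.gz")):
        genes = _read_gtf(path)
    else:
        genes = _read_bed_genes(path)
    if chrom_sizes is None:
        chrom_sizes = {}
        for g in genes:
            chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.end)
    return GenomeAnnotation(genes=genes, chrom_sizes=chrom_sizes)


def _read_gtf(path: str) -> list[GeneModel]:
    import gffutils

    with tempfile.TemporaryDirectory() as tmp:
        db = gffutils.create_db(
            path, os.path.join(tmp, "g.db"), force=True, keep_order=True,
            disable_infer_genes=True, disable_infer_transcripts=True,
            merge_strategy="create_unique",
        )
        genes: list[GeneModel] = []
        exon_map: dict[str, list[tuple[int, int]]] = {}
        for feat in db.features_of_type("exon"):
            gid = feat.attributes.get("gene_id", [None])[0]
            if gid is not None:
                exon_map.setdefault(gid, []).append((feat.start - 1, feat.end))
        for feat in db.features_of_type("gene"):
            gid = feat.attributes.get("gene_id", [feat.id])[0]
            if feat.strand not in "+-":
                logger.warning("skipping gene %s: missing strand", gid)
                continue
            genes.append(GeneModel(
                gene_id=gid, chrom=feat.seqid, strand=feat.strand,
                start=feat.start - 1, end=feat.end,
                exons=tuple(exon_map.get(gid, ())),
            ))
    return genes


def _read_bed_genes(path: str) -> list[GeneModel]:
    first = pd.read_csv(path, sep="\t", header=None, nrows=1, comment="#")
    ncol = first.shape[1]
    cols = _BED12_COLS[:ncol]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    genes = []
    for row in df.itertuples(index=False):
        if getattr(row, "strand", ".") not in "+-":
            logger.warning("skipping record %s: missing strand", getattr(row, "name", "?"))
            continue
        exons: tuple[tuple[int, int], ...] = ()
        if ncol >= 12:
            sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
            offs = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
            exons = tuple((row.start + o, row.start + o + s) for o, s in zip(offs, sizes))
        genes.append(GeneModel(gene_id=str(row.name), chrom=row.chrom, strand=row.strand,
                               start=int(row.start), end=int(row.end), exons=exons))
    return genes


def write_annotation(annotation: GenomeAnnotation, path: str) -> None:
    """Write gene models as GTF (gene + exon features, 1-based closed)."""
    with open(path, "w") as fh:
        for g in annotation:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(f"{g.chrom}\tpauseproc\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")
            for s, e in g.exons:
                fh.write(f"{g.chrom}\tpauseproc\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")


def read_signal(path: str | tuple[str, str], *, total_reads: float | None = None,
                chrom_sizes: dict[str, int] | None = None, **labels) -> SignalTrack:
    """Read a signal track from BED6 reads or a (plus, minus) bedGraph pair.

    Reads mode: ``total_reads`` defaults to the number of records.  Coverage
    mode: ``total_reads`` (library size) and ``chrom_sizes`` are required;
    overlapping bedGraph intervals within one strand are an error.
    """
    if isinstance(path, (tuple, list)):
        if total_reads is None or chrom_sizes is None:
            raise ValueError("coverage mode requires total_reads and chrom_sizes")
        coverage: dict[tuple[str, str], np.ndarray] = {}
        for fname, strand in zip(path, "+-"):
            df = pd.read_csv(fname, sep="\t", header=None,
                             names=["chrom", "start", "end", "value"], comment="#")
            for chrom, sub in df.groupby("chrom"):
                if chrom not in chrom_sizes:
                    logger.warning("skipping unknown chromosome %s in %s", chrom, fname)
                    continue
                sub = sub.sort_values("start")
                if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                    raise ValueError(f"overlapping bedGraph intervals on {chrom} in {fname}")
                arr = coverage.setdefault((chrom, strand), np.zeros(chrom_sizes[chrom]))
                for s, e, v in sub[["start", "end", "value"]].itertuples(index=False):
                    arr[s:e] = v
        return SignalTrack(coverage=coverage, total_reads=total_reads, **labels)
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"],
                     comment="#")
    if chrom_sizes is not None:
        known = df["chrom"].isin(chrom_sizes)
        if not known.all():
            logger.warning("skipping %d reads on unknown chromosomes", (~known).sum())
            df = df[known]
    return SignalTrack(reads=df[["chrom", "start", "end", "strand"]],
                       total_reads=total_reads, **labels)


def write_reads_bed(track: SignalTrack, path: str) -> None:
    if track.source_kind != "reads":
        raise ValueError("only reads-mode tracks can be written as BED6")
    df = track._reads.copy()
    df.insert(3, "name", [f"r{i}" for i in range(len(df))])
    df.insert(4, "score", 0)
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_peaks(path: str, factor: str) -> PeakSet:
    """Read BED/narrowPeak peak calls for one factor."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand",
             "signalValue", "pValue", "qValue", "summit"][: df.shape[1]]
    df.columns = names
    if "score" not in df.columns:
        df["score"] = 0.0
    return PeakSet(factor=factor, intervals=df[["chrom", "start", "end", "score"]])


def write_peaks(peaks: PeakSet, path: str) -> None:
    df = peaks.intervals.copy()
    df.insert(3, "name", [f"{peaks.factor}_{i}" for i in range(len(df))])
    df["strand"] = "."
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_genesets(path: str, annotation: GenomeAnnotation | None = None) -> dict[str, set[str]]:
    """Read named gene sets from a two-column TSV (gene_id, set label)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "label"],
                         dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return {}
    sets: dict[str, set[str]] = {}
    for label, sub in df.groupby("label"):
        sets[label] = set(sub["gene_id"])
    if annotation is not None:
        unknown = {gid for s in sets.values() for gid in s if gid not in annotation}
        if unknown:
            logger.warning("%d gene ids not in annotation (retained)", len(unknown))
    return sets


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
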