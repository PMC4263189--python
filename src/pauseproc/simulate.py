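"""Ground-truth simulator for pausing/processivity analyses.

Emits annotation, genome sequence, strand-specific read tracks, factor peak
sets and a per-gene truth table with the statistical structure the analysis
assumes: TSS-proximal RNAPII enrichment (pause strength π), a flat body
plateau (rate β reads/bp), optional terminal accumulation (τ), strand-specific
RNA coverage with a tunable full-length fraction ρ, divergent antisense reads
upstream of TSSs (fraction α of the body rate), designed factor co-occupancy
combinations, and motif plants conditional on effect group.

Window counts are Poisson so all expectations stay in closed form: for a
control gene, E[pausing index] = π, E[log2 body/TES ChIP ratio] = −log2 τ and
E[RNA TES/body ratio] = ρ.  Knockdown conditions act multiplicatively on
region expectations.  A fixed seed fully determines every emitted file.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import (TES, TSS, AnchorWindow, GeneModel, GenomeAnnotation,
                        PeakSet, SignalTrack, resolve_window, write_annotation,
                        write_fasta, write_peaks, write_reads_bed)

FACTORS = ("NELF", "SPT5", "INTS3", "INTS11")

HNBE_SEQ = "CTGGGA"
BOX3_SEQ = "AAAAACAGACC"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class EffectModel:
    """Multiplicative knockdown effects on per-region read expectations."""

    name: str
    chip_tss: float = 1.0
    chip_body: float = 1.0
    chip_tes: float = 1.0
    rna_body: float = 1.0
    rna_tes: float = 1.0
    polya: float = 1.0
    antisense: float = 1.0


#: INTS11 loss: RNAPII and total-RNA gain over bodies with the terminal
#: windows unchanged (a processivity defect); mature polyA RNA unaffected;
#: divergent antisense doubled.
INTS11_KD = EffectModel("INTS11", chip_body=4.0, rna_body=4.0, antisense=2.0)
#: INTS3 loss: the antagonistic phenotype — body occupancy drops.
INTS3_KD = EffectModel("INTS3", chip_body=0.25, rna_body=0.25, rna_tes=0.25)
CONTROL = EffectModel("control")


@dataclass(frozen=True)
class GroupSpec:
    """One co-occupancy class: its frequency, binding pattern and pause strength."""

    name: str
    frequency: float
    factors: tuple[str, ...]
    pi: float
    affected: bool = False
    tau: float | None = None  # None: tau_affected if affected else 1.0


#: Default design: pause strength rises with the NELF-associated subunits
#: bound, the fully bound class carries the knockdown effect and terminal
#: accumulation, and INTS11 appears only where INTS3 is also bound.
DEFAULT_GROUPS = (
    GroupSpec("unbound", 0.25, (), 1.0),
    GroupSpec("NELF_SPT5", 0.15, ("NELF", "SPT5"), 5.0),
    GroupSpec("NELF_SPT5_INTS3", 0.20, ("NELF", "SPT5", "INTS3"), 2.0),
    GroupSpec("NELF_SPT5_INTS3_INTS11", 0.30,
              ("NELF", "SPT5", "INTS3", "INTS11"), 10.0, affected=True),
    GroupSpec("SPT5_INTS3_INTS11", 0.10, ("SPT5", "INTS3", "INTS11"), 2.0),
)


@dataclass
class SimConfig:
    """Design of one simulated experiment; the seed determines all output."""

    seed: int = 0
    n_genes: int = 120
    gene_length: tuple[int, int] = (2000, 8000)
    gap: tuple[int, int] = (6000, 12000)
    close_neighbor_fraction: float = 0.0
    close_gap: tuple[int, int] = (500, 4000)
    chrom_name: str = "chrSim"
    margin: int = 3000
    chip_rate: float = 1.0          # β: RNAPII body expectation, reads/bp
    rna_rate: float = 0.5           # RNA-Seq sense expectation, reads/bp
    tau_affected: float = 4.0       # terminal RNAPII accumulation, affected genes
    rho: float = 1.0                # full-length fraction of total RNA
    antisense_alpha: float = 0.02   # α: divergent antisense rate, × rna_rate
    upstream_sense_rate: float = 1.0  # unregulated sense background upstream, × rna_rate
    read_length: int = 50
    groups: tuple[GroupSpec, ...] = DEFAULT_GROUPS
    n_ints11_without_ints3: int = 0
    effects: dict[str, EffectModel] = field(default_factory=lambda: {
        "control": CONTROL, "INTS11": INTS11_KD, "INTS3": INTS3_KD})
    n_replicates: int = 3
    hnbe_prob_affected: float = 0.8
    hnbe_prob_background: float = 0.1
    box3_prob_affected: float = 0.8
    box3_prob_background: float = 0.1

    def __post_init__(self):
        total = sum(g.frequency for g in self.groups)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("group frequencies must sum to 1")
        if not 0 < self.rho <= 1:
            raise ValueError("rho must lie in (0, 1]")
        for rate in (self.chip_rate, self.rna_rate, self.antisense_alpha,
                     self.upstream_sense_rate, self.tau_affected):
            if rate < 0:
                raise ValueError("rates must be >= 0")

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, *stream])


_STREAM_ANNOT, _STREAM_CHIP, _STREAM_RNA, _STREAM_MOTIF, _STREAM_PEAK = range(5)


def _condition_code(config: SimConfig, condition: str) -> int:
    names = list(config.effects)
    if condition not in names:
        raise ValueError(f"unknown condition {condition!r}; configured: {names}")
    return names.index(condition)


# ---------------------------------------------------------------------------
# Annotation, sequence and truth
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimConfig
                        ) -> tuple[GenomeAnnotation, dict[str, str], pd.DataFrame]:
    """Place non-overlapping genes on one chromosome and realize the design.

    A configured fraction of genes form deliberate close pairs (gap < 5 kb)
    to exercise the lone-gene filter; all other gaps exceed it.  Returns the
    annotation, random uniform-composition sequences and the per-gene truth
    table (group, factors, π, τ, ρ, α, effect flag, expected indices).
    """
    rng = config.rng(_STREAM_ANNOT)
    n = config.n_genes
    n_close_pairs = int(round(config.close_neighbor_fraction * n / 2))
    close_second = {2 * k + 1 for k in range(n_close_pairs)}

    lengths = rng.integers(config.gene_length[0], config.gene_length[1] + 1, n)
    strands = rng.choice(["+", "-"], n)
    genes: list[GeneModel] = []
    cursor = max(config.margin, 2500)
    for i in range(n):
        genes.append(GeneModel(gene_id=f"g{i:04d}", chrom=config.chrom_name,
                               strand=strands[i], start=int(cursor),
                               end=int(cursor + lengths[i])))
        if i + 1 in close_second:
            gap = int(rng.integers(*config.close_gap))
        else:
            gap = int(rng.integers(*config.gap))
        cursor += lengths[i] + gap
    chrom_size = int(cursor + max(config.margin, 2500))
    annotation = GenomeAnnotation(genes=genes,
                                  chrom_sizes={config.chrom_name: chrom_size})

    freqs = np.array([g.frequency for g in config.groups])
    group_idx = rng.choice(len(config.groups), size=n, p=freqs)
    truth = pd.DataFrame(index=pd.Index([g.gene_id for g in genes], name="gene_id"))
    truth["group"] = [config.groups[k].name for k in group_idx]
    truth["pi"] = [config.groups[k].pi for k in group_idx]
    truth["affected"] = [config.groups[k].affected for k in group_idx]
    for f in FACTORS:
        truth[f] = [f in config.groups[k].factors for k in group_idx]
    # designed violations of the INTS11-requires-INTS3 constraint
    candidates = truth.index[truth["NELF"] & ~truth["INTS3"] & ~truth["INTS11"]]
    n_viol = min(config.n_ints11_without_ints3, len(candidates))
    viol = rng.choice(candidates, size=n_viol, replace=False) if n_viol else []
    truth.loc[viol, "INTS11"] = True
    truth["ints11_without_ints3"] = truth["INTS11"] & ~truth["INTS3"]

    default_tau = np.where(truth["affected"], config.tau_affected, 1.0)
    group_tau = np.array([np.nan if config.groups[k].tau is None else config.groups[k].tau
                          for k in group_idx])
    truth["tau"] = np.where(np.isnan(group_tau), default_tau, group_tau)
    truth["rho"] = config.rho
    truth["alpha"] = config.antisense_alpha
    truth["close_pair"] = [i in close_second or i + 1 in close_second for i in range(n)]
    truth["expected_pausing_index"] = truth["pi"]
    truth["expected_chip_processivity"] = -np.log2(truth["tau"])
    truth["expected_rna_tes_over_body"] = truth["rho"]

    base_codes = rng.integers(0, 4, chrom_size).astype(np.uint8)
    seq = np.frombuffer(b"ACGT", dtype=np.uint8)[base_codes].tobytes().decode("ascii")
    return annotation, {config.chrom_name: seq}, truth


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------

def _draw_region_reads(rng: np.random.Generator, gene: GeneModel,
                       window: AnchorWindow, rate_per_bp: float,
                       strand: str | None, read_length: int,
                       chrom_size: int, exons: bool = False) -> list[np.ndarray]:
    """Poisson read 5′ ends uniform over a (possibly exon-restricted) window.

    ``strand=None`` assigns each read a random strand (unstranded ChIP).
    Returns [starts, ends, strands] arrays in genomic coordinates.
    """
    chrom, s, e = resolve_window(gene, window, chrom_size)
    pieces = [(s, e)]
    if exons:
        pieces = [(max(es, s), min(ee, e)) for es, ee in gene.exons
                  if min(ee, e) > max(es, s)]
    starts_all, ends_all, strands_all = [], [], []
    for ps, pe in pieces:
        n = rng.poisson(rate_per_bp * (pe - ps))
        if n == 0:
            continue
        five = rng.integers(ps, pe, n)
        if strand is None:
            st = rng.choice(["+", "-"], n)
        else:
            st = np.full(n, strand)
        plus = st == "+"
        starts = np.where(plus, five, np.maximum(five - read_length + 1, 0))
        ends = np.where(plus, np.minimum(five + read_length, chrom_size), five + 1)
        starts_all.append(starts)
        ends_all.append(ends)
        strands_all.append(st)
    if not starts_all:
        return [np.empty(0, int), np.empty(0, int), np.empty(0, "<U1")]
    return [np.concatenate(starts_all), np.concatenate(ends_all),
            np.concatenate(strands_all)]


def _make_track(parts: list[list[np.ndarray]], chrom: str, **labels) -> SignalTrack:
    starts = np.concatenate([p[0] for p in parts])
    ends = np.concatenate([p[1] for p in parts])
    strands = np.concatenate([p[2] for p in parts])
    reads = pd.DataFrame({"chrom": chrom, "start": starts.astype(int),
                          "end": ends.astype(int), "strand": strands})
    if len(reads) == 0:
        raise ValueError("simulation produced zero reads genome-wide")
    return SignalTrack(reads=reads, **labels)


def simulate_chip(config: SimConfig, annotation: GenomeAnnotation,
                  truth: pd.DataFrame, condition: str = "control",
                  replicate: int = 1) -> tuple[SignalTrack, dict[str, PeakSet]]:
    """RNAPII ChIP reads (unstranded) plus promoter peak calls per factor.

    Per-bp expectations: β·π in TSS(−250,+250), β in the rest of the body and
    β·τ in TES(−500,0), each scaled by the condition's effect multipliers for
    affected genes.  Peaks are emitted at TSS±100 of every designed bound gene
    and do not vary across conditions or replicates.
    """
    rng = config.rng(_STREAM_CHIP, _condition_code(config, condition), replicate)
    effect = config.effects[condition]
    chrom = config.chrom_name
    size = annotation.chrom_sizes[chrom]
    beta = config.chip_rate
    parts = []
    for g in annotation:
        row = truth.loc[g.gene_id]
        m_tss, m_body, m_tes = ((effect.chip_tss, effect.chip_body, effect.chip_tes)
                                if row.affected else (1.0, 1.0, 1.0))
        L = g.length
        regions = [
            (AnchorWindow(TSS, -250, 250), beta * row.pi * m_tss),
            (AnchorWindow(TSS, 250, L - 500), beta * m_body),
            (AnchorWindow(TES, -500, 0), beta * row.tau * m_tes),
        ]
        for window, rate in regions:
            parts.append(_draw_region_reads(rng, g, window, rate, None,
                                            config.read_length, size))
    track = _make_track(parts, chrom, sample_id=f"chip_{condition}_r{replicate}",
                        condition=condition, replicate=replicate)

    peak_rng = config.rng(_STREAM_PEAK)
    peaks: dict[str, PeakSet] = {}
    for factor in FACTORS:
        rows = []
        for g in annotation:
            if truth.loc[g.gene_id, factor]:
                _, s, e = resolve_window(g, AnchorWindow(TSS, -100, 100), size)
                rows.append((chrom, s, e, float(peak_rng.integers(100, 1000))))
        peaks[factor] = PeakSet(factor=factor, intervals=pd.DataFrame(
            rows, columns=["chrom", "start", "end", "score"]))
    return track, peaks


def simulate_rnaseq(config: SimConfig, annotation: GenomeAnnotation,
                    truth: pd.DataFrame, condition: str = "control",
                    assay: str = "total", replicate: int = 1) -> SignalTrack:
    """Strand-specific RNA-Seq reads over exons.

    ``assay='total'`` attenuates the terminal window TES(−500,0) to ρ·β
    (run-on-like coverage of incomplete transcripts); ``assay='polyA'`` draws
    only from full-length transcripts so body and terminal expectations are
    equal.  Divergent antisense reads are emitted at α·β on the opposite
    strand within TSS(−2000,0), over an unregulated sense-strand upstream
    background so the antisense *fraction* scales with α.
    """
    if assay not in ("total", "polyA"):
        raise ValueError("assay must be 'total' or 'polyA'")
    rng = config.rng(_STREAM_RNA, _condition_code(config, condition),
                     replicate, 0 if assay == "total" else 1)
    effect = config.effects[condition]
    chrom = config.chrom_name
    size = annotation.chrom_sizes[chrom]
    beta = config.rna_rate
    parts = []
    for g in annotation:
        row = truth.loc[g.gene_id]
        if row.affected:
            m_body, m_tes, m_polya, m_anti = (effect.rna_body, effect.rna_tes,
                                              effect.polya, effect.antisense)
        else:
            m_body = m_tes = m_polya = m_anti = 1.0
        L = g.length
        sense = g.strand
        anti = "-" if sense == "+" else "+"
        if assay == "total":
            regions = [
                (AnchorWindow(TSS, 0, L - 500), beta * m_body, sense, True),
                (AnchorWindow(TES, -500, 0), beta * row.rho * m_tes, sense, True),
            ]
        else:
            regions = [(AnchorWindow(TSS, 0, L), beta * m_polya, sense, True)]
        regions += [
            (AnchorWindow(TSS, -2000, 0), beta * row.alpha * m_anti, anti, False),
            (AnchorWindow(TSS, -2000, 0), beta * config.upstream_sense_rate,
             sense, False),
        ]
        for window, rate, strand, exonic in regions:
            parts.append(_draw_region_reads(rng, g, window, rate, strand,
                                            config.read_length, size, exons=exonic))
    return _make_track(parts, chrom,
                       sample_id=f"rna_{assay}_{condition}_r{replicate}",
                       condition=condition, replicate=replicate)


# ---------------------------------------------------------------------------
# Motif planting
# ---------------------------------------------------------------------------

def plant_motifs(config: SimConfig, sequences: dict[str, str],
                 annotation: GenomeAnnotation, truth: pd.DataFrame
                 ) -> tuple[dict[str, str], pd.DataFrame]:
    """Write hNBE/3′-box instances into the sequence with design probabilities.

    hNBE (CTGGGA) lands in TSS(−250,+250) and the 3′ box (AAAAACAGACC) in
    TES(−1500,0), on the transcribed strand (reverse-complemented into the
    reference for − strand genes).  Plant probabilities are conditional on the
    effect group.  The returned truth gains planted flags/positions and the
    realized presence (planted or background) per motif window.
    """
    from .motif_assoc import HNBE, THREE_PRIME_BOX, annotate_genes

    rng = config.rng(_STREAM_MOTIF)
    seq_arrays = {c: bytearray(s, "ascii") for c, s in sequences.items()}
    planted_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in sequences}
    plans = [
        ("hnbe", HNBE_SEQ, AnchorWindow(TSS, -250, 250),
         config.hnbe_prob_affected, config.hnbe_prob_background),
        ("box3", BOX3_SEQ, AnchorWindow(TES, -1500, 0),
         config.box3_prob_affected, config.box3_prob_background),
    ]
    for name, motif, window, p_eff, p_bg in plans:
        truth[f"planted_{name}"] = False
        truth[f"planted_{name}_offset"] = pd.array([pd.NA] * len(truth), dtype="Int64")
        k = len(motif)
        for g in annotation:
            row = truth.loc[g.gene_id]
            if rng.random() >= (p_eff if row.affected else p_bg):
                continue
            size = annotation.chrom_sizes[g.chrom]
            placed = None
            for _ in range(50):
                t = int(rng.integers(window.a, window.b - k + 1))
                anchor = g.tss if window.anchor == TSS else g.tes
                if g.strand == "+":
                    gs = anchor + t
                else:
                    gs = anchor - t - k
                ge = gs + k
                if gs < 0 or ge > size:
                    continue
                if any(gs < pe and ge > ps for ps, pe in planted_spans[g.chrom]):
                    continue  # collision with an earlier plant: redraw
                placed = (t, gs, ge)
                break
            if placed is None:
                continue
            t, gs, ge = placed
            written = motif if g.strand == "+" else motif.translate(_COMPLEMENT)[::-1]
            seq_arrays[g.chrom][gs:ge] = written.encode("ascii")
            planted_spans[g.chrom].append((gs, ge))
            truth.loc[g.gene_id, f"planted_{name}"] = True
            truth.loc[g.gene_id, f"planted_{name}_offset"] = t
    new_seqs = {c: bytes(a).decode("ascii") for c, a in seq_arrays.items()}
    presence = annotate_genes(annotation, new_seqs, [HNBE, THREE_PRIME_BOX])
    truth["has_hnbe"] = presence.loc[truth.index, "hNBE"].astype(bool)
    truth["has_box3"] = presence.loc[truth.index, "3box"].astype(bool)
    return new_seqs, truth


# ---------------------------------------------------------------------------
# Pure-Δ simulation for error-control studies, and fixture export
# ---------------------------------------------------------------------------

def simulate_delta_matrix(n_genes: int, n_replicates: int = 3,
                          effect_fraction: float = 0.0, effect_size: float = 0.0,
                          sigma: float = 0.5, seed: int = 0
                          ) -> tuple[pd.DataFrame, np.ndarray]:
    """Gaussian per-replicate Δ values with a designed affected fraction.

    Affected genes (the first ``round(effect_fraction·m)``) have mean
    ``effect_size``; all others are null.  Returns the Δ matrix and the
    boolean truth vector.
    """
    rng = np.random.default_rng(seed)
    m = n_genes
    n_eff = int(round(effect_fraction * m))
    means = np.zeros(m)
    means[:n_eff] = effect_size
    vals = rng.normal(means[:, None], sigma, size=(m, n_replicates))
    delta = pd.DataFrame(vals, index=[f"g{i:05d}" for i in range(m)],
                         columns=[f"delta_{r + 1}" for r in range(n_replicates)])
    affected = np.zeros(m, dtype=bool)
    affected[:n_eff] = True
    return delta, affected


def write_fixture(config: SimConfig, outdir: str,
                  conditions: tuple[str, ...] = ("control", "INTS11"),
                  rna: bool = True) -> dict[str, str]:
    """Emit a complete text fixture: GTF, FASTA, BED6 reads, peaks and truth.

    Returns a manifest of the written paths.  The SimConfig is echoed as JSON
    next to the data.
    """
    os.makedirs(outdir, exist_ok=True)
    annotation, seqs, truth = simulate_annotation(config)
    seqs, truth = plant_motifs(config, seqs, annotation, truth)
    manifest: dict[str, str] = {}

    def _path(name: str) -> str:
        manifest[name] = os.path.join(outdir, name)
        return manifest[name]

    write_annotation(annotation, _path("genes.gtf"))
    write_fasta(seqs, _path("genome.fa"))
    peaks_written = False
    for condition in conditions:
        for rep in range(1, config.n_replicates + 1):
            track, peaks = simulate_chip(config, annotation, truth, condition, rep)
            write_reads_bed(track, _path(f"chip_{condition}_r{rep}.bed"))
            if not peaks_written:
                for factor, pk in peaks.items():
                    write_peaks(pk, _path(f"peaks_{factor}.narrowPeak"))
                peaks_written = True
            if rna:
                rna_track = simulate_rnaseq(config, annotation, truth, condition,
                                            "total", rep)
                write_reads_bed(rna_track, _path(f"rna_total_{condition}_r{rep}.bed"))
    truth.to_csv(_path("truth.tsv"), sep="\t")
    cfg = dataclasses.asdict(config)
    cfg["groups"] = [dataclasses.asdict(g) for g in config.groups]
    cfg["effects"] = {k: dataclasses.asdict(v) for k, v in config.effects.items()}
    with open(_path("sim_config.json"), "w") as fh:
        json.dump(cfg, fh, indent=2)
    return manifest
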