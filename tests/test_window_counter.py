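import numpy as np
import pandas as pd
import pytest

from pauseproc import (TES, TSS, AnchorWindow, GeneModel, GenomeAnnotation,
                       SignalTrack, body_window, count_exonic, count_matrix,
                       count_window, metagene, resolve_window)
from pauseproc.genome_io import strands_for

from conftest import random_reads_track


def track_from_positions(positions, chrom="chr1", strand="+", total_reads=None):
    starts = np.asarray(positions)
    return SignalTrack(reads=pd.DataFrame({
        "chrom": chrom, "start": starts, "end": starts + 50, "strand": strand,
    }), total_reads=total_reads)


class TestNormalization:
    def test_rpm_arithmetic(self):
        g = GeneModel("g", "chr1", "+", 1000, 9000)
        track = track_from_positions(np.linspace(1050, 1200, 50, dtype=int),
                                     total_reads=1e7)
        rpm = count_window(track, g, AnchorWindow(TSS, 0, 500), norm="rpm")
        assert rpm == pytest.approx(5.0)

    def test_rpkm_arithmetic(self):
        g = GeneModel("g", "chr1", "+", 1000, 9000)
        track = track_from_positions(np.linspace(1000, 2990, 10, dtype=int),
                                     total_reads=1e6)
        rpkm = count_window(track, g, AnchorWindow(TSS, 0, 2000), norm="rpkm")
        assert rpkm == pytest.approx(5.0)  # 10 reads / 2 kb / 1e6

    def test_empty_window_is_nan(self):
        g = GeneModel("g", "chr1", "+", 100, 2000)
        track = track_from_positions([500])
        assert np.isnan(count_window(track, g, AnchorWindow(TSS, -500, -200),
                                     chrom_size=2000))


class TestCountOracle:
    def test_counts_equal_brute_force_containment(self, tiny_annotation):
        """Window counts equal an O(n·m) per-read 5′-end containment scan."""
        rng = np.random.default_rng(13)
        track = random_reads_track(rng, tiny_annotation.chrom_sizes, 2000)
        reads = track._reads
        five = np.where(reads.strand == "+", reads.start, reads.end - 1)
        windows = [AnchorWindow(TSS, -250, 250), AnchorWindow(TSS, 500, 1000),
                   AnchorWindow(TES, -500, 0), AnchorWindow(TSS, -2000, 0)]
        for g in tiny_annotation:
            for window in windows:
                for mode in ("both", "sense", "antisense"):
                    chrom, s, e = resolve_window(g, window,
                                                 tiny_annotation.chrom_sizes[g.chrom])
                    strands = strands_for(g.strand, mode)
                    expected = sum(1 for c, p, st in zip(reads.chrom, five, reads.strand)
                                   if c == chrom and s <= p < e and st in strands)
                    got = count_window(track, g, window, strand_mode=mode, norm="raw",
                                       chrom_size=tiny_annotation.chrom_sizes[g.chrom])
                    assert got == expected

    def test_additivity_of_split_windows(self, small_chip, small_sim):
        _, annotation, _, _ = small_sim
        track, _ = small_chip
        for g in list(annotation)[:10]:
            whole = count_window(track, g, AnchorWindow(TSS, 500, 1000), norm="raw")
            left = count_window(track, g, AnchorWindow(TSS, 500, 750), norm="raw")
            right = count_window(track, g, AnchorWindow(TSS, 750, 1000), norm="raw")
            assert whole == left + right

    def test_strand_symmetry_of_sense_counts(self, tiny_annotation):
        """Reflecting the genome (reads + genes, strands flipped) preserves
        sense-mode counts: transcription-coordinate windows are mirror-safe."""
        rng = np.random.default_rng(5)
        sizes = tiny_annotation.chrom_sizes
        track = random_reads_track(rng, sizes, 500)
        reads = track._reads
        n = reads["chrom"].map(sizes)
        mirrored_reads = pd.DataFrame({
            "chrom": reads["chrom"],
            "start": n - reads["end"],
            "end": n - reads["start"],
            "strand": reads["strand"].map({"+": "-", "-": "+"}),
        })
        mirrored_track = SignalTrack(reads=mirrored_reads)
        for g in tiny_annotation:
            size = sizes[g.chrom]
            mirrored_gene = GeneModel(
                g.gene_id, g.chrom, "-" if g.strand == "+" else "+",
                size - g.end, size - g.start,
                exons=tuple(sorted((size - e, size - s) for s, e in g.exons)))
            for mode in ("sense", "antisense", "both"):
                w = AnchorWindow(TSS, -500, 1500)
                a = count_window(track, g, w, strand_mode=mode, norm="raw",
                                 chrom_size=size)
                b = count_window(mirrored_track, mirrored_gene, w,
                                 strand_mode=mode, norm="raw", chrom_size=size)
                assert a == b


class TestExonicCounts:
    def test_single_exon_equals_plain_count(self):
        g = GeneModel("g", "chr1", "+", 1000, 9000)
        track = track_from_positions(np.arange(1500, 2500, 10))
        w = AnchorWindow(TSS, 0, 3000)
        assert count_exonic(track, g, w, strand_mode="both", norm="raw") == \
            count_window(track, g, w, strand_mode="both", norm="raw")

    def test_intron_reads_count_zero(self):
        g = GeneModel("g", "chr1", "+", 1000, 9000,
                      exons=((1000, 2000), (5000, 9000)))
        track = track_from_positions(np.arange(3000, 4000, 50))  # intron only
        assert count_exonic(track, g, AnchorWindow(TSS, 0, 8000),
                            strand_mode="both", norm="raw") == 0

    def test_multi_exon_matches_intersection_oracle(self, tiny_annotation):
        rng = np.random.default_rng(21)
        track = random_reads_track(rng, tiny_annotation.chrom_sizes, 3000)
        g = tiny_annotation["exonic_gene"]
        w = AnchorWindow(TSS, 500, 9500)
        chrom, ws, we = resolve_window(g, w, tiny_annotation.chrom_sizes[g.chrom])
        reads = track._reads
        five = np.where(reads.strand == "+", reads.start, reads.end - 1)
        pieces = [(max(es, ws), min(ee, we)) for es, ee in g.exons
                  if min(ee, we) > max(es, ws)]
        expected = sum(1 for c, p in zip(reads.chrom, five)
                       if c == chrom and any(s <= p < e for s, e in pieces))
        got = count_exonic(track, g, w, strand_mode="both", norm="raw")
        assert got == expected

    def test_rpkm_uses_exonic_length(self):
        g = GeneModel("g", "chr1", "+", 0, 10000, exons=((0, 1000), (9000, 10000)))
        track = track_from_positions(np.arange(0, 1000, 100), total_reads=1e6)
        got = count_exonic(track, g, AnchorWindow(TSS, 0, 10000), strand_mode="both")
        assert got == pytest.approx(10 / 2.0)  # 10 reads over 2 kb exonic


class TestBodyWindow:
    def test_fixed_mode(self):
        g = GeneModel("g", "chr1", "+", 0, 10000)
        w = body_window(g, "fixed")
        assert (w.anchor, w.a, w.b) == (TSS, 500, 1000)

    def test_to_end_mode_spans_to_tes(self):
        g = GeneModel("g", "chr1", "+", 0, 10000)
        w = body_window(g, "to_end")
        assert (w.a, w.b) == (500, 10000)
        assert resolve_window(g, w) == ("chr1", 500, 10000)

    def test_short_gene_flagged(self):
        assert body_window(GeneModel("g", "chr1", "+", 0, 800), "fixed") is None


class TestMetagene:
    def test_uniform_coverage_gives_flat_profile(self):
        cov = {("chr1", "+"): np.ones(30000), ("chr1", "-"): np.ones(30000)}
        track = SignalTrack(coverage=cov, total_reads=1e6)
        ann = GenomeAnnotation([GeneModel("g1", "chr1", "+", 5000, 15000),
                                GeneModel("g2", "chr1", "-", 18000, 26000)],
                               {"chr1": 30000})
        prof = metagene(track, ann, anchor=TES, norm="raw")
        np.testing.assert_allclose(prof.values, 2.0)  # both strands summed
        assert prof.n_genes == 2

    def test_unit_spike_at_anchor_lands_in_zero_bin(self):
        cov = {("chr1", "+"): np.zeros(30000)}
        cov[("chr1", "+")][15000] = 25.0
        cov[("chr1", "+")][8000 - 1] = 25.0  # − strand gene anchor, mirrored
        track = SignalTrack(coverage=cov, total_reads=1e6)
        ann = GenomeAnnotation([GeneModel("g1", "chr1", "+", 5000, 15000),
                                GeneModel("g2", "chr1", "-", 8000, 20000)],
                               {"chr1": 30000})
        prof = metagene(track, ann, anchor=TES, norm="raw", strand_mode="both")
        nonzero = np.nonzero(prof.values)[0]
        # both spikes sit at transcription offset 0 from the TES: one bin only
        assert list(prof.bin_edges[nonzero]) == [0]
        assert prof.values[nonzero].sum() == pytest.approx(1.0)  # 25/25 per gene

    def test_profile_matches_naive_per_gene_loop(self, small_sim, small_chip):
        _, annotation, _, _ = small_sim
        track, _ = small_chip
        span, width = 2000, 25
        ids = annotation.gene_ids[:12]
        prof = metagene(track, annotation, ids, anchor=TES, span=span,
                        bin_width=width, norm="rpm")
        acc = np.zeros(2 * span // width)
        for gid in ids:
            g = annotation[gid]
            a = g.tes - span if g.strand == "+" else g.tes - span
            cov = np.zeros(2 * span)
            for row in track._reads.itertuples(index=False):
                lo = max(row.start, a)
                hi = min(row.end, a + 2 * span)
                if hi > lo:
                    cov[lo - a:hi - a] += 1
            if g.strand == "-":
                cov = cov[::-1]
            acc += (cov * 1e6 / track.total_reads).reshape(-1, width).mean(axis=1)
        np.testing.assert_allclose(prof.values, acc / len(ids), rtol=1e-12)

    def test_single_gene_profile_is_its_oriented_coverage(self):
        cov = {("chr1", "+"): np.arange(30000, dtype=float)}
        track = SignalTrack(coverage=cov, total_reads=1e6)
        g = GeneModel("g", "chr1", "-", 5000, 15000)
        ann = GenomeAnnotation([g], {"chr1": 30000})
        prof = metagene(track, ann, anchor=TSS, span=1000, bin_width=1, norm="raw")
        expected = np.arange(14000, 16000, dtype=float)[::-1]
        np.testing.assert_allclose(prof.values, expected)

    def test_no_eligible_genes_raises(self):
        track = SignalTrack(coverage={("chr1", "+"): np.ones(3000)}, total_reads=10)
        ann = GenomeAnnotation([GeneModel("g", "chr1", "+", 100, 2900)], {"chr1": 3000})
        with pytest.raises(ValueError, match="no eligible genes"):
            metagene(track, ann, anchor=TES)  # ±2000 span always clipped


def test_count_matrix_layout_and_nan(self_=None):
    g1 = GeneModel("g1", "chr1", "+", 5000, 15000)
    g2 = GeneModel("g2", "chr1", "+", 100, 4000)  # upstream window clipped empty
    ann = GenomeAnnotation([g1, g2], {"chr1": 20000})
    track = track_from_positions(np.arange(4750, 5250, 10), total_reads=1000)
    track.sample_id = "s1"
    mat = count_matrix([track], ann, {"tss": AnchorWindow(TSS, -250, 250),
                                      "up": AnchorWindow(TSS, -3000, -2000)})
    assert mat.loc["g1", ("s1", "tss")] == pytest.approx(50 * 1e6 / 1000)
    assert np.isnan(mat.loc["g2", ("s1", "up")])
    assert mat.attrs["norm"] == "rpm"
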