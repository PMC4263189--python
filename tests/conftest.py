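import numpy as np
import pandas as pd
import pytest

from pauseproc import (GeneModel, GenomeAnnotation, SignalTrack, SimConfig,
                       simulate_annotation, simulate_chip, simulate_rnaseq)


@pytest.fixture(scope="session")
def tiny_annotation():
    """Three hand-built genes on two chromosomes, one multi-exon, one − strand."""
    genes = [
        GeneModel("plus_gene", "chr1", "+", 1000, 11000),
        GeneModel("minus_gene", "chr1", "-", 20000, 28000),
        GeneModel("exonic_gene", "chr2", "+", 5000, 15000,
                  exons=((5000, 7000), (9000, 11000), (13000, 15000))),
    ]
    return GenomeAnnotation(genes, {"chr1": 40000, "chr2": 30000})


def random_reads_track(rng, chrom_sizes, n_reads, read_length=50, **labels):
    """Uniform random read intervals over the given chromosomes."""
    chroms = rng.choice(list(chrom_sizes), n_reads)
    starts = np.array([rng.integers(0, chrom_sizes[c] - read_length) for c in chroms])
    return SignalTrack(
        reads=pd.DataFrame({"chrom": chroms, "start": starts,
                            "end": starts + read_length,
                            "strand": rng.choice(["+", "-"], n_reads)}),
        **labels,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A shared small simulated experiment (annotation, sequences, truth)."""
    config = SimConfig(seed=11, n_genes=40, chip_rate=0.5, rna_rate=0.5)
    annotation, sequences, truth = simulate_annotation(config)
    return config, annotation, sequences, truth


@pytest.fixture(scope="session")
def small_chip(small_sim):
    config, annotation, _, truth = small_sim
    track, peaks = simulate_chip(config, annotation, truth, "control")
    return track, peaks


@pytest.fixture(scope="session")
def small_rna(small_sim):
    config, annotation, _, truth = small_sim
    return simulate_rnaseq(config, annotation, truth, "control", "total")
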