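# pauseproc

Window-anchored analysis of RNA polymerase II (RNAPII) promoter-proximal
pausing and transcriptional processivity, for genomicists studying how
elongation factors (NELF/DSIF) and the Integrator complex (INTScom) shape
the transcription cycle at coding genes.

From a gene annotation, strand-specific read intervals or coverage tracks,
ChIP-Seq peak calls and genome sequence, the package computes:

* **Pausing index** — normalized RNAPII signal in TSS ± 250 bp over the gene
  body (+500..+1000 from TSS): `PI = (TSS + ε)/(body + ε)`. High PI = strong
  pausing.
* **Processivity index** — `log2((body + ε)/(TES−500..0 + ε))` for ChIP
  occupancy, with the mirrored TES/body orientation available for RNA
  coverage (exon-restricted body window, RPKM). Values below the control
  condition mean polymerase/transcripts fail to reach the gene end.
* **Factor co-occupancy groups** — peak-to-promoter assignment (≥ 1 bp
  overlap with TSS ± 250), mutually exclusive binding-pattern groups,
  Fisher-exact set intersections with Benjamini–Hochberg correction, the
  ±5 kb lone-gene filter, and binding-ranked gene lists.
* **Motif association** — exact IUPAC scanning of the hNBE/TAR element
  (CUGGGA → CTGGGA) at TSSs and the snRNA 3′ box (AAAAACAGACC) near TESs,
  strand-aware, with Fisher enrichment against gene sets.
* **Differential processivity** — per-replicate Δ indices, an
  empirical-Bayes moderated t (validated against limma's `eBayes`), Storey
  q-values (fixed λ = 0.5), normal-model change probabilities, pair-wise
  Wilcoxon tests, defect calling, and TESA (termination-site-associated
  RNAPII peak) detection on TES-anchored metagene profiles.
* **qPCR/NRO arithmetic** — percent of input, 2^−ΔΔCT, four-control
  nuclear-run-on normalization and the 3′/mid run-on processivity ratio.
* A fully deterministic **simulator** with closed-form expectations
  (`E[PI] = π`, `E[ProcI] = −log2 τ`, `E[TES/body] = ρ`) that emits GTF,
  FASTA, BED6 reads, narrowPeak files and a per-gene truth table, so every
  stage is testable with known ground truth.

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

Simulate a 120-gene experiment whose pause strength is designed to rise with
the NELF-associated Integrator subunits bound, then recover the design:

```python
from pauseproc import (SimConfig, simulate_annotation, simulate_chip,
                       index_table, pairwise_wilcoxon)

config = SimConfig(seed=0, n_genes=120)
annotation, sequences, truth = simulate_annotation(config)
track, peaks = simulate_chip(config, annotation, truth, "control")

table = index_table(track, annotation).join(truth)
print(table.groupby("group")[["pausing_index", "processivity_index"]]
      .median().round(2))
```

```
                        pausing_index  processivity_index
group
NELF_SPT5                        5.15               -0.02
NELF_SPT5_INTS3                  1.99               -0.01
NELF_SPT5_INTS3_INTS11           9.94               -2.00
SPT5_INTS3_INTS11                1.97                0.02
unbound                          1.02               -0.04
```

The medians land on the designed pause strengths (π = 5, 2, 10, 2, 1) and the
fully bound class shows the designed terminal RNAPII accumulation
(−log2 τ = −2 at τ = 4) — the profile of genes whose termination window
gains polymerase. The group contrast is sharp:

```python
p = pairwise_wilcoxon(
    table.loc[table.group == "NELF_SPT5_INTS3_INTS11", "pausing_index"],
    table.loc[table.group == "unbound", "pausing_index"], paired=False)
# p = 5.36e-12
```

A thin CLI covers the common entry points:

```sh
pauseproc simulate --seed 0 --n-genes 120 --out fixtures/
pauseproc indices --annotation fixtures/genes.gtf \
    --reads fixtures/chip_control_r1.bed --out indices.tsv
pauseproc motifs --annotation fixtures/genes.gtf \
    --fasta fixtures/genome.fa --out motifs.tsv
```

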