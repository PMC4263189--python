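# Methods

## Scope and model

`pauseproc` quantifies two window-anchored properties of RNA polymerase II
(RNAPII) transcription from strand-aware interval data:

* **Promoter-proximal pausing.** The pausing index of a gene is the ratio of
  normalized signal in the promoter window TSS ± 250 bp to the gene-body
  window TSS +500..+1000 bp:

      PI = (TSS_rpm + ε) / (body_rpm + ε)

  High values indicate polymerase accumulated at the pause site relative to
  the elongating pool.

* **Processivity.** The processivity index is the log2 ratio of body signal
  to terminal-window signal (TES −500..0 bp):

      ProcI = log2((body_rpm + ε) / (TES_rpm + ε))

  For ChIP occupancy the body/TES orientation is the default; RNA coverage
  (where the literature convention is sometimes TES/body) is the same
  arithmetic behind an explicit `orientation` flag, and the orientation in
  force is recorded in the table metadata so downstream sign conventions are
  never ambiguous.

All coordinates are 0-based half-open internally (BED convention; GTF is
converted on read), and window offsets are *transcription* coordinates:
negative offsets are upstream of the anchor in the direction of
transcription, so the same window resolves to mirrored genomic intervals on
the two strands. "TSS ± 250" is the half-open interval [TSS−250, TSS+250),
width 500. Multi-isoform loci are collapsed to one representative TSS/TES per
gene id.

Reads are assigned to a window when their 5′ end falls inside it, making
counts additive over a partition of the window; coverage-mode tracks sum
per-base values instead. ChIP counts ignore strand; RNA counts are
sense/antisense-resolved against the gene's strand. Normalization is r.p.m.
(reads per million) for ChIP windows and RPKM (additionally per kilobase of
counted — exonic where applicable — window) for RNA.

## Pseudocount, filters and numerical choices

* ε defaults to the r.p.m. equivalent of one read (10⁶/library size), applied
  symmetrically to numerator and denominator. It keeps indices finite and
  rank-preserving on zero-count windows and vanishes as depth grows.
* Genes shorter than 1.5 kb are excluded from index computation: the
  promoter, body and terminal windows would overlap.
* Log base 2 throughout.
* Empty (clipped) windows propagate as NA, never as 0.
* The lone-gene filter retains a gene only when no other gene's span overlaps
  its span padded by ±5 kb; it is strand-agnostic and idempotent. Antisense
  scoring should only be applied to lone genes, because the upstream window
  of a crowded gene contains the neighbor's sense reads.

## Co-occupancy, motifs and set statistics

A gene is called bound by a factor when any peak overlaps the promoter window
(TSS −250..+250) by ≥ 1 bp. Co-occupancy groups are complete binding patterns
over the factor set (NELF, SPT5, INTS3, INTS11), hence mutually exclusive by
construction; genes binding nothing form the `unbound` control group.
Set-intersection statistics use the two-sided Fisher exact test (one-sided
available for directional claims) with the unconditional odds ratio and a
Haldane 0.5 correction on zero cells (odds ratio 1 when a margin is zero —
no contrast). Multiplicity is handled by Benjamini–Hochberg.

Motif scanning is exact IUPAC matching (U mapped to T; overlapping hits all
reported; on `both`-strand scans a footprint matching both strands is
reported once). The two built-in elements are the NELF-binding element hNBE
(CTGGGA) in TSS(−250,+250) and the snRNA 3′ box (AAAAACAGACC) in
TES(−1500,0), both scanned on the sense strand by default since they act in
the nascent RNA. Two published window widths exist for the 3′ box; both are
provided (`THREE_PRIME_BOX`, 1500 bp; `THREE_PRIME_BOX_NARROW`, 1000 bp) and
the choice is surfaced rather than silently resolved. For − strand genes the
window sequence is reverse-complemented before scanning, so hit positions are
transcription-relative.

## Differential processivity

Per-gene, per-replicate index differences Δ = KD − control (replicate *i*
paired with replicate *i*) feed a one-sample empirical-Bayes moderated t:
gene-wise variances s² (df = R−1) are shrunk toward a prior (d₀, s₀²)
estimated by matching the mean and variance of log s² to a scaled-F model via
the digamma/trigamma method of moments (trigamma inverted by Newton
iteration); the posterior variance is s̃² = (d₀s₀² + d·s²)/(d₀+d) and t =
mean(Δ)/(s̃/√R) on d₀+d df. The implementation is validated in the test suite
against limma's `eBayes` to nine digits. d₀ → 0 recovers the ordinary t; d₀ →
∞ pins the variance at s₀².

P-values become Storey q-values with π̂₀ = #{p>λ}/(m(1−λ)) at fixed λ = 0.5
(the spline estimator is deliberately not reimplemented; the fixed-λ form is
stable at small m and reduces exactly to Benjamini–Hochberg when π̂₀ = 1).
A processivity *defect* is a gene with q below threshold (0.01/0.05/0.20
supported) and Δ indicating relatively decreased terminal signal — a
decrease under the tes/body orientation.

Normal-model change probabilities use a null mean/sd estimated from a
declared control gene set (Φ tail in the declared direction), reported with a
QQ correlation diagnostic for the normality assumption. Group comparisons use
Wilcoxon tests: signed-rank for paired designs (zeros dropped; exact
enumeration when ≤ 12 untied non-zero pairs, else normal approximation with
continuity correction), rank-sum otherwise (exact when min(n,m) ≤ 10 without
ties). Two-sided by default.

The TESA (termination-site-associated) peak score is max bin value in
TES(−500,0) over the mean of the TES(−2000,−500) flank on a TES-anchored
profile, called present at score ≥ 1.5. The threshold and flank are package
choices — the peak was originally a visual feature of averaged profiles, not
a quantified one.

## Simulator

The simulator emits annotation (GTF), uniform-composition sequence (FASTA),
strand-specific 50-bp reads (BED6), promoter peaks (narrowPeak) and a
machine-readable truth table, fully determined by one seed (independent
deterministic substreams per emitter/condition/replicate).

Per-gene read 5′ ends are Poisson with piecewise-constant per-bp expectation:

* ChIP: β·π in TSS(−250,+250), β elsewhere in the body, β·τ in TES(−500,0);
  default β = 1 read/bp, so a 2–8 kb gene carries well over 2000 reads.
* Total RNA: β over exons, attenuated to ρ·β in TES(−500,0) (ρ = full-length
  fraction); polyA RNA draws only full-length transcripts (no attenuation).
* Antisense: α·β on the opposite strand in TSS(−2000,0), emitted over an
  unregulated sense-strand upstream background (rate γ·β, default γ = 1,
  emulating run-through/background transcription). The background makes the
  antisense *fraction* ≈ α/γ, so a knockdown that doubles α doubles the
  fraction — without it the fraction would saturate at 1 and carry no signal.

Poisson (rather than negative-binomial) counts keep expectations closed-form:
E[PI] = π, E[ProcI] = −log2 τ, E[RNA TES/body] = ρ, so recovery tests compare
against exact truths. Overdispersion, fragment-length modeling, sequencing
error and realistic base composition are intentionally absent; passing
recovery tests therefore demonstrates correctness of the estimators under
the assumed sampling model, not robustness to real-data artifacts.

Knockdown conditions act multiplicatively on region expectations of affected
genes (the fully bound NELF/SPT5/INTS3/INTS11 class by default): the
INTS11-like model multiplies ChIP and total-RNA body rates ×4 with terminal
windows and polyA unchanged and antisense ×2 (pause release without
completion — a processivity defect); the INTS3-like model multiplies body
rates ×0.25 (the antagonistic phenotype). Pause strength rises with the
NELF-associated subunits bound (1/2/5/10 across the default groups), INTS11
appears only where INTS3 is bound (a configurable number of designed
violations exercises the consistency check), and motif plants (hNBE at TSS,
3′ box at TES, written on the transcribed strand) are conditional on the
effect group (defaults 0.8 affected / 0.1 background). After planting, the
truth table records *realized* presence per window — planted or background —
since an 11-mer has negligible background rate but the hexamer does not.

Because the simulated mini-genome has a large affected fraction (~30%),
global occupancy changes shift the r.p.m. denominator in knockdowns; on a
real genome the affected genes are a tiny fraction and the shift is
negligible. Cross-condition occupancy comparisons are therefore referenced
to non-deregulated control genes (affected median minus control median),
which is also how variations are compared in practice.

## Problem sizes used in tests and the acceptance script

Oracle-equivalence checks run on exhaustive small enumerations (all 5550
2×2 tables with margins ≤ 12; all sign patterns for n ≤ 10) and 1000 random
sequences. Parameter recovery uses 800 genes (200 per designed group) at
≥ 2000 reads/gene; error control uses 200 pure-null runs of 2000 genes × 3
replicates plus one effect run (20% affected, Δ = −2, σ = 0.5); phenotype
checks use 150 genes; motif/TESA recovery uses 500 genes with three
replicates per condition. These sizes give stable medians and tight
Monte-Carlo error while keeping a full run to a couple of minutes.

## Known limitations

* No input-chromatin or spike-in normalization; indices assume comparable
  backgrounds within a track.
* The qPCR/NRO helpers implement the standard comparative-CT arithmetic
  (percent of input, 2^−ΔΔCT, four-control run-on normalization, 3′/mid
  fold-change ratio) and expect technical replicates to be averaged upstream.
* Exact Wilcoxon enumeration is skipped in the presence of ties (normal
  approximation is used); the monotone-transform invariance holds for the
  rank-sum test, not the paired signed-rank, whose ranks depend on the scale
  of the differences.
* The paired Δ design assumes replicate-index pairing between conditions.
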