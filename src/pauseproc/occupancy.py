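"""Peak-to-promoter assignment, factor co-occupancy groups and set statistics."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import TSS_WINDOW, AnchorWindow, GenomeAnnotation, PeakSet, resolve_window

logger = logging.getLogger("pauseproc")


def assign_peaks_to_tss(peaks: PeakSet, annotation: GenomeAnnotation,
                        promoter_window: AnchorWindow = TSS_WINDOW) -> pd.Series:
    """Boolean bound/unbound per gene: ≥1 bp overlap of any peak with the promoter.

    Returns a gene-indexed boolean Series named after the factor.
    """
    if len(peaks) == 0:
        logger.warning("empty peak set for %s: all genes unbound", peaks.factor)
        return pd.Series(False, index=pd.Index(annotation.gene_ids, name="gene_id"),
                         name=peaks.factor)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in peaks.intervals.groupby("chrom"):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        order = np.argsort(starts, kind="stable")
        # running max of ends lets "any peak with start < e overlaps s" be O(log n)
        by_chrom[chrom] = (starts[order], np.maximum.accumulate(ends[order]))
    bound = {}
    for g in annotation:
        chrom, s, e = resolve_window(g, promoter_window, annotation.chrom_sizes[g.chrom])
        entry = by_chrom.get(chrom)
        if entry is None or e <= s:
            bound[g.gene_id] = False
            continue
        starts, max_ends = entry
        k = np.searchsorted(starts, e, "left")
        bound[g.gene_id] = bool(k > 0 and max_ends[k - 1] > s)
    out = pd.Series(bound, name=peaks.factor)
    out.index.name = "gene_id"
    return out


def binding_matrix(peak_sets: list[PeakSet], annotation: GenomeAnnotation,
                   promoter_window: AnchorWindow = TSS_WINDOW) -> pd.DataFrame:
    """Gene × factor boolean matrix from promoter–peak intersection."""
    cols = [assign_peaks_to_tss(p, annotation, promoter_window) for p in peak_sets]
    return pd.concat(cols, axis=1)


def define_groups(matrix: pd.DataFrame,
                  specs: dict[str, dict[str, bool]]) -> pd.Series:
    """Assign each gene to exactly one co-occupancy group.

    Each spec maps factor name → required presence; factors a spec omits must
    be absent (so specs describe complete binding patterns and are mutually
    exclusive by construction — any overlap raises).  Genes matching no spec
    are labelled ``unbound`` when they bind nothing, else ``other``.
    """
    for name, spec in specs.items():
        unknown = set(spec) - set(matrix.columns)
        if unknown:
            raise ValueError(f"group {name!r} references unknown factors {unknown}")
    labels = pd.Series("other", index=matrix.index, dtype=object)
    labels[~matrix.any(axis=1)] = "unbound"
    assigned = pd.Series(False, index=matrix.index)
    for name, spec in specs.items():
        full = {f: spec.get(f, False) for f in matrix.columns}
        mask = np.ones(len(matrix), dtype=bool)
        for f, want in full.items():
            mask &= matrix[f].to_numpy() == want
        if (assigned & mask).any():
            raise ValueError(f"group {name!r} overlaps a previous group")
        labels[mask] = name
        assigned |= mask
    return labels.rename("group")


@dataclass
class EnrichmentResult:
    """A 2×2 set-intersection test: Fisher exact p with BH-adjustable slot."""

    label_a: str
    label_b: str
    table: tuple[int, int, int, int]  # a=|A∩B|, b=|A\B|, c=|B\A|, d=neither
    odds_ratio: float
    p_value: float
    p_adjusted: float | None = None

    @property
    def direction(self) -> str:
        return "enriched" if self.odds_ratio > 1 else "depleted"


def fisher_intersection(set_a: set[str], set_b: set[str], universe: set[str],
                        *, alternative: str = "two-sided",
                        label_a: str = "A", label_b: str = "B") -> EnrichmentResult:
    """Fisher exact test of overlap between two gene sets within a universe.

    The odds ratio is the unconditional (a·d)/(b·c) with a Haldane 0.5
    correction when any cell is zero.
    """
    if not universe:
        raise ValueError("empty universe")
    set_a, set_b = set_a & universe, set_b & universe
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        odds = 1.0  # degenerate margin: no contrast to estimate
    elif min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(label_a=label_a, label_b=label_b, table=(a, b, c, d),
                            odds_ratio=float(odds), p_value=float(p))


def bh_adjust(pvalues) -> np.ndarray | pd.Series:
    """Benjamini–Hochberg step-up adjustment; NaN inputs stay NaN."""
    arr = np.asarray(pvalues, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = np.isfinite(arr)
    if ok.sum():
        out[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    if isinstance(pvalues, pd.Series):
        return pd.Series(out, index=pvalues.index, name="p_adjusted")
    return out


def lone_gene_filter(annotation: GenomeAnnotation, margin: int = 5000) -> list[str]:
    """Genes with no other gene overlapping their span padded by ±margin."""
    df = annotation.to_frame().reset_index()
    lone: list[str] = []
    for _, sub in df.groupby("chrom"):
        sub = sub.sort_values("start").reset_index(drop=True)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for i in range(len(sub)):
            left_clear = i == 0 or ends[:i].max() <= starts[i] - margin
            right_clear = i == len(sub) - 1 or starts[i + 1:].min() >= ends[i] + margin
            if left_clear and right_clear:
                lone.append(sub.at[i, "gene_id"])
    order = {gid: k for k, gid in enumerate(annotation.gene_ids)}
    return sorted(lone, key=order.__getitem__)


def rank_by_binding(promoter_signal: pd.Series, top_n: int | None = None) -> list[str]:
    """Gene ids by descending promoter signal, ties broken by gene id."""
    df = promoter_signal.rename("signal").rename_axis("gene_id").reset_index()
    df = df.sort_values(["signal", "gene_id"], ascending=[False, True], kind="stable")
    ids = df["gene_id"].tolist()
    return ids if top_n is None else ids[:top_n]
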