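"""Condition-vs-control statistics for per-gene index changes.

The pipeline's differential layer works on per-gene, per-replicate log2 index
differences Δ (knockdown − control).  Gene-wise variances are shrunk toward a
common prior with the empirical-Bayes moderated t (prior estimated by matching
the moments of log s² to a scaled-F model via digamma/trigamma), p-values are
converted to Storey q-values at a fixed λ, and processivity defects are called
at a q threshold in a declared direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .window_counter import MetageneProfile

logger = logging.getLogger("pauseproc")


def delta_index(index_kd: pd.DataFrame, index_ctrl: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-replicate Δ = KD − control on the (log) index scale.

    Inputs are gene × replicate frames; replicate *i* of the knockdown is
    paired with replicate *i* of the control.  Genes with any missing value
    are dropped (the count is logged).
    """
    if index_kd.shape[1] != index_ctrl.shape[1]:
        raise ValueError("replicate pairing requires equal replicate counts")
    common = index_kd.index.intersection(index_ctrl.index)
    delta = pd.DataFrame(
        index_kd.loc[common].to_numpy() - index_ctrl.loc[common].to_numpy(),
        index=common, columns=[f"delta_{i + 1}" for i in range(index_kd.shape[1])],
    )
    kept = delta.dropna()
    n_dropped = len(index_kd.index.union(index_ctrl.index)) - len(kept)
    if n_dropped:
        logger.info("delta_index: dropped %d genes with missing replicates", n_dropped)
    return kept


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-matched prior (d0, s0²) for gene-wise variances with df residual df.

    Matches mean and variance of log s² against the scaled-F model: the
    excess spread of log s² beyond trigamma(df/2) determines the prior df.
    Returns d0 = inf when the observed spread is at or below the theoretical
    sampling spread.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise ValueError("prior unestimable: fewer than 2 positive variances")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return d0, s0_sq


def moderated_t(delta: pd.DataFrame, prior_df: float | None = None,
                prior_s2: float | None = None) -> pd.DataFrame:
    """Empirical-Bayes moderated one-sample t on a gene × replicate Δ matrix.

    Per gene: mean Δ, sample variance s² (df = R−1), posterior variance
    s̃² = (d0·s0² + df·s²)/(d0 + df), t = mean/(s̃/√R) on d0 + df degrees of
    freedom.  ``prior_df``/``prior_s2`` override the moment-matched estimate
    (prior_df = 0 recovers the ordinary t; prior_df = inf fixes s̃ = s0).
    """
    R = delta.shape[1]
    if R < 2:
        raise ValueError("moderated t requires at least 2 replicates")
    vals = delta.to_numpy(dtype=float)
    m = vals.mean(axis=1)
    s2 = vals.var(axis=1, ddof=1)
    df = R - 1
    if prior_df is None:
        try:
            d0, s0_sq = estimate_prior(s2, df)
        except ValueError:
            logger.warning("prior unestimable; falling back to ordinary t")
            d0, s0_sq = 0.0, 0.0
    else:
        d0 = float(prior_df)
        s0_sq = float(prior_s2) if prior_s2 is not None else estimate_prior(s2, df)[1]
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(s2_post / R)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {"mean_delta": m, "s2": s2, "s2_post": s2_post, "t": t,
         "df_total": df_total, "p_value": p},
        index=delta.index,
    )
    out.attrs.update(prior_df=d0, prior_s2=s0_sq, n_replicates=R)
    return out


def qvalues(pvalues, lambda_: float = 0.5) -> np.ndarray | pd.Series:
    """Storey q-values with a fixed-λ π0 estimate.

    π̂0 = #{p > λ} / (m·(1−λ)) capped at 1; q_(i) = min_{j≥i} π̂0·m·p_(j)/j.
    With π̂0 = 1 this is exactly Benjamini–Hochberg.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    pi0 = min(1.0, float((p > lambda_).sum()) / (m * (1.0 - lambda_)))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    if isinstance(pvalues, pd.Series):
        return pd.Series(q, index=pvalues.index, name="q_value")
    return q


def change_probability(delta, control_deltas, direction: str = "decrease"
                       ) -> tuple[np.ndarray | float, float]:
    """Normal-model tail probability of an observed index change.

    The null mean and sd are estimated from a declared control gene set;
    ``direction='increase'`` returns the upper tail, ``'decrease'`` the lower
    tail.  A QQ normality diagnostic (correlation of sample vs theoretical
    normal quantiles of the control set) is returned alongside.
    """
    ctrl = np.asarray(control_deltas, dtype=float)
    ctrl = ctrl[np.isfinite(ctrl)]
    if ctrl.size < 20:
        logger.warning("change_probability: control set has only %d genes", ctrl.size)
    mu, sd = float(ctrl.mean()), float(ctrl.std(ddof=1))
    if sd <= 0:
        raise ValueError("control deltas have zero spread")
    z = (np.asarray(delta, dtype=float) - mu) / sd
    if direction == "increase":
        prob = stats.norm.sf(z)
    elif direction == "decrease":
        prob = stats.norm.cdf(z)
    else:
        raise ValueError("direction must be 'increase' or 'decrease'")
    theo = stats.norm.ppf((np.arange(1, ctrl.size + 1) - 0.5) / ctrl.size)
    qq_corr = float(np.corrcoef(np.sort(ctrl), theo)[0, 1])
    prob = prob if prob.ndim else float(prob)
    return prob, qq_corr


def pairwise_wilcoxon(values_a, values_b, *, paired: bool = True,
                      alternative: str = "two-sided") -> float:
    """Wilcoxon p-value between two samples of index values.

    Paired: signed-rank with zero differences dropped; exact null by
    enumeration when ≤12 non-zero untied pairs, normal approximation with
    continuity correction otherwise.  Unpaired: rank-sum, exact when
    min(n, m) ≤ 10 without ties.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired test requires equal lengths and gene order")
        d = a - b
        d = d[d != 0]
        if d.size == 0:
            logger.warning("pairwise_wilcoxon: all differences zero")
            return 1.0
        if d.size < 3:
            raise ValueError("paired test requires at least 3 non-zero differences")
        no_ties = np.unique(np.abs(d)).size == d.size
        method = "exact" if (d.size <= 12 and no_ties) else "approx"
        res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                             alternative=alternative, method=method)
        return float(res.pvalue)
    if min(a.size, b.size) < 3:
        raise ValueError("rank-sum test requires at least 3 per group")
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 10 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.pvalue)


def call_defects(diff: pd.DataFrame, q_threshold: float = 0.05,
                 direction: str = "decrease", lambda_: float = 0.5) -> set[str]:
    """Genes with q below threshold and Δ in the declared direction.

    ``direction`` refers to the sign of the mean Δ; with the tes/body index
    orientation a processivity defect (relatively decreased terminal signal)
    is a *decrease*, with body/tes it is an increase.
    """
    if not 0 < q_threshold <= 1:
        raise ValueError("q_threshold must be in (0, 1]")
    if len(diff) == 0:
        return set()
    q = qvalues(diff["p_value"], lambda_=lambda_)
    sign = diff["mean_delta"] < 0 if direction == "decrease" else diff["mean_delta"] > 0
    return set(diff.index[(np.asarray(q) < q_threshold) & sign.to_numpy()])


@dataclass
class TesaCall:
    """A termination-site-associated peak call on a TES-anchored profile."""

    score: float
    present: bool
    threshold: float


def detect_tesa(profile: MetageneProfile, *, peak_window: tuple[int, int] = (-500, 0),
                flank_window: tuple[int, int] = (-2000, -500),
                threshold: float = 1.5) -> TesaCall:
    """Score a TESA peak: max bin in the last 500 bp over the mean flank bin.

    Both windows are in bp relative to the TES on the profile's axis.  Returns
    an NaN score (absent) when the flank mean is zero.
    """
    centers = profile.bin_centers
    peak = profile.values[(centers >= peak_window[0]) & (centers < peak_window[1])]
    flank = profile.values[(centers >= flank_window[0]) & (centers < flank_window[1])]
    if peak.size == 0 or flank.size == 0:
        raise ValueError("peak/flank windows not covered by the profile")
    flank_mean = float(flank.mean())
    if flank_mean == 0:
        return TesaCall(score=np.nan, present=False, threshold=threshold)
    score = float(peak.max()) / flank_mean
    return TesaCall(score=score, present=score >= threshold, threshold=threshold)
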