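"""Count-based differential accessibility between stages.

The test is a negative-binomial Wald test on library-size-normalized
counts (median-of-ratios by default, robust to composition shifts when
many peaks change in one direction): per-peak method-of-moments
dispersion pooled across the two groups and shrunk toward a
bias-corrected across-peak moment estimate, a log2 fold change with a
0.5 pseudo-count, and a two-sided normal p-value. Stage-enriched peaks
are called at |log2FC| > 0.5 (strict) and BH FDR < 0.01, the thresholds
used throughout the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ArgumentError
from .coverage_peaks import CountMatrix

LABELS = ("group1_enriched", "group2_enriched", "ns")


@dataclass
class AccessibilityScore:
    """Normalized log2 abundance contrast of one peak between two stages."""

    peak_id: str
    score: float


def normalize_libsize(cm: CountMatrix, method: str = "total"
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Scale columns to a common library size.

    ``total``: size factor = column sum / geometric mean of column sums.
    ``median_of_ratios``: DESeq-style median ratio to the geometric-mean
    reference row (rows with any zero are excluded from the reference).
    Returns (scaled matrix, size factors).
    """
    counts = cm.counts
    colsums = counts.sum(axis=0)
    if (colsums == 0).any():
        bad = list(colsums.index[colsums == 0])
        raise ArgumentError(f"zero-count columns: {bad}")
    if method == "total":
        gm = np.exp(np.mean(np.log(colsums)))
        sf = colsums / gm
    elif method == "median_of_ratios":
        vals = counts.values.astype(float)
        keep = (vals > 0).all(axis=1)
        if not keep.any():
            raise ArgumentError("no all-positive rows for median-of-ratios")
        logref = np.log(vals[keep]).mean(axis=1, keepdims=True)
        sf_arr = np.exp(np.median(np.log(vals[keep]) - logref, axis=0))
        sf = pd.Series(sf_arr, index=counts.columns)
    else:
        raise ArgumentError(f"unknown normalization method {method!r}")
    return counts / sf, pd.Series(sf, index=counts.columns)


def _group_columns(cm: CountMatrix, groups) -> dict[str, list[str]]:
    if isinstance(groups, (list, tuple)) and len(groups) == 2 and all(
        isinstance(g, str) for g in groups
    ):
        stages = cm.stages()
        return {g: list(stages.index[stages == g]) for g in groups}
    raise ArgumentError("groups must be two stage labels, e.g. ('D0', 'D9')")


def nb_wald_test(cm: CountMatrix, groups, pseudocount: float = 0.5,
                 dispersion_shrinkage: bool = True, prior_df: float = 20.0,
                 normalization: str = "median_of_ratios") -> pd.DataFrame:
    """Per-peak NB Wald test between two stage groups.

    Dispersion alpha (var = mu + alpha mu^2) is estimated per peak by
    method of moments on normalized counts, pooled over the two groups,
    and (by default) shrunk toward the across-peak median with ``prior_df``
    pseudo-degrees of freedom; the floor is 1e-8. The Wald statistic is
    log2FC / SE(log2FC) with the delta-method SE under NB variance and a
    two-sided normal p. Requires >= 2 replicates per group.

    Returns a DataFrame with columns peak, baseMeanA, baseMeanB, log2fc,
    p, fdr, label (fdr/label filled by classify_enriched).
    """
    cols = _group_columns(cm, groups)
    g1, g2 = groups
    for g, cs in cols.items():
        if len(cs) < 2:
            raise ArgumentError(
                f"group {g!r} has {len(cs)} replicate(s); >= 2 are required for "
                "dispersion estimation (pool replicates or use a pooled-dispersion "
                "design)"
            )
    norm, _ = normalize_libsize(cm, method=normalization)
    x1 = norm[cols[g1]].values
    x2 = norm[cols[g2]].values
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = np.where(m1 > 0, (v1 - m1) / m1**2, 0.0)
        a2 = np.where(m2 > 0, (v2 - m2) / m2**2, 0.0)
    w1, w2 = n1 - 1, n2 - 1
    alpha = np.clip((w1 * a1 + w2 * a2) / (w1 + w2), 0.0, None)
    if dispersion_shrinkage:
        # global moment-regression prior: sum(s^2 - m) / sum(m^2), with the
        # E[m^2] = mu^2 + (mu + a mu^2)/n sampling-variance correction
        # iterated to remove the small-n bias of the naive estimator
        num = (v1 - m1).sum() + (v2 - m2).sum()
        prior = max(num / ((m1**2).sum() + (m2**2).sum()), 0.0)
        for _ in range(10):
            den = ((m1**2 - (m1 + prior * m1**2) / n1).sum()
                   + (m2**2 - (m2 + prior * m2**2) / n2).sum())
            if den <= 0:
                break
            prior = max(num / den, 0.0)
        peak_df = float(w1 + w2)
        alpha = (peak_df * alpha + prior_df * prior) / (peak_df + prior_df)
    alpha = np.maximum(alpha, 1e-8)

    log2fc = np.log2((m2 + pseudocount) / (m1 + pseudocount))
    var_mean1 = (m1 + alpha * m1**2) / n1
    var_mean2 = (m2 + alpha * m2**2) / n2
    ln2 = np.log(2.0)
    se = np.sqrt(var_mean1 / (m1 + pseudocount) ** 2
                 + var_mean2 / (m2 + pseudocount) ** 2) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.minimum(p, 1.0)
    return pd.DataFrame(
        {
            "peak": cm.feature_ids,
            "baseMeanA": m1,
            "baseMeanB": m2,
            "log2fc": log2fc,
            "p": p,
        }
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ArgumentError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify_enriched(results: pd.DataFrame, lfc_thresh: float = 0.5,
                      fdr_thresh: float = 0.01) -> pd.DataFrame:
    """Label peaks by stage enrichment at strict thresholds.

    group2_enriched iff log2fc > lfc_thresh and fdr < fdr_thresh (both
    strict); group1_enriched iff log2fc < -lfc_thresh and fdr < fdr_thresh;
    otherwise ns. Adds fdr and label columns.
    """
    out = results.copy()
    out["fdr"] = bh_fdr(out["p"].values)
    sig = out["fdr"] < fdr_thresh
    label = np.where(sig & (out["log2fc"] > lfc_thresh), "group2_enriched",
                     np.where(sig & (out["log2fc"] < -lfc_thresh),
                              "group1_enriched", "ns"))
    out["label"] = label
    return out


def accessibility_score(cm: CountMatrix, peak: str, stage_a: str, stage_b: str,
                        pseudocount: float = 0.5,
                        normalization: str = "median_of_ratios") -> AccessibilityScore:
    """log2 contrast of a peak's mean normalized count between two stages."""
    stages = cm.stages()
    for s in (stage_a, stage_b):
        if s not in set(stages):
            raise ArgumentError(f"unknown stage {s!r}")
    if peak not in cm.counts.index:
        raise ArgumentError(f"unknown peak {peak!r}")
    norm, _ = normalize_libsize(cm, method=normalization)
    ma = norm.loc[peak, stages.index[stages == stage_a]].mean()
    mb = norm.loc[peak, stages.index[stages == stage_b]].mean()
    return AccessibilityScore(peak, float(np.log2((mb + pseudocount) / (ma + pseudocount))))


def accessibility_scores(cm: CountMatrix, stage_a: str, stage_b: str,
                         pseudocount: float = 0.5,
                         normalization: str = "median_of_ratios") -> pd.Series:
    """Vectorized accessibility_score over every peak in the matrix."""
    stages = cm.stages()
    norm, _ = normalize_libsize(cm, method=normalization)
    ma = norm[stages.index[stages == stage_a]].mean(axis=1)
    mb = norm[stages.index[stages == stage_b]].mean(axis=1)
    return np.log2((mb + pseudocount) / (ma + pseudocount))
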