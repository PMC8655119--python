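"""Expression-side integration: scRNA QC, cluster markers, GSEA, and the
accessibility-by-gene-set KS comparison.

Barcode QC keeps cells with 500-8,000 detected genes and <= 10%
mitochondrial UMIs (removal conditions strict, so a cell at exactly 500
genes or exactly 10.0% passes). Markers use a two-sided Wilcoxon
rank-sum test (normal approximation with tie correction) with a 25%
minimum in-cluster detection rate and p < 0.01. GSEA is the classical
weighted Kolmogorov-Smirnov running sum with a gene-set permutation null
(10,000 permutations by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ArgumentError
from .coverage_peaks import CountMatrix


@dataclass
class QCThresholds:
    """Barcode-retention thresholds for scRNA count matrices."""

    min_genes: int = 500
    max_genes: int = 8000
    max_mito_pct: float = 10.0

    def __post_init__(self):
        if self.min_genes >= self.max_genes:
            raise ArgumentError("min_genes must be < max_genes")
        if not 0 <= self.max_mito_pct <= 100:
            raise ArgumentError("max_mito_pct must be in [0, 100]")


@dataclass
class GeneSet:
    name: str
    genes: set = field(default_factory=set)

    def __post_init__(self):
        self.genes = set(self.genes)
        if not self.genes:
            raise ArgumentError(f"gene set {self.name!r} is empty")

    def __len__(self):
        return len(self.genes)


@dataclass
class GseaResult:
    gene_set: str
    es: float
    nes: float
    fdr: float
    n_permutations: int


def qc_filter(cells: CountMatrix, mito_genes: list[str],
              thresholds: QCThresholds | None = None
              ) -> tuple[list[str], pd.DataFrame]:
    """Retain barcodes passing detected-gene and mitochondrial-UMI filters.

    A barcode is removed when it has fewer than ``min_genes`` detected
    genes, more than ``max_genes``, or a mitochondrial UMI percentage
    strictly above ``max_mito_pct``. Returns (retained barcodes, report
    with per-barcode metrics and pass/fail reasons).
    """
    thresholds = thresholds or QCThresholds()
    counts = cells.counts
    if counts.shape[1] == 0 or counts.shape[0] == 0:
        raise ArgumentError("empty count matrix")
    missing = set(mito_genes) - set(counts.index)
    if missing:
        raise ArgumentError(f"mito genes absent from matrix: {sorted(missing)}")
    detected = (counts > 0).sum(axis=0)
    total = counts.sum(axis=0)
    mito = counts.loc[list(mito_genes)].sum(axis=0) if mito_genes else 0
    with np.errstate(invalid="ignore"):
        mito_pct = np.where(total > 0, 100.0 * mito / total, 0.0)
    report = pd.DataFrame(
        {"detected_genes": detected, "total_umi": total, "mito_pct": mito_pct}
    )
    report["fail_low_genes"] = report["detected_genes"] < thresholds.min_genes
    report["fail_high_genes"] = report["detected_genes"] > thresholds.max_genes
    report["fail_mito"] = report["mito_pct"] > thresholds.max_mito_pct
    report["retained"] = ~(report["fail_low_genes"] | report["fail_high_genes"]
                           | report["fail_mito"])
    return list(report.index[report["retained"]]), report


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum z and p: normal approximation with tie
    and continuity corrections (tracks the exact permutation null to ~0.01
    at group sizes of 7-8)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ArgumentError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w = ranks[:n1].sum()
    mu = n1 * (n2 + n1 + 1) / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0, 1.0
    diff = w - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def find_markers(cells: CountMatrix, cluster_labels: pd.Series,
                 min_pct: float = 0.25, p_thresh: float = 0.01
                 ) -> dict[str, GeneSet]:
    """Per-cluster marker genes: detected in >= min_pct of in-cluster
    cells, rank-sum p < p_thresh (strict), and in-cluster mean above the
    rest. A BH-adjusted column is also computed per cluster for audit but
    selection uses raw p."""
    counts = cells.counts
    cluster_labels = pd.Series(cluster_labels)
    clusters = sorted(cluster_labels.unique())
    if len(clusters) < 2:
        raise ArgumentError("need >= 2 clusters")
    missing = set(cluster_labels.index) - set(counts.columns)
    if missing:
        raise ArgumentError(f"labelled cells absent from matrix: {sorted(missing)}")
    out: dict[str, GeneSet] = {}
    for c in clusters:
        in_cells = list(cluster_labels.index[cluster_labels == c])
        rest = list(cluster_labels.index[cluster_labels != c])
        if len(in_cells) < 3:
            raise ArgumentError(f"cluster {c!r} has < 3 cells")
        sub_in = counts[in_cells]
        sub_rest = counts[rest]
        pct = (sub_in > 0).mean(axis=1)
        candidates = counts.index[pct >= min_pct]
        markers = set()
        for g in candidates:
            xi, yi = sub_in.loc[g].values, sub_rest.loc[g].values
            if xi.mean() <= yi.mean():
                continue
            _, p = wilcoxon_rank_sum(xi, yi)
            if p < p_thresh:
                markers.add(g)
        if markers:
            out[str(c)] = GeneSet(f"cluster{c}_markers", markers)
    return out


def gsea_es(ranked: pd.DataFrame, members: set, weight_exponent: float = 1.0
            ) -> tuple[float, np.ndarray]:
    """Weighted KS running-sum enrichment score on a ranked gene table.

    ``ranked`` has columns gene, score and is ordered by descending score.
    Hits advance the running sum by |score|^weight_exponent (normalized),
    misses decrement uniformly; ES is the extremum of the running sum.
    """
    genes = ranked["gene"].values
    scores = np.abs(ranked["score"].values) ** weight_exponent
    is_hit = np.isin(genes, list(members))
    n_hit = int(is_hit.sum())
    n_miss = len(genes) - n_hit
    if n_hit == 0 or n_miss == 0:
        raise ArgumentError("gene set and ranking do not overlap usefully")
    hit_w = scores * is_hit
    denom = hit_w.sum()
    if denom == 0:
        hit_w = is_hit.astype(float)
        denom = float(n_hit)
    steps = hit_w / denom - (~is_hit) / n_miss
    running = np.cumsum(steps)
    es = running[np.argmax(np.abs(running))]
    return float(es), running


def _es_from_indices(weights: np.ndarray, hit_ix: np.ndarray, n: int) -> float:
    """ES for a hit-index set on precomputed |score|^w weights."""
    n_miss = n - len(hit_ix)
    steps = np.full(n, -1.0 / n_miss)
    hw = weights[hit_ix]
    denom = hw.sum()
    steps[hit_ix] = hw / denom if denom > 0 else 1.0 / len(hit_ix)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def gsea(ranked: pd.DataFrame, gene_set: GeneSet, weight_exponent: float = 1.0,
         n_perm: int = 10_000, seed: int = 0) -> GseaResult:
    """GSEA with a gene-set permutation null.

    NES = ES / mean(|ES*|) over same-sign permutation scores; FDR is the
    fraction of same-sign |NES*| at least as extreme. Deterministic given
    the seed.
    """
    ranked = ranked.sort_values("score", ascending=False).reset_index(drop=True)
    members = gene_set.genes & set(ranked["gene"])
    if len(members) < 5:
        raise ArgumentError(
            f"gene set {gene_set.name!r} shares only {len(members)} genes with "
            "the ranking (need >= 5)"
        )
    es, _ = gsea_es(ranked, members, weight_exponent)
    rng = np.random.default_rng(seed)
    genes = ranked["gene"].values
    n = len(genes)
    k = len(members)
    weights = np.abs(ranked["score"].values) ** weight_exponent
    null = np.empty(n_perm)
    for i in range(n_perm):
        ix = rng.choice(n, size=k, replace=False)
        null[i] = _es_from_indices(weights, ix, n)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if len(same_sign) == 0:
        nes = 0.0
        fdr = 1.0 / n_perm
    else:
        norm = np.abs(same_sign).mean()
        nes = es / norm
        null_nes = np.abs(same_sign) / norm
        fdr = float((null_nes >= abs(nes)).mean())
    fdr = min(max(fdr, 1.0 / n_perm), 1.0)
    return GseaResult(gene_set.name, es=float(es), nes=float(nes), fdr=fdr,
                      n_permutations=n_perm)


def accessibility_by_geneset_ks(scores: pd.Series,
                                assignment: dict[str, set],
                                set_a: GeneSet, set_b: GeneSet
                                ) -> dict:
    """Two-sample KS comparison of accessibility scores by gene-set link.

    Elements are split by whether any assigned gene belongs to set A vs
    set B; elements hitting both sets are excluded (count reported).
    Returns D, the asymptotic p, group sizes and the excluded count.
    """
    in_a, in_b, dropped = [], [], 0
    for peak, sc in scores.items():
        genes = assignment.get(peak, set())
        hit_a = bool(genes & set_a.genes)
        hit_b = bool(genes & set_b.genes)
        if hit_a and hit_b:
            dropped += 1
        elif hit_a:
            in_a.append(sc)
        elif hit_b:
            in_b.append(sc)
    if len(in_a) < 5 or len(in_b) < 5:
        raise ArgumentError(
            f"need >= 5 elements per group, got {len(in_a)} vs {len(in_b)}"
        )
    res = stats.ks_2samp(in_a, in_b, alternative="two-sided", method="asymp")
    return {
        "D": float(res.statistic),
        "p": float(res.pvalue),
        "n_a": len(in_a),
        "n_b": len(in_b),
        "n_excluded_dual": dropped,
    }


def read_gene_sets_gmt(path) -> dict[str, GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = GeneSet(parts[0], set(parts[2:]))
    return out


def write_gene_sets_gmt(sets: dict[str, GeneSet], path) -> None:
    with open(path, "w") as fh:
        for name, gs in sets.items():
            fh.write("\t".join([name, "chromdyn"] + sorted(gs.genes)) + "\n")
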