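"""PWM scanning, known-motif binomial enrichment, and Tn5 footprinting.

Enrichment is Homer-style over peaks: for each motif, the fraction of
background peaks with >= 1 hit sets the binomial rate, and the upper-tail
probability of the observed number of hit-bearing target peaks is
reported as -log10 p. Family summaries take the best motif per TF family
(bZIP, Zinc Finger, RUNX, Forkhead, TEA, MADS, ...). Footprints aggregate
per-base cut counts around motif hits, strand-flipped so motifs align; a
bound site shows depleted cuts over the motif core and elevated flanks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.special import logsumexp

from ._errors import ArgumentError, ParseError
from .coverage_peaks import CutSiteTrack
from .intervals_io import PeakSet

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class PWM:
    """A position weight matrix with a TF-family tag.

    ``probs`` holds per-position base probabilities (rows sum to 1); the
    log-odds matrix uses a 0.01 pseudo-count against the background base
    frequencies. The default hit threshold is 80% of the maximum
    attainable log-odds score.
    """

    motif_id: str
    family: str
    probs: np.ndarray                       # L x 4, rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold_fraction: float = 0.8

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ArgumentError("PWM probabilities must be L x 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ArgumentError("PWM probability rows must sum to 1")
        padded = (self.probs + 0.01) / (1.0 + 0.04)
        self.log_odds = np.log2(padded / self.background)
        self.max_score = float(self.log_odds.max(axis=1).sum())
        self.threshold = self.threshold_fraction * self.max_score

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> np.ndarray:
        """Log-odds matrix scanning the reverse strand on forward coords."""
        return self.log_odds[::-1, ::-1]


def pwm_from_consensus(motif_id: str, consensus: str, family: str = "",
                       strength: float = 0.94) -> PWM:
    """PWM concentrated on a consensus sequence (for simulation panels)."""
    L = len(consensus)
    probs = np.full((L, 4), (1.0 - strength) / 3.0)
    for i, b in enumerate(consensus.upper()):
        probs[i, _BASE_INDEX[b]] = strength
    return PWM(motif_id, family, probs)


def read_pwms(path) -> list[PWM]:
    """Parse a JASPAR-like PWM file with a family tag.

    Format per motif: a header ``>motif_id<TAB>family`` followed by four
    lines ``A [ 3 10 ... ]`` (brackets optional) in A/C/G/T order.
    """
    pwms = []
    header = None
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        lines = list(fh)
    lines.append(">")  # sentinel to flush the last motif

    def _flush(lineno):
        if header is None:
            return
        if set(rows) != set("ACGT"):
            raise ParseError(f"motif {header[0]!r} missing base rows", lineno)
        counts = np.array([rows[b] for b in "ACGT"], dtype=float).T
        sums = counts.sum(axis=1, keepdims=True)
        if (sums <= 0).any():
            raise ParseError(f"motif {header[0]!r} has a zero-count column", lineno)
        pwms.append(PWM(header[0], header[1], counts / sums))

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            _flush(lineno)
            parts = line[1:].split("\t")
            header = (parts[0].strip(),
                      parts[1].strip() if len(parts) > 1 else "")
            rows = {}
        else:
            base, rest = line[0].upper(), line[1:]
            if base not in "ACGT":
                raise ParseError(f"unexpected row {line[:20]!r}", lineno)
            vals = rest.replace("[", " ").replace("]", " ").split()
            try:
                rows[base] = [float(v) for v in vals]
            except ValueError:
                raise ParseError(f"non-numeric counts in row {line[:30]!r}", lineno)
    return pwms


def write_pwms(pwms: list[PWM], path, scale: int = 100) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\t{pwm.family}\n")
            counts = np.round(pwm.probs * scale).astype(int)
            for i, b in enumerate("ACGT"):
                fh.write(f"{b} [ " + " ".join(map(str, counts[:, i])) + " ]\n")


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def scan_pwm(seqs: dict[str, str], peaks: PeakSet, pwm: PWM,
             threshold: float | None = None) -> pd.DataFrame:
    """Scan both strands of each peak for log-odds hits >= threshold.

    Reverse-strand hits are reported on forward coordinates (``start`` is
    the leftmost base of the matched window). Windows containing non-ACGT
    bases are skipped. Peaks extending beyond the sequence raise.
    """
    threshold = pwm.threshold if threshold is None else threshold
    W = pwm.width
    fwd, rev = pwm.log_odds, pwm.reverse_complement()
    recs = []
    for iv in peaks:
        if iv.chrom not in seqs or iv.end > len(seqs[iv.chrom]):
            raise ArgumentError(f"peak {iv.name} extends beyond sequence {iv.chrom}")
        if iv.width < W:
            continue
        idx = _encode(seqs[iv.chrom][iv.start:iv.end])
        n_win = iv.width - W + 1
        windows = np.lib.stride_tricks.sliding_window_view(idx, W)
        valid = (windows >= 0).all(axis=1)
        pos = np.arange(n_win)[valid]
        if not len(pos):
            continue
        wv = windows[valid]
        cols = np.arange(W)
        s_fwd = fwd[cols, wv].sum(axis=1)
        s_rev = rev[cols, wv].sum(axis=1)
        for strand, sc in (("+", s_fwd), ("-", s_rev)):
            hit = sc >= threshold
            for p, s in zip(pos[hit], sc[hit]):
                recs.append((iv.name, iv.chrom, int(iv.start + p),
                             int(iv.start + p + W), strand, float(s)))
    return pd.DataFrame(recs, columns=["peak", "chrom", "start", "end",
                                       "strand", "score"])


def binomial_enrichment(target: PeakSet, background: PeakSet,
                        hits: pd.DataFrame | set,
                        motif_id: str = "", family: str = "") -> dict:
    """Homer-style binomial enrichment of hit-bearing peaks.

    The background rate is the fraction of background peaks with >= 1 hit;
    p is the upper-tail binomial probability of observing at least the
    target's hit-bearing peak count.
    """
    if len(target) < 1:
        raise ArgumentError("empty target set")
    if len(background) == 0:
        raise ArgumentError("empty background set")
    hit_names = set(hits["peak"]) if isinstance(hits, pd.DataFrame) else set(hits)
    n_t, n_b = len(target), len(background)
    k_t = sum(1 for iv in target if iv.name in hit_names)
    k_b = sum(1 for iv in background if iv.name in hit_names)
    p_hat = k_b / n_b
    p = float(stats.binom.sf(k_t - 1, n_t, p_hat))
    p = min(max(p, 1e-300), 1.0)
    return {
        "motif": motif_id,
        "family": family,
        "n_target": n_t,
        "k_target": k_t,
        "n_bg": n_b,
        "k_bg": k_b,
        "bg_rate": p_hat,
        "p": p,
        "neg_log10_p": -np.log10(p),
    }


def enrich_clusters(seqs: dict[str, str], peaks_by_cluster: dict[int, PeakSet],
                    pwms: list[PWM]) -> pd.DataFrame:
    """Per-(cluster, motif) enrichment against all other clusters' peaks.

    The background for a cluster is every consensus peak not in that
    cluster (the "total background peaks").
    """
    all_hits = {pwm.motif_id: scan_pwm(seqs, _union(peaks_by_cluster), pwm)
                for pwm in pwms}
    rows = []
    for c, target in peaks_by_cluster.items():
        bg_ivs = [iv for cc, ps in peaks_by_cluster.items() if cc != c for iv in ps]
        background = PeakSet(bg_ivs, label=f"not_cluster_{c}")
        for pwm in pwms:
            row = binomial_enrichment(target, background, all_hits[pwm.motif_id],
                                      motif_id=pwm.motif_id, family=pwm.family)
            row["cluster"] = c
            rows.append(row)
    return pd.DataFrame(rows)


def _union(peaks_by_cluster: dict[int, PeakSet]) -> PeakSet:
    return PeakSet([iv for ps in peaks_by_cluster.values() for iv in ps],
                   label="all_clusters")


def family_heatmap(table: pd.DataFrame) -> pd.DataFrame:
    """Cluster x family matrix of the best (max) -log10 p per family.

    Rows and columns are ordered by average-linkage hierarchical
    clustering on Euclidean distance; the ordering is invariant to the
    input row order.
    """
    mat = (table.pivot_table(index="cluster", columns="family",
                             values="neg_log10_p", aggfunc="max")
           .sort_index().sort_index(axis=1))
    def _order(m):
        if m.shape[0] < 3:
            return list(m.index)
        link = hierarchy.linkage(m.values, method="average", metric="euclidean")
        return list(m.index[hierarchy.leaves_list(link)])

    return mat.loc[_order(mat), _order(mat.T)]


@dataclass
class FootprintProfile:
    """Aggregated per-base cut counts around aligned motif hits."""

    motif_id: str
    window: int
    motif_width: int
    counts: np.ndarray           # length 2*window + motif_width
    n_sites: int

    @property
    def core(self) -> np.ndarray:
        return self.counts[self.window : self.window + self.motif_width]

    @property
    def flanks(self) -> np.ndarray:
        return np.concatenate([self.counts[: self.window],
                               self.counts[self.window + self.motif_width :]])


def footprint_profile(cuts: CutSiteTrack, hits: pd.DataFrame,
                      window: int = 100, motif_id: str = "") -> FootprintProfile:
    """Sum cut counts in a window around each hit, strand-flipped.

    Hits too close to a chromosome edge for the full window are skipped.
    Requires >= 1 usable hit.
    """
    if len(hits) == 0:
        raise ArgumentError("no motif hits to aggregate")
    W = int(hits["end"].iloc[0] - hits["start"].iloc[0])
    L = 2 * window + W
    profile = np.zeros(L, dtype=np.int64)
    used = 0
    for rec in hits.itertuples(index=False):
        track = cuts.tracks.get(rec.chrom)
        if track is None:
            continue
        s, e = rec.start - window, rec.end + window
        if s < 0 or e > len(track):
            continue
        seg = track[s:e]
        profile += seg[::-1] if rec.strand == "-" else seg
        used += 1
    if used == 0:
        raise ArgumentError("no hits with a full window inside the genome")
    return FootprintProfile(motif_id=motif_id, window=window, motif_width=W,
                            counts=profile, n_sites=used)


def depletion_score(fp: FootprintProfile) -> float:
    """1 - mean(core)/mean(flanks): 1 = fully protected, 0 = flat,
    negative = core-enriched. Undefined (raises) when flanks carry no
    signal."""
    flank_mean = fp.flanks.mean()
    if flank_mean <= 0:
        raise ArgumentError("zero flank signal; depletion score undefined")
    return float(1.0 - fp.core.mean() / flank_mean)


def site_cut_matrix(cuts: CutSiteTrack, hits: pd.DataFrame,
                    window: int = 100) -> np.ndarray:
    """Per-site cut vectors (n_sites x profile length), strand-aligned."""
    if len(hits) == 0:
        raise ArgumentError("no motif hits")
    W = int(hits["end"].iloc[0] - hits["start"].iloc[0])
    rows = []
    for rec in hits.itertuples(index=False):
        track = cuts.tracks.get(rec.chrom)
        if track is None:
            continue
        s, e = rec.start - window, rec.end + window
        if s < 0 or e > len(track):
            continue
        seg = track[s:e]
        rows.append(seg[::-1] if rec.strand == "-" else seg)
    if not rows:
        raise ArgumentError("no hits with a full window inside the genome")
    return np.array(rows, dtype=np.int64)


def footprint_mixture(site_counts: np.ndarray, core: tuple[int, int] | None = None,
                      max_iter: int = 200, tol: float = 1e-8, seed: int = 0
                      ) -> tuple[np.ndarray, dict]:
    """Two-component bound/unbound mixture over per-site cut vectors.

    Each component couples a positional multinomial profile with a
    negative-binomial total-count law (dispersion fixed at the
    method-of-moments estimate from all totals, which makes the
    weighted-mean M-step exact and the observed-data log-likelihood
    provably non-decreasing). Returns (posterior bound probability per
    site, info dict with the log-likelihood trace). The bound component is
    the one with the smaller share of cuts over the motif core.
    """
    X = np.asarray(site_counts, dtype=float)
    n, L = X.shape
    if n < 10:
        raise ArgumentError("need >= 10 sites for the mixture")
    core = core if core is not None else (L // 3, 2 * L // 3)
    info: dict = {"loglik": [], "converged": False, "degenerate": False}
    if np.all(X == X[0]):
        info["degenerate"] = True
        warnings.warn("all sites identical; mixture fit is degenerate")
        return np.full(n, 0.5), info

    rng = np.random.default_rng(seed)
    totals = X.sum(axis=1)
    t_mean, t_var = totals.mean(), totals.var(ddof=1)
    alpha = max((t_var - t_mean) / t_mean**2 if t_mean > 0 else 0.0, 1e-8)
    r = 1.0 / alpha

    base = X.sum(axis=0) + 1e-9
    base /= base.sum()
    profiles = np.stack([base, base])
    jitter = rng.uniform(0.9, 1.1, size=(2, L))
    profiles = profiles * jitter
    profiles /= profiles.sum(axis=1, keepdims=True)
    mus = np.array([max(np.quantile(totals, 0.35), 1e-3),
                    max(np.quantile(totals, 0.65), 2e-3)])
    pis = np.array([0.5, 0.5])

    prev_ll = -np.inf
    resp = np.full((n, 2), 0.5)
    for it in range(max_iter):
        log_comp = np.empty((n, 2))
        for c in range(2):
            p_nb = r / (r + mus[c])
            log_comp[:, c] = (
                np.log(pis[c])
                + X @ np.log(profiles[c])
                + stats.nbinom.logpmf(totals, r, p_nb)
            )
        ll_i = logsumexp(log_comp, axis=1)
        ll = float(ll_i.sum())
        info["loglik"].append(ll)
        resp = np.exp(log_comp - ll_i[:, None])
        if ll - prev_ll < tol and it > 0:
            info["converged"] = True
            break
        prev_ll = ll
        nk = resp.sum(axis=0)
        pis = np.clip(nk / n, 1e-12, None)
        pis /= pis.sum()
        for c in range(2):
            prof = resp[:, c] @ X + 1e-9
            profiles[c] = prof / prof.sum()
            mus[c] = max(float((resp[:, c] @ totals) / nk[c]), 1e-6)
    else:
        warnings.warn(f"footprint mixture did not converge in {max_iter} iterations")

    core_share = profiles[:, core[0]:core[1]].sum(axis=1)
    bound = int(np.argmin(core_share))
    info["bound_component"] = bound
    info["profiles"] = profiles
    info["means"] = mus
    return resp[:, bound], info
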