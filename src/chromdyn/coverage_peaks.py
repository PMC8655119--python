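"""From Tn5 cut sites to peaks and count matrices.

A cut-site BED holds single-base Tn5 insertion events. ``pileup`` turns it
into a per-base track, ``call_peaks`` scans fixed windows against a
genome-wide Poisson background, ``consensus_peaks`` merges peak sets across
samples/timepoints, and ``count_in_peaks`` produces the peaks x samples
count matrix consumed by the differential stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ArgumentError
from .intervals_io import Interval, PeakSet


@dataclass
class CountMatrix:
    """Non-negative integer counts (features x samples) with sample metadata.

    ``counts`` rows are feature ids (peaks or genes), columns sample ids
    (samples or cells); ``sample_meta`` is indexed by sample id with at
    least a ``stage`` column for bulk designs.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ArgumentError("count matrix contains negative entries")
        if len(self.sample_meta) and not self.sample_meta.index.equals(
            self.counts.columns
        ):
            # allow same labels in same order only
            if list(self.sample_meta.index) != list(self.counts.columns):
                raise ArgumentError("sample_meta index does not match count columns")

    @property
    def feature_ids(self):
        return list(self.counts.index)

    @property
    def sample_ids(self):
        return list(self.counts.columns)

    def stages(self) -> pd.Series:
        return self.sample_meta["stage"]

    def to_tsv(self, path):
        self.counts.to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def from_tsv(cls, path, sample_meta: pd.DataFrame | None = None):
        counts = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts, sample_meta if sample_meta is not None else pd.DataFrame())


@dataclass
class CutSiteTrack:
    """Per-base Tn5 cut counts for one sample."""

    tracks: dict[str, np.ndarray]
    label: str = ""

    @property
    def total_cuts(self) -> int:
        return int(sum(t.sum() for t in self.tracks.values()))

    @property
    def genome_length(self) -> int:
        return int(sum(len(t) for t in self.tracks.values()))


def pileup(cuts: pd.DataFrame, layout) -> CutSiteTrack:
    """Accumulate single-base cut records into a per-base track.

    ``cuts`` needs columns chrom, start (each row one insertion event);
    ``layout`` provides chrom_names/chrom_lengths. Out-of-bounds records
    raise with the offending row index.
    """
    tracks = {c: np.zeros(l, dtype=np.int64)
              for c, l in zip(layout.chrom_names, layout.chrom_lengths)}
    for chrom, sub in cuts.groupby("chrom", sort=False):
        if chrom not in tracks:
            idx = sub.index[0]
        else:
            pos = sub["start"].to_numpy()
            bad = (pos < 0) | (pos >= len(tracks[chrom]))
            if not bad.any():
                np.add.at(tracks[chrom], pos, 1)
                continue
            idx = sub.index[np.argmax(bad)]
        raise ArgumentError(f"cut record {idx} outside genome bounds ({chrom})")
    return CutSiteTrack(tracks, label=getattr(cuts, "label", ""))


def call_peaks(track: CutSiteTrack, window: int = 200, p_cutoff: float = 1e-5,
               merge_gap: int = 100) -> PeakSet:
    """Poisson sliding-window peak caller against a flat genome-wide rate.

    The background is lambda = total_cuts / genome_length per base. Windows
    of ``window`` bp (step window/2) are significant when the Poisson upper
    tail P(X >= observed) under lambda*window falls below ``p_cutoff``;
    significant windows closer than ``merge_gap`` are merged.
    """
    if window < 1:
        raise ArgumentError("window must be >= 1")
    G = track.genome_length
    if G == 0:
        raise ArgumentError("zero-length genome")
    total = track.total_cuts
    if total == 0:
        return PeakSet([], label=track.label)
    lam = total / G * window
    step = max(1, window // 2)
    peaks = []
    n = 0
    for chrom in sorted(track.tracks):
        arr = track.tracks[chrom]
        cum = np.concatenate([[0], np.cumsum(arr)])
        starts = np.arange(0, max(1, len(arr) - window + 1), step)
        obs = cum[np.minimum(starts + window, len(arr))] - cum[starts]
        # P(X >= obs) = sf(obs - 1)
        sig = stats.poisson.sf(obs - 1, lam) < p_cutoff
        cur = None
        for s, flag in zip(starts, sig):
            if not flag:
                continue
            e = min(s + window, len(arr))
            if cur is not None and s - cur[1] <= merge_gap:
                cur[1] = max(cur[1], e)
            else:
                if cur is not None:
                    n += 1
                    peaks.append(Interval(chrom, cur[0], cur[1], name=f"peak_{n}"))
                cur = [int(s), int(e)]
        if cur is not None:
            n += 1
            peaks.append(Interval(chrom, cur[0], cur[1], name=f"peak_{n}"))
    return PeakSet(peaks, label=track.label)


def consensus_peaks(peaksets: list[PeakSet], min_sets: int = 1) -> PeakSet:
    """Merged spans supported by at least ``min_sets`` of the input sets.

    Each input set contributes coverage 1 over the union of its own
    intervals (internal overlaps within one set are flattened first); the
    event sweep keeps maximal spans with coverage >= min_sets.
    """
    if not peaksets:
        raise ArgumentError("empty list of peak sets")
    if min_sets < 1:
        raise ArgumentError("min_sets must be >= 1")
    events: dict[str, list[tuple[int, int]]] = {}
    for ps in peaksets:
        for chrom, ivs in ps.by_chrom().items():
            # flatten within-set overlaps so one set never counts twice
            merged = []
            for iv in ivs:
                if merged and iv.start <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], iv.end)
                else:
                    merged.append([iv.start, iv.end])
            ev = events.setdefault(chrom, [])
            for s, e in merged:
                ev.append((s, 1))
                ev.append((e, -1))
    out = []
    n = 0
    for chrom in sorted(events):
        ev = sorted(events[chrom])
        cov = 0
        open_at = None
        for pos, delta in ev:
            prev = cov
            cov += delta
            if prev < min_sets <= cov:
                open_at = pos
            elif prev >= min_sets > cov and open_at is not None:
                if pos > open_at:
                    n += 1
                    out.append(Interval(chrom, open_at, pos, name=f"consensus_{n}"))
                open_at = None
    return PeakSet(out, label="consensus")


def count_in_peaks(peaks: PeakSet, tracks: list[CutSiteTrack],
                   sample_meta: pd.DataFrame | None = None) -> CountMatrix:
    """Count each sample's cuts inside each (non-overlapping) peak."""
    ivs = peaks.intervals
    for a, b in zip(ivs, ivs[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ArgumentError(
                f"overlapping peaks {a.name}/{b.name}; counting would double-assign"
            )
    data = {}
    for tr in tracks:
        col = []
        cums = {c: np.concatenate([[0], np.cumsum(arr)]) for c, arr in tr.tracks.items()}
        for iv in ivs:
            cum = cums.get(iv.chrom)
            if cum is None:
                col.append(0)
            else:
                e = min(iv.end, len(cum) - 1)
                col.append(int(cum[e] - cum[min(iv.start, len(cum) - 1)]))
        data[tr.label or f"sample_{len(data)}"] = col
    counts = pd.DataFrame(data, index=[iv.name for iv in ivs])
    return CountMatrix(counts, sample_meta if sample_meta is not None else pd.DataFrame())
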