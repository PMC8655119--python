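"""Genomic-interval algebra and BED/TSV I/O shared by every pipeline stage.

Coordinates are 0-based half-open throughout, matching BED. Adjacency
(``a.end == b.start``) is *not* overlap. Published genome-browser style
coordinates ("chr5: 104,216,600-104,216,700") are 1-based fully-closed;
:func:`from_browser_coords` converts them on the way in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ArgumentError, ParseError

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class Interval:
    """A named, scored genomic span (BED6 semantics, 0-based half-open)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ArgumentError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ArgumentError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ArgumentError(f"unknown strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "Interval") -> int:
        """Overlap in bases with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def sort_key(self):
        return (self.chrom, self.start, self.end)


def from_browser_coords(chrom: str, start_1based: int, end_inclusive: int,
                        name: str = ".") -> Interval:
    """Convert 1-based fully-closed browser coordinates to an Interval."""
    return Interval(chrom, start_1based - 1, end_inclusive, name)


class PeakSet:
    """An ordered collection of intervals with a provenance label.

    Intervals are kept sorted by (chrom, start, end). Names must be unique
    within a set when any name other than "." is used.
    """

    def __init__(self, intervals, label: str = ""):
        ivs = sorted(intervals, key=Interval.sort_key)
        names = [iv.name for iv in ivs if iv.name != "."]
        if len(names) != len(set(names)):
            raise ArgumentError(f"duplicate interval names in PeakSet {label!r}")
        self.intervals: list[Interval] = ivs
        self.label = label

    def __len__(self):
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other):
        return isinstance(other, PeakSet) and self.intervals == other.intervals

    def __repr__(self):
        return f"PeakSet({len(self)} intervals, label={self.label!r})"

    def by_chrom(self) -> dict[str, list[Interval]]:
        out: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def names(self) -> list[str]:
        return [iv.name for iv in self.intervals]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": [iv.name for iv in self.intervals],
                "score": [iv.score for iv in self.intervals],
                "strand": [iv.strand for iv in self.intervals],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "") -> "PeakSet":
        return cls(
            (
                Interval(
                    str(r.chrom), int(r.start), int(r.end),
                    str(getattr(r, "name", ".")),
                    float(getattr(r, "score", 0.0)),
                    str(getattr(r, "strand", ".")),
                )
                for r in df.itertuples(index=False)
            ),
            label=label,
        )


def read_bed(path, label: str = "") -> PeakSet:
    """Read a BED3/BED6 file, validating every line.

    Malformed lines (fewer than 3 columns, non-integer or negative
    coordinates, start >= end, unknown strand) raise :class:`ParseError`
    naming the 1-based line number.
    """
    path = Path(path)
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"expected >=3 tab-separated columns, got {len(fields)}", lineno)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"non-integer coordinates {fields[1]!r}/{fields[2]!r}", lineno)
            if start < 0:
                raise ParseError(f"negative start {start}", lineno)
            if start >= end:
                raise ParseError(f"start {start} >= end {end}", lineno)
            name = fields[3] if len(fields) > 3 else "."
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError:
                raise ParseError(f"non-numeric score {fields[4]!r}", lineno)
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in _STRANDS:
                raise ParseError(f"unknown strand {strand!r}", lineno)
            try:
                intervals.append(Interval(chrom, start, end, name, score, strand))
            except ArgumentError as exc:
                raise ParseError(str(exc), lineno)
    return PeakSet(intervals, label=label or path.stem)


def write_bed(peaks: PeakSet, path) -> None:
    """Write a PeakSet as canonical BED6."""
    with open(path, "w") as fh:
        for iv in peaks:
            score = int(iv.score) if float(iv.score).is_integer() else iv.score
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n")


def intersect(a: PeakSet, b: PeakSet, min_overlap: int = 1) -> PeakSet:
    """Members of ``a`` overlapping any member of ``b`` by >= min_overlap bp.

    Half-open convention: an interval ending where another starts does not
    overlap it. Output is a subset of ``a``; idempotent at min_overlap=1.
    """
    if min_overlap < 1:
        raise ArgumentError(f"min_overlap must be >= 1, got {min_overlap}")
    b_chrom = {c: (np.array([iv.start for iv in ivs]), np.array([iv.end for iv in ivs]))
               for c, ivs in b.by_chrom().items()}
    kept = []
    for iv in a:
        got = b_chrom.get(iv.chrom)
        if got is None:
            continue
        starts, ends = got
        ov = np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
        if (ov >= min_overlap).any():
            kept.append(iv)
    return PeakSet(kept, label=a.label)


def gaps(a: PeakSet) -> list[tuple[Interval, Interval, Interval]]:
    """Inter-peak gaps: (left peak, gap span, right peak) triples.

    For each chromosome the running maximum end is tracked, so a peak nested
    inside an earlier, longer one never opens a spurious gap. Overlapping or
    book-ended neighbours produce no gap; chromosome boundaries never do.
    """
    out = []
    for _, ivs in sorted(a.by_chrom().items()):
        left = ivs[0]
        max_end = left.end
        for right in ivs[1:]:
            if right.start > max_end:
                gap = Interval(right.chrom, max_end, right.start,
                               name=f"gap:{left.name}|{right.name}")
                out.append((left, gap, right))
            if right.end > max_end:
                max_end = right.end
                left = right
            elif right.start > left.end:
                # same max_end but a nearer left flank for the next gap
                left = left if left.end >= right.end else right
    return out


def nearest_tss_domains(genes: pd.DataFrame, basal_up: int = 5000,
                        basal_down: int = 1000, max_extension: int = 1_000_000,
                        chrom_lengths: dict[str, int] | None = None) -> PeakSet:
    """Basal-plus-extension regulatory domains (GREAT association rule).

    Each gene gets a strand-aware basal domain (``basal_up`` upstream,
    ``basal_down`` downstream of the TSS), then extends in both directions
    up to ``max_extension`` from the TSS, stopping at the nearest neighbour
    gene's basal domain and at chromosome bounds. Basal domains are never
    shrunk, so neighbouring domains may overlap where basal regions do.

    ``genes`` needs columns gene, chrom, tss, strand.
    """
    if genes["gene"].duplicated().any():
        dups = genes.loc[genes["gene"].duplicated(), "gene"].tolist()
        raise ArgumentError(f"duplicate gene names: {dups}")
    chrom_lengths = chrom_lengths or {}
    domains = []
    for chrom, sub in genes.groupby("chrom"):
        sub = sub.sort_values("tss").reset_index(drop=True)
        L = chrom_lengths.get(chrom, np.inf)
        basal = []
        for r in sub.itertuples(index=False):
            if r.strand == "-":
                bs, be = r.tss - basal_down, r.tss + basal_up
            else:
                bs, be = r.tss - basal_up, r.tss + basal_down
            basal.append((max(0, bs), min(L, be)))
        for i, r in enumerate(sub.itertuples(index=False)):
            bs, be = basal[i]
            lo_limit = max(0, r.tss - max_extension)
            hi_limit = min(L, r.tss + max_extension)
            if i > 0:
                lo_limit = max(lo_limit, basal[i - 1][1])
            if i < len(basal) - 1:
                hi_limit = min(hi_limit, basal[i + 1][0])
            start = max(0, min(bs, lo_limit))
            end = min(L, max(be, hi_limit))
            domains.append(Interval(chrom, int(start), int(end),
                                    name=str(r.gene), strand=str(r.strand)))
    return PeakSet(domains, label="regulatory_domains")


def assign_regions_to_genes(peaks: PeakSet, domains: PeakSet) -> dict[str, set[str]]:
    """Map each peak name to every gene whose regulatory domain it overlaps.

    Peaks overlapping no domain map to the empty set. A peak overlapping two
    domains is assigned to both.
    """
    dom_chrom = {c: (np.array([d.start for d in ds]), np.array([d.end for d in ds]),
                     np.array([d.name for d in ds], dtype=object))
                 for c, ds in domains.by_chrom().items()}
    out: dict[str, set[str]] = {}
    for iv in peaks:
        genes: set[str] = set()
        got = dom_chrom.get(iv.chrom)
        if got is not None:
            starts, ends, names = got
            hit = (np.minimum(ends, iv.end) - np.maximum(starts, iv.start)) >= 1
            genes = set(names[hit])
        out[iv.name] = genes
    return out


def read_gene_annotation(path) -> pd.DataFrame:
    """Read the minimal gene annotation TSV (gene, chrom, tss, strand)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"gene annotation missing columns {sorted(missing)}")
    return df
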