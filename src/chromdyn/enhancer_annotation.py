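"""Active-enhancer annotation from stage-matched H3K27Ac peaks.

A stage-enriched NFR is called an active enhancer when it overlaps (>= 1
bp) either a same-stage H3K27Ac peak or an "H3K27Ac-flanked" region — the
span between two adjacent H3K27Ac peaks on the same chromosome whose gap
is strictly less than 1,500 bp. Overlap, not containment, is required, so
an NFR wider than the flanked gap still qualifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._errors import ArgumentError
from .intervals_io import Interval, PeakSet, gaps

EVIDENCE = ("direct_overlap", "flanked")


@dataclass
class ActiveEnhancerSet:
    """Stage-enriched NFRs with active-enhancer evidence."""

    stage: str
    enhancers: PeakSet
    evidence: dict[str, set[str]] = field(default_factory=dict)

    def __len__(self):
        return len(self.enhancers)


def flanked_regions(k27: PeakSet, max_gap: int = 1500) -> PeakSet:
    """Gaps between adjacent same-chromosome H3K27Ac peaks, width < max_gap.

    The boundary is strict: a gap of exactly ``max_gap`` bp is not emitted.
    """
    if max_gap < 2:
        raise ArgumentError("max_gap must be >= 2")
    out = []
    for i, (_, gap, _) in enumerate(gaps(k27), start=1):
        if 1 <= gap.width < max_gap:
            out.append(Interval(gap.chrom, gap.start, gap.end, name=f"flank_{i}"))
    return PeakSet(out, label=f"{k27.label}_flanked")


def call_active_enhancers(nfrs_enriched: PeakSet, k27_enriched: PeakSet,
                          stage: str | None = None, max_gap: int = 1500,
                          k27_stage: str | None = None) -> ActiveEnhancerSet:
    """Stage-enriched NFRs supported by H3K27Ac overlap or flanking.

    Evidence per enhancer records which route(s) fired: ``direct_overlap``
    (>= 1 bp with a K27 peak) and/or ``flanked`` (>= 1 bp with a < max_gap
    inter-peak gap). When both stage labels are given they must agree.
    """
    stage = stage if stage is not None else nfrs_enriched.label
    k27_stage = k27_stage if k27_stage is not None else stage
    if stage != k27_stage:
        raise ArgumentError(
            f"stage mismatch: NFRs are {stage!r}, H3K27Ac peaks are {k27_stage!r}"
        )
    flanks = flanked_regions(k27_enriched, max_gap=max_gap)

    def _hits(targets: PeakSet) -> set[str]:
        by_chrom = {c: (np.array([t.start for t in ts]), np.array([t.end for t in ts]))
                    for c, ts in targets.by_chrom().items()}
        got = set()
        for iv in nfrs_enriched:
            arrs = by_chrom.get(iv.chrom)
            if arrs is None:
                continue
            s, e = arrs
            if ((np.minimum(e, iv.end) - np.maximum(s, iv.start)) >= 1).any():
                got.add(iv.name)
        return got

    direct = _hits(k27_enriched)
    via_flank = _hits(flanks)
    evidence: dict[str, set[str]] = {}
    kept = []
    for iv in nfrs_enriched:
        ev = set()
        if iv.name in direct:
            ev.add("direct_overlap")
        if iv.name in via_flank:
            ev.add("flanked")
        if ev:
            kept.append(iv)
            evidence[iv.name] = ev
    return ActiveEnhancerSet(stage=stage, enhancers=PeakSet(kept, label=f"{stage}_AE"),
                             evidence=evidence)
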