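"""Synthetic ATAC-seq / CUT&Tag / scRNA inputs with planted ground truth.

Every generator is deterministic given its seed and records what it
planted, so each downstream stage (differential testing, enhancer
annotation, trajectory clustering, motif enrichment, footprinting, QC,
GSEA) can be validated by truth recovery instead of against deposited
sequencing data. All randomness flows from one root seed through
per-generator ``numpy`` child streams.

Conventions: coordinates 0-based half-open; negative-binomial counts use
the mean/dispersion form var = mu + alpha * mu**2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ArgumentError, CapacityError
from .coverage_peaks import CountMatrix
from .intervals_io import Interval, PeakSet

DYNAMIC_CLASSES = ("opening", "closing", "flat")
K27_RELATIONS = ("overlap", "flanked", "distal", "none")

_BASES = np.array(list("ACGT"))


@dataclass
class GenomeLayout:
    """Chromosome names and lengths of the toy genome (stands in for a real
    reference assembly)."""

    chrom_names: list[str]
    chrom_lengths: list[int]
    seed: int = 0

    def __post_init__(self):
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ArgumentError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ArgumentError("chromosome lengths must be positive")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))


@dataclass
class PlantedTruth:
    """Ground-truth record for one regulatory element."""

    element_id: str
    interval: Interval
    dynamic_class: str
    planted_motifs: list[str] = field(default_factory=list)
    k27_relation: str = "none"

    def __post_init__(self):
        if self.dynamic_class not in DYNAMIC_CLASSES:
            raise ArgumentError(f"unknown dynamic_class {self.dynamic_class!r}")
        if self.k27_relation not in K27_RELATIONS:
            raise ArgumentError(f"unknown k27_relation {self.k27_relation!r}")


def truth_to_frame(truth: list[PlantedTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "element_id": [t.element_id for t in truth],
            "chrom": [t.interval.chrom for t in truth],
            "start": [t.interval.start for t in truth],
            "end": [t.interval.end for t in truth],
            "dynamic_class": [t.dynamic_class for t in truth],
            "planted_motifs": [",".join(t.planted_motifs) for t in truth],
            "k27_relation": [t.k27_relation for t in truth],
        }
    )


def _child_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent stream derived from the root seed and a stage name."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(hash(stream) % (2**31),))
    )


def make_genome(n_chroms: int, length: int, seed: int,
                fasta_path=None) -> tuple[GenomeLayout, dict[str, str]]:
    """Random A/C/G/T genome; same seed gives byte-identical sequence."""
    if n_chroms < 1:
        raise ArgumentError("n_chroms must be >= 1")
    if length < 10_000:
        raise ArgumentError("chromosome length must be >= 10,000 bp")
    rng = _child_rng(seed, "genome")
    names = [f"chr{i + 1}" for i in range(n_chroms)]
    seqs = {c: "".join(_BASES[rng.integers(0, 4, size=length)]) for c in names}
    layout = GenomeLayout(names, [length] * n_chroms, seed=seed)
    if fasta_path is not None:
        write_fasta(seqs, fasta_path)
    return layout, seqs


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _exact_class_counts(n: int, mix: dict[str, float], classes) -> list[int]:
    """Largest-remainder apportionment: exact when n*p is integral."""
    props = np.array([mix.get(c, 0.0) for c in classes], dtype=float)
    if not np.isclose(props.sum(), 1.0):
        raise ArgumentError(f"proportions must sum to 1, got {props.sum():.4f}")
    raw = props * n
    counts = np.floor(raw + 1e-9).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def plant_peaks(layout: GenomeLayout, n_peaks: int,
                width_range: tuple[int, int] = (200, 400),
                dynamics_mix: dict[str, float] | None = None,
                seed: int = 0, min_gap: int = 200) -> tuple[PeakSet, list[PlantedTruth]]:
    """Place non-overlapping elements and assign dynamic classes.

    Class counts follow ``dynamics_mix`` by largest-remainder apportionment
    (exact when n x proportion is integral), then classes are shuffled over
    positions. Raises CapacityError when the genome cannot hold the peaks
    with ``min_gap`` bp between them.
    """
    if n_peaks < 1:
        raise ArgumentError("n_peaks must be >= 1")
    dynamics_mix = dynamics_mix or {"opening": 0.25, "closing": 0.25, "flat": 0.5}
    rng = _child_rng(seed, "peaks")
    counts = _exact_class_counts(n_peaks, dynamics_mix, DYNAMIC_CLASSES)
    classes = np.repeat(DYNAMIC_CLASSES, counts)
    rng.shuffle(classes)

    # apportion peaks over chromosomes by length
    lens = np.array(layout.chrom_lengths, dtype=float)
    per_chrom = _exact_class_counts(
        n_peaks, dict(zip(layout.chrom_names, lens / lens.sum())), layout.chrom_names
    )
    intervals = []
    k = 0
    for chrom, L, n_c in zip(layout.chrom_names, layout.chrom_lengths, per_chrom):
        if n_c == 0:
            continue
        widths = rng.integers(width_range[0], width_range[1] + 1, size=n_c)
        need = int(widths.sum()) + (n_c + 1) * min_gap
        if need > L:
            raise CapacityError(
                f"{chrom}: need {need} bp for {n_c} peaks with {min_gap} bp gaps, "
                f"have {L}"
            )
        slack = L - int(widths.sum()) - (n_c + 1) * min_gap
        extra = rng.multinomial(slack, np.ones(n_c + 1) / (n_c + 1))
        pos = min_gap + extra[0]
        for i in range(n_c):
            k += 1
            intervals.append(Interval(chrom, int(pos), int(pos + widths[i]),
                                      name=f"nfr_{k}"))
            pos += widths[i] + min_gap + extra[i + 1]
    truth = [
        PlantedTruth(iv.name, iv, cls) for iv, cls in zip(intervals, classes)
    ]
    return PeakSet(intervals, label="planted_nfrs"), truth


def _class_multiplier(dynamic_class: str, t: int, T: int, effect_log2fc: float) -> float:
    if T == 0 or dynamic_class == "flat":
        return 1.0
    if dynamic_class == "opening":
        return 2.0 ** (effect_log2fc * t / T)
    return 2.0 ** (-effect_log2fc * t / T)


def simulate_counts(truth: list[PlantedTruth], timepoints: list[str],
                    replicates: int = 3, base_mean: float = 100.0,
                    dispersion: float = 0.1, effect_log2fc: float = 2.0,
                    seed: int = 0, depth_factors: list[float] | None = None
                    ) -> CountMatrix:
    """Replicated negative-binomial counts realizing the planted dynamics.

    Opening elements follow mean * 2**(effect_log2fc * t/T) over time index
    t (T = last index), closing the reciprocal, flat a constant mean.
    ``depth_factors`` optionally scales each sample's library size.
    """
    if not truth:
        raise ArgumentError("empty truth list")
    if dispersion <= 0:
        raise ArgumentError("dispersion must be > 0")
    if replicates < 1:
        raise ArgumentError("replicates must be >= 1")
    rng = _child_rng(seed, "counts")
    T = len(timepoints) - 1
    samples, stages, reps = [], [], []
    cols = {}
    n_samples = len(timepoints) * replicates
    depth = np.ones(n_samples) if depth_factors is None else np.asarray(depth_factors, float)
    mult = np.array(
        [[_class_multiplier(tr.dynamic_class, t, T, effect_log2fc)
          for t in range(len(timepoints))] for tr in truth]
    )
    j = 0
    for t, tp in enumerate(timepoints):
        for r in range(1, replicates + 1):
            mu = base_mean * mult[:, t] * depth[j]
            shape = 1.0 / dispersion
            lam = rng.gamma(shape, mu * dispersion)
            col = rng.poisson(lam)
            name = f"{tp}_rep{r}"
            cols[name] = col
            samples.append(name)
            stages.append(tp)
            reps.append(r)
            j += 1
    counts = pd.DataFrame(cols, index=[tr.element_id for tr in truth])
    meta = pd.DataFrame({"stage": stages, "replicate": reps}, index=samples)
    return CountMatrix(counts, meta)


def plant_k27_peaks(layout: GenomeLayout, nfrs: PeakSet,
                    truth: list[PlantedTruth],
                    relation_mix: dict[str, float] | None = None,
                    gap_for_flanked: int = 1000, k27_width: int = 400,
                    distal_distance: int = 10_001, seed: int = 0
                    ) -> tuple[PeakSet, list[PlantedTruth]]:
    """Place H3K27Ac peaks realizing each element's planted relation.

    overlap: a K27 peak centred on the NFR. flanked: two K27 peaks whose
    intervening gap is exactly ``gap_for_flanked`` bp and contains the NFR.
    distal: nearest K27 peak placed > 10 kb away. none: no peak placed.
    Placements are verified against the assembled peak set; collisions
    (NFRs too densely packed for the requested geometry) raise
    CapacityError.
    """
    if gap_for_flanked < 1:
        raise ArgumentError("gap_for_flanked must be >= 1")
    relation_mix = relation_mix or {"overlap": 0.25, "flanked": 0.25,
                                    "distal": 0.25, "none": 0.25}
    rng = _child_rng(seed, "k27")
    counts = _exact_class_counts(len(truth), relation_mix, K27_RELATIONS)
    relations = np.repeat(K27_RELATIONS, counts)
    rng.shuffle(relations)
    lengths = layout.lengths

    k27 = []
    idx = 0
    for tr, rel in zip(truth, relations):
        tr.k27_relation = str(rel)
        iv = tr.interval
        L = lengths[iv.chrom]
        if rel == "overlap":
            c = (iv.start + iv.end) // 2
            s = max(0, c - k27_width // 2)
            idx += 1
            k27.append(Interval(iv.chrom, s, min(L, s + k27_width), f"k27_{idx}"))
        elif rel == "flanked":
            margin = gap_for_flanked - iv.width
            if margin < 0:
                raise CapacityError(
                    f"{tr.element_id}: NFR width {iv.width} exceeds flanked gap "
                    f"{gap_for_flanked}"
                )
            gap_start = iv.start - margin // 2
            gap_end = gap_start + gap_for_flanked
            ls, re = gap_start - k27_width, gap_end + k27_width
            if ls < 0 or re > L:
                raise CapacityError(f"{tr.element_id}: no room for flanking peaks")
            idx += 1
            k27.append(Interval(iv.chrom, ls, gap_start, f"k27_{idx}"))
            idx += 1
            k27.append(Interval(iv.chrom, gap_end, re, f"k27_{idx}"))
        elif rel == "distal":
            s = iv.end + distal_distance
            if s + k27_width > L:
                s = iv.start - distal_distance - k27_width
            if s >= 0 and s + k27_width <= L:
                idx += 1
                k27.append(Interval(iv.chrom, s, s + k27_width, f"k27_{idx}"))
    k27_set = PeakSet(k27, label="planted_k27")
    _verify_k27(truth, k27_set)
    return k27_set, truth


def _verify_k27(truth: list[PlantedTruth], k27: PeakSet) -> None:
    by_chrom = {c: ivs for c, ivs in k27.by_chrom().items()}
    for c, ivs in by_chrom.items():
        e = 0
        for iv in ivs:
            if iv.start < e:
                raise CapacityError(
                    "planted H3K27Ac peaks collide; increase NFR spacing"
                )
            e = iv.end
    for tr in truth:
        iv = tr.interval
        ivs = by_chrom.get(iv.chrom, [])
        dists = [0 if iv.overlap_bp(p) > 0
                 else (p.start - iv.end if p.start >= iv.end else iv.start - p.end)
                 for p in ivs]
        nearest = min(dists) if dists else np.inf
        if tr.k27_relation == "overlap" and nearest != 0:
            raise CapacityError(f"{tr.element_id}: overlap relation not realized")
        if tr.k27_relation == "flanked" and nearest == 0:
            raise CapacityError(f"{tr.element_id}: flanked element touches a peak")
        if tr.k27_relation in ("distal", "none") and nearest <= 10_000:
            raise CapacityError(
                f"{tr.element_id}: {tr.k27_relation} element has a peak within 10 kb; "
                "increase NFR spacing"
            )


def plant_motifs_and_cuts(layout: GenomeLayout, seqs: dict[str, str],
                          truth: list[PlantedTruth], pwm_set,
                          timepoints: list[str],
                          enrichment_ratio: float = 5.0,
                          base_rate: float = 0.15,
                          footprint_protection: float = 0.5,
                          window: int = 100,
                          element_cut_rate: float = 0.5,
                          background_cut_rate: float = 0.005,
                          effect_log2fc: float = 2.0,
                          seed: int = 0
                          ) -> tuple[dict[str, str], dict[str, pd.DataFrame]]:
    """Write motif consensus sequences into elements and simulate cut sites.

    The first PWM in ``pwm_set`` is the planted motif: its consensus is
    written into opening elements at ``enrichment_ratio`` times the base
    planting rate used for other elements (truth records are updated).
    Per-timepoint Tn5 cut counts are Poisson: a flat genomic background,
    an elevated in-element rate scaled by the element's planted trajectory,
    and a motif-core rate multiplied by (1 - footprint_protection).
    """
    if not 0 <= footprint_protection <= 1:
        raise ArgumentError("footprint_protection must be in [0, 1]")
    if enrichment_ratio < 1:
        raise ArgumentError("enrichment_ratio must be >= 1")
    pwm = pwm_set[0]
    if window < pwm.width:
        raise ArgumentError(f"window {window} smaller than motif width {pwm.width}")
    rng = _child_rng(seed, "motifs")
    p_open = min(1.0, base_rate * enrichment_ratio)
    arrs = {c: np.frombuffer(s.encode(), dtype="S1").copy() for c, s in seqs.items()}
    cores = []  # (truth, core_start, core_end)
    for tr in truth:
        rate = p_open if tr.dynamic_class == "opening" else base_rate
        if rng.random() < rate:
            iv = tr.interval
            off = (iv.width - pwm.width) // 2
            s = iv.start + off
            arrs[iv.chrom][s : s + pwm.width] = np.frombuffer(
                pwm.consensus.encode(), dtype="S1"
            )
            tr.planted_motifs.append(pwm.motif_id)
            cores.append((tr, s, s + pwm.width))
    new_seqs = {c: a.tobytes().decode() for c, a in arrs.items()}

    core_by_elem = {tr.element_id: (cs, ce) for tr, cs, ce in cores}
    T = len(timepoints) - 1
    cuts_by_tp: dict[str, pd.DataFrame] = {}
    for t, tp in enumerate(timepoints):
        chroms, starts = [], []
        # flat background
        for c, L in layout.lengths.items():
            n_bg = rng.poisson(background_cut_rate * L)
            pos = np.sort(rng.integers(0, L, size=n_bg))
            chroms.append(np.full(n_bg, c, dtype=object))
            starts.append(pos)
        # in-element signal with footprint-protected cores
        for tr in truth:
            iv = tr.interval
            rate = element_cut_rate * _class_multiplier(
                tr.dynamic_class, t, T, effect_log2fc
            )
            lam = np.full(iv.width, rate)
            core = core_by_elem.get(tr.element_id)
            if core is not None:
                cs, ce = core
                lam[cs - iv.start : ce - iv.start] *= 1.0 - footprint_protection
            n = rng.poisson(lam)
            pos = np.repeat(np.arange(iv.start, iv.end), n)
            chroms.append(np.full(len(pos), iv.chrom, dtype=object))
            starts.append(pos)
        df = pd.DataFrame(
            {"chrom": np.concatenate(chroms), "start": np.concatenate(starts)}
        )
        df["end"] = df["start"] + 1
        cuts_by_tp[tp] = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    return new_seqs, cuts_by_tp


def write_cuts_bed(cuts: pd.DataFrame, path) -> None:
    out = cuts.copy()
    out["name"] = "."
    out["score"] = 1
    out["strand"] = "."
    out.to_csv(path, sep="\t", header=False, index=False)


def read_cuts_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    return df


def simulate_cell_matrix(specs: pd.DataFrame | None = None, n_cells: int = 100,
                         gene_count_range: tuple[int, int] = (200, 6000),
                         mito_fraction_range: tuple[float, float] = (0.0, 20.0),
                         n_genes_total: int = 10_000, n_mito_genes: int = 13,
                         seed: int = 0) -> tuple[CountMatrix, pd.DataFrame]:
    """Gene x cell counts with exactly controlled per-barcode QC metrics.

    Each barcode's detected-gene count and mitochondrial-UMI percentage are
    *constructed* (not sampled): the mito percentage is realized exactly as
    a rational fraction of UMIs, so threshold boundaries (e.g. 500 genes,
    10.0% mito) can be tested without Monte-Carlo slack. Explicit specs
    (columns n_genes, mito_pct) override random draws.
    """
    rng = _child_rng(seed, "cells")
    if specs is None:
        n_genes = rng.integers(gene_count_range[0], gene_count_range[1] + 1,
                               size=n_cells)
        mito = np.round(rng.uniform(*mito_fraction_range, size=n_cells), 2)
        specs = pd.DataFrame({"n_genes": n_genes, "mito_pct": mito})
    specs = specs.reset_index(drop=True)
    if (specs["n_genes"] < 0).any() or (specs["mito_pct"] < 0).any():
        raise ArgumentError("negative per-barcode specs")
    if (specs["mito_pct"] >= 100).any():
        raise ArgumentError("mito_pct must be < 100")

    mito_genes = [f"mt-{i + 1}" for i in range(n_mito_genes)]
    other_genes = [f"gene_{i + 1}" for i in range(n_genes_total - n_mito_genes)]
    all_genes = mito_genes + other_genes
    mat = np.zeros((len(all_genes), len(specs)), dtype=np.int64)
    gene_index = {g: i for i, g in enumerate(all_genes)}

    for j, row in specs.iterrows():
        g = int(row["n_genes"])
        m = float(row["mito_pct"])
        if g == 0:
            continue
        if m == 0.0:
            chosen = rng.choice(other_genes, size=g, replace=False)
            for gn in chosen:
                mat[gene_index[gn], j] = 1
            continue
        frac = Fraction(round(m * 10_000), 1_000_000)  # exact mito UMI share
        p, q = frac.numerator, frac.denominator
        n_unit = q - p
        if g == 1:
            if n_unit:
                raise ArgumentError(
                    f"barcode {j}: 1 detected gene incompatible with mito_pct {m}"
                )
            mat[gene_index[mito_genes[0]], j] = max(1, p)
            continue
        t = max(1, int(np.ceil((g - 1) / n_unit)))
        M, N = p * t, n_unit * t
        chosen = rng.choice(other_genes, size=g - 1, replace=False)
        base, rem = divmod(N, g - 1)
        for i, gn in enumerate(chosen):
            mat[gene_index[gn], j] = base + (1 if i < rem else 0)
        mat[gene_index[rng.choice(mito_genes)], j] = M

    counts = pd.DataFrame(mat, index=all_genes,
                          columns=[f"bc_{j + 1}" for j in range(len(specs))])
    truth = specs.copy()
    truth.index = counts.columns
    # realized metrics (equal to specs by construction; kept for audit)
    detected = (counts > 0).sum(axis=0)
    total = counts.sum(axis=0)
    mito_umi = counts.loc[mito_genes].sum(axis=0)
    truth["detected_genes"] = detected
    truth["realized_mito_pct"] = np.where(total > 0, 100.0 * mito_umi / total, 0.0)
    cm = CountMatrix(counts, pd.DataFrame(index=counts.columns))
    return cm, truth


def simulate_marker_matrix(n_clusters: int = 2, cells_per_cluster: int = 50,
                           n_genes: int = 300, markers_per_cluster: int = 10,
                           base_mean: float = 1.0, fold: float = 10.0,
                           seed: int = 0
                           ) -> tuple[CountMatrix, pd.Series, dict[str, set]]:
    """Clustered gene x cell Poisson counts with planted marker genes.

    Each cluster gets ``markers_per_cluster`` genes whose mean is ``fold``
    times the base mean in that cluster only. Returns (matrix, cell ->
    cluster labels, cluster -> planted marker set).
    """
    rng = _child_rng(seed, "markers")
    genes = [f"g{i + 1}" for i in range(n_genes)]
    cells, labels = [], []
    planted: dict[str, set] = {}
    mu = np.full((n_genes, n_clusters * cells_per_cluster), base_mean)
    col = 0
    for c in range(1, n_clusters + 1):
        gs = set(genes[(c - 1) * markers_per_cluster : c * markers_per_cluster])
        planted[str(c)] = gs
        ixs = [genes.index(g) for g in gs]
        for r in range(cells_per_cluster):
            name = f"c{c}_cell{r + 1}"
            cells.append(name)
            labels.append(str(c))
            mu[ixs, col] = base_mean * fold
            col += 1
    counts = pd.DataFrame(rng.poisson(mu), index=genes, columns=cells)
    cm = CountMatrix(counts, pd.DataFrame(index=cells))
    return cm, pd.Series(labels, index=cells), planted


def simulate_ranked_genes(n_genes: int = 2000, set_size: int = 50,
                          shift: float = 1.5, seed: int = 0
                          ) -> tuple[pd.DataFrame, list[str]]:
    """Ranked differential-expression table with one planted enriched set.

    Background scores are standard normal; the planted set's scores are
    shifted up by ``shift``, so the set concentrates at the top of the
    ranking. Returns the table sorted by descending score and the planted
    member list.
    """
    rng = _child_rng(seed, "ranked")
    genes = [f"g{i + 1}" for i in range(n_genes)]
    scores = rng.normal(0.0, 1.0, size=n_genes)
    members = list(rng.choice(genes, size=set_size, replace=False))
    member_ix = [genes.index(m) for m in members]
    scores[member_ix] += shift
    df = pd.DataFrame({"gene": genes, "score": scores}).sort_values(
        "score", ascending=False
    ).reset_index(drop=True)
    return df, members
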