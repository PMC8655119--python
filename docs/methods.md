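# Methods

`chromdyn` re-implements, as a reusable library, the computational core of
a time-course open-chromatin study of cell differentiation: calling
stage-enriched nucleosome-free regions (NFRs) from replicated ATAC-seq
count matrices, annotating active enhancers with H3K27Ac, clustering
accessibility trajectories, testing transcription-factor motif enrichment,
profiling Tn5 footprints, and integrating the chromatin results with
single-cell and bulk expression. This note records the models, the
defaults and why they were chosen, what the synthetic data do and do not
emulate, and the numerical decisions a maintainer would want to know.

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED convention); adjacency
(`a.end == b.start`) is never overlap. Genome-browser style coordinates
("chr5: 104,216,600–104,216,700") are 1-based fully-closed and are
converted on input by `intervals_io.from_browser_coords`. Interval
operations (`intersect`, `gaps`, regulatory domains, region→gene
assignment) are implemented directly and validated against quadratic
brute-force oracles in the test suite; `gaps` tracks the running maximum
end per chromosome so that an interval nested inside a longer one never
opens a spurious gap.

Region→gene association uses the basal-plus-extension rule popularized by
GREAT: each gene receives a strand-aware basal domain (default 5,000 bp
upstream, 1,000 bp downstream of the TSS) extended in both directions up
to 1,000,000 bp from the TSS, stopping at the nearest neighbouring gene's
basal domain and at chromosome bounds; basal domains are never shrunk, so
neighbouring domains may overlap where basal regions do. A peak is
assigned to every gene whose domain it overlaps (ties go to both genes;
downstream gene-level statements use the union). The three defaults are
GREAT's published defaults and are exposed as parameters.

## Differential accessibility

Counts are modelled as negative binomial with the mean/dispersion
parameterization var = μ + αμ². For a two-stage comparison with n ≥ 2
replicates per stage:

1. **Normalization.** `normalize_libsize` offers total-count scaling
   (size factor = column sum / geometric mean of column sums) and
   DESeq-style median-of-ratios. The differential test, accessibility
   scores and trajectories default to median-of-ratios: when a sizeable
   fraction of peaks moves in one direction between stages (the situation
   the study design creates), total-count scaling transfers that
   composition shift onto every flat peak as a spurious fold change; the
   median ratio is pinned by the unchanged majority. Median-of-ratios is
   itself quantile-biased when changes are strongly one-sided (≳30% of
   peaks moving the same way) — a known limitation shared with the
   standard tools.
2. **Dispersion.** Per peak, α is estimated by method of moments,
   (s² − m)/m², pooled across the two groups by degrees of freedom. At
   3v3 replicates this estimate is far too noisy to plug into a Wald
   statistic (empirical type-I ≈ 0.11 at nominal 0.05), so it is shrunk
   toward a global prior with `prior_df = 20` pseudo-degrees of freedom
   against the peak's 4 real ones. The prior is an iterated
   bias-corrected moment regression, Σ(s² − m) / Σ(m² − V̂ar(m̄)), whose
   denominator removes the sampling variance of the squared group means;
   the naive across-peak median underestimates α by ~20% at this
   replicate count. With the corrected prior the measured type-I error is
   0.052–0.057 at nominal 0.05 (Monte-Carlo over 10,000 null peaks), and
   the shrinkage can be disabled (`dispersion_shrinkage=False`).
3. **Test.** log₂FC = log₂((m₂ + 0.5)/(m₁ + 0.5)); the 0.5 pseudo-count
   avoids infinities at zero counts. The Wald statistic divides log₂FC by
   its delta-method standard error under NB variance of the group means;
   p-values are two-sided normal. A Wald test was chosen over a GLM
   likelihood ratio because it is simpler, calibration-tested, and the
   original DESeq2 numbers are not reproduction targets.
4. **Decision rule.** Benjamini–Hochberg FDR (step-up with monotone
   enforcement), then the strict thresholds log₂FC > 0.5 (stage-2
   enriched) or < −0.5 (stage-1 enriched) with FDR < 0.01. The
   accessibility score used for gene-set comparisons is the same
   normalized log₂ contrast.

## Active-enhancer annotation

An "H3K27Ac-flanked" region is the span between two adjacent (consecutive
after sorting, same chromosome) H3K27Ac peaks whose gap is strictly less
than 1,500 bp. A stage-enriched NFR is an active enhancer when it overlaps
(≥ 1 bp) a same-stage H3K27Ac peak or such a flanked region; overlap, not
containment, is required, so an NFR wider than the gap still qualifies.
Evidence (`direct_overlap`, `flanked`) is recorded per enhancer and the
two routes may co-occur. Enlarging the gap threshold can only add
enhancers (tested monotonicity).

## Trajectory clustering

Per-peak stage means on normalized counts are z-scored per row (constant
rows are excluded and reported), clustered with Lloyd's k-means on
Euclidean distance (k = 4 by default, mirroring the four element clusters
of the motivating time course; best of 20 seeded restarts by
within-cluster sum of squares). Time is treated as an ordinal index
(0…T−1), not days, because sampling is unevenly spaced. Each cluster's
mean z-trajectory is called *opening* when its Spearman correlation with
the time index is ≥ +0.8, *closing* at ≤ −0.8, otherwise *non-monotone*;
±0.8 is deliberately strict for five timepoints (a perfectly monotone
five-point trajectory has ρ = ±1; one transposition drops it to 0.7) and
is configurable. Z-scores rather than raw signal are clustered — the
standard choice for trajectory heatmaps, and the one that makes cluster
membership depend on shape rather than peak height.

## Motif analysis

PWMs carry a TF-family tag (bZIP, Zinc Finger, RUNX, Forkhead, TEA,
MADS, …). Probabilities get a 0.01 pseudo-count against the background
base frequencies before log-odds; the default hit threshold is 80% of the
maximum attainable log-odds score (the upstream tools bury this choice in
internal defaults; here it is explicit and configurable). Both strands are
scanned; reverse-strand hits are reported on forward coordinates.

Enrichment is Homer-style over peaks: k of n target peaks carry ≥ 1 hit;
the background rate p̂ is the hit-bearing fraction of the background set
(all consensus peaks outside the target cluster); the reported value is
the upper-tail binomial probability P(X ≥ k | n, p̂) as −log₁₀ p. Counting
peaks-with-a-hit rather than total hits matches the binomial formulation
and is insensitive to homotypic clusters. GC-matched background
normalization is *not* performed — a stated divergence from Homer. Family
summaries take the best motif per family per cluster; rows and columns of
the family × cluster heatmap are ordered by average-linkage hierarchical
clustering on Euclidean distance.

Footprints aggregate per-base cut counts in a window (default ±100 bp)
around motif hits, strand-flipped so motifs align. The depletion score is
1 − mean(core)/mean(flanks): 1 for a fully protected core, 0 for a flat
profile, negative for core enrichment; it is undefined (raises) when the
flanks carry no signal. The bound/unbound classifier is a two-component
mixture over per-site cut vectors: each component couples a positional
multinomial profile with a negative-binomial law on the site's total
cuts. The NB dispersion is estimated once by method of moments from all
totals and held fixed during EM — with fixed dispersion the weighted mean
is the exact M-step for the NB mean, making the observed-data
log-likelihood provably non-decreasing (asserted to 1e-8 in tests). The
profile M-step uses a 1e-9 pseudo-count (a vague Dirichlet MAP). The
bound component is identified post hoc as the one with the smaller core
share. This is a deliberate simplification of CENTIPEDE's hierarchical
model: no conservation or expression priors, no strand-specific profile.

## Expression integration

Barcode QC keeps cells with 500–8,000 detected genes and ≤ 10%
mitochondrial UMIs; the removal conditions are strict (<500, >8,000,
>10%), so boundary cells at exactly 500 genes or exactly 10.0% pass.
Markers per cluster require detection in ≥ 25% of in-cluster cells, a
two-sided Wilcoxon rank-sum p < 0.01 (normal approximation with tie and
continuity corrections; within ~0.01 of the exact permutation null at
group sizes 7–8) and a higher in-cluster mean. Raw p-values are used for
selection to match the printed 0.01 rule; a BH column is available for
audit.

GSEA is the classical weighted Kolmogorov–Smirnov running sum (hits
weighted by |score|^1, misses by a uniform decrement). The null permutes
gene-set membership, not phenotypes, because the ranking is a single bulk
contrast with no exchangeable samples. NES = ES / mean(|ES*|) over
same-sign permutation scores (10,000 by default); FDR is the fraction of
same-sign null |NES*| at least as extreme, floored at 1/n_perm. Positive
NES means enrichment at the top of the ranking; note that a single random
gene set's |NES| is itself a random variate with mean ≈ 1.05–1.1, so null
behaviour should be judged over several draws.

The accessibility-by-gene-set comparison partitions differential elements
by whether any associated gene belongs to set A or set B (elements
linked to both are excluded and counted), then applies the two-sample
two-sided KS test with the asymptotic p-value.

## Synthetic data: what it emulates and what it does not

The generators produce every input with planted, recorded truth: element
dynamics classes (opening/closing/flat, exponential in the time index —
monotone by construction, matching the "gradually open/closed" picture),
negative-binomial replicate noise (α = 0.1 by default), H3K27Ac peaks in
controlled relations (overlapping, flanking with an exact gap, distal
> 10 kb, absent), motif consensus insertions concentrated in opening
elements (planting rate 0.15, ×5 in opening elements), per-base Poisson
Tn5 cuts with protected motif cores (protection 0.5 by default; the
footprint-mixture study uses deeper coverage, 3 cuts/bp, so the two
planted classes are well separated at the site level), exactly realized
per-barcode QC metrics (rational-arithmetic construction of mitochondrial
UMI fractions), and ranked gene lists with a planted shifted set
(shift 1.5 SD, set size 50 of 2,000).

Default study conditions: 600 elements (25/25/50% opening/closing/flat)
at base mean 100 with 3 replicates for the two-stage comparison; 2,000
elements (50/50 opening/closing) across five timepoints with 2 replicates
for the time course — replicate counts follow the motivating design. The
planted effect size (log₂FC = 2 across the course) and sequencing-depth
analogues are free parameters chosen to be realistic for deeply sequenced
libraries, not calibrated to any particular dataset, which publishes no
per-peak counts.

Deliberately **not** emulated: read-level sequence data, alignment and
duplication artifacts, GC and mappability bias, batch effects,
fragment-size periodicity, doublets and ambient RNA in the cell matrix,
and correlated noise between timepoints. Passing truth-recovery tests
therefore demonstrates the correctness of the statistics and decision
rules, not robustness to the technical artifacts of real libraries.

## Peak calling on synthetic coverage

`call_peaks` is a minimal Poisson scan, not a MACS2 replication: the
background rate λ is genome-wide (the synthetic background is homogeneous
by construction), fixed windows (default 200 bp, step = window/2) are
significant when the Poisson upper tail at λ·window falls below the
cutoff (default 1e-5), and significant windows within 100 bp merge.
Consensus peaks flatten each input set and keep maximal spans covered by
at least `min_sets` sets (default 1, a pure union, since the motivating
analysis describes only "merged consensus peaks").

## Determinism and numerical edges

All randomness flows from one root seed through named child streams, so
stages can be regenerated independently; identical seeds give
byte-identical outputs, including FASTA files. Degenerate inputs are
handled explicitly: empty truth lists, zero-count columns, constant
trajectory rows, all-identical footprint sites (flagged degenerate,
posterior 0.5), zero flank signal (depletion undefined), and k-means with
k exceeding the row count all raise or flag rather than return silent
nonsense. BH q-values are clipped to 1 and order-preserving; binomial
p-values are floored at 1e-300 to keep −log₁₀ finite.
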