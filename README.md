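# chromdyn

Chromatin-accessibility dynamics during cell differentiation, as a tested,
reusable analysis pipeline. The motivating system is odontoblast (dentin-
forming cell) terminal differentiation: mouse dental papilla cells induced
to mineralize open and close regulatory chromatin in a stage-dependent way,
and the transcription-factor families occupying those regions (zinc finger,
RUNX, forkhead, TEA, MADS early; bZIP, e.g. ATF5, late) can be read out
from ATAC-seq, H3K27Ac CUT&Tag and RNA-seq. `chromdyn` implements that
entire readout for anyone analysing similar time-course open-chromatin
experiments:

* **Stage-enriched NFR calling** — nucleosome-free regions tested between
  stages with a negative-binomial Wald test on median-of-ratios-normalized
  counts (var = μ + αμ², per-peak method-of-moments dispersion shrunk
  toward a bias-corrected global moment estimate), Benjamini–Hochberg FDR,
  and the strict decision rule |log₂FC| > 0.5, FDR < 0.01.
* **Active-enhancer annotation** — a stage-enriched NFR is an active
  enhancer when it overlaps a same-stage H3K27Ac peak or an
  "H3K27Ac-flanked" region: the span between two adjacent H3K27Ac peaks
  whose gap is strictly < 1,500 bp.
* **Trajectory clustering** — per-NFR z-scored accessibility across five
  timepoints, k-means (k = 4), and per-cluster trend calls
  (opening / closing / non-monotone by Spearman ρ against the time index).
* **Motif analysis** — PWM log-odds scanning on both strands, Homer-style
  binomial enrichment of hit-bearing peaks over the total background
  peaks, TF-family heatmaps (best motif per family, hierarchically
  ordered), Tn5 footprint profiles with a depletion score
  1 − mean(core)/mean(flanks), and a two-component bound/unbound mixture
  (positional multinomial × negative-binomial totals, fitted by EM).
* **Expression integration** — scRNA barcode QC (500–8,000 detected genes,
  ≤ 10% mitochondrial UMIs; removal conditions strict), Wilcoxon
  rank-sum cluster markers (≥ 25% detection, p < 0.01), weighted-KS GSEA
  with a gene-set permutation null, and a two-sample KS comparison of
  accessibility scores grouped by associated gene set.
* **GREAT-style region→gene association** — basal-plus-extension
  regulatory domains (5 kb up / 1 kb down, ≤ 1 Mb extension).
* **Synthetic data with planted truth** — every input the pipeline
  consumes can be generated with known ground truth (dynamics classes,
  H3K27Ac relations, planted motifs, footprint protection, per-barcode QC
  metrics, enriched gene sets), so every stage is validated by truth
  recovery rather than against deposited sequencing data.

## Worked example

```python
from chromdyn import synthetic_data as sd
from chromdyn.differential_accessibility import nb_wald_test, classify_enriched
from chromdyn.enhancer_annotation import call_active_enhancers
from chromdyn.intervals_io import PeakSet

layout = sd.GenomeLayout(["chr1"], [16_000_000])
nfrs, truth = sd.plant_peaks(layout, 600, seed=1, min_gap=25_000)
cm = sd.simulate_counts(truth, ["D0", "D9"], replicates=3, seed=2)
res = classify_enriched(nb_wald_test(cm, ("D0", "D9")))
print(res["label"].value_counts().to_dict())

k27, truth = sd.plant_k27_peaks(layout, nfrs, truth, seed=3)
aes = call_active_enhancers(PeakSet(list(nfrs), label="D9"),
                            PeakSet(list(k27), label="D9"))
print(len(aes), "active enhancers")
```

prints

```
{'ns': 308, 'group2_enriched': 147, 'group1_enriched': 145}
300 active enhancers
```

Of the 600 planted elements, 150 were closing (145 recovered as
D0-enriched) and 150 opening (147 as D9-enriched); 300 carried an H3K27Ac
overlap or flanking relation and all 300 are recovered as active
enhancers.

The same pipeline runs end-to-end from the shell:

```bash
chromdyn simulate --outdir run1 --seed 7
chromdyn diff counts.tsv --meta meta.tsv --groups D0,D9 --out diff.tsv
chromdyn enhancers nfr.bed k27.bed --stage D0 --out ae.bed
chromdyn trajectory counts.tsv --meta meta.tsv --stages D0,D3,D5,D7,D9 --out clusters.tsv
```

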