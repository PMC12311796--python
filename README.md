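# g4se

Analysis toolkit for studying **G-quadruplex (G4) DNA at superenhancers
(SEs)** and its consequences for BRD4 binding, phase separation and gene
regulation. Four-stranded G4 structures are enriched in regulatory DNA; this
package provides the statistical and biophysical machinery to ask whether
folded G4s concentrate inside SEs, how G4-rich SEs differ from G4-free ones,
how strongly BRD4 binds a G4, how G4 DNA changes condensate formation in
BRD4 solutions, and whether G4-targeting ligands preferentially downregulate
genes wired to G4-rich SEs.

It is written for computational biologists who have peak/interval files
(BED), sequences (FASTA), binding or recovery traces (TSV), fluorescence
micrographs (TIFF/PNG) and qPCR Cq tables — or who want to exercise the
entire pipeline on synthetic data with planted ground truth, which the
`simulate` module generates end to end.

## What it computes

**Permutation enrichment.** For a query peak set Q and region set R, the
observed statistic is the fraction of query intervals overlapping R by ≥ 1 bp.
Each of *n* replicates redraws a length-matched control set placed uniformly
over the genome, and significance is the empirical p-value

&nbsp;&nbsp;&nbsp;&nbsp;*P* = (*r* + 1)/(*n* + 1),

where *r* counts control replicates with overlap at least the observed one.
Fold enrichment is observed / mean control.

**SE classification.** SEs are *active* (in the target cell's catalog, with
enhancer-RNA/CAGE evidence), *poised* (in the catalog, no CAGE), or
*repressed* (in other cells' catalogs only, no CAGE). Over the active+poised
population, SEs with zero folded-G4 (BG4) peaks are *G4-free* and the top
quartile by BG4 peak frequency (peaks per kb) is *G4-rich*; group coverage
differences are tested by two-sided Mann–Whitney U, and peak colocalization
is profiled as signed center offsets around BRD4 anchors.

**G4 propensity scoring.** Per-base scores +min(run, 4) for G runs,
−min(run, 4) for C runs, 0 otherwise; sliding-window means (window 25 nt);
regions with |score| ≥ 1.2 become G4 candidates (trimmed to their G/C core).

**Binding models** (sklearn-style estimators with `fit`/`predict`):

- two-site equilibrium: K_d = [G4]ᶠʳᵉᵉ[BD]ᶠʳᵉᵉ/[BD·G4] with two
  bromodomain sites per protein, fit from free-fraction titrations;
- Hill dose-response: EC50 and coefficient *h*;
- 1:1 SPR kinetics: global k_a, k_d, R_max with K_D = k_d/k_a;
- mono-exponential recovery after photobleaching:
  I(t) = plateau·(1 − e^(−kt)).

**Droplet quantification.** Otsu segmentation of condensate micrographs;
projection area, circularity 4πA/P², and a sphere-model volume fraction
Σ(4/3)πr³/(imaged area × chamber height) with r = √(A/π).

**Expression analysis.** ΔΔCq with reference-gene averaging
(log₂FC = −ΔΔCq), Welch tests on biological replicates, an up/down call at
|log₂FC| > 2 and p < 0.05, and Spearman correlation (exact permutation p for
n ≤ 10) between fold changes and promoter/SE genomic features.

## Worked example

Generate a synthetic bundle (4 × 50 Mb genome, 200 SEs, 2000 BG4 peaks
planted at 3× density inside SEs) and test G4 enrichment in SEs:

```bash
g4se simulate --seed 1 --out demo/
g4se enrich --query demo/BG4.bed --regions demo/SE_K562.bed \
    --layout demo/genome.chrom.sizes --n 20 --seed 1
```

```json
{
  "observed_fraction": 0.0675,
  "mean_control_fraction": 0.019775,
  "fold_enrichment": 3.413400758533502,
  "r": 0,
  "n": 20,
  "p_empirical": 0.047619047619047616
}
```

6.75% of BG4 peaks fall in SEs versus 1.98% for random controls — a 3.4-fold
enrichment; no control replicate reached the observation, so p = 1/21 ≈
0.048, the smallest value 20 replicates can certify. Fit the dissociation
constant from the simulated NMR-style titration (truth K_d = 6 μM):

```bash
g4se fitbind --model two_site --traces demo/trace_two_site.tsv
```

```json
{"params": {"K_d": 5.953606408443147},
 "rss": 0.0134, "ci": {"K_d": [5.67, 6.34]}, "flags": []}
```

And check the planted colocalization geometry around BRD4 anchors —
nucleosome-free DHS sites sit within 100 bp while H3K27ac clusters in the
200–500 bp flanks:

```bash
g4se profile --anchors demo/BRD4.bed --mark DHS demo/DHS.bed \
    --mark H3K27ac demo/H3K27ac.bed --layout demo/genome.chrom.sizes
# frac_within_100bp: {"DHS": 1.0, "H3K27ac": 0.017}
```

The other subcommands (`classify`, `g4score`, `droplets`, `expression`)
follow the same pattern; see `g4se <cmd> --help`.

## Layout

```
src/g4se/
  genome.py          genome layout, intervals, BED/FASTA/chrom.sizes I/O
  intervals.py       merge/intersect/coverage, relative-distance statistics
  enrichment.py      permutation tests with empirical p-values
  superenhancers.py  activity & G4-richness classification, colocalization
  g4hunter.py        G4 propensity scoring and candidate extraction
  binding.py         equilibrium/kinetic/recovery models and fitters
  droplets.py        condensate segmentation and quantification
  expression.py      ΔΔCq, regulation calls, feature correlation
  simulate.py        synthetic data with planted ground truth
  cli.py             `g4se` command-line interface
docs/methods.md      modelling assumptions, defaults, numerical choices
```
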