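# Methods

This note records the models behind each module, the defaults and why they
were chosen, the numerical decisions that affect results, and what the
synthetic-data generator does and does not emulate. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate system and interval algebra

All coordinates are 0-based half-open (BED convention); any 1-based input
dialect must be converted at the boundary. Strand is parsed and carried but
ignored by every overlap computation — the peak-level analyses here are
strand-agnostic. Chromosomes present in files but absent from the declared
genome layout are dropped with a logged count, tolerating scaffold
contamination; a hard-error mode is available.

The overlap predicate everywhere is "shares ≥ 1 base" (the BEDTools
intersect default), so bookended intervals [10,20) and [20,30) do not
overlap. Internally interval sets are mapped to a concatenated (global)
coordinate space so overlap masks and counts reduce to vectorised
`searchsorted` queries; intervals never cross chromosome boundaries, so the
mapping is exact. The test suite checks every set operation against a
per-base occupancy bitmap on small genomes.

Relative distances use interval **midpoints** (floor of (start+end)/2): for
a query midpoint between two consecutive reference midpoints separated by
gap g, the value is d/g ∈ [0, 0.5] with d the distance to the nearer one.
Midpoints were chosen because the usual genome-distribution tools bin by
feature centers; nearest-edge distances are a defensible alternative but
change the null only by O(feature width / gap). Queries outside the
reference midpoint span on their chromosome are counted separately rather
than clamped, and duplicate reference midpoints are collapsed first.
Independent query placement yields values uniform on [0, 0.5]; attraction to
the reference piles mass near 0.

## Permutation enrichment

The statistic is the fraction of query intervals overlapping the region set,
not base-pair coverage: with peaks much shorter than SEs the two agree in
rank but the fraction matches how peak/SE intersections are usually counted.
Controls preserve the query's length multiset exactly; each control interval
is placed uniformly over the genome (chromosome drawn with probability
proportional to its placeable start positions, start uniform), and controls
may overlap one another. No blacklist is applied by default; a hook exists.

The empirical p-value is (r+1)/(n+1). The tie rule is conservative: a
control replicate exactly equal to the observation increments r. A strict
"greater-than" rule is available (`tie="gt"`); with a continuous statistic
the two coincide, and with a coarse one the conservative rule protects the
type-I error at the cost of power. Default n = 20 replicates — the smallest
n that can certify p < 0.05 — with larger n used for calibration checks.

Calibration note: when the query set is small the overlap fraction is
coarse, ties become common, and the conservative rule deflates the null
rejection rate below (1/(n+1)) per α = 0.05. The calibration checks
therefore run at the generator's default 2000 query peaks, where the
statistic is nearly continuous; the measured 400-run null rejection rate is
asserted against the 99% binomial interval around 1/21.

## Synthetic data

All generators are pure functions of (parameters, seed). One global seed
expands into per-component child streams via
`SeedSequence(seed, spawn_key=(k,))` with fixed component keys, so adding or
rerunning one generator never shifts another's draws.

Genomic defaults model the analysis geometry rather than any particular
genome build: 4 chromosomes × 50 Mb; 200 target-cell SEs of 10–30 kb
(≈ 2% of the genome — small enough that a planted density ratio translates
into a nearly equal overlap fold enrichment); 2000 peaks of 150–400 bp per
mark; half of the target SEs CAGE-positive; 30% of the other cell line's SEs
shared with the target. SE and peak length distributions are uniform within
the stated ranges — real catalogs are heavier-tailed, but none of the
statistics here depend on the tail shape. Peak enrichment is planted through
the **midpoint density**: a peak's midpoint lands inside SE bases with
probability ρA/(ρA + (G−A)), making the expected overlap fold enrichment
analytically computable as ≈ ρ/(1 + (ρ−1)·A/G) up to edge terms of order
(peak length)/(SE length); at the defaults this is ≈ 2.9 for ρ = 3.
BRD4 anchors are placed inside SEs, DHS (and anchored G4) peaks at signed
offsets uniform within 100 bp of anchor centers, and H3K27ac at 200–500 bp —
the colocalization geometry of active SEs, where BRD4 sits on
nucleosome-free G4/DHS sites with acetylated nucleosomes in the flanks.

The generator does **not** emulate: chromatin-state-dependent peak widths or
scores, GC or mappability bias in control placement, overlapping SEs across
cell lines beyond the shared subset, or read-level noise. Passing tests
therefore demonstrate correctness of the machinery under the stated
placement model, not robustness to genome-composition confounders — a
GC-matched null, for instance, is explicitly out of scope.

Binding traces are exact forward-model evaluations plus i.i.d. Gaussian
noise (default sd 0.02 on normalized signals). Droplet images are 16-bit
grayscale with disk foregrounds (pixel-center rasterization) on a flat
background plus Gaussian noise; the truth records both analytic πr² and
rasterized pixel areas. Cq tables follow the ΔΔCq model exactly — one
planted log₂FC unit is one cycle — with technical-replicate noise and a
per-(condition, biological replicate) plate offset that the ΔCq step must
cancel.

## SE classification

Activity follows the catalog-membership × CAGE truth table; an SE present in
the target cell *and* elsewhere is classified by the target-cell rule (the
repressed label applies only to SEs absent from the target catalog), and
other-cell-only SEs with CAGE evidence are excluded as not applicable.
Records for other-cell-only SEs are built from the merged non-target
catalogs to avoid double counting.

"BG4 peak frequency" is overlapping-peak count per kb of SE length; per-kb
normalization prevents long SEs from being called G4-rich on length alone.
Ranking by absolute count is available (`by="count"`), since coverage-based
and frequency-based orderings are both defensible. The G4-rich threshold is
the ⌈N/4⌉-th largest value with ties included, so distinct values give
exactly ⌈N/4⌉ rich SEs and a fully tied population is entirely rich; zero-
peak SEs are G4-free regardless of the quartile. Peak "center" is
floor((start+end)/2).

Mann–Whitney U uses the exact distribution when both groups have ≤ 20
records and the pooled values are tie-free, and the tie-corrected normal
approximation otherwise (coverage fractions in realistic data are heavily
tied). The colocalization profile assigns each mark peak to its **nearest**
anchor center within the window, so a peak between two anchors is counted
once.

## G4 scoring

Per-base scores are the standard run rules: each G in a run of length L
scores +min(L, 4), each C −min(L, 4), everything else 0. The window length
defaults to 25 nt and the candidate threshold to 1.2 — the conventional
defaults of this scoring scheme; both are configurable. Window means are
computed by cumulative sums (exact, O(n)).

Candidate extraction merges qualifying windows of the same orientation whose
spans overlap, then **trims the merged span to its G-run core** (C-run core
for the negative orientation) before computing the reported score as the
mean base score over the trimmed span. Without trimming, the merged span
carries up to window−1 zero-scoring flank bases on each side and the
reported score of a short planted motif would fall below the detection
threshold even though every window over it scores well above — trimming
makes the reported region and score describe the G4 core itself. The score
is not re-thresholded after merging. Only G-rich (positive) candidates are
exported by the motif pipeline's default; C-rich candidates are retained
with negative scores. This module contains no randomness.

## Binding models

Concentrations are μM throughout; SPR time is seconds, recovery time
minutes. Unit conversion belongs at the I/O boundary.

*Two-site equilibrium.* A protein with two equivalent, independent binding
sites gives total site concentration S_T = 2B_T, and mass action yields the
bound-complex concentration as the admissible root of
C² − (G_T + S_T + K_d)C + G_T·S_T = 0; the observable is the receptor free
fraction (G_T − C)/G_T. Independence/equivalence is the minimal
two-bromodomain reading; cooperativity would need a second parameter the
single-observable titration cannot identify. Each spectral signal of a
titration point is treated as an independent observation of the same free
fraction, with no per-signal scale factor (normalization to a buffer control
is assumed complete). The fit has a single parameter K_d, optimized in
log-space with 5 geometrically spaced starts over [1e-3, 1e4] μM; a
percentile bootstrap of residuals (default 200 resamples, seeded) gives the
CI. Titrations with all free fractions ≥ 1 are flagged unidentifiable. The
default simulation regime (G_T = 12 μM folded receptor, protein to 8.4 μM,
K_d ≈ 6 μM) uses the folded-species concentration as G_T; if only total
strand is known the caller must decide which to pass.

*Hill.* F(L) = F_unbound + (F_bound − F_unbound)·Lʰ/(EC50ʰ + Lʰ), EC50 in
log-space, h bounded to (0.05, 8]; h can be pinned (h = 1 recovers
hyperbolic saturation). Flat curves are flagged unidentifiable.

*SPR 1:1 kinetics.* Association R(t) = R_eq(1 − e^(−(k_aC + k_d)t)) with
R_eq = R_maxC/(C + K_D); dissociation is a pure exponential from the
association endpoint. All concentrations share (k_a, k_d, R_max) in a global
log-space least-squares fit over a 3×3 grid of rate starts; K_D is reported
as k_d/k_a by construction. A smoothed non-monotone association phase beyond
noise is flagged (it suggests a non-1:1 mechanism). Mass-transport
limitation is out of scope.

*Recovery after photobleaching.* I(t) = plateau·(1 − e^(−kt)); the plateau
is the mobile fraction. Near-zero plateaus are flagged immobile.

Every fitter inverts its own noise-free forward model to 1e-4 relative error
(tested); the SPR closed form matches numerical ODE integration to 1e-8.

## Droplet quantification

Segmentation is Otsu thresholding (flat images short-circuit to zero
regions; a fixed threshold is available for reproducibility), 8-connected
labelling, and a minimum-area filter (default 20 px). Border-touching
regions are included but flagged — excluding them would bias the volume
fraction downward in dense fields — and touching droplets are not watershed-
split by default, since coalescence is real in these samples.

Circularity is 4πA/P² with P the boundary-walk perimeter with diagonal-step
correction. The estimator choice matters: on digital disks of r ≥ 10 px this
estimator gives circularity ≈ 0.91 (the Crofton estimator gives ≈ 0.94–0.99)
but on digital squares it gives ≈ 0.84 against the analytic π/4 ≈ 0.785,
where Crofton overshoots past 10% error; the boundary-walk estimator is the
one that keeps both shapes within their documented tolerances, and
circularity is the liquid-versus-gel readout, so the square case matters.

The volume fraction assumes spherical droplets: r = √(A/π) per region,
volume (4/3)πr³, normalized by imaged area × chamber height. Defaults:
0.65 μm/px and a 500 μm (0.5 mm) chamber. Group summaries report mean ± SD
per condition with one-way ANOVA and Dunnett comparisons against a
designated control; groups with one image are descriptive only.

## Expression analysis

Technical replicates are averaged per (gene, condition, biological
replicate). ΔCq subtracts the arithmetic mean of the reference genes' Cq
(the standard convention; equivalent to a geometric mean of expression),
which cancels per-plate offsets. log₂FC = −ΔΔCq. Gene-level p-values come
from a two-sided Welch t-test on per-biological-replicate ΔCq between
conditions: biological replicates are the correct inference unit, and with
the conventional two per condition the test is honest but low-powered —
this is surfaced rather than hidden (zero-variance degenerate cases return
0/1 explicitly). Regulation calls use strict thresholds: up iff p < 0.05 and
log₂FC > 2; down iff p < 0.05 and log₂FC < −2.

Spearman correlation ranks with average ties and computes Pearson on ranks.
For n ≤ 10 the two-tailed p is an exact permutation value over all n!
orderings (vectorised over a cached permutation-index table; n = 10 costs a
few seconds once per process), because the gene panels this analysis is
built for have about ten genes, where the t approximation is unreliable.
Above n = 10 the Student-t approximation is used. Constant features are
flagged, not computed.

## Problem sizes in the checks

The acceptance checks use: a 20 Mb, 50-SE genome (2000 peaks) for the
400-run type-I calibration; the full default geometry (200 Mb, 200 SEs) for
the 100-seed fold-enrichment recovery; 500 random instances on ≤ 10 kb
genomes for the interval-algebra oracle; 200 seeds for noisy K_d recovery;
and single 256×256 images for droplet geometry. These sizes were chosen so
Monte-Carlo errors stay well below the asserted tolerances while the whole
suite remains quick to run.
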