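# Methods

## Nonspecific binding affinity

The scanner treats every 50 bp sliding window (step 5 bp) of a DNA sequence
as a potential nonspecific target site and scores it against an ensemble of
TF binding-energy matrices.

**Energy matrices.** A motif's count/frequency matrix is converted to
per-position mismatch energies `E[j,b] = ln((f_max,j + p0)/(f_b,j + p0))`
(dimensionless, thermal units), with pseudocount `p0 = 0.01`. This is the
standard Berg–von-Hippel-style mismatch form: the consensus base is the
energy reference (exactly 0), zero counts stay finite, and the map is
invariant to rescaling counts. A site's energy is the sum of its per-position
energies; `N` scores as the per-position mean, other IUPAC ambiguity codes
are rejected so that scores stay well defined.

**Binding probability.** Two modes:

* Fermi–Dirac `P = 1/(1+exp(E−μ))`, with the chemical potential μ acting as
  the TF-concentration parameter;
* the Maxwell–Boltzmann limit `P = exp(−E)` for the concentration-independent
  / very-low-concentration case.

As printed, more negative μ *suppresses* binding probability, and the package
implements the formula exactly as stated; the observed consequence — profiles
vanish as μ → −∞, and μ ∈ {0, −10} (the defaults) carry the usable signal —
is asserted in the tests. For `E − μ ≥ 5` the Fermi–Dirac form agrees with
`exp(−(E−μ))` to better than 1% (e⁻⁵ relative error bound), which the tests
verify numerically.

**Window affinity and background.** `A = p · Σ_offsets P` with prior `p = 1`
by default. Both strands are summed per offset (TF–DNA binding is
strand-symmetric and the summation keeps A additive); a single-strand switch
exists. The background is the mean affinity over `R = 10` mononucleotide
permutations of the window — the window is too short for dinucleotide
shuffling to be stable — and `dbA = A − background` removes local composition
bias (a homopolymer window gives exactly 0). The expected nTBA of a window is
the ensemble mean of dbA over all usable motifs, assigned to the window
centre (`start + L//2`).

**Window grid.** `k = floor((N−L)/st) + 1` full windows; sequences shorter
than L yield an empty grid rather than an error. Motifs wider than L are
skipped with a warning; windows with more than L/2 ambiguous bases are
emitted as missing so assembly gaps cannot masquerade as negative dbA.

**Determinism and parallelism.** The shuffle stream for window *i* × motif
*t* is seeded from `(seed, i, t)`, so profiles are bit-identical regardless
of worker count or motif order; workers parallelise over motifs and partial
results are accumulated in motif-index order.

## Feature windows and profiles

Feature sets are uniformised before any aggregation: elements shorter than
100 bp are dropped, a 1000 bp window is centred on the element midpoint (for
TSS features, on the strand-aware 5′ base — promoter profiles are
TSS-anchored), and duplicate windows are removed; the operation is
idempotent. Profile curves subsample 200 windows, 5 draws, and report the
across-draw mean and SD of the per-offset sum (`total`) or mean. Profiles
are not strand-flipped. The affinity profile is treated as piecewise constant
between window centres (nearest centre within half a step) so that
offset-level aggregation is defined everywhere under coverage.

## Tracks

Coverage is binned at 100 bp by the interval-midpoint rule (conserves the
total count exactly). The normalisation chain is: library-size scaling to
counts per 10 million, bin-wise averaging of replicate tracks of the same
marker/cell line, `log2(x+1)`, and Z-scoring per marker per chromosome (a
genome-wide option exists). The scaling constant and chain are declared, not
asserted to match any particular external pipeline; the properties that
matter downstream — invariance to per-track positive scaling, mean 0 / SD 1
per marker — are tested. Constant or zero-total tracks are rejected (no
Z-score exists).

## Hi-C enrichment and frequencies

The contact matrix (already KR/ICE-balanced upstream; balancing is out of
scope) is Z-scored over all finite off-diagonal entries of one chromosome —
not distance-stratified, matching the single-matrix description — and pairs
with Z > 0 (strictly) are the detected interactions. Per 250 kb bin, marker
values come from the ±500 bp TSS/HOT windows inside the bin: the window-mean
signal per feature, then the across-feature **mean** for epigenomic markers
and **sum** for nTBA (the additive-affinity reading). The 12-feature table
pairs nTBA at TSS and at HOT windows for μ ∈ {0, −10} with eight epigenomic
markers; the eight markers are evaluated at TSS windows (the promoter-anchored
reading; the table does not split them by feature class).

**Rank-sum construction.** For a detected pair, enrichment is a two-sample
Mann–Whitney Z (normal approximation, tie-corrected, no continuity
correction) of the pair's values against the pooled values of 100 random
bin pairs (drawn uniformly without replacement per tested pair, excluding
it; one seeded draw shared across markers). Two sample modes exist:

* `aggregate` — sample A is the two per-bin aggregate values. With |A| = 2
  the statistic is bounded at `200/sqrt(2·200·203/12) ≈ 2.431`, *below* the
  high-enrichment threshold Z ≥ 3, so under this reading F_he is identically
  zero.
* `pooled` (pipeline default) — sample A is all individual feature-window
  values of the two bins. With ≥ 2 features per bin the bound exceeds 3 and
  the threshold is attainable.

The tension between the 2-value construction and the Z ≥ 3 threshold is a
genuine ambiguity of the procedure as described; the package implements both
modes and uses `pooled` wherever F_he is consumed downstream.

Frequencies: `Nvi` counts detected pairs touching a bin, `Nei` those with
marker Z ≥ 3 (inclusive), both divided by the chromosome's bin count
`Nt = ceil(length/250 kb)` (325 and 253 for hg19 chr17 and chr20). The
conservation law Σ Nvi = 2 × detected pairs and Nei ≤ Nvi are asserted.

## Zone clustering

Model selection uses a Kruskal-stress-like ratio
`stress(k) = sqrt(WSS(k)/TSS)` from seeded k-means fits, with a 10% elbow
rule (the selected k is the last one before the relative decrease falls
under 10%); the functional form of the originally cited stress statistic is
not publicly specified, so this ratio is the package's documented stand-in,
and k = 3 is an explicit override for the three-zone analysis.

Clustering combines two probability sources per bin: inverse-distance
probabilities to the k-means centroids (`1/(ε+d)`, ε = 10⁻¹², normalised)
and Gaussian-mixture posteriors fitted on the same F_he rows (components
matched to centroids by Hungarian assignment on centroid–mean distances;
whether the mixture should instead be fitted on the k-means score vectors is
ambiguous in the source description — fitting on the F_he rows is adopted).
The final probability is `w·p_dist + (1−w)·p_mix` with `w = 0.5` (the
weighted-sum combination is otherwise unspecified; w is configurable), label
= argmax, ties to the lower index. Singular covariances are regularised by
diagonal inflation with a warning. With k = 3, clusters ranked by mean F_i
(ascending, ties broken by mean F_he) become types I/II/III = Inactive /
Poised / Active Genomic Zones, and the I ≤ II ≤ III mean-F_i ordering is
asserted on every run.

## Synthetic fixtures

The generators define the conditions under which the pipeline is exercised:

* **Sequence fixture** — 5 kb i.i.d. background at GC 0.41 with 12 exact
  consensus instances of 5 width-8 motifs (Dirichlet columns, dominant-base
  concentration 50) planted within ±100 bp of the midpoint, random strand,
  non-overlapping. Ground truth: the profile peak should fall near the
  cluster centre.
* **Zone fixture** — 60 bins of 250 kb (20 per regime, randomly interleaved),
  5 TSS + 5 HOT windows per bin at fixed offsets. Contact value of a pair =
  sum of regime strengths (0, 1.5, 2.0) + N(0, 0.5) noise, so detected-pair
  frequency is low/medium/high per regime and, in the noise-free case,
  medium–medium pairs are still detected (the strengths satisfy
  2·s_mid > s_low + s_high). Epigenomic tracks: baseline 20 counts per 100 bp
  bin, N(0, 4) noise, +60 counts inside feature windows of high-regime bins
  for active marks (DNase, Pol2, H3K4me3, H3K4me1, H3K27ac, CTCF) and of
  medium-regime bins for repressive marks (H3K27me3, H3K9me3, with a mild
  +10 in the high regime); nTBA surrogates are N(0, 0.2) signals elevated by
  1.0 (μ=0) / 0.5 (μ=−10) in high-regime feature windows. These effect sizes
  put elevated window means far (≫5σ of the window-mean noise) above
  background, so each regime has a distinct F_he signature: repressive marks
  separate the medium regime, everything else the high regime.

What the fixtures do **not** emulate: Hi-C distance decay, nucleosome-scale
sequence structure, realistic motif co-occurrence, replicate variability, or
mapping artefacts. Passing tests therefore demonstrate correctness of the
computational chain and recoverability of planted structure — not performance
on real chromatin.

## Problem sizes and numerical choices

The test suite and the acceptance script run the scanner on 1–5 kb sequences
with 3–5 motifs (oracle comparisons at tolerance 10⁻¹⁰ use the same shuffle
stream as the implementation but recompute all affinities by explicit
loops), and the zone pipeline on the 60-bin fixture across 10 seeds — sizes
chosen so the planted effects are statistically unambiguous while a full run
stays in the minutes range on one CPU. Exponentials are clamped at ±700 to
avoid overflow; zero-variance guards use a 10⁻¹² relative tolerance since a
numerically constant array can retain O(10⁻¹⁵) round-off variance.

## Known limitations

* The energy model ignores inter-position dependence within binding sites.
* Z-scoring contacts without distance stratification conflates genomic
  distance with interaction strength; a distance-stratified
  expected/observed mode would be the natural extension.
* With few features per bin the pooled rank-sum remains coarse; Z ≥ 3 is
  near the attainable bound for 2 features per bin.
* Zone labels are per chromosome; cross-chromosome harmonisation beyond the
  core-bin intersection is not attempted.
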