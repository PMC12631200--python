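# Methods

This note documents the models, conventions and numerical choices behind
`defoliascan`, and what its synthetic-data experiments do and do not
demonstrate.

## Damage staging

Trees are staged by defoliation percentage (DP), the mean fraction of
damaged needles over standard branches: mild (DP ≤ 30 %), moderate
(30 % < DP < 50 %), severe (DP ≥ 50 %). The thresholds reflect growth
response — up to ~30 % needle loss conifers show no measurable growth
depression, while past ~50 % height and radial growth decline — so the
mild class is the actionable "early detection" target. Stage is a pure
threshold function of DP (`damage.stage_from_dp`), and every data
container validates stage/DP consistency.

## ISIC and the D-threshold filter

For band *i* and classes *z = 1..m* with per-class means m_{z,i} and
sample standard deviations S_{z,i} (ddof = 1), the instability index
between classes is the mean over the m(m−1)/2 unordered class pairs of

    (S_{z,i} + S_{j,i}) / |m_{z,i} − m_{j,i}|.

The leading pair-combination constant is a convention: any fixed
positive constant rescales all ISIC values (and hence the D series)
uniformly without changing the band ranking, and the removal threshold
is tuned downstream, so the choice is behavior-neutral. The pair mean is
used here because it keeps ISIC comparable across different class
counts.

Degenerate pairs: when two class means coincide (to a scale-relative
tolerance of 1e-12), the band cannot separate that pair and its ISIC is
+inf — no epsilon regularization. Infinities propagate to both adjacent
entries of the jump series D_i = |ISIC_i − ISIC_{i+1}|, so such bands
are removed by any finite threshold.

Removal semantics: D_i is attributed to band *i*; the last band is
judged by its left difference. Bands with D_i > T are removed. The
filter is monotone in T (retained sets nest), and ISIC itself is
invariant to positive rescaling of the reflectance matrix.

Threshold search: a coarse grid of 8 points spans [0, max finite D];
two refinement rounds each shrink the step ×10 around the incumbent
(11 points per round). The objective is mean stratified 10-fold CV
accuracy of the configured random forest on the retained bands; among
thresholds within an accuracy tolerance (default 0.005) of the best,
the one retaining fewest bands wins, then the smallest threshold.

## SPA

The successive projections algorithm operates on the column-centered
spectra matrix. Starting from a chosen band, each step appends the band
whose column has the largest Euclidean residual norm after orthogonal
projection onto the span of the selected columns (rank-1 residual
update; ties break to the lowest index; the chain truncates when all
residual norms fall below 1e-10 relative to the largest initial column
norm, so selected columns stay linearly independent). Chains are
launched from every band by default, or from an evenly spaced subsample
(`n_starts`) for speed. For each subset size k the best chain prefix by
CV accuracy defines the accuracy curve; the chosen size is the smallest
k within the accuracy tolerance of the curve maximum — accuracy first,
then parsimony. ISIC-SPA is SPA restricted to the ISIC-retained bands;
its result records both stages.

## Vegetation indices

Four families over selected-band reflectances R: NDSI (normalized
difference), DSI (difference), RSI (ratio), RA (one band over the sum of
two others). RSI and RA are read as ratios — RSI is canonically a ratio
index, and a product form would duplicate DSI's information. The search
enumerates ordered distinct pairs (triples for RA) and scores each
candidate by |Spearman ρ| against ordinal stage codes 1 < 2 < 3
(mid-rank Pearson correlation); ordered enumeration is harmless since
|ρ| absorbs sign flips. Ties break lexicographically on the wavelength
tuple. Candidates undefined on the data (zero denominator, zero rank
variance) are skipped rather than scored.

## LiDAR metrics

All metrics use returns above a 0.5 m height threshold; a tree needs at
least 10 such returns or it is flagged and dropped with a warning. The
fixed 10-metric record is: elevation percentiles 10/20/25/30 (linear
interpolation between order statistics, the most common convention,
fixed here for reproducibility), the 5th AIH percentile, and intensity
mean, sample sd, skewness, excess kurtosis (Gaussian → 0) and median.

AIH ("accumulated interval height") percentile p is defined as the
smallest height, in ascending order, at which the running sum of heights
reaches p % of the total height sum. Unlike an ordinary percentile it is
*not* translation-equivariant — it weights points by their height — and
its low percentiles are sensitive to exactly the lower-crown thinning
that early defoliation produces: removing low points pushes AIH_5
upward.

## Screening

Kruskal–Wallis with the standard tie correction and the chi-square
approximation (df = groups − 1); identical values across all groups
return (H = 0, p = 1). A feature is retained only if the overall
three-stage test *and* the mild-vs-moderate pairwise test are both
significant at raw α = 0.01. The pairwise criterion is the
early-detection filter: upper-crown elevation percentiles, for example,
only react once defoliation reaches high into the crown, pass the
overall test on severe trees alone, and are correctly dropped. No
multiple-testing correction is applied (a deliberate caveat: with 14
candidates at α = 0.01 the family-wise error is still modest).

## Splitting, classification and importance

The 6:4 stratified split allocates round(0.6 × class size) per class to
training (half-up rounding): 103/99/82 trees yield 62/59/49 training and
41/40/33 test samples — 170 and 114 in total. The classifier is a
500-tree random forest with sqrt-feature subsampling and a fixed seed
(42 by default); selection-time cross-validation uses a smaller forest
(100 trees by default) since the CV curve plateaus well below the final
model size. Confusion-matrix metrics: OA = trace/total; producer's
accuracy PA_i = N_ii / rowsum_i (recall); user's accuracy
UA_j = N_jj / colsum_j (precision); Kappa = (p_o − p_e)/(1 − p_e) with
p_e from row/column marginals. Percentages are rounded to two decimals
only at presentation.

Feature importance is mean decrease in accuracy by permutation on a
held-out set (scikit-learn's `permutation_importance`): the classical
OOB formulation needs per-tree out-of-bag predictions, which the library
forest does not expose; the held-out variant estimates the same quantity
with an explicit evaluation set, reported with its dispersion over
repeats.

## Synthetic-data generator

The generator emulates the study conditions the analysis assumes:
284 trees (103/99/82 per stage), 145 bands. DP is drawn uniformly within
each stage's interval — [5, 30], (30, 50), [50, 90] — which covers each
interval without boundary pileup and, importantly, makes adjacent stages
genuinely confusable near their shared boundary (the moderate stage is
hardest, as in real campaigns).

*Wavelength grid*: 145 evenly spaced points on [400, 1000] nm
(spacing ≈ 4.17 nm). A 4 nm resolution and a 145-band count are mutually
inconsistent over that range; the band count wins because downstream
indexing depends on it. Named wavelengths (686, 759, 926 nm) resolve to
the nearest grid band.

*Spectra*: a fixed healthy-conifer template (green peak, chlorophyll
trough at ~675 nm, red-edge ramp, NIR plateau, weak 975 nm water dip)
plus two DP effects — a positive red-edge bump (Gaussian at 718 nm,
σ = 34 nm) and a negative NIR ramp (sigmoid at 840 nm) — both linear in
DP, plus a band-correlated noise component (squared-exponential
correlation, 50 nm length-scale, via a Cholesky factor) and white noise.
The correlated component matters: it gives adjacent bands the strong
correlation that SPA and the ISIC D-series exploit on real spectra.
Defaults (gain 9e-4 and loss 1.1e-3 reflectance per % DP; smooth sd
0.012; white sd 0.003) were chosen so that noise-free monotonicity holds
bandwise in the contracted windows and classification on the synthetic
data is non-trivial — single-source test accuracies land broadly in the
70–90 % range rather than saturating. No field calibration of these
effect sizes exists; they are design choices, not estimates. Reflectance
is floored at 1e-4 (a physical surface never reflects exactly zero, and
ratio indices need positive denominators).

*Crowns*: a paraboloid crown (depth 6 m, base radius 1.5 m, base height
1 m, each with tree-to-tree Gaussian variation) is sampled at
120 returns/m² of projected area, plus 3 % understory returns below
0.5 m. A DP-proportional fraction of crown points is then removed with
probability ∝ ((z_max − z)/range)^β, β = 2 by default — feeding starts
in the lower crown — with exact removal counts (round(DP % × n)).
Intensity is Gaussian on an 8-bit-like scale (mean 160, sd 18) declining
by 0.9 units per % DP, mixed with a low-intensity exposed-wood
component whose weight grows with DP (heterogeneity → kurtosis signal),
plus a per-tree random offset (sd 9) standing in for calibration,
incidence-angle and moisture variation. The per-tree offset and the
crown-size variation are what keep per-tree metric averages (over
hundreds of returns) from becoming noiseless DP readouts.

With uniform removal (β = 0) the retained height distribution is
unchanged in expectation, so AIH_5 shows no systematic trend in DP; the
lower-crown bias is the mechanism that moves it. The property tests
assert exactly this contrast.

*What the generator does not emulate*: radiative transfer (no
PROSPECT/SAIL), atmospheric or illumination geometry, crown overlap and
occlusion between neighbors, terrain, multi-modal DP within a crown, or
spatial autocorrelation between trees. Passing tests on synthetic data
therefore demonstrate the correctness and internal consistency of the
algorithms and the qualitative fusion behavior — not field-level
accuracy of the method.

## Problem sizes in tests and the acceptance script

Unit and property tests run selectors on reduced problems (15–40 bands,
30–90 trees, 30–60-tree forests inside CV) chosen so each experiment
still has clear signal-to-noise; the full-scale synthetic pipeline in
`scripts/acceptance.py` uses the complete 284 × 145 dataset with
ISIC-SPA selection (12 SPA starts, k ≤ 8, 60-tree selection forests) and
500-tree final models. Recovery experiments ("planted" signal at known
bands) use offset patterns in which no single band separates all three
stages, so a selector must find at least two of the planted bands to
succeed.

## Known limitations

- The ISIC pair-combination constant in the literature is ambiguous;
  see above for why the choice cannot affect selections.
- Raw (uncorrected) p-values in screening, matching common practice in
  the application domain.
- The D-threshold objective is a CV accuracy estimated with a finite
  forest; near-tie decisions between thresholds can depend on the CV
  seed. The seed is fixed in `RunConfig` and fanned out per stage, so
  runs are bit-reproducible.
- The generator's effect sizes are unitless design parameters; absolute
  accuracies on synthetic data should not be read as predictions of
  field performance.
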