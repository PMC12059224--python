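# Methods

## The screening model

A double-orthogonal-gradient (DOG) sample is a 20 × 20 mm PDMS substrate
prepared with two sequential, mutually perpendicular shielded plasma
oxidation treatments, so that every position (u, v) carries a unique
combination of surface properties: wrinkled topography (wavelength λ in
μm — 0 on flat samples — and amplitude A in nm), Young's modulus E (MPa)
and water contact angle WCA (°). Four sample types span the design space:
S-W (stiffness × wettability, flat), T-S (topography × stiffness, fully
hydrophilic), T-W (topography × wettability) and T-S|W (topography ×
a double-linear combined stiffness|wettability axis).

Cells (MCF10a breast epithelial, MCF7 breast cancer) are seeded on the
samples and imaged after 24 h and 72 h in three channels: DAPI (nuclei),
phalloidin (F-actin / cell spread area) and Ki-67 (proliferation marker).
The screen's readouts per position are cell density (nuclei mm⁻²), cell
area (phalloidin μm² per cell), the percentage of Ki-67-positive nuclei,
and — for MCF7 — the density of multicellular clusters, defined as
contiguous phalloidin objects of at least 2000 μm² (two or more cells in
contact); smaller objects are single cells.

## Gradient calibration and grids

Each gradient axis is characterized by a measured profile (position vs
mean ± SD). Profiles are fitted with ordinary least squares polynomials
(order 1 by default, order 2 optional); evaluating a fitted trendline at a
coordinate gives the local material property, clamped to the envelope of
the measured means so that positions slightly beyond the outermost
measurement cannot extrapolate outside the characterized range. The
`T-S|W` sample evaluates both stiffness and WCA from the same axis
coordinate; the T-W sample carries its mild stiffness variation
(13.0–23.9 MPa, a side effect of the wettability treatment) as a passenger
parameter on the wettability axis. WCA calibrations come from flat
reference gradients, excluding topography-induced apparent-angle effects.

Two sampling grids cover a sample: 2 × 2 mm datapoint windows, 7 divisions
along a topography/stiffness/stiffness|wettability axis and 5 along a
wettability axis (S-W and T-W: 35 windows; T-S and T-S|W: 49), with
centers evenly spaced at (k + ½)·20/K mm; and the microscope's 12 × 17
grid of 1741 × 1298 μm tiles (2.26 mm² each) anchored at the sample
origin, with tiles crossing the sample boundary flagged partial and
analyzed over their clipped area. The coordinate origin sits at the
weak-oxidation corner (softest, most hydrophobic, smallest wrinkles);
both grids share it.

Surface characterization math: the Young's modulus follows from a conical-
indenter (Sneddon) fit F = (2/π)·tan α·E/(1−ν²)·δ² with tip half angle
α = 18° and Poisson ratio ν = 0.3, as a linear least-squares fit of force
against indentation squared through the origin (contact-point detection is
instrument-side and out of scope). Wrinkle wavelength is the dominant
spectral period refined by mean crest spacing; amplitude is (mean crest −
mean trough)/2; profiles with height SD below a 1 nm noise floor report
flat (0, 0).

## Synthetic screens and what they emulate

No raw images from the original screen are public, so the pipeline is
exercised end-to-end on simulated data with planted ground truth. The
generator's defaults are the study conditions:

* **Ki-67 positivity** is Bernoulli per cell: flat surfaces 0.73 (MCF10a)
  / 0.78 (MCF7) at 72 h, wrinkled topography 0.47 / 0.44 — the published
  flat-vs-topography group means. The topography effect is a flat-vs-
  wrinkled binary (wrinkle size showed no clear trend in the source data).
  24 h values (0.35/0.25 and 0.50/0.35) reflect the lower early
  proliferation and are generator choices.
* **Single-cell density** is Poisson per tile with expectation
  `density_base · f(WCA)`, where f is a quadratic with vertex at 35° (the
  reported proliferation/adhesion optimum of 30–40°), clipped to [0.2, 1].
  `density_base` is 100 mm⁻² at 72 h (45 at 24 h): cells seeded at
  5000 cm⁻² = 50 mm⁻² that have roughly doubled over three days. Single
  cells are placed by simple sequential inhibition with a ~34 μm (one cell
  diameter) hard core: a "single" cell is by definition not in contact
  with another, and pure Poisson placement would fuse neighboring rendered
  cells into spurious ≥2000 μm² objects at a rate comparable to the
  planted topography cluster rate. The Poisson count is kept, so per-tile
  totals remain Poisson.
* **MCF7 clusters** follow a Thomas-like process: Poisson parents at
  9.1 mm⁻² on flat and 3.6 mm⁻² on topography surfaces (the published
  cluster densities), each with 2 + Poisson(3) offspring (mean 5; a
  cluster has at least two cells) scattered isotropically with σ = 12 μm
  and a ~26 μm excluded-volume distance between clump members — piled
  cells tile together rather than superpose, so the clump footprint grows
  with cell count. MCF10a cells never cluster.
* **Cell geometry**: nucleus radii uniform in 4–6 μm; spread areas
  lognormal with median 800 μm² and shape σ = 0.30, chosen so essentially
  no single cell exceeds the 2000 μm² two-cell threshold (P ≈ 0.1%).

Rendering draws nuclei, cytoplasm and Ki-67-positive nuclei as soft-edged
disks (max composite), blurs with a 1 μm Gaussian PSF, adds a constant +
smooth-ramp background, Poisson shot noise and Gaussian read noise (2% of
the 16-bit range), and clips to uint16. Default resolution is 0.85 μm/px
(a 2048 × 1527 px tile); recovery experiments and tests run at 2 μm/px,
which keeps 8–12 μm nuclei well resolved at a fraction of the cost.
All randomness flows from one master seed through named
`SeedSequence` substreams keyed by condition and tile index, so identical
seeds give byte-identical truth tables and rasters, and subsetting a tile
grid does not change per-tile realizations.

**What the simulation does not emulate:** optical aberrations, uneven
illumination, focus drift, 3-D cluster structure (z-stacks are out of
scope), cell migration between tiles, spatial autocorrelation beyond
clustering, and staining variability. Passing recovery tests therefore
demonstrates that the quantification and statistics are faithful to the
planted model, not that they would be unbiased on arbitrary real imagery.

## Quantification

Per tile: (1) background subtraction by greyscale opening with a square
window of half-width 50 μm — a separable, fast analog of the rolling
ball; the opening reproduces smooth ramps and offsets (removed) but
vanishes on objects smaller than the window (preserved); output clamped
to ≥ 0. (2) Nuclei: Otsu threshold, hole filling, 8-connected components,
objects < 20 μm² removed, labels consecutive from 1. Otsu always splits a
histogram, even of pure noise, so the threshold is floored at
median + 5·1.4826·MAD of the subtracted channel; blank tiles yield empty
masks rather than hallucinated objects. (3) Ki-67: the proliferation
channel is background-subtracted, signal outside the nuclei mask cleared,
and a global Otsu over within-mask pixels classifies each nucleus by its
mean within-mask intensity. The noise floor for this threshold comes from
the outside-mask pixels: with mostly-positive nuclei the within-mask
median itself sits in the bright class. Zero nuclei report a missing
percentage. (4) Cytoskeleton objects: same segmentation; objects
≥ 2000 μm² are clusters (equality counts as a cluster), objects between
100 μm² (noise-speck floor, not in the source macro) and the threshold
are singles. (5) Tile readouts: densities divide by the analyzed (clipped)
area; area per cell is total thresholded phalloidin area over the nuclei
count. Touching nuclei are not watershed-split by default (the original
macro describes none); a distance-transform watershed sits behind a flag.
Thresholds are per tile; a per-batch option exists because the original
macro's batching is unknown.

## Screen analyses

Datapoint aggregation averages the tiles whose centers fall inside each
2 × 2 mm window (tiles in the gaps between windows are unused; the tile
grid aggregates identically), then averages across replicates; heatmap
cells record the replicate n, and missing windows stay missing. Decile
splits take the bottom/top ⌊0.1·N⌋ of the ranked values and compare them
with a KS test. Doubling time is (T_e−T_b)·ln 2 / ln(X_e/X_b) from the
24 h and 72 h densities; declines give negative values, equal densities a
missing value. ROI selection works on per-window observations (pooling
tiles × replicates; with only 3 replicate observations per group the
minimum attainable exact KS p is 0.1, so window-level pooling alone can
never reach significance): windows with a two-sample p < 0.05 are ranked
by |(x̄_MCF10a − x̄_MCF7)/√2|, the perpendicular distance from the identity
diagonal, and the top 3 per side become Pos1–3 / Neg1–3. KS is the default
per-window test for consistency with the screen's group statistics; a
Welch t-test is available (both are weak at small n). Flat-vs-topography
grouping pools all S-W windows against all T-S/T-W/T-S|W windows.
Screen-vs-translation comparison reports per-ROI deltas and whether each
ROI keeps its side of the diagonal, plus a grouped low-vs-high
seeding-density KS when seeding-resolved data are present.

## Statistics

* **Quadratic trends**: OLS on (1, x, x²); R² with intercept (never
  negative); fits with R² > 0.4 are flagged representative; the vertex
  −b₁/(2b₂) estimates the optimum (e.g. the WCA proliferation optimum).
* **Two-sample KS**: D is the sup-distance between empirical CDFs on the
  pooled support (tie-safe). For n₁+n₂ ≤ 12 the p-value is exact, by full
  enumeration of all C(n₁+n₂, n₁) label assignments; beyond that the plain
  Kolmogorov asymptotic at √(n₁n₂/(n₁+n₂))·D is used. Against the
  enumeration oracle the plain form is accurate to ~0.04 absolute at
  n₁=n₂=6 (small-sample "corrected" arguments are several times worse
  there, so they are not used).
* **PLS**: NIPALS PLS1 on SD-scaled predictors and response; a zero-SD
  column (a fixed material property) is divided by a 10⁻⁸ offset and
  carries no weight. Leave-one-out cross-validation gives PRESS and Q² per
  component. The default component count follows the standard Wold/SIMCA
  rule — components are added while the marginal 1 − PRESS_A/PRESS_{A−1}
  exceeds 0.0975 — because maximizing cumulative Q² generically selects
  full rank for near-linear responses (the extra components merely polish
  the sampling error of the first weight vector); `selection="max_q2"` is
  available. VIP_j = √(p·Σ_a SSY_a w²_ja / Σ_a SSY_a); the mean of VIP²
  over predictors is identically 1. Scaling is computed once on the full
  data before LOO, matching its role as preprocessing.

## Numerical choices and problem sizes

Recovery experiments run at 2 μm/px on full-geometry 1741 × 1298 μm
tiles: the Ki-67 recovery screens use 4 × 4 tiles × 3 replicates per cell
type, and the cluster-density recovery uses the 165 boundary-free tiles of
the 12 × 17 grid per surface class — sizes chosen to keep the sampling
error of the recovered means well below the comparison tolerances. The
recovered cluster density sits ~1.2 mm⁻² below the planted flat rate:
clusters of two (and some of three) cells have merged footprints below
2000 μm², boundary-straddling clusters lose cropped members, and at the
flat rate ~5% of clusters touch a neighbor and merge into one object.
These are genuine properties of the area-threshold definition (the
original screen's counts carry the same biases), and the recovery
tolerances absorb them.

## Known limitations

* Ki-67 calling assumes a bimodal within-mask intensity distribution; a
  tile whose nuclei are uniformly positive (or negative) can be
  misclassified in part. Planted probabilities of 0.4–0.8 are recovered
  within ±2 points.
* Touching nuclei merge without the optional watershed, slightly
  undercounting density at high confluency (<3% at the default densities).
* The exact KS enumeration is limited to pooled sizes ≤ 12 by cost; the
  asymptotic p beyond that is accurate to a few percent at moderate n.
* The generator's response model is deliberately simple (binary topography
  effect, single quadratic wettability response); it spans the published
  effect magnitudes but not biological covariance structure.
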