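# Methods

This note documents the models, conventions and numerical choices behind
`cabinlight`, in the spirit of a model-documentation page: what is
computed, under which assumptions, and where the open design decisions
were settled.

## Display model and color appearance transforms

Input images are treated as ideal sRGB on a D65 display.  The study
design this package serves was an online survey on uncalibrated consumer
devices, so no photometric display measurement exists; the display model
is therefore an explicit convention, not an inference.  Gamma-encoded
codes are linearized with the IEC 61966-2-1 EOTF (linear segment below
0.04045, offset 2.4-power above), converted to XYZ with the standard
sRGB matrix, and to cone responses with the Hunt–Pointer–Estevez-type
matrix of the IPT model.  The published 4-digit cone matrix is
normalized to a rounded D65; we rescale its rows so the sRGB-derived D65
white maps to exactly L = M = S = 1, which is the model's declared
normalization carried to full precision.  Neutral stimuli then map to
P = T = 0 exactly.

IPT applies the sign-preserving 0.43 power per cone channel, then the
opponent matrix.  Correlates are J = 100·I, c = 100·√(P²+T²),
h = atan2(T, P) in [0°, 360°).  The ×100 scaling puts IPT lightness and
chroma on CAM16's 0–100 range so the two spaces can be regressed
against each other dimension by dimension; nothing else depends on it.

CAM16 is implemented in its published forward form: CAT16 adaptation
with degree of adaptation D (clamped to [0, 1]), luminance adaptation
factor F_L, background ratio n with N_bb = N_cb = 0.725·n^(−0.2),
z = 1.48 + √n, the sign-preserving post-adaptation compression, opponent
a/b, eccentricity, achromatic response, and the correlates J, Q, C, M,
s, h and hue quadrature H.  The implementation reproduces the classic
worked-example conditions (gray stimulus XYZ = (19.01, 20, 21.78) under
D65 white at Y = 100, L_A = 318.31 cd/m², Y_b = 20, average surround) at
J = 41.7312, C = 0.1034, h = 217.07, Q = 195.37 — the values published
for that example.

Default viewing conditions are L_A = 20 cd/m² (20% of a nominal
100 cd/m² peak white), Y_b = 20, average surround.  These are
configuration values with no empirical claim attached; every pipeline
run logs them.  Achromatic stimuli (chroma below 1e−9) carry a flag and
report h = 0 by convention; hue statistics skip flagged regions.  The
inverse models, CAM16-UCS distances and gamut mapping are deliberately
out of scope: the analysis compares the three basic correlates
separately, never Euclidean color differences.

## Scene decomposition

Equirectangular images map longitude λ ∈ [−180°, 180°) linearly
left→right and latitude φ ∈ [−90°, 90°] top→bottom, with pixel centers
at half-integer offsets.  The rating perspective is extracted by
gnomonic projection: pinhole rays from the output grid (focal length set
by the horizontal field of view, default 86°), rotated by pitch then
yaw, converted to λ/φ and sampled bilinearly with the horizontal seam
wrapped.  Whether the original analysis decomposed the 86° view or the
full equirectangular render is ambiguous; the pipeline supports both and
defaults to the extracted view (`RunConfig.use_view`), with the
synthetic bundle writing masks in the matching geometry (an
equirectangular block mask is pushed through the same projection and a
view block is external when the projected indicator covers more than
half of it).

Blocks are square (default 32 px); dimensions must divide evenly —
partial blocks are rejected rather than padded, since padding would bias
region means.  Block means are computed on **linear** cone responses:
physical light averages linearly, and averaging gamma codes would
darken high-variance blocks.  This makes the grand mean of block means
equal the whole-image mean exactly, which the suite asserts.

Scene masks are explicit per-block boolean grids (JSON or 0/1 CSV), not
image segmentation: the external/interior boundary of a cabin render is
a modeling input, defined only pictorially in the source material.  The
packaged default mask marks a centered window band covering exactly 25%
of blocks.

## The contrast statistic and its analysis

For each dimension v ∈ {J, c, h} the scene-level statistic is
100·(|v_sc| − |v_il|)/(|v_sc| + |v_il|), computed once per scene from
region-aggregated correlates (the statistic is defined with a single
external and a single interior value; a per-block variant exists for
sensitivity analysis).  The absolute-value bars are honored literally,
including for hue, which is treated as a scalar angle in degrees; region
hue itself is the angle of the mean opponent vector (mean of c·cos h,
c·sin h), so antipodal hues cancel rather than average to a meaningless
midpoint.  The statistic is antisymmetric under swapping regions and
bounded in [−100, 100] (floating-point spill at the ends is clipped);
0/0 yields NaN with a warning, and hue contrast is NaN when either
region is achromatic.

Working areas: the "possible" area is the set of contrast triples over
all luminaire settings of a scene; the "preferred" area keeps settings
whose mean rating reaches a threshold, default 5 = "good" on the 7-point
scale (excellent = 7 … very bad = 1).  The threshold is a logged
configuration value — the source material never states its cut.  Boxes
are per-dimension ranges; 2-D hulls in (dJ, dc) are computed when at
least three non-collinear points exist.  An empty preferred set is
flagged, not an error.

Trend fits regress a contrast dimension on the ordered scene index
(externally bright → dark: sun city, countryside, forest, night) by
least squares, default degree 1, reporting the slope, its standard
error, the two-sided t-test against zero and adjusted R².  The pipeline
fits preferred points when at least three sceneries survive the
threshold, otherwise all points.  Space correlations are OLS of CAM16
correlates on IPT correlates per dimension; for hue, pairs straddling
the 0/360 wrap (|h_IPT − h_CAM16| > 180°) are excluded and counted.

## Ordinal statistics

The rating data are ordinal throughout, so all inference is rank-based.

*Wilcoxon signed-rank* (dependent samples): zero differences are
dropped (the classic rule, not Pratt's), tied absolute differences get
average ranks, and the asymptotic path computes z from the normal
approximation with tie-corrected variance and **no continuity
correction** — the convention of the major statistics packages, and the
one consistent with the headline z→p mapping (|z| = 3.497 →
p = 4.7×10⁻⁴).  With fewer than five nonzero differences the test
falls back to exact enumeration of all sign assignments (also available
explicitly via `method="exact"`).  At n = 8–12 the normal approximation
deviates from the exact conditional test by a few hundredths in p —
an inherent small-sample property the suite measures rather than hides.
Effect sizes use Cohen's r = |z|/√N over retained pairs, with inclusive
thresholds 0.10/0.25/0.40 for weak/medium/strong.

*Dissimilarities*: Bray–Curtis, Σ|uᵢ−vᵢ|/Σ(uᵢ+vᵢ), bounded in [0, 1]
and requiring no absolute zero — appropriate for difference ratings.
The construction from 28 paired comparisons is ambiguous in the source;
the default builds per-setting profiles (each setting's vector of mean
difference ratings against every other setting, own position zero, so
profiles share an aligned feature space) and applies Bray–Curtis; the
alternative uses the mean difference ratings directly as dissimilarities
(scaled by the rating maximum).  Both are exposed and the choice is
logged in the run configuration.

*Non-metric MDS*: SMACOF majorization — each iteration replaces
dissimilarities by the isotonic regression of current distances on the
dissimilarity ranks (PAVA), rescales to the standard sum-of-squares
normalization, and applies the Guttman transform.  The loop is
implemented in the package (scipy's PAVA) because the recovery analyses
require thousands of well-converged runs; the suite cross-checks it
against scikit-learn's independent SMACOF.  Fit is scored by Kruskal
stress-1, √(Σ(d−d̂)²/Σd²), recomputed from the final configuration so
the reported stress does not depend on the optimizer's internal
normalization.  Runs use 20 seeded restarts by default (best kept) and
are deterministic given the seed.  Tied dissimilarities are resolved by
the isotonic averaging convention; the dissimilarity constructions used
here are continuous, so ties are measure-zero.  Stress is non-increasing
in the embedding dimension up to optimizer tolerance only — the per-k
optimizations are independent.  Note a small-sample caveat the recovery
tests quantify: with 8 items (28 rank constraints) a 2-D non-metric
embedding fits a 3-D configuration's ranks perfectly in roughly a fifth
of random configurations, so "stress reaches zero at k" overstates
dimensionality certainty at this design size.

*PCoA scree*: classical scaling (double-centered −½D²,
eigendecomposition).  Variance fractions are positive eigenvalues over
their sum; negative eigenvalues (expected for non-Euclidean Bray–Curtis
input) are reported separately rather than clamped.

## Synthetic data generator

The generator emulates the study conditions, not the study's images.
Exterior archetypes are parametric palettes with target mean linear
luminances (sun city 0.75, countryside 0.70, forest 0.06, night 0.015 —
bright/bright/dim/dark, with night carrying sparse high-chroma light
sources), plus seeded texture.  Interior lighting is defined by CCT
(3000/4500/6000 K via locus approximations: the CIE daylight locus
above 4000 K, so 6504 K lands on D65, and the Kim et al. cubic
Planckian approximation below, valid to 1667 K), distribution (spot: a
Gaussian-falloff patch; spatial: uniform fill; mixed: both) and five
intensity levels at the stated percentages (spot 5/11/25/50/100%,
spatial 10/20/30/70/100%).  The eight luminaire settings L1–L8 (L8 = no
light) and the 124-image layout (4 sceneries × 6 settings × 5 levels +
4 baselines; one setting and the single-level baseline excluded, as in
the study design) are encoded as defaults.

Rating matrices come from a known latent configuration: item
dissimilarities are Euclidean distances in k_true dimensions scaled to
the 0–10 range; each subject's rating adds clipped, discretized Gaussian
noise (the simplest noise respecting scale bounds; SD 1.0 rating step by
default, 148 subjects matching the effect-size back-solve).  Preference
tables for trend recovery use a linear contrast model plus Gaussian
noise, with the 7-point rating derived from |dJ| (preference peaks where
interior and exterior lightness balance — the qualitative conclusion the
pipeline is designed to detect, used here as the latent rule).

What the generator does **not** emulate: photorealistic cabin geometry,
shadows and occlusion, device-dependent display distortions, subject
heterogeneity and response styles, or the absolute radiometry of the
original renders.  Passing recovery tests therefore demonstrate that the
analysis machinery recovers known structure under controlled conditions;
they do not validate the original study's empirical findings, and the
published headline numbers (preference means, the −26.5/−31.8/21.8
slopes, R²_adj = 0.9862, stress-zero-at-3, 76% scree) are not
reproduction targets — the underlying data were never published.

## Problem sizes and determinism

Every stochastic step takes a seed; pipeline outputs embed the full
configuration and its hash, and identical configuration plus seeds give
byte-identical files.  The test suite and the acceptance script scale
problem sizes to what the analysis needs: scene fixtures at 128–512 px
height (the reference 1024 × 512 geometry is exercised where the block
count itself is the claim), 200-seed nMDS recovery at the study's
8-item/20-restart design, 500-replicate CI coverage, and 200-dataset
Wilcoxon calibration at n = 8–12.
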