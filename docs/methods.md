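# Methods

This note documents the models, numerical conventions and design choices
behind `camoseek`, and what its synthetic tests do and do not establish.

## Image pipeline

Reflectance calibration is a per-channel linear map anchored on the two grey
patches of a photographed standard (defaults 7% and 93% reflectance), shared
across channels because the standard is spectrally flat; output is clipped to
[0, 1]. Colour conversion uses the standard sRGB → XYZ → CIELAB transform with
a D65 white point and 2° observer (the illumination the targets were
photographed under), via scikit-image. Coordinates are 0-based, x right /
y down; rotations counter-clockwise in degrees.

Target extraction assumes a roughly uniform grey field: the border grey level
is the median of the frame edge of the L plane, pixels within a configurable
threshold (default 8 L units) of it are background candidates, and the actual
background is whatever candidates a 4-connected flood fill reaches from the
frame border. The target is the complement, so interior patches that happen to
match the grey are retained (holes filled by construction). Foreground uses
8-connected labelling — the standard complementary pairing that prevents
diagonal leaks. Zero or several large components raise an error rather than
guessing; the threshold is exposed because no universal value exists. The
alpha channel is a signed-distance ramp over a configurable feather band
(default 1.5 px), so composited edges are never jagged; alpha is exactly 1
strictly inside and 0 strictly outside the band.

Compositing rotates the CIELAB planes alpha-premultiplied with bilinear
interpolation, then blends `out = bg + α (target − bg)`, which leaves
background pixels outside the alpha support bit-identical. Placement and
rotation are drawn uniformly from feasible values when not specified.
Backgrounds and targets must share a pixel/mm scale (targets are shown at
natural size).

## Camouflage metrics

**Edge disruption (GabRat).** At each point of the outline trace (sub-pixel
iso-contour of the mask) the local tangent is estimated from a circularly
smoothed copy of the trace (window ≈ 2σ). Two complex Gabor quadrature
kernels are evaluated on the image patch centred at the point: carrier along
the outline normal (responding to the boundary edge itself, i.e. edges
*parallel* to the outline) and carrier along the tangent (responding to edges
*crossing* the outline). The per-point ratio is `|orth| / (|orth| + |par|)`
and the metric is its mean over the outline, following the published GabRat
formulation. Conventions fixed here: the carrier wavelength follows the
one-octave bandwidth relation λ ≈ σ/0.5622 (the scikit-image default,
exposed as `gabor_bandwidth`); the even kernel is explicitly zero-meaned so
the metric is exactly invariant to global intensity offsets; tangent angles
are quantised to 72 orientations so kernels are built once per orientation;
points whose total energy falls below a small epsilon are excluded, and the
metric is defined as 0 when every point is below epsilon (a uniform target on
an identical uniform background has no edges anywhere). Defaults σ = 3 px on
CIE L (achromatic) and σ = 4 px on CIE A (chromatic).

**Histogram distances.** Luminance uses 100 bins over L ∈ [0, 100]; colour
uses a 200×200 joint (A, B) histogram over [−100, 100]² — finer than the
human colour-discrimination threshold. Both are normalised to sum 1 and
compared by the sum of absolute bin differences, which lies in [0, 2] (0 iff
the binned distributions coincide, 2 on disjoint support). Values outside the
colour range are clipped into the edge bins rather than dropped, since valid
CIELAB pixels can exceed ±100. Note the 2-D map distance is sample-size
sensitive: with thousands of pixels spread over 40 000 cells even identical
distributions produce sparse maps, so absolute values are comparable only at
matched pixel counts — rankings, not absolute levels, carry meaning across
region sizes.

**Granularity.** The bandpass at scale *s* is the difference of Gaussians
G(σ) − G(2σ) with σ = s·√(ln 4 / 6)/π, a constant chosen so the band's
frequency response peaks exactly at spatial wavelength *s*; adjacent dyadic
scales chain their sigmas, tiling the spectrum. Masked pixels are excluded by
normalised convolution (blur of image·mask divided by blur of mask) with
reflective padding, and the energy at each scale is the SD of the bandpassed
values inside the region. The default ladder is dyadic (2, 4, …, ≤ min
dimension / 4); spectra carry their scales so differences are only defined on
matching ladders. Pattern difference is the L1 distance between spectra.

**Surround.** The local surround is every non-target pixel within one body
length of the target, measured by Euclidean distance transform from the target
region (i.e. from the outline, not the centroid — the reading that makes "a
radius of one body length" a band of constant width around the animal), and
clipped to the frame. Body length is the diameter of the Kåsa least-squares
circle fitted to the outline. All comparative metrics are measured in the
composited scene, so background occluded by the target never contributes.

## Game simulation

Sessions hold 24 slides; the same individual phenotype repeats with
probability 0.8, otherwise a different crab is drawn uniformly (the switch
kernel is not specified by the game description; uniform is the minimal
assumption and is configurable). Background, position and rotation are
redrawn every slide. `encounters` counts all prior within-session
presentations of the current phenotype — cumulative, not run-local — matching
the models' "number of previous encounters with the current phenotype".
`novel_crab` flags a phenotype change from the previous slide. `morph_switch`
labels each slide with the *type of the most recent phenotype switch*
(cross-morph vs same-morph), carried through the following run and undefined
before a session's first switch; defining it per-slide-pair instead would make
it logically nested in `novel_crab` and the morph-switch × novelty interaction
inestimable, and the carried definition also reproduces the reduced row count
of the morph analysis (first runs drop out).

The synthetic observer draws capture times from a Weibull (default shape 1,
i.e. exponential) with per-millisecond log-hazard
β₀ + Σ βₘ·metric + β_e·encounters + Σ γₘ·metric·encounters
[+ γₙ·metric·novel + morph-switch penalty] + session intercept.
Times ≥ 15 000 ms are recorded as censored timeouts at exactly 15 000.
Defaults (β₀ = −8.2, session SD = 0.25) give medians of a few seconds and a
timeout fraction of a few percent — the regime of the real game. Because each
presentation re-composites the crab, the realised metrics of a slide scatter
around the crab's catalog summary; the observer model emulates this with
presentation-level jitter (default 0.15 of each metric's between-crab SD),
without which metric differences between consecutive repeat slides would be
identically zero and the difference models degenerate. Per-session screen
scale is drawn uniformly from 0.8–1.3 (participants' displays differ). The
1 s timeout highlight circle is a UI affair and is not modelled.

## Models

Cox fits use the partial likelihood with Efron tie handling (ties are rare at
millisecond resolution) via lifelines, with timeouts right-censored. Session
dependence is handled by a cluster-robust sandwich variance clustered on
session id — the validated fallback of the frailty formulation — rather than
an explicit log-normal frailty term, which none of the installed survival
packages provide and which the sandwich approximates well at these cluster
counts; a session-*stratified* fit (per-session baseline hazard, subsuming any
frailty intercept) is available via `ModelSpec.strata` and is what the
parameter-recovery harness uses. Note that stratifying by session absorbs
session-constant covariates (screen scale, prior play), which must then be
omitted. `ModelFit.cluster_variance` reports a between-session heterogeneity
diagnostic, not an estimated frailty variance.

Quadratic screen-position terms use R-style orthogonal polynomials (centred,
QR-orthonormalised), so coefficients are comparable across fits on the same
data. p values are two-sided Wald; no multiple-testing correction is applied.

Difference records are built per slide ≥ 2 as log(current capture ms) −
log(previous capture ms), including censored times at the ceiling (this
reproduces the n = presentations − sessions bookkeeping of the difference
analyses), with metric differences current − previous and the previous crab's
size/position carried along. The mixed models use a session random intercept
fitted by REML (statsmodels MixedLM, covariates standardised internally for
conditioning and mapped back). Because session intercepts are multiplicative
on the hazard, they are additive on log times and cancel in within-session
differences — the intercept variance therefore genuinely degenerates to ~0 on
difference responses, and the documented fallback refits by OLS (mirroring
cross-validation of the mixed fits with plain GLMs); the two coincide to
numerical precision exactly when the variance is zero.

## Synthetic data

Backgrounds are 1/f^slope broadband noise plus a narrowband "grain"
component (DoG, sigma ratio 1.25, σ = grain/4 — the midpoint of the range,
derived by integrating squared band responses over the 2-D frequency plane,
for which white noise so shaped deposits its maximum granularity energy in
the analysis band labelled by the grain), in CIELAB with configurable base
colour and chromatic jitter. Crabs are Fourier-perturbed discs with one of
four marking styles; the morph parameter distributions are chosen so the
morph label predicts the profile metrics (the catalog-validation property):
Pale/Black sit at lightness extremes with low marking contrast, Green is dark
with a strong green hue, Mottled carries interior blotches kept away from the
outline, Spotted small interior spots, and Disruptive matches the substrate
lightness while carrying high-contrast bars (~5 px, inside the σ = 3 Gabor
passband) across the outline — guaranteeing the generator's contract that
bars-crossing-outline raises GabRat above an unmarked body. The base colour
is painted across the whole cutout canvas so the feathered alpha band blends
body colour, not black.

Every generator is a pure function of (params, seed). The catalog builder
composites each crab once on a randomly drawn generated background and stores
the measured profile as that crab's summary.

What the generators do **not** emulate: real rock-pool optics (specularity,
water, illumination gradients), photo-realistic crab morphology, UV
reflectance, non-human visual systems, or observer processes beyond the
proportional-hazards abstraction (no fixation sequences or eye movements).
Passing tests therefore establish that the metrics and models behave correctly
and recover known structure — not that the specific fitted magnitudes would
match any particular real dataset, and the study's printed z statistics are
functions of its real 40 354-event dataset, which is out of reach by design.

## Problem sizes and numerical choices

The test suite and the acceptance script run scaled-down study conditions
chosen to preserve structure: 256×256 backgrounds with ~24 px crab radius
(full metric suite ≈ 0.3 s per scene), 30-crab catalogs (5 per morph),
300-session gameplay logs for descriptive fits, 834 sessions (20 016
presentations) for parameter recovery, 200 × 60-session datasets for the
permutation type-I study, and 10⁴ sessions for the sequence law. Default
image generation remains 800×600 with ~40 px crabs. Degenerate inputs fail
loudly everywhere: empty pixel sets, collinear outlines, all-censored logs,
zero-variance covariates and rank-deficient designs raise typed errors naming
the offender.
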