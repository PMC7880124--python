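# Methods

This note documents the models, conventions and numerical choices behind
`retivasc`, and what the synthetic world does and does not establish.

## Synthetic vascular scenes

`simulate_tree` grows a network of 12 major vessels (alternating
arteriole/venule) radiating from the optic-disc margin. Each centreline is a
straight baseline plus a transverse sine offset
`A·(sin(2πs/P + φ) − sin φ)` along the arc coordinate `s`; the offset is zero
at `s = 0` so every segment starts exactly at its parent's endpoint, and no
point may enter the disc interior (enforced, not just expected). Branch
events occur with probability `branching_prob` per pixel of arc; they end
the current segment and spawn a continuation (width ×0.97) plus a side
branch rotated 25–40°, one generation deeper, with Murray-law-like width
decay `2^(−1/3)` (symmetric-bifurcation exponent 3, configurable). Segments
carry a `path_id` chaining continuations, so a "vessel" for caliber purposes
is the whole trunk, while side branches count separately.

Scale: a 60 px disc radius maps to 900 µm (`px_per_micron = 1/15`), i.e. a
1024 px field ≈ 15 mm, consistent with a 45° non-mydriatic fundus camera.
Root widths (94/105 µm arterioles/venules, CV 12%) put the rasterised,
truth-mask-measured CRAE/CRVE near the population means they emulate
(≈158/211 µm across seeds).

`render_scene` rasterises each segment as an anti-aliased stroke of
thickness equal to its width (soft coverage map `V`; truth mask = `V ≥ 0.5`),
darkens a smooth vignetted background by `contrast·V` (default 0.55), adds a
soft bright disc and Gaussian pixel noise (default SD 0.05). The scenes are
deliberately not photorealistic: no colour, no fovea, no lesions, no
arteriovenous crossing artifacts beyond incidental geometric overlap.

### Tortuosity calibration

The tortuosity the pipeline measures depends on rendering, segmentation,
skeletonisation and branch splitting, not only on the generator's curvature,
so `sine_amplitude`/`sine_period`/`branching_prob` defaults (11 px, 34 px,
0.004/px) were calibrated once against the full image path — render,
segment, zone-mask 0.5–2 disc diameters, extract branches, mean chord/arc —
until the across-scene mean sat at the emulated population value 0.857, then
frozen. Two regimes limit the usable range: very short sine periods are
averaged away by rendering and skeleton smoothing (tortuosity saturates),
and dense branching splits the skeleton into short, nearly straight
fragments that bias the mean toward 1. The calibrated defaults sit inside
the monotone regime, where measured tortuosity strictly decreases with
amplitude.

## Segmentation

The line detector computes, per pixel, the mean intensity along oriented
line kernels (lengths 5–21 px, 12 orientations over 180°) minus the mean
over a 21 px window, on the inverted image so dark vessels respond
positively; scales are combined by averaging and the map is min–max
normalised. Offsets are nearest-pixel rounded, which makes the
vectorised shift-and-add implementation bit-compatible with a direct loop
implementation (tested to 1e−6).

"Double thresholding" is read as hysteresis: 8-connected components of
(response ≥ low) are kept iff they contain a pixel ≥ high. Components
smaller than 50 px are removed and background holes smaller than 20 px
filled, 8-connectivity throughout. Thresholds are response *quantiles*
(high = q0.95, low = q0.90 by default) so they transfer across contrast
settings; they were tuned once on default synthetic scenes to hold
segmentation Dice ≥ 0.80 against the truth masks and then frozen. Absolute
thresholds are available via `threshold_mode="absolute"`. Optic-disc
localisation is out of scope: the disc centre/radius come from scene
metadata or the caller.

Zones are half-open annuli on `d − r_disc` (inner-inclusive), expressed in
multiples of the disc *diameter* from the disc margin: 0.5–1 for calibers,
0.5–2 for geometry. The source text uses "disc radius" in one passage and
"disc diameter" in another for the geometry zone; this package defaults to
the diameter convention everywhere and exposes `ZoneSpec(reference="radius")`
for the variant.

## Geometry metrics

Box counts use anchors at `(i·stride, j·stride)` with partial edge boxes
included; the default grid is dyadic (2, 4, …, ≤ min(dim)/4) with
stride = δ. `D_f` is minus the OLS slope of `log N(δ)` vs `log δ` (natural
logs). Degenerate inputs return flagged values (empty mask → occupancy 0 and
a warning; all-equal counts → `D_f = 0` with a warning) rather than raising.

Lacunarity has no complete published formula in the emulated analysis
("computed like D_f but uses the standard deviation of the pixel count"),
so the default here is `L = 2 − slope(log σ_N(δ) vs log δ)`, chosen to lie
in (0, 1) for vessel-like masks and to anti-correlate with `D_f` across
density sweeps (verified property). The raw slope and the classical
gliding-box curve `Λ(δ) = (σ/μ)² + 1` are available as alternatives. A
homogeneous mask (σ_N ≡ 0) yields a flagged NaN.

Tortuosity: the skeleton (topology-preserving thinning) is classified by
8-neighbour count (end = 1, link = 2, node ≥ 3); maximal link runs between
nodes become branch segments, discarded below 10 px of arc. Because
8-connected digital paths overestimate arc length by up to ~8% (staircase
effect, which would depress chord/arc even for straight vessels), polylines
are smoothed with a 5-point moving average with pinned endpoints before
length measurement. The index is the unweighted mean of per-branch
chord/arc ratios — straight = 1, curvier < 1. The emulated analysis
describes the ratio verbally as traced-line over connecting-line (arc/chord
≥ 1), which contradicts its own population mean of 0.857; the chord/arc
convention reproduces that scale and is the default, with
`convention="arc_over_chord"` available.

## Calibers

Width at a skeleton point is `2·EDT − 0.5` pixels: the Euclidean distance
transform reaches the centre of the first background pixel, which lies
between 0 (generic orientation) and 1 px (axis-aligned) beyond the true
half-width, so half a pixel is subtracted as the orientation-averaged
excess. A vessel's width is the median over its in-zone skeleton points,
and only vessels whose skeleton spans the full annulus (within 4 px of both
boundaries) qualify — the "passes completely through the zone" rule. This
distance-transform measurement diverges from the intensity-profile
(edge-based) approach of interactive grading software; on rendered bars the
two agree to within half a pixel, and ground-truth widths are recovered
within 10% once vessels are ≥ 4 px wide and lattice quantisation is
sub-dominant.

CRAE/CRVE follow the revised Parr–Hubbard (Knudtson) procedure: the six
largest arterioles/venules (ties broken by in-zone skeleton length) are
combined pairwise largest-with-smallest, `ŵ = c·√(w_a² + w_b²)` with
c = 0.88 (arterioles) / 0.95 (venules), carrying the middle value at odd
counts, 6 → 3 → 2 → 1. These two constants and the schedule are the only
externally sourced numbers in the package. Fewer than six vessels triggers
a flagged reduced-branch variant.

## Cohort simulation

Covariates follow the emulated study population: 48.2% girls, age
N(9.9, 1.2²) years, BMI categories (8.4/80.0/9.0/2.6%), mean arterial
pressure N(80.0, 6.5²) mm Hg, passive smoking 8.4%, low maternal occupation
16.8%; visit counts 1/2/3 with probabilities 25/124/72 of 221; consecutive
examinations 49 days apart (ages advance accordingly). Child-latent metrics
are (D_f, L) bivariate normal with means/SDs (1.500/0.034, 0.495/0.042) and
correlation −0.6 (denser network ⇒ higher D_f, lower L), plus independent
τ ~ N(0.857, 0.012²), CRAE ~ N(163.8, 12.2²), CRVE ~ N(223.3, 16.5²).
Measured values add per-eye noise `√2·σ_w` (so the two-eye average has
within-examination SD σ_w), with σ_w set from per-metric reliability targets
ICC = σ_b²/(σ_b² + σ_w²) of 0.80/0.78/0.74/0.85/0.88 — inside the published
0.72–0.88 band.

Outcomes are built as centred linear predictors plus Gaussian noise from the
child *latent* metrics. The configured effect sizes are the published
*single-exposure* (one-metric-at-a-time) per-IQR estimates; because D_f and
L are correlated, using them directly as joint coefficients would inflate
every recovered marginal. The generator therefore solves
`β = Σ⁻¹ diag(Σ) m` so that the implied single-exposure slopes equal the
configured marginals exactly (identity when metrics are uncorrelated).
Geometry effects on the SDQ follow the published subscale decomposition
(summing to +1.12/−1.38/−0.99 per IQR of D_f/L/τ on the total score);
covariate effects on the total (+1.5 boys, −0.8/yr age, +2.7 passive
smoking, +2.2 low occupation) are split equally across the four subscales.
The Continuous Performance test carries (+11.0, −11.1, −13.4) ms per IQR,
the Digit-Symbol test +2.63 s per IQR of D_f; Stroop and Pattern-Comparison
geometry effects and all CRAE/CRVE effects are configured null.

SDQ subscales are latent Gaussians (base means 1.6/1.2/2.8/1.0, noise SD
1.6), rounded and clipped to [0, 10]; the total is their sum (≤ 40, the
instrument's bound), reproducing the integer floor-skewed score shape,
median ≈ 7, IQR ≈ 5 without modelling 25 items. Cognitive latencies get
child-level and examination-level noise chosen so the examination-averaged
SDs match the published marginals (e.g. CP ≈ 598 ± 48 ms).

Two attenuation mechanisms are deliberately left in rather than
pre-compensated, because the emulated analysis is subject to them too:
regression on examination-averaged *measured* metrics attenuates effects by
the averaged-metric reliability (≈0.85–0.9), and the SDQ floor clipping
attenuates subscale effects by Φ(μ/σ) (≈0.72–0.95). Recovered means
therefore sit some 10–25% below the configured marginals — within half the
published CI half-widths, which is the recovery standard the tests apply.

## Statistics

Averaging is eyes-within-examination first, then across examinations;
covariates come from the child's records with age averaged. ICC(1,1) is the
one-way ANOVA estimator `(MSB − MSW)/(MSB + (k₀ − 1)·MSW)` with the
unbalanced group-size adjustment `k₀ = (N − Σk_i²/N)/(n − 1)`; negative
estimates clip to 0 with a flag. It is implemented directly (the balanced
special case is cross-checked against `pingouin.intraclass_corr` in tests)
because available ICC routines require balanced rater structures.

Effect models are OLS (statsmodels) of the outcome on the IQR-scaled metric
plus the a priori covariates — sex (reference girls, so the reported
coefficient is boys-vs-girls), age (linear; a quadratic term is implemented
but off by default), BMI category dummies (reference normal weight; levels
absent from the analysis sample are dropped), mean arterial pressure,
maternal occupation (reference high) and passive smoking (reference
unexposed). Complete-case analysis with logged deletion counts; 95% CIs are
t-based on residual degrees of freedom. The IQR is Q3 − Q1 with
linear-interpolation quantiles on the analysis sample; fixed published IQRs
(0.04/0.06/0.02 for D_f/L/τ) can be supplied for exact comparability and
are used by the acceptance script. No multiple-testing correction is
applied, matching the emulated analysis. Rank-deficient designs raise an
error naming the collinear columns.

## What a green test does and does not establish

The synthetic world validates the *computation*: metric implementations
against analytic oracles (line/plane/Sierpinski dimensions, semicircle
chord/arc, brute-force box and pairing recomputations), the segmentation
against exact truth masks, and the statistical stage as parameter recovery
under a known generative model. It does not validate performance on real
fundus photographs (illumination artifacts, pathology, A/V classification,
disc localisation are all absent or assumed), and the published effect
estimates serve as configured truths, not as re-derived evidence about
children's behaviour.

## Known limitations

* Highly tortuous rendering regimes (bend radius ≲ vessel half-width) fuse
  inner bends, biasing distance-transform widths low; width validation uses
  gentle-curvature fixtures.
* Junction splitting biases the branch-mean tortuosity toward 1; the
  generator calibration absorbs this for the default world only.
* The SDQ clip bound is configurable per subscale (default 10, total ≤ 40);
  observed totals rarely exceed ~23, mirroring the emulated cohort's range.
* Lacunarity values from rendered scenes (~0.2) sit below the emulated
  population mean (0.495): the fast path draws table metrics from the
  configured distributions, while the image path depends on the synthetic
  vessel texture, which is sparser than a real retina at small box sizes.
  Only the fast path is calibrated to the population table.
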