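# Methods

This note documents the models behind each module, the parameters that
matter, what the synthetic generators do and do not emulate, and the
design choices made where the design was genuinely open.

## Sensitization-index screen scoring

**Model.** The screen assumes viability effects of a gene knockdown and
of the drug combine multiplicatively when they act independently. With
control-normalized viabilities r = Rc/Cc (knockdown alone) and
d = Cd/Cc (drug alone), the expected combined viability is r·d and the
index SI = r·d − Rd/Cc measures the shortfall of the observed combined
condition below that expectation. SI = 0 for any well that behaves like
the nontargeting control (identity tested exactly); SI > 0 is
sensitization, SI < 0 protection.

**Symbol convention.** The assay glossary that accompanies the original
formula lists Rd as "siRNA without drug", which duplicates Rc and makes
the index identically r·d − r regardless of the drug response of the
knockdown — under that reading the screen could not measure
sensitization at all. Rd is therefore defined here as the knockdown
**with** drug, the only reading under which SI compares observed
combination viability to the multiplicative expectation.

**Scoring procedure.** Control levels Cc and Cd are the arithmetic mean
(median available via `control_stat`) of the nontargeting wells of each
replicate, computed per plate. SI is evaluated per target per replicate
and averaged; gene scores average the gene's targets. Hits require mean
SI strictly greater than the threshold (default 0.1): a target at
exactly 0.1 is not a hit. Targets with missing wells are retained with
`status="unevaluable"` rather than dropped, so plate QC stays visible.

**Generator.** `simulate_screen_plate` draws well OD =
baseline · knockdown · drug · interaction · lognormal noise. For
programmed index s the interaction factor is g = 1 − s/(knockdown·drug),
which makes the closed-form SI of the noiseless plate exactly s — the
oracle for all recovery tests. Defaults: 30 genes × 3 duplexes plus one
nontargeting control (the published pool geometry), triplicates, drug
effect 0.5, knockdown effect 0.9, well CV 2% (typical CCK-8 replicate
scatter). The generator does not emulate spatial plate effects (edge
evaporation, gradients) or transfection-efficiency variation between
targets; passing recovery tests therefore demonstrates correctness of
the scoring arithmetic and noise propagation, not robustness to plate
artifacts.

## Dose–response fitting

**Model.** Variable-slope four-parameter logistic in log10 dose,
`y = bottom + (top − bottom)/(1 + 10^(hill (log₁₀ d − log₁₀ IC50)))`,
fitted by unweighted least squares (`scipy.optimize.curve_fit`).
Vehicle (dose 0) wells seed the top-plateau initial value but are
excluded from the log-dose fit. IC50 is the concentration at the
midpoint of the fitted plateaus, reported with delta-method standard
errors; fold changes between fits are ratios of IC50s with a CI
propagated on the log10 scale. Degenerate outcomes — observed or fitted
dynamic range below 0.05, |hill| < 0.1, or non-convergence — return
status `undetermined` with no number fabricated. The Hill slope is
unconstrained in sign; fits are accepted after reparameterizing so
top > bottom.

**Generator noise model.** Readouts are clean 4PL values times
lognormal noise with CV `noise_sd` (default 0.05). Multiplicative noise
was chosen over additive because viability readouts scatter in
proportion to signal and it matches the noise family of the plate
generator (same assay). The distinction matters quantitatively: a
Fisher-information analysis of the free 4PL at the default 6-dose
design (10⁻²–10²×IC50, 3 replicates) puts the IC50 CV floor at ~14%
under additive σ = 0.05 — no 6-dose design does better than ~12.5% —
but ~7% under 5% proportional noise, which is what the observed ~8–9%
empirical CV reflects. `noise_model="additive"` remains available.

## Tubulin biochemistry

Percent assembled tubulin is 100·P/(P+S) from pellet and supernatant
band intensities — the complementarity P↔S summing to 100% is a tested
invariant. Band levels are loading-normalized and expressed as fold of
a reference condition (reference ≡ 1). Turbidity curves (A340 vs time,
~60 min span, ≥10 points) are summarized by: plateau = mean of the
final 10% of points; maximal growth slope = the largest of centered
5-point linear-fit slopes; lag time = first time the smoothed curve
(5-point moving average, window configurable) exceeds 10% of the total
rise, flagged undefined for flat curves. The assembled-fraction formula
appears in the source assay only as an image; P/(P+S)×100 is the only
dimensionally sensible reading of pellet-over-total and is implemented
as such.

## Microtubule-network quantification

**Tubeness.** The ridge response at scale σ (default 1.0 px, matching
the common plugin setting) is |λ₂| of the Hessian of the
Gaussian-smoothed image where λ₂ < 0 and 0 elsewhere — the bright-ridge
convention, since stained microtubules are bright on dark background.
Boundary handling is reflective so a constant image has exactly zero
response. Validation uses closed forms: for a ridge of profile SD s the
centerline response is A·s·(s²+σ²)^(−3/2) and for a blob
A·s²/(s²+σ²)², so a filament outscores a punctum of equal brightness.

**Polymerized-area pipeline.** tubeness → 8-bit conversion →
binarization strictly above a threshold → particle cleanup → intersect
with the cell mask → percent of cell area. Within a comparison batch
every image shares one 8-bit window (0 to the batch-max response) and
one threshold, both derived from the designated control image.

**Threshold choice.** The default threshold is a noise floor: 3× the
robust SD of the sub-median half of the *signed* ridge response inside
the cell (the sub-median half is noise-dominated even at high filament
coverage, so the estimate is not contaminated by ridges). Otsu on the
control image was evaluated and rejected: because a ridge filter traces
centerlines, Otsu binarizes only the ridge crest and under-reports
dense networks (−17 points at 40% true coverage on generator images,
against a ±5-point recovery requirement). Ridge filters also leave
holes inside merged filament mats, where the second derivative
flattens; the cleanup step (morphological closing with a 3-px disk,
then filling enclosed holes up to 64 px; both configurable) restores
those interiors. With these defaults the measured fraction tracks the
generator's rasterized-mask truth with mean absolute error ≤ ~2 points
across 5–40% coverage. A fixed numeric threshold can be supplied to
reproduce a plugin-style workflow exactly.

**Cell contour.** Supplied as a mask, or derived from the tubulin
channel by Gaussian blur (σ = 10 px) + Otsu when no mask is given (the
source workflow does not state its contour method).

**Generator.** Filaments are persistent random walks (heading SD
0.25 rad/px step, lengths 0.15–0.6 of the image side) inside an
elliptical cell, rasterized with a ~1 px Gaussian cross-section;
Poisson photon noise plus Gaussian read noise. The ground-truth
structure mask is the dilated rasterized footprint (~2–3 px width,
matching the FWHM of the rendered cross-section). The generator does
not emulate out-of-focus light, centrosomal brightness gradients, or
neighboring cells; recovery results validate the segmentation logic on
curvilinear structures, not performance on cluttered fields of view.

**Colony counting** thresholds the image (Otsu if none given), labels
8-connected components, and counts those strictly larger than the area
cutoff (default 9 px², so a 9-px component does not count).

## EB1 comet tracking

**Detection.** Scale-normalized LoG response at `sigma_spot`; local
maxima above `min_snr` (default 5) times the MAD-based robust SD of the
response; sub-pixel refinement by intensity-weighted centroid of the
background-subtracted frame over a window of radius ⌈2.5σ⌉. The window
size matters: a 5×5 window around a σ = 1.5 px spot pulls centroids
toward pixel centers ("pixel locking", up to 0.19 px here), which
systematically shortens fast-comet displacements; at radius 4 the bias
is < 0.02 px.

**Linking.** Greedy nearest-neighbor per consecutive frame pair,
resolved globally by ascending distance, links beyond `max_disp`
forbidden, no gap closing by default (1-frame gaps are not closed; a
missed detection ends the track). `max_disp` defaults to the
displacement of a 25 µm/min comet over one frame interval plus 1 px
localization slack. Tracks shorter than `min_track_length` (default 4
frames) are dropped. Agreement with an exhaustive optimal per-pair
assignment (Hungarian) exceeds 95% at screen-like densities.

**Track QC.** Nearest-neighbor linking occasionally steals a shorter
link to a different comet; because wrong links are preferentially
short, the surviving bias is downward and grows with speed (−5% at
15 µm/min on otherwise perfect positions). Since growing tips are
near-ballistic at 2-s sampling (the generator's heading diffusion is
0.05 rad/frame; real EB comets likewise rarely reverse), a heading turn
sharper than 90° inside a track almost always marks a link error.
`track_movie` therefore splits tracks at such turns (configurable,
`max_turn_deg=None` disables), analogous to the maximum-forward-angle
filters of established plus-end tracking tools. Residual speed bias is
within ~2.5% across 5–15 µm/min.

**Rates.** Growth rate = along-track path length / track duration
(µm/min). Path speed was chosen over net start-to-end displacement
because growing tips curve; `net_rate` provides the alternative. The
per-cell summary reports cell means, the grand mean of cell means, and
the pooled distribution with 5th/95th percentiles — the box conventions
used for comet-rate figures. The commercial tracker used in the source
study does not publish its definitions or parameters, so this module is
validated by ground-truth recovery, not by reproducing that study's
specific µm/min values (its raw movies are not available).

**Generator.** Comets nucleate uniformly, move at per-track constant
speed (Normal(mean, SD) µm/min) with slight heading diffusion, rendered
as Gaussian spots at SNR = amplitude/noise-SD (default 10) over a flat
background; defaults match a 2 s × 15 frame, 0.065 µm/px acquisition.
Not emulated: comet appearance/disappearance mid-movie (catastrophe and
nucleation), comet shape anisotropy, photobleaching, or cytoplasmic
background texture.

## Clinical statistics

H-score = staining intensity (0–3) × stained-proportion quartile grade
(0–4), spanning 0–12 — the only standard construction with exactly that
range — dichotomized at ≥ 8 into high expression. Associations use the
Pearson chi-square test without continuity correction on labeled
contingency tables; p-values are reported at full precision and rounded
to 3 decimals for display. Zero expected counts raise; expected counts
below 5 attach a small-sample warning. Rows containing a not-available
level can be excluded (default) or kept as a category; the published
cohort table this module was checked against is only consistent with
N/A retained for its Menopause row (p = 0.541), which is kept as a
documented regression test. Two rows of that table (Surgery, LN status)
do not match Pearson chi-square on their printed counts under either
policy — most plausibly a different test (e.g. Fisher's exact) was used
for those sparse rows — and are excluded from the checks.

**Generator.** `simulate_contingency` draws multinomial counts per
group; group 2 adds a log-odds `effect` to the last level. `effect=0`
is the exact null used for type-I calibration (p approximately uniform
over 1,000 draws).

## Numerical conventions

Seeds: every generator accepts an integer seed or a
`numpy.random.Generator` and is byte-deterministic given it. Lognormal
noise uses mean-one parameterization (µ = −σ²/2). 8-bit conversion
rounds half to even and clips; degenerate (constant) images map to
zero. Turbidity lag on a flat curve, Pearson correlation on a constant
channel, and IC50 on flat dose-response data all return explicit
undefined flags (NaN/status) rather than numbers.

## Known limitations

- The screen scorer assumes per-plate controls; batch-level control
  pooling is not implemented.
- The polymerized-fraction cleanup (closing radius, hole size) is tuned
  for ~1 px-wide filaments at 256² scale; much thicker structures or
  strongly textured backgrounds warrant revisiting those defaults.
- The tracker has no gap closing beyond an optional single-frame flag
  and no motion model; at densities far above ~0.002 comets/px² or
  speeds near `max_disp` the turn-splitting QC cannot fully compensate
  nearest-neighbor link errors.
- Catastrophe/rescue event calling is out of scope; only growth speed
  is quantified.
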