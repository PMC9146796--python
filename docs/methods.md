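# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `spheropd`.

## Scientific setting

HCT116 colorectal cancer spheroids held in a perfused microfluidic well can
be exposed to the same free-drug concentration history a subcutaneous
xenograft experiences in a mouse. The package covers the quantitative chain
needed to compare the two systems: constructing the exposure, measuring
spheroid growth, quantifying proliferation/apoptosis staining, and scaling
on-chip growth to xenograft volume trajectories.

## Exposure construction

Plasma pharmacokinetics of oxaliplatin after a bolus dose show a peak
within the first hour and a roughly mono-exponential decline, with only
~33% of total drug unbound (free) and hence active. The module:

1. scales a tabulated total-concentration profile by the unbound fraction
   (`PlasmaBinding.unbound_fraction`, default 0.33; profiles are labelled
   `total`/`free` and a free profile is refused a second correction);
2. discretizes the free profile into a stepwise schedule whose levels are
   interval time-averages of the linearly interpolated profile. This makes
   the schedule AUC equal the profile AUC over the covered span to
   round-off (asserted at 1e-9 relative in tests), AUC being the standard
   exposure metric. The discretization rule is a package choice; nothing in
   the analysis depends on it beyond AUC preservation;
3. predicts the well concentration with a 1D advection–dispersion model.

### Channel transport

Geometry defaults: 21 × 2 × 1 mm channel, 2 µL/min flow (mean velocity
U = Q/(w·h) = 1 mm/min), well at 10.5 mm, molecular diffusivity
8.2e-6 cm²/s. Axial smearing by the parabolic (Poiseuille) profile is
modelled with the parallel-plate Taylor–Aris closure
D_eff = D(1 + Pe²/210), Pe = U·h/D ≈ 20, giving D_eff ≈ 3× molecular.
The 2:1 aspect channel is not exactly parallel-plate; the geometric factor
is exposed (`ChannelTransport.geometry_factor`) for an exact
rectangular-duct coefficient if required. The classical Taylor condition
(t ≫ h²/D) is marginal during the first seconds of a step; the closure is
adequate for the minute-scale lags of interest.

Numerics: explicit forward-Euler with central differences in space.
Under dt ≤ dx²/(2 D_eff) and cell Péclet U·dx/D_eff ≤ 2 the update is a
convex combination, so the discrete solution obeys the maximum principle
exactly; both bounds are enforced and a violating user grid raises
`CFLViolation` rather than being silently adjusted. Default dx resolves
the channel to ≤ L/400 and the default dt uses a 0.4 safety factor.
Verified behaviours: mid-rise of a step arrives at the advective transit
time (10.5 min at the well) within 5%; a completed pulse conserves the
advective flux integral to ~3e-5 (1% asserted); halving dx changes the
well trace by ~0.1% RMS (1% asserted).

## Morphometry

Bright-field spheroids are darker than the background (an `invert` flag
covers the opposite polarity). Segmentation: Gaussian smoothing with
σ = 2 px, global Otsu threshold, largest connected component, hole filling;
components under 100 px are rejected as debris (`NoSpheroidFound`).
Measurement is pixel counting: area = n·p², equivalent diameter
2√(area/π), volume as the sphere with that diameter. Sub-pixel contour
refinement is deliberately omitted — the discretization error is far below
the biological and measurement noise (recovery tests show < 2% diameter
error for 0.3–1.0 mm spheroids at SNR 10 and 2 µm/px).

## Growth statistics

GI = 1 − mean(ΔV_treated)/mean(ΔV_control) uses arithmetic means of
*per-spheroid* deltas; with balanced complete data this equals the delta of
means, and with missing data the per-spheroid form is the one computed
(excluded spheroids are counted in a warning). GI > 1 (treated shrinkage)
is reported as-is; negative mean control growth warns rather than errors.
The Welch test is implemented at formula level (Welch–Satterthwaite df)
and is verified against an independent reference implementation at 1e-10;
the count–volume regression delegates to standard OLS. The two-way
unbalanced ANOVA occasionally used for chip-vs-plate comparisons is a
standard routine deliberately not reimplemented here.

## Immunohistochemistry

Positivity is a threshold on supplied DAB optical densities — Ki67 at 0.3
per nucleus, CC3 at 0.5 per pixel, ties positive (tie handling is a package
convention). The OD scale is that of the upstream detection tool; colour
deconvolution and nucleus detection are upstream concerns, out of scope.

Shell geometry: detections are binned into equal-width annuli around the
section centre (default: detection centroid). The shell boundary is the
inner edge of the first annulus, scanning outward, whose positive fraction
exceeds the threshold (default 0.4 — midway between typical shell ~0.8 and
core < 0.05 rates, exposed as a parameter). Shell thickness is therefore
quantized at one bin width, which is the recovery tolerance used
throughout. Because how an "overall proliferating fraction" should be
weighted is ambiguous, both detection-count and annulus-area weightings
are reported.

## Two-population xenograft model

Xenografts of this line grow with an approximately constant radius speed,
V(t) = (4/3)π(αt+β)³. The package links α to on-chip data with the
thin-shell closure α = k·s: volume production per day is k × shell volume
≈ k·4πR²s, and dividing by the surface area 4πR² gives the radius speed.
It is the only dimensionally consistent closure using exactly the two
available ingredients (k from spheroids, s from histology), and it is exact
as s/R → 0.

Its finite-shell error is characterized against the explicit shell/core
ODE dR/dt = k(R³ − (R−s)³)/(3R²): the closure is an upper bound; a radius
slope fitted over 14 days from β = 2.9 mm runs ~13% low at s = 0.6 mm,
while the late-time slope (evaluated at the end of a 28-day integration,
where R has roughly tripled) is within 10% of k·s for all s/β ≤ 0.25
(measured 4.8–6.9%). The closure is therefore read as the asymptotic
radius speed of the two-population mechanism.

Parameterization used in the examples and pipeline:

* k (untreated) = ln(2.3)/2 ≈ 0.416/day, from the 2.3-fold/48 h control
  growth on-chip, measured over the first 2 days before size-related
  slowdown;
* s = 0.60 mm — a calibration, not a histological measurement: chosen so
  the closure reproduces the reported untreated radius speed of
  0.25 mm/day (plausible for a proliferating rim, but distinct from the
  1.3 mm shell of the synthetic demonstration section, whose role is to
  make the overall positive fraction ≈ 0.46);
* treated k from the full 7-day treated window (pause plus recovery);
  a 7-day treated fold of ≈ 3.6 reproduces the treated 0.11 mm/day;
* β = (3·100/4π)^{1/3} = 2.879 mm by default (100 mm³ start); a
  `rounded_beta` option uses 2.9 mm to match trajectories computed from
  rounded inputs. The 14-day endpoints under the rounded convention are
  1098 mm³ (untreated) and 367 mm³ (treated); the 367 differs from a
  sometimes-quoted 376 mm³ only because the latter reflects a treated α
  of ≈ 0.113 before rounding to 0.11;
* fold changes are reported under both V(0) conventions (model
  (4/3)πβ³ = 102.2 mm³, or nominal 100 mm³); both land inside the
  untreated 5–13× and treated 1.5–7.5× ranges observed across xenograft
  studies;
* comparison horizon 14 days.

## Synthetic generators

The generators define the study conditions under which the pipeline is
validated:

* **Growth**: 4 spheroids per arm; starting volume lognormal around
  0.05 mm³ (≈ 0.46 mm diameter) with 10% CV; control growth exponential at
  ln(2.3)/2 per day; treated arm flat for 2 days then regrowing, by default
  at the full control rate; measurements at days 0, 2 and 7. Measurement
  noise is lognormal with 2% CV applied to the *diameter* (the quantity an
  imaging chain actually measures) and cubed into volume. Under these
  defaults the closed-form GI expectation over days 0–7 is
  1 − (e^{5r} − 1)/(e^{7r} − 1) = 0.598 with r = ln(2.3)/2, and the
  simulate→measure→GI pipeline matches it within Monte-Carlo error.
  An observed GI of ~0.70 with the same pause corresponds to a partial
  recovery at ≈ 0.88× the control rate (7-day treated fold ≈ 6.2);
  the recovery rate is a free parameter for exactly that use.
* **Images**: dark disk (0.4) on bright background (1.0), 2 px linear edge
  ramp approximating defocus, additive Gaussian noise at a stated SNR.
* **Sections**: uniform point pattern in a disk; Bernoulli positivity at
  p_shell = 0.8 outside R − s and p_core = 0.03 inside (R = 4 mm,
  s = 1.3 mm, making the area-weighted overall fraction ≈ 0.45); ODs from
  lognormal components with medians 0.10 and 0.60 that straddle the 0.3
  cutoff, so thresholding recovers the true labels with > 99.5% fidelity;
  nucleus density 800/mm².
* **Plasma curve**: deterministic table, linear rise to a 9.09 µM total
  peak at 0.5 h (3.0 µM free at f_u = 0.33) then exponential decline with
  an 8 h half-life, leaving < 2% of the free peak at 48 h. This curve is
  synthetic — the measured mouse curve it emulates is not publicly
  tabulated — and is labelled as such.

What passing tests show, and do not show: parameter recovery on these
generators demonstrates the correctness and internal consistency of the
statistics and estimators under idealized conditions (single spheroid per
image, radially symmetric sections, lognormal noise). They do not certify
performance on real images with debris, focus drift or non-spherical
growth, nor on sections with irregular proliferative regions.

## Reproducibility

Every stochastic routine takes an explicit seed or seeded generator; the
pipeline derives per-stage seeds from a single config seed and writes all
of them into `summary.json`. Two runs with equal configs produce identical
artifacts (asserted in tests). Problem sizes in the test-suite recovery
studies (200 GI replicates, 500 growth-rate replicates, seven-diameter
morphometry sweep, ~40k-nucleus sections) were chosen to bring Monte-Carlo
error well below the asserted tolerances while keeping the suite fast.

## Known limitations

* The transport model is 1D; transverse gradients at the well mouth and
  uptake by the spheroid are not modelled.
* A single static unbound fraction; no binding kinetics or metabolism.
* Constant-radius growth has no saturation; it will overshoot at large
  volumes where radius speed declines.
* The α = k·s closure ignores shell thinning/compression under treatment
  and external pressure effects.
* The GI statistic inherits the usual caveats of endpoint ratios with
  small n; no longitudinal mixed-effects modelling is attempted.
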