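# Methods

This note documents the models, conventions and numerical choices behind
`thermoleaf`, and what the synthetic scenes do and do not establish about
real thermal imagery.

## Scene model and conventions

Frames are calibrated temperature grids (°C); no radiometric processing is
performed beyond carrying the emissivity (default 0.95, constant for plant
material) as metadata.  Temperatures are validated against a physical range
of 0–60 °C suited to growth-chamber work.  Pixel coordinates are 0-based,
half-open, `(row, col)` ordered.  Oval ROIs include the pixels whose centers
fall inside the ellipse inscribed in the bounding rectangle — one of several
defensible conventions; boundary-pixel treatment differs between imaging
packages and matters little for min/max statistics over hundreds of pixels.
Storage is deliberately plain: CSV grids or single-channel 32-bit float TIFF
with a JSON sidecar, round-tripping within 1e-4 °C (float32 precision at
30 °C is ~2e-6 °C).

## Temperature extraction

**Robust extremes.**  Raw ROI extremes are replaced by the 2nd/98th
percentile of ROI pixels (when ≥ 20 pixels are available), with a
`corrected` flag when they differ from the raw extreme by more than 0.3 °C.
This automates the manual correction needed when a wilting apical point
bends into a neighbouring ROI and contaminates the raw maximum.  The flag
threshold (0.3 °C) is three times the sensor resolution; the percentile pair
(2/98 %) suppresses sub-2 % contaminations while passing a leaf that
occupies ≥ 4 % of the ROI unchanged.

**Interpretation switch.**  Before stress the ROI minimum is leaf and the
maximum is background air; after wilting the minimum is air and the maximum
is the (now overheated) leaf.  The switch to `max_is_leaf` requires both the
collapse of the cool tail (robust minimum within 0.5 °C of air) and a warm
tail strictly exceeding air; switch-back additionally requires a 60-min
dwell (hysteresis).  The margin (0.5 °C, five times sensor noise) and dwell
prevent chattering while the leaf crosses air temperature.  On noiseless
synthetic scenes this rule reproduces the true leaf temperature exactly at
every frame, including through the crossing.  Air temperature is the mean of
the 3×3 cursor pixels.  Post-stress the warm extreme conflates leaf and stem
pixels; we report it as leaf temperature and note the conflation.

**Hourly aggregation** is the arithmetic mean of the frames within each
daytime hour (six at 10-min cadence), hours counted from light-on; partial
and empty hours are flagged.  The mean of a linear signal equals its value
at the mean sample time, which is the hour midpoint only for sampling
symmetric about it — the generator's 0,10,…,50-min sampling reads 2.5 min
early on a linear ramp, a bias far below sensor noise for the ramps involved.

## Leaf angle and turgor

Segmentation keeps ROI pixels contrasting with air by more than 0.8 °C
(either sign — chosen between the 3 °C transpirational offset and the 0.1 °C
noise floor), then the largest 8-connected component.  At thermal
equilibrium the plant is invisible to this rule and the measurement is
flagged `small_mask` rather than guessed; in the default scenario this
blinds the angle channel for a ~3-h window while the wilting control crosses
air temperature, which is an honest property of thermal-contrast
segmentation.  The angle is taken between the mask's principal axis (leading
eigenvector of the pixel-coordinate covariance, oriented away from the stem
anchor supplied in the ROI config) and the downward vertical: 0° hangs along
the stem, 90° is horizontal.  Nearly isotropic masks (eigenvalue ratio
< 1.2) are flagged `ambiguous_axis`.  Whole-mask principal axes stand in for
per-leaf protractor readings; on multi-leaf rosettes the two can differ.
Turgor is the linear map angle/90·100 %, clamped to [0, 100]: angles above
90° (short-term hyponasty under early stress) are measurable up to 120° but
saturate the turgor index, since the linear mapping is only defined on
[0°, 90°].

## Stress indices

CWSI and Ig are computed exactly from their defining ratios; out-of-range
CWSI values are flagged rather than clamped so bad references remain
visible.  Reference temperatures are experimental inputs.  The demo pipeline,
lacking reference surfaces, uses a documented convention — maximum daytime
air temperature as the dry reference and the mean Day-1 (well-watered) leaf
temperature as the wet reference — which suffices to show the index rising
from ≈0 to ≈1 across a wilting event but is not a measured-reference
protocol.  The conductance calibration g_s = G·Ig is exposed only when a
slope G is configured; Ig∝g_s assumes constant boundary-layer conditions,
which the package exposes but cannot validate.

## Wilting-onset detection

Onset is the first time the centred finite-difference turgor drop rate
exceeds 15 %/h and keeps exceeding it for ≥ 30 min, evaluated within
contiguous daytime runs only (day/night posture steps would otherwise
register as wilts); a one-frame cliff is caught by a separate step rule.
The threshold triggers on a wilt-type collapse (tens of %/h) but not on
diurnal angle drift (a few %/h).  Without a turgor signal the fallback is
the first sustained rise of leaf−air ΔT above −1 °C (the leaf approaching
equilibrium).  On the noiseless default scenario the detector lands exactly
on the true onset frame.

## Asymptotic kinetics fit

`AsymptoticStressModel.fit()` minimises Σ(Y − θ₁ + θ₂e^{−θ₃X})² with a
bounded trust-region least-squares polish (θ₃ > 0) started from the default
rule θ₁ = max(Y), θ₂ = range(Y), θ₃ = 1/range(X), tolerances
xtol = 1e-14 and ~1e-12 on relative RSS/gradient, 500-iteration budget.
Because the near-linear regime is a long flat valley (θ₁ and θ₂ grow
together while θ₃ → 0), the fit also profiles θ₃ over a log grid — the model
is linear in (θ₁, θ₂) given θ₃, so the profiled RSS is an exact 1-D
function — refines the best grid point by bounded scalar minimisation and
keeps whichever candidate attains the lower RSS.  This recovers both a fast
asymptotic parameter set and a near-linear one from noiseless data to better
than 1e-3 relative.  Standard errors come from (JᵀJ)⁻¹·RSS/(n−3) at the
optimum; a Jacobian condition number above 1e8 flags the fit
ill-conditioned, in which case θ₁ and θ₂ are individually weakly identified
(their difference and the initial slope θ₂θ₃ remain stable).  Residual
checks are Shapiro–Wilk normality and a Durbin–Watson statistic in (1, 3);
numerically zero residuals pass trivially.  Time series are re-anchored to
hours since onset and block-averaged into 30-min means over an 8-h window
before fitting (both configurable); fits are invariant to uniform time
shifts after re-anchoring.

**Shape classification.**  `near_linear` when θ₃·horizon < 0.5 (default
horizon 8 h), else `asymptotic`; the boundary is exclusive.  At product 0.5
the exponential deviates from its secant line by under 2 % of the amplitude,
which is the operational meaning of "indistinguishable from linear".

**Phase clustering** labels times < 0 h as before-wilt and ≥ 0 h as
after-wilt, excluding points outside the (−4, 6) h analysis window.

**Turgor–temperature relationship.**  Lowess (tricube weights, span 0.5,
2 robustness iterations — span unstated in the field protocol, recorded in
the output) within a 28.5–31.0 °C window, plus OLS slopes per treatment and
a slope-difference test via the interaction term of a two-group linear
model.  Lowess reproduces exactly linear input to numerical precision, which
anchors the smoother's correctness.

## Synthetic scenes: what they emulate and what they don't

The generator renders two plants (one control, one treated with a
stress-mitigating biostimulant) as straight elongated leaf masks attached to
vertical stems, against background at air temperature, 120×160 px frames
every 10 min over 5 days, 16:8 light with air stepping 27→33 °C.  The
trajectory grammar follows the observed experiment: a 2 °C exponential
settling transient over the first 2 h of Day 1; a 3 °C transpirational
offset by day and 1 °C by night; a pre-wilt deepening of the offset to
~5 °C on Day 3; control wilting after 5.5 h of Day-3 light, with leaf
temperature following the asymptotic law from onset and leaf angle
collapsing 55°→5° in 1 h; a treated plant tracking the near-linear
parameter set (82.81, 55.1, 0.0098 h⁻¹) for the 8-h observation window and
held constant after (extrapolating a near-linear fit beyond its window
leaves the physical range); Day-4 adaptation; and a 2.5-h treated recovery
to 2.5 °C below air after Day-5 re-watering, while the control stays at
equilibrium.  Night angle is fixed at 20° (leaves in low night position; the
exact value is a choice).  Noise is i.i.d. Gaussian, default sd 0.1 °C (the
imaging resolution), one seeded generator per sequence.

The default control kinetics are (34.0, 6.0, 0.523 h⁻¹): the published rate
with the asymptote placed 1 °C above daytime air so that the wilted canopy
reads as the ROI maximum, as the extraction protocol requires — an asymptote
below air would leave the minimum interpretation correct forever and the
switch untested.  The published parameter sets are used verbatim wherever
the printed models themselves are the object under test.

Not emulated: radiative transfer and convection, 3-D architecture and
per-leaf articulation, soil-moisture coupling (the generator drives
temperature kinetics directly), camera optics, and background clutter.
Passing the noiseless oracle therefore establishes that the extraction,
segmentation, protractor, onset and fitting *logic* is exact under the
stated scene grammar — not that the pipeline is robust to occlusion,
draughts or reflective backgrounds in real chambers.

## Problem sizes

Default test and demo runs use the full 5-day, 10-min-cadence, 120×160-px
scene (720 frames, ~2 s to generate and extract), 17-point kinetic fits,
200-replicate noise studies and 80-point slope-contrast simulations — sizes
chosen so the whole suite completes in well under a minute while leaving the
estimators' behaviour clearly resolved.
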