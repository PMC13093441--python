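# Methods

This note documents the models, numerical choices and limitations behind
`mcgkit`, in the order of the processing chain.

## Forward model

The package reduces ventricular activation at each wave peak to a single
equivalent current dipole: position (x₀, y₀) in the sensor-plane frame,
depth d below the plane (source at z = −d), in-plane moment
**Q** = (Qx, Qy) in A·m. The measured quantity is the normal field
component on the plane,

    Bz(x, y) = (μ₀/4π) · [Qx·(y−y₀) − Qy·(x−x₀)] / ((x−x₀)² + (y−y₀)² + d²)^{3/2}.

Useful exact properties, all used as test oracles:

- Bz vanishes on the line through the source parallel to **Q**;
- its extrema sit at distance d/√2 on either side of the source along the
  perpendicular axis, so the pole-to-pole distance is √2·d;
- the in-plane gradient rotated by 90°, c = (∂Bz/∂y, −∂Bz/∂x), evaluated
  above the source is proportional to **Q** itself;
- Bz is linear in **Q**, and the peak amplitude decreases monotonically
  with depth.

A cardiac cycle is three Gaussian activation envelopes (P, QRS, T)
multiplying the dipole pattern. Defaults: cycle 1 s (60 bpm); envelope
centres 0.20 / 0.40 / 0.70 s; sigmas 25 / 20 / 40 ms (i.e. total widths of
roughly 100 / 80 / 160 ms — a 20 ms QRS sigma yields a ~98 ms QRS duration
under the 5% bound rule below, matching normal adult values); moment
magnitudes 0.15 / 1 / 0.5 × 10⁻⁶ A·m. At the default 6 cm depth this puts
the R-peak field near 10⁻¹¹ T, inside the 10⁻¹⁴–10⁻¹¹ T range of cardiac
magnetic fields. Noise is additive white Gaussian per channel (default
0.2 pT for cohort simulation); no 1/f sensor noise or volume-conductor
effects are modelled.

The default array is 6×6 sensors at 4 cm pitch centred on the source
epicentre — a typical planar optically-pumped-magnetometer footprint. All
geometry is configurable.

## Synthetic cohorts

The generator encodes the clinical contrast the package targets. Healthy
controls draw their R-peak current angle from Normal(40°, 12°) (lower-left
quadrant in the ECG-style frame: 0° = subject's left, +90° = inferior) with
source depth Normal(6 cm, 0.5 cm); the PH regime draws from
Normal(115°, 25°) (lower-right) with a shallower source, Normal(4.5 cm,
0.5 cm), reflecting the right ventricle's position immediately behind the
sternum. T-wave angles track the QRS angle with class-dependent jitter
(8° HC vs 25° PH), making the T-peak current direction more dispersed in
PH. Demographics: PH 80.6% female, age ≈ Normal(41.8, 14.3); HC balanced,
age ≈ Normal(45, 9). ECG findings are class-conditional Bernoulli draws;
right-axis deviation has prevalence 0.634 in PH vs 0.032 in HC and is the
dominant finding by likelihood ratio.

`simulate_feature_table` draws the nine parameters directly (no waveforms)
for fast modelling experiments. The secondary-marker contrasts (NCD_T,
PD_R, NCD_R, CA_T) were set so cohorts are strongly but not perfectly
separable — mirroring a realistic high-performing marker panel rather than
a degenerate one; with the angle contrast fixed as above, complete
separation can still occur in some finite samples, and the logistic fitter
flags it. FMA_R is generated as CA_R − 90° + Normal(0, 5°), reproducing the
strong CA/FMA collinearity that the VIF screen is designed to catch; angle
draws are truncated to the principal branch (−180°, 180°] so this linear
relation is not broken by the wrap discontinuity. What passing tests on
these cohorts do **not** show: robustness to real-world artefacts (baseline
wander, arrhythmic beats, sensor dropout, torso conduction), or that the
synthetic effect sizes match any particular patient population.

## Preprocessing

Zero-phase 4th-order Butterworth band-pass, default 0.5–40 Hz (applied
forward-backward, so the effective magnitude response is squared). R peaks
are detected on the cross-channel RMS trace with an adaptive threshold
(baseline + 0.6 × excursion) and a 300 ms refractory period. Beats are
averaged over R-aligned windows (300 ms before to 500 ms after R). The R-
and T-peak instants are the argmax of |Bz| over all channels within ±60 ms
of the alignment point and 150–450 ms after R respectively — the
"single channel with maximum amplitude" butterfly-diagram convention. QRS
onset/offset use a relative RMS threshold θ = baseline + k·(peak −
baseline) with k = 0.05, scanning outward from the R peak; the baseline is
the median RMS of the beat. For a Gaussian envelope of sigma w this rule
gives a QRS duration of 2w·√(2·ln 20), which the tests verify analytically.

## Maps and the nine parameters

Channel values at one instant are interpolated onto a 100×100 raster over
the exact sensor bounding box with a thin-plate-spline RBF — the standard
topographic-map interpolator in biomagnetism; it is smooth, exact at the
sensors, and reproduces constants. (A piecewise-cubic Clough–Tocher
interpolant was evaluated and localised the field extrema about twice as
poorly on the 36-angle dipole scan, so the spline was adopted.) The PCD
transform uses central differences (one-sided at borders).

- **CA** — angle of the unweighted vector sum of the PCD over all pixels.
  An option restricts the sum to pixels above a magnitude quantile; the
  default uses all pixels. On noise-free dipole beats this recovers the
  moment angle essentially exactly, and is equivariant under rotation of
  the sensor frame.
- **NCD** — max/mean of the PCD magnitude: a dimensionless focality index,
  ≥ 1, scale-invariant in |Q|, larger for shallower sources. This is a
  reconstruction chosen for those properties, not a vendor formula.
- **Poles / PD** — argmax and argmin raster pixels; PD is their Euclidean
  pixel distance, by construction resolution-dependent (the raster size is
  a recorded configuration field). On closed-form rasters PD = √2·d/pitch
  within one pixel; through the 6×6-sensor interpolation the empirical
  tolerance is ~4 px.
- **FMA** — direction of the positive→negative pole axis. Perpendicular to
  CA within 1.5° on closed-form rasters; empirically within ~7° through
  the sensor-interpolation path, where pole localisation between sensors
  dominates the error. Tests assert these measured bounds per path.

Angles are reported in degrees on (−180°, 180°].

## Diagnostic modelling

Logistic fits use damped-Newton IRLS (convergence when the largest score
component < 10⁻⁸, cap 100 iterations). Complete separation is detected from
saturated fitted probabilities and flagged with a warning; estimates are
then the capped-iteration values, not finite MLEs. CA_R is scaled per 10°
before fitting (a configurable scale rule) so its odds ratio is clinically
readable; selection is invariant to such affine rescaling.

The development workflow: (1) VIF screen over the nine candidates — while
any VIF exceeds 5, the offender whose forced-covariate-adjusted univariable
model fits worst (highest deviance) is dropped, which keeps the
better-fitting member of a collinear pair such as CA_R/FMA_R; (2) forward
stepwise entry by the 1-df likelihood-ratio test at α = 0.05 (entry only,
no removal step; deterministic tie-break by candidate order), starting from
forced age + sex; (3) Youden-index cutoff over observed training scores
(classification is score ≥ cutoff; ties break to the lowest cutoff).

Internal validation is Harrell's bootstrap: each resample re-runs the
*entire* process — VIF prune, stepwise selection, refit and Youden cutoff —
and optimism is the mean bootstrap-minus-original performance difference of
the bootstrap models, subtracted from the apparent AUC/Se/Sp. A
configuration switch allows coefficient-only refitting, but full-process
validation is the default because conditioning on the selected model
understates optimism. Resamples with a single class are redrawn and
counted. AUC is the Mann–Whitney statistic with ties counted half.

Hosmer–Lemeshow uses g = 10 quantile groups, χ² = Σ(O−E)²/(E(1−p̄)),
df = g − 2 (empty groups are merged and the used count reported). The df
correction is calibrated for fitted probabilities; the test suite verifies
near-nominal rejection for a fitted well-specified model. Calibration
curves use quantile binning (default 5 bins) with exact per-bin binomial
CIs; degenerate probability vectors collapse to a single bin, flagged by
the bin count.

## Evaluation

Confusion-matrix metrics carry Clopper–Pearson exact 95% CIs (beta-quantile
inversion; closed forms at the boundaries). Ratios with zero denominators
are reported as *undefined*, never coerced to 0. The paired MCG-vs-ECG
comparison is the exact binomial McNemar test, p = min(1, 2·P(X ≤ min(b,c)))
with b = c = 0 ⇒ p = 1 (a mid-p variant is available by flag, off by
default). Group contrasts use the effect size r = |Z|/√N from the
tie-corrected normal approximation of the Mann–Whitney statistic. The
abnormal-deflection screening rule flags CA_R strictly greater than a
threshold calibrated as the 97.5th percentile of healthy-control CA_R
(reference value 62°).

The ECG comparator is a Spiegelhalter–Knill–Jones additive score: per
finding, weights ln LR(present) and ln LR(absent) with add-½ smoothing
(which also keeps one-class findings finite, flagged in the model); the
subject score is the prior log-odds plus the shrunken weight sum, with the
shrinkage factor estimated as the logistic-calibration slope of the raw
score clipped to [0, 1], and the operating threshold chosen by Youden on
training data. These details follow the original SKJ methodology; all are
configuration-exposed.

## Problem sizes and determinism

Every randomised operation takes an explicit integer seed; there is no
global random state, and fixed seeds reproduce results bit-for-bit. The
shipped experiments use: 36-angle scans for the physics oracles; 100 null
replicates (n = 200, one null candidate — entry is a single 1-df test at
α = 0.05, so the only-forced-terms rate is near-nominal only for one or two
candidates) and 50 overfit replicates (n = 40, nine null candidates,
B = 200 resamples) for the modelling-behaviour suite; and train 300 / test
200 subjects for the end-to-end synthetic analogue. These sizes were chosen
as the smallest that make the Monte-Carlo assertions stable.

## Known limitations

- Single-dipole source: no multi-dipole or distributed-source inverse
  problems, no torso volume conductor; the simulated contrast is the
  quadrant shift, not patient-realistic morphology.
- NCD and the PCD normalisation are reconstructions; device vendors do not
  publish their formulas, so absolute NCD values are not comparable to any
  instrument's output.
- PD is defined in pixels and therefore tied to the recorded raster size.
- Cohort-level clinical performance figures cannot be reproduced without
  patient data; the end-to-end suite is a synthetic analogue with
  documented effect sizes, not a reproduction.
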