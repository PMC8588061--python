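# Methods

## Energy-balance heat model

The model assumes a resting subject in thermal equilibrium: metabolic heat
production equals surface heat dissipation, which is decomposed into
radiation, convection and evaporation,

    H = R + C + E
    R = ε σ Tr⁴                       radiative flux
    C = 2.38 (tw − ts)^1.25           convective flux
    E = 3.054 (0.256 tw − 3.37)(1 − He)   evaporative flux

all in W/m². Parameters and units:

| symbol | meaning | unit | default / range |
|---|---|---|---|
| Tr | radiometric wrist temperature | K | measured; fallback tw + 273.15, explicit and flagged |
| tw | wrist skin temperature | °C | must exceed 3.37/0.256 ≈ 13.16 °C |
| ts | ambient temperature | °C | must not exceed tw (see below) |
| He | ambient relative humidity | fraction in [0, 1] | (1 − He) factor implies fraction, not percent |
| ε  | skin emissivity | — | 0.96 (skin is near-black in the thermal IR) |
| σ  | Stefan–Boltzmann constant | W m⁻² K⁻⁴ | 5.67×10⁻⁸ |
| 2.38, 1.25 | convective transfer coefficient and exponent | W m⁻² K⁻¹·²⁵ | Newton cooling with hc = 2.38 Δt^0.25 |
| 3.054 | fused latent-heat × skin-permeability constant | — | never split into its factors; configurable as one number |
| 0.256, 3.37 | linearized saturation vapour pressure at skin temperature | kPa/°C, kPa | Psk = 0.256 tw − 3.37 |

Assumptions and consequences:

* The radiative term uses the absolute fourth power of Tr with no ambient
  exchange term (no Tr⁴ − Ta⁴). This is implemented exactly as stated in
  the model definition; it makes R the dominant term (~450–520 W/m² at
  physiological temperatures) and strictly increasing in Tr.
* The convective term takes a fractional power of (tw − ts) and is
  therefore undefined for an ambient warmer than the skin. The model
  assumes net heat loss; `convective_heat` raises a flagged out-of-model
  error for tw < ts, with an opt-in `allow_signed=True` mode returning
  −2.38 |Δt|^1.25 for exploratory use only.
* Units are never guessed: the dataset schema embeds them in column names
  (`Tr_K`, `tw_C`, `He_frac`, …) and the sensor-frame validator rejects
  out-of-domain values naming the offending field.
* H is used as a regression feature, so no body-surface-area scaling is
  applied; any constant scale is absorbed by the regression coefficients.

## PPG processing

The pulse detector band-passes the channel at 0.5–8 Hz (2nd-order
Butterworth, zero-phase `sosfiltfilt` with ~3 s edge padding), then keeps
local maxima separated by at least Fs·60/220 samples (220 bpm ceiling) with
prominence at least 40% of the filtered peak-to-peak range — enough to
reject dicrotic waves while keeping the detector deterministic and free of
tuning per record. Heart rate uses only the peak count and the first/last
peak positions, so it is insensitive to beat-shape details.

The perfusion ratio is the classic pulse-oximetry ratio of ratios. Beat
windows are delimited by the infrared channel's peaks (the stronger channel
in reflective probes); within each window AC is peak-to-trough amplitude,
averaged across beats, and DC is the channel mean over the record. A
channel with no pulsation of its own yields AC = 0 (and hence r = 0 for a
flat red channel) rather than noise-driven extrema.

Saturation follows the two-wavelength Beer–Lambert inversion with
oxyhemoglobin coefficients K1 and deoxyhemoglobin coefficients K2 at
660/880 nm. The implementation enforces K2_red > K1_red and K1_ir > K2_ir,
which is exactly the condition making SpO₂ strictly decreasing in r between
the pure-oxy (r = K1_red/K1_ir → 100%) and pure-deoxy (r = K2_red/K2_ir →
0%) limits. Default coefficients come from tabulated hemoglobin extinction
spectra, but they are configuration, not calibration: all tests construct
their own coefficient sets, and slightly out-of-range r clamps to [0, 100]%
with a warning instead of erroring on sensor noise.

## Regression models

**MPR4.** With x1 = H, x2 = SpO₂, x3 = HR, x4 = BF, the design holds the 15
products of distinct predictors (4 linear, 6 pairwise, 4 triple, 1
quadruple) in a fixed documented order, with an intercept; no squared or
cubed pure powers are generated, which limits collinearity. The fit is
ordinary least squares via a pinv-based solver. Two guards apply: the fit
refuses n ≤ 45 (three observations per variable on 15 variables is the
minimum the design justifies), and it refuses a rank-deficient design,
naming the collinear columns. The rank test runs on unit-normed columns:
raw interaction products span ~8 orders of magnitude at physiological
scales, and an unscaled SVD rank test would flag numerically harmless
scaling as deficiency while the stabilized solver handles it.

**BPNN.** A feedforward network with Nin = 4 inputs, one hidden layer of
Nhid = 2·Nin + 1 = 9 hyperbolic-tangent units, and a linear output — 55
weights in total. Inputs are standardized and the target mapped to [−1, 1]
with training-set statistics stored in the results object. Training is
damped Levenberg–Marquardt on the squared-error objective with a ridge
penalty 0.5·α‖θ‖² (default α = 0.5 on the standardized scale), implemented
as augmented residuals √α·θ. The damping factor starts at 10⁻², divides by
10 on an accepted step and multiplies by 10 on a rejected one; training
stops on a gradient-norm or relative-improvement tolerance (10⁻⁸), an
absolute cost goal, damping exhaustion, or 1000 accepted steps (a
convergence flag and the per-step accepted cost history are kept).
Weight decay is the effective regularizer here because LM reaches a
training minimum in a handful of near-Newton steps — with 55 parameters
against ~100 noisy training records an unpenalized fit memorizes noise
before validation-based early stopping can intervene. Optional seeded
validation early stopping remains available (`validation_fraction`,
off by default). Initial weights are drawn uniformly (scaled by fan-in)
from a generator seeded by `seed`, making fits bit-reproducible.

**Hold-out protocol.** A seeded permutation splits records into train/test;
the default training fraction is 118/211, the calibration share of the
emulated 211-record protocol (yielding 118 train / 93 test records on the
default cohort).

## Evaluation

mARD, Pearson CORR, RMSE are standard. Two MAD variants are reported side
by side: `mad_printed` is the mean absolute deviation of the predictions
about their own mean (a spread measure that never consults the reference),
`mad_conventional` is mean |Y − X|; both definitions circulate in the
glucose-monitoring literature and only coincide for unbiased predictors, so
the report carries both, explicitly labelled. SEP is defined as the sample
standard deviation of the residuals Y − X about their mean (divisor n − 1,
configurable to n) — a spread, not a bias, measure.

The Clarke error grid is computed in mg/dL (inputs in mmol/L convert at
18.016) with the canonical 1987 piecewise boundaries encoded as explicit
inequalities; the zone-A relative-deviation boundary is inclusive at 20%
("no more than 20%" belongs to A), and the low-glucose branch of zone A
covers pairs with both values below 70 mg/dL. A second, independently coded
transcription of the grid lives in the test suite and must agree point for
point on random pairs.

## Synthetic cohort

The generator emulates the structure of a 211-record meal-protocol study on
healthy adults: per meal series, a fasting baseline (normal, mean 5.2,
sd 0.4 mmol/L) plus a gamma-shaped postprandial bump (log-normal amplitude,
peak 30–60 min after the meal) sampled 30 min before and 30/60/90/120 min
after the meal; reference glucose is clipped to [4.1, 10] mmol/L, the
healthy range the protocol targets. Vitals draw uniformly from resting
ranges (SpO₂ 94–99%, HR 55–100 bpm, BF 20–80 perfusion units); ambient
conditions from 20–30 °C and 20–80% humidity.

The ground-truth relation BG = F(H, SpO₂, HR, BF) is explicit and
configurable:

* `mpr4-span` (default): a fixed coefficient vector on the interaction
  terms, affine in H, so the polynomial model can recover it exactly and
  zero-noise end-to-end runs measure pure pipeline error;
* `saturating`: a logistic curve in H (b0 = 3.3, b1 = 7.6, h0 = 525,
  hs = 6 W/m²) plus small linear vital terms, chosen so the glucose range
  maps inside the logistic image and the demanded H stays within the energy
  model's reachable envelope (~455–620 W/m² under the ambient draw ranges).
  Its curvature in H is outside the interaction-polynomial span, giving the
  network a genuine nonlinearity to exploit. (Note hs only reparameterizes
  H affinely, so its exact value does not alter polynomial lack-of-fit.)

For each record the generator inverts F for the heat H the true glucose
demands, draws (ts, He, radiometric offset), and solves the energy balance
for tw by Brent root finding on the monotone heat-vs-tw map; draws that
cannot bracket the target are resampled (bounded retries, then an error).
The PPG waveform is a periodic two-lobe pulse template whose beat rate is
the target HR and whose AC/DC amplitudes are set — with an exact correction
for the template's mean — so the measured ratio of ratios maps back to the
target SpO₂. Observation noise is multiplicative Gaussian on the reference
glucose only (default sd 5%; metabolic observations scale with level),
applied after the truth is fixed and re-clipped to the glucose range.

What the cohort does *not* emulate: motion artifacts, probe-contact and
ambient-light disturbance, sensor drift, inter-subject calibration
differences, circadian structure, or any diabetic-range (>10 mmol/L)
glucose. Passing recovery tests therefore demonstrates correctness of the
computational chain under the model's own assumptions, not clinical
accuracy on real wrists.

## Problem sizes and numerical choices

Tests and the acceptance script run the pipeline at its native study size
(211 records, 10 s waveforms at 100 Hz; PPG-heavy checks use 20–60-record
subsets), which keeps the full suite in the tens of seconds on one CPU.
Root finding uses Brent's method at xtol 10⁻¹⁰; the energy-model oracle
equivalence is asserted at 10⁻¹² relative; SpO₂ forward/inverse round trips
at 10⁻⁹ absolute; HR recovery at ±1 bpm for 40–180 bpm, Fs ≥ 100 Hz,
≥ 10 s records. Degenerate inputs fail loudly and specifically: flat PPG
(insufficient pulsatility), saturated air (E = 0), sub-range skin
temperature (negative vapour pressure), non-finite features (named row and
field), constant series (undefined correlation).

## Known limitations

* The energy model is steady-state; transient thermal dynamics after
  posture changes or airflow shifts are out of scope.
* The BPNN's weight-decay strength is a fixed default, not evidence-tuned
  per dataset; heavy-noise or very small cohorts may prefer a different α.
* SEP lacks a universally agreed formula in the literature; the residual
  standard deviation used here is one documented convention.
* The Clarke grid's upper-right regions (above ~180 mg/dL reference) are
  never exercised by the default healthy-range cohort.
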