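# Methods

## Tissue model and photon transport

Skin is a two-layer plane-parallel slab: an epidermis of 0.06 mm carrying
melanin and a dermis of 4.94 mm carrying oxygenated and deoxygenated
hemoglobin, both with refractive index 1.4 over air. Diffuse reflectance is
the fraction of a normally incident pencil beam re-emitted from the top
surface after multiple scattering, excluding the specular component
(measurement setups cross polarizers to suppress it, and the simulator
tallies it separately).

The transport kernel is a standard weight-based photon random walk:
exponential step sampling on the total attenuation, weight deposition
w·μa/μt at each interaction, Henyey-Greenstein scattering, statistical
Fresnel reflection at the external boundaries (index-matched internal
boundary) and a laterally infinite geometry that reduces the photon state
to depth and direction cosine. Two numerical choices matter:

- **Termination.** When the weight falls below 10⁻⁴ the photon is killed
  and its residual weight added to the absorbed tally. Unlike Russian
  roulette, this conserves energy exactly in every realization — the
  package guarantees reflected + transmitted + absorbed + specular equals
  the launched weight to floating-point rounding (verified at ≤10⁻⁶
  relative) — at the cost of a bias bounded by the 10⁻⁴ threshold, far
  below Monte Carlo noise at any photon count used.
- **Similarity-transformed scattering.** The default geometry uses the
  reduced scattering coefficient with isotropic phase function
  (g = 0, μs = μs′) rather than explicit anisotropic sampling with
  g = 0.9. By the similarity relation the total diffuse reflectance is
  nearly invariant (≤0.024 absolute difference against HG sampling at
  g = 0.9 in our checks, largest in the blue) while the step count drops
  roughly eightfold. Explicit anisotropy remains available via
  `default_skin_geometry(g=0.9)` and is exercised in the tests. Because
  the same forward model generates both the calibration reference set and
  any simulated measurements, this representation choice cancels out of
  the calibrated pipeline.

Scattering spectra follow the power law μs′(λ) = μs′(500 nm)·(λ/500)^−b
with μs′(500) = 6.67 mm⁻¹, b = 1.2 (epidermis) and μs′(500) = 4.53 mm⁻¹,
b = 1.29 (dermis), typical published values for skin. Absorption uses
molar extinction tables for oxy-/deoxy-hemoglobin resampled to the
400–700 nm, 10 nm grid and converted to mm⁻¹ per vol% assuming whole blood
(150 g/L, 64500 g/mol), plus the λ^−3.33 melanosome power law for melanin.
The kernel was validated against an independently coded
diffusion-approximation oracle for a semi-infinite matched-boundary medium
at μs′/μa = 100 (agreement within 3 %).

## Colorimetry and the concentration regression

Reflectance spectra are integrated against the CIE 1931 2° observer under
D65 (both configurable), normalized so a perfect reflector has Y = 100.
The calibration matrix N₂ is the least-squares affine map
[1, X, Y, Z] → [C_m, C_HbO, C_HbR] fitted on 300 simulated spectra whose
concentrations are drawn by a seeded Latin hypercube over C_m ∈ [1, 10],
C_HbO ∈ [0.1, 5], C_HbR ∈ [0.1, 5] vol%. The affine 3×4 form (with
constant term) is used; negative estimates are clamped to zero and
flagged, never silently.

**Known limitation.** Over these decade-wide training ranges the
reflectance response is close to exponential in the chromophore contents,
and three broad spectral bands barely separate oxy- from
deoxy-hemoglobin (their green-band absorptions are similar and the
discriminating red-band absorption is small). An affine map therefore
cannot reach held-out R² ≥ 0.9 for every chromophore: measured values are
roughly 0.84–0.88 (melanin), 0.67–0.79 (C_HbO), 0.89–0.91 (C_HbR),
limited by model bias rather than Monte Carlo noise (they do not improve
with more photons). Total hemoglobin C_HbT = C_HbO + C_HbR — the quantity
the downstream analysis actually uses — recovers better, and *temporal
changes* of C_tb around a working point, which drive every hemodynamic
metric, are captured up to an affine factor that cancels in band-power
ratios and percent changes.

## Camera model

N₁ is a pure 3×3 linear map RGB → XYZ (no intercept), fitted by least
squares over the 24 chart patches; sensors are assumed linear (a gamma
hook exists but is off by default). Flat-field correction divides by the
white-diffuser response scaled by its 0.99 reflectance. Patch-mean
extraction from chart images is the caller's job.

## Signal processing

All band-passes are 6th-order Butterworth filters applied forward-backward
(zero phase, squared magnitude response). Bands: BVP 0.7–3 Hz, vasomotion
0.009–0.2 Hz, beat detection 0.7–2.5 Hz. Band power is the trapezoidal
integral of the rectangular-window one-sided periodogram over the band;
with this convention an in-band unit sinusoid integrates to 0.5. The
0.009 Hz edge has an onset transient that decays over roughly two minutes;
recordings shorter than two periods of the low edge trigger a warning and
their vasomotion power is leakage-limited.

Beats are local maxima of the 0.7–2.5 Hz signal separated by a 0.4 s
refractory period and exceeding 30 % of the running amplitude envelope
(smoothed analytic-signal magnitude), with parabolic sub-sample
refinement; all three constants are arguments. Intervals outside
300–2000 ms are flagged and excluded from PRV. For PRV the *uneven*
interval series feeds a Lomb-Scargle periodogram on 0.01–0.5 Hz (scaled to
coincide with the classical periodogram density on even sampling); the
0.4 Hz low-pass smoothing path interpolates intervals to a uniform 4 Hz
grid first and is available as an alternative input. LF is 0.04–0.15 Hz
and HF 0.15–0.4 Hz, normalized by total power in 0.04–0.4 Hz; a vanishing
HF integral makes the LF/HF ratio an explicit undefined state, never
infinity. The LF lower edge defaults to 0.04 Hz (0.01 Hz selectable).

Validation metrics are reusable operations: the de Haan-style SNR (power
in windows around the heart-rate fundamental and first harmonic versus the
rest of 0.7–4 Hz), the MAE of min-max-normalized waveforms, the spectral
heart-rate error and the Pearson correlation of matched inter-beat
intervals.

## Synthetic data

The generator is the package's study instrument, not a fixture. One
recording is

C_tb(t) = baseline + √s_p·A_p·pulse(t) + √s_v·A_v·sin(2πf_v t + φ) + ε(t),

where pulse(t) is a train of asymmetric two-Gaussian beat templates
(systolic peak at 30 % of the beat, diastolic shoulder at 65 %) whose
onsets come from an interval process with sinusoidal LF (0.1 Hz) and HF
(0.25 Hz) modulation; the HF depth is divided by the condition's LF/HF
shift factor. The template train is normalized so its 0.7–3 Hz band power
is exactly A_p²/2, which makes the pulse amplitude definition coincide
with the measured band power; the power scale factors s_p, s_v enter under
a square root. ε is white Gaussian sensor noise. All components, beat
times and parameters are stored as ground truth, and everything is seeded.

Defaults: baseline C_tb 5 vol% (60/40 oxy/deoxy split, all variation
carried by the oxygenated fraction), A_p = 0.5 vol%, A_v = 1.0 vol%,
f_v = 3 cycles/min, HR 65 BPM, modulation depths 0.03, noise σ = 0.05
vol%, 30 Hz frame rate. Cohort templates follow the three stress
experiments the package models: auditory (n = 10, 140 s per condition),
Stroop (n = 11, 360 s), mental arithmetic (n = 11, 120 s). Between-subject
parameters are log-normal; task effects are log-normal with arithmetic
mean 0.64 (pulse) and 0.50 (vasomotion) and between-subject SD 0.29 and
0.26, so cohort percent decreases disperse like the effects they emulate.
The amplitude coefficient of variation (0.3) was chosen so that a pooled
n = 32 cohort estimates the mean percent decrease to within a few
percentage points, as expected for a controlled-illumination protocol.

Rendered video is spatially uniform skin color (optionally a two-region
melanin pattern) through an affine concentration→XYZ model and a known
camera mixing matrix, plus per-pixel noise. What the generator does *not*
emulate: motion, illumination flicker, codec artifacts, spatial texture,
waveform-shape changes under stress — so passing tests demonstrate the
correctness of the measurement chain, not robustness to real-world video
degradation.

## Study analysis

Per-subject metrics are computed identically for both conditions. Task
summaries report means and SE = SD/√n; cross-task pooling is the
subject-count-weighted mean, which reproduces the published pooled cells
from the published per-task cells (one pooled LF/HF task cell differs in
the third significant figure, consistent with rounding of the printed
per-task entries). Percent change is computed on condition means — the
convention that reproduces the published 36 %/50 % headline decreases —
with the mean and SD of per-subject percent changes reported alongside.
Significance uses a two-sided paired t-test (each subject as their own
control; an unpaired variant is a flag) with no multiple-testing
correction, matching the design it mirrors.

## Problem sizes

Default photon count is 10⁵ per wavelength for one-off spectra; the
calibration round trip in the tests and the acceptance script uses 10⁴
photons per wavelength for 300 + 50 spectra (a few minutes on one core),
where Monte Carlo noise contributes ~0.3 % per XYZ channel — small against
the regression's model bias. Cohort-level claims use 20–50 seeded
replicates of the pooled 32-subject study.
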