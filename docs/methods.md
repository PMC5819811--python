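# Methods

`emfbio` implements the computational chain of a radiofrequency-exposure
study of human peripheral blood lympho-monocytes (PBLM): exposure
dosimetry in a reverberation chamber, single-cell Raman spectroscopy with
ratiometric DNA/protein markers, and mitochondrial bioenergetics. This
note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Dosimetry

A reverberation chamber is a large multimode metallic cavity whose
mechanically stirred field is statistically uniform and isotropic. The
number of resonant eigenmodes below the working frequency `f` follows the
closed-form Weyl-type count

    N = (8π/3)·a·b·d·(f/c)³ − (a+b+d)·(f/c) + 1/2,

valid when every cavity edge exceeds λ/2; the chamber operates correctly
when `N > 60` (strict inequality). The field inside a blood sample is the
externally measured rms field divided by a calibration ratio
(`E_out/E_in = 15` by default), and the specific absorption rate is
`SAR = σE_in²/ρ` with the whole-blood values σ = 1.250 S/m and
ρ = 1060 kg/m³.

Numerical conventions: `c` defaults to 3.00×10⁸ m/s, the rounded value
consistent with the three-digit chamber characterization (the CODATA value
changes the reported mode count); reported values round N to the nearest
integer, truncate λ to one decimal of cm, and round SAR to two decimals,
while all internal computation keeps full precision. The quarter-wave
antenna length is derived from the *truncated* wavelength (16.6/4 =
4.15 cm at 1.8 GHz), matching the hardware description convention.

## Synthetic data

No public single-cell Raman or oxygraph data exist for this exposure
protocol, so a seeded generator emulates both.

**Spectra.** A cell spectrum on a 700–1800 cm⁻¹ grid (default step
1 cm⁻¹, finer than the ~5 cm⁻¹/pixel instrument so that fit-quality limits
come from noise rather than discretization; a 5 cm⁻¹ instrument-faithful
mode is available via `grid_step`) is the sum of:

- Voigt bands at the catalogue positions (Gaussian σ = 4 cm⁻¹, Lorentzian
  γ = 3 cm⁻¹, FWHM ≈ 12 cm⁻¹, typical of cellular bands; the study gives
  no widths), with relative areas shaped on a nucleated blood cell probed
  over its nucleus;
- a degree-5 fluorescence continuum a few times the band heights;
- glass-substrate bands (893, 932, 964 cm⁻¹) and a weaker smooth substrate
  continuum, both *shared exactly* with the paired background record so
  that background subtraction cancels them;
- additive Gaussian detector noise, `noise_sd = 5×10⁻⁴` by default —
  S/N ≈ 100 on the strongest fingerprint bands, appropriate for a 3×20 s
  averaged confocal acquisition (the study reports only "good
  signal/noise"; this level makes marker-area recovery meaningfully
  testable without being trivially clean);
- per-band, per-cell lognormal jitter with cv = 0.05. The generator's
  "cell variability" is deliberately *per band*, not a single per-cell
  scale factor: a common scale factor is removed exactly by
  total-intensity normalization and would make between-cell ratio
  variance, and hence every group t-test, degenerate. With independent
  band jitter, marker-ratio cv ≈ √2·0.05 ≈ 7%.

An exposure scenario multiplies the DNA bands (785, 1092, 1578 cm⁻¹) by
an attenuation factor — 1.00 at 1 h (an exact null), 0.92 at 5 h, 0.88 at
12 h, 0.82 at 20 h — and the aromatic amino-acid band at 1615 cm⁻¹ by a
gain of 1.05 whenever the attenuation is active. These effect sizes are
synthetic, chosen to reproduce the qualitative signature of a cumulative
exposure effect (a control-minus-exposed ratio difference that is zero at
1 h and grows with exposure time); they are not measured values.

A fast ratio-level sampler (`sample_ratio_markers`) draws per-cell marker
ratios directly from the scenario truth (lognormal band jitter, no
spectrum synthesis or fitting). Simulation studies that need thousands of
replicate 20-vs-20 experiments — effect-direction recovery, type-I-error
calibration — use this path; the full spectrum → preprocess → fit → ratio
chain is exercised at the 100-spectrum scale, where it runs in about a
minute. What the ratio-level path does *not* test is fit-induced bias and
variance; the spectrum-level recovery test covers that separately.

**Respirometry.** Paired control/exposed oxygraph records per subject and
time point share a lognormal subject-level random effect
(`inter_subject_cv = 0.25`, reflecting the large inter-donor variability
of primary blood cells) and carry independent mean-one lognormal assay
noise (cv = 0.08). The control state has resting rate 2.0 nmol
O₂/min/10⁶ cells with an oligomycin-insensitive fraction of 0.35; the
rotenone-insensitive floor is 10% of the raw resting rate. Exposure
multiplies (resting, oligomycin) rates by (1.00, 1.00) at 1 h,
(1.00, 1.25) at 5 h, (1.50, 1.80) at 12 h and (1.55, 0.85) at 20 h —
the qualitative pattern of an early coupling impairment (raised leak)
followed by a compensatory respiration overshoot with restored coupling.
The uncoupled rate is 1.05× the resting rate (uncoupler restores
oligomycin-inhibited respiration to roughly resting levels).

## Spectral pretreatment

Three steps, in enforced order (`raw → background_subtracted →
baseline_removed → normalized`; out-of-order application raises):

1. **Background subtraction** — pointwise cell minus paired
   substrate/buffer record; backgrounds on a different grid are linearly
   interpolated onto the cell grid, extrapolation refused.
2. **Baseline removal** — a degree-5 polynomial fitted iteratively
   (ModPoly-style: refit on `min(spectrum, fit)` until the baseline
   changes by less than 10⁻⁴ of the intensity range, cap 100 iterations;
   non-convergence is flagged, never silent). The wavenumber axis is
   mapped to [−1, 1] before fitting for conditioning. The stated order
   (subtract first, then de-baseline) follows the described workflow; the
   polynomial is fitted to the peak-suppressed envelope because a plain
   fit would chase the Raman bands.
3. **Total-intensity normalization** — every channel divided by the
   signed sum over the full 700–1800 cm⁻¹ record (negative residual
   channels kept; a non-positive total is an error). Uniform grids use a
   plain channel sum, non-uniform grids trapezoidal weights. The step is
   idempotent and scale-invariant.

Group averages are pointwise means of normalized spectra with a common
group label.

Known property of the iterative polynomial scheme: the min-clipping is a
downward ratchet, so the converged baseline sits slightly *below* the true
continuum wherever band tails overlap, leaving a small positive pedestal
(∼10⁻⁴–10⁻³ of the band heights per channel) in the residual spectrum.
This is why peak areas must be extracted by profile fitting with a local
baseline (below), not by summing channels.

## Voigt deconvolution

Each spectrum is deconvolved in two windows, 700–1150 and
1530–1750 cm⁻¹; the 1150–1530 cm⁻¹ stretch is excluded by default because
its nucleic-acid features (~1416, 1488 cm⁻¹) are overwhelmed by the broad
protein/lipid CH₂ envelope near 1450 cm⁻¹ (an override exists for
exploration). The model per window is

    y(ν) = Σ_k A_k · V(ν; c_k, σ_k, γ_k) + Σ_j b_j T_j(t),

with area-parameterized Voigt profiles (scipy's Faddeeva-based
`voigt_profile`) at the catalogue band positions and a 4-term Chebyshev
(cubic) residual baseline. A constant offset alone proved insufficient:
the pedestal left by the upstream polynomial correction varies smoothly
across a window and, uncorrected, biased marker areas by up to ~18%
(noiseless); the cubic term reduces the noiseless median marker-area
error to ~0.3%. Going beyond cubic buys nothing and starts trading with
peak wings.

Numerical choices:

- Areas are nonnegative *by parameterization* (the optimizer works on u
  with A = u²), not by clipping.
- Centers are bounded to nominal ±8 cm⁻¹ and widths to σ ∈ [2.125, 12],
  γ ∈ [0, 12] cm⁻¹ (component FWHM roughly 5–45 cm⁻¹), preventing the
  main failure mode of crowded windows: two components swapping identity.
  If two components still collapse onto one center (< 1 cm⁻¹ apart), the
  lower-area one is dropped and the window refit once.
- The trust-region solver uses an analytic Jacobian derived from the
  Faddeeva function (w′(z) = 2i/√π − 2zw(z)), which makes a 13-component
  window fit ~50× cheaper than finite differencing.
- Intensities are rescaled to O(1) internally (normalized spectra have
  ~10⁻⁴ channel values, which defeats the solver's relative tolerances).
- The 56-parameter window problem has a long, flat valley: the solver is
  capped at 250 iterations, and on hitting the cap a short restart checks
  whether the residual still improves by more than 1%; if not, the fit is
  flagged converged — plateau stagnation at the noise floor is not
  optimizer failure. The fit is deterministic given data and
  configuration (fixed initialization, no random restarts).
- `peak_area` looks up the fitted component nearest a nominal catalogue
  center within ±8 cm⁻¹ and errors if none exists; a missing marker is
  recorded as absent, never as zero.

"Intensity ratio" is taken literally as the ratio of fitted Voigt *areas*
(not heights).

## Ratio markers and statistics

Three scale-free markers per cell: I785/I1003 and I1092/I1003 (DNA
backbone/phosphate vs phenylalanine) and I1578/I1615 (DNA base ring
breathing vs aromatic amino-acid C=C). Group comparisons use a two-sample
two-tailed t-test on per-cell ratios — classic pooled-variance Student by
default (matching the named test), Welch by flag. Differences follow the
control-minus-exposed convention, so DNA signal loss in exposed cells is
a positive difference. Zero pooled variance is handled as a degenerate
case (p = 1 for equal means, p → 0 otherwise) rather than NaN.

Multiplicity: the significance flag applies Bonferroni over the
3 markers × 4 exposure times family (12 comparisons, the implementer's
choice of family); raw p-values are always reported unchanged. A one-way
ANOVA across exposure times is provided as a secondary check. Per-cell
ratios are the default unit of analysis; per-experiment means can be fed
to the same comparison functions for mean±SEM-style summaries.

## Bioenergetics

Oxygraph rates are corrected by subtracting the rotenone-insensitive
(non-mitochondrial) rate and dividing by the cell number (10⁶-cell
units). A rotenone rate exceeding a raw rate — possible with assay noise —
would produce a physically meaningless negative mitochondrial rate; it is
clamped to zero with a logged warning. Derived metrics: RCR = OCRr/OCRo,
OCR_ATP = OCRr − OCRo (exact by construction), leak = OCRo/OCRr
(= 1/RCR). The uncoupled rate OCRu is carried through for completeness
but feeds no derived metric.

Exposed samples are normalized to the paired control of the *same subject
and incubation time* (pairing is mandatory; unpaired inputs are rejected
rather than averaged) — this removes the dominant inter-donor variance.
Because control-normalized quantities are ratios of positive noisy
values, their natural symmetry is multiplicative: under a null scenario
they are centered on 1 geometrically (zero-mean in log), and the
null-centering test is therefore a t-test on log-normalized values. An
arithmetic-mean test would reject any multiplicative noise model for a
bias of order cv², which is a property of ratios, not of the pipeline.

Enzyme activities follow Beer–Lambert: activity =
slope/(ε·ℓ) × V_assay × dilution / n_cells in nmol/min/10⁶ cells, with
ε₅₅₀ = 19.1 mM⁻¹cm⁻¹ (ferro-cytochrome c, cytochrome c oxidase assay) and
ε₄₁₂ = 13.6 mM⁻¹cm⁻¹ (TNB, citrate synthase assay). The COX/CS ratio
serves as a mitochondrial-mass-independent index of respiratory capacity.

## What the tests do and do not show

The synthetic generator encodes the statistical structure the analysis
assumes: Voigt bands on a smooth continuum, scale-free ratios,
multiplicative cell and donor variability, paired designs. Passing tests
therefore demonstrate that the pipeline recovers known effects of that
structure at realistic noise — they do not validate the biological effect
sizes, the absolute rates, or the study's p-values, which depend on
unreleased donor data. Problem sizes used by the heavier checks — 100
spectra for area recovery, 200 simulated experiments for effect
direction, 1000 for type-I calibration and null centering — were chosen
as the smallest giving stable verdicts for the statistical tolerances
involved.

Known limitations: no cosmic-ray despiking, wavenumber calibration or
detector-response correction; no automatic peak detection (catalogue
driven only); no mixed-effects modelling of donor variability; oxygraph
traces are assumed already segmented into rates.
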