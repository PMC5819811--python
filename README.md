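# emfbio

Dosimetry, single-cell Raman deconvolution and mitochondrial
bioenergetics metrics for radiofrequency-exposure studies of human blood
cells.

Studies that expose peripheral blood lympho-monocytes (PBLM) to a
1.8 GHz electromagnetic field inside a reverberation chamber need three
computational stages, and this package implements all of them as a tested
library with a thin CLI:

1. **Dosimetry** — eigenmode count of the chamber
   `N = (8π/3)abd(f/c)³ − (a+b+d)(f/c) + ½` with the `N > 60` validity
   rule, internal field `E_in = E_out/15` from the calibration ratio, and
   specific absorption rate `SAR = σE_in²/ρ`.
2. **Single-cell Raman analysis** — background subtraction, iterative
   degree-5 polynomial fluorescence removal, total-intensity
   normalization, Voigt-profile deconvolution of the 700–1150 and
   1530–1750 cm⁻¹ windows, and the three scale-free DNA/protein markers
   I₇₈₅/I₁₀₀₃, I₁₀₉₂/I₁₀₀₃ and I₁₅₇₈/I₁₆₁₅ with two-sample t-tests
   (Bonferroni-corrected flags) and exposure-time trend analysis.
3. **Bioenergetics** — rotenone-corrected, cell-normalized oxygen
   consumption rates, RCR = OCRr/OCRo, OCR_ATP = OCRr − OCRo, proton-leak
   fraction, pairwise control normalization, and Beer–Lambert enzyme
   activities (citrate synthase, cytochrome c oxidase).

Because no such single-cell dataset is public, a seeded synthetic-data
generator (`emfbio.synthetic`) emulates both the spectra and the
respirometry cohorts with the statistical structure the analysis assumes,
so every stage is testable end to end. See `docs/methods.md` for models,
parameter defaults and design decisions.

## Worked example

```python
import warnings, numpy as np
import emfbio as eb
from emfbio.peaks import WINDOW_LOW, WINDOW_HIGH, fit_region
from emfbio.preprocess import preprocess
from emfbio.ratiometrics import compare_groups, compute_ratios
from emfbio.synthetic import SpectrumScenario, generate_experiment

# exposure dosimetry of a 150 x 85 x 85 cm chamber at 1.8 GHz, 200 V/m
result = eb.run_dosimetry(
    eb.ChamberSpec(a=1.5, b=0.85, d=0.85, f=1.8e9),
    eb.FieldCalibration(e_out=200.0, ratio=15.0),
    eb.TissueProperties(sigma=1.250, rho=1060.0),
)
print(f"modes N = {result.n_modes_reported}, valid = {result.chamber_valid}")
print(f"lambda = {result.wavelength_reported_cm} cm, E_in = {result.e_in:.1f} V/m, "
      f"SAR = {result.sar_reported} W/kg")

# 20 control vs 20 exposed synthetic cells at 20 h, full pipeline
def marker_set(scenario, n=20, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cell, bg in generate_experiment(scenario, n, rng):
            norm, _ = preprocess(cell, bg)
            out.append(compute_ratios(fit_region(norm, WINDOW_LOW),
                                      fit_region(norm, WINDOW_HIGH),
                                      group=scenario.group,
                                      exposure_hours=scenario.exposure_hours))
    return out

ctrl = marker_set(SpectrumScenario(group="control"), seed=1)
expo = marker_set(SpectrumScenario(group="exposed", exposure_hours=20.0), seed=2)
for marker in ("I785/I1003", "I1092/I1003", "I1578/I1615"):
    c = compare_groups(ctrl, expo, marker, exposure_hours=20.0)
    print(f"{marker}: control {c.mean_control:.3f}, exposed {c.mean_exposed:.3f}, "
          f"difference {c.difference:+.3f}, p = {c.p_two_tailed:.2e}")
```

Output:

```
modes N = 1942, valid = True
lambda = 16.6 cm, E_in = 13.3 V/m, SAR = 0.21 W/kg
I785/I1003: control 0.887, exposed 0.717, difference +0.171, p = 2.15e-06
I1092/I1003: control 0.657, exposed 0.559, difference +0.098, p = 1.96e-05
I1578/I1615: control 1.258, exposed 1.040, difference +0.219, p = 3.82e-06
```

The chamber supports 1942 modes at 1.8 GHz (well above the 60-mode
validity threshold), the blood sample sees 13.3 V/m and absorbs
0.21 W/kg. The 20-hour exposure scenario attenuates the DNA bands by
0.82, and the recovered control-minus-exposed differences are positive
for all three markers — DNA signal lost relative to protein signal —
at p-values far below 0.05 for 20 cells per group.

The same chain is available from the shell:

```bash
emfbio dosimetry --a 1.5 --b 0.85 --d 0.85 --f 1.8e9 --e-out 200 --ratio 15
emfbio simulate --out sim/ --n-cells 20 --seed 1
emfbio preprocess --manifest sim/manifest.csv --out pre/
emfbio fit --manifest pre/preprocessed.csv --out peaks.csv
emfbio ratios --peaks peaks.csv --out ratios.csv
emfbio compare --ratios ratios.csv --out comparisons.csv
emfbio respiro --input sim/respirometry.csv --out respiro.csv
```

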