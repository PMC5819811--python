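"""Seeded synthetic data with the statistical structure the analysis assumes.

No single-cell Raman spectra or oxygraph traces are publicly available for
this kind of exposure experiment, so every pipeline stage is exercised on
synthetic records:

* **Spectra** — a sum of Voigt bands at the catalogue positions on a
  700-1800 cm^-1 grid, a smooth degree-5 fluorescence continuum, glass
  substrate bands (893/932/964 cm^-1) shared with a paired background
  record, additive Gaussian detector noise, and independent lognormal
  per-band cell-to-cell variability.  An exposure scenario attenuates the
  DNA bands (785, 1092, 1578 cm^-1) by a factor that decreases with
  exposure time and slightly boosts the aromatic amino-acid band at
  1615 cm^-1; the 1-hour scenario is an exact null.
* **Ratio markers** — per-cell marker ratios drawn directly from the
  scenario truth (lognormal band jitter, no spectral fit), for simulation
  studies that need thousands of replicate experiments.
* **Respirometry** — paired control/exposed oxygraph records sharing a
  subject-level random effect, with a rotenone-insensitive floor and
  multiplicative exposure effects on the resting and oligomycin rates.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .bioenergetics import EnzymeAssay, RespirometrySample
from .peaks import GLASS_CENTERS
from .ratiometrics import MARKERS, RatioMarkers
from .spectra import RamanSpectrum, SpectrumMeta

__all__ = [
    "SyntheticPeak",
    "SpectrumScenario",
    "RespirometryScenario",
    "DEFAULT_CELL_PEAKS",
    "generate_cell_spectrum",
    "generate_background_spectrum",
    "generate_experiment",
    "sample_ratio_markers",
    "generate_respirometry_cohort",
    "assay_for_activity",
]

#: DNA-related bands attenuated by exposure.
DNA_CENTERS = (785.0, 1092.0, 1578.0)
#: Aromatic amino-acid band slightly boosted by exposure.
PROTEIN_CENTER = 1615.0
#: Marker bands used by the ratiometric analysis.
MARKER_CENTERS = (785.0, 1003.0, 1092.0, 1578.0, 1615.0)


@dataclass(frozen=True)
class SyntheticPeak:
    center: float
    area: float
    sigma: float = 4.0        # Gaussian width, cm^-1
    gamma: float = 3.0        # Lorentzian half-width, cm^-1


# Relative band areas loosely shaped on a nucleated blood cell probed over
# the nucleus: strong phenylalanine (1003), CH2 envelope (1460) and
# Amide I (1665), clear DNA backbone/base bands.
DEFAULT_CELL_PEAKS: tuple[SyntheticPeak, ...] = tuple(
    SyntheticPeak(c, a) for c, a in (
        (725.0, 0.35), (747.0, 0.30), (785.0, 0.80), (830.0, 0.35),
        (853.0, 0.40), (1003.0, 0.90), (1031.0, 0.45), (1060.0, 0.50),
        (1092.0, 0.60), (1127.0, 0.35), (1173.0, 0.25), (1223.0, 0.35),
        (1260.0, 0.45), (1307.0, 0.50), (1341.0, 0.55), (1378.0, 0.35),
        (1416.0, 0.25), (1460.0, 1.20), (1488.0, 0.25), (1578.0, 0.60),
        (1615.0, 0.45), (1665.0, 1.10),
    )
)

DEFAULT_GLASS_PEAKS: tuple[SyntheticPeak, ...] = tuple(
    SyntheticPeak(c, a, 6.0, 4.0) for c, a in
    zip(GLASS_CENTERS, (0.25, 0.30, 0.35))
)

#: Exposure-time DNA-band attenuation: exact null at 1 h, then a loss that
#: deepens with exposure time.
DEFAULT_DNA_ATTENUATION: Mapping[float, float] = {
    0.0: 1.00, 1.0: 1.00, 5.0: 0.92, 12.0: 0.88, 20.0: 0.82,
}

# Degree-5 fluorescence continuum on the [-1, 1]-mapped axis: broad,
# positive, decaying toward high wavenumber, a few times the band heights.
DEFAULT_FLUORESCENCE = (1.2, -0.6, 0.25, -0.1, 0.05, -0.02)
# Weaker smooth continuum of the coated coverslip + PBS, shared by the
# cell record and its paired background.
DEFAULT_BACKGROUND = (0.4, -0.15, 0.05, 0.0, 0.0, 0.0)


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


@dataclass(frozen=True)
class SpectrumScenario:
    """Generating conditions for one group x exposure-time cell population."""

    group: str = "control"
    exposure_hours: float = 0.0
    peak_catalogue: tuple[SyntheticPeak, ...] = DEFAULT_CELL_PEAKS
    glass_peaks: tuple[SyntheticPeak, ...] = DEFAULT_GLASS_PEAKS
    dna_attenuation: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_DNA_ATTENUATION))
    protein_gain: float = 1.05
    fluorescence_coeffs: tuple[float, ...] = DEFAULT_FLUORESCENCE
    background_coeffs: tuple[float, ...] = DEFAULT_BACKGROUND
    # detector noise giving S/N ~ 100 on the strongest fingerprint bands,
    # typical of a 3 x 20 s averaged confocal acquisition
    noise_sd: float = 0.0005
    cell_variability_cv: float = 0.05
    grid_step: float = 1.0
    wn_min: float = 700.0
    wn_max: float = 1800.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in ("control", "exposed"):
            raise ValueError(f"group must be control|exposed, got {self.group!r}")
        att = dict(self.dna_attenuation)
        for h, a in att.items():
            if not 0.0 < a <= 1.0:
                raise ValueError(f"attenuation at {h} h must be in (0, 1], got {a}")
        if att.get(1.0, 1.0) != 1.0:
            raise ValueError("1 h exposure must be an exact null (attenuation 1)")
        hours = sorted(att)
        for a, b in zip(hours[:-1], hours[1:]):
            if att[b] > att[a] + 1e-12:
                raise ValueError("dna_attenuation must be non-increasing in exposure time")
        if not self.grid_step > 0:
            raise ValueError("grid_step must be > 0")
        lo, hi = self.wn_min, self.wn_max
        for pk in self.peak_catalogue:
            if not lo <= pk.center <= hi:
                raise ValueError(f"catalogue center {pk.center} outside grid [{lo}, {hi}]")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.wn_max - self.wn_min) / self.grid_step)) + 1
        return self.wn_min + self.grid_step * np.arange(n)

    def band_effect(self, center: float) -> float:
        """Multiplicative exposure effect on one band's area."""
        if self.group != "exposed":
            return 1.0
        att = dict(self.dna_attenuation).get(self.exposure_hours, 1.0)
        if center in DNA_CENTERS:
            return att
        if center == PROTEIN_CENTER and att < 1.0:
            return self.protein_gain
        return 1.0

    def expected_area(self, center: float) -> float:
        for pk in self.peak_catalogue:
            if pk.center == center:
                return pk.area * self.band_effect(center)
        raise KeyError(f"no catalogue band at {center} cm^-1")

    def true_ratio(self, marker: str) -> float:
        num_c, den_c, _, _ = MARKERS[marker]
        return self.expected_area(num_c) / self.expected_area(den_c)


def _poly_on_grid(grid: np.ndarray, coeffs: tuple[float, ...],
                  lo: float, hi: float) -> np.ndarray:
    t = 2.0 * (grid - lo) / (hi - lo) - 1.0
    return np.polynomial.polynomial.polyval(t, np.asarray(coeffs, dtype=float))


def _voigt_sum(grid: np.ndarray, peaks, areas) -> np.ndarray:
    from scipy.special import voigt_profile
    out = np.zeros_like(grid)
    for pk, a in zip(peaks, areas):
        out += a * voigt_profile(grid - pk.center, pk.sigma, pk.gamma)
    return out


def generate_cell_spectrum(
    scenario: SpectrumScenario,
    rng: np.random.Generator | None = None,
    sample_id: str = "cell",
    return_truth: bool = False,
):
    """One synthetic cell spectrum (raw state).

    Cellular band areas carry the scenario's exposure effect and an
    independent mean-one lognormal jitter per band; the glass bands and the
    substrate continuum are scenario constants, identical to the paired
    background record, so they cancel exactly under background subtraction
    at zero noise.  With ``return_truth`` the realized per-band areas are
    returned alongside the spectrum.
    """
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    grid = scenario.grid
    s = _lognormal_sigma(scenario.cell_variability_cv)
    if s > 0:
        jitter = rng.lognormal(-0.5 * s * s, s, size=len(scenario.peak_catalogue))
    else:
        jitter = np.ones(len(scenario.peak_catalogue))
    areas = np.array([
        pk.area * scenario.band_effect(pk.center) * j
        for pk, j in zip(scenario.peak_catalogue, jitter)
    ])
    y = _voigt_sum(grid, scenario.peak_catalogue, areas)
    y += _voigt_sum(grid, scenario.glass_peaks,
                    [pk.area for pk in scenario.glass_peaks])
    y += _poly_on_grid(grid, scenario.fluorescence_coeffs,
                       scenario.wn_min, scenario.wn_max)
    y += _poly_on_grid(grid, scenario.background_coeffs,
                       scenario.wn_min, scenario.wn_max)
    if scenario.noise_sd > 0:
        y = y + rng.normal(0.0, scenario.noise_sd, size=grid.size)
    spec = RamanSpectrum(
        grid, y,
        meta=SpectrumMeta(sample_id=sample_id, group=scenario.group,
                          exposure_hours=scenario.exposure_hours, kind="cell"),
    )
    if return_truth:
        truth = {pk.center: a for pk, a in zip(scenario.peak_catalogue, areas)}
        return spec, truth
    return spec


def generate_background_spectrum(
    scenario: SpectrumScenario,
    rng: np.random.Generator | None = None,
    sample_id: str = "background",
) -> RamanSpectrum:
    """Paired substrate/buffer record: glass bands + smooth continuum +
    noise, no cellular bands and no fluorescence."""
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    grid = scenario.grid
    y = _voigt_sum(grid, scenario.glass_peaks,
                   [pk.area for pk in scenario.glass_peaks])
    y += _poly_on_grid(grid, scenario.background_coeffs,
                       scenario.wn_min, scenario.wn_max)
    if scenario.noise_sd > 0:
        y = y + rng.normal(0.0, scenario.noise_sd, size=grid.size)
    return RamanSpectrum(
        grid, y,
        meta=SpectrumMeta(sample_id=sample_id, group=scenario.group,
                          exposure_hours=scenario.exposure_hours, kind="background"),
    )


def generate_experiment(
    scenario: SpectrumScenario,
    n_cells: int,
    rng: np.random.Generator | None = None,
) -> list[tuple[RamanSpectrum, RamanSpectrum]]:
    """n paired (cell, background) raw measurements from one scenario."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    out = []
    for i in range(n_cells):
        cell = generate_cell_spectrum(
            scenario, rng,
            sample_id=f"{scenario.group}-{scenario.exposure_hours:g}h-{i:03d}")
        bg = generate_background_spectrum(
            scenario, rng,
            sample_id=f"bg-{scenario.group}-{scenario.exposure_hours:g}h-{i:03d}")
        out.append((cell, bg))
    return out


def sample_ratio_markers(
    scenario: SpectrumScenario,
    n_cells: int,
    rng: np.random.Generator | None = None,
) -> list[RatioMarkers]:
    """Per-cell marker ratios drawn directly from the scenario truth.

    Each marker band's area is its expected value times an independent
    mean-one lognormal jitter (cv = ``cell_variability_cv``), and ratios
    are formed without synthesizing or fitting a spectrum — the fast path
    for simulation studies with thousands of replicate experiments.
    """
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    s = _lognormal_sigma(scenario.cell_variability_cv)
    expected = {c: scenario.expected_area(c) for c in MARKER_CENTERS}
    out = []
    for i in range(n_cells):
        if s > 0:
            jit = rng.lognormal(-0.5 * s * s, s, size=len(MARKER_CENTERS))
        else:
            jit = np.ones(len(MARKER_CENTERS))
        areas = {c: expected[c] * j for c, j in zip(MARKER_CENTERS, jit)}
        ratios = {
            name: areas[num] / areas[den]
            for name, (num, den, _, _) in MARKERS.items()
        }
        out.append(RatioMarkers(
            sample_id=f"{scenario.group}-{scenario.exposure_hours:g}h-{i:03d}",
            group=scenario.group, exposure_hours=scenario.exposure_hours,
            ratios=ratios,
        ))
    return out


#: Exposure effects on (resting, oligomycin) rates: leak rises at 5-12 h,
#: resting respiration overshoots ~1.5x at 12-20 h, leak drops below the
#: control at 20 h.
DEFAULT_OCR_EFFECTS: Mapping[float, tuple[float, float]] = {
    1.0: (1.00, 1.00),
    5.0: (1.00, 1.25),
    12.0: (1.50, 1.80),
    20.0: (1.55, 0.85),
}


@dataclass(frozen=True)
class RespirometryScenario:
    """Generating conditions for paired control/exposed oxygraph cohorts."""

    baseline_ocrr: float = 2.0          # nmol O2/min/10^6 cells at rest
    coupling_fraction: float = 0.35     # OCRo/OCRr of the control state
    uncoupled_factor: float = 1.05      # OCRu relative to OCRr
    effects: Mapping[float, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_OCR_EFFECTS))
    rotenone_fraction: float = 0.10     # rotenone-insensitive / raw resting
    inter_subject_cv: float = 0.25
    assay_cv: float = 0.08
    n_cells: float = 10.0               # 10^6-cell units per assay
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.baseline_ocrr >= 0:
            raise ValueError("baseline_ocrr must be >= 0")
        if not 0.0 < self.coupling_fraction < 1.0:
            raise ValueError("coupling_fraction must be in (0, 1)")
        if not 0.0 <= self.rotenone_fraction < 1.0:
            raise ValueError("rotenone_fraction must be in [0, 1)")
        for h, (sr, so) in dict(self.effects).items():
            if sr < 0 or so < 0:
                raise ValueError(f"effect shifts at {h} h must be >= 0")

    def null(self) -> "RespirometryScenario":
        """Same conditions with every exposure effect set to 1."""
        return replace(self, effects={h: (1.0, 1.0) for h in dict(self.effects)})


def _make_sample(scn: RespirometryScenario, c_r: float, c_o: float, c_u: float,
                 subject: str, group: str, hours: float) -> RespirometrySample:
    # rotenone-insensitive floor so that floor = fraction x raw resting rate
    f = scn.rotenone_fraction
    rot_percell = f / (1.0 - f) * c_r
    n = scn.n_cells
    return RespirometrySample(
        ocr_resting_raw=(c_r + rot_percell) * n,
        ocr_oligomycin_raw=(c_o + rot_percell) * n,
        ocr_uncoupled_raw=(c_u + rot_percell) * n,
        ocr_rotenone=rot_percell * n,
        n_cells=n, subject=subject, group=group, exposure_hours=hours,
    )


def generate_respirometry_cohort(
    scenario: RespirometryScenario,
    n_subjects: int,
    rng: np.random.Generator | None = None,
) -> list[tuple[RespirometrySample, RespirometrySample]]:
    """Paired (control, exposed) oxygraph records per subject x time point.

    Both members of a pair share the subject-level lognormal random effect
    (primary blood cells differ a lot between donors); each assay carries
    its own mean-one lognormal measurement noise.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    s_sub = _lognormal_sigma(scenario.inter_subject_cv)
    s_assay = _lognormal_sigma(scenario.assay_cv)

    def _noise() -> float:
        return rng.lognormal(-0.5 * s_assay**2, s_assay) if s_assay > 0 else 1.0

    pairs = []
    for j in range(n_subjects):
        u = rng.lognormal(-0.5 * s_sub**2, s_sub) if s_sub > 0 else 1.0
        subject = f"S{j:02d}"
        for hours, (shift_r, shift_o) in sorted(dict(scenario.effects).items()):
            base_r = scenario.baseline_ocrr * u
            base_o = scenario.coupling_fraction * base_r
            c_r = base_r * _noise()
            c_o = base_o * _noise()
            c_u = scenario.uncoupled_factor * base_r * _noise()
            e_r = base_r * shift_r * _noise()
            e_o = base_o * shift_o * _noise()
            e_u = scenario.uncoupled_factor * base_r * shift_r * _noise()
            pairs.append((
                _make_sample(scenario, c_r, c_o, c_u, subject, "control", hours),
                _make_sample(scenario, e_r, e_o, e_u, subject, "exposed", hours),
            ))
    return pairs


def assay_for_activity(
    activity: float,
    epsilon: float,
    n_cells: float = 5.0,
    assay_volume_ml: float = 1.0,
    dilution: float = 8.0,
    path_length: float = 1.0,
    cv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> EnzymeAssay:
    """Absorbance-kinetics record whose Beer-Lambert readout equals the
    given activity (nmol/min/10^6 cells), up to optional lognormal noise."""
    slope = activity * n_cells / (assay_volume_ml * 1000.0 * dilution) \
        * epsilon * path_length
    if cv > 0:
        rng = np.random.default_rng(0) if rng is None else rng
        s = _lognormal_sigma(cv)
        slope *= rng.lognormal(-0.5 * s * s, s)
    return EnzymeAssay(slope=slope, epsilon=epsilon, path_length=path_length,
                       assay_volume_ml=assay_volume_ml, dilution=dilution,
                       n_cells=n_cells)
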