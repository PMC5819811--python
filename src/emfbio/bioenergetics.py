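"""Mitochondrial respirometry metrics and spectrophotometric enzyme activities.

Oxygraph rates from intact cells (resting OCRr, oligomycin-inhibited OCRo,
uncoupled OCRu) are corrected for the rotenone-insensitive residual — the
non-mitochondrial part of oxygen consumption — and normalized to the cell
number, giving rates in nmol O2/min/10^6 cells.  From these:

* RCR       = OCRr / OCRo   (coupling of oxidative phosphorylation)
* OCR_ATP   = OCRr - OCRo   (respiration driving ATP synthesis)
* leak      = OCRo / OCRr   (proton-leak fraction, the reciprocal of RCR)

Exposed samples are expressed relative to the paired control of the same
subject and incubation time, which removes the large inter-individual
variability of primary blood cells.

Citrate synthase and cytochrome c oxidase activities come from linear
absorbance kinetics via Beer-Lambert (epsilon 13.6 mM^-1 cm^-1 for TNB at
412 nm and 19.1 mM^-1 cm^-1 for cytochrome c at 550 nm), normalized to
cell number.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "RespirometrySample",
    "CorrectedRates",
    "BioenergeticMetrics",
    "EnzymeAssay",
    "EPSILON_CYT_C_550",
    "EPSILON_TNB_412",
    "correct_and_normalize",
    "derive_metrics",
    "normalize_to_control",
    "enzyme_activity",
    "cox_cs_ratio",
]

#: Extinction coefficient of ferro-cytochrome c at 550 nm (mM^-1 cm^-1).
EPSILON_CYT_C_550 = 19.1
#: Extinction coefficient of TNB at 412 nm (mM^-1 cm^-1).
EPSILON_TNB_412 = 13.6


class PairingError(ValueError):
    """Control/exposed records do not belong to the same subject and time."""


@dataclass(frozen=True)
class RespirometrySample:
    """Raw oxygraph rates (nmol O2/min) for one assay of n_cells x 10^6 cells."""

    ocr_resting_raw: float
    ocr_oligomycin_raw: float
    ocr_uncoupled_raw: float
    ocr_rotenone: float
    n_cells: float                      # in units of 10^6 cells
    subject: str = ""
    group: str = "control"
    exposure_hours: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ocr_resting_raw", "ocr_oligomycin_raw",
                     "ocr_uncoupled_raw", "ocr_rotenone"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        if not self.n_cells > 0:
            raise ValueError(f"n_cells must be > 0, got {self.n_cells!r}")


@dataclass(frozen=True)
class CorrectedRates:
    """Rotenone-corrected, per-10^6-cell rates."""

    ocr_r: float
    ocr_o: float
    ocr_u: float
    subject: str = ""
    group: str = "control"
    exposure_hours: float = 0.0
    clamped: tuple[str, ...] = ()


def correct_and_normalize(s: RespirometrySample) -> CorrectedRates:
    """(raw - rotenone) / n_cells for each rate.

    A rotenone rate exceeding a raw rate (possible with assay noise) would
    yield a negative mitochondrial rate, which is physically meaningless:
    the corrected rate is clamped to 0 and the event flagged and warned.
    """
    out = {}
    clamped = []
    for key, raw in (("ocr_r", s.ocr_resting_raw),
                     ("ocr_o", s.ocr_oligomycin_raw),
                     ("ocr_u", s.ocr_uncoupled_raw)):
        value = (raw - s.ocr_rotenone) / s.n_cells
        if value < 0:
            warnings.warn(
                f"rotenone-insensitive rate {s.ocr_rotenone} exceeds raw {key} "
                f"({raw}); clamping corrected rate to 0", stacklevel=2)
            value = 0.0
            clamped.append(key)
        out[key] = value
    return CorrectedRates(**out, subject=s.subject, group=s.group,
                          exposure_hours=s.exposure_hours,
                          clamped=tuple(clamped))


@dataclass(frozen=True)
class BioenergeticMetrics:
    ocr_r: float
    ocr_o: float
    ocr_u: float
    rcr: float | None          # OCRr/OCRo; None when OCRo = 0
    ocr_atp: float             # OCRr - OCRo
    leak_fraction: float | None  # OCRo/OCRr; None when OCRr = 0
    subject: str = ""
    group: str = "control"
    exposure_hours: float = 0.0


def derive_metrics(rates: CorrectedRates) -> BioenergeticMetrics:
    """RCR, OCR_ATP and the proton-leak fraction from corrected rates."""
    rcr = rates.ocr_r / rates.ocr_o if rates.ocr_o > 0 else None
    leak = rates.ocr_o / rates.ocr_r if rates.ocr_r > 0 else None
    return BioenergeticMetrics(
        ocr_r=rates.ocr_r, ocr_o=rates.ocr_o, ocr_u=rates.ocr_u,
        rcr=rcr, ocr_atp=rates.ocr_r - rates.ocr_o, leak_fraction=leak,
        subject=rates.subject, group=rates.group,
        exposure_hours=rates.exposure_hours,
    )


_NORMALIZABLE = ("ocr_r", "ocr_o", "ocr_u", "ocr_atp", "rcr", "leak_fraction")


def normalize_to_control(
    exposed: BioenergeticMetrics,
    control: BioenergeticMetrics,
    metric: str,
) -> float:
    """Exposed metric divided by the paired control value.

    Pairing by (subject, exposure time) is mandatory; for ``leak_fraction``
    this is the within-assay OCRo/OCRr of the exposed sample divided by the
    same quantity of its control.
    """
    if metric not in _NORMALIZABLE:
        raise ValueError(f"unknown metric {metric!r}; one of {_NORMALIZABLE}")
    if exposed.subject != control.subject or exposed.exposure_hours != control.exposure_hours:
        raise PairingError(
            f"exposed ({exposed.subject}, {exposed.exposure_hours} h) and control "
            f"({control.subject}, {control.exposure_hours} h) are not a matched pair"
        )
    ev = getattr(exposed, metric)
    cv = getattr(control, metric)
    if ev is None or cv is None:
        raise ValueError(f"metric {metric!r} undefined on one member of the pair")
    if not cv > 0:
        raise ValueError(f"control {metric} = {cv} is not positive; cannot normalize")
    return ev / cv


@dataclass(frozen=True)
class EnzymeAssay:
    """Linear absorbance kinetics of a marker-enzyme assay."""

    slope: float               # absorbance change per min
    epsilon: float             # mM^-1 cm^-1
    path_length: float = 1.0   # cm
    assay_volume_ml: float = 1.0
    dilution: float = 1.0
    n_cells: float = 1.0       # in units of 10^6 cells

    def __post_init__(self) -> None:
        if not self.path_length > 0:
            raise ValueError("path_length must be > 0")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be > 0")
        if not self.n_cells > 0:
            raise ValueError("n_cells must be > 0")


def enzyme_activity(a: EnzymeAssay) -> float:
    """Beer-Lambert conversion of an absorbance slope to enzyme activity.

    slope/(epsilon*path) is the concentration rate in mM/min = nmol/uL/min;
    scaling by the assay volume (in mL, x1000 uL) and dilution and dividing
    by the cell number gives nmol/min/10^6 cells.
    """
    conc_rate_mM_per_min = a.slope / (a.epsilon * a.path_length)
    nmol_per_min = conc_rate_mM_per_min * a.assay_volume_ml * 1000.0
    return nmol_per_min * a.dilution / a.n_cells


def cox_cs_ratio(cox_activity: float, cs_activity: float) -> float:
    """Cytochrome c oxidase activity per unit citrate synthase activity
    (a mitochondrial-mass-independent index of respiratory capacity)."""
    if not cs_activity > 0:
        raise ValueError(f"citrate synthase activity must be > 0, got {cs_activity!r}")
    return cox_activity / cs_activity
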