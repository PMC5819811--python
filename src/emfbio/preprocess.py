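"""Spectral pretreatment: background subtraction, fluorescence baseline
removal, total-intensity normalization, group averaging.

The pipeline mirrors the standard single-cell Raman workflow: (1) subtract
the paired substrate/buffer background recorded next to each cell; (2)
remove the broad cell-autofluorescence and stray-light continuum, modelled
as a fifth-order polynomial fitted iteratively so that it hugs the
peak-free envelope rather than the peaks; (3) divide every channel by the
total spectral intensity, which normalizes away sampling-volume and
laser-power variation between cells.  Processed spectra from one group are
then averaged pointwise.

Step order is enforced through the spectrum's processing state: applying a
step out of order raises, it does not warn.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .spectra import RamanSpectrum, SpectrumMeta

__all__ = [
    "PipelineOrderError",
    "BaselineResult",
    "subtract_background",
    "remove_baseline",
    "normalize_total",
    "average_spectra",
    "preprocess",
]


class PipelineOrderError(RuntimeError):
    """A pretreatment step was applied out of order."""


class AlignmentError(ValueError):
    """Background grid cannot be aligned with the cell grid."""


class NormalizationError(ValueError):
    """Total spectral intensity is not positive."""


def _require_state(s: RamanSpectrum, expected: str, op: str) -> None:
    if s.state != expected:
        raise PipelineOrderError(
            f"{op} expects a {expected!r} spectrum, got {s.state!r}"
        )


def subtract_background(cell: RamanSpectrum, background: RamanSpectrum) -> RamanSpectrum:
    """Pointwise cell minus background.

    Background recorded on a different grid is linearly interpolated onto
    the cell grid; extrapolation beyond the background's range is refused.
    """
    _require_state(cell, "raw", "subtract_background")
    _require_state(background, "raw", "subtract_background")
    bw, bi = background.wavenumbers, background.intensities
    if np.array_equal(bw, cell.wavenumbers):
        bg = bi
    else:
        if bw[0] > cell.wavenumbers[0] + 1e-9 or bw[-1] < cell.wavenumbers[-1] - 1e-9:
            raise AlignmentError(
                f"background range ({bw[0]}, {bw[-1]}) does not cover the cell grid "
                f"({cell.wavenumbers[0]}, {cell.wavenumbers[-1]})"
            )
        bg = np.interp(cell.wavenumbers, bw, bi)
    return cell.with_intensities(cell.intensities - bg, state="background_subtracted")


@dataclass(frozen=True)
class BaselineResult:
    baseline: np.ndarray
    converged: bool
    n_iterations: int


def remove_baseline(
    s: RamanSpectrum,
    order: int = 5,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[RamanSpectrum, BaselineResult]:
    """Iterative polynomial baseline removal (ModPoly-style).

    A degree-``order`` polynomial is fitted to the spectrum, the spectrum
    is clipped from above at the fit, and the fit repeated; the polynomial
    thus migrates to the peak-free envelope, modelling fluorescence and
    stray light without chasing the Raman bands.  The wavenumber axis is
    affinely mapped onto [-1, 1] before fitting for conditioning.
    Convergence: max change of the fitted baseline below ``tol`` times the
    intensity range.  Non-convergence is flagged on the result, never
    silent.
    """
    _require_state(s, "background_subtracted", "remove_baseline")
    y = s.intensities
    if y.size < order + 1:
        raise ValueError(f"need at least {order + 1} points for a degree-{order} fit")
    w = s.wavenumbers
    t = 2.0 * (w - w[0]) / (w[-1] - w[0]) - 1.0
    scale = np.ptp(y)
    if scale == 0.0:
        scale = max(abs(y[0]), 1.0)
    y_work = y.copy()
    prev = None
    converged = False
    for it in range(1, max_iter + 1):
        coefs = np.polynomial.polynomial.polyfit(t, y_work, order)
        base = np.polynomial.polynomial.polyval(t, coefs)
        if prev is not None and np.max(np.abs(base - prev)) < tol * scale:
            converged = True
            break
        prev = base
        y_work = np.minimum(y_work, base)
    return (
        s.with_intensities(y - base, state="baseline_removed"),
        BaselineResult(baseline=base, converged=converged, n_iterations=it),
    )


def normalize_total(s: RamanSpectrum) -> RamanSpectrum:
    """Divide every channel by the total spectral intensity.

    The total is the signed sum over the full record (negative residual
    channels are kept, not clipped); a non-positive total is an error.
    Idempotent and invariant to overall intensity scale.
    """
    _require_state(s, "baseline_removed", "normalize_total")
    total = s.total_intensity()
    if not total > 0:
        raise NormalizationError(f"total spectral intensity {total} is not positive")
    return s.with_intensities(s.intensities / total, state="normalized")


def renormalize(s: RamanSpectrum) -> RamanSpectrum:
    """normalize_total for spectra already in the normalized state
    (used to show idempotence and when averaging drifts the total)."""
    total = s.total_intensity()
    if not total > 0:
        raise NormalizationError(f"total spectral intensity {total} is not positive")
    return s.with_intensities(s.intensities / total)


def average_spectra(group: list[RamanSpectrum]) -> RamanSpectrum:
    """Pointwise mean of normalized spectra from one group.

    Spectra on grids differing from the first one are linearly resampled
    (no extrapolation).  Mixed group labels are an error.
    """
    if not group:
        raise ValueError("cannot average an empty list of spectra")
    first = group[0]
    labels = {(s.meta.group, s.meta.exposure_hours) for s in group}
    if len(labels) > 1:
        raise ValueError(f"mixed groups in average: {sorted(labels)}")
    for s in group:
        _require_state(s, "normalized", "average_spectra")
    acc = np.zeros_like(first.intensities)
    for s in group:
        if np.array_equal(s.wavenumbers, first.wavenumbers):
            acc += s.intensities
        else:
            w = s.wavenumbers
            if w[0] > first.wavenumbers[0] + 1e-9 or w[-1] < first.wavenumbers[-1] - 1e-9:
                raise AlignmentError("spectrum grid does not cover the reference grid")
            acc += np.interp(first.wavenumbers, w, s.intensities)
    mean = acc / len(group)
    meta = replace(first.meta, n_averaged=len(group),
                   sample_id=f"mean[{first.meta.group},{first.meta.exposure_hours}h,n={len(group)}]")
    return RamanSpectrum(first.wavenumbers, mean, meta=meta, state="normalized")


def preprocess(
    cell: RamanSpectrum,
    background: RamanSpectrum,
    order: int = 5,
) -> tuple[RamanSpectrum, BaselineResult]:
    """Full pretreatment of one cell: subtract, de-baseline, normalize."""
    sub = subtract_background(cell, background)
    debased, diag = remove_baseline(sub, order=order)
    return normalize_total(debased), diag
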