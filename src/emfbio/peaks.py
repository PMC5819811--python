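"""Voigt-profile deconvolution of preprocessed Raman spectra.

Each analysis window is modelled as a sum of area-parameterized Voigt
profiles (Gaussian-Lorentzian convolutions) plus a low-order Chebyshev
residual baseline that absorbs what the global polynomial correction
leaves behind (the floor of overlapping Lorentzian tails).
The two default windows, 700-1150 and 1530-1750 cm^-1, bracket the bands
that can be attributed unambiguously to specific cellular components; the
crowded 1150-1530 cm^-1 stretch, dominated by the overlapping CH2
deformation envelope near 1450 cm^-1, is excluded by default.

Initial peak positions come from a fixed catalogue of band assignments
(DNA ring-breathing and phosphate modes, aromatic amino-acid modes,
glass-substrate modes, Amide I).  Centers are constrained to the nominal
position +/- a small tolerance and widths are bounded, which prevents the
classic failure mode of crowded-window deconvolution: two components
swapping identity.  Areas are kept nonnegative by construction: the
optimizer works on u with area = u**2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import voigt_profile as _voigt_unit, wofz

from .spectra import RamanSpectrum

__all__ = [
    "VoigtPeak",
    "RegionFit",
    "PeakCatalogue",
    "FitConfig",
    "DEFAULT_CATALOGUE",
    "WINDOW_LOW",
    "WINDOW_HIGH",
    "voigt_profile",
    "fit_region",
    "peak_area",
]

WINDOW_LOW = (700.0, 1150.0)
WINDOW_HIGH = (1530.0, 1750.0)

#: Band catalogue: nominal center (cm^-1) -> assignment.
#: n.a. = nucleic acids, p. = proteins, l. = lipids, c. = carbohydrates.
_CATALOGUE_ENTRIES = (
    (725.0, "ring breathing, n.a."),
    (747.0, "ring breathing, n.a."),
    (785.0, "O-P-O stretch + ring breathing, n.a."),
    (830.0, "O-P-O stretch, n.a. + ring breathing, Tyr"),
    (853.0, "O-P-O stretch, n.a. + ring breathing, Tyr"),
    (893.0, "glass substrate"),
    (932.0, "glass substrate"),
    (964.0, "glass substrate"),
    (1003.0, "symmetric ring breathing, Phe"),
    (1031.0, "C-H in-plane bend, Phe"),
    (1060.0, "C-O/C-C, c. + C-N stretch, p. + C-C stretch, l."),
    (1092.0, "PO2- stretch, n.a."),
    (1127.0, "C-N stretch, p. + C-O, c. + C-C stretch, l."),
    (1173.0, "C-H bend, Tyr"),
    (1223.0, "Amide III, p."),
    (1260.0, "Amide III, p."),
    (1307.0, "CH2 twist, l."),
    (1341.0, "CH3 deform/CH2 wag, p. and n.a."),
    (1378.0, "CH bend, Trp + ring breathing, n.a. + CH3 bend, l."),
    (1416.0, "ring breathing, n.a."),
    (1460.0, "CH2 scissor, l. and p."),
    (1488.0, "ring breathing, n.a."),
    (1578.0, "ring breathing, n.a."),
    (1615.0, "C=C, Tyr/Trp"),
    (1665.0, "Amide I, p. + C=C stretch, l."),
)

#: Centers of the glass-substrate bands (cancel after background subtraction).
GLASS_CENTERS = (893.0, 932.0, 964.0)


class PeakFitError(ValueError):
    """Invalid fitting input or degenerate peak model."""


@dataclass(frozen=True)
class VoigtPeak:
    """One fitted component: area-parameterized Voigt line."""

    center: float            # cm^-1
    area: float              # intensity x cm^-1, >= 0
    sigma: float             # Gaussian width (std dev), cm^-1
    gamma: float             # Lorentzian half-width, cm^-1
    at_bound: bool = False   # center pinned to its allowed window edge

    @property
    def fwhm(self) -> float:
        """Voigt FWHM via the Olivero-Longbothum approximation."""
        fg = 2.0 * np.sqrt(2.0 * np.log(2.0)) * self.sigma
        fl = 2.0 * self.gamma
        return 0.5346 * fl + np.sqrt(0.2166 * fl**2 + fg**2)


@dataclass(frozen=True)
class PeakCatalogue:
    """Nominal band centers with assignments; fits are catalogue-driven."""

    entries: tuple[tuple[float, str], ...] = _CATALOGUE_ENTRIES

    def centers_in(self, window: tuple[float, float]) -> tuple[float, ...]:
        lo, hi = window
        return tuple(c for c, _ in self.entries if lo <= c <= hi)

    def assignment(self, center: float) -> str:
        for c, a in self.entries:
            if c == center:
                return a
        raise KeyError(center)


DEFAULT_CATALOGUE = PeakCatalogue()


@dataclass(frozen=True)
class FitConfig:
    """Deconvolution bounds and optimizer settings.

    center_tol bounds each center to nominal +/- tol (the detector samples
    at ~5 cm^-1/pixel, so larger drifts would mean a mis-assigned band);
    sigma/gamma bounds keep component FWHMs roughly inside [5, 45] cm^-1.
    n_baseline is the number of Chebyshev terms of the per-window residual
    baseline (4 = cubic); the upstream degree-5 correction leaves a smooth
    residual of the overlapping-tail floor that a constant cannot absorb.
    """

    center_tol: float = 8.0
    sigma_bounds: tuple[float, float] = (2.125, 12.0)
    gamma_bounds: tuple[float, float] = (0.0, 12.0)
    sigma_init: float = 4.0
    gamma_init: float = 3.0
    n_baseline: int = 4
    max_nfev: int = 250
    duplicate_tol: float = 1.0   # fitted centers closer than this collapse
    ftol: float = 1e-12
    xtol: float = 1e-12


@dataclass(frozen=True)
class RegionFit:
    """Result of deconvolving one spectral window."""

    window: tuple[float, float]
    peaks: tuple[VoigtPeak, ...]
    baseline_coeffs: tuple[float, ...]
    residual_rms: float
    converged: bool
    n_evaluations: int
    dropped_centers: tuple[float, ...] = ()

    @property
    def offset(self) -> float:
        """Mean residual-baseline level of the window (leading Chebyshev
        coefficient)."""
        return self.baseline_coeffs[0]


def voigt_profile(x, center: float, sigma: float, gamma: float, area: float = 1.0):
    """Area-parameterized Voigt line shape.

    Integrates to ``area`` over the real line; reduces to a Gaussian for
    gamma=0 and to a Lorentzian for sigma=0.
    """
    if sigma < 0 or gamma < 0:
        raise PeakFitError("widths must be nonnegative")
    if sigma == 0 and gamma == 0:
        raise PeakFitError("degenerate profile: sigma and gamma both zero")
    return area * _voigt_unit(np.asarray(x, dtype=float) - center, sigma, gamma)


def peak_profile(x, peak: VoigtPeak):
    return voigt_profile(x, peak.center, peak.sigma, peak.gamma, peak.area)


_SQRT2 = np.sqrt(2.0)
_SQRT2PI = np.sqrt(2.0 * np.pi)
_ISQRTPI = 1.0 / np.sqrt(np.pi)


def _voigt_parts(x, c, s, g):
    """Unit-area Voigt profiles and their partial derivatives.

    Uses the Faddeeva function: V = Re[w(z)]/(sigma*sqrt(2*pi)) with
    z = (x - c + i*gamma)/(sigma*sqrt(2)) and w'(z) = 2i/sqrt(pi) - 2zw(z).
    Shapes (n_peaks, n_x).
    """
    sc = s[:, None]
    z = ((x[None, :] - c[:, None]) + 1j * g[:, None]) / (sc * _SQRT2)
    w = wofz(z)
    v = w.real / (sc * _SQRT2PI)
    wp = 2j * _ISQRTPI - 2.0 * z * w
    dvdx = (wp / (sc * _SQRT2)).real / (sc * _SQRT2PI)
    dvdg = -(wp / (sc * _SQRT2)).imag / (sc * _SQRT2PI)
    dvds = (wp * (-z / sc)).real / (sc * _SQRT2PI) - v / sc
    return v, dvdx, dvds, dvdg


def _initial_area(x: np.ndarray, y: np.ndarray, center: float, fwhm: float) -> float:
    idx = int(np.argmin(np.abs(x - center)))
    height = max(y[idx] - np.percentile(y, 10), 0.0)
    return max(height * fwhm * 1.064, 1e-12)   # Gaussian height-area relation


def fit_region(
    s: RamanSpectrum,
    window: tuple[float, float],
    catalogue: PeakCatalogue = DEFAULT_CATALOGUE,
    config: FitConfig = FitConfig(),
) -> RegionFit:
    """Nonlinear least-squares deconvolution of one window.

    The model is sum of Voigts (one per catalogue band inside the window)
    plus the low-order residual baseline.  If two components collapse onto the same
    center (closer than ``config.duplicate_tol``), the lower-area one is
    dropped and the window refit once.
    """
    if s.state != "normalized":
        raise PeakFitError(f"fit_region expects a normalized spectrum, got state {s.state!r}")
    lo, hi = window
    if lo < s.wavenumbers[0] - 1e-9 or hi > s.wavenumbers[-1] + 1e-9:
        raise PeakFitError(f"window {window} outside spectrum range "
                           f"({s.wavenumbers[0]}, {s.wavenumbers[-1]})")
    centers = catalogue.centers_in(window)
    if not centers:
        raise PeakFitError(f"catalogue has no bands inside window {window}")
    x, y = s.window(lo, hi)
    # normalized spectra have ~1e-4 channel intensities; rescale to O(1)
    # so the optimizer's relative tolerances behave, undo on output
    y_scale = float(np.max(np.abs(y)))
    if y_scale == 0.0:
        y_scale = 1.0
    return _fit_once(x, y / y_scale, y_scale, window, centers, config, dropped=())


def _fit_once(x, y, y_scale, window, centers, config, dropped) -> RegionFit:
    n = len(centers)
    nb = config.n_baseline
    if x.size < 4 * n + nb:
        raise PeakFitError(f"window has {x.size} points for {4 * n + nb} parameters")
    c0 = np.array(centers, dtype=float)
    t = 2.0 * (x - x[0]) / (x[-1] - x[0]) - 1.0
    basis = np.polynomial.chebyshev.chebvander(t, nb - 1)

    def unpack(p):
        return p[:n], p[n:2 * n], p[2 * n:3 * n], p[3 * n:4 * n], p[4 * n:]

    def residuals(p):
        u, c, s, g, b = unpack(p)
        v, _, _, _ = _voigt_parts(x, c, s, g)
        return (u**2) @ v + basis @ b - y

    def jacobian(p):
        u, c, s, g, b = unpack(p)
        v, dvdx, dvds, dvdg = _voigt_parts(x, c, s, g)
        a = (u**2)[:, None]
        jac = np.empty((x.size, 4 * n + nb))
        jac[:, :n] = (2.0 * u[:, None] * v).T
        jac[:, n:2 * n] = (-a * dvdx).T
        jac[:, 2 * n:3 * n] = (a * dvds).T
        jac[:, 3 * n:4 * n] = (a * dvdg).T
        jac[:, 4 * n:] = basis
        return jac

    fwhm0 = VoigtPeak(0.0, 0.0, config.sigma_init, config.gamma_init).fwhm
    u0 = np.sqrt([_initial_area(x, y, c, fwhm0) for c in c0])
    p0 = np.concatenate([
        u0, c0,
        np.full(n, config.sigma_init), np.full(n, config.gamma_init),
        np.zeros(nb),
    ])
    # linear solve for the initial baseline given the initial peak guess
    peaks0 = residuals(p0) + y - basis @ np.zeros(nb)
    b0, *_ = np.linalg.lstsq(basis, y - peaks0, rcond=None)
    p0[4 * n:] = b0
    lower = np.concatenate([
        np.full(n, -np.inf), c0 - config.center_tol,
        np.full(n, config.sigma_bounds[0]), np.full(n, config.gamma_bounds[0]),
        np.full(nb, -np.inf),
    ])
    upper = np.concatenate([
        np.full(n, np.inf), c0 + config.center_tol,
        np.full(n, config.sigma_bounds[1]), np.full(n, config.gamma_bounds[1]),
        np.full(nb, np.inf),
    ])
    res = least_squares(
        residuals, p0, jac=jacobian, bounds=(lower, upper),
        method="trf", max_nfev=config.max_nfev, x_scale="jac",
        ftol=config.ftol, xtol=config.xtol, gtol=None,
    )
    nfev = res.nfev
    converged = res.status > 0
    if res.status == 0:
        # iteration cap hit inside the flat valley of this 4n+nb-parameter
        # problem; rerun briefly from the solution — if the residual no
        # longer improves materially the fit has plateaued, which is
        # convergence for practical purposes, not optimizer failure
        rms_before = float(np.sqrt(np.mean(res.fun**2)))
        res = least_squares(
            residuals, res.x, jac=jacobian, bounds=(lower, upper),
            method="trf", max_nfev=25, x_scale="jac",
            ftol=config.ftol, xtol=config.xtol, gtol=None,
        )
        nfev += res.nfev
        rms_after = float(np.sqrt(np.mean(res.fun**2)))
        converged = res.status > 0 or rms_after > 0.99 * rms_before
    p = res.x
    fitted_centers = p[n:2 * n]

    # tie-break: two catalogue bands converging onto one center
    order = np.argsort(fitted_centers)
    for a, b in zip(order[:-1], order[1:]):
        if abs(fitted_centers[a] - fitted_centers[b]) < config.duplicate_tol and not dropped:
            areas = p[0:n] ** 2
            loser = a if areas[a] <= areas[b] else b
            warnings.warn(
                f"bands {centers[a]:.0f} and {centers[b]:.0f} cm^-1 collapsed; "
                f"refitting without {centers[loser]:.0f}",
                stacklevel=2,
            )
            kept = tuple(c for i, c in enumerate(centers) if i != loser)
            return _fit_once(x, y, y_scale, window, kept, config,
                             dropped=dropped + (centers[loser],))

    peaks = []
    for i in np.argsort(fitted_centers):
        center = float(fitted_centers[i])
        at_bound = (abs(center - (centers[i] - config.center_tol)) < 1e-6
                    or abs(center - (centers[i] + config.center_tol)) < 1e-6)
        if at_bound:
            warnings.warn(f"fitted center {center:.1f} cm^-1 pinned at its bound",
                          stacklevel=2)
        peaks.append(VoigtPeak(
            center=center, area=float(p[i] ** 2) * y_scale,
            sigma=float(p[2 * n + i]), gamma=float(p[3 * n + i]),
            at_bound=at_bound,
        ))
    return RegionFit(
        window=window,
        peaks=tuple(peaks),
        baseline_coeffs=tuple(float(b) * y_scale for b in p[4 * n:]),
        residual_rms=float(np.sqrt(np.mean(res.fun**2))) * y_scale,
        converged=bool(converged),
        n_evaluations=int(nfev),
        dropped_centers=dropped,
    )


def peak_area(fit: RegionFit, nominal_center: float, tol: float = 8.0) -> float:
    """Area of the fitted component nearest ``nominal_center``.

    Raises LookupError if no fitted center lies within ``tol`` cm^-1 and
    PeakFitError if the fit did not converge.
    """
    if not fit.converged:
        raise PeakFitError("peak_area requires a converged fit")
    if not fit.peaks:
        raise LookupError(f"fit of window {fit.window} has no peaks")
    dists = [abs(pk.center - nominal_center) for pk in fit.peaks]
    i = int(np.argmin(dists))
    if dists[i] > tol:
        raise LookupError(
            f"no fitted peak within {tol} cm^-1 of {nominal_center} "
            f"(nearest at {fit.peaks[i].center:.1f})"
        )
    return fit.peaks[i].area
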