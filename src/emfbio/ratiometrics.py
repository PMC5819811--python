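"""Ratiometric DNA/protein markers and group statistics.

Three area ratios of fitted Voigt bands act as intensity-scale-free
markers of the DNA-to-protein balance of a cell:

* I785/I1003  — DNA backbone/ring modes vs phenylalanine ring breathing
* I1092/I1003 — DNA phosphodioxy stretch vs phenylalanine
* I1578/I1615 — DNA base ring breathing vs aromatic amino-acid C=C

Control and exposed groups are compared per marker and exposure time with
a two-sample two-tailed t-test (classic pooled-variance Student by
default, Welch by flag); differences follow the control-minus-exposed
convention, so a loss of DNA signal in exposed cells shows as a positive
difference.  The significance flag applies a Bonferroni correction over
the 3-marker x 4-time family; raw p-values are always reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .peaks import RegionFit, WINDOW_HIGH, WINDOW_LOW, peak_area

__all__ = [
    "MARKERS",
    "RatioMarkers",
    "GroupComparison",
    "TrendResult",
    "compute_ratios",
    "compare_groups",
    "difference_trend",
    "anova_across_times",
]

#: marker name -> (numerator center, denominator center, numerator window, denominator window)
MARKERS: dict[str, tuple[float, float, tuple[float, float], tuple[float, float]]] = {
    "I785/I1003": (785.0, 1003.0, WINDOW_LOW, WINDOW_LOW),
    "I1092/I1003": (1092.0, 1003.0, WINDOW_LOW, WINDOW_LOW),
    "I1578/I1615": (1578.0, 1615.0, WINDOW_HIGH, WINDOW_HIGH),
}

#: Bonferroni family: 3 markers x 4 exposure times.
DEFAULT_FAMILY_SIZE = 12


@dataclass(frozen=True)
class RatioMarkers:
    """The three marker ratios for one cell; a missing band is recorded as
    None with a reason, never as zero."""

    sample_id: str = ""
    group: str = "control"
    exposure_hours: float = 0.0
    ratios: dict[str, float] = field(default_factory=dict)
    missing: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.ratios.items():
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"ratio {name} must be finite and > 0, got {value!r}")

    def get(self, marker: str) -> float | None:
        return self.ratios.get(marker)


def compute_ratios(
    fit_low: RegionFit,
    fit_high: RegionFit,
    sample_id: str = "",
    group: str = "control",
    exposure_hours: float = 0.0,
    tol: float = 8.0,
) -> RatioMarkers:
    """Marker ratios from the two window fits of one spectrum."""
    if tuple(fit_low.window) != WINDOW_LOW or tuple(fit_high.window) != WINDOW_HIGH:
        raise ValueError(
            f"expected fits over {WINDOW_LOW} and {WINDOW_HIGH}, "
            f"got {fit_low.window} and {fit_high.window}"
        )
    fits = {WINDOW_LOW: fit_low, WINDOW_HIGH: fit_high}
    ratios: dict[str, float] = {}
    missing: dict[str, str] = {}
    for name, (num_c, den_c, num_w, den_w) in MARKERS.items():
        try:
            num = peak_area(fits[num_w], num_c, tol=tol)
            den = peak_area(fits[den_w], den_c, tol=tol)
        except LookupError as exc:
            missing[name] = str(exc)
            continue
        if den <= 0 or num <= 0:
            missing[name] = f"non-positive area (num={num:.3g}, den={den:.3g})"
            continue
        ratios[name] = num / den
    return RatioMarkers(sample_id=sample_id, group=group,
                        exposure_hours=exposure_hours,
                        ratios=ratios, missing=missing)


@dataclass(frozen=True)
class GroupComparison:
    marker: str
    exposure_hours: float
    n_control: int
    n_exposed: int
    mean_control: float
    mean_exposed: float
    difference: float          # control - exposed
    t_statistic: float
    p_two_tailed: float
    significant: bool
    alpha: float = 0.05
    n_comparisons: int = DEFAULT_FAMILY_SIZE


def _extract(values: list[RatioMarkers] | list[float], marker: str) -> np.ndarray:
    if values and isinstance(values[0], RatioMarkers):
        xs = [m.get(marker) for m in values]
        return np.array([x for x in xs if x is not None], dtype=float)
    return np.asarray(values, dtype=float)


def compare_groups(
    control: list[RatioMarkers] | list[float],
    exposed: list[RatioMarkers] | list[float],
    marker: str,
    exposure_hours: float = 0.0,
    equal_var: bool = True,
    alpha: float = 0.05,
    n_comparisons: int = DEFAULT_FAMILY_SIZE,
) -> GroupComparison:
    """Two-sample two-tailed t-test on per-cell marker ratios.

    ``difference`` is mean(control) - mean(exposed).  Zero pooled variance
    is degenerate: p = 1 when the means coincide, p -> 0 otherwise.  The
    ``significant`` flag uses the Bonferroni-corrected threshold
    alpha / n_comparisons; the raw two-tailed p is reported unchanged.
    """
    c = _extract(control, marker)
    e = _extract(exposed, marker)
    if c.size < 2 or e.size < 2:
        raise ValueError(f"need >= 2 values per group, got {c.size} and {e.size}")
    mean_c, mean_e = float(c.mean()), float(e.mean())
    if c.std(ddof=1) == 0.0 and e.std(ddof=1) == 0.0:
        same = math.isclose(mean_c, mean_e, rel_tol=0.0, abs_tol=0.0)
        t_stat = 0.0 if same else math.inf * math.copysign(1.0, mean_c - mean_e)
        p = 1.0 if same else 0.0
    else:
        t_stat, p = stats.ttest_ind(c, e, equal_var=equal_var)
        t_stat, p = float(t_stat), float(p)
    return GroupComparison(
        marker=marker,
        exposure_hours=exposure_hours,
        n_control=int(c.size),
        n_exposed=int(e.size),
        mean_control=mean_c,
        mean_exposed=mean_e,
        difference=mean_c - mean_e,
        t_statistic=t_stat,
        p_two_tailed=p,
        significant=bool(p < alpha / n_comparisons),
        alpha=alpha,
        n_comparisons=n_comparisons,
    )


@dataclass(frozen=True)
class TrendResult:
    marker: str
    hours: tuple[float, ...]
    differences: tuple[float, ...]
    verdict: str               # non-decreasing | other | insufficient


def difference_trend(comparisons: list[GroupComparison]) -> TrendResult:
    """Order control-minus-exposed differences by exposure time and judge
    monotonicity (the expected signature of a cumulative exposure effect)."""
    if not comparisons:
        raise ValueError("no comparisons given")
    markers = {c.marker for c in comparisons}
    if len(markers) > 1:
        raise ValueError(f"mixed markers in trend: {sorted(markers)}")
    ordered = sorted(comparisons, key=lambda c: c.exposure_hours)
    hours = tuple(c.exposure_hours for c in ordered)
    diffs = tuple(c.difference for c in ordered)
    if len(ordered) < 2:
        verdict = "insufficient"
    elif all(b >= a for a, b in zip(diffs[:-1], diffs[1:])):
        verdict = "non-decreasing"
    else:
        verdict = "other"
    return TrendResult(marker=ordered[0].marker, hours=hours,
                       differences=diffs, verdict=verdict)


def anova_across_times(groups: list[list[RatioMarkers] | list[float]], marker: str):
    """One-way ANOVA F-test across exposure-time groups (secondary check
    backing the pairwise comparisons)."""
    arrays = [_extract(g, marker) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)
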