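"""Single-cell Raman spectrum container and plain-text I/O.

Spectra live on a strictly increasing wavenumber grid (cm^-1) inside the
cellular fingerprint region 700-1800 cm^-1 and carry group metadata
(control/exposed, exposure time in hours) plus a processing-state tag so
the pretreatment pipeline can enforce its step order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path


import numpy as np

__all__ = ["RamanSpectrum", "SpectrumMeta", "read_spectrum", "write_spectrum"]

#: Processing states in pipeline order.
STATES = ("raw", "background_subtracted", "baseline_removed", "normalized")


@dataclass(frozen=True)
class SpectrumMeta:
    sample_id: str = ""
    group: str = "control"          # control | exposed
    exposure_hours: float = 0.0
    kind: str = "cell"              # cell | background
    n_averaged: int = 1


@dataclass(frozen=True)
class RamanSpectrum:
    """One cell's (or background's) wavenumber/intensity trace."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: SpectrumMeta = field(default_factory=SpectrumMeta)
    state: str = "raw"

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", i)
        if w.ndim != 1 or i.ndim != 1 or w.shape != i.shape:
            raise ValueError("wavenumbers and intensities must be equal-length 1-D arrays")
        if w.size < 2:
            raise ValueError("spectrum needs at least two channels")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        if self.state not in STATES:
            raise ValueError(f"unknown processing state {self.state!r}")

    def with_intensities(self, intensities: np.ndarray, state: str | None = None) -> "RamanSpectrum":
        return replace(self, intensities=np.asarray(intensities, dtype=float),
                       state=self.state if state is None else state)

    def total_intensity(self) -> float:
        """Signed total over the record: plain sum on a uniform grid,
        trapezoidal weights otherwise."""
        steps = np.diff(self.wavenumbers)
        if np.allclose(steps, steps[0], rtol=1e-6, atol=0.0):
            return float(self.intensities.sum())
        return float(np.trapezoid(self.intensities, self.wavenumbers))

    def window(self, low: float, high: float) -> tuple[np.ndarray, np.ndarray]:
        m = (self.wavenumbers >= low) & (self.wavenumbers <= high)
        return self.wavenumbers[m], self.intensities[m]


def write_spectrum(s: RamanSpectrum, path: str | Path) -> None:
    """Two-column whitespace text; metadata in '#'-prefixed header lines."""
    path = Path(path)
    header = (
        f"# sample_id: {s.meta.sample_id}\n"
        f"# group: {s.meta.group}\n"
        f"# exposure_hours: {s.meta.exposure_hours}\n"
        f"# kind: {s.meta.kind}\n"
        f"# state: {s.state}\n"
        "# wavenumber_cm-1 intensity\n"
    )
    body = "\n".join(f"{w:.4f} {i:.8e}" for w, i in zip(s.wavenumbers, s.intensities))
    path.write_text(header + body + "\n")


def read_spectrum(path: str | Path) -> RamanSpectrum:
    """Read a two-column text spectrum written by :func:`write_spectrum`
    (or any whitespace/CSV two-column file with '#' comments)."""
    path = Path(path)
    meta_kv: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                k, _, v = stripped.partition(":")
                meta_kv[k.strip()] = v.strip()
            continue
        parts = line.replace(",", " ").split()
        if len(parts) >= 2:
            rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise ValueError(f"no data rows in {path}")
    arr = np.array(rows, dtype=float)
    meta = SpectrumMeta(
        sample_id=meta_kv.get("sample_id", path.stem),
        group=meta_kv.get("group", "control"),
        exposure_hours=float(meta_kv.get("exposure_hours", 0.0)),
        kind=meta_kv.get("kind", "cell"),
    )
    return RamanSpectrum(arr[:, 0], arr[:, 1], meta=meta,
                         state=meta_kv.get("state", "raw"))
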