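"""FT-MIR spectrum processing and humification indices.

Mid-infrared spectra of peat are reduced to four band-height ratios used
as decomposition proxies, each normalised by the polysaccharide band at
1090 cm-1:

    Hi1 = 1420/1090 (phenolic and aliphatic structures / polysaccharides)
    Hi2 = 1510/1090 (aromatics, amide C=O / polysaccharides)
    Hi3 = 1630/1090 (aromatic C=C, COO-, protein / polysaccharides)
    Hi4 = 1720/1090 (carbonylic and carboxylic C=O / polysaccharides)

Spectra are baseline-corrected with a rubberband (lower convex hull)
baseline, area-normalised, and band heights taken as the local maximum
within a window around each band centre. Because the indices are ratios
they are invariant to multiplicative rescaling and, up to the hull
approximation, to any additive linear baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import INDEX_BANDS_CM1, REFERENCE_BAND_CM1

__all__ = [
    "Spectrum",
    "HumificationIndices",
    "baseline_correct",
    "normalize",
    "peak_height",
    "humification_indices",
    "read_spectrum_csv",
]


@dataclass(frozen=True)
class Spectrum:
    """A wavenumber/absorbance series with strictly increasing wavenumbers."""

    wavenumbers: np.ndarray  # cm-1, ascending
    absorbance: np.ndarray  # arbitrary units

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavenumbers", np.asarray(self.wavenumbers, dtype=float))
        object.__setattr__(self, "absorbance", np.asarray(self.absorbance, dtype=float))
        if self.wavenumbers.size < 2 or self.wavenumbers.shape != self.absorbance.shape:
            raise ValueError("need >= 2 points with matching wavenumber/absorbance arrays")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.wavenumbers, self.absorbance, **kwargs)
        ax.set_xlabel("wavenumber (cm$^{-1}$)")
        ax.set_ylabel("absorbance")
        return ax


def _lower_hull(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the lower convex hull of (x, y), x strictly increasing."""
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # pop k if it lies on or above the chord j -> i
            if (x[k] - x[j]) * (y[i] - y[j]) - (y[k] - y[j]) * (x[i] - x[j]) <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull, dtype=int)


def baseline_correct(spectrum: Spectrum) -> Spectrum:
    """Subtract a rubberband (lower convex hull) baseline.

    The baseline is the lower convex hull of the spectrum, linearly
    interpolated between support points; the corrected absorbance is zero
    at every support point and non-negative elsewhere. Idempotent up to
    hull tolerance on an already corrected spectrum.
    """
    if spectrum.wavenumbers.size < 3:
        raise ValueError("baseline correction needs at least 3 points")
    idx = _lower_hull(spectrum.wavenumbers, spectrum.absorbance)
    baseline = np.interp(
        spectrum.wavenumbers, spectrum.wavenumbers[idx], spectrum.absorbance[idx]
    )
    return Spectrum(spectrum.wavenumbers, spectrum.absorbance - baseline)


def normalize(spectrum: Spectrum) -> Spectrum:
    """Scale so the integrated absorbance (trapezoid rule) equals one.

    Shape-preserving: all height ratios are unchanged, so humification
    indices are invariant to this step (it fixes the scale of
    intermediate files).
    """
    area = float(np.trapezoid(spectrum.absorbance, spectrum.wavenumbers))
    if area <= 0:
        raise ValueError("cannot normalize a spectrum with non-positive integrated absorbance")
    return Spectrum(spectrum.wavenumbers, spectrum.absorbance / area)


def peak_height(spectrum: Spectrum, center: float, half_window: float = 10.0) -> float:
    """Maximum absorbance within ``center +/- half_window`` cm-1.

    Using the window maximum rather than the value at the exact
    wavenumber makes the height robust to grid offsets.
    """
    lo, hi = center - half_window, center + half_window
    if lo < spectrum.wavenumbers[0] or hi > spectrum.wavenumbers[-1]:
        raise ValueError(
            f"window [{lo}, {hi}] cm-1 falls outside the spectral range "
            f"[{spectrum.wavenumbers[0]}, {spectrum.wavenumbers[-1]}]"
        )
    mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    return float(spectrum.absorbance[mask].max())


@dataclass(frozen=True)
class HumificationIndices:
    """The four FT-MIR band-height ratios (unitless)."""

    hi1: float  # 1420/1090
    hi2: float  # 1510/1090
    hi3: float  # 1630/1090
    hi4: float  # 1720/1090

    def as_dict(self) -> dict[str, float]:
        return {"hi1": self.hi1, "hi2": self.hi2, "hi3": self.hi3, "hi4": self.hi4}

    def summary(self) -> str:
        return (
            f"Hi1 (1420/1090) = {self.hi1:.3f}\n"
            f"Hi2 (1510/1090) = {self.hi2:.3f}\n"
            f"Hi3 (1630/1090) = {self.hi3:.3f}\n"
            f"Hi4 (1720/1090) = {self.hi4:.3f}"
        )


def humification_indices(
    spectrum: Spectrum,
    half_window: float = 10.0,
    bands=INDEX_BANDS_CM1,
    reference_band: float = REFERENCE_BAND_CM1,
) -> HumificationIndices:
    """Baseline-correct, normalise, and compute the four band ratios."""
    processed = normalize(baseline_correct(spectrum))
    ref = peak_height(processed, reference_band, half_window)
    if ref <= 0:
        raise ValueError(
            f"reference band at {reference_band} cm-1 has non-positive height; "
            "indices are undefined"
        )
    heights = [peak_height(processed, b, half_window) for b in bands]
    return HumificationIndices(*(h / ref for h in heights))


def read_spectrum_csv(path) -> Spectrum:
    """Read a two-column wavenumber,absorbance CSV (header optional)."""
    df = pd.read_csv(Path(path), comment="#")
    if df.shape[1] < 2:
        raise ValueError("expected two columns: wavenumber, absorbance")
    wn = df.iloc[:, 0].to_numpy(dtype=float)
    ab = df.iloc[:, 1].to_numpy(dtype=float)
    order = np.argsort(wn)
    return Spectrum(wn[order], ab[order])
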