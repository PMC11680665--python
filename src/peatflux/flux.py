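"""Headspace CO2 time series -> production rates per gram organic carbon.

Closed-jar incubations accumulate CO2 in the headspace; each gas sampling
removes a small volume that is replaced with ambient air, diluting the
signal. This module reconstructs the cumulative mass of CO2-C produced
(adding back what each withdrawal removed and subtracting what each
ambient refill introduced), fits an ordinary least-squares line through
cumulative mass versus time, and expresses the slope per gram of organic
carbon. Replicates whose regression r^2 does not exceed a quality
threshold (0.8 by default) are flagged for discard.

A diagnostic for the CO2 that stays dissolved in the sample's pore water
(Henry's law plus the first carbonate dissociation) is provided; it is
reported, never applied as a correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import statsmodels.api as sm

from .constants import (
    DEFAULT_PRESSURE_KPA,
    DEFAULT_TEMPERATURE_C,
    HENRY_KH_25C,
    HENRY_VANT_HOFF_K,
    KELVIN_OFFSET,
    MOLAR_MASS_C,
    PKA1_CARBONIC,
    R_J_PER_MOL_K,
)

__all__ = [
    "Sample",
    "HeadspaceSeries",
    "FluxResults",
    "HeadspaceFluxModel",
    "ppm_to_mass",
    "dilution_correct",
    "fit_rate",
    "qc_summary",
    "QCSummary",
    "dissolved_fraction",
]

MATERIALS = ("peat", "growing_media")
VON_POST_CLASSES = ("3-4", "5-6", "7-8")


@dataclass(frozen=True)
class Sample:
    """Metadata for one incubated material.

    Parameters
    ----------
    sample_id : str
    material : {"peat", "growing_media"}
    von_post : {"3-4", "5-6", "7-8"}
        Humification class on the von Post field scale.
    dry_mass : float
        Dry mass of the incubated subsample, g.
    org_c_fraction : float
        Organic carbon per gram dry mass (g C / g).
    solid_delta13c : float
        delta13C of the solid material, permil VPDB. Used as the biotic
        end-member delta0 in source partitioning.
    """

    sample_id: str
    material: str
    von_post: str
    dry_mass: float
    org_c_fraction: float
    solid_delta13c: float

    def __post_init__(self) -> None:
        if self.material not in MATERIALS:
            raise ValueError(f"material must be one of {MATERIALS}, got {self.material!r}")
        if self.von_post not in VON_POST_CLASSES:
            raise ValueError(f"von_post must be one of {VON_POST_CLASSES}, got {self.von_post!r}")
        if not self.dry_mass > 0:
            raise ValueError("dry_mass must be positive")
        if not 0 < self.org_c_fraction <= 1:
            raise ValueError("org_c_fraction must be in (0, 1]")

    @property
    def org_c_mass(self) -> float:
        """Organic carbon mass, g."""
        return self.dry_mass * self.org_c_fraction


@dataclass(frozen=True)
class HeadspaceSeries:
    """Timed CO2 mixing ratios from one jar replicate.

    ``event_times`` are the sampling events after which ``withdrawal_volume``
    mL of headspace was withdrawn and replaced with ambient air; by default
    every recorded time is such an event (the final one has no effect on
    the correction).
    """

    sample_id: str
    replicate: int
    times: np.ndarray  # hours
    co2_ppm: np.ndarray
    jar_volume: float = 250.0  # mL
    sample_volume: float = 10.0  # mL
    withdrawal_volume: float = 5.0  # mL per event
    ambient_ppm: float | None = None
    temperature: float = DEFAULT_TEMPERATURE_C  # C
    pressure: float = DEFAULT_PRESSURE_KPA  # kPa
    event_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "co2_ppm", np.asarray(self.co2_ppm, dtype=float))
        if self.times.ndim != 1 or self.times.shape != self.co2_ppm.shape:
            raise ValueError("times and co2_ppm must be 1-d arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.co2_ppm < 0):
            raise ValueError("co2_ppm must be non-negative")
        if not self.jar_volume > self.sample_volume >= 0:
            raise ValueError("require jar_volume > sample_volume >= 0")
        if self.event_times is not None:
            object.__setattr__(self, "event_times", np.asarray(self.event_times, dtype=float))

    @property
    def headspace_volume(self) -> float:
        """Effective gas volume, mL (jar minus sample)."""
        return self.jar_volume - self.sample_volume

    def sampling_events(self) -> np.ndarray:
        """Times at which gas was withdrawn and replaced."""
        if self.event_times is not None:
            return self.event_times
        return self.times


def ppm_to_mass(
    co2_ppm,
    headspace_volume: float,
    temperature: float = DEFAULT_TEMPERATURE_C,
    pressure: float = DEFAULT_PRESSURE_KPA,
):
    """Convert a CO2 mixing ratio to mg of CO2-C via the ideal gas law.

    mass [mg C] = ppm * 1e-6 * P V / (R T) * 12.011 g/mol * 1000 mg/g.
    Strictly linear in both ppm and volume.

    Parameters
    ----------
    co2_ppm : float or array_like
    headspace_volume : float, mL
    temperature : float, C
    pressure : float, kPa
    """
    co2_ppm = np.asarray(co2_ppm, dtype=float)
    if np.any(co2_ppm < 0):
        raise ValueError("co2_ppm must be non-negative")
    if not headspace_volume > 0:
        raise ValueError("headspace_volume must be positive")
    if not temperature > -KELVIN_OFFSET:
        raise ValueError("temperature below absolute zero")
    t_k = temperature + KELVIN_OFFSET
    mol_gas = (pressure * 1e3) * (headspace_volume * 1e-6) / (R_J_PER_MOL_K * t_k)
    mass = co2_ppm * 1e-6 * mol_gas * MOLAR_MASS_C * 1e3
    return mass if mass.ndim else float(mass)


def dilution_correct(series: HeadspaceSeries) -> np.ndarray:
    """Cumulative produced CO2-C mass (mg) at each time point.

    Adds back, for each sampling event before time t_i, the CO2-C removed
    with the withdrawn gas (at the pre-withdrawal concentration) and
    subtracts the CO2-C introduced by the ambient-air refill. With zero
    production and an ambient-equilibrated jar the corrected series is
    identically zero (mass conservation).
    """
    events = series.sampling_events()
    if events.size and series.ambient_ppm is None:
        raise ValueError("ambient_ppm is required to correct for replacement events")
    v = series.headspace_volume
    mass = ppm_to_mass(series.co2_ppm, v, series.temperature, series.pressure)
    phi = series.withdrawal_volume / v
    ambient_mass = (
        ppm_to_mass(series.ambient_ppm, v, series.temperature, series.pressure)
        if series.ambient_ppm is not None
        else 0.0
    )
    # net mass removed at each event; events coincide with sampling times
    correction = np.zeros_like(mass)
    for t_ev in np.atleast_1d(events):
        idx = np.nonzero(np.isclose(series.times, t_ev))[0]
        if idx.size == 0:
            raise ValueError(f"event at t={t_ev} h does not coincide with a sampling time")
        i = int(idx[0])
        after = series.times > series.times[i]
        correction[after] += phi * (mass[i] - ambient_mass)
    return mass - mass[0] + correction


@dataclass(frozen=True)
class FluxResults:
    """OLS estimate of a jar's CO2 production rate.

    ``rate`` is in mg CO2-C per g organic C per day; ``qc_pass`` applies
    the r^2 > r2_min rule (False when r^2 is undefined).
    """

    sample_id: str
    replicate: int
    rate: float
    rate_se: float
    r_squared: float
    n_points: int
    qc_pass: bool
    r2_min: float = 0.8

    def summary(self) -> str:
        r2 = "undefined" if np.isnan(self.r_squared) else f"{self.r_squared:.4f}"
        return (
            f"Headspace flux fit: {self.sample_id} rep {self.replicate + 1}\n"
            f"  rate      {self.rate:.4f} +/- {self.rate_se:.4f} mg CO2-C g orgC-1 d-1\n"
            f"  r-squared {r2} (QC {'pass' if self.qc_pass else 'FAIL'}, "
            f"threshold {self.r2_min})\n"
            f"  n points  {self.n_points}"
        )


class HeadspaceFluxModel:
    """OLS model of dilution-corrected cumulative CO2-C mass against time.

    Parameters
    ----------
    series : HeadspaceSeries
    sample : Sample
        Supplies the organic-C mass that normalises the slope.
    r2_min : float
        QC threshold on r^2 (replicates at or below it are flagged).
    """

    def __init__(self, series: HeadspaceSeries, sample: Sample, r2_min: float = 0.8):
        if series.times.size < 3:
            raise ValueError("at least 3 time points are required")
        if sample.org_c_mass <= 0:
            raise ValueError("sample has zero organic carbon mass")
        self.series = series
        self.sample = sample
        self.r2_min = r2_min
        self.cumulative_mass = dilution_correct(series)  # mg C
        self.times_days = series.times / 24.0

    def fit(self) -> FluxResults:
        x = sm.add_constant(self.times_days)
        res = sm.OLS(self.cumulative_mass, x).fit()
        slope = float(res.params[1])  # mg C per day, whole jar
        slope_se = float(res.bse[1])
        tss = float(np.sum((self.cumulative_mass - self.cumulative_mass.mean()) ** 2))
        r2 = float(res.rsquared) if tss > 0 else float("nan")
        org_c = self.sample.org_c_mass
        qc = bool(np.isfinite(r2) and r2 > self.r2_min)
        return FluxResults(
            sample_id=self.series.sample_id,
            replicate=self.series.replicate,
            rate=slope / org_c,
            rate_se=slope_se / org_c,
            r_squared=r2,
            n_points=int(self.series.times.size),
            qc_pass=qc,
            r2_min=self.r2_min,
        )


def fit_rate(series: HeadspaceSeries, sample: Sample, r2_min: float = 0.8) -> FluxResults:
    """Convenience wrapper: fit a :class:`HeadspaceFluxModel` and return results."""
    return HeadspaceFluxModel(series, sample, r2_min=r2_min).fit()


@dataclass(frozen=True)
class QCSummary:
    retained: tuple
    discarded: tuple
    discard_fraction: float


def qc_summary(estimates: Iterable[FluxResults]) -> QCSummary:
    """Split flux estimates by their QC flag and report the discard fraction."""
    estimates = list(estimates)
    if not estimates:
        raise ValueError("no estimates supplied")
    kept = tuple(e for e in estimates if e.qc_pass)
    dropped = tuple(e for e in estimates if not e.qc_pass)
    return QCSummary(kept, dropped, len(dropped) / len(estimates))


def dissolved_fraction(
    pH: float,
    temperature: float = DEFAULT_TEMPERATURE_C,
    headspace_volume: float = 244.0,
    water_volume: float = 6.0,
) -> float:
    """Fraction of produced CO2 residing in solution at equilibrium.

    Partitions CO2 between the jar headspace (ideal gas) and the sample
    water, where the dissolved pool is aqueous CO2* (Henry's law, with a
    van 't Hoff temperature correction) plus bicarbonate from the first
    carbonate dissociation. The fraction increases with pH and with water
    volume; it is a diagnostic for how much production the headspace-only
    calculation misses, not a correction that is applied.

    Parameters
    ----------
    pH : float
    temperature : float, C
    headspace_volume, water_volume : float, mL
    """
    if not 0 < pH < 14:
        raise ValueError("pH must be in (0, 14)")
    if not headspace_volume > 0 or water_volume < 0:
        raise ValueError("volumes must be positive (water_volume may be zero)")
    t_k = temperature + KELVIN_OFFSET
    kh = HENRY_KH_25C * math.exp(HENRY_VANT_HOFF_K * (1.0 / t_k - 1.0 / 298.15))
    # per atm of CO2 partial pressure:
    gas_mol = (headspace_volume * 1e-3) / (0.0820574 * t_k)  # L atm / (L atm mol-1 K-1 K)
    aq_co2 = kh * (water_volume * 1e-3)
    bicarb = aq_co2 * 10.0 ** (pH - PKA1_CARBONIC)
    dissolved = aq_co2 + bicarb
    return dissolved / (dissolved + gas_mol)
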