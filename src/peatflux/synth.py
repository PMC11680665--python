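"""Synthetic incubation datasets with known ground truth.

Emulates the laboratory design end to end so every downstream stage is
testable without real data: jars accumulate CO2 linearly between
sampling events (constant per-sample production), concentration
incubations replace each 5 mL gas sample with ambient air, isotope
incubations replace 25 mL with CO2-free gas, observed delta13C follows
two-pool Keeling mixing between the starting ambient pool and a source
whose signature is the flux-weighted mean of the peat and lime
end-members, and FT-MIR spectra are Gaussian peaks at the five index
bands on a smooth convex baseline.

Defaults mirror the incubation design this package models: 28 peat and
24 growing-media samples in von Post classes (10, 9, 9) and (12, 6, 6),
triplicates, ~10 g subsamples in 250 mL jars at 23 C, concentration
sampling at 0/6/24/48 h and isotope sampling at 0/2/4/6 h, instrument
noise of 0.4 permil on delta13C. Rates are drawn from Gamma
distributions (positive by construction) whose means and spreads follow
the measured group statistics: peat total ~0.063 mg CO2-C g orgC-1 d-1,
growing-media biotic ~0.147 with a lime share averaging 22.5%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .flux import HeadspaceSeries, Sample, ppm_to_mass
from .keeling import IsotopeSeries
from .spectra import Spectrum
from .constants import INDEX_BANDS_CM1, REFERENCE_BAND_CM1

__all__ = [
    "TrueState",
    "GeneratorConfig",
    "SynthDataset",
    "generate_samples",
    "simulate_headspace",
    "simulate_isotopes",
    "simulate_spectrum",
    "generate_dataset",
    "write_dataset",
    "CONCENTRATION_SCHEDULE_H",
    "ISOTOPE_SCHEDULE_H",
    "GROUP_PROFILES",
]

CONCENTRATION_SCHEDULE_H = (0.0, 6.0, 24.0, 48.0)
ISOTOPE_SCHEDULE_H = (0.0, 2.0, 4.0, 6.0)

# Per-group generative profiles: organic C (fraction of dry mass), solid
# delta13C (permil), humification-index ratios (Hi1..Hi4 relative to the
# 1090 cm-1 band) and biogeochemical covariate means/sds used only for
# correlation-pipeline smoke tests.
GROUP_PROFILES: dict[tuple[str, str], dict] = {
    ("peat", "3-4"): dict(n=10, org_c=0.5208, delta_solid=-27.00,
                          hi=(0.51, 0.33, 0.67, 0.61),
                          pH=(3.83, 0.03), doc=(1.25, 0.03), tdn=(0.09, 0.009), cn=(62.57, 2.9)),
    ("peat", "5-6"): dict(n=9, org_c=0.5122, delta_solid=-26.65,
                          hi=(0.60, 0.46, 0.84, 0.71),
                          pH=(3.86, 0.06), doc=(1.21, 0.12), tdn=(0.08, 0.009), cn=(47.88, 2.8)),
    ("peat", "7-8"): dict(n=9, org_c=0.4839, delta_solid=-26.91,
                          hi=(0.91, 0.84, 1.30, 0.80),
                          pH=(5.10, 0.30), doc=(1.04, 0.21), tdn=(0.12, 0.009), cn=(30.83, 2.2)),
    ("growing_media", "3-4"): dict(n=12, org_c=0.4188, delta_solid=-27.16,
                                   hi=(0.57, 0.39, 0.76, 0.41),
                                   pH=(5.78, 0.31), doc=(2.13, 0.35), tdn=(0.48, 0.21), cn=(45.00, 3.7)),
    ("growing_media", "5-6"): dict(n=6, org_c=0.4556, delta_solid=-27.27,
                                   hi=(0.70, 0.52, 0.99, 0.64),
                                   pH=(5.33, 0.22), doc=(1.44, 0.12), tdn=(0.41, 0.07), cn=(42.92, 2.2)),
    ("growing_media", "7-8"): dict(n=6, org_c=0.4445, delta_solid=-27.57,
                                   hi=(1.02, 0.89, 1.42, 0.76),
                                   pH=(6.21, 0.24), doc=(0.96, 0.12), tdn=(0.55, 0.07), cn=(30.44, 2.2)),
}

# Rate model (mg CO2-C g orgC-1 d-1): Gamma draws matched to the group
# mean and between-sample sd; media lime share Beta-distributed.
PEAT_RATE_MEAN, PEAT_RATE_SD = 0.063, 0.024
MEDIA_BIOTIC_MEAN, MEDIA_BIOTIC_SD = 0.147, 0.083
LIME_FRACTION_MEAN, LIME_FRACTION_SD = 0.225, 0.10
LIME_DELTA_MEAN, LIME_DELTA_SD = -0.03, 0.28


@dataclass(frozen=True)
class TrueState:
    """Generative ground truth for one sample.

    Rates in mg CO2-C per g organic C per day; ``delta_peat`` and
    ``delta_lime`` are the biotic and carbonate end-members (permil
    VPDB); ``peak_heights`` maps FT-MIR band centre (cm-1) to the true
    Gaussian peak height.
    """

    sample_id: str
    biotic_rate: float
    lime_rate: float
    delta_peat: float
    delta_lime: float
    peak_heights: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.biotic_rate < 0 or self.lime_rate < 0:
            raise ValueError("rates must be non-negative")
        if not self.delta_lime > self.delta_peat:
            raise ValueError("delta_lime must exceed delta_peat")

    @property
    def total_rate(self) -> float:
        return self.biotic_rate + self.lime_rate

    @property
    def lime_fraction(self) -> float:
        return self.lime_rate / self.total_rate if self.total_rate > 0 else 0.0

    def source_delta(self, epsilon: float = 0.0) -> float:
        """Flux-weighted delta13C of the emitted CO2 mixture."""
        if self.total_rate == 0:
            raise ValueError("no production: source signature undefined")
        return (
            self.biotic_rate * self.delta_peat
            + self.lime_rate * (self.delta_lime - epsilon)
        ) / self.total_rate


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study; defaults are the incubation design."""

    n_peat: int = 28
    n_growing_media: int = 24
    replicates: int = 3
    seed: int = 0
    noise_ppm: float = 10.0
    noise_delta: float = 0.4
    jar_volume: float = 250.0  # mL
    sample_volume: float = 10.0  # mL
    ambient_ppm: float = 420.0
    ambient_delta: float = -8.5  # permil VPDB
    temperature: float = 23.0  # C
    pressure: float = 101.325  # kPa
    withdrawal_volume: float = 5.0  # mL, concentration incubations
    iso_withdrawal_volume: float = 25.0  # mL, isotope incubations
    epsilon: float = 0.0  # permil, carbonate fractionation in the generator
    dry_mass_mean: float = 10.0  # g
    dry_mass_sd: float = 0.5
    peak_sigma: float = 12.0  # cm-1, Gaussian peak width
    reference_height: float = 0.4  # absorbance units at 1090 cm-1
    baseline_coeffs: tuple[float, float, float] = (0.05, 0.02, 0.03)  # convex quadratic
    noise_absorbance: float = 0.0

    def __post_init__(self) -> None:
        if self.n_peat < 0 or self.n_growing_media < 0:
            raise ValueError("sample counts must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.jar_volume > self.sample_volume >= 0:
            raise ValueError("require jar_volume > sample_volume >= 0")
        for name in ("noise_ppm", "noise_delta", "noise_absorbance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def headspace_volume(self) -> float:
        return self.jar_volume - self.sample_volume


def _gamma_params(mean: float, sd: float) -> tuple[float, float]:
    shape = (mean / sd) ** 2
    return shape, mean / shape


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    nu = mean * (1 - mean) / sd**2 - 1
    return mean * nu, (1 - mean) * nu


def generate_samples(config: GeneratorConfig) -> list[tuple[Sample, TrueState]]:
    """Draw sample metadata and generative ground truth, reproducibly.

    Peat samples have no lime (lime_rate = 0); growing media get a
    Beta-distributed lime share converted to a lime rate on top of the
    biotic rate. von Post classes are filled in the design proportions
    (peat 10:9:9, media 12:6:6), scaled to the requested counts.
    """
    rng = np.random.default_rng(config.seed)
    out: list[tuple[Sample, TrueState]] = []
    for material, total_n in (("peat", config.n_peat), ("growing_media", config.n_growing_media)):
        groups = [(vp, prof) for (mat, vp), prof in GROUP_PROFILES.items() if mat == material]
        design_n = np.array([prof["n"] for _, prof in groups], dtype=float)
        counts = np.floor(design_n / design_n.sum() * total_n).astype(int)
        # distribute the remainder to the largest design groups
        for i in np.argsort(-design_n)[: total_n - counts.sum()]:
            counts[i] += 1
        k = 0
        for (vp, prof), n_grp in zip(groups, counts):
            for _ in range(n_grp):
                k += 1
                sid = f"{'P' if material == 'peat' else 'G'}{k:02d}"
                dry_mass = max(rng.normal(config.dry_mass_mean, config.dry_mass_sd), 1.0)
                org_c = float(np.clip(rng.normal(prof["org_c"], 0.01), 0.05, 1.0))
                delta_solid = rng.normal(prof["delta_solid"], 0.15)
                if material == "peat":
                    shape, scale = _gamma_params(PEAT_RATE_MEAN, PEAT_RATE_SD)
                    biotic = rng.gamma(shape, scale)
                    lime = 0.0
                    delta_lime = LIME_DELTA_MEAN  # unused: no lime pool
                else:
                    shape, scale = _gamma_params(MEDIA_BIOTIC_MEAN, MEDIA_BIOTIC_SD)
                    biotic = rng.gamma(shape, scale)
                    a, b = _beta_params(LIME_FRACTION_MEAN, LIME_FRACTION_SD)
                    f = rng.beta(a, b)
                    lime = biotic * f / (1.0 - f)
                    delta_lime = rng.normal(LIME_DELTA_MEAN, LIME_DELTA_SD)
                heights = {REFERENCE_BAND_CM1: config.reference_height}
                for band, ratio in zip(INDEX_BANDS_CM1, prof["hi"]):
                    heights[band] = config.reference_height * ratio * (1 + rng.normal(0, 0.01))
                sample = Sample(
                    sample_id=sid,
                    material=material,
                    von_post=vp,
                    dry_mass=float(dry_mass),
                    org_c_fraction=org_c,
                    solid_delta13c=float(delta_solid),
                )
                truth = TrueState(
                    sample_id=sid,
                    biotic_rate=float(biotic),
                    lime_rate=float(lime),
                    delta_peat=float(delta_solid),
                    delta_lime=float(delta_lime),
                    peak_heights=heights,
                )
                out.append((sample, truth))
    return out


def _rate_ppm_per_hour(total_rate: float, sample: Sample, config: GeneratorConfig) -> float:
    """Convert a whole-jar production rate (mg C/day) into ppm/hour."""
    mass_per_ppm = ppm_to_mass(1.0, config.headspace_volume, config.temperature, config.pressure)
    mg_per_day = total_rate * sample.org_c_mass
    return mg_per_day / 24.0 / mass_per_ppm


def _concentration_path(
    rate_ppm_h: float,
    schedule: np.ndarray,
    refill_ppm_factor: float,
    refill_ambient_ppm: float,
    ambient_ppm: float,
) -> np.ndarray:
    """Piecewise-linear concentration; events replace gas after each sampling.

    After each recorded time the concentration is mixed as
    c <- c * (1 - phi) + refill * phi where phi is the replaced volume
    fraction; ``refill_ambient_ppm`` is the refill gas concentration
    (ambient air for concentration incubations, 0 for CO2-free gas).
    """
    c = ambient_ppm
    out = np.empty(schedule.size)
    prev_t = schedule[0]
    for i, t in enumerate(schedule):
        c += rate_ppm_h * (t - prev_t)
        out[i] = c
        c = c * (1 - refill_ppm_factor) + refill_ambient_ppm * refill_ppm_factor
        prev_t = t
    return out


def _check_schedule(schedule) -> np.ndarray:
    schedule = np.asarray(schedule, dtype=float)
    if schedule.size < 2 or np.any(np.diff(schedule) <= 0):
        raise ValueError("schedule must be strictly increasing with >= 2 times")
    if schedule[0] != 0:
        raise ValueError("schedule must start at 0 h")
    return schedule


def simulate_headspace(
    sample: Sample,
    truth: TrueState,
    schedule=CONCENTRATION_SCHEDULE_H,
    config: GeneratorConfig = GeneratorConfig(),
    replicate: int = 0,
    rng: np.random.Generator | None = None,
) -> HeadspaceSeries:
    """Concentration incubation: linear accumulation, ambient-air refills.

    Total production is constant at ``truth.total_rate``; each sampling
    removes ``config.withdrawal_volume`` mL of headspace, replaced by
    ambient air; Gaussian noise of sd ``config.noise_ppm`` is added last.
    """
    schedule = _check_schedule(schedule)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    phi = config.withdrawal_volume / config.headspace_volume
    ppm = _concentration_path(
        _rate_ppm_per_hour(truth.total_rate, sample, config),
        schedule,
        phi,
        config.ambient_ppm,
        config.ambient_ppm,
    )
    if config.noise_ppm > 0:
        ppm = ppm + rng.normal(0, config.noise_ppm, ppm.size)
    return HeadspaceSeries(
        sample_id=sample.sample_id,
        replicate=replicate,
        times=schedule,
        co2_ppm=np.clip(ppm, 0, None),
        jar_volume=config.jar_volume,
        sample_volume=config.sample_volume,
        withdrawal_volume=config.withdrawal_volume,
        ambient_ppm=config.ambient_ppm,
        temperature=config.temperature,
        pressure=config.pressure,
    )


def simulate_isotopes(
    sample: Sample,
    truth: TrueState,
    schedule=ISOTOPE_SCHEDULE_H,
    config: GeneratorConfig = GeneratorConfig(),
    replicate: int = 0,
    rng: np.random.Generator | None = None,
) -> IsotopeSeries:
    """Isotope incubation: Keeling mixing over CO2-free refills.

    The concentration trajectory accumulates source CO2 and is diluted by
    CO2-free refills (25 mL replaced, adding no CO2 mass). The observed
    delta13C at total concentration C_t follows the two-pool identity

        delta = delta_s + (C_a / C_t) * (delta_a - delta_s)

    with (C_a, delta_a) the starting ambient pool and delta_s the
    flux-weighted source signature, so every noiseless point lies exactly
    on the Keeling line (an idealisation of refill mixing; see the
    methods note). Gaussian noise of sd ``config.noise_delta`` is added
    to delta last.
    """
    schedule = _check_schedule(schedule)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    phi = config.iso_withdrawal_volume / config.headspace_volume
    ppm = _concentration_path(
        _rate_ppm_per_hour(truth.total_rate, sample, config),
        schedule,
        phi,
        0.0,  # CO2-free refill gas
        config.ambient_ppm,
    )
    if np.any(ppm <= 0):
        raise ValueError("zero total CO2 concentration: delta13C undefined")
    if truth.total_rate > 0:
        delta_s = truth.source_delta(config.epsilon)
        d13c = delta_s + (config.ambient_ppm / ppm) * (config.ambient_delta - delta_s)
    else:
        d13c = np.full(ppm.size, config.ambient_delta)
    if config.noise_ppm > 0:
        ppm = np.clip(ppm + rng.normal(0, config.noise_ppm, ppm.size), 1.0, None)
    if config.noise_delta > 0:
        d13c = d13c + rng.normal(0, config.noise_delta, d13c.size)
    return IsotopeSeries(
        sample_id=sample.sample_id,
        replicate=replicate,
        times=schedule,
        co2_ppm=ppm,
        d13c=d13c,
    )


def simulate_spectrum(
    truth: TrueState,
    grid=None,
    config: GeneratorConfig = GeneratorConfig(),
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Gaussian index-band peaks on a smooth convex baseline.

    Grid defaults to 600-4000 cm-1 at 2 cm-1 spacing. The baseline is a
    low-order (convex quadratic) polynomial so that rubberband correction
    removes it exactly up to chord tolerance.
    """
    if grid is None:
        grid = np.arange(600.0, 4000.0 + 2.0, 2.0)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty wavenumber grid")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    b0, b1, b2 = config.baseline_coeffs
    x = (grid - grid[0]) / max(grid[-1] - grid[0], 1.0)
    absorbance = b0 + b1 * x + b2 * (2 * x - 1) ** 2
    for center, height in truth.peak_heights.items():
        absorbance = absorbance + height * np.exp(
            -0.5 * ((grid - center) / config.peak_sigma) ** 2
        )
    if config.noise_absorbance > 0:
        absorbance = absorbance + rng.normal(0, config.noise_absorbance, grid.size)
    return Spectrum(grid, absorbance)


@dataclass
class SynthDataset:
    """In-memory synthetic study: tables plus ground truth."""

    samples: list[Sample]
    truths: list[TrueState]
    samples_table: pd.DataFrame
    headspace: pd.DataFrame  # sample_id, replicate, time_h, co2_ppm
    isotopes: pd.DataFrame  # sample_id, replicate, time_h, co2_ppm, d13c_permil
    spectra: dict[str, Spectrum]
    config: GeneratorConfig

    def headspace_series(self) -> list[HeadspaceSeries]:
        cfg = self.config
        out = []
        for (sid, rep), grp in self.headspace.groupby(["sample_id", "replicate"], sort=True):
            out.append(
                HeadspaceSeries(
                    sample_id=sid,
                    replicate=int(rep),
                    times=grp["time_h"].to_numpy(),
                    co2_ppm=grp["co2_ppm"].to_numpy(),
                    jar_volume=cfg.jar_volume,
                    sample_volume=cfg.sample_volume,
                    withdrawal_volume=cfg.withdrawal_volume,
                    ambient_ppm=cfg.ambient_ppm,
                    temperature=cfg.temperature,
                    pressure=cfg.pressure,
                )
            )
        return out

    def isotope_series(self) -> list[IsotopeSeries]:
        out = []
        for (sid, rep), grp in self.isotopes.groupby(["sample_id", "replicate"], sort=True):
            out.append(
                IsotopeSeries(
                    sample_id=sid,
                    replicate=int(rep),
                    times=grp["time_h"].to_numpy(),
                    co2_ppm=grp["co2_ppm"].to_numpy(),
                    d13c=grp["d13c_permil"].to_numpy(),
                )
            )
        return out


def generate_dataset(config: GeneratorConfig, include_spectra: bool = True) -> SynthDataset:
    """Generate the full synthetic study from one seed."""
    pairs = generate_samples(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    hs_rows, iso_rows = [], []
    spectra: dict[str, Spectrum] = {}
    meta_rows = []
    for sample, truth in pairs:
        prof = GROUP_PROFILES[(sample.material, sample.von_post)]
        meta_rows.append(
            {
                "sample_id": sample.sample_id,
                "material": sample.material,
                "von_post": sample.von_post,
                "dry_mass_g": sample.dry_mass,
                "org_c_fraction": sample.org_c_fraction,
                "solid_d13c_permil": sample.solid_delta13c,
                # covariates for correlation smoke tests only
                "pH": rng.normal(*prof["pH"]),
                "doc_mg_gC": max(rng.normal(*prof["doc"]), 0.01),
                "tdn_mg_gC": max(rng.normal(*prof["tdn"]), 0.005),
                "cn_ratio": max(rng.normal(*prof["cn"]), 5.0),
            }
        )
        for rep in range(config.replicates):
            hs = simulate_headspace(sample, truth, config=config, replicate=rep, rng=rng)
            for t, c in zip(hs.times, hs.co2_ppm):
                hs_rows.append(
                    {"sample_id": sample.sample_id, "replicate": rep, "time_h": t, "co2_ppm": c}
                )
            iso = simulate_isotopes(sample, truth, config=config, replicate=rep, rng=rng)
            for t, c, d in zip(iso.times, iso.co2_ppm, iso.d13c):
                iso_rows.append(
                    {
                        "sample_id": sample.sample_id,
                        "replicate": rep,
                        "time_h": t,
                        "co2_ppm": c,
                        "d13c_permil": d,
                    }
                )
        if include_spectra:
            spectra[sample.sample_id] = simulate_spectrum(truth, config=config, rng=rng)
    return SynthDataset(
        samples=[s for s, _ in pairs],
        truths=[t for _, t in pairs],
        samples_table=pd.DataFrame(meta_rows),
        headspace=pd.DataFrame(hs_rows),
        isotopes=pd.DataFrame(iso_rows),
        spectra=spectra,
        config=config,
    )


def write_dataset(dataset: SynthDataset, out_dir) -> None:
    """Write CSV tables, per-sample spectra and a ground-truth JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.samples_table.to_csv(out / "samples.csv", index=False)
    dataset.headspace.to_csv(out / "headspace.csv", index=False)
    dataset.isotopes.to_csv(out / "isotopes.csv", index=False)
    spec_dir = out / "spectra"
    if dataset.spectra:
        spec_dir.mkdir(exist_ok=True)
    for sid, spec in dataset.spectra.items():
        pd.DataFrame(
            {"wavenumber_cm1": spec.wavenumbers, "absorbance": spec.absorbance}
        ).to_csv(spec_dir / f"{sid}.csv", index=False)
    truth = {
        t.sample_id: {
            "biotic_rate": t.biotic_rate,
            "lime_rate": t.lime_rate,
            "delta_peat": t.delta_peat,
            "delta_lime": t.delta_lime,
            "peak_heights": {str(k): v for k, v in t.peak_heights.items()},
        }
        for t in dataset.truths
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
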