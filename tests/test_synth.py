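"""Generator behaviour: determinism, design counts, and generative identities."""

import numpy as np
import pandas as pd
import pytest

from peatflux import (
    GeneratorConfig,
    Sample,
    TrueState,
    generate_dataset,
    generate_samples,
    simulate_headspace,
    simulate_isotopes,
    simulate_spectrum,
    write_dataset,
)
from peatflux.spectra import peak_height
from peatflux.synth import CONCENTRATION_SCHEDULE_H


def test_empty_design_gives_empty_list():
    cfg = GeneratorConfig(n_peat=0, n_growing_media=0)
    assert generate_samples(cfg) == []


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        GeneratorConfig(n_peat=-1)


def test_default_design_counts_and_materials():
    pairs = generate_samples(GeneratorConfig(seed=0))
    assert len(pairs) == 52
    materials = [s.material for s, _ in pairs]
    assert materials.count("peat") == 28
    assert materials.count("growing_media") == 24
    # peat carries no lime pool; media always do
    for s, t in pairs:
        if s.material == "peat":
            assert t.lime_rate == 0.0
        else:
            assert t.lime_rate > 0.0
            assert abs(t.delta_lime) < 2.0  # lime end-member near 0 permil
        assert -29 < t.delta_peat < -25


def test_fixed_seed_is_bit_identical():
    a = generate_dataset(GeneratorConfig(seed=1), include_spectra=True)
    b = generate_dataset(GeneratorConfig(seed=1), include_spectra=True)
    pd.testing.assert_frame_equal(a.headspace, b.headspace)
    pd.testing.assert_frame_equal(a.isotopes, b.isotopes)
    pd.testing.assert_frame_equal(a.samples_table, b.samples_table)
    for sid in a.spectra:
        np.testing.assert_array_equal(a.spectra[sid].absorbance, b.spectra[sid].absorbance)


def _still_sample() -> tuple[Sample, TrueState]:
    sample = Sample("X1", "peat", "3-4", dry_mass=10.0, org_c_fraction=0.5,
                    solid_delta13c=-27.0)
    truth = TrueState("X1", biotic_rate=0.0, lime_rate=0.0, delta_peat=-27.0,
                      delta_lime=-0.03)
    return sample, truth


def test_zero_production_relaxes_only_via_replacement(noiseless_config):
    sample, truth = _still_sample()
    hs = simulate_headspace(sample, truth, config=noiseless_config)
    # starting at ambient with ambient refills: concentration never moves
    np.testing.assert_allclose(hs.co2_ppm, noiseless_config.ambient_ppm)


def test_no_events_zero_noise_is_exactly_linear(media_pair, noiseless_config):
    sample, truth = media_pair
    cfg = GeneratorConfig(seed=1, noise_ppm=0, noise_delta=0, withdrawal_volume=0.0)
    hs = simulate_headspace(sample, truth, config=cfg)
    slopes = np.diff(hs.co2_ppm) / np.diff(hs.times)
    np.testing.assert_allclose(slopes, slopes[0], rtol=1e-12)


def test_noiseless_series_piecewise_linear_between_events(media_pair, noiseless_config):
    sample, truth = media_pair
    schedule = (0.0, 6.0, 12.0, 24.0, 36.0, 48.0)
    hs = simulate_headspace(sample, truth, schedule, config=noiseless_config)
    # within-interval slope equals the constant production slope after
    # accounting for the event dilution at the interval start
    phi = noiseless_config.withdrawal_volume / noiseless_config.headspace_volume
    rate_slope = None
    for i in range(1, len(schedule)):
        c_start = hs.co2_ppm[i - 1] * (1 - phi) + noiseless_config.ambient_ppm * phi
        slope = (hs.co2_ppm[i] - c_start) / (hs.times[i] - hs.times[i - 1])
        rate_slope = slope if rate_slope is None else rate_slope
        assert slope == pytest.approx(rate_slope, rel=1e-12)


def test_non_increasing_schedule_rejected(media_pair, noiseless_config):
    sample, truth = media_pair
    with pytest.raises(ValueError):
        simulate_headspace(sample, truth, (0.0, 6.0, 6.0), config=noiseless_config)
    with pytest.raises(ValueError):
        simulate_isotopes(sample, truth, (2.0, 4.0), config=noiseless_config)


def test_keeling_identity_holds_at_every_point(media_pair, noiseless_config):
    sample, truth = media_pair
    iso = simulate_isotopes(sample, truth, config=noiseless_config)
    ds = truth.source_delta()
    ca, da = noiseless_config.ambient_ppm, noiseless_config.ambient_delta
    expected = ds + (ca / iso.co2_ppm) * (da - ds)
    np.testing.assert_allclose(iso.d13c, expected, atol=1e-12)


def test_single_source_limit_recovers_delta_peat(peat_pair, noiseless_config):
    from peatflux import fit_keeling

    sample, truth = peat_pair
    assert truth.lime_rate == 0.0
    iso = simulate_isotopes(sample, truth, config=noiseless_config)
    fit = fit_keeling(iso)
    assert fit.intercept == pytest.approx(truth.delta_peat, abs=1e-9)


@pytest.mark.parametrize(
    "biotic, lime, dp, dl, expected",
    [
        (0.1, 0.1, -27.0, 0.0, -13.5),  # equal-mass mixing
        (0.78, 0.22, -27.37, -0.03, (0.78 * -27.37 + 0.22 * -0.03) / 1.0),  # ~ -21.4
    ],
)
def test_source_delta_is_flux_weighted_mean(biotic, lime, dp, dl, expected):
    truth = TrueState("m", biotic_rate=biotic, lime_rate=lime, delta_peat=dp, delta_lime=dl)
    assert truth.source_delta() == pytest.approx(expected, abs=1e-12)
    if biotic == 0.78:
        assert truth.source_delta() == pytest.approx(-21.4, abs=0.05)


def test_spectrum_generator_extractor_consistency():
    truth = TrueState("s", 0.1, 0.0, -27.0, -0.03,
                      peak_heights={1090.0: 0.4, 1420.0: 0.2, 1720.0: 0.3})
    cfg = GeneratorConfig(baseline_coeffs=(0.0, 0.0, 0.0), noise_absorbance=0.0)
    spec = simulate_spectrum(truth, config=cfg)
    for center, h in truth.peak_heights.items():
        assert peak_height(spec, center) == pytest.approx(h, rel=1e-6)


def test_spectrum_empty_grid_rejected():
    truth = TrueState("s", 0.1, 0.0, -27.0, -0.03, peak_heights={1090.0: 0.4})
    with pytest.raises(ValueError):
        simulate_spectrum(truth, grid=np.array([]))


def test_write_dataset_round_trip(tmp_path):
    cfg = GeneratorConfig(seed=2, n_peat=2, n_growing_media=2)
    ds = generate_dataset(cfg)
    write_dataset(ds, tmp_path)
    assert (tmp_path / "samples.csv").exists()
    assert (tmp_path / "truth.json").exists()
    hs = pd.read_csv(tmp_path / "headspace.csv")
    assert set(hs.columns) == {"sample_id", "replicate", "time_h", "co2_ppm"}
    iso = pd.read_csv(tmp_path / "isotopes.csv")
    assert "d13c_permil" in iso.columns
    assert len(list((tmp_path / "spectra").glob("*.csv"))) == 4
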