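"""Flux module: gas conversion, dilution correction, rate fits, QC, dissolution."""

import numpy as np
import pytest

from peatflux import (
    GeneratorConfig,
    HeadspaceSeries,
    Sample,
    dilution_correct,
    dissolved_fraction,
    fit_rate,
    generate_samples,
    ppm_to_mass,
    qc_summary,
    simulate_headspace,
)


def make_sample(**kw) -> Sample:
    defaults = dict(sample_id="S1", material="peat", von_post="3-4",
                    dry_mass=10.0, org_c_fraction=0.5, solid_delta13c=-27.0)
    defaults.update(kw)
    return Sample(**defaults)


class TestPpmToMass:
    def test_zero_ppm_is_zero_mass(self):
        assert ppm_to_mass(0.0, 240.0) == 0.0

    def test_ideal_gas_oracle(self):
        # independent oracle: n = PV/RT = 101325 Pa * 240e-6 m3 / (8.314 * 296.15 K)
        n_air = 101325 * 240e-6 / (8.31446 * 296.15)
        expected = 1000e-6 * n_air * 12.011 * 1e3  # mg C
        assert n_air == pytest.approx(9.876e-3, rel=1e-3)
        assert ppm_to_mass(1000.0, 240.0, 23.0, 101.325) == pytest.approx(expected, rel=1e-12)
        assert ppm_to_mass(1000.0, 240.0) == pytest.approx(0.1186, abs=2e-4)

    def test_linear_in_ppm_and_volume(self):
        m = ppm_to_mass(500.0, 120.0)
        assert ppm_to_mass(1000.0, 120.0) == pytest.approx(2 * m)
        assert ppm_to_mass(500.0, 240.0) == pytest.approx(2 * m)

    def test_negative_ppm_rejected(self):
        with pytest.raises(ValueError):
            ppm_to_mass(-1.0, 240.0)


class TestDilutionCorrect:
    def test_zero_production_gives_all_zeros(self):
        series = HeadspaceSeries("S1", 0, times=[0, 6, 24, 48],
                                 co2_ppm=[420.0] * 4, ambient_ppm=420.0)
        np.testing.assert_allclose(dilution_correct(series), 0.0, atol=1e-15)

    def test_no_events_reduces_to_raw_differencing(self):
        series = HeadspaceSeries("S1", 0, times=[0, 6, 24], co2_ppm=[400, 700, 1600],
                                 ambient_ppm=400.0, event_times=np.array([]))
        got = dilution_correct(series)
        expected = ppm_to_mass(np.array([400, 700, 1600.0]), series.headspace_volume) - \
            ppm_to_mass(400.0, series.headspace_volume)
        np.testing.assert_allclose(got, expected)

    def test_missing_ambient_with_events_rejected(self):
        series = HeadspaceSeries("S1", 0, times=[0, 6, 24], co2_ppm=[400, 700, 1600],
                                 ambient_ppm=None)
        with pytest.raises(ValueError):
            dilution_correct(series)

    def test_round_trip_against_generator(self, media_pair, noiseless_config):
        sample, truth = media_pair
        hs = simulate_headspace(sample, truth, config=noiseless_config)
        cum = dilution_correct(hs)
        slope_per_day = np.polyfit(hs.times / 24.0, cum, 1)[0]
        assert slope_per_day == pytest.approx(truth.total_rate * sample.org_c_mass, rel=1e-9)

    def test_invariant_to_number_of_sampling_events(self, media_pair, noiseless_config):
        # events redistribute but never create mass: corrected cumulative
        # production at 48 h is identical for sparse and dense schedules
        sample, truth = media_pair
        sparse = simulate_headspace(sample, truth, (0.0, 24.0, 48.0), config=noiseless_config)
        dense = simulate_headspace(sample, truth, tuple(np.arange(0.0, 49.0, 6.0)),
                                   config=noiseless_config)
        assert dilution_correct(sparse)[-1] == pytest.approx(
            dilution_correct(dense)[-1], rel=1e-10)


class TestFitRate:
    def test_exact_linear_input_recovers_rate(self):
        sample = make_sample()
        rate = 0.15  # mg CO2-C / g orgC / day
        slope_mg_day = rate * sample.org_c_mass
        v = 240.0
        times = np.array([0.0, 6.0, 24.0, 48.0])
        mass0 = ppm_to_mass(400.0, v)
        ppm = (mass0 + slope_mg_day * times / 24.0) / ppm_to_mass(1.0, v)
        series = HeadspaceSeries("S1", 0, times, ppm, ambient_ppm=400.0,
                                 event_times=np.array([]))
        res = fit_rate(series, sample)
        assert res.rate == pytest.approx(0.15, rel=1e-12)
        assert res.r_squared == pytest.approx(1.0)
        assert res.qc_pass

    def test_constant_concentration_degenerate_fit(self):
        series = HeadspaceSeries("S1", 0, [0, 6, 24, 48], [420.0] * 4, ambient_ppm=420.0)
        res = fit_rate(series, make_sample())
        assert res.rate == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(res.r_squared)
        assert not res.qc_pass

    def test_too_few_points_rejected(self):
        series = HeadspaceSeries("S1", 0, [0, 6], [420, 600], ambient_ppm=420.0)
        with pytest.raises(ValueError):
            fit_rate(series, make_sample())

    def test_mass_equivariance(self, media_pair, noiseless_config):
        # doubling dry mass at a fixed headspace series halves the per-gram rate
        sample, truth = media_pair
        hs = simulate_headspace(sample, truth, config=noiseless_config)
        heavy = make_sample(sample_id=sample.sample_id, dry_mass=2 * sample.dry_mass,
                            org_c_fraction=sample.org_c_fraction)
        light = make_sample(sample_id=sample.sample_id, dry_mass=sample.dry_mass,
                            org_c_fraction=sample.org_c_fraction)
        assert fit_rate(hs, heavy).rate == pytest.approx(fit_rate(hs, light).rate / 2)

    def test_noisy_recovery_within_two_se(self, media_pair, rng):
        # 1000 noisy replicates: the mean recovered rate sits within 2 se of truth
        sample, truth = media_pair
        cfg = GeneratorConfig(seed=1, noise_ppm=10.0)
        rates = []
        for _ in range(1000):
            hs = simulate_headspace(sample, truth, config=cfg, rng=rng)
            rates.append(fit_rate(hs, sample).rate)
        rates = np.asarray(rates)
        se = rates.std(ddof=1) / np.sqrt(rates.size)
        assert abs(rates.mean() - truth.total_rate) < 2 * se


class TestQcSummary:
    def _est(self, r2):
        from peatflux.flux import FluxResults

        qc = bool(np.isfinite(r2) and r2 > 0.8)
        return FluxResults("S", 0, 0.1, 0.01, r2, 4, qc)

    def test_all_good_discards_nothing(self):
        out = qc_summary([self._est(1.0)] * 4)
        assert out.discard_fraction == 0.0
        assert len(out.retained) == 4

    def test_counting(self):
        out = qc_summary([self._est(1.0), self._est(0.95), self._est(0.9), self._est(0.5)])
        assert out.discard_fraction == pytest.approx(0.25)

    def test_default_noise_discard_fraction_below_10pct(self, rng):
        cfg = GeneratorConfig(seed=5)
        pairs = generate_samples(cfg)
        fits = []
        for sample, truth in pairs:
            for rep in range(cfg.replicates):
                hs = simulate_headspace(sample, truth, config=cfg, replicate=rep, rng=rng)
                fits.append(fit_rate(hs, sample))
        assert qc_summary(fits).discard_fraction < 0.10


class TestDissolvedFraction:
    def test_vanishing_water_gives_zero(self):
        assert dissolved_fraction(5.0, water_volume=0.0) == 0.0

    def test_monotone_in_ph_and_water(self):
        assert dissolved_fraction(6.2) > dissolved_fraction(4.0)
        assert dissolved_fraction(6.2, water_volume=12.0) > dissolved_fraction(
            6.2, water_volume=6.0)

    def test_speciation_oracle_and_20pct_bound(self):
        # independent carbonate-speciation oracle at KH = 3.4e-2 M/atm, pK1 = 6.35
        t_k = 296.15
        kh = 3.4e-2 * np.exp(2400 * (1 / t_k - 1 / 298.15))
        gas = 0.244 / (0.0820574 * t_k)
        aq = kh * 0.006 * (1 + 10 ** (6.2 - 6.35))
        expected = aq / (aq + gas)
        got = dissolved_fraction(6.2, 23.0, 244.0, 6.0)
        assert got == pytest.approx(expected, rel=1e-9)
        assert got <= 0.20

    def test_invalid_ph_rejected(self):
        with pytest.raises(ValueError):
            dissolved_fraction(0.0)
        with pytest.raises(ValueError):
            dissolved_fraction(14.5)
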