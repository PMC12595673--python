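import numpy as np
import pytest
from scipy.integrate import quad
from scipy.signal import periodogram

from assrkit.errors import ParameterError
from assrkit.synth import (CohortSpec, cohort_density_grid,
                           DEFAULT_BAND_DENSITY, expected_plf, iter_cohort,
                           new_ground_truth, simulate_assr_trial,
                           simulate_background, simulate_cohort)

FS = 2000.0


class TestExpectedPLF:
    def test_uniform_and_point_mass_limits(self):
        assert expected_plf(0.0) == 0.0
        assert expected_plf(1e6) >= 0.999

    def test_matches_von_mises_integral_oracle(self):
        """Independent oracle: mean resultant length by direct numerical
        integration of the von Mises density."""
        for kappa in (0.5, 2.0, 5.0):
            norm = quad(lambda x: np.exp(kappa * np.cos(x)),
                        -np.pi, np.pi)[0]
            r = quad(lambda x: np.cos(x) * np.exp(kappa * np.cos(x)),
                     -np.pi, np.pi)[0] / norm
            assert expected_plf(kappa) == pytest.approx(r, abs=1e-10)
        assert expected_plf(2.0) == pytest.approx(0.6978, abs=5e-4)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ParameterError):
            expected_plf(-1.0)


class TestBackground:
    def test_flat_density_against_periodogram_oracle(self):
        """Exponent 0 at unit total variance: one-sided density
        sigma^2/(fs/2), verified with scipy's periodogram."""
        rng = np.random.default_rng(3)
        psds = []
        for _ in range(200):
            x = simulate_background(1.0, FS, exponent=0.0,
                                    aperiodic_density_uv2=0.001, rng=rng)
            f, p = periodogram(x, fs=FS)
            psds.append(p)
        mean_psd = np.mean(psds, axis=0)
        sel = (f >= 10) & (f <= 900)
        assert mean_psd[sel].mean() == pytest.approx(0.001, rel=0.10)

    def test_zero_density_gives_silence(self):
        rng = np.random.default_rng(0)
        x = simulate_background(1.0, FS, exponent=2.0,
                                aperiodic_density_uv2=0.0, rng=rng)
        assert np.all(x == 0)

    def test_determinism(self):
        a = simulate_background(1.0, FS, 1.0, [(10.0, 4.0, 5.0)],
                                np.random.default_rng(42), 0.5)
        b = simulate_background(1.0, FS, 1.0, [(10.0, 4.0, 5.0)],
                                np.random.default_rng(42), 0.5)
        np.testing.assert_array_equal(a, b)

    def test_negative_density_rejected(self):
        with pytest.raises(ParameterError):
            simulate_background(1.0, FS, 0.0, [(10.0, 4.0, -1.0)],
                                np.random.default_rng(0))

    def test_variance_matches_density_integral(self):
        """Sample variance ~ integral of the target density (1–1000 Hz)."""
        freqs = np.fft.rfftfreq(4000, 1 / FS)
        dens = cohort_density_grid(freqs, DEFAULT_BAND_DENSITY, 2.0)
        from assrkit.synth import _shaped_noise
        target = np.trapezoid(dens, freqs)
        rng = np.random.default_rng(9)
        variances = [_shaped_noise(dens, 4000, FS, rng).var()
                     for _ in range(100)]
        assert np.mean(variances) == pytest.approx(target, rel=0.15)


class TestASSRTrial:
    def test_point_mass_kappa_degenerate_phases(self):
        rng = np.random.default_rng(1)
        phases = [simulate_assr_trial(40.0, 1.0, 1e6, 0.0, (-1.0, 1.0),
                                      FS, rng)[1] for _ in range(100)]
        resultant = np.abs(np.mean(np.exp(1j * np.array(phases))))
        circ_sd = np.sqrt(-2 * np.log(resultant))
        assert circ_sd < 0.01

    def test_zero_kappa_uniform_phases(self):
        """Rayleigh test at alpha = 0.001 over 1000 draws."""
        rng = np.random.default_rng(2)
        phases = np.array([
            simulate_assr_trial(40.0, 1.0, 0.0, 0.0, (-1.0, 1.0), FS,
                                rng)[1]
            for _ in range(1000)])
        n = phases.size
        r_bar = np.abs(np.mean(np.exp(1j * phases)))
        # reject uniformity when n R^2 > -ln(alpha)
        assert n * r_bar ** 2 < -np.log(0.001)

    def test_zero_amplitude_leaves_background_only(self):
        freqs = np.fft.rfftfreq(4000, 1 / FS)
        dens = np.where((freqs >= 1) & (freqs <= 1000), 0.1, 0.0)
        e0, _ = simulate_assr_trial(40.0, 0.0, 2.0, 0.3, (-1.0, 1.0), FS,
                                    np.random.default_rng(5),
                                    background_density=dens)
        e2, _ = simulate_assr_trial(40.0, 2.0, 2.0, 0.3, (-1.0, 1.0), FS,
                                    np.random.default_rng(5),
                                    background_density=dens)
        t = -1.0 + np.arange(4000) / FS
        pre = t < 0
        np.testing.assert_array_equal(e0[pre], e2[pre])
        assert np.any(e0[~pre] != e2[~pre])

    def test_window_must_cover_train(self):
        with pytest.raises(ParameterError):
            simulate_assr_trial(40.0, 1.0, 1.0, 0.0, (-1.0, 0.5), FS,
                                np.random.default_rng(0))


class TestCohort:
    def _tiny_spec(self, **kw):
        defaults = dict(n_males=2, n_females=2, n_days=1,
                        stim_rates_hz=(40.0,), n_trials=4,
                        conditions=("baseline",), seed=3)
        defaults.update(kw)
        return CohortSpec(**defaults)

    def test_session_count(self):
        sessions, _ = simulate_cohort(self._tiny_spec())
        assert len(sessions) == 4
        ids = {es.meta["animal_id"] for es in sessions}
        assert ids == {"M01", "M02", "F01", "F02"}

    def test_bit_identical_datasets_for_same_seed(self):
        a, gta = simulate_cohort(self._tiny_spec())
        b, gtb = simulate_cohort(self._tiny_spec())
        for ea, eb in zip(a, b):
            np.testing.assert_array_equal(ea.data, eb.data)
        assert gta.sessions == gtb.sessions

    def test_zero_within_animal_variance_repeats_parameters(self):
        spec = self._tiny_spec(n_days=3, sigma_day=0.0, sigma_resid=0.0)
        gt = new_ground_truth(spec)
        list(iter_cohort(spec, gt))
        for aid in ("M01", "F02"):
            amps = {gt.sessions[f"{aid}/day{d}/baseline/r40"]["amp_uv"]
                    for d in (1, 2, 3)}
            assert len(amps) == 1  # identical generating amplitude per day

    def test_invalid_rate_rejected_before_generation(self):
        with pytest.raises(ParameterError, match="rates"):
            list(iter_cohort(self._tiny_spec(stim_rates_hz=(30.0,))))

    def test_empty_conditions_rejected(self):
        with pytest.raises(ParameterError):
            list(iter_cohort(self._tiny_spec(conditions=())))

    def test_intended_icc_formula(self):
        spec = self._tiny_spec(sigma_animal=0.3, sigma_day=0.1,
                               sigma_resid=0.28)
        expected = 0.09 / (0.09 + 0.01 + 0.0784)
        assert spec.intended_icc() == pytest.approx(expected)

    def test_ket_band_multipliers_scale_density(self):
        spec = CohortSpec(conditions=("SAL", "KET"))
        sal = spec.band_power_uv2[("M", "SAL")]
        ket = spec.band_power_uv2[("M", "KET")]
        assert ket["delta"] < sal["delta"]
        assert ket["low_gamma"] > sal["low_gamma"]
        assert ket["high_gamma"] > sal["high_gamma"]
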