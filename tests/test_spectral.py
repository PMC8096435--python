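"""Power spectra and the 1.7x-over-background oscillation call."""
import numpy as np
import pytest

from embryopulse import spectral
from embryopulse.piv import VelocityField


def _field(u: np.ndarray, v: np.ndarray | None = None,
           dt: float = 5.0) -> VelocityField:
    """Wrap (n_t, n_vec) component series into a single-row vector grid."""
    u = np.asarray(u, dtype=float)
    if u.ndim == 1:
        u = u[:, None]
    v = np.zeros_like(u) if v is None else np.asarray(v, dtype=float)
    n_t, n_vec = u.shape
    return VelocityField(
        x_um=np.arange(n_vec, dtype=float), y_um=np.zeros(1),
        u=u.reshape(n_t, 1, n_vec), v=v.reshape(n_t, 1, n_vec),
        valid=np.ones((n_t, 1, n_vec), dtype=bool),
        pixel_size=0.5, frame_interval=dt,
    )


class TestEmbryoSpectrum:
    def test_constant_velocity_gives_zero_power(self):
        field = _field(np.full(120, 3.2), np.full((120, 1), -1.1))
        spec = spectral.embryo_spectrum(field)
        assert np.allclose(spec.power, 0.0, atol=1e-20)

    def test_pure_sine_dominates_nearest_grid_periods(self):
        # oracle: the DFT of a sinusoid concentrates at the grid
        # frequencies nearest the true one (80 s sits between two bins of
        # the 600 s record, so the two straddling bins share the power)
        t = np.arange(120) * 5.0
        field = _field(np.sin(2 * np.pi * t / 80.0))
        spec = spectral.embryo_spectrum(field)
        straddle = np.argsort(np.abs(spec.periods - 80.0))[:2]
        assert np.argmax(spec.power) in straddle
        assert spec.power[straddle].sum() > 0.7 * spec.power.sum()
        assert 50.0 <= spec.periods[np.argmax(spec.power)] <= 120.0

    def test_too_few_time_points_rejected(self):
        field = _field(np.sin(np.arange(10)))
        with pytest.raises(ValueError, match="32"):
            spectral.embryo_spectrum(field)

    def test_white_noise_rarely_called_oscillating(self):
        # Monte-Carlo null at the protocol's record length: 200 seeded
        # repetitions of white-noise velocity fields with 50 vectors
        n_false = 0
        for s in range(200):
            rng = np.random.default_rng(1000 + s)
            field = _field(rng.standard_normal((119, 50)),
                           rng.standard_normal((119, 50)))
            spec = spectral.embryo_spectrum(field)
            call = spectral.call_oscillation(spec)
            n_false += call.is_oscillating
        assert n_false <= 10  # non-oscillating in >= 95% of runs


class TestOscillationCall:
    def test_flat_spectrum_ratio_one_not_oscillating(self):
        spec = spectral.PowerSpectrum(
            periods=595.0 / np.arange(1, 60), power=np.full(59, 3.3))
        call = spectral.call_oscillation(spec)
        assert call.ratio == pytest.approx(1.0)
        assert not call.is_oscillating

    def test_threshold_boundary_counts_as_oscillating(self):
        periods = 595.0 / np.arange(1, 60)
        power = np.ones(59)
        in_band = (periods >= 50) & (periods <= 120)
        k = np.argmax(in_band)
        n = len(power)
        # set the band peak so that peak / mean == 1.7 exactly
        power[k] = 1.7 * (n - 1) / (n - 1.7)
        call = spectral.call_oscillation(
            spectral.PowerSpectrum(periods=periods, power=power))
        assert call.ratio == pytest.approx(1.7)
        assert call.is_oscillating

    def test_end_to_end_oscillating_movie_detected(self, oscillating_field):
        field, keep, truth = oscillating_field
        spec = spectral.embryo_spectrum(field, keep=keep)
        call = spectral.call_oscillation(spec)
        assert call.is_oscillating
        assert 50.0 <= call.peak_period <= 120.0
        # within one frequency bin of the true 80 s period
        freqs = np.sort(1.0 / spec.periods)
        df = freqs[1] - freqs[0]
        assert abs(1.0 / call.peak_period - 1.0 / truth.period) <= df

    def test_scaling_velocities_preserves_call(self):
        rng = np.random.default_rng(2)
        t = np.arange(119) * 5.0
        u = np.sin(2 * np.pi * t / 80.0)[:, None] + 0.3 * rng.standard_normal(
            (119, 20))
        base = spectral.call_oscillation(
            spectral.embryo_spectrum(_field(u)))
        scaled = spectral.call_oscillation(
            spectral.embryo_spectrum(_field(3.0 * u)))
        assert scaled.amplitude == pytest.approx(9.0 * base.amplitude)
        assert scaled.background == pytest.approx(9.0 * base.background)
        assert scaled.ratio == pytest.approx(base.ratio)
        assert scaled.is_oscillating == base.is_oscillating

    def test_constant_drift_does_not_change_call(self):
        rng = np.random.default_rng(3)
        u = 0.5 * rng.standard_normal((119, 20))
        base = spectral.call_oscillation(spectral.embryo_spectrum(_field(u)))
        drifted = spectral.call_oscillation(
            spectral.embryo_spectrum(_field(u + 7.5)))
        assert drifted.ratio == pytest.approx(base.ratio)
        assert drifted.is_oscillating == base.is_oscillating

    def test_detection_power_monotone_in_amplitude(self):
        # seeded sweep: P(oscillating) non-decreasing with true amplitude
        t = np.arange(119) * 5.0
        sine = np.sin(2 * np.pi * t / 80.0)[:, None]
        rates = []
        for amp in (0.0, 0.2, 0.6, 1.5):
            hits = 0
            for s in range(40):
                rng = np.random.default_rng(500 + s)
                u = amp * sine + rng.standard_normal((119, 30))
                call = spectral.call_oscillation(
                    spectral.embryo_spectrum(_field(u)))
                hits += call.is_oscillating
            rates.append(hits / 40)
        assert all(b >= a for a, b in zip(rates, rates[1:]))
        assert rates[0] < 0.5 and rates[-1] == 1.0

    def test_empty_band_rejected(self):
        spec = spectral.PowerSpectrum(periods=np.array([10.0, 5.0]),
                                      power=np.ones(2))
        with pytest.raises(ValueError, match="band"):
            spectral.call_oscillation(spec)


class TestGenotypeSpectrum:
    def test_single_spectrum_mean_is_itself_sem_undefined(self):
        spec = spectral.PowerSpectrum(periods=np.array([100.0, 50.0]),
                                      power=np.array([1.0, 2.0]))
        df = spectral.genotype_spectrum([spec])
        assert np.allclose(df.power_mean, spec.power)
        assert df.power_sem.isna().all()

    def test_identical_spectra_sem_zero(self):
        spec = spectral.PowerSpectrum(periods=np.array([100.0, 50.0]),
                                      power=np.array([1.0, 2.0]))
        df = spectral.genotype_spectrum([spec, spec])
        assert np.allclose(df.power_mean, spec.power)
        assert np.allclose(df.power_sem, 0.0)

    def test_sem_scales_like_sd_over_sqrt_n(self, rng):
        periods = 595.0 / np.arange(1, 60)
        base = np.ones(59)
        n = 40
        sd = 0.2
        specs = [
            spectral.PowerSpectrum(
                periods=periods,
                power=np.abs(base + rng.normal(0, sd, 59)))
            for _ in range(n)
        ]
        df = spectral.genotype_spectrum(specs)
        assert df.power_sem.mean() == pytest.approx(sd / np.sqrt(n), rel=0.3)

    def test_mismatched_grids_rejected(self):
        s1 = spectral.PowerSpectrum(periods=np.array([100.0, 50.0]),
                                    power=np.ones(2))
        s2 = spectral.PowerSpectrum(periods=np.array([90.0, 45.0]),
                                    power=np.ones(2))
        with pytest.raises(ValueError, match="grid"):
            spectral.genotype_spectrum([s1, s2])
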