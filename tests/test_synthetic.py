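"""Generator contracts: ground truth, reproducibility, study conditions."""
import numpy as np
import pytest

from embryopulse import events, synthetic
from embryopulse.io import read_movie, write_movie


class TestMovieGenerator:
    def test_static_case_all_frames_identical(self):
        spec = synthetic.SyntheticMovieSpec(
            image_size=(96, 96), embryo_radius=16.0, oscillation_period=0.0,
            noise_sd=0.0, drift=(0.0, 0.0), n_frames=5, seed=0)
        movie, truth = synthetic.make_movie(spec)
        assert np.array_equal(movie.frames[0], movie.frames[1])
        assert np.array_equal(movie.frames[0], movie.frames[-1])
        assert np.all(truth.radius_um == spec.embryo_radius)

    def test_boundary_radius_fourier_peak_at_set_period(self):
        # oracle: DFT of the analytic r(t) samples. An 80 s period on the
        # 600 s record falls between two frequency bins; the peak must land
        # on one of the two straddling grid periods, which together carry
        # the bulk of the power.
        spec = synthetic.SyntheticMovieSpec(seed=1)  # 120 frames at 5 s, 80 s
        _, truth = synthetic.make_movie(spec)
        r = truth.radius_um - truth.radius_um.mean()
        power = np.abs(np.fft.rfft(r)[1:]) ** 2
        freqs = np.fft.rfftfreq(len(r), d=spec.frame_interval)[1:]
        grid_periods = 1.0 / freqs
        straddle = np.argsort(np.abs(grid_periods - 80.0))[:2]
        assert np.argmax(power) in straddle
        assert power[straddle].sum() > 0.7 * power.sum()

    def test_default_acquisition_is_120_frames_every_5s(self):
        spec = synthetic.SyntheticMovieSpec()
        assert spec.n_frames == 120
        assert spec.frame_interval == 5.0
        assert spec.n_frames * spec.frame_interval == 600.0  # 10 min

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            synthetic.SyntheticMovieSpec(oscillation_period=8.0,
                                         frame_interval=5.0)

    def test_embryo_exceeding_frame_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            synthetic.SyntheticMovieSpec(image_size=(64, 64),
                                         embryo_radius=40.0)

    def test_same_seed_bit_identical(self):
        spec = synthetic.SyntheticMovieSpec(image_size=(64, 64),
                                            embryo_radius=10.0, n_frames=3,
                                            seed=11)
        m1, _ = synthetic.make_movie(spec)
        m2, _ = synthetic.make_movie(spec)
        assert np.array_equal(m1.frames, m2.frames)

    def test_tiff_roundtrip_preserves_calibration(self, tmp_path):
        spec = synthetic.SyntheticMovieSpec(image_size=(48, 48),
                                            embryo_radius=8.0, n_frames=3,
                                            seed=2)
        movie, _ = synthetic.make_movie(spec)
        path = tmp_path / "movie.tif"
        write_movie(path, movie)
        back = read_movie(path)
        assert back.n_frames == 3
        assert back.pixel_size == pytest.approx(movie.pixel_size, rel=1e-6)
        assert back.frame_interval == pytest.approx(movie.frame_interval)
        assert np.allclose(back.frames, np.round(movie.frames), atol=0.5)


class TestAngleSeries:
    def test_noiseless_final_angle_equals_plateau(self, presets):
        series = synthetic.make_angle_series(presets["WT"], 5, noise_sd=0.0,
                                             seed=3)
        for s in series:
            assert s.angles_deg[-1] == pytest.approx(s.truth["angle_end"])

    def test_flat_series_when_no_compaction(self, presets):
        import dataclasses

        flat = dataclasses.replace(presets["WT"], angle_start=100.0,
                                   angle_end=100.0, angle_start_sd=0.0,
                                   angle_end_sd=0.0)
        series = synthetic.make_angle_series(flat, 3, noise_sd=0.0, seed=4)
        for s in series:
            assert np.allclose(s.angles_deg, 100.0)

    def test_wt_cohort_mean_final_angle(self, presets):
        # 23 embryos as in the wild-type cohort; 147 ± 2 (SEM)
        series = synthetic.make_angle_series(presets["WT"], 23, noise_sd=5.0,
                                             seed=0)
        mean_final = np.mean([s.angles_deg[1] for s in series])
        assert abs(mean_final - 147.0) <= 2 * 2.0

    def test_reproducible(self, presets):
        a = synthetic.make_angle_series(presets["WT"], 4, seed=9)
        b = synthetic.make_angle_series(presets["WT"], 4, seed=9)
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1.angles_deg, s2.angles_deg)


class TestTimelines:
    def test_all_failures_yield_single_cell_with_attempts(self, presets):
        import dataclasses

        fail = dataclasses.replace(presets["mzMyh9;mzMyh10"],
                                   division_failure_prob=1.0)
        tls = synthetic.make_timeline(fail, 3, seed=5)
        for tl in tls:
            assert events.final_cell_count(tl) == 1
            attempts = [e for e in tl.events if e.type == "failed_division"]
            assert len(attempts) == 5  # one attempt per wave, single cell

    def test_no_failures_five_waves_give_32_cells(self, presets):
        tls = synthetic.make_timeline(presets["WT"], 3, seed=6)
        for tl in tls:
            assert events.final_cell_count(tl) == 32

    def test_wt_interwave_gap_near_published_duration(self, presets):
        tls = synthetic.make_timeline(presets["WT"], 23, seed=0)
        gaps = [events.stage_duration(tl, 3, 4) for tl in tls]
        assert abs(np.mean(gaps) - 7.0) <= 2 * 0.3  # 7.0 ± 0.3 (SEM)

    def test_events_on_half_hour_grid(self, presets):
        tls = synthetic.make_timeline(presets["mzMyh9"], 4, seed=7)
        for tl in tls:
            for e in tl.events:
                assert (e.time_h / 0.5) == pytest.approx(round(e.time_h / 0.5))

    def test_reproducible(self, presets):
        a = synthetic.make_timeline(presets["mzMyh9;mzMyh10"], 4, seed=8)
        b = synthetic.make_timeline(presets["mzMyh9;mzMyh10"], 4, seed=8)
        for t1, t2 in zip(a, b):
            assert t1.events == t2.events


class TestAreaSeries:
    def test_noiseless_slope_recovers_rate_exactly(self, presets):
        from embryopulse.morphometrics import growth_rate

        series = synthetic.make_area_series(presets["WT"], 3, noise_sd=0.0,
                                            seed=10)
        for s in series:
            fit = growth_rate(s)
            assert fit.rate_um2_min == pytest.approx(
                s.truth["growth_rate_um2_min"], abs=1e-9)

    def test_minimum_coverage_enforced(self, presets):
        with pytest.raises(ValueError):
            synthetic.make_area_series(presets["WT"], 2, hours=5)


class TestStainStack:
    def test_unit_ratio_measured_near_one(self):
        from embryopulse.quantify import measure_cells

        stack, rois, px = synthetic.make_stain_stack(6, 1.0, seed=0)
        recs = measure_cells(stack[0], rois, px)
        for r in recs:
            assert r.nc_ratio == pytest.approx(1.0, abs=0.05)

    def test_single_cell_is_outer(self):
        _, rois, _ = synthetic.make_stain_stack(1, 2.0, seed=1)
        assert rois.position_true.tolist() == ["outer"]

    def test_generated_label_count(self):
        _, rois, _ = synthetic.make_stain_stack(58, 1.5, inner_fraction=0.4,
                                                seed=2)
        assert len(rois) == 58
        assert (rois.position_true == "inner").sum() == round(0.4 * 58)
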