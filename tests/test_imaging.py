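"""ROI intensity, kymographs, length measurement, localization, onset."""

import numpy as np
import pytest

from pifeflow import simgen
from pifeflow.containers import ImageStack, Kymograph, ROI, Trajectory
from pifeflow.imaging import (
    NoPeakError,
    build_kymograph,
    detect_association_start,
    extract_roi_intensity,
    localize_qd,
    measure_length,
)


def _stack(pixels, dt=0.1, px=0.167):
    return ImageStack(pixels=np.asarray(pixels), frame_interval_s=dt,
                      pixel_size_um=px)


class TestRoiIntensity:
    def test_uniform_frame_gives_zero(self):
        stack = _stack(np.full((3, 20, 30), 7, dtype=np.uint16))
        roi = ROI(5, 10, 5, 15, tether_col=5)
        traj = extract_roi_intensity(stack, roi)
        np.testing.assert_allclose(traj.values, 0.0)

    def test_single_dye_on_dark_background(self, r82a):
        p = r82a.replace(noise_sd=0.0)
        stack, _ = simgen.render_movie(
            [{"tether_rc": (16, 10), "lengths_um": np.full(3, 3.0),
              "per_dye_brightness": np.full((3, 1), 1e4)}],
            p, frame_shape=(32, 64), baseline_counts=0.0, rng=0)
        roi = ROI(10, 23, 5, 40, tether_col=10)
        traj = extract_roi_intensity(stack, roi)
        assert traj.values[0] == pytest.approx(1e4, rel=1e-3)

    def test_association_fold_matches_ground_truth(self, r82a):
        """Rendered association movie -> ROI fold increase matches the
        generator's per-dye brightness sum within 5%."""
        p = r82a.replace(noise_sd=0.0, concentration_nM=100.0)
        rng = np.random.default_rng(11)
        traj, truth = simgen.simulate_association_trajectory(
            p, 40.0, baseline_s=5.0, rng=rng, bleaching=False)
        stack, _ = simgen.render_movie(
            [{"tether_rc": (16, 4), "lengths_um": np.full(traj.values.size, 6.0),
              "per_dye_brightness": truth.per_dye_brightness}],
            p, frame_shape=(32, 52), baseline_counts=100.0,
            read_noise_sd=1.0, rng=rng)
        roi = ROI(10, 23, 2, 48, tether_col=4)
        measured = extract_roi_intensity(stack, roi)
        true_sum = truth.per_dye_brightness.sum(axis=1)
        fold_measured = measured.values[-50:].mean() / measured.values[:40].mean()
        fold_true = true_sum[-50:].mean() / true_sum[:40].mean()
        assert fold_measured == pytest.approx(fold_true, rel=0.05)


class TestKymograph:
    def test_single_frame_equals_column_sums(self):
        rng = np.random.default_rng(0)
        pixels = rng.integers(0, 100, size=(1, 20, 30)).astype(np.uint16)
        roi = ROI(5, 15, 5, 25, tether_col=5)
        kym = build_kymograph(_stack(pixels), roi)
        frame = pixels[0].astype(float)
        sub = frame[5:15, 5:25]
        # background via the same rule: median of the 2-px ring
        outer = frame[3:17, 3:27]
        mask = np.ones(outer.shape, bool)
        mask[2:-2, 2:-2] = False
        bg = np.median(outer[mask])
        np.testing.assert_allclose(kym.values[0], (sub - bg).sum(axis=0))

    def test_constant_stack_gives_identical_rows(self):
        pixels = np.tile(np.arange(600, dtype=np.uint16).reshape(20, 30),
                         (4, 1, 1))
        roi = ROI(5, 15, 5, 25, tether_col=5)
        kym = build_kymograph(_stack(pixels), roi)
        for row in kym.values[1:]:
            np.testing.assert_array_equal(row, kym.values[0])

    def test_column_sum_matches_roi_intensity(self):
        """Summing the kymograph over position reproduces the integrated
        ROI intensity frame by frame (same background rule)."""
        rng = np.random.default_rng(3)
        pixels = rng.integers(0, 500, size=(6, 24, 40)).astype(np.uint16)
        roi = ROI(6, 18, 8, 30, tether_col=8)
        stack = _stack(pixels)
        kym = build_kymograph(stack, roi)
        traj = extract_roi_intensity(stack, roi)
        np.testing.assert_allclose(kym.values.sum(axis=1), traj.values,
                                   rtol=1e-12, atol=1e-8)


class TestMeasureLength:
    def _kym(self, values):
        return Kymograph(values=np.asarray(values, float), pixel_size_um=0.167,
                         frame_interval_s=0.1)

    def test_contiguous_block_width(self):
        v = np.zeros((4, 40))
        v[:, 10:25] = 1000.0
        traj = measure_length(self._kym(v))
        np.testing.assert_allclose(traj.values, 15 * 0.167)

    def test_all_dark_flagged_zero(self):
        traj = measure_length(self._kym(np.zeros((5, 30))))
        np.testing.assert_allclose(traj.values, 0.0)
        assert traj.flags["empty_frames"] == [0, 1, 2, 3, 4]

    def test_offset_invariance(self):
        rng = np.random.default_rng(5)
        v = rng.normal(10, 2, size=(8, 50))
        v[:, 5:30] += 500.0
        a = measure_length(self._kym(v)).values
        b = measure_length(self._kym(v + 123.4)).values
        np.testing.assert_allclose(a, b)

    def test_rendered_movie_precompaction_length(self, clean_wt):
        """Length from a rendered compaction movie matches L0 within 1 px
        before the lag, and the extent shrinks during compaction."""
        rng = np.random.default_rng(3)
        traj, truth = simgen.simulate_compaction_trajectory(clean_wt, 12.0,
                                                            rng=rng)
        occ = simgen.simulate_occupancy(clean_wt, 12.0, rng=rng)
        itraj, itruth = simgen.simulate_intensity_trajectory(
            occ, clean_wt, rng=rng, bleaching=False)
        stack, _ = simgen.render_movie(
            [{"tether_rc": (16, 5), "lengths_um": traj.values,
              "per_dye_brightness": itruth.per_dye_brightness}],
            clean_wt, frame_shape=(32, 64), baseline_counts=100.0, rng=rng)
        kym = build_kymograph(stack, ROI(10, 23, 2, 50, tether_col=5))
        # dye pile-up at the tether stretches the intensity range; a low
        # threshold fraction keeps extended frames above threshold
        lengths = measure_length(kym, threshold_fraction=0.1)
        pre = lengths.values[:int(truth.lag_s / clean_wt.dt) - 1]
        assert np.all(np.abs(pre - truth.l0_um) <= 1.01 * 0.167)
        smooth = np.convolve(lengths.values, np.ones(5) / 5, mode="valid")
        during = smooth[int(truth.lag_s / clean_wt.dt) + 5:]
        assert np.all(np.diff(during) <= 0.167 + 1e-9)
        assert during[-1] < during[0] - 2.0


class TestLocalizeQD:
    def test_noiseless_center_identity(self):
        x = np.arange(40.0)
        y = 500 * np.exp(-0.5 * ((x - 17.0) / 2.0) ** 2)
        assert localize_qd(y, pixel_size_um=0.167) == pytest.approx(
            17.0 * 0.167, abs=1e-6)

    def test_subpixel_shift_recovered(self):
        x = np.arange(40.0)
        y = 500 * np.exp(-0.5 * ((x - 17.4) / 2.0) ** 2)
        assert localize_qd(y) == pytest.approx(17.4, abs=0.02)

    def test_integer_shift_equivariance(self):
        x = np.arange(60.0)
        y = 800 * np.exp(-0.5 * ((x - 20.3) / 1.5) ** 2) + 50
        base = localize_qd(y)
        shifted = localize_qd(np.roll(y, 7))
        assert shifted - base == pytest.approx(7.0, abs=1e-3)

    def test_flat_profile_raises(self):
        with pytest.raises(NoPeakError):
            localize_qd(np.full(30, 5.0))

    def test_monte_carlo_precision_at_snr_10(self):
        # diffraction-limited PSF (sigma ~0.65 px at 0.167 um pixels),
        # peak SNR 10: localization spread stays below 0.1 px and the
        # mean is unbiased well below 0.05 px
        rng = np.random.default_rng(7)
        x = np.arange(40.0)
        errs = []
        for _ in range(500):
            y = 1000 * np.exp(-0.5 * ((x - 17.3) / 0.65) ** 2)
            y = y + rng.normal(0, 100, x.size)
            errs.append(localize_qd(y) - 17.3)
        errs = np.array(errs)
        assert np.std(errs) < 0.1
        assert abs(np.mean(errs)) < 0.05


class TestOnsetDetection:
    def test_constant_trajectory_not_detected(self):
        traj = Trajectory(time_s=np.arange(200) * 0.1, values=np.ones(200),
                          kind="fold")
        assert detect_association_start(traj, 20) is None

    def test_noiseless_step_detected_exactly(self):
        y = np.zeros(200)
        y[100:] = 5.0
        traj = Trajectory(time_s=np.arange(200) * 0.1, values=y, kind="fold")
        assert detect_association_start(traj, 20) == 100

    def test_short_baseline_rejected(self):
        traj = Trajectory(time_s=np.arange(50) * 0.1, values=np.zeros(50),
                          kind="fold")
        with pytest.raises(ValueError):
            detect_association_start(traj, 3)

    def test_simulated_association_onset_recovery(self, r82a):
        from pifeflow.kinetics import normalize_fold
        errs = []
        seeds = np.random.SeedSequence(77).spawn(50)
        for s in seeds:
            rng = np.random.default_rng(s)
            traj, truth = simgen.simulate_association_trajectory(
                r82a, 30.0, baseline_s=5.0, rng=rng, concentration_nM=100.0)
            fold = normalize_fold(traj, 20)
            t0 = detect_association_start(fold, baseline_window=20)
            assert t0 is not None
            errs.append(abs(t0 - round(truth.onset_s / r82a.dt)))
        assert np.median(errs) <= 3
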