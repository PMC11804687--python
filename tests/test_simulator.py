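"""Gait simulator: cohort statistics, speed classes, waveform physics."""
import numpy as np
import pytest

from gaitspeed.io import OTHER_LABEL
from gaitspeed.simulate import (BoutSpec, compute_percent_hrmax,
                                default_protocol, sample_cohort, simulate_bout,
                                simulate_protocol, speed_to_class)

FS = 50.0


class TestCohort:
    def test_size_and_determinism(self):
        a = sample_cohort(24, seed=1)
        b = sample_cohort(24, seed=1)
        assert len(a) == 24
        assert [p.height for p in a] == [p.height for p in b]
        assert sample_cohort(0, seed=1) == []

    def test_negative_n_rejected(self):
        with pytest.raises(ValueError):
            sample_cohort(-1, seed=1)

    def test_anthropometric_envelopes(self):
        cohort = sample_cohort(1000, seed=1)
        heights = np.array([p.height for p in cohort])
        masses = np.array([p.mass for p in cohort])
        ages = np.array([p.age for p in cohort])
        assert 165 <= heights.mean() <= 180
        assert 58.4 <= masses.mean() <= 99.5
        assert 23 <= ages.mean() <= 62
        assert heights.min() >= 156.5 and heights.max() <= 198.5
        sexes = {p.sex for p in cohort}
        assert sexes == {"female", "male"}


class TestSpeedToClass:
    @pytest.mark.parametrize("v,mode,expected", [
        (3.1, "walk", "slow"),
        (4.0, "walk", "slow"),
        (4.05, "walk", "slow"),
        (4.06, "walk", "moderate"),
        (4.9, "walk", "moderate"),
        (5.45, "walk", "moderate"),
        (5.46, "walk", "brisk"),
        (6.1, "walk", "brisk"),
        (8.3, "jog", "jogging"),
        (7.1, "jog", "jogging"),
    ])
    def test_binning(self, v, mode, expected):
        assert speed_to_class(v, mode) == expected

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            speed_to_class(-0.1, "walk")


class TestPercentHrmax:
    def test_hr_equal_to_max(self):
        assert compute_percent_hrmax(40, 180) == pytest.approx(100.0)

    def test_printed_mean_age(self):
        # HRmax(36.1) = 208 - 0.7*36.1 = 182.73; 100*100/182.73 = 54.725...
        assert compute_percent_hrmax(36.1, 100) == pytest.approx(54.73, abs=0.01)

    @pytest.mark.parametrize("age,hr", [(0, 100), (30, 0), (-5, 100)])
    def test_invalid_inputs(self, age, hr):
        with pytest.raises(ValueError):
            compute_percent_hrmax(age, hr)


class TestSimulateBout:
    def test_constant_bout_mean_speed_in_interval(self, profile):
        bout = BoutSpec("walk", ("constant", 2.3, 3.7), 60.0)
        _, _, speed = simulate_bout(profile, bout, FS)
        assert 2.3 <= speed.mean() <= 3.7 <= 4.0

    def test_zero_speed_is_gravity_plus_noise_only(self, profile):
        from dataclasses import replace

        quiet = replace(profile, noise_sd=0.0)
        bout = BoutSpec("walk", ("constant", 0.0, 0.0), 10.0)
        thigh, back, speed = simulate_bout(quiet, bout, FS)
        assert np.all(speed == 0)
        # no gait harmonic: every sample equals the static gravity projection
        assert np.ptp(thigh, axis=0).max() < 1e-12
        assert np.ptp(back, axis=0).max() < 1e-12
        assert np.allclose(np.linalg.norm(thigh, axis=1), 1.0)

    def test_spectral_peak_at_step_frequency(self, profile):
        from dataclasses import replace

        quiet = replace(profile, noise_sd=0.0)
        bout = BoutSpec("walk", ("constant", 5.0, 5.0), 60.0)
        thigh, _, speed = simulate_bout(quiet, bout, FS)
        f_expected = (quiet.cadence_intercept + quiet.cadence_slope * 5.0) / 60.0
        x = thigh[:, 0] - thigh[:, 0].mean()
        spectrum = np.abs(np.fft.rfft(x))
        freqs = np.fft.rfftfreq(len(x), 1 / FS)
        f_peak = freqs[np.argmax(spectrum)]
        assert abs(f_peak - f_expected) <= 1.0 / bout.duration  # one bin

    def test_jog_requires_jogging_speed(self):
        with pytest.raises(ValueError):
            BoutSpec("jog", ("constant", 5.0, 5.0), 60.0)

    def test_cadence_and_energy_increase_with_speed(self, profile):
        from dataclasses import replace

        quiet = replace(profile, noise_sd=0.0)
        energies, fpeaks = [], []
        for v in (3.0, 4.0, 5.0, 6.0):
            thigh, _, _ = simulate_bout(
                quiet, BoutSpec("walk", ("constant", v, v), 30.0), FS)
            x = thigh[:, 0] - thigh[:, 0].mean()
            energies.append(float(np.mean(x ** 2)))
            freqs = np.fft.rfftfreq(len(x), 1 / FS)
            fpeaks.append(freqs[np.argmax(np.abs(np.fft.rfft(x)))])
        assert np.all(np.diff(energies) > 0)
        assert np.all(np.diff(fpeaks) > 0)

    def test_thigh_moves_more_than_back(self, profile):
        bout = BoutSpec("walk", ("constant", 4.4, 5.3), 30.0)
        thigh, back, _ = simulate_bout(profile, bout, FS)
        assert np.ptp(thigh[:, 0]) > np.ptp(back[:, 0])

    def test_jog_peaks_exceed_brisk_peaks_for_whole_cohort(self):
        brisk = BoutSpec("walk", ("constant", 5.7, 6.8), 20.0)
        jog = BoutSpec("jog", ("constant", 7.1, 9.7), 20.0)
        for p in sample_cohort(24, seed=3):
            tb, _, _ = simulate_bout(p, brisk, FS)
            tj, _, _ = simulate_bout(p, jog, FS)
            assert (np.linalg.norm(tj, axis=1).max()
                    > np.linalg.norm(tb, axis=1).max())


class TestSimulateProtocol:
    def test_default_protocol_labelled_duration(self, profile):
        rs = simulate_protocol(profile, default_protocol(), FS)
        durations = rs.labels.duration_by_class()
        labelled = sum(v for k, v in durations.items() if k != OTHER_LABEL)
        assert labelled == pytest.approx(25 * 60)
        assert rs.thigh.fs == FS

    def test_labels_partition_recording(self, short_set):
        iv = short_set.labels.intervals
        assert iv[0][0] == 0.0
        assert iv[-1][1] == pytest.approx(short_set.thigh.duration)
        for (_, e0, _), (s1, _, _) in zip(iv, iv[1:]):
            assert s1 == pytest.approx(e0)

    def test_ramp_label_sequence(self, short_set):
        # last bout is the slow->brisk->slow ramp; collapse its class runs
        jog_end = max(e for s, e, c in short_set.labels.intervals if c == "jogging")
        seq = [c for s, e, c in short_set.labels.intervals
               if s >= jog_end and c != OTHER_LABEL]
        assert seq == ["slow", "moderate", "brisk", "moderate", "slow"]

    def test_label_trace_consistency(self, short_set):
        from gaitspeed.simulate import classify_speed

        fs = short_set.thigh.fs
        for s, e, c in short_set.labels.intervals:
            if c == OTHER_LABEL:
                continue
            i0, i1 = int(round(s * fs)), int(round(e * fs))
            mode = "jog" if c == "jogging" else "walk"
            got = classify_speed(short_set.speed_trace[i0:i1], mode)
            assert np.all(got == c)

    def test_thigh_back_cover_identical_spans(self, short_set):
        assert short_set.thigh.n_samples == short_set.back.n_samples
        assert short_set.speed_trace.shape == (short_set.thigh.n_samples,)
        assert np.all(np.isfinite(short_set.speed_trace))
        assert np.all(short_set.speed_trace >= 0)

    def test_bit_identical_rerun(self, profile, short_protocol):
        a = simulate_protocol(profile, short_protocol, FS)
        b = simulate_protocol(profile, short_protocol, FS)
        assert np.array_equal(a.thigh.samples, b.thigh.samples)
        assert np.array_equal(a.back.samples, b.back.samples)
        assert a.labels.intervals == b.labels.intervals

    def test_empty_protocol_rejected(self, profile):
        from gaitspeed.simulate import ProtocolSpec

        with pytest.raises(ValueError):
            simulate_protocol(profile, ProtocolSpec(bouts=[]), FS)
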