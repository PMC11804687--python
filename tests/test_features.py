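"""Feature catalogue, window segmentation, labelling and extraction."""
import numpy as np
import pandas as pd
import pytest

from conftest import random_window
from naive_features import naive_all_features

from gaitspeed.features import (METADATA_COLUMNS, WindowSpec, build_catalogue,
                                build_feature_matrix, extract_window_features,
                                feature_columns, label_window, segment_windows,
                                split_gravity_body)
from gaitspeed.io import LabelTrack, Recording

FS = 50.0


class TestCatalogue:
    @pytest.mark.parametrize("setup,expected", [
        ("dual", 161), ("thigh", 78), ("back", 78)])
    def test_feature_counts(self, setup, expected):
        cat = build_catalogue(setup)
        assert len(cat) == expected
        assert len(set(cat.names)) == expected

    def test_unknown_setup_rejected(self):
        with pytest.raises(ValueError):
            build_catalogue("wrist")

    def test_json_export(self, tmp_path):
        import json

        path = tmp_path / "cat.json"
        build_catalogue("thigh").to_json(path)
        entries = json.load(open(path))
        assert len(entries) == 78
        assert {"name", "channel", "formula"} <= set(entries[0])


class TestSegmentation:
    def _recs(self, n):
        z = np.zeros((n, 3))
        return (Recording("P", "thigh", FS, z), Recording("P", "back", FS, z))

    def test_exact_division(self):
        t, b = self._recs(int(300 * FS))
        labels = LabelTrack([(0, 300, "slow")])
        assert len(segment_windows(t, b, labels, WindowSpec(5.0))) == 60

    def test_trailing_partial_window_dropped(self):
        t, b = self._recs(int(301.5 * FS))
        labels = LabelTrack([(0, 301.5, "slow")])
        assert len(segment_windows(t, b, labels, WindowSpec(5.0))) == 60

    def test_window_longer_than_recording(self):
        t, b = self._recs(int(2 * FS))
        labels = LabelTrack([(0, 2, "slow")])
        assert segment_windows(t, b, labels, WindowSpec(5.0)) == []

    def test_bout_span_window_count(self, short_set):
        # 5 x 30-s bouts: the labelled span yields 150 one-second windows
        wins = segment_windows(short_set.thigh, short_set.back,
                               short_set.labels, WindowSpec(1.0))
        assert len(wins) == short_set.thigh.n_samples // int(FS)
        kept = [w for w in wins if w.label is not None]
        assert 140 <= len(kept) <= 150


class TestLabelWindow:
    def test_pure_window(self):
        labels = LabelTrack([(0, 10, "brisk")])
        assert label_window(labels, 2, 7) == "brisk"

    def test_strict_majority(self):
        labels = LabelTrack([(0, 3, "slow"), (3, 5, "moderate")])
        assert label_window(labels, 0, 5) == "slow"  # 60/40

    def test_tie_discarded(self):
        labels = LabelTrack([(0, 5, "slow"), (5, 10, "moderate")])
        assert label_window(labels, 2.5, 7.5) is None

    def test_other_majority_discarded(self):
        labels = LabelTrack([(0, 8, "other"), (8, 10, "slow")])
        assert label_window(labels, 0, 10) is None


class TestGravityBodySplit:
    def test_constant_input(self):
        arr = np.tile([0.2, 0.0, 0.98], (250, 1))
        gravity, body = split_gravity_body(arr, FS)
        assert np.max(np.abs(gravity - arr)) < 1e-9
        assert np.max(np.abs(body)) <= 1e-6

    def test_fast_sine_goes_to_body(self):
        t = np.arange(250) / FS
        x = np.sin(2 * np.pi * 5.0 * t)
        _, body = split_gravity_body(x, FS)
        assert np.mean(body ** 2) >= 0.99 * np.mean(x ** 2)

    def test_gravity_recovered_under_gait_sine(self):
        t = np.arange(250) / FS
        arr = np.column_stack([
            0.3 + 0.4 * np.sin(2 * np.pi * 2.0 * t),
            0.0 * t,
            0.95 + 0.3 * np.sin(2 * np.pi * 2.0 * t + 1.0),
        ])
        gravity, _ = split_gravity_body(arr, FS)
        assert abs(gravity[:, 0].mean() - 0.3) < 0.02
        assert abs(gravity[:, 2].mean() - 0.95) < 0.02


class TestExtraction:
    def test_constant_window_degenerate_features(self):
        cat = build_catalogue("thigh")
        win = {"thigh": np.tile([0.1, 0.2, 0.97], (150, 1))}
        vec = dict(zip(cat.names, extract_window_features(win, FS, cat)))
        assert vec["thigh_x_std"] == pytest.approx(0.0, abs=1e-12)
        assert vec["thigh_mag_zcr"] == 0.0
        assert vec["thigh_x_spectral_entropy"] == 0.0
        assert np.all(np.isfinite(list(vec.values())))

    def test_sine_window_closed_form(self):
        # 2 Hz unit sine over 3 s: integer cycles => rms = 1/sqrt(2)
        cat = build_catalogue("thigh")
        t = np.arange(150) / FS
        win = {"thigh": np.column_stack(
            [np.sin(2 * np.pi * 2.0 * t), np.zeros(150), np.ones(150)])}
        vec = dict(zip(cat.names, extract_window_features(win, FS, cat)))
        assert vec["thigh_x_rms"] == pytest.approx(0.7071, abs=1e-3)
        assert abs(vec["thigh_x_dom_freq"] - 2.0) <= 1.0 / 3.0

    def test_identical_axes_correlate_perfectly(self):
        cat = build_catalogue("back")
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 150)
        win = {"back": np.column_stack([x, x, np.ones(150)])}
        vec = dict(zip(cat.names, extract_window_features(win, FS, cat)))
        assert vec["back_corr_xy"] == pytest.approx(1.0)

    def test_nan_input_rejected(self):
        cat = build_catalogue("thigh")
        win = {"thigh": np.full((100, 3), np.nan)}
        with pytest.raises(ValueError, match="non-finite"):
            extract_window_features(win, FS, cat)

    @pytest.mark.parametrize("setup", ["thigh", "dual"])
    def test_matches_naive_oracle(self, setup):
        cat = build_catalogue(setup)
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.choice([1, 3]) * FS)
            win = {"thigh": random_window(rng, n, FS),
                   "back": random_window(rng, n, FS)}
            got = dict(zip(cat.names, extract_window_features(win, FS, cat)))
            expected = naive_all_features(win, FS, setup)
            for name in cat.names:
                assert got[name] == pytest.approx(expected[name], abs=1e-8), name


class TestFeatureMatrix:
    def test_column_layout_and_counts(self, cohort4_features):
        df = cohort4_features
        assert list(df.columns[:5]) == METADATA_COLUMNS
        assert len(feature_columns(df)) == 161
        assert not df.isna().any().any()
        assert set(df["label"]) <= {"slow", "moderate", "brisk", "jogging"}

    def test_dominant_frequency_orders_walking_speeds(self, cohort4_features):
        means = cohort4_features.groupby("label")["thigh_x_dom_freq"].mean()
        assert means["slow"] < means["moderate"] < means["brisk"]

    def test_participant_order_permutation_safe(self, cohort4_sets):
        a = build_feature_matrix(cohort4_sets, "thigh", WindowSpec(3.0))
        b = build_feature_matrix(list(reversed(cohort4_sets)), "thigh",
                                 WindowSpec(3.0))
        pd.testing.assert_frame_equal(a, b)

    def test_empty_input_keeps_header(self):
        df = build_feature_matrix([], "dual", WindowSpec(5.0))
        assert len(df) == 0
        assert len(feature_columns(df)) == 161

    def test_mixed_sampling_rates_rejected(self, cohort4_sets):
        from dataclasses import replace

        bad = cohort4_sets[0]
        bad = type(bad)(profile=bad.profile,
                        thigh=replace(bad.thigh, fs=100.0),
                        back=bad.back, labels=bad.labels,
                        speed_trace=bad.speed_trace)
        with pytest.raises(ValueError, match="mixed"):
            build_feature_matrix([bad, cohort4_sets[1]], "dual", WindowSpec(5.0))

    def test_row_counts_match_per_participant_bookkeeping(self, cohort4_sets):
        spec = WindowSpec(5.0)
        total = 0
        for rs in cohort4_sets:
            wins = segment_windows(rs.thigh, rs.back, rs.labels, spec)
            total += sum(1 for w in wins if w.label is not None)
        df = build_feature_matrix(cohort4_sets, "back", spec)
        assert len(df) == total
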