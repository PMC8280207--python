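import numpy as np
import pytest

from deeppbs.preprocessing import (SEGMENT_SECONDS, VALID_RANGES,
                                   SegmentedSample, Standardizer,
                                   apply_valid_ranges, build_global_features,
                                   make_labels, preprocess_recording,
                                   segment_recording, truncate_or_pad)
from deeppbs.synthetic_cohort import (SIGNALS, ClinicalRecord, RawRecording,
                                      SyntheticSpec, generate_cohort)


def constant_recording(hours, value=60.0, infant_id="x"):
    n = int(hours * 3600)
    series = {s: np.full(n, float(value)) for s in SIGNALS}
    series["NIBP-M"] = np.full(n, np.nan)
    return RawRecording(infant_id=infant_id, start_time=0.0, series=series,
                        bp_channel="ART-M")


def survivor(infant_id="x"):
    return ClinicalRecord(infant_id=infant_id, sex="male", race="White",
                          ga_weeks=26.7, birth_weight_g=929.0, died=False,
                          death_time=None, prior_stay_hours=0.0,
                          crib2_score=10)


class TestValidRanges:
    @pytest.mark.parametrize("signal,value,kept", [
        ("HR", 251.0, False),      # above the closed upper endpoint
        ("HR", 250.0, True),
        ("HR", 0.0, False),        # open lower endpoint
        ("SPO2", 100.0, True),
        ("ART-M", 10.0, True),     # closed lower endpoint
        ("NIBP-M", 10.0, False),   # open lower endpoint
        ("NIBP-M", 10.5, True),
        ("RR", 121.0, False),
    ])
    def test_endpoint_openness(self, signal, value, kept):
        out = apply_valid_ranges(np.array([value]), signal)
        assert np.isfinite(out[0]) == kept

    def test_unknown_signal_rejected(self):
        with pytest.raises(KeyError, match="unknown signal"):
            apply_valid_ranges(np.array([1.0]), "TEMP")

    def test_filtering_is_idempotent(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-50, 300, size=500)
        once = apply_valid_ranges(x, "HR")
        twice = apply_valid_ranges(once, "HR")
        np.testing.assert_array_equal(once, twice)

    def test_in_range_values_unchanged(self):
        x = np.array([1.0, 100.0, 250.0])
        np.testing.assert_array_equal(apply_valid_ranges(x, "HR"), x)


class TestTruncateOrPad:
    def test_long_recording_keeps_last_80h(self):
        rec = constant_recording(100.0)
        window, pad, start = truncate_or_pad(rec, 80.0)
        assert len(window["HR"]) == 80 * 3600
        assert pad == 0
        assert start == 20 * 3600

    def test_exact_length_recording_unchanged(self):
        rec = constant_recording(80.0)
        window, pad, start = truncate_or_pad(rec, 80.0)
        assert len(window["HR"]) == 80 * 3600 and pad == 0 and start == 0

    def test_short_recording_records_leading_deficit(self):
        window, pad, _ = truncate_or_pad(constant_recording(10.0), 80.0)
        assert len(window["HR"]) == 10 * 3600
        assert pad == 70 * 3600

    def test_under_six_hours_excluded(self):
        with pytest.raises(ValueError, match="6"):
            truncate_or_pad(constant_recording(5.0), 80.0)


class TestSegmentation:
    def test_80h_recording_gives_959_segments_1500_features_length_960(self):
        rec = constant_recording(80.0)
        window, pad, start = truncate_or_pad(rec, 80.0)
        window["NIBP-M"] = np.zeros_like(window["NIBP-M"])
        X, pad_mask, end_times = segment_recording(window, pad, start, 80.0)
        assert X.shape == (960, 1500)
        assert (~pad_mask).sum() == 959
        assert not X[959].any()           # terminal all-zero segment
        assert pad_mask[959]

    def test_constant_signal_rolls_to_constant(self):
        rec = constant_recording(8.0, value=77.0)
        window, pad, start = truncate_or_pad(rec, 8.0)
        window["NIBP-M"] = np.zeros_like(window["NIBP-M"])
        X, pad_mask, _ = segment_recording(window, pad, start, 8.0)
        hr_block = X[~pad_mask][:, :SEGMENT_SECONDS]
        np.testing.assert_allclose(hr_block, 77.0)

    def test_segment_boundaries_are_exact_on_a_ramp(self):
        # x[t] = t  =>  rolled[j] = mean(t in [j, j+300)) = j + 149.5;
        # segment k starts at rolled second 300k
        hours = 8.0
        n = int(hours * 3600)
        series = {s: np.arange(n, dtype=float) for s in SIGNALS}
        rec = RawRecording("r", 0.0, series, "ART-M")
        window, pad, start = truncate_or_pad(rec, hours)
        X, pad_mask, _ = segment_recording(window, pad, start, hours)
        real = np.flatnonzero(~pad_mask)
        for k in (0, 1, 50, len(real) - 1):
            expected = 300.0 * k + 149.5
            assert X[real[k], 0] == pytest.approx(expected)
            assert X[real[k], 299] == pytest.approx(expected + 299)

    def test_short_recording_zero_pads_leading_segments(self):
        rec = constant_recording(10.0)
        window, pad, start = truncate_or_pad(rec, 80.0)
        window["NIBP-M"] = np.zeros_like(window["NIBP-M"])
        X, pad_mask, _ = segment_recording(window, pad, start, 80.0)
        # 10 h: (36000 - 300)/300 = 119 real segments, 840 leading pads
        assert (~pad_mask).sum() == 119
        assert pad_mask[:840].all()
        assert not X[:840].any()

    def test_unimputed_window_rejected(self):
        rec = constant_recording(8.0)
        window, pad, start = truncate_or_pad(rec, 8.0)
        with pytest.raises(ValueError, match="impute"):
            segment_recording(window, pad, start, 8.0)


class TestLabels:
    @staticmethod
    def full_scale_times():
        S = 960
        end_times = np.append(300.0 * (np.arange(S - 1) + 2), np.nan)
        pad_mask = np.zeros(S, dtype=bool)
        pad_mask[S - 1] = True
        return end_times, pad_mask

    def death_at(self, death_time):
        return ClinicalRecord("x", "female", "Black", 25.0, 700.0, True,
                              death_time, 0.0, 14)

    def test_death_at_window_end_marks_final_72_segments(self):
        end_times, pad_mask = self.full_scale_times()
        labels, tp = make_labels(self.death_at(288000.0), end_times, pad_mask)
        assert labels.sum() == 72          # 6 h / 5 min
        assert tp == 887
        assert labels[887:959].all() and not labels[:887].any()

    def test_death_3h_after_window_marks_final_36_segments(self):
        end_times, pad_mask = self.full_scale_times()
        labels, tp = make_labels(self.death_at(288000.0 + 3 * 3600),
                                 end_times, pad_mask)
        assert labels.sum() == 36
        assert tp == 923

    def test_survivor_is_all_not_alert_with_sentinel_turning_point(self):
        end_times, pad_mask = self.full_scale_times()
        labels, tp = make_labels(survivor(), end_times, pad_mask)
        assert not labels.any()
        assert tp == 959

    def test_death_before_window_start_rejected(self):
        end_times, pad_mask = self.full_scale_times()
        with pytest.raises(ValueError, match="precedes"):
            make_labels(self.death_at(-100.0), end_times, pad_mask)

    def test_alert_steps_form_contiguous_suffix_of_unpadded_region(
            self, tiny_samples):
        for s in tiny_samples:
            alert = np.flatnonzero(s.labels == 1)
            if alert.size:
                assert np.array_equal(
                    alert, np.arange(alert[0], alert[-1] + 1))
                real = np.flatnonzero(~s.pad_mask)
                assert alert[-1] == real[-1]
                assert s.turning_point == alert[0]
            else:
                assert s.turning_point == len(s.labels) - 1


class TestGlobalFeatures:
    def test_nine_entries_with_single_race_dummy(self):
        g = build_global_features(survivor())
        assert g.shape == (9,)
        assert g[0] == 1.0                     # male
        assert g[1] == pytest.approx(26.7)
        assert g[2] == pytest.approx(929.0)
        assert g[4:].sum() == 1.0
        assert g[4 + 3] == 1.0                 # White dummy

    def test_other_race_sets_other_dummy(self):
        c = ClinicalRecord("x", "female", "Other", 27.0, 1000.0, False, None,
                           12.0, None)
        g = build_global_features(c)
        assert g[0] == 0.0
        assert g[8] == 1.0 and g[4:8].sum() == 0.0

    def test_unrecognized_race_rejected(self):
        c = ClinicalRecord("x", "male", "Martian", 27.0, 1000.0, False, None,
                           0.0, None)
        with pytest.raises(ValueError, match="race"):
            build_global_features(c)


class TestPipelineComposition:
    def test_synthetic_recording_yields_consistent_sample(self, tiny_cohort):
        spec, recordings, clinical = tiny_cohort
        by_id = {c.infant_id: c for c in clinical}
        rec = recordings[0]
        sample = preprocess_recording(
            rec, by_id[rec.infant_id],
            imputer=lambda X, feature_names=None: np.where(
                np.isnan(X), np.nanmean(X, axis=0), X),
            target_hours=spec.recording_hours)
        S = int(spec.recording_hours * 12)
        assert sample.X.shape == (S, 1500)
        assert sample.pad_mask[S - 1]
        assert np.isfinite(sample.X).all()
        assert sample.global_features.shape == (9,)

    def test_standardizer_zeroes_mean_and_keeps_pad_rows(self, tiny_samples):
        scaler = Standardizer.fit(tiny_samples)
        z = [scaler.transform(s) for s in tiny_samples]
        rows = np.vstack([s.X[~s.pad_mask] for s in z])
        np.testing.assert_allclose(rows.mean(axis=0), 0.0, atol=1e-9)
        for s in z:
            assert not s.X[s.pad_mask].any()
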