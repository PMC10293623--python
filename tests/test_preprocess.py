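"""Cleaning chain: flat channels, referencing, ocular removal, epoching,
peak-to-peak rejection."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mubeta import (
    apply_average_reference,
    detect_flat_channels,
    extract_epochs,
    interpolate_spherical_spline,
    reject_by_ptp,
    remove_ocular_components,
)
from mubeta.preprocess import bandpass_fir
from mubeta.simulate import EventMarker, RawRecording
from mubeta.montage import default_montage

from conftest import make_epochs


def make_raw(data, labels=None, kinds=None, events=(), fs=500.0):
    n_ch = data.shape[0]
    montage = default_montage()
    if labels is None:
        labels = list(montage)[:n_ch]
    if kinds is None:
        kinds = ["EEG" if not l.startswith("EOG") else "EOG" for l in labels]
    return RawRecording(
        data=np.asarray(data, dtype=float), fs=fs, channel_labels=list(labels),
        channel_kinds=list(kinds), montage=montage, events=list(events), meta={},
    )


class TestFlatChannels:
    def test_zero_channel_flagged(self):
        rng = np.random.default_rng(0)
        data = rng.normal(0, 10, (4, 1000))
        data[2] = 0.0
        raw = make_raw(data, labels=["Fp1", "Fp2", "F7", "F3"])
        assert detect_flat_channels(raw, min_std_uV=0.01) == ["F7"]

    def test_constant_nonzero_channel_flagged(self):
        rng = np.random.default_rng(1)
        data = rng.normal(0, 10, (3, 500))
        data[0] = 42.0
        raw = make_raw(data, labels=["Fp1", "Fp2", "F7"])
        assert detect_flat_channels(raw, min_std_uV=0.01) == ["Fp1"]

    def test_noisy_channels_not_flagged(self):
        rng = np.random.default_rng(2)
        raw = make_raw(rng.normal(0, 10, (3, 500)), labels=["Fp1", "Fp2", "F7"])
        assert detect_flat_channels(raw, min_std_uV=0.1) == []


class TestInterpolation:
    def test_constant_recording_reproduced(self):
        labels = ["Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4"]
        data = np.full((8, 100), 5.0)
        data[4] = 0.0  # C3 flat
        raw = make_raw(data, labels=labels)
        fixed = interpolate_spherical_spline(raw, ["C3"])
        np.testing.assert_allclose(fixed.data[4], 5.0, rtol=1e-6)
        np.testing.assert_array_equal(fixed.data[0], raw.data[0])  # good untouched

    def test_weights_are_data_independent(self):
        labels = ["Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4"]
        rng = np.random.default_rng(3)
        a = make_raw(rng.normal(0, 1, (8, 50)), labels=labels)
        b = make_raw(rng.normal(0, 1, (8, 50)), labels=labels)
        # same montage -> same linear map: interpolating summed data equals
        # the sum of interpolations
        ab = make_raw(a.data + b.data, labels=labels)
        fa = interpolate_spherical_spline(a, ["C3"]).data[4]
        fb = interpolate_spherical_spline(b, ["C3"]).data[4]
        fab = interpolate_spherical_spline(ab, ["C3"]).data[4]
        np.testing.assert_allclose(fab, fa + fb, atol=1e-9)

    def test_non_eeg_bad_channel_rejected(self):
        raw = make_raw(np.zeros((6, 10)), labels=["Fp1", "Fp2", "F3", "F4", "C3", "EOGV"])
        with pytest.raises(ValueError, match="not an EEG channel"):
            interpolate_spherical_spline(raw, ["EOGV"])


class TestAverageReference:
    def test_two_channel_example(self):
        raw = make_raw(np.array([[1.0], [3.0]]), labels=["C3", "C4"])
        ref = apply_average_reference(raw)
        np.testing.assert_allclose(ref.data[:, 0], [-1.0, 1.0])

    def test_eeg_sum_is_zero_and_eog_untouched(self, small_recording):
        ref = apply_average_reference(small_recording)
        eeg_sum = ref.data[ref.eeg_indices].sum(axis=0)
        np.testing.assert_allclose(eeg_sum, 0.0, atol=1e-9)
        np.testing.assert_array_equal(
            ref.data[ref.eog_indices], small_recording.data[small_recording.eog_indices]
        )

    def test_idempotent(self, small_recording):
        once = apply_average_reference(small_recording)
        twice = apply_average_reference(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)

    def test_sum_to_zero_survives_linear_stages(self, small_recording):
        ref = bandpass_fir(apply_average_reference(small_recording), 1.0, 40.0)
        np.testing.assert_allclose(ref.data[ref.eeg_indices].sum(axis=0), 0.0, atol=1e-8)


class TestOcularRemoval:
    def test_clean_recording_is_untouched(self, small_recording):
        ref = apply_average_reference(small_recording)
        out, report = remove_ocular_components(ref, corr_threshold=0.7)
        assert report.removed == []
        assert np.abs(out.data - ref.data).max() < 1e-6

    def test_blinks_removed_from_frontal_channels(self, blinky_recording):
        ref = apply_average_reference(blinky_recording)
        eogv = ref.data[ref.channel_index("EOGV")]
        fp1_before = ref.data[ref.channel_index("Fp1")]
        assert abs(np.corrcoef(fp1_before, eogv)[0, 1]) > 0.6
        out, report = remove_ocular_components(ref, corr_threshold=0.7)
        assert len(report.removed) >= 1
        fp1_after = out.data[out.channel_index("Fp1")]
        assert abs(np.corrcoef(fp1_after, eogv)[0, 1]) < 0.2


class TestEpoching:
    def test_sample_count_and_order(self, small_recording):
        epochs = extract_epochs(small_recording, -2.0, 7.0)
        assert epochs.data.shape == (18, 34, 4500)
        expected = [e.condition for e in small_recording.events]
        assert list(epochs.condition) == expected

    def test_event_near_edge_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(4)
        events = [EventMarker(100, 0, "ME", "LEFT"), EventMarker(2000, 0, "ME", "RIGHT")]
        raw = make_raw(rng.normal(0, 1, (4, 7000)), labels=["Fp1", "Fp2", "F3", "F4"],
                       events=events)
        with caplog.at_level(logging.WARNING, logger="mubeta.preprocess"):
            epochs = extract_epochs(raw, -2.0, 7.0)
        assert epochs.n_trials == 1
        assert list(epochs.condition) == ["RIGHT"]
        assert any("dropping event" in m for m in caplog.messages)


class TestRejection:
    def test_threshold_boundaries(self):
        data = np.zeros((1, 3, 4500))
        data[0, 1, 100] = 60.0
        data[0, 1, 200] = -70.0  # ptp = 130 on one channel
        rejected, rep = reject_by_ptp(make_epochs(data), threshold_uV=120.0)
        assert not rejected.kept[0] and rep.n_rejected == 1
        kept, rep2 = reject_by_ptp(make_epochs(data), threshold_uV=150.0)
        assert kept.kept[0] and rep2.n_rejected == 0
        assert rep.ptp_uV[0] == pytest.approx(130.0)

    def test_all_zero_epochs_kept(self):
        epochs, rep = reject_by_ptp(make_epochs(np.zeros((5, 2, 100))), 120.0)
        assert rep.n_rejected == 0 and epochs.kept.all()

    def test_eog_channels_excluded_from_criterion(self):
        data = np.zeros((1, 2, 100))
        data[0, 1, 0] = 500.0  # huge deflection, but on the EOG channel
        epochs = make_epochs(data, labels=["C3", "EOGV"], kinds=["EEG", "EOG"])
        out, rep = reject_by_ptp(epochs, 120.0)
        assert out.kept[0]

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(min_value=1.0, max_value=300.0), min_size=2, max_size=6))
    def test_rejection_is_threshold_monotone(self, thresholds):
        rng = np.random.default_rng(7)
        data = rng.normal(0, 40, (20, 3, 200))
        epochs = make_epochs(data)
        counts = [reject_by_ptp(epochs, th)[1].n_rejected for th in sorted(thresholds)]
        assert counts == sorted(counts, reverse=True)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            reject_by_ptp(make_epochs(np.zeros((1, 1, 10))), 0.0)
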