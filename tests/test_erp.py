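"""Offline ERP pipeline: merging, interpolation, TBT rejection, window measures."""

import numpy as np
import pandas as pd
import pytest

from p300lab.containers import EEGRecording, epoch_recording
from p300lab.erp import (
    OfflineConfig,
    compute_erp,
    measure_late_erp,
    merge_blocks,
    preprocess_offline,
    tbt_reject,
    window_max,
    window_mean,
)
from p300lab.montage import channel_positions, interpolate_channels
from p300lab.pipeline import measure_erp_blocks
from p300lab.scheduler import generate_sequence
from p300lab.synthetic import DEFAULT_CHANNELS, ErpGroundTruth, NoiseSpec, RecordingSpec, simulate_recording
from tests.conftest import make_epochs


def _block(seed=0, sfreq=500.0, n_trials=16, noise=None, truth=None):
    seq = generate_sequence(n_trials, 0.25, seed=seed)
    return simulate_recording(
        RecordingSpec(sampling_rate=sfreq),
        seq,
        truth or ErpGroundTruth(),
        noise or NoiseSpec.silent(),
        seed=seed,
    )


class TestPreprocessOffline:
    def test_merge_preserves_event_count_and_rate_reconciliation(self):
        pre = _block(seed=0, sfreq=500.0)
        post = _block(seed=1, sfreq=250.0)
        merged = preprocess_offline(pre, post)
        assert merged.sfreq == 250.0
        assert len(merged.events) == len(pre.events) + len(post.events)
        assert set(merged.events["block"]) == {"pre", "post"}

    def test_post_events_shifted_by_pre_duration(self):
        pre, post = _block(seed=0), _block(seed=1)
        merged = merge_blocks(pre, post)
        shift = merged.events.loc[merged.events["block"] == "post", "onset"].iloc[0] - post.events["onset"].iloc[0]
        assert shift == pytest.approx(pre.duration)

    def test_interpolated_channel_tracks_smooth_field(self, rng):
        # a smooth scalp field: linear function of electrode position
        ch = list(DEFAULT_CHANNELS)
        pos = channel_positions(ch)
        field = 2.0 * pos[:, 0] + 1.5 * pos[:, 1] - 0.5 * pos[:, 2]
        t = np.linspace(0, 1, 500)
        data = np.outer(field, np.sin(2 * np.pi * 2.0 * t))
        corrupted = data.copy()
        corrupted[ch.index("P3")] = rng.normal(size=500)
        repaired = interpolate_channels(corrupted, ch, ["P3"])
        r = np.corrcoef(repaired[ch.index("P3")], data[ch.index("P3")])[0, 1]
        assert r > 0.9

    def test_too_many_bad_channels_warns_but_proceeds(self):
        pre, post = _block(seed=0), _block(seed=1)
        with pytest.warns(UserWarning, match="interpolating 4"):
            merged = preprocess_offline(pre, post, bad_channels=["Fp1", "Fp2", "F3", "F4"])
        assert merged.n_samples > 0

    def test_pipeline_linearity_in_input_scale(self):
        truth = ErpGroundTruth(p300_amplitude=10.0)
        pre, post = _block(seed=3, truth=truth), _block(seed=4, truth=truth)
        m1 = measure_erp_blocks(pre, post, OfflineConfig())
        pre.data *= 2.0
        post.data *= 2.0
        m2 = measure_erp_blocks(pre, post, OfflineConfig())
        for block in ("pre", "post"):
            assert m2[block]["p300_mean"] == pytest.approx(2 * m1[block]["p300_mean"], rel=1e-6)
            assert m2[block]["late_erp"] == pytest.approx(2 * m1[block]["late_erp"], rel=1e-6)


class TestTbtReject:
    def _clean_epochs(self, n_ep=20, n_ch=22, n_t=100, rng=None):
        rng = rng or np.random.default_rng(0)
        data = rng.normal(0, 5, size=(n_ep, n_ch, n_t))
        return make_epochs(data, ch_names=list(DEFAULT_CHANNELS))

    def test_clean_data_unchanged(self, rng):
        epochs = self._clean_epochs(rng=rng)
        out = tbt_reject(epochs)
        assert out.n_epochs == 20
        assert np.array_equal(out.data, epochs.data)
        assert out.ch_names == epochs.ch_names

    def test_channel_bad_in_twenty_percent_excluded_globally(self, rng):
        epochs = self._clean_epochs(n_ep=100, rng=rng)
        bad_ch = epochs.ch_names.index("T7")
        for ep in range(20):  # 20% > 15%
            epochs.data[ep, bad_ch, 0] = 200.0
            epochs.data[ep, bad_ch, 1] = -200.0
        out = tbt_reject(epochs)
        assert "T7" not in out.ch_names
        assert out.n_epochs == 100

    def test_channel_bad_in_exactly_fifteen_percent_retained(self, rng):
        # the exclusion rule is strict: "more than 15%" keeps a 15% channel
        epochs = self._clean_epochs(n_ep=100, rng=rng)
        bad_ch = epochs.ch_names.index("T8")
        for ep in range(15):
            epochs.data[ep, bad_ch, 0] = 200.0
            epochs.data[ep, bad_ch, 1] = -200.0
        out = tbt_reject(epochs)
        assert "T8" in out.ch_names

    def test_boundary_ten_vs_eleven_bad_channels(self, rng):
        epochs = self._clean_epochs(n_ep=40, rng=rng)
        # epoch 3: exactly 10 bad channels -> retained and repaired
        epochs.data[3, :10, 0] = 400.0
        # epoch 7: 11 bad channels -> dropped
        epochs.data[7, :11, 0] = 400.0
        out = tbt_reject(epochs)
        assert 7 in out.rejected
        assert 3 in out.kept
        row = np.flatnonzero(out.kept == 3)[0]
        assert np.abs(out.data[row, :10, 0]).max() < 100.0  # repaired by interpolation

    def test_peak_to_peak_exactly_at_threshold_not_marked(self):
        data = np.zeros((5, 22, 100))
        data[:, 0, 0] = 75.0
        data[:, 0, 1] = -75.0  # ptp exactly 150
        out = tbt_reject(make_epochs(data, ch_names=list(DEFAULT_CHANNELS)))
        assert out.ch_names == list(DEFAULT_CHANNELS)
        assert out.n_epochs == 5
        assert np.array_equal(out.data, data)

    def test_all_epochs_dropped_raises(self):
        # every epoch carries 15 bad channels; with global channel exclusion
        # disabled (strict > 1.0 never fires), every epoch exceeds the
        # 10-bad-channel limit and the block is unusable
        data = np.zeros((4, 22, 100))
        data[:, :15, 0] = 400.0
        epochs = make_epochs(data, ch_names=list(DEFAULT_CHANNELS))
        cfg = OfflineConfig(max_bad_epoch_fraction_per_channel=1.0)
        with pytest.raises(ValueError, match="all epochs"):
            tbt_reject(epochs, cfg)


class TestComputeErp:
    def test_step_signal_measures_one_in_every_window(self):
        sfreq = 250.0
        n_t = int(2.0 * sfreq)
        t = -0.5 + np.arange(n_t) / sfreq
        data = np.tile(np.where(t >= 0, 1.0, 0.0), (6, 1, 1))
        epochs = make_epochs(data, sfreq=sfreq, tmin=-0.5)
        erp = compute_erp(epochs, by=[])
        cond = erp["all"]
        assert cond.mean_amplitude == pytest.approx(1.0)
        assert cond.max_amplitude == pytest.approx(1.0)
        assert cond.late_amplitude == pytest.approx(1.0)
        assert cond.n_epochs == 6

    def test_max_at_least_mean_on_same_window(self, rng):
        data = rng.normal(size=(8, 1, 500))
        epochs = make_epochs(data, sfreq=250.0, tmin=-0.5)
        cfg = OfflineConfig(p300_mean_window=(250.0, 550.0))
        erp = compute_erp(epochs, cfg, by=[])
        assert erp["all"].max_amplitude >= erp["all"].mean_amplitude

    def test_target_exceeds_standard_directionally(self):
        rec = _block(seed=5, n_trials=40, noise=NoiseSpec.silent())
        epochs = epoch_recording(
            rec,
            rec.events["onset"].to_numpy(dtype=float),
            -0.5,
            1.5,
            baseline=(-0.5, 0.0),
            events=rec.events,
        )
        erp = compute_erp(epochs, by=["trial_type"])
        assert erp["target"].mean_amplitude > erp["standard"].mean_amplitude

    def test_empty_condition_missing_not_zero(self):
        data = np.zeros((4, 1, 500))
        epochs = make_epochs(data, sfreq=250.0, tmin=-0.5)
        epochs.events["trial_type"] = "standard"
        erp = compute_erp(epochs, by=["trial_type"])
        assert "target" not in erp.conditions
        assert "standard" in erp.conditions

    def test_injected_late_component_measured_at_window_center(self):
        truth = ErpGroundTruth(n700_amplitude=-2.0, p300_amplitude=0.1, target_standard_ratio=2.0)
        seq = generate_sequence(8, 0.25, seed=2)
        rec = simulate_recording(RecordingSpec(), seq, truth, NoiseSpec.silent(), seed=0)
        targets = rec.events[rec.events["trial_type"] == "target"]
        epochs = epoch_recording(rec, targets["onset"].to_numpy(dtype=float), -0.5, 1.5, baseline=(-0.5, 0.0))
        avg = epochs.average()[epochs.channel_index("Pz")]
        center = np.argmin(np.abs(epochs.times - 0.8))
        assert avg[center] == pytest.approx(-2.0, abs=0.1)

    def test_window_conventions_half_open_and_earliest_tie(self):
        times = np.arange(0, 1.0, 0.005)  # grid hits 0.55 exactly
        wave = np.zeros_like(times)
        wave[(times >= 0.3) & (times < 0.35)] = 2.0  # plateau: tie on the max
        val, lat = window_max(wave, times, (250.0, 550.0))
        assert val == 2.0
        assert lat == pytest.approx(300.0, abs=2.1)
        # half-open: a sample exactly at the upper edge is excluded
        wave2 = np.zeros_like(times)
        wave2[110] = 99.0  # t = 0.55
        assert window_mean(wave2, times, (200.0, 550.0)) == pytest.approx(0.0, abs=1e-12)


class TestExciseSegments:
    def test_events_shifted_and_dropped(self):
        from p300lab.erp import excise_segments

        rec = _block(seed=2, n_trials=12)
        ev0 = rec.events.copy()
        cut = (float(ev0["onset"].iloc[3]) - 0.05, float(ev0["onset"].iloc[3]) + 0.2)
        out = excise_segments(rec, [cut])
        assert len(out.events) == len(ev0) - 1  # the trial inside the cut is gone
        assert out.n_samples == rec.n_samples - int(round((cut[1] - cut[0]) * rec.sfreq))
        # later events shift left by the removed duration
        shifted = out.events["onset"].iloc[3]
        assert shifted == pytest.approx(ev0["onset"].iloc[4] - (cut[1] - cut[0]), abs=1e-9)
        # earlier events untouched
        assert out.events["onset"].iloc[0] == pytest.approx(ev0["onset"].iloc[0])
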