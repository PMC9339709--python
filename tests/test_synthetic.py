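"""Ground-truth construction, determinism and statistical structure of the generator."""

import numpy as np
import pytest
from scipy import signal

from p300lab.containers import epoch_recording
from p300lab.scheduler import generate_sequence
from p300lab.synthetic import (
    BehaviorGroundTruth,
    EffectSpec,
    ErpGroundTruth,
    NoiseSpec,
    RecordingSpec,
    simulate_behavior,
    simulate_crossover_study,
    simulate_outcome_measures,
    simulate_recording,
)


def _single_target_sequence(seed=1):
    seq = generate_sequence(4, 0.25, seed=seed)
    return seq


class TestSimulateRecording:
    def test_noiseless_peak_at_configured_latency_and_amplitude(self):
        seq = _single_target_sequence()
        truth = ErpGroundTruth(p300_latency=350.0, p300_amplitude=5.0)
        rec = simulate_recording(RecordingSpec(), seq, truth, NoiseSpec.silent(), seed=0)
        pz = rec.data[rec.channel_index("Pz")]
        onset = seq.trials.loc[seq.trials["trial_type"] == "target", "onset"].iloc[0]
        t = rec.times - onset
        win = (t >= 0.250) & (t <= 0.450)
        i = np.argmax(pz[win])
        assert t[win][i] == pytest.approx(0.350, abs=1.5 / rec.sfreq)
        assert pz[win][i] == pytest.approx(5.0, rel=5e-3)

    def test_marker_counts_match_design(self):
        seq = generate_sequence(400, 0.25, seed=1)
        rec = simulate_recording(RecordingSpec(), seq, ErpGroundTruth(), NoiseSpec(), seed=1)
        assert len(rec.events) == 400
        assert (rec.events["trial_type"] == "target").sum() == 100

    def test_same_seed_byte_identical(self):
        seq = generate_sequence(40, 0.25, seed=2)
        a = simulate_recording(RecordingSpec(), seq, ErpGroundTruth(), NoiseSpec(), seed=9)
        b = simulate_recording(RecordingSpec(), seq, ErpGroundTruth(), NoiseSpec(), seed=9)
        assert np.array_equal(a.data, b.data)

    def test_onset_beyond_duration_rejected(self):
        seq = generate_sequence(40, 0.25, seed=2)
        spec = RecordingSpec(duration=10.0)
        with pytest.raises(ValueError, match="fit within"):
            simulate_recording(spec, seq, ErpGroundTruth(), NoiseSpec.silent(), seed=0)

    def test_unknown_topography_channel_rejected(self):
        seq = _single_target_sequence()
        truth = ErpGroundTruth()
        truth.topography_weights = {"Pz": 1.0, "Qz9": 0.5}
        with pytest.raises(ValueError, match="unknown channels"):
            simulate_recording(RecordingSpec(), seq, truth, NoiseSpec.silent(), seed=0)

    def test_target_minus_standard_difference_matches_truth(self):
        seq = generate_sequence(8, 0.25, seed=4)
        truth = ErpGroundTruth(p300_amplitude=10.0, target_standard_ratio=2.5, n700_amplitude=0.0)
        rec = simulate_recording(RecordingSpec(), seq, truth, NoiseSpec.silent(), seed=0)
        pz = rec.channel_index("Pz")
        lat = truth.p300_latency / 1000.0

        def peak(trial_type):
            onsets = seq.trials.loc[seq.trials["trial_type"] == trial_type, "onset"]
            return np.mean([rec.data[pz][int(round((o + lat) * rec.sfreq))] for o in onsets])

        diff = peak("target") - peak("standard")
        assert diff == pytest.approx(10.0 - 10.0 / 2.5, rel=1e-2)

    def test_burst_spectral_peak_at_ero_frequency(self):
        seq = _single_target_sequence()
        truth = ErpGroundTruth(ero_frequency=3.0, p300_latency=400.0)
        rec = simulate_recording(RecordingSpec(), seq, truth, NoiseSpec.silent(), seed=0)
        pz = rec.data[rec.channel_index("Pz")]
        onset = seq.trials.loc[seq.trials["trial_type"] == "target", "onset"].iloc[0]
        t = rec.times - onset
        seg = pz[(t >= 0.2) & (t <= 0.6)]
        freqs, psd = signal.periodogram(seg, fs=rec.sfreq, nfft=5000, detrend=False)
        band = (freqs >= 1.0) & (freqs <= 8.0)
        assert freqs[band][np.argmax(psd[band])] == pytest.approx(3.0, abs=0.1)

    def test_white_noise_degrades_single_trials_not_grand_average(self):
        seq = generate_sequence(120, 0.25, seed=6)
        truth = ErpGroundTruth()
        clean = simulate_recording(RecordingSpec(), seq, truth, NoiseSpec.silent(), seed=0)
        onsets = seq.trials.loc[seq.trials["trial_type"] == "target", "onset"].to_numpy()

        def epochs_for(sd, seed):
            noise = NoiseSpec(0.0, 0.0, 0.0, sd, 0.0, 0.0)
            rec = simulate_recording(RecordingSpec(), seq, truth, noise, seed=seed)
            return epoch_recording(rec, onsets, -0.2, 0.8).data[:, rec.channel_index("Pz"), :]

        ref = epoch_recording(clean, onsets, -0.2, 0.8).data[:, clean.channel_index("Pz"), :]
        prev_snr = np.inf
        for sd in (1.0, 4.0, 16.0):
            ep = epochs_for(sd, seed=3)
            resid = ep - ref
            snr = ref.var() / resid.var()
            assert snr < prev_snr
            prev_snr = snr
            # grand average converges on the clean ERP (30 targets, noise ~ sd/sqrt(30))
            ga_err = (ep.mean(axis=0) - ref.mean(axis=0)).std()
            assert ga_err < 3.0 * sd / np.sqrt(ep.shape[0])


class TestSimulateBehavior:
    def test_perfect_performance(self):
        seq = generate_sequence(40, 0.25, seed=1)
        truth = BehaviorGroundTruth(p_omission=0.0, p_commission=0.0)
        table = simulate_behavior(seq, truth, seed=0)
        target_side = "right"
        targets = table["trial_type"] == "target"
        assert (table.loc[targets, "response"] == target_side).all()
        assert (table.loc[~targets, "response"] == "left").all()

    def test_omission_rate_binomial_oracle(self, rng):
        # mean omission count over replicates matches n*p (binomial oracle)
        seq = generate_sequence(400, 0.25, seed=1)
        truth = BehaviorGroundTruth(p_omission=0.2, p_commission=0.0)
        counts = []
        for rep in range(60):
            table = simulate_behavior(seq, truth, seed=rep)
            targets = table["trial_type"] == "target"
            counts.append((table.loc[targets, "response"] != "right").sum())
        n, p = 100, 0.2
        se = np.sqrt(n * p * (1 - p) / len(counts))
        assert np.mean(counts) == pytest.approx(n * p, abs=4 * se)

    def test_zero_rt_scale_gives_zero_variability(self):
        seq = generate_sequence(40, 0.25, seed=1)
        truth = BehaviorGroundTruth(rt_scale=0.0, p_omission=0.0, p_commission=0.0)
        table = simulate_behavior(seq, truth, seed=0)
        rts = table["response_time"].dropna()
        assert rts.std() == 0.0


class TestCrossoverStudy:
    def test_minimum_subjects_enforced(self):
        with pytest.raises(ValueError, match="at least 2"):
            simulate_crossover_study(n_subjects=1, seed=0)

    def test_counterbalanced_order(self):
        study = simulate_crossover_study(n_subjects=20, seed=0, n_trials=8)
        first = [s.order[0] for s in study.subjects]
        assert first.count("actual") == 10
        assert first.count("sham") == 10

    def test_ledger_records_all_subject_truth(self):
        study = simulate_crossover_study(n_subjects=4, seed=3, n_trials=8)
        led = study.ledger()
        assert led["n_subjects"] == 4
        assert len(led["subjects"]) == 4
        for rec in led["subjects"]:
            assert 250.0 <= rec["p300_latency_ms"] <= 550.0
            assert 1.0 <= rec["ero_frequency_hz"] <= 8.0

    def test_post_block_effects_enter_recordings(self):
        eff = EffectSpec(0, 0, 0, 0, 0, 0, 30.0, 30.0, 0, 0)
        study = simulate_crossover_study(n_subjects=2, effects=eff, seed=1, n_trials=40)
        pre = study.behavior(0, "actual", "pre")
        post = study.behavior(0, "actual", "post")
        t_pre = pre["trial_type"] == "target"
        t_post = post["trial_type"] == "target"
        miss_pre = (pre.loc[t_pre, "response"] != "right").mean()
        miss_post = (post.loc[t_post, "response"] != "right").mean()
        assert miss_post > miss_pre  # +30 percentage points is visible at n=10 targets


class TestOutcomeModel:
    def test_effect_structure(self):
        eff = EffectSpec(0, 0, 1.0, 0.0, 0, 0, 0, 0, 0, 0)
        df = simulate_outcome_measures(200, eff, seed=0, measures=("late_erp",))
        cell = df.pivot_table(index="subject", columns=["intervention", "block"], values="value")
        contrast = (cell[("actual", "post")] - cell[("actual", "pre")]) - (
            cell[("sham", "post")] - cell[("sham", "pre")]
        )
        assert contrast.mean() == pytest.approx(1.0, abs=0.2)
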