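"""Reference experiments: recovery, calibration and phase-locking studies.

These functions run the package's own chain end to end at fixed study
conditions and return measured quantities (errors, rates, estimates).
They back the validation suite and the reproduction script; sizes are
chosen so a full run stays within desk-scale compute (see the methods
note for the problem sizes and why they suffice).
"""

from __future__ import annotations

import numpy as np

from .online import extract_stim_params
from .scheduler import (
    IndividualStimParams,
    TacsWaveformSpec,
    generate_sequence,
    schedule_phase_locked,
    synthesize_waveform,
)
from .stats import interaction_contrast, rm_anova_2x2
from .synthetic import EffectSpec, simulate_crossover_study


def phase_lock_sweep(
    frequencies=(1.0, 1.7, 2.9, 3.7, 4.6, 5.8, 7.3, 8.0),
    latency_ms: float = 350.0,
    n_trials: int = 120,
    seed: int = 0,
) -> dict:
    """Schedule blocks across the 1-8 Hz band and read back the phase error.

    For every frequency, targets are scheduled against a synthesized
    waveform and the waveform is evaluated (in continuous time) at
    onset + latency; reported are the worst relative amplitude deviation
    from the plateau maximum and the largest circular SD of the phase
    error across frequencies.
    """
    worst_amp_dev = 0.0
    worst_circ_sd = 0.0
    n_targets_total = 0
    for i, f in enumerate(frequencies):
        seq = generate_sequence(n_trials, 0.25, seed=seed + i, start=12.0)
        spec = TacsWaveformSpec(mode="actual", frequency=f, total_duration=seq.duration + 30.0)
        wf = synthesize_waveform(spec, 500.0)
        params = IndividualStimParams(p300_latency=latency_ms, stim_frequency=f)
        sched = schedule_phase_locked(seq, wf.pulse_times, params)
        targ = sched.trials[sched.trials["trial_type"] == "target"]
        t_peak = targ["onset"].to_numpy() + latency_ms / 1000.0
        in_plateau = (t_peak >= spec.plateau[0]) & (t_peak <= spec.plateau[1])
        t_peak = t_peak[in_plateau]
        n_targets_total += t_peak.size
        values = wf.value(t_peak)
        worst_amp_dev = max(worst_amp_dev, float(np.max(1.0 - values / wf.amplitude)))
        err = np.angle(np.exp(1j * (wf.phase(t_peak) - np.pi / 2)))
        r = np.abs(np.mean(np.exp(1j * err)))
        circ_sd = float(np.degrees(np.sqrt(-2 * np.log(max(r, 1e-300)))))
        worst_circ_sd = max(worst_circ_sd, circ_sd)
    return {
        "max_amplitude_deviation": worst_amp_dev,
        "max_circular_sd_deg": worst_circ_sd,
        "n_targets": n_targets_total,
    }


def online_recovery_study(n_subjects: int = 50, seed: int = 0) -> dict:
    """Per-subject P300-latency and ERO-frequency recovery at default noise.

    Each subject contributes one full 400-trial pre-intervention block;
    the online chain (filter, epoch, statistical rejection, estimators)
    runs on it and errors against the ground truth are collected.
    """
    study = simulate_crossover_study(n_subjects=n_subjects, effects=EffectSpec.null(), seed=seed)
    lat_err, freq_err = [], []
    for s in range(n_subjects):
        truth = study.subjects[s].erp
        params = extract_stim_params(study.recording(s, "actual", "pre"))
        lat_err.append(params.p300_latency - truth.p300_latency)
        freq_err.append(params.stim_frequency - truth.ero_frequency)
    lat_err = np.asarray(lat_err)
    freq_err = np.asarray(freq_err)
    return {
        "latency_errors_ms": lat_err,
        "frequency_errors_hz": freq_err,
        "median_abs_latency_error_ms": float(np.median(np.abs(lat_err))),
        "median_abs_frequency_error_hz": float(np.median(np.abs(freq_err))),
        "n_subjects": n_subjects,
    }


def erp_effect_recovery_study(
    n_replicates: int = 20,
    n_subjects: int = 20,
    injected_uv: float = 1.0,
    n_trials: int = 60,
    seed: int = 0,
) -> dict:
    """Recovery of an actual-only pre-to-post P300 change by the ERP stage.

    Each replicate simulates a crossover study with ``injected_uv`` added
    to the post-actual P300 window mean, runs the offline ERP chain per
    block, and estimates the interaction contrast; the median estimate
    across replicates is the recovered effect.
    """
    from .pipeline import run_scaled_study

    effects = EffectSpec(injected_uv, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    estimates = []
    for rep in range(n_replicates):
        outcomes = run_scaled_study(n_subjects, effects, seed=seed + rep, n_trials=n_trials)
        estimates.append(float(np.mean(interaction_contrast(outcomes))))
    estimates = np.asarray(estimates)
    return {
        "estimates_uv": estimates,
        "median_estimate_uv": float(np.median(estimates)),
        "injected_uv": injected_uv,
        "n_replicates": n_replicates,
        "n_subjects": n_subjects,
    }


def interaction_type_one_error_study(
    n_replicates: int = 500,
    n_subjects: int = 19,
    n_trials: int = 12,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the 2x2 interaction under a null effect specification.

    Every replicate renders EEG for all four blocks per subject (at
    reduced trial counts and montage), measures the target P300 through
    the ERP chain, and tests the interaction at ``alpha``.
    """
    from .pipeline import run_scaled_study

    rejections = 0
    for rep in range(n_replicates):
        outcomes = run_scaled_study(n_subjects, EffectSpec.null(), seed=seed + rep, n_trials=n_trials)
        if rm_anova_2x2(outcomes).interaction.p < alpha:
            rejections += 1
    return {
        "rejection_rate": rejections / n_replicates,
        "n_replicates": n_replicates,
        "n_subjects": n_subjects,
        "alpha": alpha,
    }
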