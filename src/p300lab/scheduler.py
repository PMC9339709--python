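"""Oddball sequence generation and tACS-phase-locked stimulus scheduling.

The central idea: during the intervention block, target stimuli are delayed
so that the P300 each target elicits (a fixed, individually measured latency
after stimulus onset) lands exactly on a positive peak of the running tACS
sinusoid.  The stimulator emits a pulse at every ascending zero-crossing of
its waveform; from pulse time, stimulation frequency and P300 latency the
required onset delay has a closed form (see :func:`compute_target_delay`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: On-screen duration of each stimulus, in seconds.
STIMULUS_DURATION = 0.5


@dataclass
class StimulusSequence:
    """Ordered oddball trials: onsets, types and tilt sides.

    ``trials`` has columns ``onset`` (s), ``trial_type`` (``target`` /
    ``standard``) and ``tilt`` (``left`` / ``right``).  Onsets are strictly
    increasing; successive gaps equal stimulus duration + drawn ISI plus any
    scheduling delay added later.
    """

    trials: pd.DataFrame
    isi_range: tuple[float, float]
    standard_side: str
    seed: int | None = None

    def __post_init__(self) -> None:
        onsets = self.trials["onset"].to_numpy()
        if onsets.size and not np.all(np.diff(onsets) > 0):
            raise ValueError("onsets must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def onsets(self) -> np.ndarray:
        return self.trials["onset"].to_numpy(dtype=float)

    @property
    def is_target(self) -> np.ndarray:
        return (self.trials["trial_type"] == "target").to_numpy()

    @property
    def n_targets(self) -> int:
        return int(self.is_target.sum())

    @property
    def duration(self) -> float:
        """Time from start to end of the last stimulus presentation."""
        return float(self.onsets[-1] + STIMULUS_DURATION) if self.n_trials else 0.0

    def copy(self) -> "StimulusSequence":
        return replace(self, trials=self.trials.copy())


def generate_sequence(
    n_trials: int = 400,
    p_target: float = 0.25,
    isi_range: tuple[float, float] = (1.0, 2.5),
    standard_side: str = "left",
    seed: int = 0,
    start: float = 2.0,
) -> StimulusSequence:
    """Draw an oddball sequence with an exact-count target allocation.

    Exactly ``n_trials * p_target`` targets (must be an integer count) are
    uniformly shuffled among the standards; ISIs are uniform on
    ``isi_range``; the tilt of standards is ``standard_side`` and targets
    tilt the opposite way.  ``start`` offsets the first onset so that
    pre-stimulus epoch windows fit in the recording.
    """
    if not 0 < p_target < 1:
        raise ValueError("p_target must be in (0, 1)")
    lo, hi = isi_range
    if lo > hi or lo < 0:
        raise ValueError("invalid ISI range")
    n_targets_f = n_trials * p_target
    n_targets = round(n_targets_f)
    if abs(n_targets_f - n_targets) > 1e-9:
        raise ValueError("n_trials * p_target must be an integer (exact-count design)")
    if standard_side not in ("left", "right"):
        raise ValueError("standard_side must be 'left' or 'right'")

    rng = np.random.default_rng(seed)
    types = np.array(["standard"] * (n_trials - n_targets) + ["target"] * n_targets)
    rng.shuffle(types)
    isis = rng.uniform(lo, hi, size=n_trials)
    onsets = start + np.concatenate(([0.0], np.cumsum(STIMULUS_DURATION + isis[:-1])))
    target_side = "right" if standard_side == "left" else "left"
    tilt = np.where(types == "target", target_side, standard_side)
    trials = pd.DataFrame({"onset": onsets, "trial_type": types, "tilt": tilt})
    return StimulusSequence(trials=trials, isi_range=(lo, hi), standard_side=standard_side, seed=seed)


@dataclass
class TacsWaveformSpec:
    """Stimulation waveform parameters.

    ``actual`` runs for ``total_duration`` (default 20 min); ``sham`` ramps
    up for ``fade_duration``, holds a 10 s plateau and ramps down, i.e. a
    30 s envelope with the defaults, then stays silent.
    """

    mode: str = "actual"
    frequency: float = 4.0
    intensity_peak_to_peak: float = 1.0  # mA
    fade_duration: float = 10.0  # s
    total_duration: float | None = None  # s; None -> mode default

    SHAM_PLATEAU: float = 10.0

    def __post_init__(self) -> None:
        if self.mode not in ("actual", "sham"):
            raise ValueError("mode must be 'actual' or 'sham'")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.intensity_peak_to_peak <= 0:
            raise ValueError("intensity must be positive")
        if self.total_duration is None:
            self.total_duration = 1200.0 if self.mode == "actual" else 2 * self.fade_duration + self.SHAM_PLATEAU

    @property
    def envelope_duration(self) -> float:
        """Length of the nonzero-envelope support in seconds."""
        if self.mode == "sham":
            return 2 * self.fade_duration + self.SHAM_PLATEAU
        return float(self.total_duration)

    @property
    def plateau(self) -> tuple[float, float]:
        """Full-amplitude window ``[t0, t1]``."""
        return (self.fade_duration, self.envelope_duration - self.fade_duration)


@dataclass
class TacsWaveform:
    """Synthesized tACS signal: sampled array, continuous evaluator, pulses."""

    spec: TacsWaveformSpec
    sfreq: float
    samples: np.ndarray = field(repr=False)
    pulse_times: np.ndarray

    @property
    def amplitude(self) -> float:
        """Plateau peak amplitude (half the peak-to-peak intensity), mA."""
        return self.spec.intensity_peak_to_peak / 2.0

    def envelope(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        fade = self.spec.fade_duration
        sup = self.spec.envelope_duration
        env = np.clip(np.minimum(t / fade, (sup - t) / fade), 0.0, 1.0)
        return np.where((t <= 0) | (t >= sup), 0.0, env)

    def value(self, t: np.ndarray) -> np.ndarray:
        """Continuous-time waveform value in mA (exact, not sample lookup)."""
        t = np.asarray(t, dtype=float)
        return self.amplitude * self.envelope(t) * np.sin(2 * np.pi * self.spec.frequency * t)

    def phase(self, t: np.ndarray) -> np.ndarray:
        """Instantaneous phase in radians, wrapped to [-pi, pi); 0 = ascending zero-crossing."""
        return np.angle(np.exp(1j * 2 * np.pi * self.spec.frequency * np.asarray(t, dtype=float)))


def synthesize_waveform(spec: TacsWaveformSpec, sampling_rate: float, pulses_in_fades: bool = False) -> TacsWaveform:
    """Sample the tACS sinusoid with linear fade ramps and emit its pulse stream.

    Pulses mark ascending zero-crossings of the sinusoid; by default only
    those during the full-amplitude plateau are emitted (a stimulator's
    pulse output during amplitude ramps is not used for scheduling).
    """
    if sampling_rate < 4 * spec.frequency:
        raise ValueError("sampling_rate must be at least 4x the stimulation frequency")
    n = int(round(spec.total_duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    wf = TacsWaveform(spec=spec, sfreq=sampling_rate, samples=np.empty(0), pulse_times=np.empty(0))
    wf.samples = wf.value(t)
    t0, t1 = (0.0, spec.envelope_duration) if pulses_in_fades else spec.plateau
    period = 1.0 / spec.frequency
    k0 = math.ceil(t0 / period - 1e-12)
    k1 = math.floor(t1 / period + 1e-12)
    wf.pulse_times = np.arange(k0, k1 + 1) * period
    return wf


def envelope_support(waveform: "TacsWaveform", refine_iters: int = 80) -> float:
    """Length (s) of the interval over which the stimulation envelope is nonzero.

    Edges are located by bisection on the continuous envelope between the
    outermost zero/nonzero sample pairs, so linear fade ramps yield the
    support to float precision.
    """
    t = np.arange(waveform.samples.size) / waveform.sfreq
    env = waveform.envelope(t)
    nz = np.flatnonzero(env > 0)
    if nz.size == 0:
        return 0.0

    def _edge(lo: float, hi: float, rising: bool) -> float:
        for _ in range(refine_iters):
            mid = 0.5 * (lo + hi)
            positive = waveform.envelope(np.array([mid]))[0] > 0
            if positive == rising:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    start = t[nz[0]] if nz[0] == 0 else _edge(t[nz[0] - 1], t[nz[0]], rising=True)
    if nz[-1] == t.size - 1:
        end = waveform.spec.envelope_duration if waveform.envelope(np.array([t[-1]]))[0] > 0 else t[-1]
    else:
        end = _edge(t[nz[-1] + 1], t[nz[-1]], rising=True)
    return float(end - start)


def compute_target_delay(
    pulse_time: float,
    stim_frequency: float,
    p300_latency: float,
    min_lead: float = 0.2,
) -> float:
    """Smallest delay ``d >= min_lead`` placing the P300 on a tACS positive peak.

    A pulse at ``pulse_time`` marks an ascending zero-crossing, so positive
    peaks occur at ``pulse_time + T/4 + k*T`` (``T = 1/f``).  Showing the
    stimulus at ``pulse_time + d`` puts the P300 at ``pulse_time + d +
    p300_latency``; the smallest admissible ``d`` solves
    ``d + p300_latency - T/4 = k*T`` with ``d >= min_lead``.
    The result always satisfies ``d < min_lead + T``.
    """
    if not 1.0 <= stim_frequency <= 8.0:
        raise ValueError("stim_frequency must lie in [1, 8] Hz")
    if min_lead < 0:
        raise ValueError("min_lead must be non-negative")
    period = 1.0 / stim_frequency
    k = math.ceil((min_lead + p300_latency - period / 4.0) / period - 1e-12)
    d = period / 4.0 + k * period - p300_latency
    # guard against float droop below the floor
    if d < min_lead:
        d += period
    return d


@dataclass
class IndividualStimParams:
    """Per-subject parameters driving the intervention block."""

    p300_latency: float  # ms
    stim_frequency: float  # Hz, within [1, 8]
    n_epochs_used: int | None = None
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.p300_latency) or not np.isfinite(self.stim_frequency):
            raise ValueError("stimulation parameters must be finite")
        if not 1.0 <= self.stim_frequency <= 8.0:
            raise ValueError("stim_frequency must lie in [1, 8] Hz")


def schedule_phase_locked(
    sequence: StimulusSequence,
    pulses: np.ndarray | None,
    params: IndividualStimParams,
    min_lead: float = 0.2,
) -> StimulusSequence:
    """Shift target onsets so each elicited P300 coincides with a tACS peak.

    For every target the presentation waits (from its nominal onset) for the
    next stimulator pulse, then adds the closed-form delay of
    :func:`compute_target_delay`.  All later trials inherit the accumulated
    shift (cascade), so ISI structure between neighbours is preserved.
    Standards are never gated.  ``pulses=None`` means no constraint (sham
    block): the sequence is returned unchanged.
    """
    if pulses is None:
        return sequence.copy()
    pulses = np.asarray(pulses, dtype=float)
    if pulses.size == 0:
        raise ValueError("empty pulse stream")
    latency_s = params.p300_latency / 1000.0
    out = sequence.trials.copy()
    onsets = out["onset"].to_numpy(dtype=float)
    is_target = (out["trial_type"] == "target").to_numpy()
    offset = 0.0
    waits = np.zeros(len(out))
    for i in range(len(out)):
        nominal = onsets[i] + offset
        if is_target[i]:
            j = int(np.searchsorted(pulses, nominal))
            if j >= pulses.size:
                # past the last pulse (end of plateau): leave unconstrained
                onsets[i] = nominal
                continue
            d = compute_target_delay(pulses[j], params.stim_frequency, latency_s, min_lead)
            actual = pulses[j] + d
            waits[i] = actual - nominal
            offset += actual - nominal
            onsets[i] = actual
        else:
            onsets[i] = nominal
    out["onset"] = onsets
    out["scheduling_wait"] = waits
    return replace(sequence, trials=out)
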