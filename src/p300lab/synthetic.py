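"""Synthetic EEG / behavior generator with configurable ground truth.

The generator realizes the event-related-oscillation (ERO) account of the
P300: every stimulus adds a Gaussian-windowed low-frequency burst whose
largest positive half-wave is the P300.  On top of that it produces 1/f
background activity, occipital alpha, white sensor noise, occasional
blink-like transients, a late negative target component, and plausible
oddball response behavior.  All parameters are explicit and recorded in a
ground-truth ledger so that every analysis stage can be checked against
what was injected.

Scalp topography is a fixed per-channel weight vector (no head model).  The
P300 weights form a dipolar centro-parietal pattern that sums to zero
across the full montage, so common-average re-referencing leaves the Pz
amplitude unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import DEFAULT_CHANNELS, EEGRecording
from .scheduler import STIMULUS_DURATION, StimulusSequence, generate_sequence

# Dipolar centro-parietal P300 topography; weights sum to exactly zero over
# the 22-channel montage so that common-average referencing is transparent
# at Pz.
P300_TOPOGRAPHY: dict[str, float] = {
    "Fp1": -0.80, "Fp2": -0.80, "AFz": -0.70, "F3": -0.50, "Fz": -0.45,
    "F4": -0.50, "T7": -0.35, "C3": 0.30, "Cz": 0.55, "C4": 0.30,
    "T8": -0.35, "CPz": 0.80, "P7": 0.05, "P3": 0.65, "Pz": 1.00,
    "P4": 0.65, "P8": 0.05, "POz": 0.80, "O1": 0.20, "O2": 0.20,
    "M1": -0.55, "M2": -0.55,
}

ALPHA_TOPOGRAPHY: dict[str, float] = {
    "O1": 1.0, "O2": 1.0, "POz": 0.9, "Pz": 0.6, "P3": 0.5, "P4": 0.5,
    "P7": 0.5, "P8": 0.5, "CPz": 0.3, "M1": 0.3, "M2": 0.3,
}

BLINK_TOPOGRAPHY: dict[str, float] = {
    "Fp1": 1.0, "Fp2": 1.0, "AFz": 0.7, "F3": 0.35, "Fz": 0.35, "F4": 0.35,
}

#: 9-channel subset whose P300 weights also sum to zero; used for
#: scaled-down replicate studies where simulating 22 channels is wasteful.
REDUCED_CHANNELS: tuple[str, ...] = ("Fp1", "Fp2", "Fz", "Cz", "CPz", "Pz", "POz", "M1", "M2")

# Pre->post effect components are DC-balanced double Gaussians (narrow
# positive lobe minus an equal-area wide lobe), so they pass the offline
# 0.5 Hz high-pass almost untouched and the injected window-mean change is
# what the ERP stage should recover.
_EFFECT_SIGMA = 0.08  # s, narrow lobe
_EFFECT_SIGMA_WIDE = 0.30  # s, compensating lobe
P300_WINDOW = (0.200, 0.550)  # s, mean-amplitude window of the ERP stage
LATE_WINDOW = (0.700, 1.000)  # s
_P300_EFFECT_CENTER = 0.375  # s
_LATE_EFFECT_CENTER = 0.850  # s


def topography_vector(weights: dict[str, float], ch_names: list[str], default: float = 0.0) -> np.ndarray:
    return np.array([weights.get(c, default) for c in ch_names], dtype=float)


@dataclass
class RecordingSpec:
    """Geometry and rate of a simulated recording block."""

    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    sampling_rate: float = 500.0
    duration: float | None = None  # s; None -> derived from the sequence

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        labels = list(self.channel_labels)
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        if "Pz" not in labels:
            raise ValueError("Pz (the analysis channel) must be present")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)


@dataclass
class ErpGroundTruth:
    """Event-locked signal parameters.

    ``p300_amplitude`` is the peak amplitude (microvolt, at Pz) of the
    target ERO burst; standards get ``p300_amplitude /
    target_standard_ratio``.  The burst is a cosine at ``ero_frequency``
    under a Gaussian envelope with sigma = a quarter period, so its largest
    positive half-wave peaks exactly at ``p300_latency``.
    ``p300_offset`` / ``late_offset`` add broad difference components whose
    mean over the respective measurement window equals the given value
    (microvolt, at Pz) -- this is how pre-to-post intervention effects are
    injected.  ``ero_scale`` multiplies the burst amplitude (used to shift
    ROI log-power).
    """

    p300_latency: float = 350.0  # ms
    ero_frequency: float = 4.0  # Hz, in [1, 8]
    p300_amplitude: float = 20.0  # microvolt at Pz (burst peak, target)
    n700_amplitude: float = -0.2  # microvolt at Pz, peak of late component
    target_standard_ratio: float = 2.5
    topography_weights: dict[str, float] | None = None
    n700_latency: float = 800.0  # ms
    n700_sigma: float = 0.15  # s
    p300_offset: float = 0.0  # microvolt, window-mean shift (targets)
    late_offset: float = 0.0  # microvolt, window-mean shift (targets)
    ero_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 200.0 <= self.p300_latency <= 600.0:
            raise ValueError("p300_latency must lie in [200, 600] ms")
        if not 1.0 <= self.ero_frequency <= 8.0:
            raise ValueError("ero_frequency must lie in [1, 8] Hz")
        if self.target_standard_ratio <= 1.0:
            raise ValueError("target_standard_ratio must exceed 1")


@dataclass
class NoiseSpec:
    """Background-activity model.

    Defaults describe an ICA-cleaned mobile recording: ~4-5 microvolt RMS
    broadband at Pz, dominated by the 1/f floor plus moderate occipital
    alpha.  ``artifact_rate`` is the fraction of trials carrying a
    high-amplitude frontal transient (blink-like), which gives the
    rejection stages realistic work.
    """

    one_over_f_exponent: float = 1.0
    pink_sd: float = 4.0  # microvolt, per channel
    alpha_amplitude: float = 5.0  # microvolt at 10 Hz (occipital max)
    white_noise_sd: float = 2.0  # microvolt
    artifact_rate: float = 0.05
    artifact_amplitude: float = 250.0  # microvolt

    def __post_init__(self) -> None:
        for name in ("one_over_f_exponent", "pink_sd", "alpha_amplitude", "white_noise_sd", "artifact_rate", "artifact_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def silent(cls) -> "NoiseSpec":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class EffectSpec:
    """Pre-to-post intervention effects injected into post blocks.

    ERP deltas are window-mean shifts in microvolt at Pz; the ERO delta is
    a log10-power shift in the ROI; behavioral deltas are percentage-point
    changes.  Defaults qualitatively reproduce the reference findings: no
    differential P300 change, a late-component increase under actual
    stimulation only, and a block-wise worsening of omission rate under
    both interventions.
    """

    delta_p300_actual: float = -0.28
    delta_p300_sham: float = -0.28
    delta_n700_actual: float = 0.80
    delta_n700_sham: float = 0.25
    delta_ero_power_actual: float = -0.05
    delta_ero_power_sham: float = -0.05
    delta_omission_actual: float = 9.0  # percentage points
    delta_omission_sham: float = 9.0
    delta_commission_actual: float = 1.5
    delta_commission_sham: float = 1.5

    @classmethod
    def null(cls) -> "EffectSpec":
        return cls(0, 0, 0, 0, 0, 0, 0, 0, 0, 0)

    def p300_delta(self, intervention: str) -> float:
        return self.delta_p300_actual if intervention == "actual" else self.delta_p300_sham

    def n700_delta(self, intervention: str) -> float:
        return self.delta_n700_actual if intervention == "actual" else self.delta_n700_sham

    def ero_delta(self, intervention: str) -> float:
        return self.delta_ero_power_actual if intervention == "actual" else self.delta_ero_power_sham

    def omission_delta(self, intervention: str) -> float:
        return self.delta_omission_actual if intervention == "actual" else self.delta_omission_sham

    def commission_delta(self, intervention: str) -> float:
        return self.delta_commission_actual if intervention == "actual" else self.delta_commission_sham


@dataclass
class BehaviorGroundTruth:
    """Response model: lognormal RTs, omission/commission probabilities."""

    rt_location: float = float(np.log(0.45))  # log-seconds
    rt_scale: float = 0.25
    p_omission: float = 0.18
    p_commission: float = 0.14

    def __post_init__(self) -> None:
        for p in (self.p_omission, self.p_commission):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.rt_scale < 0:
            raise ValueError("rt_scale must be non-negative")


def _pink_noise(n_ch: int, n_samples: int, exponent: float, sd: float, sfreq: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent noise, per-channel independent, normalized to ``sd``."""
    if sd == 0:
        return np.zeros((n_ch, n_samples))
    from scipy.fft import irfft, next_fast_len

    n_fft = next_fast_len(n_samples)
    n_f = n_fft // 2 + 1
    freqs = np.fft.rfftfreq(n_fft, 1.0 / sfreq)
    shape = np.zeros(n_f, dtype=np.float32)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    draws = rng.standard_normal((n_ch, 2 * n_f), dtype=np.float32)
    spec = (draws[:, :n_f] + 1j * draws[:, n_f:]) * shape
    x = irfft(spec, n=n_fft, axis=1)[:, :n_samples].astype(float)
    # spectrum has no DC component, so the mean is ~0 and a single-pass
    # sum of squares suffices for normalization
    rms = np.sqrt(np.einsum("ij,ij->i", x, x) / n_samples)
    x *= (sd / rms)[:, None]
    return x


def _effect_component(t: np.ndarray, center: float, window: tuple[float, float], delta: float, sfreq: float) -> np.ndarray:
    """DC-balanced double Gaussian whose mean over ``window`` equals ``delta``."""
    s, s2 = _EFFECT_SIGMA, _EFFECT_SIGMA_WIDE
    g = np.exp(-((t - center) ** 2) / (2 * s**2)) - (s / s2) * np.exp(-((t - center) ** 2) / (2 * s2**2))
    tw = np.arange(window[0], window[1], 1.0 / sfreq)
    wmean = (np.exp(-((tw - center) ** 2) / (2 * s**2)) - (s / s2) * np.exp(-((tw - center) ** 2) / (2 * s2**2))).mean()
    return g * (delta / wmean)


def simulate_recording(
    spec: RecordingSpec,
    sequence: StimulusSequence,
    truth: ErpGroundTruth,
    noise: NoiseSpec,
    seed: int,
) -> EEGRecording:
    """Render a continuous EEG block for one oddball sequence.

    Each stimulus adds the ERO burst (target amplitude scaled by the
    target/standard ratio and per-channel topography); targets additionally
    get the late negative component and any configured effect components.
    The marker stream carries trial type, tilt and onset.  Identical seeds
    yield identical output.
    """
    ch_names = list(spec.channel_labels)
    duration = spec.duration if spec.duration is not None else sequence.duration + 6.0
    onsets = sequence.onsets
    if onsets.size and (onsets[-1] + STIMULUS_DURATION > duration):
        raise ValueError("sequence onsets do not fit within the recording duration")
    n_samples = int(round(duration * spec.sampling_rate))
    fs = spec.sampling_rate
    rng = np.random.default_rng(seed)

    weights = truth.topography_weights if truth.topography_weights is not None else P300_TOPOGRAPHY
    unknown = [c for c in weights if c not in ch_names] if truth.topography_weights is not None else []
    if unknown:
        raise ValueError(f"topography references unknown channels: {unknown}")
    w = topography_vector(weights, ch_names)

    # --- event-locked signal at Pz (scaled per channel by the topography)
    source = np.zeros(n_samples)
    is_target = sequence.is_target
    lat = truth.p300_latency / 1000.0
    f0 = truth.ero_frequency
    sigma = 1.0 / (4.0 * f0)  # quarter period
    half = 5.0 * sigma
    n700_lat = truth.n700_latency / 1000.0
    for onset, target in zip(onsets, is_target):
        amp = truth.p300_amplitude * truth.ero_scale
        if not target:
            amp /= truth.target_standard_ratio
        t0 = onset + lat
        i0, i1 = max(0, int((t0 - half) * fs)), min(n_samples, int((t0 + half) * fs) + 1)
        tt = np.arange(i0, i1) / fs - t0
        source[i0:i1] += amp * np.cos(2 * np.pi * f0 * tt) * np.exp(-(tt**2) / (2 * sigma**2))
        if target:
            tn0 = onset + n700_lat
            j0, j1 = max(0, int((tn0 - 5 * truth.n700_sigma) * fs)), min(n_samples, int((tn0 + 5 * truth.n700_sigma) * fs) + 1)
            tn = np.arange(j0, j1) / fs - tn0
            source[j0:j1] += truth.n700_amplitude * np.exp(-(tn**2) / (2 * truth.n700_sigma**2))
            if truth.p300_offset or truth.late_offset:
                k0, k1 = max(0, int((onset - 1.0) * fs)), min(n_samples, int((onset + 2.5) * fs))
                tk = np.arange(k0, k1) / fs - onset
                if truth.p300_offset:
                    source[k0:k1] += _effect_component(tk, _P300_EFFECT_CENTER, P300_WINDOW, truth.p300_offset, fs)
                if truth.late_offset:
                    source[k0:k1] += _effect_component(tk, _LATE_EFFECT_CENTER, LATE_WINDOW, truth.late_offset, fs)

    data = np.outer(w, source)

    # --- background activity
    if noise.pink_sd > 0:
        data += _pink_noise(len(ch_names), n_samples, noise.one_over_f_exponent, noise.pink_sd, fs, rng)
    if noise.alpha_amplitude > 0:
        t = np.arange(n_samples) / fs
        wa = topography_vector(ALPHA_TOPOGRAPHY, ch_names, default=0.1)
        phases = rng.uniform(0, 2 * np.pi, size=len(ch_names))
        env_phase = rng.uniform(0, 2 * np.pi, size=len(ch_names))
        env = 0.5 + 0.5 * np.sin(2 * np.pi * 0.08 * t[None, :] + env_phase[:, None])
        data += (noise.alpha_amplitude * wa)[:, None] * env * np.sin(2 * np.pi * 10.0 * t[None, :] + phases[:, None])
    if noise.white_noise_sd > 0:
        data += rng.normal(0.0, noise.white_noise_sd, size=data.shape)
    if noise.artifact_rate > 0 and noise.artifact_amplitude > 0 and onsets.size:
        wb = topography_vector(BLINK_TOPOGRAPHY, ch_names, default=0.02)
        hit = rng.random(onsets.size) < noise.artifact_rate
        for onset in onsets[hit]:
            t0 = onset + rng.uniform(0.0, 0.5)
            width = 0.30
            i0, i1 = int(t0 * fs), min(n_samples, int((t0 + width) * fs))
            if i0 >= n_samples:
                continue
            tt = np.arange(i0, i1) / fs - t0
            blink = noise.artifact_amplitude * 0.5 * (1 - np.cos(2 * np.pi * tt / width))
            data[:, i0:i1] += wb[:, None] * blink[None, :]

    events = sequence.trials.copy()
    events["duration"] = STIMULUS_DURATION
    return EEGRecording(data=data, sfreq=fs, ch_names=ch_names, events=events)


def simulate_behavior(sequence: StimulusSequence, truth: BehaviorGroundTruth, seed: int) -> pd.DataFrame:
    """One row per trial: response side (``left``/``right``/``none``) and RT.

    Targets are answered correctly except with probability ``p_omission``
    (split between no press and the wrong key); standards receive the
    target key with probability ``p_commission``.  RTs are lognormal.
    """
    rng = np.random.default_rng(seed)
    rows = []
    target_side = "right" if sequence.standard_side == "left" else "left"
    for _, trial in sequence.trials.iterrows():
        is_target = trial["trial_type"] == "target"
        correct_side = trial["tilt"]
        rt = float(np.exp(truth.rt_location + truth.rt_scale * rng.standard_normal()))
        if is_target:
            if rng.random() < truth.p_omission:
                if rng.random() < 0.5:
                    response, rt = "none", np.nan
                else:
                    response = sequence.standard_side  # wrong key
            else:
                response = correct_side
        else:
            response = target_side if rng.random() < truth.p_commission else correct_side
        rows.append((trial["onset"], trial["trial_type"], trial["tilt"], response, rt))
    return pd.DataFrame(rows, columns=["onset", "trial_type", "tilt", "response", "response_time"])


# ---------------------------------------------------------------------------
# Crossover study
# ---------------------------------------------------------------------------

INTERVENTIONS = ("actual", "sham")
BLOCKS = ("pre", "post")


@dataclass
class SubjectTruth:
    """Per-subject ground-truth parameters (drawn random effects)."""

    subject: int
    order: tuple[str, str]  # intervention on day 2, day 3
    erp: ErpGroundTruth
    behavior: BehaviorGroundTruth
    standard_side: str
    block_jitter: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)


@dataclass
class CrossoverStudy:
    """Lazy container for a simulated pre/post x actual/sham study.

    Recordings are rendered on demand (deterministically from the study
    seed) so a full study never needs to be held in memory at once.
    """

    n_subjects: int
    subjects: list[SubjectTruth]
    effects: EffectSpec
    noise: NoiseSpec
    rec_spec: RecordingSpec
    n_trials: int
    seed: int

    def _seed_for(self, subject: int, intervention: str, block: str, stream: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(
            entropy=self.seed,
            spawn_key=(subject, INTERVENTIONS.index(intervention), BLOCKS.index(block), stream),
        )

    def _block_truth(self, subj: SubjectTruth, intervention: str, block: str) -> ErpGroundTruth:
        truth = replace(subj.erp)
        jit = subj.block_jitter.get((intervention, block), {})
        truth.p300_offset = jit.get("p300", 0.0)
        truth.late_offset = jit.get("late", 0.0)
        ero_jit = jit.get("ero", 0.0)
        if block == "post":
            truth.p300_offset += self.effects.p300_delta(intervention)
            truth.late_offset += self.effects.n700_delta(intervention)
            ero_jit += self.effects.ero_delta(intervention)
        truth.ero_scale = 10.0 ** (ero_jit / 2.0)  # log10-power shift -> amplitude factor
        return truth

    def sequence(self, subject: int, intervention: str, block: str) -> StimulusSequence:
        seed = int(self._seed_for(subject, intervention, block, 0).generate_state(1)[0] % (2**31))
        return generate_sequence(
            n_trials=self.n_trials,
            p_target=0.25,
            standard_side=self.subjects[subject].standard_side,
            seed=seed,
        )

    def recording(self, subject: int, intervention: str, block: str) -> EEGRecording:
        subj = self.subjects[subject]
        seq = self.sequence(subject, intervention, block)
        truth = self._block_truth(subj, intervention, block)
        seed = int(self._seed_for(subject, intervention, block, 1).generate_state(1)[0] % (2**31))
        return simulate_recording(self.rec_spec, seq, truth, self.noise, seed)

    def behavior(self, subject: int, intervention: str, block: str) -> pd.DataFrame:
        subj = self.subjects[subject]
        seq = self.sequence(subject, intervention, block)
        truth = subj.behavior
        if block == "post":
            truth = replace(
                truth,
                p_omission=float(np.clip(truth.p_omission + self.effects.omission_delta(intervention) / 100.0, 0, 1)),
                p_commission=float(np.clip(truth.p_commission + self.effects.commission_delta(intervention) / 100.0, 0, 1)),
            )
        seed = int(self._seed_for(subject, intervention, block, 2).generate_state(1)[0] % (2**31))
        return simulate_behavior(seq, truth, seed)

    def ledger(self) -> dict:
        """JSON-serializable record of every ground-truth parameter."""
        return {
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "n_trials": self.n_trials,
            "effects": vars(self.effects).copy(),
            "noise": vars(self.noise).copy(),
            "subjects": [
                {
                    "subject": s.subject,
                    "order": list(s.order),
                    "standard_side": s.standard_side,
                    "p300_latency_ms": s.erp.p300_latency,
                    "ero_frequency_hz": s.erp.ero_frequency,
                    "p300_amplitude_uv": s.erp.p300_amplitude,
                    "n700_amplitude_uv": s.erp.n700_amplitude,
                    "p_omission": s.behavior.p_omission,
                    "p_commission": s.behavior.p_commission,
                    "rt_location": s.behavior.rt_location,
                    "rt_scale": s.behavior.rt_scale,
                }
                for s in self.subjects
            ],
        }


def simulate_crossover_study(
    n_subjects: int = 19,
    effects: EffectSpec | None = None,
    seed: int = 0,
    noise: NoiseSpec | None = None,
    rec_spec: RecordingSpec | None = None,
    n_trials: int = 400,
    latency_sd: float = 40.0,
    frequency_sd: float = 1.2,
    amplitude_sd: float = 3.0,
    block_amplitude_sd: float = 0.40,
    block_late_sd: float = 0.30,
    block_ero_sd: float = 0.04,
) -> CrossoverStudy:
    """Draw subject-level random effects and build a lazy study container.

    Intervention order is counterbalanced deterministically (even-indexed
    subjects receive actual stimulation first), as is the standard-tilt
    assignment.  Block-level jitter models session-to-session variability
    of the ERP measures beyond sensor noise.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for a crossover study")
    effects = effects if effects is not None else EffectSpec()
    noise = noise if noise is not None else NoiseSpec()
    rec_spec = rec_spec if rec_spec is not None else RecordingSpec()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(999,)))
    subjects = []
    for i in range(n_subjects):
        erp = ErpGroundTruth(
            p300_latency=float(np.clip(rng.normal(350.0, latency_sd), 250.0, 550.0)),
            ero_frequency=float(np.clip(rng.normal(4.0, frequency_sd), 1.5, 7.5)),
            p300_amplitude=float(np.clip(rng.normal(20.0, amplitude_sd), 5.0, None)),
            n700_amplitude=float(rng.normal(-0.2, 0.15)),
        )
        behavior = BehaviorGroundTruth(
            rt_location=float(rng.normal(np.log(0.45), 0.15)),
            rt_scale=float(np.clip(rng.normal(0.25, 0.05), 0.05, None)),
            p_omission=float(np.clip(rng.normal(0.18, 0.06), 0.02, 0.6)),
            p_commission=float(np.clip(rng.normal(0.14, 0.05), 0.01, 0.5)),
        )
        jitter = {
            (iv, bl): {
                "p300": float(rng.normal(0.0, block_amplitude_sd)),
                "late": float(rng.normal(0.0, block_late_sd)),
                "ero": float(rng.normal(0.0, block_ero_sd)),
            }
            for iv in INTERVENTIONS
            for bl in BLOCKS
        }
        subjects.append(
            SubjectTruth(
                subject=i,
                order=("actual", "sham") if i % 2 == 0 else ("sham", "actual"),
                erp=erp,
                behavior=behavior,
                standard_side="left" if (i // 2) % 2 == 0 else "right",
                block_jitter=jitter,
            )
        )
    return CrossoverStudy(
        n_subjects=n_subjects,
        subjects=subjects,
        effects=effects,
        noise=noise,
        rec_spec=rec_spec,
        n_trials=n_trials,
        seed=seed,
    )


# Parametric distributional model of the measured outcomes; the cell SDs
# abstract what the full EEG chain produces and are used for fast
# statistical calibration oracles (type-I error, power) where rendering
# thousands of EEG blocks would add nothing.
OUTCOME_MODELS: dict[str, dict[str, float]] = {
    "p300_mean": {"mu": 3.0, "subject_sd": 1.3, "cell_sd": 0.50},
    "late_erp": {"mu": -0.1, "subject_sd": 1.2, "cell_sd": 0.443},
    "ero_power": {"mu": 0.63, "subject_sd": 0.30, "cell_sd": 0.06},
    "omission_rate": {"mu": 17.5, "subject_sd": 12.0, "cell_sd": 5.0},
    "rt_mean": {"mu": 0.45, "subject_sd": 0.08, "cell_sd": 0.03},
}

_OUTCOME_DELTAS = {
    "p300_mean": EffectSpec.p300_delta,
    "late_erp": EffectSpec.n700_delta,
    "ero_power": EffectSpec.ero_delta,
    "omission_rate": EffectSpec.omission_delta,
    "rt_mean": lambda self, iv: 0.0,
}


def simulate_outcome_measures(
    n_subjects: int,
    effects: EffectSpec | None = None,
    seed: int = 0,
    measures: tuple[str, ...] = ("p300_mean", "late_erp", "ero_power", "omission_rate", "rt_mean"),
) -> pd.DataFrame:
    """Draw outcome cells directly from the distributional study model.

    Returns a long table (subject, intervention, block, measure, value)
    with the same effect structure as the full EEG chain.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    effects = effects if effects is not None else EffectSpec()
    rng = np.random.default_rng(seed)
    rows = []
    for m in measures:
        model = OUTCOME_MODELS[m]
        delta_fn = _OUTCOME_DELTAS[m]
        for s in range(n_subjects):
            u = rng.normal(0.0, model["subject_sd"])
            for iv in INTERVENTIONS:
                for bl in BLOCKS:
                    val = model["mu"] + u + rng.normal(0.0, model["cell_sd"])
                    if bl == "post":
                        val += delta_fn(effects, iv)
                    rows.append((s, iv, bl, m, val))
    return pd.DataFrame(rows, columns=["subject", "intervention", "block", "measure", "value"])
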