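"""On-site parameter extraction from the pre-intervention block.

The intervention needs two per-subject numbers before it can start: the
P300 latency (peak of the target-epoch average at Pz between 250 and
450 ms) and the individual stimulation frequency (1-8 Hz power maximum in
a +/-200 ms segment around that latency).  This module reproduces that
chain: band-pass filtering and detrending, optional removal of artifact
components from a linear decomposition, statistical epoch rejection
(kurtosis and joint-probability z-scores), and the two estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .containers import EEGRecording, EpochSet, epoch_recording


@dataclass
class OnlineConfig:
    highpass: float = 0.1  # Hz
    lowpass: float = 40.0  # Hz
    ica_epoch_length: float = 2.0  # s
    erp_epoch_window: tuple[float, float] = (-2.0, 5.0)  # s
    baseline_window: tuple[float, float] = (-2.0, 0.0)  # s
    rejection_sd: float = 3.0
    latency_search_window: tuple[float, float] = (250.0, 450.0)  # ms
    freq_search_band: tuple[float, float] = (1.0, 8.0)  # Hz
    freq_time_halfwidth: float = 200.0  # ms
    freq_resolution: float = 0.1  # Hz
    channel: str = "Pz"

    #: wider latency window for subjects whose P300 peaks late
    WIDE_LATENCY_WINDOW = (250.0, 600.0)

    def __post_init__(self) -> None:
        if not 0 < self.highpass < self.lowpass:
            raise ValueError("need 0 < highpass < lowpass")
        w = self.erp_epoch_window
        if w[0] >= w[1]:
            raise ValueError("epoch window must be well-ordered")


def preprocess_online(raw: EEGRecording, cfg: OnlineConfig | None = None) -> EEGRecording:
    """Band-limit (0.1-40 Hz) and linearly detrend the continuous signal."""
    cfg = cfg or OnlineConfig()
    if raw.n_channels < 1:
        raise ValueError("recording has no channels")
    nyq = raw.sfreq / 2.0
    if cfg.lowpass >= nyq:
        raise ValueError("lowpass must be below Nyquist")
    from .erp import bandlimit

    out = raw.copy()
    out.data = signal.detrend(bandlimit(out.data, cfg.highpass, cfg.lowpass, raw.sfreq), axis=1, type="linear")
    return out


@dataclass
class LinearDecomposition:
    """Invertible linear source model ``data = mixing @ sources``."""

    mixing: np.ndarray  # (n_channels, n_components)
    unmixing: np.ndarray  # (n_components, n_channels)

    def __post_init__(self) -> None:
        recon = self.mixing @ self.unmixing
        if not np.allclose(recon @ self.mixing, self.mixing, atol=1e-6):
            raise ValueError("decomposition is not invertible on its component space")

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    def sources(self, data: np.ndarray) -> np.ndarray:
        return self.unmixing @ data


def fit_ica(raw: EEGRecording, n_components: int | None = None, seed: int = 0, max_iter: int = 500) -> LinearDecomposition:
    """FastICA on the continuous data (components = full channel rank by default)."""
    from sklearn.decomposition import FastICA

    ica = FastICA(n_components=n_components, random_state=seed, max_iter=max_iter, whiten="unit-variance")
    ica.fit(raw.data.T)
    return LinearDecomposition(mixing=ica.mixing_, unmixing=ica.components_)


def correlation_selector(reference: np.ndarray, threshold: float = 0.7):
    """Build a selector flagging components correlated with a reference trace.

    ``reference`` is one or more artifact reference signals (e.g. simulated
    EOG/ECG), shape ``(n_refs, n_samples)`` or ``(n_samples,)``.  Returns a
    callable mapping (decomposition, data) -> list of component indices
    whose time course correlates with any reference above ``threshold``.
    """
    ref = np.atleast_2d(np.asarray(reference, dtype=float))

    def select(decomp: LinearDecomposition, data: np.ndarray) -> list[int]:
        sources = decomp.sources(data)
        picked = []
        for k in range(sources.shape[0]):
            for r in ref:
                c = np.corrcoef(sources[k], r)[0, 1]
                if np.abs(c) > threshold:
                    picked.append(k)
                    break
        return picked

    return select


def remove_artifact_components(
    raw: EEGRecording,
    decomposition: LinearDecomposition,
    selector,
) -> EEGRecording:
    """Reconstruct the signal without the selected components.

    ``selector`` is either an explicit list of component indices or a
    callable ``(decomposition, data) -> indices``.  Selecting every
    component is rejected (no signal would remain).
    """
    picked = selector(decomposition, raw.data) if callable(selector) else list(selector)
    if len(picked) == decomposition.n_components:
        raise ValueError("refusing to remove all components: no signal would remain")
    out = raw.copy()
    if not picked:
        return out
    sources = decomposition.sources(raw.data)
    artifact = decomposition.mixing[:, picked] @ sources[picked]
    out.data = raw.data - artifact
    return out


def _zscore_across(values: np.ndarray) -> np.ndarray:
    """Z-score along axis 0, defined as 0 where the spread is zero."""
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mu) / sd
    return np.where(sd > 0, z, 0.0)


def reject_epochs_stat(epochs: EpochSet, sd_threshold: float = 3.0) -> EpochSet:
    """Drop epochs with outlying kurtosis or joint log-probability.

    Per channel and pooled over channels, epoch kurtosis and the Gaussian
    negative log-likelihood of the epoch's samples (channel-wise Gaussian
    fitted across all epochs) are z-scored across epochs; any |z| above
    ``sd_threshold`` drops the epoch, with the triggering metric logged.
    Retained epochs are returned bit-identical.
    """
    if epochs.n_epochs < 3:
        raise ValueError("need at least 3 epochs for statistical rejection")
    data = epochs.data  # (n_ep, n_ch, n_t)
    kurt = stats.kurtosis(data, axis=2, fisher=True, bias=True)  # (n_ep, n_ch)
    kurt_global = kurt.mean(axis=1)
    mu = data.mean(axis=(0, 2))
    sd = data.std(axis=(0, 2))
    sd = np.where(sd > 0, sd, 1.0)
    # mean NLL per epoch/channel under the across-epoch Gaussian (constant
    # terms dropped: z-scoring removes them anyway)
    nll = ((data - mu[None, :, None]) ** 2 / (2 * sd[None, :, None] ** 2)).mean(axis=2)
    nll_global = nll.mean(axis=1)

    z_kurt = _zscore_across(kurt)
    z_kurt_g = _zscore_across(kurt_global)
    z_nll = _zscore_across(nll)
    z_nll_g = _zscore_across(nll_global)

    reasons = {}
    for i in range(epochs.n_epochs):
        if np.any(np.abs(z_kurt[i]) > sd_threshold):
            reasons[i] = f"kurtosis z={np.abs(z_kurt[i]).max():.2f}"
        elif np.abs(z_kurt_g[i]) > sd_threshold:
            reasons[i] = f"global kurtosis z={np.abs(z_kurt_g[i]):.2f}"
        elif np.any(np.abs(z_nll[i]) > sd_threshold):
            reasons[i] = f"joint probability z={np.abs(z_nll[i]).max():.2f}"
        elif np.abs(z_nll_g[i]) > sd_threshold:
            reasons[i] = f"global joint probability z={np.abs(z_nll_g[i]):.2f}"

    keep = np.array([i for i in range(epochs.n_epochs) if i not in reasons], dtype=int)
    if keep.size == 0:
        raise ValueError("all epochs rejected: block unusable")
    out = epochs.copy()
    out.data = epochs.data[keep]
    out.events = epochs.events.iloc[keep].reset_index(drop=True)
    rejected = dict(epochs.rejected)
    for i, why in reasons.items():
        rejected[int(epochs.kept[i])] = why
    out.kept = epochs.kept[keep]
    out.rejected = rejected
    out.log = epochs.log + [f"statistical rejection dropped {len(reasons)}/{epochs.n_epochs} epochs"]
    return out


@dataclass
class LatencyEstimate:
    latency_ms: float
    peak_uv: float
    low_confidence: bool = False


def estimate_p300_latency(
    epochs: EpochSet,
    channel: str = "Pz",
    window: tuple[float, float] = (250.0, 450.0),
) -> LatencyEstimate:
    """Latency (ms) of the maximum of the across-epoch average at ``channel``.

    Ties break toward the earliest sample; a flat or non-positive average
    in the window is flagged low-confidence.
    """
    ci = epochs.channel_index(channel)
    times_ms = epochs.times * 1000.0
    mask = (times_ms >= window[0]) & (times_ms < window[1])
    if not mask.any():
        raise ValueError("latency window outside epoch")
    avg = epochs.average()[ci][mask]
    i = int(np.argmax(avg))  # argmax returns the first maximum: earliest-tie rule
    flat = bool(np.ptp(avg) == 0.0 or avg[i] <= 0)
    return LatencyEstimate(latency_ms=float(times_ms[mask][i]), peak_uv=float(avg[i]), low_confidence=flat)


def _segment_psd(epochs: EpochSet, ci: int, t0_ms: float, t1_ms: float, nfft: int):
    times_ms = epochs.times * 1000.0
    mask = (times_ms >= t0_ms) & (times_ms <= t1_ms)
    if not mask.any() or times_ms[0] > t0_ms or times_ms[-1] < t1_ms:
        raise ValueError("frequency segment outside epoch")
    seg = epochs.data[:, ci, :][:, mask]
    # plain zero-padded periodogram: windowing or mean-subtraction would
    # leak the burst's nonzero mean into neighbouring bins and bias the peak
    freqs, psd = signal.periodogram(seg, fs=epochs.sfreq, window="boxcar", nfft=nfft, detrend=False, axis=1)
    return freqs, psd.mean(axis=0)


def estimate_stim_frequency(
    epochs: EpochSet,
    latency_ms: float,
    band: tuple[float, float] = (1.0, 8.0),
    halfwidth_ms: float = 200.0,
    resolution: float = 0.1,
    channel: str = "Pz",
    baseline_correction: bool = True,
) -> float:
    """Frequency (Hz) of the event-related power maximum around the P300.

    Per epoch, a Hann-windowed, zero-padded periodogram of the ``channel``
    segment ``[latency - halfwidth, latency + halfwidth]`` is computed at
    ``resolution`` Hz bin spacing and averaged across epochs.  With
    ``baseline_correction`` (default) the averaged spectrum of an
    equally long pre-stimulus segment is subtracted first, which removes
    the 1/f background tilt that would otherwise bias the argmax toward
    the lowest frequency of the band.  Ties -> lower frequency.
    """
    ci = epochs.channel_index(channel)
    nfft = int(np.ceil(epochs.sfreq / resolution))
    freqs, mean_psd = _segment_psd(epochs, ci, latency_ms - halfwidth_ms, latency_ms + halfwidth_ms, nfft)
    if baseline_correction:
        width = 2 * halfwidth_ms
        try:
            _, base_psd = _segment_psd(epochs, ci, -100.0 - width, -100.0, nfft)
            mean_psd = np.maximum(mean_psd - base_psd, 0.0)
        except ValueError:
            pass  # epoch has no pre-stimulus room; fall back to raw spectrum
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise ValueError("band outside spectral grid")
    # argmax returns the first (lowest-frequency) bin on ties
    return float(freqs[in_band][int(np.argmax(mean_psd[in_band]))])


def extract_stim_params(
    raw: EEGRecording,
    cfg: OnlineConfig | None = None,
    decomposition: LinearDecomposition | None = None,
    selector=None,
):
    """Full online chain: filter, (optionally) clean, epoch, reject, estimate.

    Returns :class:`~p300lab.scheduler.IndividualStimParams`.
    """
    from .scheduler import IndividualStimParams

    cfg = cfg or OnlineConfig()
    clean = preprocess_online(raw, cfg)
    if decomposition is not None and selector is not None:
        clean = remove_artifact_components(clean, decomposition, selector)
    targets = clean.events[clean.events["trial_type"] == "target"]
    epochs = epoch_recording(
        clean,
        targets["onset"].to_numpy(dtype=float),
        tmin=cfg.erp_epoch_window[0],
        tmax=cfg.erp_epoch_window[1],
        baseline=cfg.baseline_window,
        events=targets.reset_index(drop=True),
    )
    epochs = reject_epochs_stat(epochs, cfg.rejection_sd)
    est = estimate_p300_latency(epochs, cfg.channel, cfg.latency_search_window)
    freq = estimate_stim_frequency(
        epochs,
        est.latency_ms,
        band=cfg.freq_search_band,
        halfwidth_ms=cfg.freq_time_halfwidth,
        resolution=cfg.freq_resolution,
        channel=cfg.channel,
    )
    freq = float(np.clip(freq, 1.0, 8.0))
    return IndividualStimParams(
        p300_latency=est.latency_ms,
        stim_frequency=freq,
        n_epochs_used=epochs.n_epochs,
        low_confidence=est.low_confidence,
    )
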