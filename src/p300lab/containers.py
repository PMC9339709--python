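"""Core in-memory containers shared across the analysis stages.

Conventions
-----------
* Time is represented in seconds internally; user-facing measures are in ms.
* Signals are stored channel-major, in microvolts.
* Epoch windows are half-open ``[tmin, tmax)`` in sample space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: 22-channel 10/20 montage of the mobile recording setup.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "AFz", "F3", "Fz", "F4", "T7", "C3", "Cz", "C4", "T8",
    "CPz", "P7", "P3", "Pz", "P4", "P8", "POz", "O1", "O2", "M1", "M2",
)


@dataclass
class EEGRecording:
    """Continuous multichannel EEG with an event (marker) table.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``, in microvolts.
    sfreq
        Sampling rate in Hz.
    ch_names
        Channel labels (10/20 names); must be unique.
    events
        One row per marker with at least ``onset`` (s) and ``trial_type``
        columns; extra columns are carried through untouched.
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["onset", "trial_type"]))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        self.ch_names = list(self.ch_names)
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("channel count mismatch between data and ch_names")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sfreq

    def channel_index(self, name: str) -> int:
        try:
            return self.ch_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None

    def copy(self) -> "EEGRecording":
        return EEGRecording(self.data.copy(), self.sfreq, list(self.ch_names), self.events.copy())


@dataclass
class EpochSet:
    """Trials x channels x samples array with rejection bookkeeping.

    ``kept`` holds the original trial indices of the rows in ``data``;
    ``rejected`` maps original trial indices to the reason they were dropped.
    The invariant ``len(kept) + len(rejected) == original trial count`` is
    maintained by every rejection stage.
    """

    data: np.ndarray  # (n_epochs, n_channels, n_samples)
    sfreq: float
    ch_names: list[str]
    tmin: float
    events: pd.DataFrame
    kept: np.ndarray
    rejected: dict[int, str] = field(default_factory=dict)
    baseline: tuple[float, float] | None = None
    log: list[str] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_original(self) -> int:
        return len(self.kept) + len(self.rejected)

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.sfreq

    def channel_index(self, name: str) -> int:
        try:
            return self.ch_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in epochs") from None

    def copy(self) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy(),
            ch_names=list(self.ch_names),
            events=self.events.copy(),
            kept=self.kept.copy(),
            rejected=dict(self.rejected),
            log=list(self.log),
        )

    def average(self) -> np.ndarray:
        """Across-epoch mean, shape (n_channels, n_samples)."""
        if self.n_epochs == 0:
            raise ValueError("no epochs to average")
        return self.data.mean(axis=0)


def epoch_recording(
    rec: EEGRecording,
    onsets: np.ndarray,
    tmin: float,
    tmax: float,
    baseline: tuple[float, float] | None = None,
    events: pd.DataFrame | None = None,
) -> EpochSet:
    """Cut ``[tmin, tmax)`` windows around stimulus onsets.

    Trials whose window does not fit inside the recording are dropped and
    logged (reason ``"window outside recording"``).  Baseline correction
    subtracts the per-channel mean over ``[baseline[0], baseline[1])``.
    """
    onsets = np.asarray(onsets, dtype=float)
    if events is None:
        events = pd.DataFrame({"onset": onsets})
    n_per = int(round((tmax - tmin) * rec.sfreq))
    starts = np.round((onsets + tmin) * rec.sfreq).astype(int)
    ok = (starts >= 0) & (starts + n_per <= rec.n_samples)
    kept_idx = np.flatnonzero(ok)
    rejected = {int(i): "window outside recording" for i in np.flatnonzero(~ok)}
    data = np.stack([rec.data[:, s : s + n_per] for s in starts[ok]]) if kept_idx.size else np.empty((0, rec.n_channels, n_per))
    epochs = EpochSet(
        data=data,
        sfreq=rec.sfreq,
        ch_names=list(rec.ch_names),
        tmin=tmin,
        events=events.iloc[kept_idx].reset_index(drop=True),
        kept=kept_idx,
        rejected=rejected,
        baseline=baseline,
    )
    if baseline is not None:
        apply_baseline(epochs, baseline)
    return epochs


def apply_baseline(epochs: EpochSet, baseline: tuple[float, float]) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over ``[b0, b1)`` in place."""
    b0, b1 = baseline
    times = epochs.times
    mask = (times >= b0) & (times < b1)
    if not mask.any():
        raise ValueError("baseline window outside epoch")
    epochs.data -= epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    epochs.baseline = (b0, b1)
    return epochs
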