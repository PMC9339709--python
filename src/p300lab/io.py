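"""Reading and writing: recordings, BIDS-style event tables, configs, ledgers.

Signals are serialized through MNE.  EDF and BrainVision files are read
natively; on-disk output uses MNE's FIF format with a BIDS-style
``events.tsv`` sidecar (onset, duration, trial_type, plus any extra
columns, carried through verbatim).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EEGRecording


def write_events_tsv(events: pd.DataFrame, path) -> Path:
    path = Path(path)
    lead = [c for c in ("onset", "duration", "trial_type") if c in events.columns]
    cols = lead + [c for c in events.columns if c not in lead]
    events[cols].to_csv(path, sep="\t", index=False, na_rep="n/a")
    return path


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["n/a"])


def save_recording(rec: EEGRecording, path, events_path=None) -> Path:
    """Write a recording to FIF (+ events.tsv sidecar).

    MNE stores EEG in volts; data are converted from microvolts on write
    and back on read.
    """
    import mne

    path = Path(path)
    if not path.name.endswith(("raw.fif", "raw.fif.gz")):
        path = path.with_name(path.stem + "_raw.fif")
    info = mne.create_info(rec.ch_names, sfreq=rec.sfreq, ch_types="eeg")
    raw = mne.io.RawArray(rec.data * 1e-6, info, verbose="error")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw.save(path, overwrite=True, verbose="error")
    if events_path is None:
        events_path = path.with_name(path.name.replace("_raw.fif", "_events.tsv"))
    write_events_tsv(rec.events, events_path)
    return path


def load_recording(path, events_path=None) -> EEGRecording:
    """Read FIF/EDF/BrainVision into an :class:`EEGRecording` (microvolts)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if path.suffix == ".fif" or path.name.endswith(".fif.gz"):
            raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
        elif path.suffix.lower() == ".edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        elif path.suffix.lower() == ".vhdr":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        else:
            raise ValueError(f"unrecognized recording format: {path.name}")
    if events_path is None:
        cand = path.with_name(path.name.replace("_raw.fif", "_events.tsv"))
        events_path = cand if cand.exists() else None
    events = read_events_tsv(events_path) if events_path else pd.DataFrame(columns=["onset", "trial_type"])
    return EEGRecording(
        data=raw.get_data() * 1e6,
        sfreq=float(raw.info["sfreq"]),
        ch_names=list(raw.ch_names),
        events=events,
    )


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def save_json(obj: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonify(obj), indent=2, allow_nan=True) + "\n")
    return path


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())


def load_yaml(path) -> dict:
    import yaml

    return yaml.safe_load(Path(path).read_text())
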