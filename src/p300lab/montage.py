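"""Electrode geometry helpers: 10/20 positions and spherical-spline interpolation.

Spherical-spline interpolation follows the classical EEG approach (surface
splines on a sphere fitted through the electrode positions); the matrix is
computed once per bad-channel set and applied as a linear map from good to
bad channels.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np


@lru_cache(maxsize=1)
def _montage_positions() -> dict[str, np.ndarray]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1020")
    return {k: np.asarray(v, dtype=float) for k, v in montage.get_positions()["ch_pos"].items()}


def channel_positions(ch_names: list[str]) -> np.ndarray:
    """Unit-sphere-projected 3D positions for the given 10/20 labels."""
    pos_map = _montage_positions()
    missing = [c for c in ch_names if c not in pos_map]
    if missing:
        raise KeyError(f"no template position for channels: {missing}")
    pos = np.array([pos_map[c] for c in ch_names])
    pos = pos - pos.mean(axis=0)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return pos


def interpolation_matrix(ch_names, bads) -> np.ndarray:
    return _interpolation_matrix_cached(tuple(ch_names), tuple(bads))


@lru_cache(maxsize=256)
def _interpolation_matrix_cached(ch_names: tuple, bads: tuple) -> np.ndarray:
    """Spherical-spline map from good channels to bad channels.

    Returns a matrix ``M`` of shape ``(len(bads), n_good)`` such that
    ``repaired[bads] = M @ data[goods]``.
    """
    from mne.channels.interpolation import _make_interpolation_matrix

    bads = list(bads)
    goods = [c for c in ch_names if c not in bads]
    if not goods:
        raise ValueError("cannot interpolate: no good channels left")
    unknown = [c for c in bads if c not in ch_names]
    if unknown:
        raise KeyError(f"bad channels not in montage: {unknown}")
    pos = channel_positions(ch_names)
    idx = {c: i for i, c in enumerate(ch_names)}
    pos_good = pos[[idx[c] for c in goods]]
    pos_bad = pos[[idx[c] for c in bads]]
    return _make_interpolation_matrix(pos_good, pos_bad)


def interpolate_channels(data: np.ndarray, ch_names: list[str], bads: list[str]) -> np.ndarray:
    """Replace ``bads`` rows of ``data`` (channels x samples) by spline estimates."""
    if not bads:
        return data
    mat = interpolation_matrix(ch_names, bads)
    goods_idx = [i for i, c in enumerate(ch_names) if c not in bads]
    bads_idx = [ch_names.index(c) for c in bads]
    out = data.copy()
    out[bads_idx] = mat @ data[goods_idx]
    return out
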