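"""Sensor-space preprocessing: band-pass filtering, bad-channel
interpolation, and REST re-referencing toward an infinity reference."""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .types import EEGRecording, ElectrodeMontage, Leadfield

__all__ = ["bandpass", "interpolate_channels", "rest_rereference"]


def bandpass(recording: EEGRecording, lo_hz: float = 1.0, hi_hz: float = 80.0,
             order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass; channel means (DC) removed first."""
    ny = recording.fs / 2.0
    if not 0.0 < lo_hz < hi_hz < ny:
        raise ValueError(f"band ({lo_hz}, {hi_hz}) Hz infeasible at fs={recording.fs}")
    b, a = sps.butter(order, [lo_hz / ny, hi_hz / ny], btype="bandpass")
    data = recording.data - recording.data.mean(axis=1, keepdims=True)
    out = sps.filtfilt(b, a, data, axis=1)
    return recording.copy_with_data(out)


def interpolate_channels(
    recording: EEGRecording,
    bad_names: list[str],
    montage: ElectrodeMontage,
    n_neighbors: int = 4,
) -> EEGRecording:
    """Replace bad channels by the inverse-distance-weighted mean of their
    nearest good neighbors (weights sum to 1 per bad channel)."""
    bad = set(bad_names)
    unknown = bad - set(recording.channel_names)
    if unknown:
        raise ValueError(f"unknown channels {sorted(unknown)}")
    if not bad:
        return recording.copy_with_data(recording.data.copy())
    if bad >= set(recording.channel_names):
        raise ValueError("cannot interpolate: all channels marked bad")

    pos = {n: p for n, p in zip(montage.names, montage.positions)}
    good = [n for n in recording.channel_names if n not in bad]
    if len(good) < n_neighbors:
        raise ValueError(f"fewer than {n_neighbors} good neighbors available")
    ch_index = {n: i for i, n in enumerate(recording.channel_names)}
    data = recording.data.copy()
    for name in bad_names:
        d = np.array([np.linalg.norm(pos[name] - pos[g]) for g in good])
        nearest = np.argsort(d)[:n_neighbors]
        w = 1.0 / np.maximum(d[nearest], 1e-9)
        w = w / w.sum()
        rows = [ch_index[good[i]] for i in nearest]
        data[ch_index[name]] = w @ recording.data[rows]
    return recording.copy_with_data(data)


def rest_rereference(
    recording: EEGRecording,
    leadfield: Leadfield,
    svd_rtol: float = 1e-6,
) -> EEGRecording:
    """Reference Electrode Standardization Technique.

    The average-referenced data are mapped to source space with the
    truncated-SVD minimum-norm fit of the average-referenced gain, then
    re-expressed through the unreferenced gain, approximating a recording
    against a reference at infinity. Idempotent up to numerical tolerance.
    """
    if recording.channel_names != leadfield.channel_names:
        raise ValueError("recording channels do not match leadfield montage")
    if leadfield.gain_unref is None:
        raise ValueError("leadfield carries no unreferenced gain")
    G_avg = leadfield.gain
    U, s, Vt = np.linalg.svd(G_avg, full_matrices=False)
    keep = s > svd_rtol * s[0]
    if keep.sum() < 2:
        raise ValueError("average-referenced gain is rank-deficient beyond tolerance")
    pinv = (Vt[keep].T / s[keep]) @ U[:, keep].T

    data = recording.data - recording.data.mean(axis=0, keepdims=True)
    out = leadfield.gain_unref @ (pinv @ data)
    return recording.copy_with_data(out, reference_tag="REST")
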