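"""Seed-based envelope connectivity.

Seed ROI time courses are decomposed with a short-time Fourier transform
(Hamming windows, 50% overlap); for every frequency bin and seed pair the
zero-lag leakage component is removed by orthogonalization, log power
envelopes are correlated across windows, the two orthogonalization
directions are averaged and Fisher-transformed, and per-bin z-values are
averaged within canonical frequency bands.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import get_window

from .synthetic import DEFAULT_BANDS
from .types import (
    ConnectivityMatrix,
    NetworkConnectivitySummary,
    NetworkDefinition,
    SourceGrid,
    SourceTimeCourses,
    TFCoefficients,
)

__all__ = [
    "extract_seed_timecourses",
    "stft",
    "orthogonalized_envelope_correlation",
    "band_average",
    "network_summary",
    "intra_vs_inter_contrast",
    "connectivity_matrix",
]


def extract_seed_timecourses(
    sources: SourceTimeCourses,
    network_def: NetworkDefinition,
    grid: SourceGrid,
) -> np.ndarray:
    """Scalar time course per seed ROI, shape (n_seeds, n_samples).

    Nodes within ``roi_radius`` of a seed are stacked and projected onto
    the ROI's dominant orientation (first right singular vector of the
    node × component moment matrix); the sign is fixed so the projection
    correlates positively with the strongest-power node's dominant
    component.
    """
    n_samples = sources.moments.shape[2]
    node_pos = grid.positions[sources.node_indices]
    out = np.empty((len(network_def.seed_names), n_samples))
    for k, seed_pos in enumerate(network_def.seed_positions):
        d = np.linalg.norm(node_pos - seed_pos, axis=1)
        members = np.flatnonzero(d <= network_def.roi_radius)
        if members.size == 0:
            raise ValueError(
                f"seed {network_def.seed_names[k]!r}: ROI contains no source node")
        stack = sources.moments[members].reshape(members.size * 3, n_samples)
        # dominant orientation across nodes and components
        U, s, Vt = np.linalg.svd(stack, full_matrices=False)
        series = s[0] * Vt[0]
        # intrinsic sign convention (invariant to a global flip of all
        # moments): the largest-magnitude sample of the series is positive
        if series[np.argmax(np.abs(series))] < 0:
            series = -series
        out[k] = series
    return out


def stft(
    seed_series: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    overlap: float = 0.5,
) -> TFCoefficients:
    """Hamming-tapered windowed DFT of seed time courses.

    With 2 s windows the bins are spaced 0.5 Hz; consecutive windows
    overlap by ``overlap`` (50% default), so a T-second series yields
    (T − window)/hop + 1 windows.
    """
    x = np.atleast_2d(np.asarray(seed_series, dtype=float))
    nperseg = int(round(window_s * fs))
    if x.shape[1] < nperseg:
        raise ValueError("series shorter than one window")
    hop = int(round(nperseg * (1.0 - overlap)))
    if hop < 1:
        raise ValueError("overlap too large")
    n_win = (x.shape[1] - nperseg) // hop + 1
    taper = get_window("hamming", nperseg)
    starts = np.arange(n_win) * hop
    frames = np.stack([x[:, s0:s0 + nperseg] for s0 in starts], axis=2)  # (seeds, nperseg, win)
    frames = frames - frames.mean(axis=1, keepdims=True)   # per-segment demean
    spectra = np.fft.rfft(frames * taper[None, :, None], axis=1)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    return TFCoefficients(
        spectra=np.transpose(spectra, (0, 1, 2)),
        freqs=freqs,
        window_s=window_s,
        overlap=overlap,
    )


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two (bins, windows) arrays;
    degenerate (constant) rows yield 0."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((ac**2).mean(axis=1))
    sb = np.sqrt((bc**2).mean(axis=1))
    num = (ac * bc).mean(axis=1)
    den = sa * sb
    out = np.zeros(a.shape[0])
    ok = den > 1e-300
    out[ok] = num[ok] / den[ok]
    return out


def orthogonalized_envelope_correlation(
    tf_x: np.ndarray,
    tf_y: np.ndarray,
    eps_scale: float = 1e-12,
) -> np.ndarray:
    """Per-bin Fisher-z orthogonalized log-power envelope correlation.

    ``tf_x``/``tf_y`` are complex (bins, windows) arrays on identical bins
    and windows. Per bin, Y is orthogonalized on X (imaginary part of
    Y·conj(X)/|X|), log power envelopes are Pearson-correlated across
    windows, roles are swapped, the two correlations averaged and
    atanh-transformed. Pure zero-lag leakage (Y ∝ X, real factor) gives
    z = 0 by construction.
    """
    X = np.asarray(tf_x)
    Y = np.asarray(tf_y)
    if X.shape != Y.shape or X.ndim != 2:
        raise ValueError("coefficient arrays must share (bins, windows) shape")
    if X.shape[1] < 10:
        raise ValueError("need at least 10 windows")
    ax = np.abs(X)
    ay = np.abs(Y)
    dead = np.all(ax == 0, axis=1) | np.all(ay == 0, axis=1)
    if dead.any():
        raise ValueError(f"zero-power frequency bin {int(np.flatnonzero(dead)[0])}")
    px = ax**2
    py = ay**2
    med = np.median(np.r_[px.ravel(), py.ravel()])
    eps = eps_scale * max(med, 1e-300)
    y_perp = np.imag(Y * np.conj(X) / np.maximum(ax, 1e-300))
    x_perp = np.imag(X * np.conj(Y) / np.maximum(ay, 1e-300))
    r1 = _pearson_rows(np.log(y_perp**2 + eps), np.log(px + eps))
    r2 = _pearson_rows(np.log(x_perp**2 + eps), np.log(py + eps))
    r = 0.5 * (r1 + r2)
    return np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7))


def band_average(
    per_bin_z: np.ndarray,
    freqs: np.ndarray,
    band_edges: dict[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Mean z over the bins falling in each half-open band [lo, hi)."""
    if band_edges is None:
        band_edges = DEFAULT_BANDS
    out = {}
    for name, (lo, hi) in band_edges.items():
        sel = (freqs >= lo) & (freqs < hi)
        if not sel.any():
            raise ValueError(f"band {name}: no frequency bins in [{lo}, {hi})")
        out[name] = float(np.mean(per_bin_z[sel]))
    return out


def connectivity_matrix(
    seed_series: np.ndarray,
    fs: float,
    seed_names: list[str],
    band_edges: dict[str, tuple[float, float]] | None = None,
    window_s: float = 2.0,
    overlap: float = 0.5,
) -> ConnectivityMatrix:
    """Full seed × seed band-limited Fisher-z connectivity matrices."""
    if band_edges is None:
        band_edges = DEFAULT_BANDS
    tf = stft(seed_series, fs, window_s, overlap)
    n = len(seed_names)
    mats = {band: np.zeros((n, n)) for band in band_edges}
    for i in range(n):
        for j in range(i + 1, n):
            per_bin = orthogonalized_envelope_correlation(tf.spectra[i], tf.spectra[j])
            per_band = band_average(per_bin, tf.freqs, band_edges)
            for band, val in per_band.items():
                mats[band][i, j] = mats[band][j, i] = val
    return ConnectivityMatrix(z=mats, band_edges=dict(band_edges), seed_names=list(seed_names))


def network_summary(
    conn: ConnectivityMatrix,
    network_def: NetworkDefinition,
    band: str,
) -> NetworkConnectivitySummary:
    """Network × network mean z: diagonal averages within-network seed
    pairs, off-diagonal averages all between-network pairs."""
    if conn.seed_names != network_def.seed_names:
        raise ValueError("connectivity seeds do not match the network definition")
    nets = network_def.networks
    m = conn.z[band]
    out = np.zeros((len(nets), len(nets)))
    for a, net_a in enumerate(nets):
        ia = network_def.seeds_of(net_a)
        if len(ia) < 2:
            raise ValueError(f"network {net_a} has fewer than 2 seeds")
        pairs = [(i, j) for ii, i in enumerate(ia) for j in ia[ii + 1:]]
        out[a, a] = np.mean([m[i, j] for i, j in pairs])
        for bnd in range(a + 1, len(nets)):
            ib = network_def.seeds_of(nets[bnd])
            vals = [m[i, j] for i in ia for j in ib]
            out[a, bnd] = out[bnd, a] = np.mean(vals)
    return NetworkConnectivitySummary(values=out, networks=nets)


def intra_vs_inter_contrast(
    per_subject_summaries: list[NetworkConnectivitySummary],
    network: str,
) -> float:
    """One-tailed Wilcoxon signed-rank contrast of intra- vs mean
    inter-network connectivity across replicates, reported as a signed
    z-score (positive = intra > inter)."""
    from .stats import wilcoxon_signed_rank

    if len(per_subject_summaries) < 6:
        raise ValueError("need at least 6 replicates")
    intra, inter = [], []
    for s in per_subject_summaries:
        k = s.networks.index(network)
        intra.append(s.values[k, k])
        others = [s.values[k, j] for j in range(len(s.networks)) if j != k]
        inter.append(np.mean(others))
    _, _, z = wilcoxon_signed_rank(np.asarray(intra), np.asarray(inter),
                                   alternative="greater")
    return z
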