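"""Synthetic study inputs: spherical head phantom, scalp montage, network
layout, and coupled dipole source activity.

The phantom is a set of concentric tissue shells on an isotropic voxel grid
(optionally subdivided into 12 tissue classes by deterministic angular and
radial sectors, so that merging the classes reproduces the 3-shell geometry
voxel for voxel). Source activity is band-limited noise whose log power
envelopes follow a prescribed within-/between-network correlation structure,
which is exactly the quantity the connectivity stage estimates.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from . import labels as L
from .types import (
    EEGRecording,
    ElectrodeMontage,
    Leadfield,
    NetworkDefinition,
    SourceGrid,
    SourceTimeCourses,
    TissueLabelVolume,
)

__all__ = [
    "DEFAULT_BANDS",
    "make_phantom",
    "make_montage",
    "make_network_definition",
    "simulate_sources",
    "project_to_sensors",
]

#: Canonical EEG frequency bands, Hz (half-open intervals [lo, hi)).
DEFAULT_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 80.0),
}

_DEFAULT_SHELL_RATIOS = (("scalp", 1.0), ("skull", 85.0 / 92.0), ("brain", 80.0 / 92.0))


def _default_shell_spec(outer_radius_mm: float):
    return tuple((name, outer_radius_mm * ratio) for name, ratio in _DEFAULT_SHELL_RATIOS)


def make_phantom(
    outer_radius_mm: float = 92.0,
    shell_spec: tuple[tuple[str, float], ...] | None = None,
    voxel_mm: float = 4.0,
    twelve_tissue: bool = False,
) -> TissueLabelVolume:
    """Build a concentric-shell head phantom as a labeled voxel volume.

    Parameters
    ----------
    outer_radius_mm : scalp outer radius.
    shell_spec : ``((name, outer_radius), ...)`` listed outermost to
        innermost with strictly decreasing radii. Default: scalp/skull/brain
        shells scaled from a 92/85/80 mm adult head.
    voxel_mm : isotropic voxel size. The thinnest shell must span at least
        one voxel, otherwise the discrete volume cannot represent it.
    twelve_tissue : subdivide the three shells into 12 tissue classes by
        deterministic angular/radial sectors. Merging those classes back
        reproduces the 3-shell labeling exactly.
    """
    if voxel_mm <= 0:
        raise ValueError("voxel_mm must be positive")
    if shell_spec is None:
        shell_spec = _default_shell_spec(outer_radius_mm)
    names = [s[0] for s in shell_spec]
    radii = np.asarray([s[1] for s in shell_spec], dtype=float)
    if abs(radii[0] - outer_radius_mm) > 1e-9:
        raise ValueError("outermost shell radius must equal outer_radius_mm")
    if np.any(np.diff(radii) >= 0):
        raise ValueError("shell radii must be strictly decreasing (outermost first)")
    thicknesses = np.r_[-np.diff(radii), radii[-1]]
    if thicknesses.min() < voxel_mm:
        raise ValueError(
            f"voxel size {voxel_mm} mm too coarse for thinnest shell "
            f"({thicknesses.min():g} mm)"
        )

    half = int(math.ceil(outer_radius_mm / voxel_mm)) + 1
    n = 2 * half + 1                    # odd: a voxel center sits at the origin
    c = half
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -c * voxel_mm

    ax = (np.arange(n) - c) * voxel_mm
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    R = np.sqrt(X**2 + Y**2 + Z**2)

    shells = np.zeros((n, n, n), dtype=np.int16)
    # assign innermost last so inner labels overwrite outer ones
    for k, r in enumerate(radii):
        shells[R <= r] = k + 1

    if len(shell_spec) == 3 and names == ["scalp", "skull", "brain"]:
        lab3 = np.zeros_like(shells)
        lab3[shells == 1] = L.SCALP
        lab3[shells == 2] = L.SKULL
        lab3[shells == 3] = L.BRAIN
        if not twelve_tissue:
            return TissueLabelVolume(lab3, voxel_mm, affine, dict(L.LABELS_3))
        lab12 = _subdivide_12(lab3, X, Y, Z, R, radii)
        return TissueLabelVolume(lab12, voxel_mm, affine, dict(L.LABELS_12))

    if twelve_tissue:
        raise ValueError("twelve_tissue mode requires the scalp/skull/brain 3-shell spec")
    label_dict = {k + 1: name for k, name in enumerate(names)}
    return TissueLabelVolume(shells, voxel_mm, affine, label_dict)


def _subdivide_12(lab3, X, Y, Z, R, radii):
    """Deterministic 3-shell -> 12-tissue subdivision (pure relabeling)."""
    r_scalp, r_skull, r_brain = radii
    out = np.zeros_like(lab3)
    with np.errstate(invalid="ignore", divide="ignore"):
        dx, dy, dz = X / R, Y / R, Z / R
    dx = np.nan_to_num(dx)
    dy = np.nan_to_num(dy)
    dz = np.nan_to_num(dz)

    # --- scalp shell -> skin / muscle / fat / eyes -------------------------
    scalp = lab3 == L.SCALP
    eye_dirs = np.array([[0.35, 0.92, 0.05], [-0.35, 0.92, 0.05]])
    eye_dirs /= np.linalg.norm(eye_dirs, axis=1, keepdims=True)
    cos_eye = np.maximum(
        dx * eye_dirs[0, 0] + dy * eye_dirs[0, 1] + dz * eye_dirs[0, 2],
        dx * eye_dirs[1, 0] + dy * eye_dirs[1, 1] + dz * eye_dirs[1, 2],
    )
    is_eye = cos_eye > math.cos(math.radians(14.0))
    out[scalp & is_eye] = L.EYES
    out[scalp & ~is_eye & (dz < -0.3)] = L.FAT
    out[scalp & ~is_eye & (dz >= -0.3) & (dz < 0.1)] = L.MUSCLE
    out[scalp & ~is_eye & (dz >= 0.1)] = L.SKIN

    # --- skull shell -> compact / spongy (radial thirds) -------------------
    skull = lab3 == L.SKULL
    t = (R - r_brain) / max(r_skull - r_brain, 1e-12)
    spongy = skull & (t > 1.0 / 3.0) & (t <= 2.0 / 3.0)
    out[skull] = L.COMPACT_BONE
    out[spongy] = L.SPONGY_BONE

    # --- intracranial -> CSF / GM / WM / cerebellum / brainstem ------------
    brain = lab3 == L.BRAIN
    rb = R / max(r_brain, 1e-12)
    cerebellar = (dy < -0.45) & (dz < -0.2)
    rho = np.sqrt(X**2 + Y**2)
    stem = (rho < 0.15 * r_brain) & (Z < -0.1 * r_brain)

    out[brain] = L.CORTICAL_WM
    out[brain & (rb > 0.80)] = L.CORTICAL_GM
    out[brain & cerebellar] = L.CEREBELLAR_WM
    out[brain & cerebellar & (rb > 0.80)] = L.CEREBELLAR_GM
    out[brain & stem & ~cerebellar & (rb <= 0.80)] = L.BRAINSTEM
    out[brain & (rb > 0.94)] = L.CSF
    return out


def make_montage(
    n_electrodes: int,
    phantom: TissueLabelVolume,
    coverage_polar_angle_deg: float = 120.0,
) -> ElectrodeMontage:
    """Quasi-uniform (Fibonacci lattice) electrode cap on the phantom scalp.

    Electrodes are placed on a spherical cap of the given polar half-angle
    around the vertex (+z) and projected onto the scalp surface.
    Deterministic for fixed inputs.
    """
    if n_electrodes < 4:
        raise ValueError("need at least 4 electrodes")
    if not 0.0 < coverage_polar_angle_deg <= 180.0:
        raise ValueError("coverage angle must be in (0, 180] degrees")

    from .head_model import project_electrodes_to_scalp

    cos_max = math.cos(math.radians(coverage_polar_angle_deg))
    i = np.arange(n_electrodes)
    z = 1.0 - (i + 0.5) * (1.0 - cos_max) / n_electrodes
    phi = i * math.pi * (3.0 - math.sqrt(5.0))    # golden angle
    s = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    dirs = np.c_[s * np.cos(phi), s * np.sin(phi), z]

    r_outer = _outer_scalp_radius(phantom)
    positions = dirs * r_outer
    names = [f"E{k + 1:03d}" for k in range(n_electrodes)]
    fid_r = r_outer
    fiducials = {
        "NAS": np.array([0.0, fid_r, 0.0]),
        "LPA": np.array([-fid_r, 0.0, 0.0]),
        "RPA": np.array([fid_r, 0.0, 0.0]),
    }
    montage = ElectrodeMontage(names, positions, head_center=np.zeros(3),
                               fiducials=fiducials)
    return project_electrodes_to_scalp(montage, phantom)


def _outer_scalp_radius(phantom: TissueLabelVolume) -> float:
    nz = np.argwhere(phantom.labels > 0)
    world = phantom.voxel_to_world(nz)
    return float(np.linalg.norm(world, axis=1).max())


# 21 seeds / 6 networks: unit directions (RAS) mimicking a bilateral DMN,
# DAN, SMN, VN and strongly lateralized VAN (right) / LN (left) layout.
_SEED_TABLE = [
    ("PCC", "DMN", (0.0, -0.6, 0.8)),
    ("MPFC", "DMN", (0.0, 0.9, 0.45)),
    ("lANG", "DMN", (-0.8, -0.55, 0.3)),
    ("rANG", "DMN", (0.8, -0.55, 0.3)),
    ("lFEF", "DAN", (-0.45, 0.35, 0.85)),
    ("rFEF", "DAN", (0.45, 0.35, 0.85)),
    ("lIPS", "DAN", (-0.65, -0.5, 0.6)),
    ("rIPS", "DAN", (0.65, -0.5, 0.6)),
    ("rTPJ", "VAN", (0.9, -0.25, 0.15)),
    ("rIFG", "VAN", (0.85, 0.55, 0.0)),
    ("lTPJ", "LN", (-0.9, -0.25, 0.15)),
    ("lIFG", "LN", (-0.85, 0.55, 0.0)),
    ("SMA", "SMN", (0.0, 0.1, 1.0)),
    ("lS1", "SMN", (-0.55, -0.1, 0.85)),
    ("rS1", "SMN", (0.55, -0.1, 0.85)),
    ("lS2", "SMN", (-0.95, 0.05, 0.2)),
    ("rS2", "SMN", (0.95, 0.05, 0.2)),
    ("lV4v", "VN", (-0.5, -0.85, -0.1)),
    ("rV4v", "VN", (0.5, -0.85, -0.1)),
    ("lV5", "VN", (-0.85, -0.5, -0.1)),
    ("rV5", "VN", (0.85, -0.5, -0.1)),
]

LATERALIZED_NETWORKS = ("VAN", "LN")


def make_network_definition(
    phantom: TissueLabelVolume,
    roi_radius: float = 6.0,
    seed_radius_fraction: float = 0.85,
) -> NetworkDefinition:
    """Default 6-network / 21-seed layout inside the phantom grey matter.

    VAN and LN are lateralized (all seeds in one hemisphere); the other four
    networks are bilateral. Seeds sit on a sphere at ``seed_radius_fraction``
    of the brain radius, which places them inside the cortical grey-matter
    band of the 12-tissue phantom and inside the brain shell of the 3-shell
    one.
    """
    gm_labels = _grey_labels(phantom)
    r_brain = _innermost_shell_radius(phantom)
    radius = seed_radius_fraction * r_brain

    names, nets, dirs = [], [], []
    for name, net, d in _SEED_TABLE:
        names.append(name)
        nets.append(net)
        dirs.append(np.asarray(d, dtype=float))
    dirs = np.array([d / np.linalg.norm(d) for d in dirs])
    positions = dirs * radius

    # voxelization can put the nominal radius just outside the grey band at
    # coarse resolutions: nudge each seed radially to the nearest GM voxel
    seed_labels = phantom.label_at(positions)
    step = phantom.voxel_size / 4.0
    for i in np.flatnonzero(~np.isin(seed_labels, gm_labels)):
        found = False
        for dr in np.arange(step, 0.3 * r_brain, step):
            for cand_r in (radius - dr, radius + dr):
                if cand_r <= 0 or cand_r >= r_brain:
                    continue
                cand = dirs[i] * cand_r
                if phantom.label_at(cand[None])[0] in gm_labels:
                    positions[i] = cand
                    found = True
                    break
            if found:
                break
        if not found:
            raise ValueError(f"grey matter too small for the requested layout: "
                             f"seed {names[i]} cannot be placed")
    d2 = np.linalg.norm(positions[:, None] - positions[None], axis=-1)
    np.fill_diagonal(d2, np.inf)
    min_sep = max(2.0 * roi_radius, 12.0)
    if d2.min() < min_sep:
        raise ValueError(f"seed separation {d2.min():.1f} mm below {min_sep:g} mm")

    return NetworkDefinition(
        seed_names=names,
        seed_positions=positions,
        network_of_seed=dict(zip(names, nets)),
        roi_radius=roi_radius,
    )


def _grey_labels(phantom: TissueLabelVolume) -> tuple[int, ...]:
    names = {v: k for k, v in phantom.label_dict.items()}
    if "brain" in names:
        return (names["brain"],)
    return tuple(names[n] for n in ("cortical grey matter", "cerebellar grey matter")
                 if n in names)


def _innermost_shell_radius(phantom: TissueLabelVolume) -> float:
    """Outer radius of the brain compartment (merged if 12-tissue)."""
    names = {v: k for k, v in phantom.label_dict.items()}
    if "brain" in names:
        mask = phantom.labels == names["brain"]
    else:
        brain_lbls = [lbl for lbl, nm in phantom.label_dict.items()
                      if L.MERGE_12_TO_3.get(lbl) == L.BRAIN]
        mask = np.isin(phantom.labels, brain_lbls)
    world = phantom.voxel_to_world(np.argwhere(mask))
    return float(np.linalg.norm(world, axis=1).max())


def _bandlimited_noise(rng, n_samples, fs, lo, hi):
    """Unit-variance band-pass filtered white noise."""
    x = rng.standard_normal(n_samples)
    ny = fs / 2.0
    b, a = sps.butter(4, [lo / ny, hi / ny], btype="bandpass")
    y = sps.filtfilt(b, a, x)
    return y / (y.std() + 1e-30)


def _smooth_unit_noise(rng, n_samples, fs, timescale_s):
    """Unit-variance low-pass noise: the building block of log-envelopes."""
    x = rng.standard_normal(n_samples)
    y = gaussian_filter1d(x, sigma=timescale_s * fs, mode="wrap")
    return (y - y.mean()) / (y.std() + 1e-30)


def _one_over_f_noise(rng, n_samples, fs, f_min=1.0):
    """Unit-variance 1/f-amplitude noise (flat below f_min)."""
    spec = rng.standard_normal(n_samples // 2 + 1) + 1j * rng.standard_normal(n_samples // 2 + 1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amp = 1.0 / np.maximum(f, f_min)
    y = np.fft.irfft(spec * amp, n=n_samples)
    return (y - y.mean()) / (y.std() + 1e-30)


def simulate_sources(
    network_def: NetworkDefinition,
    grid: SourceGrid,
    band_spec: dict[str, tuple[float, float]] | None = None,
    intra_coupling: float = 0.9,
    inter_coupling: float = 0.1,
    duration_s: float = 300.0,
    fs: float = 250.0,
    rng_seed: int = 0,
    seed_amplitude_nAm: float = 10.0,
    background_rel_amplitude: float = 0.2,
    n_background: int = 100,
    envelope_timescale_s: float = 0.25,
    log_envelope_sd: float = 0.4,
) -> SourceTimeCourses:
    """Simulate coupled band-limited dipole activity at the network seeds.

    Each seed's activity per band is band-pass noise modulated by a
    log-normal envelope. The log-envelope is a fixed mixture of a global
    component (weight ``sqrt(inter_coupling)``), a per-network component
    (``sqrt(intra_coupling - inter_coupling)``) and a private component, so
    the log-envelope correlation equals ``intra_coupling`` within a network
    and ``inter_coupling`` between networks, in expectation. Non-seed
    background activity is 1/f noise at ``n_background`` randomly chosen
    grid nodes. Dipole orientations are radial, fixed per node.
    """
    if band_spec is None:
        band_spec = {"alpha": DEFAULT_BANDS["alpha"]}
    if not 0.0 <= inter_coupling < intra_coupling <= 1.0 and not (
        intra_coupling == inter_coupling == 0.0
    ):
        raise ValueError("need 0 <= inter_coupling < intra_coupling <= 1 (or both 0)")
    if duration_s < 60.0:
        raise ValueError("duration must be at least 60 s")
    for name, (lo, hi) in band_spec.items():
        if not 0.0 < lo < hi < fs / 2.0:
            raise ValueError(f"band {name}: edges ({lo}, {hi}) outside (0, fs/2)")

    rng = np.random.default_rng(rng_seed)
    n_samples = int(round(duration_s * fs))
    n_seeds = len(network_def.seed_names)
    networks = network_def.networks
    net_index = {n: i for i, n in enumerate(networks)}

    # seed -> nearest grid node
    d = np.linalg.norm(grid.positions[None] - network_def.seed_positions[:, None], axis=-1)
    seed_nodes = np.argmin(d, axis=1)

    c_g = math.sqrt(inter_coupling)
    c_n = math.sqrt(max(intra_coupling - inter_coupling, 0.0))
    c_p = math.sqrt(max(1.0 - intra_coupling, 0.0))

    seed_series = np.zeros((n_seeds, n_samples))
    envcorr: dict[str, np.ndarray] = {}
    for band_name, (lo, hi) in band_spec.items():
        g = _smooth_unit_noise(rng, n_samples, fs, envelope_timescale_s)
        s_net = np.array([_smooth_unit_noise(rng, n_samples, fs, envelope_timescale_s)
                          for _ in networks])
        target = np.full((n_seeds, n_seeds), inter_coupling)
        for i in range(n_seeds):
            net_i = network_def.network_of_seed[network_def.seed_names[i]]
            for j in range(n_seeds):
                net_j = network_def.network_of_seed[network_def.seed_names[j]]
                if net_i == net_j:
                    target[i, j] = intra_coupling
        np.fill_diagonal(target, 1.0)
        envcorr[band_name] = target

        for i, name in enumerate(network_def.seed_names):
            k = net_index[network_def.network_of_seed[name]]
            p = _smooth_unit_noise(rng, n_samples, fs, envelope_timescale_s)
            log_env = log_envelope_sd * (c_g * g + c_n * s_net[k] + c_p * p)
            env = np.exp(log_env - log_envelope_sd**2 / 2.0)
            carrier = _bandlimited_noise(rng, n_samples, fs, lo, hi)
            seed_series[i] += env * carrier

    # background 1/f activity at randomly chosen non-seed nodes
    others = np.setdiff1d(np.arange(grid.n_nodes), seed_nodes)
    n_bg = min(n_background, len(others))
    bg_nodes = rng.choice(others, size=n_bg, replace=False) if n_bg else np.array([], int)
    bg_series = np.array([
        background_rel_amplitude * _one_over_f_noise(rng, n_samples, fs)
        for _ in range(n_bg)
    ]).reshape(n_bg, n_samples)

    node_indices = np.r_[seed_nodes, bg_nodes]
    series = np.vstack([seed_series, bg_series]) if n_bg else seed_series
    dirs = grid.positions[node_indices]
    norms = np.linalg.norm(dirs, axis=1, keepdims=True)
    dirs = np.where(norms > 1e-9, dirs / np.maximum(norms, 1e-9),
                    np.array([0.0, 0.0, 1.0]))
    moments = seed_amplitude_nAm * dirs[:, :, None] * series[:, None, :]

    return SourceTimeCourses(
        node_indices=node_indices,
        moments=moments,
        fs=fs,
        ground_truth_envcorr=envcorr,
    )


def project_to_sensors(
    leadfield: Leadfield,
    sources: SourceTimeCourses,
    sensor_noise_snr_db: float = 10.0,
    rng_seed: int = 0,
) -> EEGRecording:
    """Project dipole moments through the leadfield and add sensor noise.

    Noise is spatially white Gaussian, average-referenced, and scaled so
    that mean-over-channels signal variance / noise variance matches the
    requested SNR. ``snr_db=inf`` disables noise.
    """
    if np.isnan(sensor_noise_snr_db):
        raise ValueError("SNR must be finite or +inf")
    if sources.node_indices.size and sources.node_indices.max() >= leadfield.n_nodes:
        raise ValueError("source node index outside leadfield grid")

    n_samples = sources.moments.shape[2]
    cols = (3 * sources.node_indices[:, None] + np.arange(3)[None]).ravel()
    flat = sources.moments.reshape(-1, n_samples)
    data = leadfield.gain[:, cols] @ flat

    if np.isfinite(sensor_noise_snr_db):
        rng = np.random.default_rng(rng_seed)
        noise = rng.standard_normal(data.shape)
        noise -= noise.mean(axis=0, keepdims=True)      # average reference
        var_sig = data.var(axis=1).mean()
        var_noise = noise.var(axis=1).mean()
        snr_lin = 10.0 ** (sensor_noise_snr_db / 10.0)
        if var_noise > 0 and var_sig > 0:
            noise *= math.sqrt(var_sig / (snr_lin * var_noise))
        data = data + noise

    return EEGRecording(
        channel_names=list(leadfield.channel_names),
        data=data,
        fs=sources.fs,
        reference_tag="average",
    )
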