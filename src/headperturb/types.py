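"""Core domain containers shared across the pipeline.

All world coordinates are RAS millimetres; voxel indices are 0-based.
Dipole moments are expressed in nA·m, potentials in µV, conductivities in S/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TissueLabelVolume",
    "ElectrodeMontage",
    "NetworkDefinition",
    "SourceTimeCourses",
    "EEGRecording",
    "ConductivityVolume",
    "SourceGrid",
    "Leadfield",
    "InverseOperator",
    "TFCoefficients",
    "ConnectivityMatrix",
    "NetworkConnectivitySummary",
    "PerturbationSpec",
]


@dataclass
class TissueLabelVolume:
    """Voxelized head segmentation: integer labels on an isotropic grid.

    ``affine`` maps 0-based voxel indices to world mm; ``label_dict`` maps
    each nonzero label to a tissue name. Background (air) is label 0.
    """

    labels: np.ndarray          # 3-D int array
    voxel_size: float           # mm, isotropic
    affine: np.ndarray          # 4x4 voxel-index -> world-mm
    label_dict: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.label_dict)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from label_dict")

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world-mm points to (fractional) voxel indices."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        homog = np.c_[pts, np.ones(len(pts))]
        return (homog @ inv.T)[:, :3]

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        homog = np.c_[idx, np.ones(len(idx))]
        return (homog @ self.affine.T)[:, :3]

    def label_at(self, points_mm: np.ndarray) -> np.ndarray:
        """Nearest-voxel label at world points (0 outside the volume)."""
        vox = np.rint(self.world_to_voxel(points_mm)).astype(int)
        out = np.zeros(len(vox), dtype=self.labels.dtype)
        inside = np.all((vox >= 0) & (vox < self.labels.shape), axis=1)
        ii = vox[inside]
        out[inside] = self.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out


@dataclass
class ElectrodeMontage:
    """Named electrode positions in world mm, plus fiducials and head center."""

    names: list[str]
    positions: np.ndarray               # (n, 3) mm
    head_center: np.ndarray             # (3,) mm
    fiducials: dict[str, np.ndarray] | None = None   # NAS/LPA/RPA

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.head_center = np.asarray(self.head_center, dtype=float)
        if len(self.names) != len(self.positions):
            raise ValueError("names and positions length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("electrode names must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def copy_with_positions(self, positions: np.ndarray) -> "ElectrodeMontage":
        return ElectrodeMontage(
            names=list(self.names),
            positions=np.asarray(positions, dtype=float).copy(),
            head_center=self.head_center.copy(),
            fiducials=None if self.fiducials is None
            else {k: v.copy() for k, v in self.fiducials.items()},
        )


@dataclass
class NetworkDefinition:
    """Seed ROIs grouped into networks (resting-state network layout)."""

    seed_names: list[str]
    seed_positions: np.ndarray          # (n_seeds, 3) mm
    network_of_seed: dict[str, str]
    roi_radius: float = 6.0             # mm

    def __post_init__(self) -> None:
        self.seed_positions = np.asarray(self.seed_positions, dtype=float)
        for name in self.seed_names:
            if name not in self.network_of_seed:
                raise ValueError(f"seed {name!r} has no network assignment")
        counts: dict[str, int] = {}
        for net in self.network_of_seed.values():
            counts[net] = counts.get(net, 0) + 1
        for net, c in counts.items():
            if c < 2:
                raise ValueError(f"network {net!r} has fewer than 2 seeds")

    @property
    def networks(self) -> list[str]:
        seen: list[str] = []
        for name in self.seed_names:
            net = self.network_of_seed[name]
            if net not in seen:
                seen.append(net)
        return seen

    def seeds_of(self, network: str) -> list[int]:
        return [i for i, s in enumerate(self.seed_names)
                if self.network_of_seed[s] == network]


@dataclass
class SourceTimeCourses:
    """Dipole moment time series for a subset of grid nodes.

    ``moments`` has shape (n_nodes, 3, n_samples) in nA·m. For simulated
    data, ``ground_truth_envcorr`` stores the per-band seed-pair correlation
    matrices of the generating log-envelopes.
    """

    node_indices: np.ndarray            # indices into a SourceGrid
    moments: np.ndarray                 # (n_nodes, 3, n_samples), nA·m
    fs: float
    ground_truth_envcorr: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.node_indices = np.asarray(self.node_indices, dtype=int)
        self.moments = np.asarray(self.moments, dtype=float)
        if self.moments.ndim != 3 or self.moments.shape[1] != 3:
            raise ValueError("moments must have shape (n_nodes, 3, n_samples)")
        if len(self.node_indices) != self.moments.shape[0]:
            raise ValueError("node_indices / moments mismatch")
        if not np.all(np.isfinite(self.moments)):
            raise ValueError("non-finite moments")


@dataclass
class EEGRecording:
    """Multichannel scalp recording, µV."""

    channel_names: list[str]
    data: np.ndarray                    # (channels, samples), µV
    fs: float
    reference_tag: str = "common"       # {average, REST, common}

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels, samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel count mismatch")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite samples in recording")

    def copy_with_data(self, data: np.ndarray, reference_tag: str | None = None) -> "EEGRecording":
        return EEGRecording(
            channel_names=list(self.channel_names),
            data=np.asarray(data, dtype=float),
            fs=self.fs,
            reference_tag=reference_tag or self.reference_tag,
        )


@dataclass
class ConductivityVolume:
    """Per-voxel isotropic conductivity (S/m); 0 outside the head."""

    sigma: np.ndarray                   # 3-D float array, S/m
    voxel_size: float                   # mm
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma < 0):
            raise ValueError("negative conductivity")


@dataclass
class SourceGrid:
    """Regular dipole lattice restricted to generating tissue labels."""

    positions: np.ndarray               # (n_nodes, 3) world mm
    spacing: float                      # mm
    generating_labels: tuple[int, ...]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)

    @property
    def n_nodes(self) -> int:
        return len(self.positions)


@dataclass
class Leadfield:
    """Gain matrix: channels × (nodes·3), µV per nA·m.

    ``gain`` is average-referenced. ``gain_unref`` keeps the solver's native
    reference (reference electrode at zero potential) and is needed by REST.
    """

    gain: np.ndarray
    channel_names: list[str]
    node_positions: np.ndarray
    reference: str = "average"
    gain_unref: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.shape[0] != len(self.channel_names):
            raise ValueError("gain rows / channel names mismatch")
        if self.gain.shape[1] != 3 * len(self.node_positions):
            raise ValueError("gain columns must be 3 × n_nodes")
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("non-finite leadfield entries")

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.gain.shape[1] // 3


@dataclass
class InverseOperator:
    """Linear inverse kernel: (nodes·3) × channels."""

    kernel: np.ndarray
    alpha: float
    iterations: int
    converged: bool
    node_positions: np.ndarray | None = None
    history: list[float] | None = None    # per-iteration max relative weight change

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        if self.kernel.shape[0] % 3:
            raise ValueError("kernel rows must come in per-node triplets")
        if not np.all(np.isfinite(self.kernel)):
            raise ValueError("non-finite inverse kernel")

    @property
    def n_nodes(self) -> int:
        return self.kernel.shape[0] // 3


@dataclass
class TFCoefficients:
    """Short-time Fourier coefficients: seeds × bins × windows."""

    spectra: np.ndarray                 # complex (seeds, bins, windows)
    freqs: np.ndarray                   # Hz, per bin
    window_s: float
    overlap: float
    taper: str = "hamming"

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.spectra.ndim != 3:
            raise ValueError("spectra must be (seeds, bins, windows)")
        if self.spectra.shape[1] != len(self.freqs):
            raise ValueError("bin count mismatch")

    @property
    def n_windows(self) -> int:
        return self.spectra.shape[2]


@dataclass
class ConnectivityMatrix:
    """Seed × seed Fisher-z envelope correlations, one matrix per band."""

    z: dict[str, np.ndarray]            # band name -> (seeds, seeds)
    band_edges: dict[str, tuple[float, float]]
    seed_names: list[str]

    def __post_init__(self) -> None:
        n = len(self.seed_names)
        for band, m in self.z.items():
            m = np.asarray(m, dtype=float)
            if m.shape != (n, n):
                raise ValueError(f"band {band}: matrix shape {m.shape} != ({n},{n})")
            off = ~np.eye(n, dtype=bool)
            if not np.all(np.isfinite(m[off])):
                raise ValueError(f"band {band}: non-finite off-diagonal entries")
            if not np.allclose(m, m.T, atol=1e-10, equal_nan=True):
                raise ValueError(f"band {band}: matrix not symmetric")
            self.z[band] = m

    @property
    def bands(self) -> list[str]:
        return list(self.z)


@dataclass
class NetworkConnectivitySummary:
    """Network × network mean Fisher z (diagonal = intra-network)."""

    values: np.ndarray                  # (networks, networks)
    networks: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.allclose(self.values, self.values.T, atol=1e-10, equal_nan=True):
            raise ValueError("summary not symmetric")


_ELECTRODE_MAGNITUDES = (0.25, 0.5, 0.75, 1.0)
_SEG_VARIANTS = ("12layer_wts", "3layer_wts", "3layer_template")


@dataclass(frozen=True)
class PerturbationSpec:
    """One test model: an electrode error, a device preset, or a segmentation variant."""

    kind: str                           # {electrode, segmentation}
    error_type: str | None = None      # {systematic, random}
    magnitude_cm: float | None = None
    device: str | None = None          # {3dscan, digitizer}
    segmentation_variant: str | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        has_err = self.error_type is not None or self.magnitude_cm is not None
        active = [self.device is not None, has_err, self.segmentation_variant is not None]
        if sum(active) != 1:
            raise ValueError("exactly one of device / (error_type, magnitude) / "
                             "segmentation_variant must be set")
        if self.kind == "electrode":
            if self.segmentation_variant is not None:
                raise ValueError("electrode spec cannot carry a segmentation variant")
            if has_err:
                if self.error_type not in ("systematic", "random"):
                    raise ValueError(f"unknown error_type {self.error_type!r}")
                if self.magnitude_cm not in _ELECTRODE_MAGNITUDES:
                    raise ValueError(f"magnitude must be one of {_ELECTRODE_MAGNITUDES}")
            elif self.device not in ("3dscan", "digitizer"):
                raise ValueError(f"unknown device {self.device!r}")
        elif self.kind == "segmentation":
            if self.segmentation_variant not in _SEG_VARIANTS:
                raise ValueError(f"unknown segmentation variant {self.segmentation_variant!r}")
        else:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")

    @property
    def model_id(self) -> str:
        if self.device is not None:
            return f"device:{self.device}"
        if self.segmentation_variant is not None:
            return f"seg:{self.segmentation_variant}"
        return f"elec:{self.error_type}:{self.magnitude_cm:g}cm"
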