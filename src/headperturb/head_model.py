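"""Head-model construction: conductivity assignment, tissue merging,
segmentation degradation, electrode scalp projection, and the regular
dipole source grid.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from . import labels as L
from .types import ConductivityVolume, ElectrodeMontage, SourceGrid, TissueLabelVolume

__all__ = [
    "assign_conductivities",
    "merge_to_three_layers",
    "emulate_template_segmentation",
    "project_electrodes_to_scalp",
    "build_source_grid",
]


def assign_conductivities(
    labels: TissueLabelVolume,
    table: dict[str, float] | None = None,
) -> ConductivityVolume:
    """Per-voxel conductivity lookup (S/m); air (label 0) maps to 0.

    ``table`` maps tissue names to conductivities and must cover every
    label present in the volume. Defaults depend on the label dictionary
    (3-shell or 12-tissue).
    """
    if table is None:
        names = set(labels.label_dict.values())
        if names <= set(L.DEFAULT_CONDUCTIVITY_3):
            table = L.DEFAULT_CONDUCTIVITY_3
        else:
            table = L.DEFAULT_CONDUCTIVITY_12
    present = np.unique(labels.labels)
    lut = np.zeros(int(present.max()) + 1)
    for lbl in present:
        if lbl == 0:
            continue
        name = labels.label_dict[int(lbl)]
        if name not in table:
            raise ValueError(f"conductivity table missing tissue {name!r} (label {lbl})")
        if table[name] <= 0:
            raise ValueError(f"non-positive conductivity for {name!r}")
        lut[int(lbl)] = table[name]
    sigma = lut[labels.labels]
    return ConductivityVolume(sigma, labels.voxel_size, labels.affine.copy())


def merge_to_three_layers(labels12: TissueLabelVolume) -> TissueLabelVolume:
    """Merge the 12 tissue classes into scalp / skull / brain.

    Brain collects cortical and cerebellar grey and white matter, brainstem
    and CSF; skull collects compact and spongy bone; scalp collects skin,
    muscle, fat and eyes. Pure relabeling: nonzero voxel count is conserved.
    """
    present = set(np.unique(labels12.labels).tolist()) - {0}
    unknown = present - set(L.MERGE_12_TO_3)
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)} for the 12-class dictionary")
    for lbl in present:
        if labels12.label_dict.get(lbl) != L.LABELS_12[lbl]:
            raise ValueError(f"label {lbl} does not follow the 12-class dictionary")
    lut = np.zeros(13, dtype=labels12.labels.dtype)
    for src, dst in L.MERGE_12_TO_3.items():
        lut[src] = dst
    merged = lut[labels12.labels]
    return TissueLabelVolume(merged, labels12.voxel_size, labels12.affine.copy(),
                             dict(L.LABELS_3))


def emulate_template_segmentation(
    labels: TissueLabelVolume,
    warp_amplitude_mm: float,
    warp_smoothness_mm: float = 15.0,
    rng_seed: int = 0,
) -> TissueLabelVolume:
    """Degrade a segmentation by resampling through a smooth random warp.

    The displacement field is Gaussian-filtered vector noise rescaled so
    that the RMS displacement magnitude equals ``warp_amplitude_mm``;
    labels are pulled back with nearest-neighbor interpolation. Amplitude 0
    returns the input unchanged. Emulates the mis-segmentation incurred by
    warping a template segmentation instead of segmenting the individual
    image.
    """
    if warp_amplitude_mm < 0:
        raise ValueError("warp amplitude must be >= 0")
    if warp_smoothness_mm <= labels.voxel_size:
        raise ValueError("warp smoothness must exceed the voxel size")
    if warp_amplitude_mm == 0:
        return TissueLabelVolume(labels.labels.copy(), labels.voxel_size,
                                 labels.affine.copy(), dict(labels.label_dict))

    rng = np.random.default_rng(rng_seed)
    shape = labels.labels.shape
    sigma_vox = warp_smoothness_mm / labels.voxel_size
    disp = np.stack([
        gaussian_filter(rng.standard_normal(shape), sigma_vox, mode="constant")
        for _ in range(3)
    ])
    rms = np.sqrt((disp**2).sum(axis=0).mean())
    disp *= warp_amplitude_mm / (rms * labels.voxel_size + 1e-30)   # voxels

    idx = np.indices(shape).astype(float)
    coords = idx + disp
    warped = map_coordinates(labels.labels, coords, order=0, mode="constant", cval=0)
    return TissueLabelVolume(warped, labels.voxel_size, labels.affine.copy(),
                             dict(labels.label_dict))


def _scalp_mask(labels: TissueLabelVolume) -> np.ndarray:
    """Nonzero-tissue mask; its outer surface is the scalp."""
    return labels.labels > 0


def project_electrodes_to_scalp(
    montage: ElectrodeMontage,
    labels: TissueLabelVolume,
    step_fraction: float = 0.25,
) -> ElectrodeMontage:
    """Move each electrode to the outermost head-surface point along the
    ray from head_center through its position. Names and order preserved;
    idempotent up to the ray sampling step (a quarter voxel).
    """
    center = montage.head_center
    center_vox = np.rint(labels.world_to_voxel(center[None])[0]).astype(int)
    shape = labels.labels.shape
    if not (np.all(center_vox >= 0) and np.all(center_vox < shape)):
        raise ValueError("head_center outside the label volume")

    mask = _scalp_mask(labels)
    step = step_fraction * labels.voxel_size
    # generous upper bound on the head extent along any ray
    r_max = labels.voxel_size * max(shape) * 0.87

    new_positions = np.empty_like(montage.positions)
    for k, pos in enumerate(montage.positions):
        d = pos - center
        nd = np.linalg.norm(d)
        if nd < 1e-9:
            raise ValueError(f"electrode {montage.names[k]} coincides with head_center")
        d = d / nd
        radii = np.arange(step, r_max, step)
        pts = center[None] + radii[:, None] * d[None]
        vox = np.rint(labels.world_to_voxel(pts)).astype(int)
        inside = np.all((vox >= 0) & (vox < shape), axis=1)
        hit = np.zeros(len(radii), dtype=bool)
        vi = vox[inside]
        hit[inside] = mask[vi[:, 0], vi[:, 1], vi[:, 2]]
        if not hit.any():
            raise ValueError(f"ray for electrode {montage.names[k]} misses the head")
        r_surf = radii[np.flatnonzero(hit).max()]
        new_positions[k] = center + r_surf * d
    return montage.copy_with_positions(new_positions)


def build_source_grid(
    labels: TissueLabelVolume,
    spacing_mm: float = 6.0,
    generating_labels: tuple[int, ...] | None = None,
) -> SourceGrid:
    """Regular dipole lattice restricted to the generating tissue labels.

    The lattice is aligned to the world origin (node coordinates are integer
    multiples of the spacing), so node placement is reproducible across
    volumes sharing a world frame. Default generating labels are the
    grey-matter classes of the volume's dictionary.
    """
    if spacing_mm < labels.voxel_size:
        raise ValueError("grid spacing must be at least the voxel size")
    if generating_labels is None:
        names = {v: k for k, v in labels.label_dict.items()}
        if "brain" in names:
            generating_labels = (names["brain"],)
        else:
            generating_labels = tuple(
                names[n] for n in ("cortical grey matter", "cerebellar grey matter")
                if n in names
            )
    if not generating_labels:
        raise ValueError("no generating labels")

    corner_lo = labels.voxel_to_world(np.zeros((1, 3)))[0]
    corner_hi = labels.voxel_to_world(np.array([labels.labels.shape]) - 1)[0]
    lo = np.ceil(np.minimum(corner_lo, corner_hi) / spacing_mm).astype(int)
    hi = np.floor(np.maximum(corner_lo, corner_hi) / spacing_mm).astype(int)
    axes = [np.arange(a, b + 1) * spacing_mm for a, b in zip(lo, hi)]
    XX, YY, ZZ = np.meshgrid(*axes, indexing="ij")
    pts = np.c_[XX.ravel(), YY.ravel(), ZZ.ravel()]
    lab = labels.label_at(pts)
    keep = np.isin(lab, generating_labels)
    if not keep.any():
        raise ValueError("source grid is empty for the given generating labels")
    return SourceGrid(pts[keep], spacing_mm, tuple(int(g) for g in generating_labels))
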