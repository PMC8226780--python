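"""Head-model test models: electrode positioning errors (systematic rigid
rotations and per-electrode random displacements), device presets, and
degraded segmentation variants."""

from __future__ import annotations

import math

import numpy as np

from .head_model import (
    assign_conductivities,
    emulate_template_segmentation,
    merge_to_three_layers,
    project_electrodes_to_scalp,
)
from .types import (
    ConductivityVolume,
    ElectrodeMontage,
    PerturbationSpec,
    SourceGrid,
    TissueLabelVolume,
)

__all__ = [
    "systematic_rotation",
    "random_displacement",
    "device_preset",
    "make_test_model",
    "electrode_error_grid",
    "AXES",
]

#: Signed head rotation axes: anteroposterior (y), mediolateral (x),
#: longitudinal (z).
AXES = {
    "AP+": np.array([0.0, 1.0, 0.0]),
    "AP-": np.array([0.0, -1.0, 0.0]),
    "ML+": np.array([1.0, 0.0, 0.0]),
    "ML-": np.array([-1.0, 0.0, 0.0]),
    "LONG+": np.array([0.0, 0.0, 1.0]),
    "LONG-": np.array([0.0, 0.0, -1.0]),
}


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    a = axis / np.linalg.norm(axis)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def systematic_rotation(
    montage: ElectrodeMontage,
    magnitude_cm: float,
    axis: str = "random-choice",
    rng_seed: int = 0,
    labels: TissueLabelVolume | None = None,
) -> ElectrodeMontage:
    """One rigid rotation of the whole montage (co-registration error).

    The rotation angle is calibrated so the mean pre-projection electrode
    displacement equals ``magnitude_cm`` exactly: the chord displacement of
    an electrode at perpendicular distance ρ from the axis is 2ρ·sin(θ/2),
    so θ = 2·arcsin(d / (2·mean ρ)). If ``labels`` is given, rotated
    electrodes are re-projected onto the scalp.
    """
    if magnitude_cm < 0:
        raise ValueError("magnitude must be >= 0")
    if montage.head_center is None:
        raise ValueError("montage lacks a head_center")
    if magnitude_cm == 0:
        return montage.copy_with_positions(montage.positions)
    rng = np.random.default_rng(rng_seed)
    if axis == "random-choice":
        axis = list(AXES)[rng.integers(len(AXES))]
    if axis not in AXES:
        raise ValueError(f"unknown axis {axis!r}")
    a = AXES[axis]

    rel = montage.positions - montage.head_center
    rho = np.linalg.norm(rel - np.outer(rel @ a, a), axis=1)
    mean_rho = rho.mean()
    d_mm = magnitude_cm * 10.0
    arg = d_mm / (2.0 * mean_rho)
    if arg > 1.0:
        raise ValueError("magnitude too large for this montage")
    theta = 2.0 * math.asin(arg)
    Rm = _rotation_matrix(a, theta)
    new = (rel @ Rm.T) + montage.head_center
    out = montage.copy_with_positions(new)
    if labels is not None:
        out = project_electrodes_to_scalp(out, labels)
    return out


def random_displacement(
    montage: ElectrodeMontage,
    magnitude_cm: float,
    rng_seed: int = 0,
    labels: TissueLabelVolume | None = None,
) -> ElectrodeMontage:
    """Independent per-electrode rotations (localization error).

    Each electrode is rotated about the head center within the plane
    spanned by its radial direction and a uniformly-random tangential
    direction, through the angle that makes its chord displacement exactly
    ``magnitude_cm``.
    """
    if magnitude_cm < 0:
        raise ValueError("magnitude must be >= 0")
    if magnitude_cm == 0:
        return montage.copy_with_positions(montage.positions)
    rng = np.random.default_rng(rng_seed)
    d_mm = magnitude_cm * 10.0
    rel = montage.positions - montage.head_center
    new = np.empty_like(rel)
    for k, p in enumerate(rel):
        r = np.linalg.norm(p)
        if d_mm > 2.0 * r:
            raise ValueError("magnitude exceeds electrode diameter range")
        phat = p / r
        # random tangential direction
        while True:
            v = rng.standard_normal(3)
            t = v - (v @ phat) * phat
            nt = np.linalg.norm(t)
            if nt > 1e-9:
                t /= nt
                break
        axis = np.cross(phat, t)           # rotation moves p toward t
        theta = 2.0 * math.asin(d_mm / (2.0 * r))
        new[k] = _rotation_matrix(axis, theta) @ p
    out = montage.copy_with_positions(new + montage.head_center)
    if labels is not None:
        out = project_electrodes_to_scalp(out, labels)
    return out


def device_preset(
    montage: ElectrodeMontage,
    device: str,
    rng_seed: int = 0,
    labels: TissueLabelVolume | None = None,
) -> ElectrodeMontage:
    """Electrode-error presets for common positioning devices.

    3D scanning: a 0.25 cm systematic error and no random error.
    Digitizer: a 0.5 cm systematic error plus a 0.25 cm random error.
    The rotation direction is drawn from ``rng_seed`` (randomized across
    participants); magnitudes are fixed per device.
    """
    rng = np.random.default_rng(rng_seed)
    s1, s2 = int(rng.integers(2**31)), int(rng.integers(2**31))
    if device == "3dscan":
        return systematic_rotation(montage, 0.25, "random-choice", s1, labels)
    if device == "digitizer":
        out = systematic_rotation(montage, 0.5, "random-choice", s1, labels=None)
        return random_displacement(out, 0.25, s2, labels)
    raise ValueError(f"unknown device {device!r}")


def electrode_error_grid():
    """The 4 magnitudes × 2 error types = 8 electrode test models."""
    specs = []
    for error_type in ("systematic", "random"):
        for mag in (0.25, 0.5, 0.75, 1.0):
            specs.append(PerturbationSpec(kind="electrode", error_type=error_type,
                                          magnitude_cm=mag))
    return specs


def make_test_model(
    labels12: TissueLabelVolume,
    montage: ElectrodeMontage,
    grid: SourceGrid,
    spec: PerturbationSpec,
    conductivity_table: dict[str, float] | None = None,
    warp_amplitude_mm: float = 2.0,
    warp_smoothness_mm: float = 15.0,
) -> tuple[ConductivityVolume, ElectrodeMontage, SourceGrid]:
    """Build one test model, varying a single component of the reference.

    The reference workflow uses the individual 12-tissue segmentation with
    the given montage and grid. Electrode specs perturb only the montage.
    Segmentation specs rebuild the conductivity volume from a randomly
    warped segmentation: ``12layer_wts`` keeps 12 tissue classes,
    ``3layer_wts`` merges them to three (both keep the reference
    electrodes); ``3layer_template`` additionally swaps in the template
    montage, i.e. the unperturbed electrode lattice re-projected on the
    distorted scalp.
    """
    ref_sigma = assign_conductivities(labels12, conductivity_table)

    if spec.kind == "electrode":
        if spec.device is not None:
            new_mon = device_preset(montage, spec.device, spec.rng_seed, labels12)
        elif spec.error_type == "systematic":
            new_mon = systematic_rotation(montage, spec.magnitude_cm, "random-choice",
                                          spec.rng_seed, labels12)
        else:
            new_mon = random_displacement(montage, spec.magnitude_cm,
                                          spec.rng_seed, labels12)
        return ref_sigma, new_mon, grid

    warped12 = emulate_template_segmentation(labels12, warp_amplitude_mm,
                                             warp_smoothness_mm, spec.rng_seed)
    if spec.segmentation_variant == "12layer_wts":
        sigma = assign_conductivities(warped12, conductivity_table)
        return sigma, montage, grid
    warped3 = merge_to_three_layers(warped12)
    sigma = assign_conductivities(warped3, conductivity_table)
    if spec.segmentation_variant == "3layer_wts":
        return sigma, montage, grid
    # 3layer_template: template electrode positions on the distorted scalp
    template_mon = project_electrodes_to_scalp(montage, warped3)
    return sigma, template_mon, grid
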