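"""File formats: NIfTI label volumes (+ JSON label sidecar), .sfp montages,
HDF5 recordings/leadfields, and a minimal EDF export."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .types import EEGRecording, ElectrodeMontage, Leadfield, TissueLabelVolume

__all__ = [
    "save_phantom", "load_phantom",
    "save_montage_sfp", "load_montage_sfp",
    "save_recording_h5", "load_recording_h5",
    "save_leadfield_h5", "load_leadfield_h5",
    "export_edf",
]


def save_phantom(phantom: TissueLabelVolume, path: str | Path) -> None:
    """NIfTI-1 int16 label image plus a ``<stem>_labels.json`` sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(phantom.labels.astype(np.int16), phantom.affine)
    img.header.set_zooms((phantom.voxel_size,) * 3)
    nib.save(img, str(path))
    sidecar = path.with_name(path.name.replace(".nii.gz", "").replace(".nii", "")
                             + "_labels.json")
    sidecar.write_text(json.dumps({str(k): v for k, v in phantom.label_dict.items()},
                                  indent=2))


def load_phantom(path: str | Path) -> TissueLabelVolume:
    path = Path(path)
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int16)
    voxel = float(img.header.get_zooms()[0])
    sidecar = path.with_name(path.name.replace(".nii.gz", "").replace(".nii", "")
                             + "_labels.json")
    label_dict = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    return TissueLabelVolume(labels, voxel, np.asarray(img.affine), label_dict)


def save_montage_sfp(montage: ElectrodeMontage, path: str | Path) -> None:
    """Columnar text: ``name x y z`` in mm; fiducials first as NAS/LPA/RPA."""
    lines = []
    if montage.fiducials:
        for name in ("NAS", "LPA", "RPA"):
            if name in montage.fiducials:
                x, y, z = montage.fiducials[name]
                lines.append(f"{name}\t{x:.4f}\t{y:.4f}\t{z:.4f}")
    for name, p in zip(montage.names, montage.positions):
        lines.append(f"{name}\t{p[0]:.4f}\t{p[1]:.4f}\t{p[2]:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_montage_sfp(path: str | Path,
                     head_center=(0.0, 0.0, 0.0)) -> ElectrodeMontage:
    names, positions = [], []
    fiducials = {}
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if len(parts) != 4:
            continue
        name, x, y, z = parts
        vec = np.array([float(x), float(y), float(z)])
        if name in ("NAS", "LPA", "RPA"):
            fiducials[name] = vec
        else:
            names.append(name)
            positions.append(vec)
    return ElectrodeMontage(names, np.array(positions),
                            head_center=np.asarray(head_center, dtype=float),
                            fiducials=fiducials or None)


def save_recording_h5(recording: EEGRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data)
        f.create_dataset("fs", data=recording.fs)
        f.create_dataset("channel_names",
                         data=np.array(recording.channel_names, dtype="S"))
        f.attrs["reference"] = recording.reference_tag


def load_recording_h5(path: str | Path) -> EEGRecording:
    with h5py.File(path, "r") as f:
        return EEGRecording(
            channel_names=[n.decode() for n in f["channel_names"][()]],
            data=f["data"][()],
            fs=float(f["fs"][()]),
            reference_tag=str(f.attrs.get("reference", "common")),
        )


def save_leadfield_h5(lf: Leadfield, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=lf.gain)
        f.create_dataset("channel_names", data=np.array(lf.channel_names, dtype="S"))
        f.create_dataset("node_positions", data=lf.node_positions)
        f.attrs["reference"] = lf.reference
        if lf.gain_unref is not None:
            f.create_dataset("gain_unref", data=lf.gain_unref)


def load_leadfield_h5(path: str | Path) -> Leadfield:
    with h5py.File(path, "r") as f:
        return Leadfield(
            gain=f["gain"][()],
            channel_names=[n.decode() for n in f["channel_names"][()]],
            node_positions=f["node_positions"][()],
            reference=str(f.attrs.get("reference", "average")),
            gain_unref=f["gain_unref"][()] if "gain_unref" in f else None,
        )


def export_edf(recording: EEGRecording, path: str | Path,
               physical_max_uv: float | None = None) -> None:
    """Minimal EDF (16-bit) export for interoperability.

    One data record per second; each channel scaled to its physical range.
    Sampling rate must be an integer number of samples per second.
    """
    fs = recording.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    data = recording.data
    n_ch, n_samp = data.shape
    n_rec = n_samp // spr
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF record (1 s)")
    data = data[:, :n_rec * spr]

    if physical_max_uv is None:
        physical_max_uv = float(max(np.abs(data).max(), 1e-6)) * 1.0001
    # the physical range is stored as ASCII in 8-char fields: round-trip the
    # printed value so the scaling matches what a reader will parse
    pmax = float(f"{physical_max_uv:.6g}"[:8])
    pmin = -pmax
    dmin, dmax = -32768, 32767
    scaled = np.clip((data - pmin) / (pmax - pmin) * (dmax - dmin) + dmin,
                     dmin, dmax)
    digital = np.rint(scaled).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    header = bytearray()
    header += pad("0", 8)                        # version
    header += pad("X X X X", 80)                 # patient id
    header += pad("Startdate X X X X", 80)       # recording id
    header += pad("01.01.00", 8)                 # start date
    header += pad("00.00.00", 8)                 # start time
    header += pad(str(256 + 256 * n_ch), 8)      # header bytes
    header += pad("", 44)                        # reserved
    header += pad(str(n_rec), 8)                 # number of records
    header += pad("1", 8)                        # record duration, s
    header += pad(str(n_ch), 4)                  # number of signals
    for name in recording.channel_names:
        header += pad(name, 16)
    header += b" " * (80 * n_ch)                 # transducer
    for _ in range(n_ch):
        header += pad("uV", 8)
    for _ in range(n_ch):
        header += pad(f"{pmin:.6g}", 8)
    for _ in range(n_ch):
        header += pad(f"{pmax:.6g}", 8)
    for _ in range(n_ch):
        header += pad(str(dmin), 8)
    for _ in range(n_ch):
        header += pad(str(dmax), 8)
    header += b" " * (80 * n_ch)                 # prefiltering
    for _ in range(n_ch):
        header += pad(str(spr), 8)
    header += b" " * (32 * n_ch)                 # reserved

    with open(path, "wb") as f:
        f.write(bytes(header))
        for r in range(n_rec):
            chunk = digital[:, r * spr:(r + 1) * spr]
            f.write(chunk.tobytes())
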