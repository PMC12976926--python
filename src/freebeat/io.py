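"""File formats: HDF5 containers, complex NIfTI pairs, CSV/JSON artifacts.

Conventions
-----------
* Acquisitions and low-rank motion models live in self-contained HDF5 files
  with a ``schema`` attribute for forward compatibility.
* Complex volumes are stored as a 4D NIfTI with two volumes (real, imag)
  along the fourth axis plus a JSON sidecar declaring the convention; binary
  masks are plain 3D uint8 NIfTI.  Voxel sizes go in the header zooms.
* Volume curves and detected cycles are CSV; summaries are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from freebeat.encoding import AcquisitionSet, CoilMaps, ReferenceImage
from freebeat.motion import LowRankMotion
from freebeat.trajectory import FrameBinning, SamplingSchedule, bin_frames
from freebeat.volumetrics import CardiacCycle, EFSummary, VolumeCurve

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# HDF5: acquisition, schedule, motion
# ---------------------------------------------------------------------------

def save_acquisition(path: str | Path, acq: AcquisitionSet,
                     voxel_size_mm=(1.0, 1.0, 1.0), seed: int | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA_VERSION
        f.attrs["tr_ms"] = acq.schedule.tr_ms
        f.attrs["matrix"] = acq.schedule.matrix
        f.attrs["golden_angle_deg"] = acq.schedule.golden_angle_deg
        f.attrs["voxel_size_mm"] = voxel_size_mm
        f.attrs["noise_sigma"] = acq.noise_sigma
        f.attrs["readouts_per_frame"] = acq.binning.readouts_per_frame
        if seed is not None:
            f.attrs["seed"] = seed
        f.create_dataset("samples", data=acq.samples.astype(np.complex64))
        f.create_dataset("ky", data=acq.schedule.readouts[:, 0])
        f.create_dataset("kz", data=acq.schedule.readouts[:, 1])
        f.create_dataset("time_ms", data=acq.timestamps_ms)


def load_acquisition(path: str | Path) -> tuple[AcquisitionSet, tuple[float, float, float]]:
    with h5py.File(path, "r") as f:
        readouts = np.stack([f["ky"][:], f["kz"][:]], axis=1).astype(np.int64)
        schedule = SamplingSchedule(
            readouts=readouts,
            matrix=tuple(int(v) for v in f.attrs["matrix"]),
            tr_ms=float(f.attrs["tr_ms"]),
            golden_angle_deg=float(f.attrs["golden_angle_deg"]),
        )
        binning = bin_frames(schedule, int(f.attrs["readouts_per_frame"]))
        acq = AcquisitionSet(
            samples=f["samples"][:].astype(np.complex128),
            schedule=schedule,
            binning=binning,
            noise_sigma=float(f.attrs["noise_sigma"]),
        )
        voxel = tuple(float(v) for v in f.attrs["voxel_size_mm"])
    return acq, voxel


def save_schedule(path: str | Path, schedule: SamplingSchedule) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA_VERSION
        f.attrs["tr_ms"] = schedule.tr_ms
        f.attrs["matrix"] = schedule.matrix
        f.attrs["golden_angle_deg"] = schedule.golden_angle_deg
        f.create_dataset("ky", data=schedule.readouts[:, 0])
        f.create_dataset("kz", data=schedule.readouts[:, 1])


def load_schedule(path: str | Path) -> SamplingSchedule:
    with h5py.File(path, "r") as f:
        readouts = np.stack([f["ky"][:], f["kz"][:]], axis=1).astype(np.int64)
        return SamplingSchedule(
            readouts=readouts,
            matrix=tuple(int(v) for v in f.attrs["matrix"]),
            tr_ms=float(f.attrs["tr_ms"]),
            golden_angle_deg=float(f.attrs["golden_angle_deg"]),
        )


def save_motion(path: str | Path, model: LowRankMotion,
                voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA_VERSION
        f.attrs["grid_shape"] = model.grid_shape
        f.attrs["full_shape"] = model.full_shape
        f.attrs["rank"] = model.rank
        f.attrs["frame_rate_hz"] = model.frame_rate_hz
        f.attrs["voxel_size_mm"] = voxel_size_mm
        f.create_dataset("Phi", data=model.Phi)
        f.create_dataset("Psi", data=model.Psi)


def load_motion(path: str | Path) -> LowRankMotion:
    with h5py.File(path, "r") as f:
        return LowRankMotion(
            Phi=f["Phi"][:],
            Psi=f["Psi"][:],
            grid_shape=tuple(int(v) for v in f.attrs["grid_shape"]),
            full_shape=tuple(int(v) for v in f.attrs["full_shape"]),
            rank=int(f.attrs["rank"]),
            frame_rate_hz=float(f.attrs["frame_rate_hz"]),
        )


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


def save_complex_nifti(path: str | Path, image: ReferenceImage) -> None:
    """Complex volume as a 4D NIfTI (real, imag along axis 3) + JSON sidecar."""
    path = Path(path)
    stacked = np.stack([image.data.real, image.data.imag], axis=-1).astype(np.float32)
    nib.save(nib.Nifti1Image(stacked, _affine(image.voxel_size_mm)), str(path))
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz
    meta = {
        "complex_convention": "volume 0 = real part, volume 1 = imaginary part",
        "voxel_size_mm": list(image.voxel_size_mm),
        "schema": SCHEMA_VERSION,
    }
    Path(str(sidecar) + ".json").write_text(json.dumps(meta, indent=2))


def load_complex_nifti(path: str | Path) -> ReferenceImage:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    data = arr[..., 0].astype(np.float64) + 1j * arr[..., 1].astype(np.float64)
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ReferenceImage(data=data, voxel_size_mm=voxel)


def save_mask_nifti(path: str | Path, mask: np.ndarray, voxel_size_mm) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), _affine(voxel_size_mm)), str(path))


def load_mask_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj).astype(np.uint8), voxel


def save_coilmaps(path: str | Path, maps: CoilMaps) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA_VERSION
        f.create_dataset("maps", data=maps.maps.astype(np.complex64))


def load_coilmaps(path: str | Path) -> CoilMaps:
    with h5py.File(path, "r") as f:
        return CoilMaps(maps=f["maps"][:].astype(np.complex128))


# ---------------------------------------------------------------------------
# CSV / JSON artifacts
# ---------------------------------------------------------------------------

def save_volume_curve_csv(path: str | Path, curve: VolumeCurve) -> None:
    header = "time_s,volume_ml"
    data = np.column_stack([curve.times_s, curve.volumes_ml])
    np.savetxt(path, data, delimiter=",", header=header, comments="")


def load_volume_curve_csv(path: str | Path) -> VolumeCurve:
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    times = data[:, 0]
    dt = np.median(np.diff(times)) if len(times) > 1 else 1.0
    return VolumeCurve(times_s=times, volumes_ml=data[:, 1], frame_rate_hz=1.0 / dt)


def save_cycles_csv(path: str | Path, cycles: list[CardiacCycle], curve: VolumeCurve) -> None:
    header = "peak_t_s,trough_t_s,edv_ml,esv_ml,ef_pct"
    rows = [
        (curve.times_s[c.peak_index], curve.times_s[c.trough_index],
         c.edv_ml, c.esv_ml, c.ef_pct)
        for c in cycles
    ]
    np.savetxt(path, np.array(rows).reshape(-1, 5), delimiter=",", header=header, comments="")


def save_summary_json(path: str | Path, summary: EFSummary, extra: dict | None = None) -> None:
    payload = {
        "mean_ef_pct": summary.mean_pct,
        "std_ef_pct": summary.std_pct,
        "std_defined": summary.std_defined,
        "n_cycles": summary.n_cycles,
        "histogram": {
            "bin_edges_pct": summary.bin_edges.tolist(),
            "counts": summary.counts.tolist(),
        },
        "schema": SCHEMA_VERSION,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def save_beat_events_csv(path: str | Path, schedule) -> None:
    """Beat-onset events (ECG-style) of a phantom beat schedule."""
    onsets = np.concatenate([[0.0], np.cumsum(schedule.intervals_s)[:-1]])
    header = "onset_s,interval_s,amplitude_mult"
    rows = np.column_stack([onsets, schedule.intervals_s, schedule.amplitude_mults])
    np.savetxt(path, rows, delimiter=",", header=header, comments="")


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def load_yaml(path: str | Path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def save_yaml(path: str | Path, payload: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(payload, f, sort_keys=True)
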