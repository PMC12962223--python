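"""Readers and writers for the toolkit's on-disk formats.

Volumetric data (masks, off-resonance in Hz, flip-angle maps in degrees)
travel as NIfTI-1; complex sensitivities as paired real/imaginary NIfTI
volumes per coil with a JSON sidecar carrying coil labels and grid
provenance. Pulse programs and Q/VOP containers travel as HDF5. All
round-trips are bit-exact for the array payloads.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .core import (
    ChannelFieldSet,
    ChannelSchedule,
    CoilLabel,
    OffResonanceMap,
    PulseProgram,
    PulseTiming,
    VoxelGrid,
)
from .sar import QMatrixSet, VOPSet

__all__ = [
    "save_volume", "load_volume", "save_grid_mask", "load_grid",
    "save_fields", "load_fields", "save_db0", "load_db0",
    "save_pulse", "load_pulse", "save_qset", "load_qset",
    "save_vops", "load_vops",
]


class SchemaError(ValueError):
    """A sidecar or container is missing a required field."""


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def save_volume(path: str | Path, grid: VoxelGrid, values: np.ndarray) -> None:
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), _affine(grid))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_grid_mask(path: str | Path, grid: VoxelGrid) -> None:
    save_volume(path, grid, grid.mask.astype(np.float64))


def load_grid(mask_path: str | Path) -> VoxelGrid:
    data, aff = load_volume(mask_path)
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return VoxelGrid(data.shape, spacing, origin, data > 0.5)


def save_db0(path: str | Path, db0: OffResonanceMap) -> None:
    save_volume(path, db0.grid, db0.values)


def load_db0(path: str | Path, grid: VoxelGrid) -> OffResonanceMap:
    data, _ = load_volume(path)
    return OffResonanceMap(grid, data)


def save_fields(directory: str | Path, fields: ChannelFieldSet) -> None:
    """Write per-coil real/imag NIfTI pairs plus a JSON sidecar and mask."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_grid_mask(d / "mask.nii", fields.grid)
    for c in range(fields.n_coils):
        save_volume(d / f"coil{c:02d}_real.nii", fields.grid, fields.sensitivities[c].real)
        save_volume(d / f"coil{c:02d}_imag.nii", fields.grid, fields.sensitivities[c].imag)
    sidecar = {
        "n_coils": fields.n_coils,
        "coil_labels": [
            {"row": l.row, "element": l.element, "azimuth_deg": l.azimuth_deg}
            for l in fields.labels
        ],
        "grid": {"shape": list(fields.grid.shape),
                 "spacing_m": list(fields.grid.spacing),
                 "origin_m": list(fields.grid.origin)},
        "units": "rad/(V*s)",
    }
    (d / "fields.json").write_text(json.dumps(sidecar, indent=1))


def load_fields(directory: str | Path) -> ChannelFieldSet:
    d = Path(directory)
    sidecar = json.loads((d / "fields.json").read_text())
    for key in ("n_coils", "coil_labels", "grid"):
        if key not in sidecar:
            raise SchemaError(f"fields.json missing required field {key!r}")
    grid = load_grid(d / "mask.nii")
    nc = int(sidecar["n_coils"])
    sens = np.empty((nc,) + grid.shape, dtype=complex)
    for c in range(nc):
        re, _ = load_volume(d / f"coil{c:02d}_real.nii")
        im, _ = load_volume(d / f"coil{c:02d}_imag.nii")
        sens[c] = re + 1j * im
    labels = []
    for entry in sidecar["coil_labels"]:
        for key in ("row", "element", "azimuth_deg"):
            if key not in entry:
                raise SchemaError(f"coil label missing required field {key!r}")
        labels.append(CoilLabel(entry["row"], int(entry["element"]),
                                float(entry["azimuth_deg"])))
    return ChannelFieldSet(grid, sens, labels)


def save_pulse(path: str | Path, pulse: PulseProgram) -> None:
    with h5py.File(str(path), "w") as f:
        f.create_dataset("amplitudes", data=pulse.amplitudes)
        f.create_dataset("k_locations", data=pulse.k_locations)
        f.create_dataset("schedule/coil_map", data=pulse.schedule.coil_map)
        if pulse.schedule.step_labels is not None:
            f.create_dataset(
                "schedule/step_labels",
                data=np.array(pulse.schedule.step_labels, dtype=h5py.string_dtype()),
            )
        t = f.create_group("timing")
        t.attrs["sub_pulse_duration_s"] = pulse.timing.sub_pulse_duration
        t.attrs["tr_s"] = pulse.timing.tr
        t.attrs["switch_gap_s"] = pulse.timing.switch_gap
        t.attrs["blip_duration_s"] = pulse.timing.blip_duration
        f.attrs["meta_json"] = json.dumps(pulse.meta)


def load_pulse(path: str | Path) -> PulseProgram:
    with h5py.File(str(path), "r") as f:
        for name in ("amplitudes", "k_locations", "schedule/coil_map", "timing"):
            if name not in f:
                raise SchemaError(f"pulse container missing {name!r}")
        labels = None
        if "schedule/step_labels" in f:
            labels = tuple(s.decode() for s in f["schedule/step_labels"][()])
        t = f["timing"].attrs
        timing = PulseTiming(float(t["sub_pulse_duration_s"]), float(t["tr_s"]),
                             float(t["switch_gap_s"]), float(t["blip_duration_s"]))
        return PulseProgram(
            f["amplitudes"][()], f["k_locations"][()], timing,
            ChannelSchedule(f["schedule/coil_map"][()], labels),
            meta=json.loads(f.attrs.get("meta_json", "{}")),
        )


def save_qset(path: str | Path, q: QMatrixSet) -> None:
    with h5py.File(str(path), "w") as f:
        g = f.create_group("Q")
        g.create_dataset("matrices", data=q.matrices)
        g.create_dataset("voxel_ids", data=np.asarray(q.voxel_ids).astype("S"))
        g.create_dataset("model_tag", data=np.asarray(q.model_tags).astype("S"))


def load_qset(path: str | Path) -> QMatrixSet:
    with h5py.File(str(path), "r") as f:
        if "Q/matrices" not in f:
            raise SchemaError("Q container missing 'Q/matrices'")
        return QMatrixSet(
            f["Q/matrices"][()],
            np.array([s.decode() for s in f["Q/voxel_ids"][()]]),
            np.array([s.decode() for s in f["Q/model_tag"][()]]),
        )


def save_vops(path: str | Path, vops: VOPSet) -> None:
    with h5py.File(str(path), "w") as f:
        g = f.create_group("VOP")
        g.create_dataset("matrices", data=vops.matrices)
        g.create_dataset("overestimation_term", data=vops.overestimation_term)
        if vops.worst_case_overestimation is not None:
            g.attrs["worst_case_overestimation"] = vops.worst_case_overestimation
        g.attrs["meta_json"] = json.dumps(vops.meta, default=str)


def load_vops(path: str | Path) -> VOPSet:
    with h5py.File(str(path), "r") as f:
        if "VOP/matrices" not in f:
            raise SchemaError("VOP container missing 'VOP/matrices'")
        g = f["VOP"]
        wc = g.attrs.get("worst_case_overestimation")
        return VOPSet(
            g["matrices"][()], g["overestimation_term"][()],
            None if wc is None else float(wc),
            json.loads(g.attrs.get("meta_json", "{}")),
        )
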