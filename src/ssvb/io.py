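"""NIfTI / YAML / JSON input-output and run manifests.

Images are NIfTI-1: 4D difference data plus a 3D binary mask in, one 3D map
per fitted parameter out (float32 on disk, float64 internally; unmasked
voxels are NaN).  Schedules and constants are YAML; manifests and ground
truth are JSON.  A manifest records the command, configuration snapshot and
seed so a run can be reproduced bit-identically on one thread.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .kinetics import AcquisitionSchedule, TissueConstants, get_schedule
from .simulate import ASLDataset
from .spatial import VoxelGrid

__all__ = [
    "read_asl_nifti",
    "write_dataset_nifti",
    "write_param_maps",
    "load_schedule",
    "save_schedule",
    "load_constants",
    "write_manifest",
]


def read_asl_nifti(path, mask_path, schedule: AcquisitionSchedule) -> ASLDataset:
    """Load a 4D difference image and 3D mask into a masked dataset.

    The 4D length must equal the schedule's timepoint count N; affine and
    orientation are carried through for write-back.
    """
    img = nib.load(str(path))
    mask_img = nib.load(str(mask_path))
    data4d = np.asarray(img.dataobj, dtype=float)
    mask = np.asarray(mask_img.dataobj) > 0
    if data4d.ndim != 4:
        raise ValueError(f"expected 4D image, got shape {data4d.shape}")
    if mask.shape != data4d.shape[:3]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image grid "
            f"{data4d.shape[:3]}"
        )
    if not np.allclose(img.affine, mask_img.affine, atol=1e-4):
        raise ValueError("image and mask affines differ")
    if data4d.shape[3] != schedule.n_timepoints:
        raise ValueError(
            f"image has {data4d.shape[3]} volumes but the schedule defines "
            f"{schedule.n_timepoints} timepoints"
        )
    grid = VoxelGrid(mask)
    return ASLDataset(
        grid=grid,
        data=data4d[mask],
        schedule=schedule,
        affine=np.asarray(img.affine),
    )


def write_dataset_nifti(dataset: ASLDataset, out_dir) -> dict:
    """Write a dataset as 4D data + mask NIfTI and a ground-truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    shape = dataset.grid.shape
    vol = np.zeros(shape + (dataset.schedule.n_timepoints,), dtype=np.float32)
    vol[dataset.grid.mask] = dataset.data
    affine = dataset.affine
    paths = {}
    nib.save(nib.Nifti1Image(vol, affine), str(out_dir / "asl_diff.nii.gz"))
    nib.save(
        nib.Nifti1Image(dataset.grid.mask.astype(np.uint8), affine),
        str(out_dir / "mask.nii.gz"),
    )
    paths["data"] = out_dir / "asl_diff.nii.gz"
    paths["mask"] = out_dir / "mask.nii.gz"
    if dataset.true_cbf is not None:
        sidecar = {
            "true_cbf": float(dataset.true_cbf[0]),
            "true_att": float(dataset.true_att[0]),
            "noise_sd": dataset.noise_sd,
            "schedule": dataset.schedule.name,
        }
        (out_dir / "ground_truth.json").write_text(
            json.dumps(sidecar, indent=2))
        paths["truth"] = out_dir / "ground_truth.json"
    return paths


def write_param_maps(fit, grid: VoxelGrid, affine: np.ndarray, out_dir) -> dict:
    """One 3D float32 NIfTI per fitted map; unmasked voxels are NaN."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    maps = {
        "cbf": fit.cbf_map,
        "att": fit.att_map,
        "cbf_sd": fit.cbf_sd_map,
        "att_sd": fit.att_sd_map,
        "noise_var": fit.noise_var_map,
    }
    paths = {}
    for name, values in maps.items():
        vol = grid.unravel(np.asarray(values, dtype=float)).astype(np.float32)
        path = out_dir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(vol, affine), str(path))
        paths[name] = path
    trace = np.asarray(fit.cost_trace, dtype=float)
    np.savetxt(out_dir / "cost_trace.csv", trace[:, None],
               delimiter=",", header="cost", comments="")
    paths["cost_trace"] = out_dir / "cost_trace.csv"
    return paths


def load_schedule(path) -> tuple[AcquisitionSchedule, TissueConstants]:
    """Read a schedule (and optional constants overrides) from YAML/JSON.

    Keys: ``label_duration`` (s), ``plds`` (list of s), ``repeats``
    (list of int, defaults to 1 per PLD), optional ``constants`` mapping
    with ``t1_tissue``/``t1_blood``/``partition_coeff``/``m0a``.  A bare
    string key ``preset`` selects a shipped schedule.
    """
    raw = yaml.safe_load(Path(path).read_text())
    constants = load_constants_from_dict(raw.get("constants") or {})
    if "preset" in raw:
        return get_schedule(raw["preset"]), constants
    plds = raw["plds"]
    schedule = AcquisitionSchedule(
        label_duration=float(raw["label_duration"]),
        plds=tuple(plds),
        repeats=tuple(raw.get("repeats", [1] * len(plds))),
        name=raw.get("name", "custom"),
    )
    return schedule, constants


def save_schedule(schedule: AcquisitionSchedule, path,
                  constants: TissueConstants | None = None) -> None:
    doc = {
        "name": schedule.name,
        "label_duration": schedule.label_duration,
        "plds": list(schedule.plds),
        "repeats": list(schedule.repeats),
    }
    if constants is not None:
        doc["constants"] = {
            "t1_tissue": constants.t1_tissue,
            "t1_blood": constants.t1_blood,
            "partition_coeff": constants.partition_coeff,
            "m0a": constants.m0a,
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_constants_from_dict(overrides: dict) -> TissueConstants:
    allowed = {"t1_tissue", "t1_blood", "partition_coeff", "m0a"}
    bad = set(overrides) - allowed
    if bad:
        raise ValueError(f"unknown constants keys: {sorted(bad)}")
    return TissueConstants(**{k: float(v) for k, v in overrides.items()})


def load_constants(path) -> TissueConstants:
    return load_constants_from_dict(yaml.safe_load(Path(path).read_text()) or {})


def write_manifest(out_dir, command: str, config: dict, seed: int | None,
                   **extra) -> Path:
    """JSON run manifest: command, config snapshot, seed, timestamps."""
    from . import __version__

    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        **extra,
    }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
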