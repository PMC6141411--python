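"""NIfTI-1 and JSON input/output.

Conventions: 4D NIfTI files carry (x, y, z, gate) for gated series and
(x, y, z, frame) for dynamic sequences; in memory the time-like axis comes
first.  Each volume file has a JSON sidecar next to it (same stem, ``.json``
extension) holding the timing information NIfTI cannot: ``cycle_ms`` and
gate count for gated data, frame starts/durations for dynamic data.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import DynamicFrameSequence, GroundTruth, default_planes
from .segmentation import GatedImageSeries

__all__ = [
    "sidecar_path",
    "read_gated_nifti",
    "write_gated_nifti",
    "read_dynamic_nifti",
    "write_dynamic_nifti",
    "write_phantom",
]


def sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def _load_4d(path):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected 4D gated series, got {data.ndim}D in {path}")
    zooms = img.header.get_zooms()[:3]
    voxel = float(zooms[0])
    if voxel <= 0:
        raise ValueError(f"non-positive voxel size in {path}")
    if not np.allclose(zooms, voxel, rtol=1e-3):
        raise ValueError(f"expected cubic voxels, got zooms {zooms} in {path}")
    # (x, y, z, t) on disk -> (t, x, y, z) in memory
    return np.moveaxis(data, -1, 0).astype(float), voxel


def _read_sidecar(path) -> dict:
    sc = sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"missing sidecar JSON {sc}")
    with open(sc) as fh:
        return json.load(fh)


def read_gated_nifti(path) -> GatedImageSeries:
    """Read a gated 4D NIfTI plus its timing sidecar."""
    data, voxel = _load_4d(path)
    meta = _read_sidecar(path)
    if "cycle_ms" not in meta:
        raise ValueError(f"sidecar of {path} lacks 'cycle_ms'")
    series = GatedImageSeries(
        intensities=np.clip(data, 0, None),
        voxel_size_mm=voxel,
        cycle_ms=float(meta["cycle_ms"]),
        orientation=meta.get("orientation", "short_axis"),
    )
    n = meta.get("n_gates")
    if n is not None and int(n) != series.n_gates:
        raise ValueError(
            f"sidecar declares {n} gates but {path} has {series.n_gates}"
        )
    return series


def write_gated_nifti(series: GatedImageSeries, path) -> None:
    affine = np.diag([series.voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(
        np.moveaxis(series.intensities, 0, -1).astype(np.float32), affine
    )
    img.header.set_zooms((series.voxel_size_mm,) * 3 + (1.0,))
    nib.save(img, str(path))
    with open(sidecar_path(path), "w") as fh:
        json.dump(
            {
                "cycle_ms": series.cycle_ms,
                "n_gates": series.n_gates,
                "orientation": series.orientation,
            },
            fh,
            indent=2,
        )


def read_dynamic_nifti(path) -> DynamicFrameSequence:
    """Read a dynamic 4D NIfTI plus its frame-timing sidecar."""
    data, voxel = _load_4d(path)
    meta = _read_sidecar(path)
    for key in ("frame_start_s", "frame_duration_s"):
        if key not in meta:
            raise ValueError(f"sidecar of {path} lacks '{key}'")
    return DynamicFrameSequence(
        data=np.clip(data, 0, None),
        start_s=np.asarray(meta["frame_start_s"], dtype=float),
        duration_s=np.asarray(meta["frame_duration_s"], dtype=float),
        voxel_size_mm=voxel,
    )


def write_dynamic_nifti(frames: DynamicFrameSequence, path) -> None:
    affine = np.diag([frames.voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.moveaxis(frames.data, 0, -1).astype(np.float32), affine)
    img.header.set_zooms((frames.voxel_size_mm,) * 3 + (1.0,))
    nib.save(img, str(path))
    with open(sidecar_path(path), "w") as fh:
        json.dump(
            {
                "frame_start_s": frames.start_s.tolist(),
                "frame_duration_s": frames.duration_s.tolist(),
            },
            fh,
            indent=2,
        )


def write_phantom(config, dynamic, gated, truth: GroundTruth, outdir) -> dict:
    """Write a rendered phantom study: volumes, planes, truth and masks.

    Returns a dict of the written paths.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gated": out / "gated.nii.gz",
        "dynamic": out / "dynamic.nii.gz",
        "planes": out / "planes.json",
        "ground_truth": out / "ground_truth.json",
        "lv_mask": out / "lv_mask.nii.gz",
        "rv_mask": out / "rv_mask.nii.gz",
    }
    write_gated_nifti(gated, paths["gated"])
    write_dynamic_nifti(dynamic, paths["dynamic"])
    default_planes(config).to_json(paths["planes"])
    payload = truth.to_dict()
    payload["config"] = json.loads(config.model_dump_json())
    with open(paths["ground_truth"], "w") as fh:
        json.dump(payload, fh, indent=2)
    affine = np.diag([config.voxel_size_mm] * 3 + [1.0])
    for key, masks in (("lv_mask", truth.lv_masks), ("rv_mask", truth.rv_masks)):
        nib.save(
            nib.Nifti1Image(np.moveaxis(masks, 0, -1).astype(np.uint8), affine),
            str(paths[key]),
        )
    return paths
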