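"""NIfTI / CSV / YAML / JSON input-output helpers.

Maps travel as NIfTI with a JSON sidecar recording units and provenance;
tables as CSV; phantom and pipeline configuration as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .fieldmap import EchoSeries, FieldMap

__all__ = ["save_map", "load_map", "save_echo_series", "load_echo_series",
           "save_labels", "load_labels", "load_yaml", "save_json"]


def _affine(voxel_size):
    a = np.eye(4)
    a[0, 0], a[1, 1], a[2, 2] = voxel_size
    return a


def save_map(path, values, *, units=None, voxel_size=(1, 1, 1), affine=None,
             sidecar: dict | None = None):
    """Write a 3D map as NIfTI plus a JSON sidecar with units/metadata."""
    path = Path(path)
    vals = np.asarray(getattr(values, "values", values), dtype=np.float64)
    img = nib.Nifti1Image(vals, affine if affine is not None else _affine(voxel_size))
    nib.save(img, path)
    meta = dict(sidecar or {})
    if units is not None:
        meta["units"] = units
    if meta:
        path.with_suffix("").with_suffix(".json").write_text(
            json.dumps(meta, indent=2, default=float))
    return path


def load_map(path, b0_strength=3.0, b0_direction=(0, 0, 1)) -> FieldMap:
    path = Path(path)
    img = nib.load(path)
    sidecar = path.with_suffix("").with_suffix(".json")
    units = "ppm"
    if sidecar.exists():
        units = json.loads(sidecar.read_text()).get("units", "ppm")
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    return FieldMap(np.asarray(img.dataobj, dtype=float), units, vs,
                    b0_strength, np.asarray(b0_direction, float), img.affine)


def save_echo_series(path_stem, series: EchoSeries):
    """Write magnitude and phase 4D NIfTI volumes plus a JSON sidecar."""
    stem = Path(path_stem)
    aff = series.affine if series.affine is not None else _affine(series.voxel_size)
    nib.save(nib.Nifti1Image(np.abs(series.data).astype(np.float64), aff),
             stem.with_name(stem.name + "_mag.nii.gz"))
    nib.save(nib.Nifti1Image(np.angle(series.data).astype(np.float64), aff),
             stem.with_name(stem.name + "_phase.nii.gz"))
    meta = {"te_list_s": [float(t) for t in series.te_list],
            "b0_strength_T": series.b0_strength,
            "b0_direction": [float(v) for v in series.b0_direction],
            "voxel_size_mm": [float(v) for v in series.voxel_size]}
    stem.with_name(stem.name + ".json").write_text(json.dumps(meta, indent=2))
    return stem


def load_echo_series(path_stem) -> EchoSeries:
    stem = Path(path_stem)
    mag = nib.load(stem.with_name(stem.name + "_mag.nii.gz"))
    pha = nib.load(stem.with_name(stem.name + "_phase.nii.gz"))
    meta = json.loads(stem.with_name(stem.name + ".json").read_text())
    data = np.asarray(mag.dataobj) * np.exp(1j * np.asarray(pha.dataobj))
    return EchoSeries(data, np.asarray(meta["te_list_s"]),
                      tuple(meta["voxel_size_mm"]), meta["b0_strength_T"],
                      np.asarray(meta["b0_direction"]), mag.affine)


def save_labels(path, labels, voxel_size=(1, 1, 1)):
    vals = np.asarray(getattr(labels, "values", labels)).astype(np.int16)
    nib.save(nib.Nifti1Image(vals, _affine(voxel_size)), path)
    table = getattr(labels, "table", None)
    if table:
        Path(path).with_suffix("").with_suffix(".json").write_text(json.dumps(
            {str(k): list(v) for k, v in table.items()}, indent=2))
    return Path(path)


def load_labels(path):
    from .masking import ROILabelMap

    img = nib.load(path)
    values = np.asarray(img.dataobj).astype(np.int32)
    sidecar = Path(path).with_suffix("").with_suffix(".json")
    table = {}
    if sidecar.exists():
        table = {int(k): tuple(v) for k, v in
                 json.loads(sidecar.read_text()).items()}
    else:
        table = {int(l): (str(l), "") for l in np.unique(values) if l != 0}
    return ROILabelMap(values, table)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_json(path, obj):
    Path(path).write_text(json.dumps(obj, indent=2, default=float))
    return Path(path)
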