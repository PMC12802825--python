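"""NIfTI and JSON serialisation.

Volumes are stored as NIfTI-1 with the affine encoding voxel spacing;
array axes are reordered between the package convention ``(t, z, y, x)``
and the NIfTI convention ``(x, y, z, t)`` on the way in and out.  Frame
times live in a JSON sidecar (``<stem>.times.json``) for explicitness;
when the sidecar is absent the header TR is used as a uniform frame
interval.  Label legends are stored in a ``<stem>.legend.json`` sidecar.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import CTPVolume, FormatError, LabelMap

__all__ = [
    "save_ctp",
    "load_ctp",
    "save_image",
    "load_image",
    "save_labelmap",
    "load_labelmap",
    "save_json",
    "load_json",
]


def _stem(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)])
    return path


def _affine(spacing_mm, origin_mm=(0.0, 0.0, 0.0)) -> np.ndarray:
    dz, dy, dx = spacing_mm
    oz, oy, ox = origin_mm
    aff = np.diag([dx, dy, dz, 1.0])
    aff[:3, 3] = [ox, oy, oz]
    return aff


def save_ctp(vol: CTPVolume, path, dtype=np.float32) -> None:
    path = Path(path)
    arr = np.asarray(vol.data, dtype=dtype).transpose(3, 2, 1, 0)  # -> (x, y, z, t)
    img = nib.Nifti1Image(arr, _affine(vol.spacing_mm, vol.origin_mm))
    img.header.set_data_dtype(dtype)
    dt = np.diff(vol.frame_times_s)
    img.header["pixdim"][4] = dt[0] if dt.size else 1.0
    nib.save(img, path)
    sidecar = _stem(path).with_suffix(".times.json")
    sidecar.write_text(json.dumps({"frame_times_s": vol.frame_times_s.tolist()}))


def load_ctp(path) -> CTPVolume:
    path = Path(path)
    img = nib.load(path)
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 4:
        raise FormatError(f"expected a 4D NIfTI, got {arr.ndim}D: {path}")
    zooms = img.header.get_zooms()
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    t = img.affine[:3, 3]
    origin = (float(t[2]), float(t[1]), float(t[0]))
    sidecar = _stem(path).with_suffix(".times.json")
    if sidecar.exists():
        times = np.asarray(json.loads(sidecar.read_text())["frame_times_s"], dtype=float)
    else:
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        times = np.arange(arr.shape[3]) * tr
    return CTPVolume(arr.transpose(3, 2, 1, 0), spacing, times, origin)


def save_image(image: np.ndarray, spacing_mm, path, dtype=np.float32) -> None:
    """Save a 3D image (mask, CBV map, temporal average) as NIfTI-1."""
    arr = np.asarray(image, dtype=dtype).transpose(2, 1, 0)
    img = nib.Nifti1Image(arr, _affine(spacing_mm))
    img.header.set_data_dtype(dtype)
    nib.save(img, Path(path))


def load_image(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(Path(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 3:
        raise FormatError(f"expected a 3D NIfTI, got {arr.ndim}D: {path}")
    zooms = img.header.get_zooms()
    return arr.transpose(2, 1, 0), (float(zooms[2]), float(zooms[1]), float(zooms[0]))


def save_labelmap(labels: LabelMap, spacing_mm, path) -> None:
    path = Path(path)
    save_image(labels.labels, spacing_mm, path, dtype=np.int16)
    legend = {str(k): v for k, v in labels.legend.items()}
    _stem(path).with_suffix(".legend.json").write_text(json.dumps(legend))


def load_labelmap(path) -> tuple[LabelMap, tuple[float, float, float]]:
    path = Path(path)
    arr, spacing = load_image(path)
    sidecar = _stem(path).with_suffix(".legend.json")
    legend = (
        {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
        if sidecar.exists()
        else {}
    )
    return LabelMap(arr.astype(np.int16), legend), spacing


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        return super().default(o)


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, cls=_NumpyEncoder, indent=1))


def load_json(path):
    return json.loads(Path(path).read_text())
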