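"""Core containers and errors shared by every pipeline stage.

Conventions
-----------
* 4D arrays are ordered ``(time, z, y, x)``; 3D arrays ``(z, y, x)``.
* Voxel spacing is ``(dz, dy, dx)`` in millimetres.
* World coordinates are ``index * spacing`` relative to the centre of
  voxel ``(0, 0, 0)``, in millimetres, ordered ``(z, y, x)``.
* Intensities are Hounsfield units (HU).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class CTPLacError(Exception):
    """Base class for all package-specific failures."""


class GridError(CTPLacError):
    """A geometric object does not fit on, or match, the voxel grid."""


class EmptyMaskError(CTPLacError):
    """Brain masking produced an empty mask (e.g. an all-air volume)."""


class EmptyReferenceError(CTPLacError):
    """The lesion reference region is empty after tissue exclusion."""


class SphereOutsideMaskError(CTPLacError):
    """A lesion sphere extends outside the brain mask."""


class NoEnhancementError(CTPLacError):
    """No voxel shows positive contrast enhancement (no AIF candidates)."""


class RoiError(CTPLacError):
    """A measurement ROI escapes its target structure or the brain mask."""


class FormatError(CTPLacError):
    """A file on disk does not have the expected layout."""


#: Canonical structure names a label legend may use.
STRUCTURE_NAMES = (
    "background",
    "skull",
    "gray_matter",
    "white_matter",
    "ventricle",
    "artery",
    "nucleus_caudate",
    "capsula_interna",
    "putamen",
    "thalamus",
    "pons",
)

#: Deep structures in which lacunar infarcts are typically found and
#: into which artificial lesions are placed.
TARGET_STRUCTURES = (
    "nucleus_caudate",
    "capsula_interna",
    "putamen",
    "thalamus",
    "pons",
)


@dataclass
class CTPVolume:
    """A 4D CT perfusion acquisition.

    Parameters
    ----------
    data:
        HU values, shape ``(n_frames, nz, ny, nx)``.
    spacing_mm:
        Voxel spacing ``(dz, dy, dx)``, strictly positive.
    frame_times_s:
        Acquisition time of each frame in seconds, strictly increasing.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    frame_times_s: np.ndarray
    #: world position (z, y, x) of the centre of voxel (0, 0, 0); nonzero
    #: for derived grids (thick slices sit 3 thin slices into the stack)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.data.ndim != 4:
            raise FormatError(f"expected 4D (t, z, y, x) data, got shape {self.data.shape}")
        if self.data.shape[0] < 3:
            raise FormatError("a CTP volume needs at least 3 timeframes")
        if self.frame_times_s.shape != (self.data.shape[0],):
            raise FormatError("frame_times_s length must equal the number of frames")
        if not np.all(np.diff(self.frame_times_s) > 0):
            raise FormatError("frame times must be strictly increasing")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise GridError(f"spacing must be three positive numbers, got {self.spacing_mm}")
        self.origin_mm = tuple(float(s) for s in self.origin_mm)
        if not np.isfinite(self.data).all():
            raise FormatError("volume contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def copy(self) -> "CTPVolume":
        return CTPVolume(
            self.data.copy(), self.spacing_mm, self.frame_times_s.copy(), self.origin_mm
        )


@dataclass
class LabelMap:
    """Integer region map on the spatial grid of an associated volume."""

    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError(f"expected 3D labels, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("labels must be an integer array")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.legend)
        if missing:
            raise FormatError(f"labels {sorted(missing)} missing from the legend")

    def mask_of(self, name: str) -> np.ndarray:
        """Boolean mask of the structure called ``name`` (may be empty)."""
        ids = [k for k, v in self.legend.items() if v == name]
        out = np.zeros(self.labels.shape, dtype=bool)
        for k in ids:
            out |= self.labels == k
        return out

    def copy(self) -> "LabelMap":
        return LabelMap(self.labels.copy(), dict(self.legend))
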