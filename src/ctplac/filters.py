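"""Edge-preserving bilateral denoising of 4D CTP data.

Two range metrics are supported, selected by ``FilterParams.mode``:

* ``tips`` (time-intensity profile similarity): the range distance between
  two voxels is the mean squared difference between their whole
  time-attenuation curves (HU^2).
* ``tavg`` (temporal-average guided): the range distance is the squared
  difference between the temporal means of the two curves (HU^2).  The
  temporal average is a static, high-SNR guide image, which makes this
  variant robust to noise at the cost of discarding temporal dynamics.

Each voxel's output TAC is the normalised weighted average over an
axis-aligned box neighbourhood of physical half-width ``3 * sigma_d``:

    w_i = exp(-dd_i^2 / (2 sigma_d^2)) * exp(-dr_i^2 / (2 sigma_r^2))

with ``dd_i`` the Euclidean distance in mm (anisotropic spacing honoured)
and ``dr_i`` the range distance in HU^2.  A single weight per voxel pair
is applied to all frames; at volume borders the weights renormalise over
the voxels that exist.  The range sigma ``sigma_r`` carries units of HU^2
to match the squared-units range distance; the alternative reading with a
linear range exponent ``exp(-dr_i / (2 sigma_r))`` is available through
``FilterParams.squared_range_exponent=False``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .core import CTPVolume, GridError

__all__ = [
    "FilterParams",
    "range_distance_tips",
    "range_distance_tavg",
    "estimate_sigma_r",
    "bilateral_filter",
    "noise2noise_pair",
]


@dataclass(frozen=True)
class FilterParams:
    """Bilateral filter parameters.

    ``sigma_d`` is the spatial kernel width in mm (2 mm is the optimum for
    lesions near the detection limit); ``sigma_r`` the range kernel width
    in HU^2; the kernel support extends exactly ``3 * sigma_d`` per axis.
    """

    sigma_d_mm: float = 2.0
    sigma_r_hu2: float = 1.0
    mode: str = "tavg"
    squared_range_exponent: bool = True

    def __post_init__(self) -> None:
        if self.sigma_d_mm <= 0:
            raise ValueError("sigma_d must be > 0")
        if self.sigma_r_hu2 <= 0:
            raise ValueError("sigma_r must be > 0")
        if self.mode not in ("tips", "tavg"):
            raise ValueError(f"unknown mode {self.mode!r}; use 'tips' or 'tavg'")

    @property
    def extent_mm(self) -> float:
        """Kernel half-width per axis (always ``3 * sigma_d``)."""
        return 3.0 * self.sigma_d_mm


def range_distance_tips(tac_a, tac_b) -> float:
    """Mean squared difference between two whole TACs (HU^2)."""
    a = np.asarray(tac_a, dtype=float)
    b = np.asarray(tac_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("TACs must have equal nonzero length")
    return float(np.mean((a - b) ** 2))


def range_distance_tavg(mean_a: float, mean_b: float) -> float:
    """Squared difference between two TAC temporal means (HU^2)."""
    return float(mean_a - mean_b) ** 2


def estimate_sigma_r(vol: CTPVolume, ventricle_mask: np.ndarray, mode: str) -> float:
    """Estimate the range sigma (HU^2) from ventricle voxels.

    ``tips``: mean over ventricle voxels of the sample temporal variance of
    each voxel's TAC.  ``tavg``: sample variance across ventricle voxels of
    their temporal-average values.  Ventricles are used because their TACs
    are enhancement-free, so their variability reflects noise alone.
    """
    ventricle_mask = np.asarray(ventricle_mask, dtype=bool)
    if ventricle_mask.shape != vol.spatial_shape:
        raise GridError("ventricle mask shape does not match the volume")
    n = int(ventricle_mask.sum())
    if n < 2:
        raise ValueError(f"need >= 2 ventricle voxels, got {n}")
    tacs = np.asarray(vol.data, dtype=np.float64)[:, ventricle_mask]  # (T, N)
    if mode == "tips":
        return float(tacs.var(axis=0, ddof=1).mean())
    if mode == "tavg":
        return float(tacs.mean(axis=0).var(ddof=1))
    raise ValueError(f"unknown mode {mode!r}")


@njit(cache=True)
def _filter_tavg(data, guide, mask, off, sw, inv_2sr2, squared, out):
    # data: (z, y, x, t) float64; guide: (z, y, x); off: (K, 3) int64;
    # sw: (K,) spatial weights; inv_2sr2 = 1 / (2 * sigma_r^2) for the
    # squared reading, 1 / (2 * sigma_r) otherwise.
    nz, ny, nx, nt = data.shape
    nk = off.shape[0]
    acc = np.empty(nt)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    for f in range(nt):
                        out[z, y, x, f] = data[z, y, x, f]
                    continue
                for f in range(nt):
                    acc[f] = 0.0
                wsum = 0.0
                g0 = guide[z, y, x]
                for k in range(nk):
                    z2 = z + off[k, 0]
                    y2 = y + off[k, 1]
                    x2 = x + off[k, 2]
                    if z2 < 0 or z2 >= nz or y2 < 0 or y2 >= ny or x2 < 0 or x2 >= nx:
                        continue
                    dg = g0 - guide[z2, y2, x2]
                    dr = dg * dg
                    if squared:
                        w = sw[k] * np.exp(-(dr * dr) * inv_2sr2)
                    else:
                        w = sw[k] * np.exp(-dr * inv_2sr2)
                    wsum += w
                    for f in range(nt):
                        acc[f] += w * data[z2, y2, x2, f]
                for f in range(nt):
                    out[z, y, x, f] = acc[f] / wsum


@njit(cache=True)
def _filter_tips(data, mask, off, sw, inv_2sr2, squared, out):
    nz, ny, nx, nt = data.shape
    nk = off.shape[0]
    acc = np.empty(nt)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    for f in range(nt):
                        out[z, y, x, f] = data[z, y, x, f]
                    continue
                for f in range(nt):
                    acc[f] = 0.0
                wsum = 0.0
                for k in range(nk):
                    z2 = z + off[k, 0]
                    y2 = y + off[k, 1]
                    x2 = x + off[k, 2]
                    if z2 < 0 or z2 >= nz or y2 < 0 or y2 >= ny or x2 < 0 or x2 >= nx:
                        continue
                    msd = 0.0
                    for f in range(nt):
                        d = data[z, y, x, f] - data[z2, y2, x2, f]
                        msd += d * d
                    dr = msd / nt
                    if squared:
                        w = sw[k] * np.exp(-(dr * dr) * inv_2sr2)
                    else:
                        w = sw[k] * np.exp(-dr * inv_2sr2)
                    wsum += w
                    for f in range(nt):
                        acc[f] += w * data[z2, y2, x2, f]
                for f in range(nt):
                    out[z, y, x, f] = acc[f] / wsum


def _kernel_offsets(params: FilterParams, spacing_mm):
    """Box-kernel offsets and their spatial Gaussian weights.

    The box is truncated at ``3 * sigma_d`` physical mm per axis,
    converted to voxel radii by ``ceil``; weights use the Euclidean
    distance in mm.
    """
    radii = [int(np.ceil(params.extent_mm / s)) for s in spacing_mm]
    oz, oy, ox = np.meshgrid(
        np.arange(-radii[0], radii[0] + 1),
        np.arange(-radii[1], radii[1] + 1),
        np.arange(-radii[2], radii[2] + 1),
        indexing="ij",
    )
    off = np.stack([oz.ravel(), oy.ravel(), ox.ravel()], axis=1).astype(np.int64)
    d2 = (
        (off[:, 0] * spacing_mm[0]) ** 2
        + (off[:, 1] * spacing_mm[1]) ** 2
        + (off[:, 2] * spacing_mm[2]) ** 2
    )
    sw = np.exp(-d2 / (2.0 * params.sigma_d_mm**2))
    return off, sw


def bilateral_filter(
    vol: CTPVolume,
    params: FilterParams,
    mask: np.ndarray | None = None,
) -> CTPVolume:
    """Bilateral-filter a 4D volume; returns a new float64 volume.

    When ``mask`` is given, only in-mask voxels are filtered (out-of-mask
    voxels pass through unchanged); neighbourhood voxels are not masked,
    since the range kernel already suppresses dissimilar tissue such as
    skull.  In ``tavg`` mode the guide image is the temporal average of
    ``vol`` itself; in ``tips`` mode the full 4D data serve as their own
    guide.
    """
    if mask is None:
        mask = np.ones(vol.spatial_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.spatial_shape:
        raise GridError("mask shape does not match the volume")

    data = np.ascontiguousarray(
        np.asarray(vol.data, dtype=np.float64).transpose(1, 2, 3, 0)
    )
    off, sw = _kernel_offsets(params, vol.spacing_mm)
    if params.squared_range_exponent:
        inv = 1.0 / (2.0 * params.sigma_r_hu2**2)
    else:
        inv = 1.0 / (2.0 * params.sigma_r_hu2)
    out = np.empty_like(data)
    if params.mode == "tavg":
        guide = data.mean(axis=3)
        _filter_tavg(data, guide, mask, off, sw, inv, params.squared_range_exponent, out)
    else:
        _filter_tips(data, mask, off, sw, inv, params.squared_range_exponent, out)
    return CTPVolume(
        out.transpose(3, 0, 1, 2).copy(),
        vol.spacing_mm,
        vol.frame_times_s.copy(),
        vol.origin_mm,
    )


def noise2noise_pair(
    vol: CTPVolume,
    t: int,
    early1: int,
    early2: int,
    bolus_arrival_index: int = 2,
):
    """Construct one self-supervised denoising training pair.

    The network input is ``(frame(t), frame(early1))``; the target is an
    independent noise realisation of the enhancement at ``t``, built by
    averaging the neighbouring frames and subtracting a different early
    (pre-bolus) frame:

        target = (frame(t-1) + frame(t+1)) / 2 - frame(early2)

    No model training is performed here; this realises the data contract
    only.
    """
    nt = vol.n_frames
    if not 0 < t < nt - 1:
        raise ValueError(f"t={t} must be strictly inside the sequence (0, {nt - 1})")
    if early1 == early2:
        raise ValueError("early1 and early2 must differ")
    for e in (early1, early2):
        if not 0 <= e < bolus_arrival_index:
            raise ValueError(f"early frame {e} is not pre-bolus (< {bolus_arrival_index})")
    data = np.asarray(vol.data, dtype=np.float64)
    approximation = (data[t - 1] + data[t + 1]) / 2.0
    target = approximation - data[early2]
    return (data[t].copy(), data[early1].copy()), target
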