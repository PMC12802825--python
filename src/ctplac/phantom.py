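"""Synthetic 4D CT perfusion head phantom.

The phantom emulates the structure of a thin-slice (0.7 mm) low-dose CTP
acquisition of the deep brain: a skull ring around gray- and white-matter
compartments, CSF-filled ventricles, the deep gray nuclei in which lacunar
infarcts typically occur (caudate nucleus, internal capsule, putamen,
thalamus, pons), and a small arterial voxel cluster that carries the
arterial input function.  Every voxel's time-attenuation curve (TAC) is

    TAC(t) = baseline HU + scale * AIF(t) + noise,

where the AIF is a gamma-variate bolus curve, ``scale`` is the structure's
relative blood volume, and the noise is i.i.d. zero-mean Gaussian per
voxel-frame.  Ground truth (AIF, noise level, per-structure blood volume)
is returned alongside the image so downstream stages can be validated
without clinical data.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gamma as _gamma_fn

from .core import (
    CTPVolume,
    GridError,
    LabelMap,
    STRUCTURE_NAMES,
)

__all__ = [
    "EnhancementModel",
    "PhantomConfig",
    "PhantomTruth",
    "gamma_variate",
    "gamma_variate_auc",
    "generate_phantom",
    "mirror_case",
]

#: Fixed label ids used by the generator.
LABEL_IDS = {name: i for i, name in enumerate(STRUCTURE_NAMES)}
LEGEND = {i: name for name, i in LABEL_IDS.items() if name != "background"}


@dataclass(frozen=True)
class EnhancementModel:
    """Gamma-variate contrast-enhancement model.

    The bolus curve is the peak-normalised gamma variate

        g(t) = A * ((t - t0) / (alpha * beta))**alpha
                 * exp(alpha - (t - t0) / beta)        for t > t0,
        g(t) = 0                                       otherwise,

    which reaches its maximum ``A`` at ``t = t0 + alpha * beta``.

    Parameters
    ----------
    amplitude_hu:
        Peak enhancement ``A`` in HU (arterial blood).
    t0_s:
        Bolus arrival time in seconds.
    alpha:
        Dimensionless shape parameter (> 0).
    beta_s:
        Time scale in seconds (> 0).
    """

    amplitude_hu: float = 250.0
    t0_s: float = 6.0
    alpha: float = 2.5
    beta_s: float = 2.0

    def __post_init__(self) -> None:
        if self.amplitude_hu < 0:
            raise ValueError("amplitude must be >= 0")
        if self.alpha <= 0 or self.beta_s <= 0:
            raise ValueError("alpha and beta must be > 0")


def gamma_variate(model: EnhancementModel, t) -> np.ndarray:
    """Evaluate the gamma-variate enhancement at times ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    dt = t - model.t0_s
    out = np.zeros(t.shape)
    pos = dt > 0
    x = dt[pos] / (model.alpha * model.beta_s)
    out[pos] = model.amplitude_hu * x**model.alpha * np.exp(model.alpha - dt[pos] / model.beta_s)
    return out if out.shape else float(out)


def gamma_variate_auc(model: EnhancementModel) -> float:
    """Closed-form area under the gamma variate over ``t in (t0, inf)``.

    Equals ``A * exp(alpha) * beta * alpha**(-alpha) * Gamma(alpha + 1)``.
    """
    a, b = model.alpha, model.beta_s
    return float(model.amplitude_hu * np.exp(a) * b * a ** (-a) * _gamma_fn(a + 1.0))


# Baseline HU per structure: textbook soft-tissue values; only the relative
# contrast matters downstream.
DEFAULT_BASELINES_HU = {
    "background": -1000.0,
    "skull": 1000.0,
    "gray_matter": 38.0,
    "white_matter": 30.0,
    "ventricle": 4.0,
    "artery": 45.0,
    "nucleus_caudate": 40.0,
    "capsula_interna": 32.0,
    "putamen": 40.0,
    "thalamus": 39.0,
    "pons": 36.0,
}

# Relative blood volume per structure (dimensionless fraction of the AIF).
# Gray matter ~4 mL/100 g and white matter ~2 mL/100 g for a brain density
# of 1.04 g/mL; the artery carries the unscaled AIF.
DEFAULT_SCALES = {
    "background": 0.0,
    "skull": 0.0,
    "gray_matter": 0.04,
    "white_matter": 0.02,
    "ventricle": 0.0,
    "artery": 1.0,
    "nucleus_caudate": 0.04,
    "capsula_interna": 0.02,
    "putamen": 0.04,
    "thalamus": 0.04,
    "pons": 0.03,
}


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, timing and noise of the synthetic acquisition.

    The default grid is a 28-slice slab at the native thin-slice spacing of
    0.7 mm covering the deep gray nuclei, with 1 mm in-plane sampling on an
    84 x 84 matrix: the smallest slab that holds every target structure, a
    10 mm lesion together with its 5 mm-radius reference sphere anywhere
    within a structure, and the 25-voxel noise ROI inside a thalamus.  16
    frames 2 s apart span a 30 s bolus passage.  The default noise level
    of 10 HU per thin-slice voxel-frame reflects a low-dose (120 kVp /
    35 mAs) acquisition; thick slices derived by 7-slice averaging inherit
    ``10/sqrt(7)`` HU.
    """

    shape: tuple[int, int, int, int] = (16, 28, 84, 84)
    spacing_mm: tuple[float, float, float] = (0.7, 1.0, 1.0)
    frame_interval_s: float = 2.0
    noise_sigma_hu: float = 10.0
    model: EnhancementModel = field(default_factory=EnhancementModel)
    baselines_hu: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES_HU))
    scales: dict = field(default_factory=lambda: dict(DEFAULT_SCALES))

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.shape[0]) * self.frame_interval_s

    @property
    def bolus_arrival_index(self) -> int:
        """Index of the first frame at or after bolus arrival."""
        return int(np.searchsorted(self.frame_times_s, self.model.t0_s))


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    aif_curve: np.ndarray  # enhancement HU per frame (the unscaled AIF)
    noise_sigma_hu: float
    structure_scales: dict[str, float]  # true relative blood volume
    baselines_hu: dict[str, float]
    model: EnhancementModel
    bolus_arrival_index: int

    def expected_cbv(self, brain_density_g_ml: float = 1.04) -> dict[str, float]:
        """True CBV in mL/100 g implied by each structure's blood fraction."""
        return {
            name: 100.0 * s / brain_density_g_ml
            for name, s in self.structure_scales.items()
        }


def _ellipsoid(zz, yy, xx, center, semi) -> np.ndarray:
    cz, cy, cx = center
    sz, sy, sx = semi
    return (
        ((zz - cz) / sz) ** 2 + ((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2
    ) <= 1.0


def _paint_labels(spatial_shape, spacing_mm) -> np.ndarray:
    """Paint the anatomical label map with axis-aligned ellipsoids.

    Later structures overwrite earlier ones; placements are chosen so that
    overlaps are marginal.  Raises :class:`GridError` if any structure ends
    up without voxels.
    """
    nz, ny, nx = spatial_shape
    dz, dy, dx = spacing_mm
    z = np.arange(nz) * dz
    y = np.arange(ny) * dy
    x = np.arange(nx) * dx
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    zc = (nz - 1) * dz / 2.0
    yc = (ny - 1) * dy / 2.0
    xc = (nx - 1) * dx / 2.0

    half = min(yc, xc)  # in-plane physical half-extent
    skull_outer = half - 3.0
    brain_r = half - 7.0
    if brain_r <= 20.0:
        raise GridError("grid too small: in-plane brain radius below 20 mm")

    r_inplane = np.sqrt((yy - yc) ** 2 + (xx - xc) ** 2)
    labels = np.zeros(spatial_shape, dtype=np.int16)

    def paint(name, mask):
        labels[mask] = LABEL_IDS[name]

    paint("skull", (r_inplane >= brain_r) & (r_inplane < skull_outer))
    paint("gray_matter", r_inplane < brain_r)
    # Central white matter; deep structures are embedded in or around it.
    paint("white_matter", _ellipsoid(zz, yy, xx, (zc, yc, xc), (12, 30, 34)))
    for sx in (-8.0, 8.0):
        paint("ventricle", _ellipsoid(zz, yy, xx, (zc, yc - 7.5, xc + sx), (6, 6, 5)))
    for sx in (-16.0, 16.0):
        paint("thalamus", _ellipsoid(zz, yy, xx, (zc, yc + 10.5, xc + sx), (8, 14, 14)))
    for sx in (-12.0, 12.0):
        paint("nucleus_caudate", _ellipsoid(zz, yy, xx, (zc, yc - 11.5, xc + sx), (4.5, 4.5, 4.5)))
    for sx in (-26.0, 26.0):
        paint("putamen", _ellipsoid(zz, yy, xx, (zc, yc - 4.0, xc + sx), (7, 5, 4)))
    for sx in (-20.0, 20.0):
        paint("capsula_interna", _ellipsoid(zz, yy, xx, (zc, yc - 7.5, xc + sx), (5, 4, 3)))
    paint("pons", _ellipsoid(zz, yy, xx, (zc, yc + 25.5, xc), (9, 8, 7)))
    # Single artery: a small off-centre cylinder through all slices.  The
    # lateral offset deliberately breaks left-right symmetry.
    artery = np.sqrt((yy - (yc - 23.5)) ** 2 + (xx - (xc + 6.0)) ** 2) <= 2.0
    paint("artery", artery)

    for name, lid in LABEL_IDS.items():
        if name == "background":
            continue
        if not (labels == lid).any():
            raise GridError(f"grid too small to contain structure '{name}'")
    return labels


def structure_centers_mm(
    labels: LabelMap, spacing_mm: tuple[float, float, float]
) -> dict[str, list[tuple[float, float, float]]]:
    """World-mm centroid of each connected component of each structure.

    Used to pick lesion insertion sites; bilateral structures yield one
    centre per side, ordered by descending component size.
    """
    from scipy import ndimage

    out: dict[str, list[tuple[float, float, float]]] = {}
    sp = np.asarray(spacing_mm)
    for name in set(labels.legend.values()):
        mask = labels.mask_of(name)
        if not mask.any():
            continue
        comp, n = ndimage.label(mask, structure=np.ones((3, 3, 3), bool))
        sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1))
        order = np.argsort(sizes)[::-1] + 1
        centers = ndimage.center_of_mass(mask, comp, index=order)
        out[name] = [tuple(np.asarray(c) * sp) for c in centers]
    return out


def generate_phantom(
    config: PhantomConfig | None = None, seed: int = 0
) -> tuple[CTPVolume, LabelMap, PhantomTruth]:
    """Generate a seeded synthetic CTP volume with labels and ground truth.

    Deterministic for a fixed ``(config, seed)`` pair.
    """
    cfg = config or PhantomConfig()
    if any(s <= 0 for s in cfg.spacing_mm):
        raise GridError(f"spacing must be positive, got {cfg.spacing_mm}")
    if cfg.noise_sigma_hu < 0:
        raise ValueError("noise sigma must be >= 0")
    n_t = cfg.shape[0]
    spatial = cfg.shape[1:]
    labels = _paint_labels(spatial, cfg.spacing_mm)

    t = cfg.frame_times_s
    aif = gamma_variate(cfg.model, t)

    base_lut = np.zeros(max(LABEL_IDS.values()) + 1)
    scale_lut = np.zeros_like(base_lut)
    for name, lid in LABEL_IDS.items():
        base_lut[lid] = cfg.baselines_hu[name]
        scale_lut[lid] = cfg.scales[name]
        if cfg.scales[name] < 0:
            raise ValueError(f"negative blood-volume scale for '{name}'")

    base = base_lut[labels]
    scale = scale_lut[labels]
    clean = base[None] + scale[None] * aif[:, None, None, None]

    rng = np.random.default_rng(seed)
    data = clean + rng.normal(0.0, cfg.noise_sigma_hu, size=(n_t, *spatial))
    vol = CTPVolume(data, cfg.spacing_mm, t)
    label_map = LabelMap(labels, dict(LEGEND))
    truth = PhantomTruth(
        aif_curve=aif,
        noise_sigma_hu=cfg.noise_sigma_hu,
        structure_scales=dict(cfg.scales),
        baselines_hu=dict(cfg.baselines_hu),
        model=cfg.model,
        bolus_arrival_index=cfg.bolus_arrival_index,
    )
    return vol, label_map, truth


def noiseless(config: PhantomConfig | None = None) -> PhantomConfig:
    """A copy of ``config`` with the voxel noise switched off."""
    cfg = config or PhantomConfig()
    return replace(cfg, noise_sigma_hu=0.0)


def mirror_case(vol: CTPVolume, labels: LabelMap) -> tuple[CTPVolume, LabelMap]:
    """Left-right mirror (flip of the x axis) of a volume and its labels.

    An involution: applying it twice returns the originals.
    """
    mvol = CTPVolume(
        vol.data[..., ::-1].copy(), vol.spacing_mm, vol.frame_times_s.copy(), vol.origin_mm
    )
    mlab = LabelMap(labels.labels[..., ::-1].copy(), dict(labels.legend))
    return mvol, mlab
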