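"""Artificial lacunar infarct (ALI) insertion and test-set design.

An ALI is created inside an existing acquisition by *enhancement-curve
subtraction*: the mean contrast-enhancement curve of a 5 mm-radius
reference sphere around the lesion centre is subtracted from every voxel
of the lesion sphere (diameter 5, 7 or 10 mm), removing the iodine signal
while keeping the background CT intensity and the native noise texture.
Voxels whose temporal-average intensity deviates more than two standard
deviations from the reference-region mean are treated as different tissue:
they contribute neither to the reference curve nor are they modified.

The test-set builder reproduces the observer-study design: 50 cases made
of 10 lesion-free controls plus 40 lesions split 10/20/10 over diameters
5/7/10 mm, spread across the five deep target structures, with optional
left-right mirroring per case.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    CTPVolume,
    EmptyReferenceError,
    GridError,
    SphereOutsideMaskError,
    TARGET_STRUCTURES,
)

__all__ = [
    "ALISpec",
    "ALIRecord",
    "TestSetConfig",
    "TestCase",
    "TestSetDesign",
    "REFERENCE_RADIUS_MM",
    "sphere_voxels",
    "insert_ali",
    "build_test_set",
]

#: Radius of the reference sphere whose mean enhancement curve is removed.
REFERENCE_RADIUS_MM = 5.0

#: Observer-study diameter split: diameter (mm) -> number of lesions.
DEFAULT_DIAMETER_SPLIT = {5.0: 10, 7.0: 20, 10.0: 10}


@dataclass(frozen=True)
class ALISpec:
    """Prescription of one spherical artificial lacunar infarct."""

    center_mm: tuple[float, float, float]  # world (z, y, x)
    diameter_mm: float
    structure: str | None = None

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("diameter must be positive")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


@dataclass
class ALIRecord:
    """Realised record of one inserted lesion.

    ``included`` / ``excluded`` partition the voxels of the lesion sphere:
    excluded voxels failed the 2-SD different-tissue rule and were left
    unmodified.  ``subtracted_curve`` is the enhancement curve (HU per
    frame) removed from every included voxel.
    """

    spec: ALISpec
    included: np.ndarray  # (N, 3) int voxel indices
    excluded: np.ndarray  # (M, 3) int voxel indices
    subtracted_curve: np.ndarray  # (n_frames,) HU
    reference_voxel_count: int = 0


def sphere_voxels(
    center_mm,
    radius_mm: float,
    spatial_shape,
    spacing_mm,
    origin_mm=(0.0, 0.0, 0.0),
) -> np.ndarray:
    """Voxels whose physical centres lie within ``radius_mm`` of a point.

    Respects anisotropic spacing; returns an ``(N, 3)`` array of ``(z, y,
    x)`` indices.  Raises :class:`GridError` if the sphere extends beyond
    the physical grid bounds (voxel extents, i.e. half a voxel beyond the
    outermost centres).
    """
    center = np.asarray(center_mm, dtype=float)
    sp = np.asarray(spacing_mm, dtype=float)
    origin = np.asarray(origin_mm, dtype=float)
    shape = np.asarray(spatial_shape, dtype=int)
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    lo = origin - sp / 2.0
    hi = origin + (shape - 1) * sp + sp / 2.0
    if np.any(center - radius_mm < lo) or np.any(center + radius_mm > hi):
        raise GridError(
            f"sphere (center {tuple(center)}, r={radius_mm} mm) exceeds grid bounds"
        )
    rel = center - origin
    lo_idx = np.maximum(np.ceil((rel - radius_mm) / sp).astype(int), 0)
    hi_idx = np.minimum(np.floor((rel + radius_mm) / sp).astype(int), shape - 1)
    axes = [np.arange(lo_idx[i], hi_idx[i] + 1) for i in range(3)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    d2 = (
        (zz * sp[0] - rel[0]) ** 2
        + (yy * sp[1] - rel[1]) ** 2
        + (xx * sp[2] - rel[2]) ** 2
    )
    keep = d2 <= radius_mm**2
    return np.stack([zz[keep], yy[keep], xx[keep]], axis=1)


def insert_ali(
    vol: CTPVolume,
    spec: ALISpec,
    mask: np.ndarray,
    bolus_arrival_index: int = 2,
    reference_radius_mm: float = REFERENCE_RADIUS_MM,
) -> tuple[CTPVolume, ALIRecord]:
    """Insert one artificial lacunar infarct; the input is left untouched.

    Procedure:

    1. The reference region is every voxel within ``reference_radius_mm``
       of the centre that lies inside the brain mask.
    2. Reference voxels whose temporal average deviates more than two
       sample standard deviations from the region mean are excluded (one
       pass).
    3. The subtracted curve is the per-frame mean over the remaining
       reference voxels, re-baselined to zero over the pre-bolus frames
       (frames strictly before ``bolus_arrival_index``).
    4. The curve is subtracted from every frame of every lesion-sphere
       voxel that passed the 2-SD rule; failing voxels are recorded as
       excluded and left unmodified.
    """
    if bolus_arrival_index < 1 or bolus_arrival_index >= vol.n_frames:
        raise ValueError("bolus_arrival_index must leave >= 1 pre-bolus frame")
    ref_idx = sphere_voxels(
        spec.center_mm, reference_radius_mm, vol.spatial_shape, vol.spacing_mm, vol.origin_mm
    )
    ali_idx = sphere_voxels(
        spec.center_mm, spec.radius_mm, vol.spatial_shape, vol.spacing_mm, vol.origin_mm
    )
    in_mask = mask[ali_idx[:, 0], ali_idx[:, 1], ali_idx[:, 2]]
    if not in_mask.all():
        raise SphereOutsideMaskError(
            f"{int((~in_mask).sum())} lesion voxels fall outside the brain mask"
        )
    ref_in_mask = mask[ref_idx[:, 0], ref_idx[:, 1], ref_idx[:, 2]]
    ref_idx = ref_idx[ref_in_mask]
    if ref_idx.shape[0] < 2:
        raise EmptyReferenceError("reference region has fewer than 2 in-mask voxels")

    data = np.asarray(vol.data, dtype=np.float64)
    ref_tacs = data[:, ref_idx[:, 0], ref_idx[:, 1], ref_idx[:, 2]]  # (T, Nref)
    tavg = ref_tacs.mean(axis=0)
    m = tavg.mean()
    sd = tavg.std(ddof=1)
    keep_ref = np.abs(tavg - m) <= 2.0 * sd
    if not keep_ref.any():
        raise EmptyReferenceError("reference region empty after 2-SD exclusion")

    curve = ref_tacs[:, keep_ref].mean(axis=1)
    curve = curve - curve[:bolus_arrival_index].mean()

    # Apply the same 2-SD rule to the lesion voxels (a subset of the
    # reference region whenever the lesion radius <= reference radius).
    ali_tavg = data[:, ali_idx[:, 0], ali_idx[:, 1], ali_idx[:, 2]].mean(axis=0)
    keep_ali = np.abs(ali_tavg - m) <= 2.0 * sd
    included = ali_idx[keep_ali]
    excluded = ali_idx[~keep_ali]

    out = data.copy()
    out[:, included[:, 0], included[:, 1], included[:, 2]] -= curve[:, None]
    new_vol = CTPVolume(out, vol.spacing_mm, vol.frame_times_s.copy(), vol.origin_mm)
    record = ALIRecord(
        spec=spec,
        included=included,
        excluded=excluded,
        subtracted_curve=curve,
        reference_voxel_count=int(keep_ref.sum()),
    )
    return new_vol, record


@dataclass(frozen=True)
class TestSetConfig:
    """Observer-study design: controls plus a lesion-diameter split."""

    n_controls: int = 10
    diameter_split: tuple = tuple(sorted(DEFAULT_DIAMETER_SPLIT.items()))
    structures: tuple = TARGET_STRUCTURES
    mirror: bool = True

    @property
    def n_alis(self) -> int:
        return sum(n for _, n in self.diameter_split)

    @property
    def n_cases(self) -> int:
        return self.n_controls + self.n_alis


@dataclass
class TestCase:
    """One observer-study case: a source volume, optionally with a lesion."""

    case_id: str
    source_id: str
    spec: ALISpec | None = None
    mirror: bool = False

    @property
    def is_control(self) -> bool:
        return self.spec is None


@dataclass
class TestSetDesign:
    cases: list[TestCase] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cases)

    @property
    def controls(self) -> list[TestCase]:
        return [c for c in self.cases if c.is_control]

    def diameter_count(self, diameter_mm: float) -> int:
        return sum(
            1
            for c in self.cases
            if c.spec is not None and c.spec.diameter_mm == diameter_mm
        )


def build_test_set(
    source_ids,
    config: TestSetConfig | None = None,
    seed: int = 0,
    sites=None,
) -> TestSetDesign:
    """Build the observer-study case list; deterministic for a fixed seed.

    Parameters
    ----------
    source_ids:
        Identifiers of the available source acquisitions.
    config:
        Controls and diameter split; the default reproduces the 50-case
        design (10 controls, 10 x 5 mm, 20 x 7 mm, 10 x 10 mm).
    seed:
        Seeds slot shuffling, diameter assignment and mirroring.
    sites:
        Optional ``{source_id: {structure: [(z, y, x) mm, ...]}}`` lookup
        of candidate lesion centres.  When omitted, lesion centres are
        left as ``None``-free placeholders at ``(nan, nan, nan)`` to be
        resolved against a concrete volume later.

    Raises
    ------
    ValueError
        If the requested lesions exceed the available unique
        ``(source, structure)`` slots.
    """
    cfg = config or TestSetConfig()
    source_ids = list(source_ids)
    rng = np.random.default_rng(seed)

    structures = list(cfg.structures)
    n_ali = cfg.n_alis
    n_slots = len(source_ids) * len(structures)
    if n_ali > n_slots:
        raise ValueError(
            f"{n_ali} lesions requested but only {n_slots} unique "
            "(source, structure) slots available"
        )

    # Spread lesions as evenly as possible over the target structures,
    # drawing sources without repeating a (source, structure) pair.
    per_struct = [n_ali // len(structures)] * len(structures)
    for i in range(n_ali % len(structures)):
        per_struct[i] += 1
    slots: list[tuple[str, str]] = []
    for structure, count in zip(structures, per_struct):
        if count > len(source_ids):
            raise ValueError(
                f"structure '{structure}' needs {count} distinct sources, "
                f"only {len(source_ids)} available"
            )
        chosen = rng.permutation(len(source_ids))[:count]
        slots.extend((source_ids[j], structure) for j in chosen)

    diameters: list[float] = []
    for d, n in cfg.diameter_split:
        diameters.extend([float(d)] * n)
    diameters = list(rng.permutation(diameters))

    cases: list[TestCase] = []
    for (src, structure), d in zip(slots, diameters):
        center = (float("nan"),) * 3
        if sites is not None:
            options = sites[src][structure]
            center = tuple(options[rng.integers(len(options))])
        cases.append(
            TestCase(
                case_id="",
                source_id=src,
                spec=ALISpec(center_mm=center, diameter_mm=d, structure=structure),
                mirror=bool(cfg.mirror and rng.integers(2)),
            )
        )

    n_ctrl_sources = min(cfg.n_controls, len(source_ids))
    ctrl_sources = [
        source_ids[j] for j in rng.permutation(len(source_ids))[:n_ctrl_sources]
    ]
    while len(ctrl_sources) < cfg.n_controls:
        ctrl_sources.append(source_ids[int(rng.integers(len(source_ids)))])
    for src in ctrl_sources:
        cases.append(
            TestCase(
                case_id="",
                source_id=src,
                spec=None,
                mirror=bool(cfg.mirror and rng.integers(2)),
            )
        )

    order = rng.permutation(len(cases))
    cases = [cases[i] for i in order]
    for i, c in enumerate(cases):
        c.case_id = f"case_{i:03d}"
    return TestSetDesign(cases=cases)
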