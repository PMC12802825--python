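"""End-to-end orchestration: phantom -> lesion -> filter grid -> CBV -> CNR.

``run_pipeline`` evaluates every requested (range-metric mode, slice
thickness) combination on a set of seeded phantoms, each carrying one
inserted artificial lacunar infarct, and returns per-case and summary
contrast / noise / CNR tables plus a provenance record.  A rerun with the
same configuration and seed is identical.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ali import ALISpec, insert_ali, sphere_voxels
from .core import TARGET_STRUCTURES, CTPLacError
from .evaluate import (
    NOISE_ROI_DIAMETER_VOX,
    compute_cnr,
    measure_contrast,
    measure_noise,
    thalamus_roi,
)
from .filters import FilterParams, bilateral_filter, estimate_sigma_r
from .perfusion import compute_cbv, extract_aif
from .phantom import PhantomConfig, generate_phantom, structure_centers_mm
from .preprocess import brain_mask, make_thick_slices, temporal_average, thick_mask

__all__ = ["PipelineConfig", "run_pipeline", "child_seeds"]

#: Lesion diameter cycle matching the 10:20:10 split over 5/7/10 mm.
DIAMETER_CYCLE_MM = (7.0, 5.0, 7.0, 10.0)


def child_seeds(root_seed: int, n: int) -> list[int]:
    """Deterministic per-stage child seeds derived from one root seed."""
    state = np.random.SeedSequence(root_seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


@dataclass(frozen=True)
class PipelineConfig:
    """Full study configuration: phantom, lesions, filter grid, evaluation."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    n_phantoms: int = 20
    modes: tuple = ("tavg", "tips")
    thicknesses: tuple = ("thin", "thick")
    sigma_d_mm: float = 2.0
    roi_diameter_vox: int = NOISE_ROI_DIAMETER_VOX
    seed: int = 0

    def __post_init__(self) -> None:
        combos = [(m, t) for m in self.modes for t in self.thicknesses]
        if len(combos) != len(set(combos)):
            raise ValueError("duplicate mode/thickness combination")
        for m in self.modes:
            if m not in ("tavg", "tips"):
                raise ValueError(f"unknown mode {m!r}")
        for t in self.thicknesses:
            if t not in ("thin", "thick"):
                raise ValueError(f"unknown thickness {t!r}")


def _stage(name: str, case: str):
    """Context that tags stage failures with stage name and case id."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise CTPLacError(f"stage '{name}' failed for case '{case}': {exc}") from exc
            return False

    return _Ctx()


def _process_case(cfg: PipelineConfig, index: int, seed: int) -> list[dict]:
    case = f"case_{index:03d}"
    with _stage("phantom", case):
        vol, labels, truth = generate_phantom(cfg.phantom, seed=seed)
        bolus = truth.bolus_arrival_index
    with _stage("preprocess", case):
        tavg = temporal_average(vol)
        mask = brain_mask(tavg)
    with _stage("insert_ali", case):
        rng = np.random.default_rng(seed)
        structure = TARGET_STRUCTURES[index % len(TARGET_STRUCTURES)]
        diameter = DIAMETER_CYCLE_MM[index % len(DIAMETER_CYCLE_MM)]
        sites = structure_centers_mm(labels, vol.spacing_mm)[structure]
        site = np.asarray(sites[int(rng.integers(len(sites)))])
        # Lesions occur anywhere within a structure: jitter the centre so
        # its position is arbitrary relative to thick-slab boundaries (z
        # jitter of half a 7-slice slab gives a uniform slab phase).
        dz = vol.spacing_mm[0]
        jitter = rng.uniform(-1.0, 1.0, 3) * np.array([3.5 * dz, 2.0, 2.0])
        center = tuple(site + jitter)
        spec = ALISpec(center_mm=center, diameter_mm=diameter, structure=structure)
        vol_ali, record = insert_ali(vol, spec, mask, bolus_arrival_index=bolus)
    with _stage("aif", case):
        aif = extract_aif(vol, mask, bolus_arrival_index=bolus)

    rows = []
    for thickness in cfg.thicknesses:
        with _stage(f"prepare_{thickness}", case):
            if thickness == "thin":
                v_orig, v_ali, m = vol, vol_ali, mask
                vent = labels.mask_of("ventricle")
                thal = labels.mask_of("thalamus")
                idx = record.included
            else:
                v_orig, v_ali = make_thick_slices(vol), make_thick_slices(vol_ali)
                m = thick_mask(mask)
                # strict vote: range statistics need pure-CSF slabs
                vent = thick_mask(labels.mask_of("ventricle"), min_votes=7)
                thal = thick_mask(labels.mask_of("thalamus"))
                idx = sphere_voxels(
                    spec.center_mm,
                    spec.radius_mm,
                    v_orig.spatial_shape,
                    v_orig.spacing_mm,
                    v_orig.origin_mm,
                )
                inside = m[idx[:, 0], idx[:, 1], idx[:, 2]]
                idx = idx[inside]
            roi = thalamus_roi(thal, m, diameter_vox=cfg.roi_diameter_vox)
        for mode in cfg.modes:
            with _stage(f"filter_{mode}_{thickness}", case):
                sigma_r = estimate_sigma_r(v_orig, vent, mode)
                params = FilterParams(cfg.sigma_d_mm, sigma_r, mode)
                f_orig = bilateral_filter(v_orig, params, m)
                f_ali = bilateral_filter(v_ali, params, m)
            with _stage(f"cbv_{mode}_{thickness}", case):
                cbv_orig = compute_cbv(f_orig, aif, m, bolus_arrival_index=bolus)
                cbv_ali = compute_cbv(f_ali, aif, m, bolus_arrival_index=bolus)
            with _stage(f"cnr_{mode}_{thickness}", case):
                contrast = measure_contrast(cbv_ali, cbv_orig, idx)
                noise = measure_noise(cbv_orig, roi)
                rows.append(
                    {
                        "case": case,
                        "structure": structure,
                        "diameter_mm": diameter,
                        "mode": mode,
                        "thickness": thickness,
                        "sigma_r_hu2": sigma_r,
                        "contrast": contrast,
                        "noise": noise,
                        "cnr": compute_cnr(contrast, noise),
                    }
                )
    return rows


def run_pipeline(cfg: PipelineConfig | None = None, outdir=None) -> dict:
    """Run the full study; returns CNR tables and provenance.

    The bundle holds ``cnr_table`` (one row per case x mode x thickness),
    ``cnr_summary`` (mean contrast/noise/CNR per combination) and
    ``provenance``.  When ``outdir`` is given, both tables and the
    provenance record are written there.
    """
    cfg = cfg or PipelineConfig()
    seeds = child_seeds(cfg.seed, cfg.n_phantoms)
    rows = []
    for i, s in enumerate(seeds):
        rows.extend(_process_case(cfg, i, s))
    table = pd.DataFrame(rows)
    summary = (
        table.groupby(["mode", "thickness"], as_index=False)[["contrast", "noise", "cnr"]]
        .mean()
        .sort_values(["mode", "thickness"], ignore_index=True)
    )
    provenance = {
        "package": "ctplac",
        "version": __version__,
        "numpy": np.__version__,
        "seed": cfg.seed,
        "config": _config_dict(cfg),
    }
    bundle = {"cnr_table": table, "cnr_summary": summary, "provenance": provenance}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "cnr_table.csv", index=False)
        summary.to_csv(outdir / "cnr_summary.csv", index=False)
        from .io import save_json

        save_json(provenance, outdir / "provenance.json")
    return bundle


def _config_dict(cfg) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return obj

    return convert(cfg)
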