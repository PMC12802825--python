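"""Quantitative and qualitative lesion-detectability evaluation.

Quantitative: contrast (CBV in the lesion vs the same voxels in the
lesion-free map), noise (sample SD of CBV in a homogeneous circular
thalamus ROI, default diameter 25 in-plane voxels) and their ratio, the
contrast-to-noise ratio (CNR).  The CNR magnitude is reported: the lesion
is a CBV deficit, so ``contrast = CBV_normal - CBV_ALI`` is positive for a
visible lesion.

Qualitative: point annotations with 5-level Likert confidence are matched
against ground-truth lesion centres, the Likert scale is dichotomised at
the F1-maximising cumulative threshold, and method differences are tested
with paired bootstrap 95% confidence intervals over cases.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .ali import ALIRecord, ALISpec
from .core import GridError, RoiError

__all__ = [
    "LIKERT_LEVELS",
    "CONFIDENCE_MAP",
    "Annotation",
    "CNRResult",
    "DetectionResult",
    "measure_contrast",
    "measure_noise",
    "thalamus_roi",
    "compute_cnr",
    "match_annotations",
    "dichotomize_and_score",
    "f1_score",
    "confidence_scores",
    "paired_bootstrap_ci",
    "scripted_observer",
]

#: Likert levels ordered from most to least confident that a lesion is present.
LIKERT_LEVELS = ("certainly", "probably", "possibly", "probably_not", "certainly_not")

#: Confidence value of each Likert level: the extremes of the scale express
#: the highest confidence (in either direction), "possibly" the lowest.
CONFIDENCE_MAP = {
    "certainly": 1.0,
    "probably": 0.5,
    "possibly": 0.0,
    "probably_not": 0.5,
    "certainly_not": 1.0,
}

#: Default in-plane diameter (voxels) of the circular noise ROI.
NOISE_ROI_DIAMETER_VOX = 25

#: Default matching tolerance beyond the lesion radius (mm).
MATCH_TOLERANCE_MM = 2.0


@dataclass(frozen=True)
class Annotation:
    """One observer mark: a world-mm point with a Likert confidence."""

    case_id: str
    location_mm: tuple[float, float, float]  # (z, y, x)
    likert: str

    def __post_init__(self) -> None:
        if self.likert not in LIKERT_LEVELS:
            raise ValueError(f"unknown Likert level {self.likert!r}")


@dataclass
class CNRResult:
    """Contrast, noise and CNR of one method/thickness combination."""

    contrast: float  # mL/100 g, CBV_normal - CBV_ALI
    noise: float  # mL/100 g
    cnr: float
    per_ali_contrast: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class DetectionResult:
    """Detection counts and scores at the F1-maximising Likert threshold."""

    tp: int
    fp: int
    fn: int
    sensitivity: float
    precision: float
    f1: float
    threshold: str
    per_case_tp: np.ndarray = field(default_factory=lambda: np.empty(0))
    per_case_fp: np.ndarray = field(default_factory=lambda: np.empty(0))
    per_case_fn: np.ndarray = field(default_factory=lambda: np.empty(0))


def _mean_at(cbv: np.ndarray, indices: np.ndarray) -> float:
    return float(cbv[indices[:, 0], indices[:, 1], indices[:, 2]].mean())


def measure_contrast(cbv_with_ali, cbv_without, record) -> float:
    """``CBV_normal - CBV_ALI`` over the lesion's included voxels.

    ``record`` may be an :class:`~ctplac.ali.ALIRecord` or a plain
    ``(N, 3)`` index array (used when evaluating on a resampled grid).
    Positive when the infarct darkens the map.
    """
    cbv_with_ali = np.asarray(cbv_with_ali)
    cbv_without = np.asarray(cbv_without)
    if cbv_with_ali.shape != cbv_without.shape:
        raise GridError("CBV maps are on different grids")
    idx = record.included if isinstance(record, ALIRecord) else np.asarray(record)
    if idx.size == 0:
        raise ValueError("no included lesion voxels to measure")
    return _mean_at(cbv_without, idx) - _mean_at(cbv_with_ali, idx)


def thalamus_roi(
    labels,
    mask: np.ndarray,
    diameter_vox: int = NOISE_ROI_DIAMETER_VOX,
) -> np.ndarray:
    """In-plane circular ROI at the centroid of one thalamus.

    ``labels`` may be a :class:`~ctplac.core.LabelMap` or a boolean
    thalamus mask.  Picks the largest connected thalamus component, takes
    the axial slice through its centroid, and returns the ``(N, 3)``
    indices of a disc of the requested diameter (in voxels).  Raises
    :class:`RoiError` if the disc escapes the thalamus label or the brain
    mask.
    """
    thal = labels if isinstance(labels, np.ndarray) else labels.mask_of("thalamus")
    thal = thal.astype(bool)
    if not thal.any():
        raise RoiError("no thalamus in the label map")
    comp, n = ndimage.label(thal, structure=np.ones((3, 3, 3), bool))
    sizes = np.bincount(comp.ravel())[1:]
    largest = comp == (int(np.argmax(sizes)) + 1)
    cz, cy, cx = ndimage.center_of_mass(largest)
    z = int(round(cz))
    r = diameter_vox / 2.0
    ny, nx = largest.shape[1:]
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    ys, xs = np.nonzero(disc)
    idx = np.stack([np.full_like(ys, z), ys, xs], axis=1)
    inside = thal[idx[:, 0], idx[:, 1], idx[:, 2]] & mask[idx[:, 0], idx[:, 1], idx[:, 2]]
    if not inside.all():
        raise RoiError(
            f"noise ROI (diameter {diameter_vox} voxels) escapes the thalamus/mask"
        )
    return idx


def measure_noise(cbv: np.ndarray, roi_indices: np.ndarray) -> float:
    """Sample SD of CBV over the noise-ROI voxels (mL/100 g)."""
    vals = np.asarray(cbv)[roi_indices[:, 0], roi_indices[:, 1], roi_indices[:, 2]]
    if vals.size < 2:
        raise RoiError("noise ROI needs at least 2 voxels")
    return float(vals.std(ddof=1))


def compute_cnr(contrast: float, noise: float) -> float:
    """Contrast-to-noise ratio; requires strictly positive noise."""
    if noise <= 0:
        raise ValueError("noise must be > 0")
    return contrast / noise


@dataclass
class MatchResult:
    """Stratified matching of annotations against ground-truth lesions."""

    # one entry per annotation: its Likert level, whether it hit a lesion,
    # and its case id
    likert: list[str]
    hit: np.ndarray  # bool per annotation
    case_of_annotation: list[str]
    n_alis: int
    case_ids: list[str]  # every case in the truth (controls included)
    case_of_ali: list[str]


def match_annotations(
    annotations,
    truth: dict[str, list[ALISpec]],
    tolerance_mm: float = MATCH_TOLERANCE_MM,
) -> MatchResult:
    """Greedy closest-first matching of annotations to lesion centres.

    An annotation can hit a lesion of the same case when it lies within
    ``lesion radius + tolerance_mm`` of the centre; each lesion accepts at
    most one annotation (the closest wins) and each annotation is used at
    most once.  Control cases contribute false positives only.

    ``truth`` maps every case id (controls included, with an empty list)
    to its lesion specs.
    """
    case_ids = list(truth.keys())
    if len(case_ids) != len(set(case_ids)):
        raise ValueError("duplicate case ids in truth")
    annotations = list(annotations)
    hit = np.zeros(len(annotations), dtype=bool)
    ali_taken: set[tuple[str, int]] = set()
    pairs = []
    for ai, ann in enumerate(annotations):
        if ann.case_id not in truth:
            raise ValueError(f"annotation for unknown case {ann.case_id!r}")
        for li, spec in enumerate(truth[ann.case_id]):
            d = float(
                np.linalg.norm(np.asarray(ann.location_mm) - np.asarray(spec.center_mm))
            )
            if d <= spec.radius_mm + tolerance_mm:
                pairs.append((d, ai, li))
    for d, ai, li in sorted(pairs, key=lambda p: p[0]):
        ann = annotations[ai]
        key = (ann.case_id, li)
        if hit[ai] or key in ali_taken:
            continue
        hit[ai] = True
        ali_taken.add(key)
    case_of_ali = [cid for cid, specs in truth.items() for _ in specs]
    return MatchResult(
        likert=[a.likert for a in annotations],
        hit=hit,
        case_of_annotation=[a.case_id for a in annotations],
        n_alis=len(case_of_ali),
        case_ids=case_ids,
        case_of_ali=case_of_ali,
    )


def f1_score(sensitivity: float, precision: float) -> float:
    """Harmonic mean of sensitivity (recall) and precision; 0 when both 0."""
    if sensitivity + precision == 0:
        return 0.0
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def _counts_at_threshold(match: MatchResult, threshold: str):
    rank = {lvl: i for i, lvl in enumerate(LIKERT_LEVELS)}
    cut = rank[threshold]
    above = np.array([rank[lvl] <= cut for lvl in match.likert], dtype=bool)
    tp = int((above & match.hit).sum())
    fp = int((above & ~match.hit).sum())
    fn = match.n_alis - tp
    return tp, fp, fn, above


def dichotomize_and_score(match: MatchResult) -> DetectionResult:
    """Scores at the F1-maximising cumulative Likert threshold.

    All five thresholds (annotation counts as a detection when its level
    is at least as confident as the threshold) are evaluated; ties break
    toward the stricter threshold.  Returns per-case TP/FP/FN vectors for
    paired bootstrapping.
    """
    best = None
    for threshold in LIKERT_LEVELS:
        tp, fp, fn, _ = _counts_at_threshold(match, threshold)
        sens = tp / (tp + fn) if tp + fn else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        f1 = f1_score(sens, prec)
        if best is None or f1 > best[0]:
            best = (f1, threshold, tp, fp, fn, sens, prec)
    f1, threshold, tp, fp, fn, sens, prec = best
    _, _, _, above = _counts_at_threshold(match, threshold)
    idx = {cid: i for i, cid in enumerate(match.case_ids)}
    per_tp = np.zeros(len(match.case_ids))
    per_fp = np.zeros(len(match.case_ids))
    per_fn = np.zeros(len(match.case_ids))
    for ai, cid in enumerate(match.case_of_annotation):
        if above[ai]:
            if match.hit[ai]:
                per_tp[idx[cid]] += 1
            else:
                per_fp[idx[cid]] += 1
    for cid in match.case_of_ali:
        per_fn[idx[cid]] += 1
    per_fn -= per_tp
    return DetectionResult(
        tp=tp,
        fp=fp,
        fn=fn,
        sensitivity=sens,
        precision=prec,
        f1=f1,
        threshold=threshold,
        per_case_tp=per_tp,
        per_case_fp=per_fp,
        per_case_fn=per_fn,
    )


def confidence_scores(likert_levels) -> float:
    """Mean observer confidence of a collection of Likert levels.

    The scale's extremes map to 1.0, its middle to 0.0; callers may append
    implicit "certainly_not" decisions for unannotated locations.
    """
    levels = list(likert_levels)
    if not levels:
        raise ValueError("no Likert levels given")
    vals = []
    for lvl in levels:
        if lvl not in CONFIDENCE_MAP:
            raise ValueError(f"unknown Likert level {lvl!r}")
        vals.append(CONFIDENCE_MAP[lvl])
    return float(np.mean(vals))


def paired_bootstrap_ci(
    per_case_a,
    per_case_b,
    statistic=np.mean,
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
):
    """Paired bootstrap CI for ``statistic(b) - statistic(a)`` over cases.

    Cases are resampled with replacement, keeping the pairing; the CI is
    the percentile interval and the difference is significant when the CI
    excludes zero.  ``statistic`` must accept an ``axis`` keyword (e.g.
    ``np.mean``).

    Returns ``(estimate, (ci_low, ci_high), significant)``.
    """
    a = np.asarray(per_case_a, dtype=float)
    b = np.asarray(per_case_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired case vectors must be 1D of equal length")
    if a.size == 0:
        raise ValueError("empty input")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    estimate = float(statistic(b, axis=0) - statistic(a, axis=0))
    idx = rng.integers(0, a.size, size=(n_boot, a.size))
    diffs = statistic(b[idx], axis=1) - statistic(a[idx], axis=1)
    lo, hi = np.percentile(diffs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    significant = not (lo <= 0.0 <= hi)
    return estimate, (float(lo), float(hi)), significant


def scripted_observer(
    truth: dict[str, list[ALISpec]],
    cnr_of_case: dict[str, float],
    seed: int = 0,
    detect_threshold: float = 2.0,
    fp_rate: float = 0.05,
    jitter_mm: float = 1.0,
    fp_location_mm=(0.0, 0.0, 0.0),
) -> list[Annotation]:
    """Synthetic observer for end-to-end tests — not a model of humans.

    Annotates each lesion whose CNR exceeds ``detect_threshold`` at its
    centre (with sub-voxel jitter), grading Likert confidence by CNR;
    control cases receive a false-positive annotation with probability
    ``fp_rate``.
    """
    rng = np.random.default_rng(seed)
    annotations = []
    for cid, specs in truth.items():
        for spec in specs:
            cnr = cnr_of_case.get(cid, 0.0)
            if cnr < detect_threshold:
                continue
            if cnr >= 3 * detect_threshold:
                lvl = "certainly"
            elif cnr >= 2 * detect_threshold:
                lvl = "probably"
            else:
                lvl = "possibly"
            loc = tuple(np.asarray(spec.center_mm) + rng.uniform(-jitter_mm, jitter_mm, 3))
            annotations.append(Annotation(cid, loc, lvl))
        if not specs and rng.random() < fp_rate:
            annotations.append(Annotation(cid, tuple(fp_location_mm), "possibly"))
    return annotations
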