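# Methods

`ctplac` quantifies how reconstruction slice thickness and robust noise
filtering affect the detectability of small (lacunar) infarcts in CT
perfusion (CTP), using simulated lesions in a synthetic 4D head phantom so
that every stage is testable without clinical data.

## The synthetic acquisition

The phantom emulates a thin-slice, low-dose CTP acquisition of the deep
brain. Every voxel's time-attenuation curve (TAC) is

    TAC(t) = B_s + f_s · AIF(t) + ε,   ε ~ N(0, σ²) i.i.d. per voxel-frame,

where `B_s` is the structure's baseline attenuation (HU), `f_s` its
relative blood volume (dimensionless), and the arterial input function
(AIF) is a peak-normalised gamma variate

    AIF(t) = A · ((t − t0)/(αβ))^α · exp(α − (t − t0)/β)   for t > t0,

zero before bolus arrival `t0`, with peak `A` at `t = t0 + αβ`.

Defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| grid | 28 × 84 × 84 voxels | smallest slab holding all deep structures, a 10 mm lesion with its 5 mm-radius reference sphere anywhere inside a structure, and the 25-voxel noise ROI |
| spacing | (0.7, 1.0, 1.0) mm | 0.7 mm is the native thin-slice spacing; 1 mm in-plane sampling of a slab through the basal ganglia |
| frames | 16, every 2 s | a 30 s bolus passage |
| AIF | A = 250 HU, t0 = 6 s, α = 2.5, β = 2 s | gives a tissue enhancement peak of ~10 HU at gray-matter blood volume, matching the order of magnitude of low-kVp, low-mAs acquisitions |
| noise σ | 10 HU per thin-slice voxel-frame | plausible for a 120 kVp / 35 mAs thin-slice reconstruction; 7-slice averaging reduces it by √7 |
| baselines | gray 38, white 30, CSF 4, skull 1000, artery 45 HU | textbook values; only relative contrast matters downstream |
| blood volumes | gray/deep gray 0.04, white 0.02, pons 0.03, artery 1.0, CSF 0 | ~4 and ~2 mL/100 g for gray and white matter at brain density 1.04 g/mL |

Structures are axis-aligned ellipsoids (skull ring, gray/white
compartments, paired ventricles, thalami, caudate nuclei, putamina,
internal capsules, a pons) plus an off-centre arterial cylinder carrying
the unscaled AIF; the lateral artery offset deliberately breaks mirror
symmetry. A single root seed derives all per-stage child seeds, so every
output is bit-reproducible.

What the phantom does **not** model: partial-volume anatomy at structure
boundaries (labels are crisp), spatially correlated CT noise, beam
hardening, motion, spectral effects, or realistic vasculature. Passing
tests therefore demonstrate the *mechanics* of the analysis — lesion
nulling, filter behaviour, CBV arithmetic, statistics — and the
qualitative filter/thickness ordering, not clinical effect sizes.

## Preprocessing

The brain mask thresholds the temporal average to a [0, 100] HU window,
fills holes per axial slice (recovering dense vessels), and keeps the
largest 26-connected 3D component. Thick slices average non-overlapping
groups of 7 consecutive thin slices anchored at slice 0 (trailing
remainder dropped), turning 0.7 mm into 4.9 mm spacing; the thick grid
carries a +3·dz z-origin so world coordinates agree across
reconstructions. Masks are resampled to the thick grid by 7-slice
majority vote; statistics that require pure tissue (range-sigma
estimation in the ventricles) use a strict 7/7 vote so partial-volume
slabs do not masquerade as noise.

## Artificial lacunar infarcts

A lesion is a sphere of 5, 7 or 10 mm diameter. The mean
contrast-enhancement curve of a fixed 5 mm-radius reference sphere around
the centre — per-frame mean over reference voxels, re-baselined to zero
over the pre-bolus frames — is subtracted from every lesion voxel. This
removes the iodine signal ("zero blood volume") while preserving the
background intensity and the native noise. Voxels whose temporal average
deviates more than two sample standard deviations from the
reference-region mean are treated as different tissue: excluded from the
curve estimate and left unmodified (one pass, non-iterative). The
reference region includes the lesion sphere itself, and insertion always
happens on thin slices; thick slices are derived afterwards.

Choices made where the procedure was open: "enhancement" is the TAC minus
its pre-bolus baseline mean (subtracting raw TACs would destroy the
background intensity); the 5 mm reference radius is fixed for all lesion
diameters; the exclusion SD is the sample (n−1) SD over reference-voxel
temporal averages.

## Bilateral filtering

Each in-mask voxel's TAC is replaced by a normalised weighted average of
its box neighbourhood (half-width exactly 3σ_d per axis, converted to
voxel radii by `ceil` on anisotropic grids):

    w_i = exp(−Δd_i² / 2σ_d²) · exp(−Δr_i² / 2σ_r²)

with Δd the Euclidean distance in mm and Δr the range distance in HU²:
the mean squared difference between whole TACs (TIPS mode) or the squared
difference of TAC temporal means (temporal-average guided mode). One
weight per voxel pair applies to all frames; weights renormalise over
existing voxels at volume borders. Because Δr already carries squared
units, σ_r is in HU² and enters through a squared exponent; the
alternative linear reading `exp(−Δr/2σ_r)` is available via
`FilterParams(squared_range_exponent=False)` for sensitivity checks.

σ_d defaults to 2 mm (the optimum reported for lesions near the detection
limit; 1 and 3 mm selectable). σ_r is estimated from ventricle voxels of
the volume being filtered — CSF has no enhancement, so its variability is
noise: the mean temporal variance of ventricle TACs (TIPS) or the spatial
variance of ventricle temporal averages (tAvg). Filtering is restricted
to brain-mask centres (skull intensities would poison range statistics);
neighbour voxels are not masked because the range kernel already
suppresses dissimilar tissue. TIPS weights are computed on raw TACs.

The production kernel is a compiled (numba) loop verified against a plain
quadruple-loop implementation of the equation to 1e-6 HU on random
volumes, for both range metrics and both exponent readings.

`noise2noise_pair` realises the self-supervised denoising data contract —
input `(frame(t), early frame)`, target `(frame(t−1)+frame(t+1))/2 −
other early frame` — so that training-pair construction is testable;
network training itself is out of scope.

## CBV mapping

CBV is an area-under-curve ratio:

    CBV = 100 · (∫ enhancement dt / ∫ AIF dt) / ρ,   ρ = 1.04 g/mL,

with trapezoidal integration over frame times, enhancement defined
against the pre-bolus baseline (frames strictly before the bolus-arrival
index, default the first frames before t0), negatives clipped to zero and
NaN outside the mask. This is a documented stand-in for the
nonlinear-regression perfusion models used on clinical data: it is exact
on noiseless input (recovering each structure's blood-volume fraction to
machine precision) and preserves the one property the detectability
analysis needs — enhancement-free tissue maps to CBV ≈ 0. No venous
output function is needed. The AIF is the mean enhancement curve of the
10 strongest-enhancing in-mask voxels of the unfiltered thin-slice
volume.

## Evaluation

**Quantitative.** For each filter × thickness combination, contrast is
`CBV_normal − CBV_lesion` over the lesion's included voxels, comparing the
denoised lesion scan against the denoised original at the same voxels
(positive for a visible deficit; the CNR magnitude is reported). Noise is
the sample SD of CBV in a circular in-plane ROI of 25 voxels diameter
placed at the centroid of one thalamus, one ROI per slice thickness.
CNR = contrast / noise.

**Qualitative.** Point annotations carry a 5-level Likert confidence
(certainly / probably / possibly / probably-not / certainly-not a
lesion). An annotation may hit a lesion of its case when it lies within
the lesion radius plus a 2 mm tolerance (rim clicks must count); each
lesion accepts at most one annotation, closest first. The Likert scale is
dichotomised at the cumulative threshold that maximises F1, ties broken
toward the stricter threshold; sensitivity, precision and F1 are reported
with per-case count vectors. Confidence maps the scale's extremes to 1.0
and its middle to 0.0. Method differences use a paired bootstrap over
cases (default 10 000 replicates, percentile 2.5/97.5 CI); a difference is
significant when the CI excludes zero. A scripted observer — annotating
lesions whose CNR exceeds a threshold, grading confidence by CNR — serves
as fixture machinery for end-to-end tests; it is not a model of human
readers.

**Study layout.** The CNR ranking study uses 20 seeded phantoms, one
lesion each, cycling through the five target structures and a
7/5/7/10 mm diameter cycle (reproducing the 1:2:1 diameter mix). Lesion
centres are jittered uniformly within ±3.5 thin slices axially and ±2 mm
in-plane around structure centroids, so lesion positions are arbitrary
relative to thick-slab boundaries — on a symmetric grid, un-jittered
centroids would always coincide with slab centres and suppress the
partial-volume effect that distinguishes the reconstructions. The
observer-study builder reproduces the 50-case design (10 controls,
10 × 5 mm, 20 × 7 mm, 10 × 10 mm lesions spread evenly over the five
structures, unique source/structure slots, optional per-case mirroring).

## Numerical conventions

Sample (n−1) variance wherever variances are estimated. Arrays are
`(t, z, y, x)`; world mm = origin + index · spacing; all serialised
coordinates are world mm. Volumes compute in float64 and are written to
NIfTI-1 as float32 with frame times in a JSON sidecar. Degenerate inputs
raise typed errors (empty mask, empty reference region after exclusion,
sphere outside mask/grid, enhancement-free volume, non-positive AIF area,
ROI escaping its structure).

## Known limitations

Absolute CNR and detection values depend on the phantom's noise level,
enhancement amplitude and geometry and are not clinical estimates; only
orderings and invariances are meaningful. The AUC-ratio CBV ignores
delay/dispersion and tracer kinetics. The i.i.d. noise model favours both
bilateral filters relative to real, spatially correlated CT noise. The
2D/3D U-Net comparison arm and motion correction are out of scope.
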