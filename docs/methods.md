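# Methods

This note records the models, conventions and design choices behind
`perflung`, in the spirit of a statistical-software methods appendix.

## Geometry and volumetric conventions

All volumes live on axis-aligned grids in a right-handed world space in
millimetres; voxel indices are 0-based and voxel centres define the
sample points, so index `(i,j,k)` sits at `origin + index * spacing`.
NIfTI-1 is the on-disk format; on read, spacing is recovered as the
column norms of the affine (oblique rotations are not represented — the
grid model is axis-aligned). Masks are binarised at 0.5 on read and may
only be resampled with nearest-neighbour interpolation, which preserves
binarity; scalar volumes default to trilinear. Every cross-grid
operation resamples onto the planning (dose/structure) grid, never onto
the SPECT grid, matching the clinical convention of fusing SPECT onto
the planning CT. Voxels pulled back outside the source extent are set
to 0. There is no partial-volume weighting at mask edges: a voxel is in
or out, a known limitation shared with most clinical DVH engines.

## Perfused and anatomic lung

The anatomic lung is `lungs AND NOT gtv_itv AND NOT central_airways`
(trachea + proximal bronchial tree). Some clinical figure conventions
subtract the PTV rather than the GTV/ITV; both behaviours are
implemented (`subtract="gtv"` default, `"ptv"` optional) because the
field uses both and the intent of any one report cannot be guessed.

Perfused lung follows the two-step definition. Step 1 in clinical
practice is a manual contour of all tracer-containing voxels; the
reproducible surrogate here keeps voxels above a count floor
(`floor_fraction`, default 1% of the maximum count, which removes
Poisson-level background), restricts them to the at-most-two largest
connected components intersecting the lung mask (the two lungs;
extra-pulmonary tracer such as shunt is thereby excluded), and applies a
radius-1 morphological closing to make the contour contiguous. Closing
can annex a thin rim of zero-count voxels at concave notches (e.g. the
defect rim); these never enter the thresholded masks, and
`closing_radius=0` disables the step. Step 2 keeps boundary voxels with
counts **greater than or equal to** a fraction (0.20, 0.25, 0.30, 0.40,
0.50 by default) of the maximum voxel perfusion count within the
boundary — the comparison is inclusive by definition. The absolute
maximum is used by default; a robust percentile (`max_count_percentile`,
e.g. 99.5) is available to guard against hot-pixel artefacts but is off
because the definition of the thresholds references the maximum count.
Nestedness (p50 ⊆ p40 ⊆ … ⊆ p20 ⊆ boundary) and invariance under
positive rescaling of the counts follow from the construction and are
enforced by tests.

## Registration

The clinical workflow (automated intensity registration with manual
adjustment by a radiologist) is operator-driven; the reproducible
surrogate is a landmark (point-pair) rigid registration through the
structures a radiologist would use — the lung apices (stable under
inspiration, unlike the diaphragm), the hila, and the tumour-associated
perfusion defect. The Kabsch/SVD solution gives the least-squares
proper rotation (det +1, no scaling) and translation; at least three
non-collinear pairs are required. The RMS landmark residual is reported
as a misregistration diagnostic and raises a warning above a
configurable ceiling (default 15 mm) without failing the run, because a
large residual is a data-quality signal, not an algorithmic error.
Deformable registration — the principled fix for breath-hold vs
free-breathing inflation differences — is deliberately out of scope; the
residual can diagnose but not correct a systematic perfused-vs-anatomic
DVH shift.

## Dosimetry

Vx and MLD are computed voxelwise (inclusive ≥ at the threshold), never
from histogram bins; the binned cumulative curve (default 0.1 Gy bins)
exists only for plotting and export. Inclusive ≥ is fixed for
reproducibility — on a continuous dose grid the choice is measure-zero,
but ties occur on synthetic plateaus. Fractional denominators are
per-structure: aVx uses the anatomic-mask volume, pVx the p20-mask
volume, with the p20 lung treated as an independent organ-at-risk. MLD
is reported in cGy following the clinical reporting convention; the
planning constraints checked are MLD < 20 Gy and V20 < 35%.

## Synthetic phantom

The phantom emulates the *inputs* of the clinical pipeline, not the
physics that produced them.

- **Geometry**: two ellipsoidal lungs (default semi-axes 55×75×110 mm,
  ~4.2 l total, matching a mid-inspiration adult thorax), a spherical
  tumour (default radius 18 mm) inside one lung, a midline trachea
  cylinder with a carinal bar for the proximal airways, and a PTV equal
  to the tumour plus a 10 mm circumferential margin. The default grid is
  5 mm isotropic (56×38×52); dose-grid resolution is fully configurable
  since clinical export resolutions vary.
- **Dose**: prescription (default 64 Gy, the middle of the 60–66 Gy
  2 Gy-fraction radical range) inside the PTV and
  `D0·exp(−d/penumbra)` at distance `d` outside it. This is an analytic
  stand-in, not a beam model: the "penumbra" length (default 22 mm)
  lumps the whole low-dose bath of a conformal plan into one scale,
  chosen so the default phantom lands in the clinically typical range
  (aV20 ≈ 14%, MLD ≈ 8 Gy, constraints met). Its virtue is a
  closed-form oracle: the x Gy isodose surface is the sphere of radius
  `R_PTV + penumbra·ln(D0/x)`, giving exact expected Vx values.
- **Perfusion**: mean counts fall linearly from the base (default 100
  per voxel, a realistic SPECT count level) to `apex_scale` (default
  0.25) of that at the apex — supine MAA SPECT shows a marked
  gradient — with a hard spherical defect of zero mean counts around
  the tumour (default tumour radius + 15 mm), and Poisson sampling.
  The linear gradient makes every threshold mask an analytically known
  axial slab.

What the phantom does **not** emulate: respiratory motion and
breath-hold/free-breathing misalignment (beyond the rigid shifts the
registration tests inject), CT texture, attenuation and scatter in
SPECT, irregular multi-focal perfusion loss, multi-lesion disease, and
realistic absolute anatomic-to-perfused volume ratios (the clinical
p20/anatomic ratio ≈ 0.5 cannot be produced by a linear gradient; the
phantom's ratio is higher). Passing tests therefore demonstrate
correctness of the computational pipeline under controlled conditions,
not clinical performance on real images.

## Cohort and outcome model

Per patient, the cohort prior varies tumour radius (10–24 mm),
laterality and position within the lung, defect margin (5–20 mm),
penumbra (12–32 mm) and prescription (60 or 66 Gy); metrics are then
computed by the real segmentation/dosimetry path, never short-circuited.
One shared generator, seeded once, drives the whole cohort.

Outcomes are generated from explicit models on the centred metrics:

- P(FEV1 deterioration) = logistic(β₀ + β₁·(aV10 − mean aV10)),
  defaults β₀ = 0, β₁ = 0.12 per percentage point;
- ΔFEV1 (%) ~ Normal(δ₀ − γ·(aV10 − mean), σ), defaults δ₀ = −8%,
  γ = 0.8, σ = 8%;
- P(RALI) = logistic(α₀ + α₁·(aV50 − mean aV50)), defaults α₀ = −2.2,
  α₁ = 1.5 per percentage point.

The defaults were fixed once so that the model-implied operating
characteristics under the default prior match the magnitudes reported in
the clinical literature this package is designed to analyse
(deterioration AUC ≈ 0.76, RALI rate ≈ 0.15–0.2 with AUC ≈ 0.88); they
are stated in config and are not claimed to reproduce any published
table numerically. ΔFEV1 is generated as a summary change and
back-filled into the visit series (months 1–24) with a linear ramp to a
nadir at month 12 and mild recovery after; only the summary change is
analysed, so the visit-level trajectory is a plausible carrier, not a
model. RALI events are placed as early grade-2 pneumonitis (month 3)
two times in three and late grade-3 fibrosis (month 12) otherwise,
mirroring the typical early/late event mix.

For the parameter-recovery properties (AUC of the generating metric
within ±0.05 of the model-implied value; β₁ sign recovered in ≥ 95 of
100 replicates at n = 200) the phantom geometry is drawn once per seed
and the outcome labels are redrawn per replicate: outcomes are
conditionally independent of geometry given the metrics, so replicating
the geometry would add computation without statistical content. The
model-implied AUC itself is computed by a large-sample simulation
oracle (repeated label redraws on the same metric values).

## Statistics

- ΔFEV1 uses 100·(follow-up − baseline)/baseline with a configurable
  summary rule; **nadir** (minimum over follow-ups) is the default as
  the most common spirometry summary, with `last` and `at_month`
  available. Patients with no follow-up are excluded.
- The median split labels `change < median` deteriorating and
  `change ≥ median` stable; the median patient goes to the stable group,
  which yields the 21/20 split at n = 41 with distinct values. A cohort
  of identical changes is a degenerate split and an error.
- The t-test is the pooled-variance (Student) form, not Welch, matching
  the named clinical analysis. Zero pooled variance is an error.
- Mann–Whitney U is exact by enumeration of all label assignments when
  the pooled n ≤ 12 (RALI groups are small, and the normal approximation
  is poor there); above that, a tie-corrected normal approximation with
  a 0.5 continuity correction. Ties count 0.5 toward U in both branches.
- ROC analysis computes AUC by pairwise concordance (ties 0.5), which
  equals U/(n₁n₀) exactly; the curve sweeps every observed value as an
  inclusive ≥ cutoff; the reported cutoff maximises Youden
  J = sensitivity + specificity − 1, ties resolved toward the lower
  cutoff so the most inclusive of equally good rules is reported.
  Youden J is the standard criterion when a single
  sensitivity/specificity pair is to be quoted.
- Each comparison table carries eight rows (V5–V50 and MLD), so the
  Bonferroni-corrected level is α/8 = 0.00625 at α = 0.05; the
  significance flag is `p < α/m` exactly.
- Degenerate event splits (no RALI events, or all events) produce
  explicit "not estimable" rows rather than failures.

## Pipeline

`run_pipeline` executes simulate → segment → DVH → analyze under a
validated JSON config, writing every artefact plus the resolved config
and a log to a run directory; identical config + seed give byte-identical
CSVs. Config validation aggregates all failing keys into a single
error. Figures (volume boxplots, ROC curves, DVH overlay) are rendered
from the exported CSVs, never from in-memory state, so every plotted
number is independently checkable; partial runs yield a report with an
explicit gap list.

## Problem sizes

The default phantom grid (5 mm, ~110k voxels) and the cohort sizes used
in tests and the acceptance script (41–200 patients) were chosen so the
full simulation study runs in seconds on a single core while keeping
several hundred voxels across each lung — enough for stable Vx
estimates at all thresholds.
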