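# perflung — functional-lung dosimetry with SPECT perfusion volumes

In radical radiotherapy for non-small-cell lung cancer, the dose that
spills into normal lung drives radiation-associated lung injury (RALI —
early radiation pneumonitis or late pulmonary fibrosis) and loss of
respiratory function. Treatment planning conventionally treats the
anatomic lung (delineated on CT) as a uniform organ-at-risk, but lung
function is regionally heterogeneous: ⁹⁹ᵐTc-MAA perfusion SPECT maps
first-pass pulmonary blood flow and identifies the lung that is actually
*perfused*. `perflung` is a research pipeline for asking whether
dose–volume metrics computed on perfused lung discriminate adverse
outcomes better than the same metrics on anatomic lung.

The package is aimed at radiotherapy physicists and imaging researchers.
It provides, as an importable library:

- a volumetric core (NIfTI IO, axis-aligned grids in mm, rigid
  resampling) shared by all stages;
- **perfusion segmentation**: the perfused lung is built in two steps —
  a boundary around all tracer-containing lung voxels, then nested
  "perfusion volumes" p20…p50 keeping voxels with counts ≥ 20…50% of the
  maximum voxel perfusion count; the anatomic lung is the CT lung volume
  minus GTV/ITV and the trachea + proximal bronchial tree;
- **landmark co-registration**: a Kabsch least-squares rigid fit through
  paired anatomical landmarks (lung apices, hila, the tumour-associated
  perfusion defect) aligning free-breathing SPECT to the breath-hold
  planning grid, with the RMS residual as a misregistration diagnostic;
- **dosimetry**: cumulative DVHs and the canonical metrics
  Vx = 100·|{v ∈ S : D(v) ≥ x Gy}| / |S| for x ∈ {5, 10, 13, 20, 30,
  40, 50} and MLD = mean dose over S (cGy), computed voxelwise on the
  planning grid for the anatomic (aVx, aMLD) and perfused p20 (pVx,
  pMLD) lung, plus the planning constraints MLD < 20 Gy and V20 < 35%;
- **outcome statistics**: fractional FEV1 change
  ΔFEV1 = 100·(follow-up − baseline)/baseline (nadir follow-up by
  default), a median split into deteriorating (Δ < median) vs stable
  groups, CTCAE-based pneumonitis (worst grade ≥ 2 within 6 months) and
  RALI (any visit over 0–24 months) labels, pooled-variance t-tests,
  exact small-sample and continuity/tie-corrected Mann–Whitney U tests,
  Bonferroni correction (α/m, with m = 8 dose levels per table), and
  concordance ROC analysis (AUC = U/(n₁n₀)) with Youden-J cutoffs;
- a **synthetic thorax-phantom and cohort generator** so every stage is
  testable without patient data: ellipsoidal lungs with an embedded
  tumour, an analytic plateau+exponential-penumbra dose, a linear
  apex-to-base perfusion gradient with a tumour-adjacent defect and
  Poisson noise, and per-patient FEV1/CTCAE outcomes statistically
  linked to the dose metrics through explicit logistic models.

## Worked example

`examples/` holds one short narrative script per capability. Running
`python examples/02_perfusion_volumes.py` prints:

```
max voxel perfusion count: 128
anatomic lung:    3742 ml
boundary:         3625 ml
p20:              3585 ml
p25:              3480 ml
p30:              3237 ml
p40:              2546 ml
p50:              1774 ml
```

The perfusion volumes are nested and shrink monotonically with the
threshold, and all are smaller than the anatomic lung because the
tumour-adjacent defect carries no tracer. `examples/04_cohort_analysis.py`
simulates a 41-patient cohort and prints the report tables; e.g. the
anatomic-lung comparison starts:

```
FEV1 groups: 21 stable / 20 deteriorating
Bonferroni threshold: 0.00625

    metric  group_ref  group_event  difference  p_value   auc
       aV5     31.034       39.248       8.214    0.011 0.726
      aV10     22.085       29.269       7.184    0.008 0.740
```

Each row compares one dose metric between the stable (`group_ref`) and
deteriorating (`group_event`) FEV1 groups; `difference` is the
event-minus-reference summary, and `auc` is the metric's ability to
discriminate the groups. The low-dose metrics (V10/V13) show the largest
separation, mirroring the generative link from aV10 to FEV1 decline.

A full reproducible run (simulate → segment → DVH → analyze → report)
is one call — `perflung run --seed 1 --outdir runs` — or
`perflung.run_pipeline(config, outdir)` from Python; every artefact,
the resolved config and a log land in the run directory, and the same
config + seed give byte-identical outputs.

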