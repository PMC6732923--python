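"""Synthetic thorax phantoms and outcome-linked patient cohorts.

The phantom is an analytic stand-in for the imaging inputs of a
functional-lung dosimetry study: two ellipsoidal lungs with an embedded
spherical tumour, a planning dose distribution that is flat inside the
PTV (tumour plus a 1 cm circumferential margin) and falls off
exponentially outside it, and a perfusion count map with a linear
apex-to-base gradient, a perfusion defect around the tumour and Poisson
counting noise.  The analytic dose model gives closed-form DVH oracles;
it is not a beam model.

Cohorts draw per-patient phantom variations, compute dose metrics with
the dosimetry module, and generate spirometry and CTCAE outcomes whose
statistical link to the metrics is explicit and tunable: the probability
of FEV1 deterioration follows a logistic model in a named low-dose
metric (default aV10) and the probability of radiation-associated lung
injury (RALI) follows a logistic model in aV50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .dosimetry import patient_metrics
from .perfusion import DEFAULT_THRESHOLDS, anatomic_lung_volume, build_perfusion_set
from .volume import GridSpec, ImageVolume, StructureSet

__all__ = [
    "VISIT_MONTHS",
    "PhantomSpec",
    "OutcomeModel",
    "CohortPrior",
    "PatientRecord",
    "generate_phantom",
    "simulate_outcomes",
    "simulate_cohort",
    "cohort_tables",
]

#: Follow-up visit schedule in months after the end of radiotherapy.
VISIT_MONTHS = (1, 3, 6, 9, 12, 15, 18, 24)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, dose and perfusion parameters for one thorax phantom.

    Lengths are mm, dose Gy, counts are Poisson means.  The default grid
    is 5 mm isotropic over a 280 x 190 x 260 mm thorax with ~4.2 l of
    lung, a right-sided tumour and a 64 Gy prescription (2 Gy-fraction
    radical schedule range 60-66 Gy).
    """

    shape: tuple[int, int, int] = (56, 38, 52)
    spacing: tuple[float, float, float] = (5.0, 5.0, 5.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # lateral (x), antero-posterior (y), cranio-caudal (z) in world mm
    left_lung_centre: tuple[float, float, float] = (75.0, 95.0, 128.0)
    right_lung_centre: tuple[float, float, float] = (205.0, 95.0, 128.0)
    lung_radii: tuple[float, float, float] = (55.0, 75.0, 110.0)
    tumour_centre: tuple[float, float, float] = (190.0, 95.0, 160.0)
    tumour_radius_mm: float = 18.0
    ptv_margin_mm: float = 10.0
    prescription_gy: float = 64.0
    penumbra_mm: float = 22.0
    mean_counts: float = 100.0
    apex_scale: float = 0.25
    defect_radius_mm: float = 33.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.prescription_gy <= 80):
            raise ValueError("prescription dose must lie in (0, 80] Gy")
        if self.penumbra_mm <= 0:
            raise ValueError("penumbra length must be positive")
        if self.tumour_radius_mm <= 0 or self.defect_radius_mm <= 0:
            raise ValueError("tumour and defect radii must be positive")
        if self.mean_counts <= 0:
            raise ValueError("mean counts must be positive")
        if not (0 < self.apex_scale <= 1):
            raise ValueError("apex_scale must lie in (0, 1]")
        c = np.asarray(self.tumour_centre, dtype=float)
        inside = any(
            float(
                np.sum(((c - np.asarray(lc)) / np.asarray(self.lung_radii)) ** 2)
            )
            <= 1.0
            for lc in (self.left_lung_centre, self.right_lung_centre)
        )
        if not inside:
            raise ValueError("tumour centre must lie inside one lung ellipsoid")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.shape, self.spacing, self.origin)


def _ellipsoid(xs, ys, zs, centre, radii) -> np.ndarray:
    cx, cy, cz = centre
    rx, ry, rz = radii
    return ((xs - cx) / rx) ** 2 + ((ys - cy) / ry) ** 2 + ((zs - cz) / rz) ** 2 <= 1.0


def _sphere(xs, ys, zs, centre, radius) -> np.ndarray:
    cx, cy, cz = centre
    return (xs - cx) ** 2 + (ys - cy) ** 2 + (zs - cz) ** 2 <= radius**2


def generate_phantom(
    spec: PhantomSpec, add_noise: bool = True
) -> tuple[ImageVolume, ImageVolume, StructureSet]:
    """Build (dose, spect, structures) for one phantom.

    Construction
    ------------
    * lungs: union of the two ellipsoids minus the tumour sphere
    * PTV: tumour sphere expanded by the circumferential margin
    * dose: prescription inside the PTV, ``D0 * exp(-d / penumbra)`` at
      distance ``d`` (mm) outside it
    * perfusion mean: linear gradient from ``apex_scale * mean_counts``
      at the lung apex to ``mean_counts`` at the base, zero inside the
      spherical defect around the tumour; Poisson sampled when
      ``add_noise`` (deterministic for a fixed ``spec.seed``)
    """
    grid = spec.grid
    xs, ys, zs = grid.coordinate_grids()

    tumour = _sphere(xs, ys, zs, spec.tumour_centre, spec.tumour_radius_mm)
    lungs_full = _ellipsoid(
        xs, ys, zs, spec.left_lung_centre, spec.lung_radii
    ) | _ellipsoid(xs, ys, zs, spec.right_lung_centre, spec.lung_radii)
    if not (lungs_full & tumour).any():
        raise ValueError("tumour does not intersect the lungs on this grid")
    lungs = lungs_full & ~tumour

    # trachea: midline cylinder in the upper mediastinum, plus a carinal bar
    mid_x = 0.5 * (spec.left_lung_centre[0] + spec.right_lung_centre[0])
    mid_y = spec.left_lung_centre[1]
    z_top = spec.left_lung_centre[2] + spec.lung_radii[2]
    carina_z = spec.left_lung_centre[2] + 0.15 * spec.lung_radii[2]
    trachea = ((xs - mid_x) ** 2 + (ys - mid_y) ** 2 <= 12.0**2) & (
        (zs >= carina_z) & (zs <= z_top)
    )
    bronchi = (
        (np.abs(zs - carina_z) <= 8.0)
        & (np.abs(ys - mid_y) <= 10.0)
        & (np.abs(xs - mid_x) <= 45.0)
    )
    airways = trachea | bronchi
    lungs = lungs & ~airways

    ptv = _sphere(xs, ys, zs, spec.tumour_centre, spec.tumour_radius_mm + spec.ptv_margin_mm)

    # analytic dose: plateau inside PTV, exponential penumbra outside
    dist_mm = distance_transform_edt(~ptv, sampling=spec.spacing)
    with np.errstate(under="ignore"):
        dose_arr = spec.prescription_gy * np.exp(-dist_mm / spec.penumbra_mm)
    dose_arr[ptv] = spec.prescription_gy

    # perfusion mean: apex (high z) down-weighted relative to the base
    z_lo = spec.left_lung_centre[2] - spec.lung_radii[2]
    frac_from_base = np.clip((zs - z_lo) / (z_top - z_lo), 0.0, 1.0)
    rel = 1.0 + (spec.apex_scale - 1.0) * frac_from_base
    mean_map = np.where(lungs, spec.mean_counts * rel, 0.0)
    defect = _sphere(xs, ys, zs, spec.tumour_centre, spec.defect_radius_mm)
    mean_map[defect] = 0.0
    if add_noise:
        rng = np.random.default_rng(spec.seed)
        spect_arr = rng.poisson(mean_map).astype(np.float32)
    else:
        spect_arr = mean_map.astype(np.float32)

    geom = dict(spacing=spec.spacing, origin=spec.origin)
    as_mask = lambda a: ImageVolume(a.astype(np.uint8), role="mask", **geom)
    structures = StructureSet(
        lungs=as_mask(lungs),
        gtv_itv=as_mask(tumour),
        ptv=as_mask(ptv),
        central_airways=as_mask(airways),
    )
    dose = ImageVolume(dose_arr.astype(np.float32), role="dose_gy", **geom)
    spect = ImageVolume(spect_arr, role="spect_counts", **geom)
    return dose, spect, structures


@dataclass(frozen=True)
class OutcomeModel:
    """Generative link between dose metrics and clinical outcomes.

    ``P(deterioration) = logistic(beta0 + beta1 * (m - mean(m)))`` for the
    named metric ``m`` (default aV10, %); mean ΔFEV1 is
    ``delta0 - gamma * (m - mean(m))`` with Gaussian noise ``sigma`` (all
    in % of baseline); ``P(RALI) = logistic(alpha0 + alpha1 * (aV50 -
    mean(aV50)))``.  Coefficients are per percentage point of the
    centred metric.
    """

    metric: str = "aV10"
    beta0: float = 0.0
    beta1: float = 0.12
    delta0: float = -8.0
    gamma: float = 0.8
    sigma: float = 8.0
    alpha0: float = -2.2
    alpha1: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class PatientRecord:
    """One simulated patient: dose metrics plus longitudinal outcomes."""

    patient_id: str
    metrics: dict[str, float]
    baseline_fev1_l: float
    fev1_by_month: dict[int, float]
    ctcae_by_month: dict[int, int]
    delta_fev1_pct: float
    true_deterioration: bool
    true_rali: bool

    def __post_init__(self) -> None:
        if self.baseline_fev1_l <= 0:
            raise ValueError("baseline FEV1 must be positive")
        if any(v <= 0 for v in self.fev1_by_month.values()):
            raise ValueError("FEV1 values must be positive")
        if any(g not in range(6) for g in self.ctcae_by_month.values()):
            raise ValueError("CTCAE grades must lie in 0..5")


@dataclass(frozen=True)
class CohortPrior:
    """Distribution over phantom specs for cohort simulation.

    Tumour size, cranio-caudal position, laterality, perfusion-defect
    margin, prescription (60 or 66 Gy) and penumbra vary per patient;
    everything else follows :class:`PhantomSpec` defaults (or the
    ``base`` spec supplied here).
    """

    base: PhantomSpec = field(default_factory=PhantomSpec)
    tumour_radius_range_mm: tuple[float, float] = (10.0, 24.0)
    defect_margin_range_mm: tuple[float, float] = (5.0, 20.0)
    penumbra_range_mm: tuple[float, float] = (12.0, 32.0)
    prescriptions_gy: tuple[float, ...] = (60.0, 66.0)
    axial_offset_frac: float = 0.55

    def sample(self, rng: np.random.Generator) -> PhantomSpec:
        b = self.base
        radius = rng.uniform(*self.tumour_radius_range_mm)
        side = self.base.right_lung_centre if rng.random() < 0.6 else self.base.left_lung_centre
        rx, ry, rz = b.lung_radii
        # offset within the chosen lung, kept safely inside the ellipsoid
        u = rng.uniform(-self.axial_offset_frac, self.axial_offset_frac, size=3)
        centre = (
            side[0] + u[0] * 0.5 * rx,
            side[1] + u[1] * 0.4 * ry,
            side[2] + u[2] * rz,
        )
        return replace(
            b,
            tumour_centre=centre,
            tumour_radius_mm=radius,
            defect_radius_mm=radius + rng.uniform(*self.defect_margin_range_mm),
            penumbra_mm=rng.uniform(*self.penumbra_range_mm),
            prescription_gy=float(rng.choice(self.prescriptions_gy)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )


def _fev1_weight(month: int) -> float:
    # linear ramp to the nadir at 12 months, mild recovery afterwards
    if month <= 12:
        return month / 12.0
    return 1.0 - 0.25 * (month - 12) / 12.0


def simulate_outcomes(
    metrics: pd.DataFrame,
    model: OutcomeModel,
    rng: np.random.Generator,
) -> list[PatientRecord]:
    """Draw spirometry and CTCAE outcomes for a table of dose metrics.

    ΔFEV1 (%) has mean ``delta0 - gamma * centred metric`` and sd
    ``sigma``; it is back-filled into the visit series with its nadir at
    month 12.  The deterioration label is an independent logistic draw on
    the same centred metric; CTCAE grade ≥ 2 (the RALI event) follows a
    logistic draw on centred aV50, placed at an early visit (grade 2
    pneumonitis) two times out of three and otherwise late (fibrosis).
    """
    m = metrics[model.metric].to_numpy(dtype=float)
    m_c = m - m.mean()
    v50_c = metrics["aV50"].to_numpy(dtype=float)
    v50_c = v50_c - v50_c.mean()

    p_det = _logistic(model.beta0 + model.beta1 * m_c)
    p_rali = _logistic(model.alpha0 + model.alpha1 * v50_c)

    records = []
    for i in range(len(metrics)):
        delta = model.delta0 - model.gamma * m_c[i] + rng.normal(0.0, model.sigma)
        delta = float(np.clip(delta, -80.0, 60.0))
        baseline = float(np.clip(rng.normal(2.2, 0.5), 1.0, 4.0))
        fev1 = {
            mo: baseline * (1.0 + delta / 100.0 * _fev1_weight(mo))
            for mo in VISIT_MONTHS
        }
        det = bool(rng.random() < p_det[i])
        rali = bool(rng.random() < p_rali[i])
        grades = {mo: int(rng.random() < 0.3) for mo in VISIT_MONTHS}
        if rali:
            if rng.random() < 2.0 / 3.0:
                grades[3] = 2  # early-phase grade 2 pneumonitis
            else:
                grades[12] = 3  # late-phase fibrosis
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:03d}",
                metrics={k: float(v) for k, v in metrics.iloc[i].items()},
                baseline_fev1_l=baseline,
                fev1_by_month=fev1,
                ctcae_by_month=grades,
                delta_fev1_pct=delta,
                true_deterioration=det,
                true_rali=rali,
            )
        )
    return records


def simulate_cohort(
    n: int,
    model: OutcomeModel | None = None,
    prior: CohortPrior | None = None,
    seed: int | None = None,
    keep_volumes: bool = False,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
):
    """Simulate ``n`` patients: phantom, dose metrics and outcomes.

    Returns ``(records, volumes)`` where ``volumes`` is a list of
    ``(dose, spect, structures)`` triples when ``keep_volumes`` is true
    (``keep_volumes='first'`` retains only the first patient's volumes
    to bound memory; otherwise ``None``).  One shared generator, seeded
    once, drives the whole cohort, so a fixed seed reproduces records
    and volumes exactly.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 patients")
    model = model or OutcomeModel()
    prior = prior or CohortPrior()
    rng = np.random.default_rng(model.seed if seed is None else seed)

    rows = []
    vols = [] if keep_volumes else None
    for i in range(n):
        spec = prior.sample(rng)
        dose, spect, structures = generate_phantom(spec)
        anat = anatomic_lung_volume(structures)
        pset = build_perfusion_set(spect, structures.lungs, thresholds=thresholds)
        rows.append(patient_metrics(dose, anat, pset))
        if keep_volumes is True or (keep_volumes == "first" and i == 0):
            vols.append((dose, spect, structures))
    metrics = pd.DataFrame(rows)
    records = simulate_outcomes(metrics, model, rng)
    return records, vols


def cohort_tables(records: list[PatientRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten records into (metrics, visits) tables.

    ``metrics``: one row per patient with dose metrics, baseline FEV1 and
    generative truth.  ``visits``: one row per patient-visit with FEV1
    (l) and CTCAE grade, the layout written to ``cohort.csv``.
    """
    mrows, vrows = [], []
    for r in records:
        row = {"patient_id": r.patient_id, **r.metrics}
        row["baseline_fev1_l"] = r.baseline_fev1_l
        row["delta_fev1_pct"] = r.delta_fev1_pct
        row["true_deterioration"] = r.true_deterioration
        row["true_rali"] = r.true_rali
        mrows.append(row)
        for mo in sorted(r.fev1_by_month):
            vrows.append(
                {
                    "patient_id": r.patient_id,
                    "month": mo,
                    "fev1_l": r.fev1_by_month[mo],
                    "ctcae_grade": r.ctcae_by_month.get(mo, math.nan),
                }
            )
    return pd.DataFrame(mrows), pd.DataFrame(vrows)
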