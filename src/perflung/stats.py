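"""Clinical-outcome derivations and the statistical battery.

Covers the fractional-change spirometry summary, the median split into
deteriorating vs stable FEV1, CTCAE-based radiation-associated lung
injury (RALI) classification, pooled-variance t-tests, exact and
tie-corrected Mann-Whitney U tests, Bonferroni correction, concordance
ROC analysis with Youden-J cutoffs, and the full per-cohort report
tables comparing anatomic and perfused lung dose-volume metrics between
outcome groups.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SpirometryChange",
    "GroupComparison",
    "TestResult",
    "RocResult",
    "fractional_change",
    "median_split",
    "classify_rali",
    "student_t_test",
    "mann_whitney_u",
    "bonferroni_alpha",
    "roc_analysis",
    "reported_difference",
    "run_full_analysis",
    "AnalysisReport",
]

METRIC_SUFFIXES = ("V5", "V10", "V13", "V20", "V30", "V40", "V50", "MLD_cGy")


@dataclass
class SpirometryChange:
    """Fractional change of a spirometric measure relative to baseline."""

    patient_id: str
    baseline_l: float
    followup_l: float
    change_pct: float
    measure: str = "FEV1"

    def __post_init__(self) -> None:
        expected = 100.0 * (self.followup_l - self.baseline_l) / self.baseline_l
        if not math.isclose(self.change_pct, expected, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("change_pct inconsistent with baseline and follow-up")


def fractional_change(
    visit_values: dict[int, float],
    baseline: float,
    summary_rule: str = "nadir",
    at_month: int | None = None,
    patient_id: str = "",
    measure: str = "FEV1",
) -> SpirometryChange:
    """Summarise follow-up spirometry as a percentage change from baseline.

    ``summary_rule`` selects the follow-up value: ``nadir`` (minimum over
    all follow-up visits, the default), ``last`` (latest visit) or
    ``at_month`` (a fixed visit).  Change is ``100 * (follow-up -
    baseline) / baseline``; negative values indicate deterioration.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    if not visit_values:
        raise ValueError("at least one follow-up visit is required")
    if summary_rule == "nadir":
        follow = min(visit_values.values())
    elif summary_rule == "last":
        follow = visit_values[max(visit_values)]
    elif summary_rule == "at_month":
        if at_month is None or at_month not in visit_values:
            raise ValueError(f"no visit at month {at_month}")
        follow = visit_values[at_month]
    else:
        raise ValueError(f"unknown summary rule {summary_rule!r}")
    change = 100.0 * (follow - baseline) / baseline
    return SpirometryChange(patient_id, baseline, follow, change, measure)


def median_split(changes: list[SpirometryChange]) -> pd.Series:
    """Split patients at the median fractional change.

    ``change < median`` labels a patient "deteriorating"; ``change >=
    median`` (including the median patient) labels them "stable", so an
    odd cohort with distinct values splits (n-1)/2 vs (n+1)/2.
    """
    if len(changes) < 2:
        raise ValueError("median split needs at least 2 patients")
    vals = np.array([c.change_pct for c in changes])
    if np.ptp(vals) == 0:
        raise ValueError("all changes identical; median split is degenerate")
    med = float(np.median(vals))
    labels = np.where(vals < med, "deteriorating", "stable")
    return pd.Series(labels, index=[c.patient_id for c in changes], name="fev1_group")


def classify_rali(
    grades_by_month: dict[int, int], window: str = "any"
) -> bool | None:
    """Classify an event from per-visit CTCAE grades.

    ``window='early'`` uses visits up to and including 6 months (the
    radiation-pneumonitis window); ``window='any'`` uses all visits over
    0-24 months (RALI: pneumonitis or late fibrosis).  The event is a
    worst in-window grade >= 2.  Returns ``None`` when no visit falls in
    the window (patient excluded from that analysis).
    """
    if window not in ("early", "any"):
        raise ValueError("window must be 'early' or 'any'")
    if any(g not in range(6) for g in grades_by_month.values()):
        raise ValueError("CTCAE grades must lie in 0..5")
    horizon = 6 if window == "early" else 24
    in_window = [g for mo, g in grades_by_month.items() if 0 <= mo <= horizon]
    if not in_window:
        return None
    return max(in_window) >= 2


@dataclass
class TestResult:
    p_value: float
    difference: float
    statistic: float = math.nan


def student_t_test(group_a, group_b) -> TestResult:
    """Two-sided independent Student's t-test (pooled variance).

    ``difference`` is ``mean(group_b) - mean(group_a)``; call with the
    reference (stable) group first.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if sp2 == 0:
        raise ValueError("zero pooled variance; t-test undefined")
    res = sps.ttest_ind(a, b, equal_var=True)
    return TestResult(
        p_value=float(res.pvalue),
        difference=float(b.mean() - a.mean()),
        statistic=float(res.statistic),
    )


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    # pairs where a > b count 1, ties count 0.5
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_u(group_a, group_b, exact_max_n: int = 12) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact by enumeration of all label assignments when the pooled sample
    size is at most ``exact_max_n`` (the two-sided p-value is the
    fraction of assignments at least as far from the null mean
    ``n_a n_b / 2`` as observed); otherwise a tie-corrected normal
    approximation with a 0.5 continuity correction.  Ties contribute 0.5
    to U in both branches.
    ``difference`` is ``median(group_b) - median(group_a)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least 1 value")
    u_obs = _u_statistic(a, b)
    n_a, n_b = a.size, b.size
    mu = n_a * n_b / 2.0
    diff = float(np.median(b) - np.median(a))

    if n_a + n_b <= exact_max_n:
        pooled = np.concatenate([a, b])
        dev_obs = abs(u_obs - mu) - 1e-12
        hits = total = 0
        for idx in itertools.combinations(range(n_a + n_b), n_a):
            sel = np.zeros(n_a + n_b, dtype=bool)
            sel[list(idx)] = True
            u = _u_statistic(pooled[sel], pooled[~sel])
            total += 1
            if abs(u - mu) >= dev_obs:
                hits += 1
        return TestResult(p_value=hits / total, difference=diff, statistic=u_obs)

    # tie-corrected normal approximation with continuity correction
    pooled = np.concatenate([a, b])
    n = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return TestResult(p_value=1.0, difference=diff, statistic=u_obs)
    z = max(0.0, abs(u_obs - mu) - 0.5) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(z)
    return TestResult(p_value=min(1.0, float(p)), difference=diff, statistic=u_obs)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-comparison significance threshold ``alpha / m``."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be at least 1")
    return alpha / m


@dataclass
class RocResult:
    auc: float
    cutoff: float
    sensitivity_pct: float
    specificity_pct: float
    curve: pd.DataFrame = field(repr=False, default=None)


def roc_analysis(values, labels) -> RocResult:
    """ROC analysis of a continuous metric against a binary outcome.

    AUC is the pairwise concordance probability (ties 0.5), identical to
    ``U / (n1 n0)`` from the Mann-Whitney statistic.  The curve sweeps
    every observed value as an inclusive ``metric >= cutoff`` positivity
    rule; the optimal cutoff maximises Youden J = sensitivity +
    specificity - 1, ties resolved toward the lower cutoff.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(bool)
    if x.shape != y.shape:
        raise ValueError("values and labels must align")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC analysis needs both outcome classes")

    pos, neg = x[y], x[~y]
    auc = _u_statistic(pos, neg) / (n_pos * n_neg)

    cutoffs = np.unique(x)
    rows = [
        {"cutoff": math.inf, "sensitivity": 0.0, "specificity": 1.0, "youden_j": 0.0}
    ]
    best = (-math.inf, math.inf)  # (J, cutoff); prefer higher J then lower cutoff
    for c in cutoffs[::-1]:
        sens = float((pos >= c).mean())
        spec = float((neg < c).mean())
        j = sens + spec - 1.0
        rows.append(
            {"cutoff": float(c), "sensitivity": sens, "specificity": spec, "youden_j": j}
        )
        if j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and c < best[1]):
            best = (j, float(c))
    curve = pd.DataFrame(rows)
    at = curve[curve["cutoff"] == best[1]].iloc[0]
    return RocResult(
        auc=float(auc),
        cutoff=best[1],
        sensitivity_pct=100.0 * float(at["sensitivity"]),
        specificity_pct=100.0 * float(at["specificity"]),
        curve=curve,
    )


def reported_difference(stable_summary: float, deteriorating_summary: float, ndigits: int = 1) -> float:
    """Difference column of the report tables: affected-group summary minus
    reference-group summary, rounded to the printed precision."""
    return round(deteriorating_summary - stable_summary, ndigits)


@dataclass
class GroupComparison:
    """One report-table row comparing a dose metric between two groups."""

    metric: str
    summary_a: float
    summary_b: float
    difference: float
    test: str
    p_value: float
    significant: bool
    auc: float = math.nan
    cutoff: float = math.nan
    sensitivity_pct: float = math.nan
    specificity_pct: float = math.nan

    def __post_init__(self) -> None:
        if not math.isnan(self.auc) and not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")


@dataclass
class AnalysisReport:
    """All report tables for one cohort (FEV1 and RALI comparisons plus
    the anatomic-vs-perfused absolute-volume comparison)."""

    labels: pd.DataFrame
    fev1_anatomic: pd.DataFrame
    fev1_perfused: pd.DataFrame
    rali_perfused: pd.DataFrame
    rali_anatomic: pd.DataFrame
    pneumonitis_perfused: pd.DataFrame
    volume_comparison: pd.DataFrame
    roc_curves: pd.DataFrame
    alpha: float
    m_comparisons: int

    @property
    def bonferroni_threshold(self) -> float:
        return bonferroni_alpha(self.alpha, self.m_comparisons)


def _comparison_table(
    metrics: pd.DataFrame,
    event: pd.Series,
    prefix: str,
    test: str,
    threshold: float,
    curves: list,
    table_name: str,
) -> pd.DataFrame:
    """One table: eight metric rows (V5..V50, MLD) compared between groups."""
    rows = []
    for suffix in METRIC_SUFFIXES:
        col = f"{prefix}{suffix}"
        name = col.replace("_cGy", " (cGy)")
        vals = metrics[col]
        grp_ref = vals[~event].to_numpy(dtype=float)
        grp_evt = vals[event].to_numpy(dtype=float)
        if len(grp_ref) == 0 or len(grp_evt) == 0:
            rows.append(
                {
                    "metric": name,
                    "group_ref": np.nan,
                    "group_event": np.nan,
                    "difference": np.nan,
                    "test": test,
                    "p_value": np.nan,
                    "significant": False,
                    "auc": np.nan,
                    "cutoff": np.nan,
                    "sensitivity_pct": np.nan,
                    "specificity_pct": np.nan,
                    "note": "not estimable (one group empty)",
                }
            )
            continue
        if test == "student_t":
            res = student_t_test(grp_ref, grp_evt)
            s_ref, s_evt = float(grp_ref.mean()), float(grp_evt.mean())
        else:
            res = mann_whitney_u(grp_ref, grp_evt)
            s_ref, s_evt = float(np.median(grp_ref)), float(np.median(grp_evt))
        roc = roc_analysis(
            vals[event.index].to_numpy(dtype=float), event.to_numpy()
        )
        c = roc.curve.copy()
        c.insert(0, "metric", name)
        c.insert(0, "table", table_name)
        curves.append(c)
        rows.append(
            {
                "metric": name,
                "group_ref": s_ref,
                "group_event": s_evt,
                "difference": res.difference,
                "test": test,
                "p_value": res.p_value,
                "significant": bool(res.p_value < threshold),
                "auc": roc.auc,
                "cutoff": roc.cutoff,
                "sensitivity_pct": roc.sensitivity_pct,
                "specificity_pct": roc.specificity_pct,
                "note": "",
            }
        )
    return pd.DataFrame(rows)


def run_full_analysis(
    metrics: pd.DataFrame,
    visits: pd.DataFrame,
    alpha: float = 0.05,
    m_comparisons: int = 8,
    summary_rule: str = "nadir",
    rali_window: str = "any",
) -> AnalysisReport:
    """Run the complete outcome battery on a cohort.

    Parameters
    ----------
    metrics : DataFrame
        One row per patient with columns ``patient_id``,
        ``baseline_fev1_l``, the aVx/pVx/MLD metrics and the absolute
        structure volumes (``anat_ml``, ``p20_ml`` ...).
    visits : DataFrame
        One row per patient-visit: ``patient_id``, ``month``, ``fev1_l``,
        ``ctcae_grade``.

    Produces four comparison tables (anatomic and perfused metrics vs the
    ΔFEV1 median split; perfused and anatomic metrics vs RALI), an early
    pneumonitis table, and the anatomic-vs-perfused absolute-volume
    comparison (one-way ANOVA plus pairwise tests).  Each table has
    eight metric rows (V5...V50 and MLD), the Bonferroni divisor.
    """
    required = {"patient_id", "baseline_fev1_l"}
    missing = sorted(required - set(metrics.columns))
    for prefix in ("a", "p"):
        missing += sorted(
            f"{prefix}{s}" for s in METRIC_SUFFIXES if f"{prefix}{s}" not in metrics.columns
        )
    if missing:
        raise ValueError(f"metrics table is missing columns: {missing}")
    metrics = metrics.set_index("patient_id", drop=False)
    threshold = bonferroni_alpha(alpha, m_comparisons)

    # --- ΔFEV1 median split -------------------------------------------------
    changes = []
    for pid, grp in visits.groupby("patient_id"):
        series = {
            int(r.month): float(r.fev1_l)
            for r in grp.itertuples()
            if np.isfinite(r.fev1_l)
        }
        if not series:
            continue
        baseline = float(metrics.loc[pid, "baseline_fev1_l"])
        changes.append(
            fractional_change(series, baseline, summary_rule=summary_rule, patient_id=pid)
        )
    groups = median_split(changes)
    det = groups == "deteriorating"

    # --- CTCAE classifications ----------------------------------------------
    rali, pneum = {}, {}
    for pid, grp in visits.groupby("patient_id"):
        grades = {
            int(r.month): int(r.ctcae_grade)
            for r in grp.itertuples()
            if np.isfinite(r.ctcae_grade)
        }
        rali[pid] = classify_rali(grades, window=rali_window)
        pneum[pid] = classify_rali(grades, window="early")
    rali_s = pd.Series(rali, name="rali").dropna().astype(bool)
    pneum_s = pd.Series(pneum, name="pneumonitis").dropna().astype(bool)

    curves: list = []
    fev1_a = _comparison_table(
        metrics.loc[det.index], det, "a", "student_t", threshold, curves, "fev1_anatomic"
    )
    fev1_p = _comparison_table(
        metrics.loc[det.index], det, "p", "student_t", threshold, curves, "fev1_perfused"
    )

    def _event_table(series: pd.Series, prefix: str, name: str) -> pd.DataFrame:
        sub = metrics.loc[series.index]
        if series.nunique() < 2:
            rows = [
                {
                    "metric": f"{prefix}{s}".replace("_cGy", " (cGy)"),
                    "group_ref": np.nan,
                    "group_event": np.nan,
                    "difference": np.nan,
                    "test": "mann_whitney",
                    "p_value": np.nan,
                    "significant": False,
                    "auc": np.nan,
                    "cutoff": np.nan,
                    "sensitivity_pct": np.nan,
                    "specificity_pct": np.nan,
                    "note": "not estimable (no events)"
                    if not series.any()
                    else "not estimable (all events)",
                }
                for s in METRIC_SUFFIXES
            ]
            return pd.DataFrame(rows)
        return _comparison_table(sub, series, prefix, "mann_whitney", threshold, curves, name)

    rali_p = _event_table(rali_s, "p", "rali_perfused")
    rali_a = _event_table(rali_s, "a", "rali_anatomic")
    pneum_p = _event_table(pneum_s, "p", "pneumonitis_perfused")

    # --- absolute-volume comparison (anatomic vs perfused thresholds) -------
    vol_cols = ["anat_ml"] + [
        c for c in ("p20_ml", "p25_ml", "p30_ml", "p40_ml", "p50_ml") if c in metrics
    ]
    vol_rows = []
    if len(vol_cols) >= 2:
        samples = [metrics[c].to_numpy(dtype=float) for c in vol_cols]
        anova = sps.f_oneway(*samples)
        for c in vol_cols[1:]:
            t = student_t_test(metrics[c], metrics["anat_ml"])
            vol_rows.append(
                {
                    "structure": c.replace("_ml", ""),
                    "mean_ml": float(metrics[c].mean()),
                    "sd_ml": float(metrics[c].std(ddof=1)),
                    "anatomic_mean_ml": float(metrics["anat_ml"].mean()),
                    "pairwise_p": t.p_value,
                    "significant": bool(t.p_value < threshold),
                    "anova_p": float(anova.pvalue),
                }
            )
    volume_comparison = pd.DataFrame(vol_rows)

    labels = pd.DataFrame(
        {
            "fev1_group": groups,
            "rali": pd.Series(rali),
            "pneumonitis": pd.Series(pneum),
        }
    )
    labels.index.name = "patient_id"

    return AnalysisReport(
        labels=labels.reset_index(),
        fev1_anatomic=fev1_a,
        fev1_perfused=fev1_p,
        rali_perfused=rali_p,
        rali_anatomic=rali_a,
        pneumonitis_perfused=pneum_p,
        volume_comparison=volume_comparison,
        roc_curves=pd.concat(curves, ignore_index=True) if curves else pd.DataFrame(),
        alpha=alpha,
        m_comparisons=m_comparisons,
    )
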