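"""End-to-end orchestration: simulate -> segment -> dvh -> analyze -> report.

A run is driven by a JSON-serialisable config and writes every artefact
under a run directory together with the resolved config and a log, so
that config + seed regenerate all numbers exactly.  Figures are drawn
from the exported CSVs, never from in-memory state, so all plotted data
is independently checkable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from datetime import datetime
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .dosimetry import cumulative_dvh
from .perfusion import DEFAULT_THRESHOLDS, anatomic_lung_volume, build_perfusion_set
from .stats import run_full_analysis
from .synthetic import CohortPrior, OutcomeModel, cohort_tables, simulate_cohort
from .volume import write_volume

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline", "render_report"]

logger = logging.getLogger("perflung")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {"n": 20},
    "thresholds": list(DEFAULT_THRESHOLDS),
    "stats": {
        "alpha": 0.05,
        "m_comparisons": 8,
        "summary_rule": "nadir",
        "rali_window": "any",
    },
    "write_volumes": False,
}

_TABLE_FILES = {
    "fev1_anatomic": "table3.csv",
    "fev1_perfused": "table4.csv",
    "rali_perfused": "table5.csv",
    "rali_anatomic": "table_rali_anatomic.csv",
    "pneumonitis_perfused": "table_pneumonitis.csv",
    "volume_comparison": "table2_volumes.csv",
}


def validate_config(config: dict) -> dict:
    """Merge a user config over the defaults, aggregating every error."""
    errors: list[str] = []
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if key in ("simulate", "stats") and isinstance(val, dict):
            merged[key].update(val)
        elif key in merged or key in ("inputs", "outcome_model", "prior"):
            merged[key] = val
        else:
            errors.append(f"unknown config key: {key!r}")
    if not isinstance(merged["seed"], int):
        errors.append("seed must be an integer")
    n = merged["simulate"].get("n")
    if not (isinstance(n, int) and n >= 2):
        errors.append("simulate.n must be an integer >= 2")
    ts = merged["thresholds"]
    if not ts or any(not (0 < t < 1) for t in ts):
        errors.append("thresholds must be fractions in (0, 1)")
    if 0.20 not in [round(t, 6) for t in ts]:
        errors.append("thresholds must include 0.20 (the perfused organ-at-risk)")
    st = merged["stats"]
    if not (0 < st["alpha"] < 1):
        errors.append("stats.alpha must lie in (0, 1)")
    if st["m_comparisons"] < 1:
        errors.append("stats.m_comparisons must be >= 1")
    if st["summary_rule"] not in ("nadir", "last", "at_month"):
        errors.append("stats.summary_rule must be nadir|last|at_month")
    if st["rali_window"] not in ("early", "any"):
        errors.append("stats.rali_window must be early|any")
    inputs = merged.get("inputs") or {}
    for role, path in inputs.items():
        if not Path(path).exists():
            errors.append(f"inputs.{role}: no such file: {path}")
    if errors:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(errors))
    return merged


def run_pipeline(config: dict, outdir: str | Path, timestamp: bool = True) -> Path:
    """Execute the full pipeline for one config; return the run directory."""
    cfg = validate_config(config)
    outdir = Path(outdir)
    if timestamp:
        run_dir = outdir / datetime.now().strftime("run-%Y%m%d-%H%M%S")
    else:
        run_dir = outdir
    run_dir.mkdir(parents=True, exist_ok=True)

    log_path = run_dir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        (run_dir / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True))
        seed = cfg["seed"]
        n = cfg["simulate"]["n"]
        model = OutcomeModel(**cfg.get("outcome_model", {}), seed=seed)
        prior = CohortPrior()
        logger.info("simulating cohort: n=%d seed=%d", n, seed)
        records, vols = simulate_cohort(
            n,
            model=model,
            prior=prior,
            seed=seed,
            keep_volumes=True if cfg["write_volumes"] else "first",
            thresholds=tuple(cfg["thresholds"]),
        )
        metrics, visits = cohort_tables(records)
        metrics.to_csv(run_dir / "metrics.csv", index=False)
        visits.to_csv(run_dir / "cohort.csv", index=False)

        if cfg["write_volumes"] and vols:
            vol_dir = run_dir / "volumes"
            vol_dir.mkdir(exist_ok=True)
            for rec, (dose, spect, structures) in zip(records, vols):
                write_volume(dose, vol_dir / f"{rec.patient_id}_dose.nii.gz")
                write_volume(spect, vol_dir / f"{rec.patient_id}_spect.nii.gz")
                write_volume(structures.lungs, vol_dir / f"{rec.patient_id}_lungs.nii.gz")

        # example DVH export for the first patient (anatomic and p20 lung)
        if vols:
            dose, spect, structures = vols[0]
            anat = anatomic_lung_volume(structures)
            pset = build_perfusion_set(
                spect, structures.lungs, thresholds=tuple(cfg["thresholds"])
            )
            rows = []
            for name, mask in (("anatomic", anat), ("p20", pset.p20)):
                dvh = cumulative_dvh(dose, mask, structure=name)
                rows.append(
                    pd.DataFrame(
                        {
                            "structure": name,
                            "dose_gy": dvh.bin_edges_gy,
                            "volume_pct": dvh.cumulative_pct,
                        }
                    )
                )
            pd.concat(rows, ignore_index=True).to_csv(run_dir / "dvh.csv", index=False)

        logger.info("running outcome analysis")
        report = run_full_analysis(metrics, visits, **cfg["stats"])
        for attr, fname in _TABLE_FILES.items():
            getattr(report, attr).to_csv(run_dir / fname, index=False)
        report.labels.to_csv(run_dir / "labels.csv", index=False)
        report.roc_curves.to_csv(run_dir / "roc_curves.csv", index=False)
        summary = {
            "n_patients": n,
            "seed": seed,
            "bonferroni_threshold": report.bonferroni_threshold,
            "alpha": report.alpha,
            "m_comparisons": report.m_comparisons,
        }
        (run_dir / "summary.json").write_text(json.dumps(summary, indent=2))
        logger.info("run complete: %s", run_dir)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return run_dir


def render_report(run_dir: str | Path) -> Path:
    """Render figures and a markdown summary from a run directory's CSVs."""
    run_dir = Path(run_dir)
    gaps: list[str] = []

    # Figure-2 analogue: boxplot of absolute volumes per structure
    metrics_path = run_dir / "metrics.csv"
    if metrics_path.exists():
        metrics = pd.read_csv(metrics_path)
        vol_cols = [c for c in metrics.columns if c.endswith("_ml")]
        order = ["anat_ml"] + sorted(
            [c for c in vol_cols if c != "anat_ml"],
            key=lambda c: int(c.strip("p_ml")),
        )
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.boxplot(
            [metrics[c] for c in order], tick_labels=[c.replace("_ml", "") for c in order]
        )
        ax.set_ylabel("absolute volume (ml)")
        ax.set_title("Anatomic vs perfused lung volumes")
        fig.tight_layout()
        fig.savefig(run_dir / "volumes_boxplot.png", dpi=120)
        plt.close(fig)
    else:
        gaps.append("metrics.csv missing: volumes boxplot skipped")

    # Figure-3/4 analogue: ROC curves
    roc_path = run_dir / "roc_curves.csv"
    if roc_path.exists() and roc_path.stat().st_size > 1:
        roc = pd.read_csv(roc_path)
        if len(roc):
            for table, grp in roc.groupby("table"):
                fig, ax = plt.subplots(figsize=(5, 5))
                for metric, c in grp.groupby("metric"):
                    c = c.sort_values("sensitivity")
                    ax.plot(1 - c["specificity"], c["sensitivity"], label=metric, lw=1)
                ax.plot([0, 1], [0, 1], "k--", lw=0.7)
                ax.set_xlabel("1 - specificity")
                ax.set_ylabel("sensitivity")
                ax.set_title(f"ROC: {table}")
                ax.legend(fontsize=6)
                fig.tight_layout()
                fig.savefig(run_dir / f"roc_{table}.png", dpi=120)
                plt.close(fig)
        else:
            gaps.append("roc_curves.csv empty: ROC figures skipped")
    else:
        gaps.append("roc_curves.csv missing: ROC figures skipped")

    # Figure-1 analogue: DVH overlay
    dvh_path = run_dir / "dvh.csv"
    if dvh_path.exists():
        dvh = pd.read_csv(dvh_path)
        fig, ax = plt.subplots(figsize=(6, 4))
        for name, c in dvh.groupby("structure"):
            ax.plot(c["dose_gy"], c["volume_pct"], label=name)
        ax.set_xlabel("dose (Gy)")
        ax.set_ylabel("volume (%)")
        ax.set_title("Cumulative DVH (patient 1)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(run_dir / "dvh_overlay.png", dpi=120)
        plt.close(fig)
    else:
        gaps.append("dvh.csv missing: DVH overlay skipped")

    lines = ["# Run report", ""]
    summary_path = run_dir / "summary.json"
    if summary_path.exists():
        summary = json.loads(summary_path.read_text())
        lines += [f"- {k}: {v}" for k, v in summary.items()]
    for attr, fname in _TABLE_FILES.items():
        path = run_dir / fname
        if not path.exists():
            gaps.append(f"{fname} missing: {attr} table omitted")
            continue
        df = pd.read_csv(path)
        lines += ["", f"## {attr}", "", "```", df.to_string(index=False), "```"]
    if (run_dir / "table5.csv").exists():
        t5 = pd.read_csv(run_dir / "table5.csv")
        if "note" in t5 and t5["note"].fillna("").str.contains("not estimable").any():
            gaps.append("RALI comparison not estimable (degenerate event groups)")
    if gaps:
        lines += ["", "## Gaps", ""] + [f"- {g}" for g in gaps]
    out = run_dir / "report.md"
    out.write_text("\n".join(lines) + "\n")
    return out
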