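"""End-to-end orchestration: simulate or load -> segment -> features -> fit.

The functions here bind the sensor modules and the mixed-effects layer into
the full analysis: per-run turn-feature extraction from the insole traces,
trial/subject exclusions, the on-snow eq1 fits for the five force outcomes,
the eq3 fits for the static pressure outcomes, and the eq2 fits for the
(transformed) subjective scores.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .effects_stats import EffectEstimate, fit_model, summarize_effects, transform_fit_score
from .force_features import (
    ForceTrace,
    apply_exclusions,
    enforce_alternation,
    extract_turn_features,
    features_to_frame,
    segment_turns_force,
    total_force,
)
from .static_pressure import build_region_scheme, dorsal_metrics, plantar_region_metrics
from .synthetic_data import CohortBundle, RunBundle, SUBJECTIVE_ITEMS

logger = logging.getLogger(__name__)

FORCE_OUTCOMES = (
    "peak_downhill_force", "rfd", "time_to_peak", "peak_uphill_force", "average_force",
)
# items rated 0-10 where 5 is the optimum; folded to |score - 5| before eq2
FOLDED_ITEMS = ("forefoot", "midfoot", "heel", "cuff")

__all__ = [
    "FORCE_OUTCOMES",
    "FOLDED_ITEMS",
    "run_force_pipeline",
    "cohort_turn_features",
    "static_observations",
    "subjective_observations",
    "run_pipeline",
    "load_cohort",
    "validate_inputs",
]


def run_force_pipeline(
    left: ForceTrace,
    right: ForceTrace,
    metadata: dict,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Turn features for one run: truncate, segment, alternate, extract."""
    cfg = config or PipelineConfig()
    left = left.truncate(cfg.analysis_window_s)
    right = right.truncate(cfg.analysis_window_s)
    totals = {"left": total_force(left), "right": total_force(right)}
    extrema = segment_turns_force(
        totals["left"], totals["right"],
        cutoff=cfg.segmentation_cutoff_hz,
        min_separation=cfg.min_separation_s,
        prominence_factor=cfg.prominence_factor,
    )
    retained = enforce_alternation(extrema["left"].maxima, extrema["right"].maxima)
    feats = extract_turn_features(
        left, right, extrema, retained, metadata,
        feature_cutoff=cfg.feature_cutoff_hz,
        peak_window_half_s=cfg.peak_window_half_s,
        refine_half_s=cfg.refine_half_s,
    )
    return features_to_frame(feats)


def cohort_turn_features(
    runs: list[RunBundle], config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Per-turn features for every run, with exclusions applied."""
    cfg = config or PipelineConfig()
    frames = []
    for run in runs:
        meta = {
            "subject_id": run.subject_id,
            "config": run.config,
            "trial_no": run.trial_no,
        }
        frames.append(run_force_pipeline(run.force_left, run.force_right, meta, cfg))
    features = pd.concat([f for f in frames if not f.empty], ignore_index=True)
    kept, report = apply_exclusions(
        features, cfg.min_turns_per_trial, cfg.subject_drop_fraction
    )
    for trial in report["dropped_trials"]:
        logger.info("excluded trial %s: fewer than %d turns", trial, cfg.min_turns_per_trial)
    for s in report["excluded_subjects"]:
        logger.info("excluded subject %s", s)
    return kept, report


def static_observations(
    statics, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Tidy eq3 observation table from static trials.

    One row per subject x condition with the dorsal whole-pad metrics and the
    eight regional plantar peak pressures / contact areas as columns, plus
    the shell-overlap covariate.
    """
    cfg = config or PipelineConfig()
    rows = []
    for st in statics:
        d = dorsal_metrics(st.dorsal, cfg.contact_threshold_kpa)
        scheme = build_region_scheme(st.plantar)
        regions = plantar_region_metrics(st.plantar, scheme, cfg.contact_threshold_kpa)
        row = {
            "subject_id": st.truth.subject_id,
            "condition": st.truth.condition,
            "config": st.truth.config,
            "overlap": st.truth.overlap,
            "dorsal_mean": d.mean_pressure,
            "dorsal_sd": d.sd_pressure,
            "dorsal_total": d.total_pressure,
            "dorsal_peak": d.peak_pressure,
            "dorsal_contact_area": d.contact_area,
        }
        for name, metrics in regions.items():
            row[f"{name}_peak"] = metrics["peak_pressure"]
            row[f"{name}_area"] = metrics["contact_area"]
        rows.append(row)
    return pd.DataFrame(rows)


def subjective_observations(subjective: pd.DataFrame) -> pd.DataFrame:
    """Apply the optimal-fit fold to the regional items ahead of eq2."""
    df = subjective.copy()
    for item in FOLDED_ITEMS:
        df[item] = [transform_fit_score(s) for s in df[item]]
    return df


@dataclass
class PipelineReport:
    turn_features: pd.DataFrame
    exclusions: dict
    estimates: list
    summary: pd.DataFrame
    static_table: pd.DataFrame
    subjective_table: pd.DataFrame


def run_pipeline(bundle: CohortBundle, config: PipelineConfig | None = None) -> PipelineReport:
    """Full analysis of a cohort bundle; returns all tables and model fits."""
    cfg = config or PipelineConfig()
    features, report = cohort_turn_features(bundle.runs, cfg)
    estimates: list[EffectEstimate] = []
    for outcome in FORCE_OUTCOMES:
        estimates.append(fit_model(features, "eq1", outcome))
    static_table = static_observations(bundle.statics, cfg) if bundle.statics else pd.DataFrame()
    if not static_table.empty:
        for outcome in ("dorsal_mean", "dorsal_sd", "dorsal_total", "dorsal_peak",
                        "dorsal_contact_area", "lateral_heel_peak",
                        "medial_midfoot_peak", "lateral_midfoot_peak"):
            estimates.append(fit_model(static_table, "eq3", outcome))
    subj = subjective_observations(bundle.subjective) if not bundle.subjective.empty else pd.DataFrame()
    if not subj.empty:
        for item in SUBJECTIVE_ITEMS:
            estimates.append(fit_model(subj, "eq2", item))
    summary = summarize_effects(estimates, cfg.alpha)
    return PipelineReport(
        turn_features=features,
        exclusions=report,
        estimates=estimates,
        summary=summary,
        static_table=static_table,
        subjective_table=subj,
    )


# ---------------------------------------------------------------------------
# on-disk cohorts


def load_cohort(root) -> CohortBundle:
    """Load a cohort written in the documented directory layout.

    Expects ``cohort/<subject>/<config>/trial<N>/{imu,force}_{left,right}.csv``,
    ``static/<subject>/<condition>/{dorsal,plantar}.csv`` with JSON sidecars
    and ``meta.json``, and ``subjective.csv``.  IMU files are optional per
    run; missing force files are an error.
    """
    from .force_features import ForceTrace
    from .imu_edge import KinematicTrace
    from .signal_core import UniformSeries
    from .static_pressure import PressureGrid
    from .synthetic_data import CohortBundle, RunBundle, RunTruth, SimConfig

    root = Path(root)
    runs = []
    cohort_dir = root / "cohort"
    if not cohort_dir.is_dir():
        raise FileNotFoundError(f"{cohort_dir} not found")
    for subj_dir in sorted(cohort_dir.iterdir()):
        for cfg_dir in sorted(p for p in subj_dir.iterdir() if p.is_dir()):
            for trial_dir in sorted(p for p in cfg_dir.iterdir() if p.is_dir()):
                trial_no = int(trial_dir.name.replace("trial", ""))
                for name in ("force_left.csv", "force_right.csv"):
                    if not (trial_dir / name).exists():
                        raise FileNotFoundError(f"missing {trial_dir / name}")
                imu = {}
                for side in ("left", "right"):
                    p = trial_dir / f"imu_{side}.csv"
                    if p.exists():
                        imu[side] = KinematicTrace(UniformSeries.from_csv(p), side)
                    else:
                        imu[side] = KinematicTrace(
                            UniformSeries(np.zeros(2), 1125.0), side
                        )
                truth = RunTruth(
                    subject_id=subj_dir.name, config=cfg_dir.name, trial_no=trial_no,
                    flat_times=np.array([]), turns=[], gyro_bias={},
                )
                runs.append(
                    RunBundle(
                        subject_id=subj_dir.name, config=cfg_dir.name,
                        trial_no=trial_no,
                        imu_left=imu["left"], imu_right=imu["right"],
                        force_left=ForceTrace.from_csv(trial_dir / "force_left.csv", "left"),
                        force_right=ForceTrace.from_csv(trial_dir / "force_right.csv", "right"),
                        truth=truth,
                    )
                )
    statics = []
    static_dir = root / "static"
    if static_dir.is_dir():
        for subj_dir in sorted(static_dir.iterdir()):
            for cond_dir in sorted(p for p in subj_dir.iterdir() if p.is_dir()):
                meta = json.loads((cond_dir / "meta.json").read_text())
                truth = SimpleNamespace(
                    subject_id=subj_dir.name, condition=cond_dir.name,
                    config=meta["config"], overlap=float(meta["overlap"]),
                )
                statics.append(
                    SimpleNamespace(
                        dorsal=PressureGrid.from_files(cond_dir / "dorsal.csv"),
                        plantar=PressureGrid.from_files(cond_dir / "plantar.csv"),
                        truth=truth,
                    )
                )
    subj_path = root / "subjective.csv"
    subjective = pd.read_csv(subj_path) if subj_path.exists() else pd.DataFrame()
    subject_ids = sorted({r.subject_id for r in runs})
    return CohortBundle(
        config=SimConfig(n_subjects=max(len(subject_ids), 1)),
        runs=runs, statics=statics, subjective=subjective,
        subject_ids=subject_ids,
    )


def validate_inputs(root) -> dict:
    """Structural validation of an on-disk cohort tree.

    Checks column names, sampling uniformity (within 1%, no gaps over two
    nominal intervals), force non-negativity, dorsal grid geometry (18 x 10)
    and manifest completeness.  Returns ``{"failures": [...], "n_checked":
    int}``; an empty failure list means the tree is well-formed.
    """
    from .static_pressure import DORSAL_SHAPE

    root = Path(root)
    failures: list[str] = []
    n_checked = 0

    def check_uniform(path, cols):
        nonlocal n_checked
        n_checked += 1
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            failures.append(f"{path}: unreadable ({exc})")
            return
        missing = set(cols) - set(df.columns)
        if missing:
            failures.append(f"{path}: missing columns {sorted(missing)}")
            return
        t = df["time_s"].to_numpy(float)
        if t.size < 2:
            failures.append(f"{path}: fewer than 2 samples")
            return
        dt = np.diff(t)
        med = float(np.median(dt))
        if med <= 0 or np.any(np.abs(dt - med) > 0.01 * med):
            failures.append(f"{path}: non-uniform sampling")
        if np.any(dt > 2.0 * med):
            failures.append(f"{path}: time gap exceeding two sample intervals")
        value_cols = [c for c in cols if c != "time_s"]
        if value_cols and np.any(df[value_cols].to_numpy(float) < 0):
            failures.append(f"{path}: negative force values")

    cohort_dir = root / "cohort"
    if cohort_dir.is_dir():
        for trial_dir in sorted(cohort_dir.glob("*/*/trial*")):
            for side in ("left", "right"):
                fp = trial_dir / f"force_{side}.csv"
                if fp.exists():
                    check_uniform(
                        fp, ["time_s", "heel_n", "medial_forefoot_n", "lateral_forefoot_n"]
                    )
                else:
                    failures.append(f"{fp}: missing")
                ip = trial_dir / f"imu_{side}.csv"
                if ip.exists():
                    n_checked += 1
                    df = pd.read_csv(ip)
                    if not {"time_s", "value"}.issubset(df.columns):
                        failures.append(f"{ip}: missing columns")
    static_dir = root / "static"
    if static_dir.is_dir():
        for dorsal in sorted(static_dir.glob("*/*/dorsal.csv")):
            n_checked += 1
            grid = np.loadtxt(dorsal, delimiter=",", ndmin=2)
            if grid.shape != DORSAL_SHAPE:
                failures.append(
                    f"{dorsal}: dorsal grid is {grid.shape}, expected {DORSAL_SHAPE}"
                )
    manifest_path = root / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        for rel in manifest:
            n_checked += 1
            if not (root / rel).exists():
                failures.append(f"{rel}: listed in manifest but absent")
    return {"failures": failures, "n_checked": n_checked}
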