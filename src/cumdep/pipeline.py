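"""End-to-end pipeline: simulate/load -> validate -> classify -> derive
exposures -> calibrate VIM -> find cutoff -> fit the model ladder -> report.

Every stage writes its intermediate table as CSV under the run's output
directory so each report row is traceable; `metadata.json` stamps the seed,
cutoff source and value, VIM calibration, time origin, ties method and a
hash of the configuration. Reruns with identical config and seed reproduce
the artifacts byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as clf
from . import exposures as expo
from . import variability as vvv
from .cutpoint import optimal_cutoff
from .scales import get_scale
from .simulate import SimulationConfig, cohort_preset, simulate_cognition_adl, simulate_cohort
from .survival import (
    ModelSpec,
    fit_cox,
    km_estimate,
    rcs_fit,
    trend_test,
)

log = logging.getLogger("cumdep.pipeline")


@dataclass
class RunConfig:
    """One pipeline run: data source, cutoff policy, model ladder, output."""

    preset: str = "cesd8"
    n_participants: int = 2000
    seed: int = 1
    panel_path: str | None = None          # load instead of simulate
    participants_path: str | None = None
    cutoff_source: str = "screening"       # screening | search | fixed
    fixed_cutoff: float | None = None
    duration_window: tuple[int, int] = (0, 1)
    time_origin: str = "baseline"
    ties_method: str = "efron"
    models: tuple[str, ...] = ("M1", "M2", "M3", "M4")
    subgroups: tuple[str, ...] = ()
    true_loghr: dict = field(default_factory=dict)
    min_age: float = 50.0
    outdir: str = "results/run"

    def __post_init__(self) -> None:
        if self.cutoff_source not in ("screening", "search", "fixed"):
            raise ValueError(f"unknown cutoff source {self.cutoff_source!r}")
        if self.cutoff_source == "fixed" and self.fixed_cutoff is None:
            raise ValueError("fixed cutoff source requires fixed_cutoff")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def validate_panel(
    panel: pd.DataFrame,
    participants: pd.DataFrame,
    classified: pd.DataFrame | None = None,
    min_age: float = 50.0,
    n_waves: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sequential exclusion cascade; returns (report, retained participants).

    Steps, in order: (1) missing sociodemographics; (2) age below the
    cohort threshold; (3) prevalent dementia at baseline; (4) loss to
    follow-up (fewer than `n_waves` panel rows); (5) incomplete symptom,
    cognitive or functional assessments. Counts removed at each step are
    reported; they sum to input minus analytic n.
    """
    steps = []
    keep = participants.copy()
    demo = ["age", "female", "married", "education", "urban"]
    present = [c for c in demo if c in keep.columns]
    bad = keep[present].isna().any(axis=1)
    steps.append(("missing_sociodemographics", int(bad.sum())))
    keep = keep[~bad]

    bad = keep["age"] < min_age
    steps.append(("age_below_threshold", int(bad.sum())))
    keep = keep[~bad]

    if classified is not None:
        prevalent = set(
            classified.loc[classified["first_positive_wave"] == 1, "id"].unique()
        )
    else:
        prevalent = set()
    bad = keep["id"].isin(prevalent)
    steps.append(("prevalent_dementia", int(bad.sum())))
    keep = keep[~bad]

    counts = panel.groupby("id")["wave"].nunique()
    lost = set(counts[counts < n_waves].index) | (
        set(keep["id"]) - set(counts.index)
    )
    bad = keep["id"].isin(lost)
    steps.append(("loss_to_follow_up", int(bad.sum())))
    keep = keep[~bad]

    check_cols = [c for c in ("score", "memory", "orientation", "executive", "adl")
                  if c in panel.columns]
    incomplete = set(
        panel.loc[panel[check_cols].isna().any(axis=1), "id"].unique()
    )
    bad = keep["id"].isin(incomplete)
    steps.append(("incomplete_assessments", int(bad.sum())))
    keep = keep[~bad]

    report = pd.DataFrame(steps, columns=["step", "n_removed"])
    for step, nrem in steps:
        log.info("exclusion %s: removed %d", step, nrem)
    return report, keep


def _select_cutoff(cfg: RunConfig, scale, panel, analytic):
    if cfg.cutoff_source == "screening":
        return float(scale.high_threshold), None
    if cfg.cutoff_source == "fixed":
        return float(cfg.fixed_cutoff), None
    baseline = panel[panel["wave"] == 1].set_index("id").loc[analytic["id"]]
    res = optimal_cutoff(
        baseline["score"].to_numpy(),
        analytic["time"].to_numpy(),
        analytic["event"].to_numpy(),
    )
    return float(res.cutoff), res


def _fit_table(analytic: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Hazard-ratio ladder report: one row per exposure term x model."""
    rows = []
    analytic = analytic.copy()
    analytic["burden_nonneg"] = (analytic["burden_class"] == "nonnegative").astype(int)
    analytic["slope_nonneg"] = (analytic["slope"] >= 0).astype(int)
    analytic["dur_2y"] = (analytic["duration_years"] == 2).astype(int)
    analytic["dur_4y"] = (analytic["duration_years"] == 4).astype(int)
    medians = {}
    for var in ("cumds", "cumads"):
        qa = expo.assign_quartiles(analytic[var].to_numpy())
        analytic[f"{var}_q"] = qa.labels
        for q in (2, 3, 4):
            analytic[f"{var}_q{q}"] = (qa.labels == q).astype(int)
        medians[var] = qa.medians
    pats = pd.get_dummies(analytic["pattern"], prefix="pat").astype(int)
    analytic = pd.concat([analytic, pats], axis=1)
    pat_cols = [c for c in pats.columns if c != "pat_decrease_decrease"]

    codings: list[tuple[str, list[str], str | None]] = [
        ("cumulative", ["cumds"], None),
        ("cumulative_average", ["cumads"], None),
        ("cumds_quartile", ["cumds_q2", "cumds_q3", "cumds_q4"], "Q1"),
        ("cumads_quartile", ["cumads_q2", "cumads_q3", "cumads_q4"], "Q1"),
        ("burden", ["burden_nonneg"], "<0"),
        ("duration", ["dur_2y", "dur_4y"], "0y"),
        ("slope", ["slope_nonneg"], "<0"),
        ("pattern", pat_cols, "decrease_decrease"),
    ]
    for name in ("sd", "cv", "vim"):
        if name in analytic.columns and analytic[name].notna().sum() > 0:
            codings.append((name, [name], None))

    for model_id in cfg.models:
        spec = ModelSpec(model_id, time_origin=cfg.time_origin,
                         ties_method=cfg.ties_method)
        for coding, cols, ref in codings:
            sub = analytic.dropna(subset=cols)
            try:
                fit = fit_cox(sub, cols, spec)
            except ValueError as err:
                log.warning("skipping %s under %s: %s", coding, model_id, err)
                continue
            for col in cols:
                t = fit.terms.loc[col]
                rows.append({
                    "model": model_id, "coding": coding, "term": col,
                    "reference": ref, "hr": t["hr"], "ci_lower": t["ci_lower"],
                    "ci_upper": t["ci_upper"], "p": t["p"],
                    "n": fit.n, "events": fit.n_events,
                })
            if coding in ("cumds_quartile", "cumads_quartile"):
                var = coding.split("_")[0]
                p_trend = trend_test(
                    analytic, analytic[f"{var}_q"].to_numpy(),
                    medians[var], spec,
                )
                rows.append({"model": model_id, "coding": coding,
                             "term": "p_trend", "reference": ref,
                             "hr": np.nan, "ci_lower": np.nan,
                             "ci_upper": np.nan, "p": p_trend,
                             "n": len(analytic), "events": int(analytic["event"].sum())})
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns a dict of output paths and key results."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.panel_path:
        panel = pd.read_csv(cfg.panel_path)
        participants = pd.read_csv(cfg.participants_path)
        scale = get_scale(cfg.preset if cfg.preset.upper() in
                          ("CESD8", "CESD10", "EUROD") else "CESD8")
        sim_cfg = None
    else:
        sim_cfg = cohort_preset(
            cfg.preset, n_participants=cfg.n_participants, seed=cfg.seed,
            true_loghr=dict(cfg.true_loghr), duration_window=cfg.duration_window,
            min_age=cfg.min_age,
        )
        cohort = simulate_cognition_adl(simulate_cohort(sim_cfg))
        panel, participants = cohort.panel, cohort.participants
        scale = sim_cfg.scale
    log.info("stage simulate/load: %d participants, %d panel rows",
             len(participants), len(panel))

    norms = clf.compute_norms(panel)
    classified = clf.classify_dementia(panel, norms)
    class_flat = classified.drop_duplicates("id")[["id", "first_positive_wave"]]
    log.info("stage classify: %d algorithmic cases",
             int(class_flat["first_positive_wave"].notna().sum()))

    report, analytic_parts = validate_panel(
        panel, participants, classified, min_age=cfg.min_age
    )
    log.info("stage validate: %d -> %d participants",
             len(participants), len(analytic_parts))

    cutoff, cut_res = _select_cutoff(cfg, scale, panel, analytic_parts)
    log.info("stage cutoff (%s): %.3g", cfg.cutoff_source, cutoff)

    exposures = expo.derive_exposures(
        panel[panel["id"].isin(analytic_parts["id"])], cutoff,
        duration_window=cfg.duration_window,
    )
    var_stats, calib = vvv.add_variability(
        panel[panel["id"].isin(analytic_parts["id"])]
    )
    analytic = (
        analytic_parts.merge(exposures, on="id")
        .merge(var_stats, on="id")
        .merge(class_flat, on="id")
    )
    if cfg.time_origin == "exposure_end":
        span = 2.0 * 2  # landmark at the final exposure wave
        analytic = analytic[analytic["time"] > span].copy()
        analytic["time"] = analytic["time"] - span
    log.info("stage derive: %d analytic rows; VIM beta %.3f (n=%d)",
             len(analytic), calib.beta, calib.n_used)

    ladder = _fit_table(analytic, cfg)
    spline = rcs_fit(analytic, "cumads",
                     ModelSpec(cfg.models[-1], time_origin=cfg.time_origin))
    qa = expo.assign_quartiles(analytic["cumds"].to_numpy())
    analytic["cumds_quartile"] = qa.labels
    km = km_estimate(analytic, "cumds_quartile")
    km_rows = []
    for g, curve in km.curves.items():
        c = curve.copy()
        c.insert(0, "group", g)
        km_rows.append(c)
    km_df = pd.concat(km_rows, ignore_index=True)

    meta = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "cutoff_source": cfg.cutoff_source,
        "cutoff": cutoff,
        "duration_window": list(cfg.duration_window),
        "time_origin": cfg.time_origin,
        "ties_method": cfg.ties_method,
        "vim_beta": calib.beta,
        "vim_intercept": calib.intercept,
        "vim_n_used": calib.n_used,
        "n_input": int(len(participants)),
        "n_analytic": int(len(analytic)),
        "events": int(analytic["event"].sum()),
        "km_logrank_p": km.logrank_p,
        "spline_knots": spline.n_knots,
        "spline_p_overall": spline.p_overall,
        "spline_p_nonlinear": spline.p_nonlinear,
    }

    paths = {}
    artifacts = {
        "panel.csv": panel,
        "participants.csv": participants,
        "classification.csv": classified,
        "exclusions.csv": report,
        "exposures.csv": exposures,
        "variability.csv": var_stats,
        "cox_ladder.csv": ladder,
        "spline_curve.csv": spline.curve,
        "km.csv": km_df,
    }
    if cut_res is not None:
        artifacts["cutpoint_grid.csv"] = cut_res.grid
    for name, df in artifacts.items():
        p = outdir / name
        df.to_csv(p, index=False, float_format="%.10g")
        paths[name] = str(p)
    with open(outdir / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    paths["metadata.json"] = str(outdir / "metadata.json")
    return {"paths": paths, "metadata": meta, "ladder": ladder,
            "analytic": analytic}
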