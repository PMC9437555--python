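"""End-to-end orchestration: simulate/load -> derive -> merge -> analyse.

One reproducible run derives monthly adherence from telemetry, merges the
final-month measures, and emits the report tables: a trend-model
coefficient table, a margins table, agreement statistics, and diagnostic
accuracy with cluster-bootstrap CIs, plus ROC points for plotting.  All
outputs are plain CSV; a run log records the configuration hash and the
record counts at every filter step so row accounting is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement, diagnostics, events, measures, simulate, trend

logger = logging.getLogger("adheremon")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``sim`` (simulator settings) or ``inputs`` (paths to
    events/roster/selfreport/viral CSVs) must be provided.  The comparison
    analyses (agreement, diagnostics) are restricted to one arm — the
    control arm by default, so measure differences cannot be intervention
    effects — while the trend model always uses both arms.
    """

    out_dir: str = "adheremon_run"
    sim: simulate.SimConfig | None = field(default_factory=simulate.SimConfig)
    inputs: dict | None = None
    missed_threshold: int = 4
    min_observed_days: int = 15
    window_days: int = 30
    excluded_days: int = 7
    vl_cutoff: float = measures.VL_CUTOFF_PRIMARY
    arm_filter: str = "control"  # control | all
    bootstrap_replicates: int = 1000
    bootstrap_seed: int = 20140101
    fit_trend: bool = True

    def __post_init__(self):
        if self.arm_filter not in ("control", "all"):
            raise ValueError("arm_filter must be 'control' or 'all'")
        if self.vl_cutoff <= 0:
            raise ValueError("vl_cutoff must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        inputs = raw.pop("inputs", None)
        sim = simulate.SimConfig(**sim_raw) if sim_raw is not None else (
            None if inputs is not None else simulate.SimConfig())
        return cls(sim=sim, inputs=inputs, **raw)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _load_inputs(cfg: RunConfig):
    if cfg.inputs is not None:
        ev = events.parse_event_log(cfg.inputs["events"])
        roster = pd.read_csv(cfg.inputs["roster"])
        sr = pd.read_csv(cfg.inputs["selfreport"])
        vl = pd.read_csv(cfg.inputs["viral"])
        months = cfg.inputs.get("months")
        if months is None:
            months = int(sr["month_index"].max())
    else:
        truth, ev, sr, vl = simulate.simulate_trial(cfg.sim)
        roster = truth.roster.drop(columns=["v"])
        months = cfg.sim.months
    return ev, roster, sr, vl, months


def _merge_final_month(monthly, roster, sr, vl, months, cfg: RunConfig):
    em12 = monthly[monthly["month_index"] == months][
        ["participant_id", "days_observed", "days_missed", "category"]
    ].rename(columns={"category": "em_category", "days_missed": "em_days_missed"})
    em12.loc[em12["em_category"] == events.CATEGORY_UNOBSERVED, "em_category"] = pd.NA
    sr12 = sr[sr["month_index"] == months][
        ["participant_id", "days_missed_recall", "category"]
    ].rename(columns={"category": "sr_category"})
    vl_cls = vl[["participant_id", "copies_per_ml"]].copy()
    vl_cls["vl_category"] = [
        "suppressed" if s else "unsuppressed"
        for s in measures.classify_viral_load(vl_cls["copies_per_ml"].to_numpy(),
                                              cfg.vl_cutoff)
    ]
    merged = (roster[["participant_id", "clinic_id", "arm", "age_group"]]
              .merge(em12, on="participant_id", how="left")
              .merge(sr12, on="participant_id", how="left")
              .merge(vl_cls, on="participant_id", how="left"))
    return merged


def _diagnostic_rows(merged, test_col, score_col, cfg: RunConfig, label):
    sub = merged.dropna(subset=[test_col, "vl_category"])
    t, _ = agreement.cross_classify(sub[test_col], sub["vl_category"])
    res = diagnostics.sens_spec(t)
    auc_bin = diagnostics.auc_binary(t)
    scored = sub.dropna(subset=[score_col])
    auc_mod, roc = diagnostics.auc_model(
        scored[score_col], scored["vl_category"] == "unsuppressed")
    boot_cfg = diagnostics.BootstrapConfig(
        n_replicates=cfg.bootstrap_replicates, seed=cfg.bootstrap_seed)

    def stat_factory(kind):
        def stat(df):
            tt, _ = agreement.cross_classify(df[test_col], df["vl_category"])
            r = diagnostics.sens_spec(tt)
            if kind == "sens":
                return r.sensitivity
            if kind == "spec":
                return r.specificity
            d = df.dropna(subset=[score_col])
            a, _ = diagnostics.auc_model(d[score_col], d["vl_category"] == "unsuppressed")
            return a
        return stat

    cis = {}
    for kind in ("sens", "spec", "auc"):
        ci = diagnostics.cluster_bootstrap_ci(stat_factory(kind), sub, boot_cfg)
        cis[kind] = (ci.lower, ci.upper)
    roc["test"] = label
    return {
        "test": label,
        "tp": t.n11, "fp": t.n10, "fn": t.n01, "tn": t.n00,
        "sensitivity": res.sensitivity,
        "sens_wilson_low": res.sensitivity_ci[0], "sens_wilson_high": res.sensitivity_ci[1],
        "sens_boot_low": cis["sens"][0], "sens_boot_high": cis["sens"][1],
        "specificity": res.specificity,
        "spec_wilson_low": res.specificity_ci[0], "spec_wilson_high": res.specificity_ci[1],
        "spec_boot_low": cis["spec"][0], "spec_boot_high": cis["spec"][1],
        "auc_binary": auc_bin,
        "auc_model": auc_mod,
        "auc_boot_low": cis["auc"][0], "auc_boot_high": cis["auc"][1],
    }, roc


def sensitivity_sweep(merged: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Re-dichotomize and re-evaluate under alternative cut-offs.

    Crosses the adherence rules {>4 missed days, percent adherence at
    95/90/85%} with viral-load cut-offs {50, 1000 copies/ml}, recomputing
    sensitivity and specificity of both measures from the merged
    final-month data for each combination (8 variants per measure).
    """
    rules = [("missed_gt4", None), ("pct_95", 95.0), ("pct_90", 90.0), ("pct_85", 85.0)]
    cutoffs = (measures.VL_CUTOFF_PRIMARY, measures.VL_CUTOFF_SENSITIVITY)
    rows = []
    for cutoff in cutoffs:
        vl_cat = pd.Series(
            pd.NA, index=merged.index, dtype=object)
        has_vl = merged["copies_per_ml"].notna()
        vl_cat[has_vl] = [
            "suppressed" if s else "unsuppressed"
            for s in measures.classify_viral_load(
                merged.loc[has_vl, "copies_per_ml"].to_numpy(), cutoff)
        ]
        for rule, pct in rules:
            for label, missed_col, obs_col in (
                    ("em", "em_days_missed", "days_observed"),
                    ("sr", "days_missed_recall", None)):
                sub = merged.dropna(subset=[missed_col]).copy()
                if obs_col is not None:
                    sub = sub[sub[obs_col] > 0]
                    observed = sub[obs_col].to_numpy()
                else:
                    observed = np.full(len(sub), 30)
                missed = sub[missed_col].to_numpy()
                if pct is None:
                    cat = np.where(missed > cfg.missed_threshold, "poor", "good")
                else:
                    cat = measures.percent_adherence_threshold(missed, observed, pct)
                try:
                    t, _ = agreement.cross_classify(cat, vl_cat.loc[sub.index])
                    res = diagnostics.sens_spec(t)
                except ValueError:
                    continue
                rows.append({
                    "test": label, "rule": rule, "vl_cutoff": cutoff, "n": t.n,
                    "sensitivity": res.sensitivity, "specificity": res.specificity,
                    "auc_binary": (res.sensitivity + res.specificity) / 2,
                })
    return pd.DataFrame(rows)


def run_all(cfg: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline and write all report CSVs.

    Returns the mapping of output names to paths.  Deterministic given the
    seeds in ``cfg``; any stage failure propagates with the stage named.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"config_hash: {cfg.config_hash()}"]

    def note(msg):
        logger.info(msg)
        log_lines.append(msg)

    ev, roster, sr, vl, months = _load_inputs(cfg)
    note(f"inputs: {len(ev)} events, {len(roster)} roster rows, "
         f"{len(sr)} self-reports, {len(vl)} viral loads, {months} months")

    span_days = cfg.excluded_days + months * cfg.window_days
    em_cfg = events.EmPipelineConfig(
        excluded_days=cfg.excluded_days, window_days=cfg.window_days,
        missed_threshold=cfg.missed_threshold, min_observed_days=cfg.min_observed_days)
    monthly = events.events_to_monthly(ev, roster, span_days, em_cfg)
    n_unobs = int((monthly["category"] == events.CATEGORY_UNOBSERVED).sum())
    note(f"derived monthly: {len(monthly)} participant-months "
         f"({n_unobs} unobserved, {len(monthly) - n_unobs} classifiable)")

    merged = _merge_final_month(monthly, roster, sr, vl, months, cfg)
    comp = merged if cfg.arm_filter == "all" else merged[merged["arm"] == "control"]
    note(f"merged month-{months} measures: {len(merged)} rows; "
         f"comparison subset ({cfg.arm_filter}): {len(comp)} rows")

    paths: dict[str, Path] = {}

    def save(name, df):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p

    save("monthly", monthly)
    save("merged", merged)

    table5 = agreement.agreement_report(
        comp, pairs=[("vl_category", "em_category"),
                     ("vl_category", "sr_category"),
                     ("em_category", "sr_category")],
        strata="age_group")
    save("table5", table5)
    note(f"agreement table: {len(table5)} rows")

    diag_rows, rocs = [], []
    for test_col, score_col, label in (
            ("em_category", "em_days_missed", "em"),
            ("sr_category", "days_missed_recall", "sr")):
        row, roc = _diagnostic_rows(comp, test_col, score_col, cfg, label)
        diag_rows.append(row)
        rocs.append(roc)
    save("table6", pd.DataFrame(diag_rows))
    save("roc", pd.concat(rocs, ignore_index=True))
    sweep = sensitivity_sweep(comp, cfg)
    save("table6_sweep", sweep)
    note("diagnostics: 2 tests with cluster-bootstrap CIs "
         f"(B={cfg.bootstrap_replicates})")

    if cfg.fit_trend:
        obs = (monthly[monthly["category"] != events.CATEGORY_UNOBSERVED]
               .merge(roster[["participant_id", "clinic_id", "arm"]], on="participant_id"))
        obs["good"] = obs["category"] == events.CATEGORY_GOOD
        fit = trend.fit_three_level_logit(obs)
        save("table3", fit.summary_frame().reset_index(names="term"))
        save("margins", trend.margins_table(fit))
        contrasts, inter = trend.time_contrasts(fit)
        save("contrasts", contrasts)
        note(f"trend model: n={fit.n_obs} obs, {fit.n_participants} participants, "
             f"{fit.n_clinics} clinics, converged={fit.converged}"
             + (f", interaction chi2({inter.df})={inter.statistic:.2f} "
                f"p={inter.p_value:.3f}" if inter else ""))

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    paths["run_log"] = out / "run_log.txt"
    return paths
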