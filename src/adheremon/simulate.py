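"""Synthetic cluster-randomized adherence cohort.

Generates a full synthetic trial — clinics, an adolescent roster, daily
pill-box telemetry, monthly self-reports and month-12 viral loads — with
the statistical structure the analysis modules assume:

* monthly good-adherence follows the three-level logistic model with the
  published fixed effects (declining month effects, small arm effect) and
  random-intercept variances (clinic 0.089, participant 10.610);
* self-report over-reports adherence by binomial thinning of the true
  missed days (social-desirability under-report), calibrated so ~97% of
  month-12 self-reports are "good";
* viral non-suppression couples only weakly to month-12 adherence, via
  conditional rates taken from the trial's published cross-classification
  (non-suppression 32% among good vs 37% among poor adherers), so the
  electronic measure shows the characteristic low sensitivity / high
  specificity pattern.

Every draw flows from a single seed; identical config + seed yields
byte-identical CSV output.  Within-category missed-day counts and the
month-to-month dependence beyond the shared random intercepts are
assumptions, not estimates — see the package methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from .events import (
    CATEGORY_GOOD,
    CATEGORY_POOR,
    SIGNAL_HEARTBEAT,
    SIGNAL_INTAKE,
    SIGNAL_NONE,
)

#: published month effects (log-odds vs. month 1), months 2..12
MONTH_EFFECTS = (-1.202, -1.787, -1.875, -2.177, -2.217, -2.166,
                 -2.473, -2.373, -2.517, -1.798, -2.416)
#: published month x arm interaction effects, months 2..12
INTERACTION_EFFECTS = (-0.415, -0.217, -0.091, -0.369, -0.069, 0.573,
                       0.021, 0.190, -0.176, -0.343, -0.116)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic trial.

    Defaults reproduce the published design: 39 clinics (19 control / 20
    intervention) of ~18 adolescents each followed for 12 months, with the
    published trend-model coefficients and variance components.  The
    self-report and viral-load couplings are calibrated once so that the
    month-12 control-arm summaries match the trial's reported marginal
    conditions (97% self-report good; ~33% non-suppression with electronic
    sensitivity ~0.2).
    """

    n_clinics: int = 39
    #: None -> 19 control clinics in the full 39-clinic design, otherwise
    #: an even split (rounded down, at least 1)
    n_control_clinics: int | None = None
    participants_per_clinic: int = 18
    months: int = 12
    beta0: float = 6.044
    beta_month: tuple[float, ...] = MONTH_EFFECTS
    beta_arm: float = 0.339
    beta_interaction: tuple[float, ...] = INTERACTION_EFFECTS
    sigma2_clinic: float = 0.089
    sigma2_participant: float = 10.610
    #: probability a truly missed day is admitted in the 30-day recall
    sr_recall_prob: float = 0.332
    #: per-day probability the device malfunctions (emits "none" only)
    malfunction_rate: float = 0.01
    #: logit of non-suppression among good adherers
    vl_alpha0: float = -0.7464
    #: added log-odds of non-suppression for poor month-12 adherence
    vl_alpha1: float = 0.1943
    #: geometric parameter of the missed-day count above the threshold
    missed_geom_p: float = 0.2
    missed_threshold: int = 4
    window_days: int = 30
    run_in_days: int = 7
    seed: int = 1

    def __post_init__(self):
        # effect vectors longer than needed (e.g. the 11-month defaults with
        # a shorter follow-up) are truncated; shorter ones are an error
        for name in ("beta_month", "beta_interaction"):
            vec = tuple(getattr(self, name))
            if len(vec) < self.months - 1:
                raise ValueError(f"{name} must have at least months-1 entries")
            object.__setattr__(self, name, vec[: self.months - 1])
        if self.n_control_clinics is None:
            object.__setattr__(
                self, "n_control_clinics",
                19 if self.n_clinics == 39 else max(1, self.n_clinics // 2),
            )
        if not (0 < self.n_control_clinics <= self.n_clinics):
            raise ValueError("n_control_clinics must lie in 1..n_clinics")
        for name in ("sigma2_clinic", "sigma2_participant"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("sr_recall_prob", "malfunction_rate", "missed_geom_p"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class CohortTruth:
    """Latent state of a simulated cohort.

    ``clinics``: clinic_id, arm, u (clinic random effect).
    ``roster``: participant_id, clinic_id, arm, v, demographics, issue_date.
    ``monthly``: participant_id, month_index, eta, p_good, good, days_missed,
    category (good/poor under the >threshold rule, by construction).
    """

    config: SimConfig
    clinics: pd.DataFrame
    roster: pd.DataFrame
    monthly: pd.DataFrame = field(repr=False)


def _stage_rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stage])


def simulate_cohort(cfg: SimConfig = SimConfig()) -> CohortTruth:
    """Draw the latent cohort: random effects, monthly adherence, roster.

    Monthly good-adherence is Bernoulli with
    ``logit p = beta0 + beta_month[m] + (beta_arm + beta_interaction[m]) * arm
    + u_clinic + v_participant``; the true missed-day count is then drawn
    consistent with the category — uniform on 0..threshold when good, and
    threshold+1 plus a truncated geometric (right-skewed, mean ~9 days)
    when poor.
    """
    rng = _stage_rng(cfg, 0)
    C, ppc, M = cfg.n_clinics, cfg.participants_per_clinic, cfg.months

    clinic_ids = [f"C{c + 1:02d}" for c in range(C)]
    arms = np.array(["control"] * cfg.n_control_clinics
                    + ["intervention"] * (C - cfg.n_control_clinics))
    u = rng.normal(0.0, np.sqrt(cfg.sigma2_clinic), size=C)
    clinics = pd.DataFrame({"clinic_id": clinic_ids, "arm": arms, "u": u})

    P = C * ppc
    part_clinic = np.repeat(np.arange(C), ppc)
    v = rng.normal(0.0, np.sqrt(cfg.sigma2_participant), size=P)
    pids = [f"P{i + 1:04d}" for i in range(P)]

    # roster demographics loosely matching the trial's baseline table
    age = np.clip(np.round(rng.normal(12.4, 1.98, size=P)), 10, 16).astype(int)
    sex = rng.choice(["female", "male"], size=P, p=[0.563, 0.437])
    orphan = rng.choice(["double", "single", "none"], size=P, p=[0.264, 0.380, 0.356])
    regimen = rng.choice(["first", "second", "third"], size=P, p=[0.624, 0.368, 0.008])
    pills = rng.choice(["<2", "2-4", ">4"], size=P, p=[0.634, 0.221, 0.145])
    freq = rng.choice(["once", "twice"], size=P, p=[0.127, 0.873])
    issue_offset = rng.integers(0, 365, size=P)
    issue_date = pd.Timestamp("2014-01-01") + pd.to_timedelta(issue_offset, unit="D")
    roster = pd.DataFrame(
        {
            "participant_id": pids,
            "clinic_id": np.array(clinic_ids)[part_clinic],
            "arm": arms[part_clinic],
            "v": v,
            "age": age,
            "age_group": np.where(age <= 13, "10-13", "14-16"),
            "sex": sex,
            "orphanhood": orphan,
            "regimen": regimen,
            "pills_per_day": pills,
            "dose_frequency": freq,
            "issue_date": issue_date.date,
        }
    )

    arm_ind = (arms[part_clinic] == "intervention").astype(float)
    month_eff = np.r_[0.0, cfg.beta_month]
    inter_eff = np.r_[0.0, cfg.beta_interaction]
    eta = (cfg.beta0
           + month_eff[None, :]
           + (cfg.beta_arm + inter_eff[None, :]) * arm_ind[:, None]
           + u[part_clinic][:, None]
           + v[:, None])  # (P, M)
    p_good = special.expit(eta)
    good = rng.random((P, M)) < p_good

    # missed days consistent with the dichotomy
    thr = cfg.missed_threshold
    missed_good = rng.integers(0, thr + 1, size=(P, M))
    geom = rng.geometric(cfg.missed_geom_p, size=(P, M)) - 1
    missed_poor = np.minimum(thr + 1 + geom, cfg.window_days)
    days_missed = np.where(good, missed_good, missed_poor)

    monthly = pd.DataFrame(
        {
            "participant_id": np.repeat(pids, M),
            "month_index": np.tile(np.arange(1, M + 1), P),
            "eta": eta.ravel(),
            "p_good": p_good.ravel(),
            "good": good.ravel(),
            "days_missed": days_missed.ravel(),
            "category": np.where(good.ravel(), CATEGORY_GOOD, CATEGORY_POOR),
        }
    )
    return CohortTruth(config=cfg, clinics=clinics, roster=roster, monthly=monthly)


def simulate_daily_events(truth: CohortTruth) -> pd.DataFrame:
    """Emit the device event stream implied by the latent cohort.

    Day 1..run_in is a novelty run-in with several openings per day (to be
    excluded downstream); month m then covers days run_in + (m-1)*30 + 1
    .. run_in + m*30.  Missed days emit a heartbeat, taken days one to
    three intakes (repeat openings are rarer after the run-in), and
    malfunction days emit a single "none" signal whatever the truth.
    """
    cfg = truth.config
    rng = _stage_rng(cfg, 1)
    rows_pid, rows_ts, rows_sig = [], [], []
    monthly = truth.monthly.sort_values(["participant_id", "month_index"])
    missed_by_pm = monthly.set_index(["participant_id", "month_index"])["days_missed"]
    base_time = pd.Timedelta(hours=8)

    for _, part in truth.roster.iterrows():
        pid = part["participant_id"]
        issue = pd.Timestamp(part["issue_date"])
        for d in range(1, cfg.run_in_days + 1):
            n_open = int(rng.integers(2, 5))
            for k in range(n_open):
                rows_pid.append(pid)
                rows_ts.append(issue + pd.Timedelta(days=d - 1) + base_time
                               + pd.Timedelta(hours=3 * k))
                rows_sig.append(SIGNAL_INTAKE)
        for m in range(1, cfg.months + 1):
            dm = int(missed_by_pm.loc[(pid, m)])
            missed_days = rng.choice(cfg.window_days, size=dm, replace=False)
            is_missed = np.zeros(cfg.window_days, dtype=bool)
            is_missed[missed_days] = True
            malfunction = rng.random(cfg.window_days) < cfg.malfunction_rate
            n_open_taken = rng.choice([1, 2, 3], size=cfg.window_days, p=[0.8, 0.15, 0.05])
            for d in range(cfg.window_days):
                abs_day = cfg.run_in_days + (m - 1) * cfg.window_days + d
                ts0 = issue + pd.Timedelta(days=abs_day) + base_time
                if malfunction[d]:
                    rows_pid.append(pid); rows_ts.append(ts0); rows_sig.append(SIGNAL_NONE)
                elif is_missed[d]:
                    rows_pid.append(pid); rows_ts.append(ts0); rows_sig.append(SIGNAL_HEARTBEAT)
                else:
                    for k in range(int(n_open_taken[d])):
                        rows_pid.append(pid)
                        rows_ts.append(ts0 + pd.Timedelta(hours=4 * k))
                        rows_sig.append(SIGNAL_INTAKE)
    return pd.DataFrame({"participant_id": rows_pid, "timestamp": rows_ts,
                         "signal": rows_sig})


def simulate_self_report(truth: CohortTruth) -> pd.DataFrame:
    """Monthly 30-day recalls: binomial thinning of the true missed days.

    Each truly missed day is admitted with probability ``sr_recall_prob``,
    so the report never exceeds the truth — the simplest mechanism for
    social-desirability/recall under-reporting of missed doses.
    """
    cfg = truth.config
    rng = _stage_rng(cfg, 2)
    m = truth.monthly
    reported = rng.binomial(m["days_missed"].to_numpy(), cfg.sr_recall_prob)
    return pd.DataFrame(
        {
            "participant_id": m["participant_id"].to_numpy(),
            "month_index": m["month_index"].to_numpy(),
            "days_missed_recall": reported,
            "category": np.where(reported > cfg.missed_threshold,
                                 CATEGORY_POOR, CATEGORY_GOOD),
        }
    )


def simulate_viral_load(truth: CohortTruth) -> pd.DataFrame:
    """Final-month viral loads weakly coupled to final-month adherence.

    P(unsuppressed) = expit(vl_alpha0 + vl_alpha1 * poor_final_month); the
    copies/ml value is then drawn from a log10-scale mixture whose two
    components sit strictly below and at-or-above the 50 copies/ml cut-off,
    so dichotomizing the copies reproduces the binary draw exactly.
    """
    cfg = truth.config
    rng = _stage_rng(cfg, 3)
    last = truth.monthly[truth.monthly["month_index"] == cfg.months]
    last = last.sort_values("participant_id")
    poor = (last["category"] == CATEGORY_POOR).to_numpy().astype(float)
    p_unsupp = special.expit(cfg.vl_alpha0 + cfg.vl_alpha1 * poor)
    unsupp = rng.random(len(last)) < p_unsupp
    log10_supp = rng.uniform(0.0, np.log10(49.0), size=len(last))
    log10_unsupp = rng.uniform(np.log10(50.0), 5.7, size=len(last))
    copies = np.where(unsupp, 10 ** log10_unsupp, 10 ** log10_supp)
    return pd.DataFrame(
        {
            "participant_id": last["participant_id"].to_numpy(),
            "month_index": cfg.months,
            "copies_per_ml": np.round(copies, 1),
            "suppressed": ~unsupp,
        }
    )


def simulate_trial(cfg: SimConfig = SimConfig()):
    """Full trial bundle: (truth, events, self-report, viral-load) frames."""
    truth = simulate_cohort(cfg)
    events = simulate_daily_events(truth)
    sr = simulate_self_report(truth)
    vl = simulate_viral_load(truth)
    return truth, events, sr, vl


def write_trial_csvs(cfg: SimConfig, out_dir) -> dict[str, Path]:
    """Simulate and write events/roster/selfreport/viral/truth CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth, events, sr, vl = simulate_trial(cfg)
    paths = {}
    roster = truth.roster.drop(columns=["v"])
    for name, df in (("events", events), ("roster", roster),
                     ("selfreport", sr), ("viral", vl),
                     ("truth", truth.monthly)):
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths
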