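"""Diagnostic accuracy of adherence measures against viral non-suppression.

Poor adherence is treated as a diagnostic "positive" for the outcome viral
non-suppression: sensitivity = TP/(TP+FN) among unsuppressed participants,
specificity = TN/(TN+FP) among suppressed ones, with Wilson score 95%
confidence intervals.  Two AUC variants are provided: the binary-marker AUC
(sensitivity + specificity)/2, which is the Mann-Whitney probability for a
dichotomous test, and an empirical-ROC AUC over a continuous adherence
score (e.g. missed days).  Confidence intervals that must respect the
cluster-randomized design come from a cluster bootstrap that resamples
whole clinics with replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.proportion import proportion_confint

from .agreement import TwoByTwo


@dataclass(frozen=True)
class DiagnosticResult:
    """Sensitivity/specificity (Wilson CIs) of a binary test, plus its AUC."""

    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    n_cases: int
    n_controls: int
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None


@dataclass(frozen=True)
class BootstrapConfig:
    """Cluster-bootstrap settings: replicates, seed, and the cluster column."""

    n_replicates: int = 1000
    seed: int = 0
    cluster_col: str = "clinic_id"
    alpha: float = 0.05
    max_redraw_factor: int = 10

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def sens_spec(t: TwoByTwo, alpha: float = 0.05) -> DiagnosticResult:
    """Sensitivity and specificity from a test-vs-outcome 2x2 table.

    The table must be oriented with measure A = the adherence test
    (positive = poor adherence) and measure B = the outcome (positive =
    unsuppressed), so TP = n11, FP = n10, FN = n01, TN = n00.
    """
    tp, fp, fn, tn = t.n11, t.n10, t.n01, t.n00
    n_cases = tp + fn
    n_controls = tn + fp
    if n_cases == 0:
        raise ValueError("no cases (unsuppressed): sensitivity undefined")
    if n_controls == 0:
        raise ValueError("no controls (suppressed): specificity undefined")
    sens = tp / n_cases
    spec = tn / n_controls
    sens_ci = proportion_confint(tp, n_cases, alpha=alpha, method="wilson")
    spec_ci = proportion_confint(tn, n_controls, alpha=alpha, method="wilson")
    return DiagnosticResult(
        sensitivity=sens,
        sensitivity_ci=(float(sens_ci[0]), float(sens_ci[1])),
        specificity=spec,
        specificity_ci=(float(spec_ci[0]), float(spec_ci[1])),
        n_cases=n_cases,
        n_controls=n_controls,
    )


def auc_binary(t: TwoByTwo) -> float:
    """AUC of a dichotomous test: (sensitivity + specificity) / 2.

    Equals the Mann-Whitney probability P(score_case > score_control) +
    0.5 * P(tie) when the test is coded 0/1 with orientation fixed at
    poor adherence => non-suppression (never flipped to exceed 0.5).
    """
    n_cases = t.n11 + t.n01
    n_controls = t.n10 + t.n00
    if n_cases == 0:
        raise ValueError("no cases (unsuppressed): AUC undefined")
    if n_controls == 0:
        raise ValueError("no controls (suppressed): AUC undefined")
    return (t.n11 / n_cases + t.n00 / n_controls) / 2


def auc_model(score, case) -> tuple[float, pd.DataFrame]:
    """Empirical-ROC AUC for a continuous adherence score.

    Parameters
    ----------
    score
        Continuous marker per participant, oriented so that *higher* means
        worse adherence (e.g. missed days in the month).
    case
        Boolean outcome per participant, True = unsuppressed.

    Returns
    -------
    (auc, roc_points)
        Trapezoid-rule AUC with ties counted 1/2, and a frame of
        (threshold, fpr, tpr) points for plotting.  A constant score yields
        AUC 0.5 with a degenerate-score warning.
    """
    score = np.asarray(score, dtype=float)
    case = np.asarray(case, dtype=bool)
    if score.shape != case.shape:
        raise ValueError("score and case must have equal length")
    if np.isnan(score).any():
        raise ValueError("score must be non-missing for all included participants")
    if case.all() or (~case).all():
        raise ValueError("need at least one case and one control")
    if np.ptp(score) == 0:
        warnings.warn("constant score: ROC is degenerate, AUC = 0.5", stacklevel=2)
        roc = pd.DataFrame({"threshold": [np.inf, score[0]], "fpr": [0.0, 1.0], "tpr": [0.0, 1.0]})
        return 0.5, roc
    auc = float(roc_auc_score(case.astype(int), score))
    fpr, tpr, thr = roc_curve(case.astype(int), score)
    roc = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return auc, roc


@dataclass(frozen=True)
class BootstrapCI:
    lower: float
    upper: float
    n_redraws: int
    estimates: np.ndarray = field(repr=False, compare=False, default=None)


def cluster_bootstrap_ci(
    statistic: Callable[[pd.DataFrame], float],
    data: pd.DataFrame,
    config: BootstrapConfig = BootstrapConfig(),
) -> BootstrapCI:
    """Percentile bootstrap CI resampling whole clusters with replacement.

    Each replicate draws the original number of clusters with replacement
    and keeps every row of each drawn cluster, respecting intra-clinic
    correlation.  Replicates on which ``statistic`` raises (e.g. a resample
    with no cases) are redrawn; the redraw count is reported.  Deterministic
    under a fixed seed.
    """
    clusters = data[config.cluster_col].unique()
    if len(clusters) < 2:
        warnings.warn("fewer than 2 clusters: bootstrap CI is degenerate", stacklevel=2)
    rng = np.random.default_rng(config.seed)
    groups = {c: df for c, df in data.groupby(config.cluster_col, sort=False)}
    estimates = np.empty(config.n_replicates)
    n_redraws = 0
    max_attempts = config.n_replicates * config.max_redraw_factor
    attempts = 0
    i = 0
    while i < config.n_replicates:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"statistic failed on too many bootstrap replicates ({n_redraws} redraws)"
            )
        attempts += 1
        drawn = rng.choice(clusters, size=len(clusters), replace=True)
        sample = pd.concat([groups[c] for c in drawn], ignore_index=True)
        try:
            estimates[i] = statistic(sample)
        except Exception:
            n_redraws += 1
            continue
        i += 1
    lo, hi = np.quantile(estimates, [config.alpha / 2, 1 - config.alpha / 2])
    return BootstrapCI(lower=float(lo), upper=float(hi), n_redraws=n_redraws, estimates=estimates)
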