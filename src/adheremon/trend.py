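"""Three-level logistic model of monthly adherence trends.

Monthly good-adherence indicators (level 1) are nested in participants
(level 2) nested in clinics (level 3):

    logit P(good_cim = 1 | u_c, v_i) = x_cim' beta + u_c + v_i
    u_c ~ N(0, sigma2_clinic),  v_i ~ N(0, sigma2_participant)

with fixed effects for month (categorical, month 1 reference), treatment
arm, and month x arm interaction.  The marginal likelihood integrates the
random intercepts out by nested Gauss-Hermite quadrature — the outer sum
over clinic nodes, the inner over participant nodes — and is maximized by
L-BFGS-B with an analytic gradient; standard errors come from the inverse
of a finite-difference Hessian of that gradient.  Variance components are
optimized on the log-standard-deviation scale, which keeps them positive
and makes their Wald intervals sensible.

Population-averaged ("marginal") predicted probabilities integrate the
inverse-logit over both random-effect distributions on a dense quadrature
grid; per-month contrasts against month 1 and a joint Wald test of the
month x arm interaction mirror the usual post-fit contrast machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, special, stats

ARM_CONTROL = "control"
ARM_INTERVENTION = "intervention"


def _gh_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Probabilists' Gauss-Hermite nodes and normalized log-weights."""
    x, w = hermegauss(n)
    return x, np.log(w) - np.log(w.sum())


def _arm_indicator(arm_values) -> np.ndarray:
    arr = np.asarray(arm_values)
    if arr.dtype.kind in "biu":
        return arr.astype(float)
    return (arr == ARM_INTERVENTION).astype(float)


@dataclass
class _Design:
    X: np.ndarray
    columns: list[str]
    months: list[int]
    has_arm: bool
    has_interaction: bool

    def row(self, month: int, arm) -> np.ndarray:
        """Design row for a (month, arm) cell, matching the fit's coding."""
        x = np.zeros(len(self.columns))
        x[0] = 1.0
        a = float(_arm_indicator([arm])[0])
        for j, name in enumerate(self.columns):
            if name == f"month_{month}":
                x[j] = 1.0
            elif name == "arm":
                x[j] = a
            elif name == f"month_{month}:arm":
                x[j] = a
        return x


def _build_design(data: pd.DataFrame, include_interaction: bool) -> _Design:
    months = sorted(int(m) for m in data["month_index"].unique())
    arm = _arm_indicator(data["arm"])
    has_arm = len(np.unique(arm)) > 1
    n = len(data)
    cols: list[str] = ["const"]
    mats = [np.ones(n)]
    for m in months[1:]:
        cols.append(f"month_{m}")
        mats.append((data["month_index"].to_numpy() == m).astype(float))
    if has_arm:
        cols.append("arm")
        mats.append(arm)
        if include_interaction:
            for m in months[1:]:
                cols.append(f"month_{m}:arm")
                mats.append(((data["month_index"].to_numpy() == m) & (arm == 1)).astype(float))
    X = np.column_stack(mats)
    return _Design(X=X, columns=cols, months=months, has_arm=has_arm,
                   has_interaction=has_arm and include_interaction)


@dataclass
class ThreeLevelLogitFit:
    """Maximum-likelihood fit of the three-level logistic trend model."""

    params: pd.Series
    cov: pd.DataFrame
    sigma2_clinic: float
    sigma2_participant: float
    #: Wald 95% CIs for the variance components (log-sd scale, squared back)
    sigma2_clinic_ci: tuple[float, float] | None
    sigma2_participant_ci: tuple[float, float] | None
    loglike: float
    converged: bool
    n_obs: int
    n_participants: int
    n_clinics: int
    design: _Design = field(repr=False)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglike

    def summary_frame(self, alpha: float = 0.05) -> pd.DataFrame:
        """Coefficient table with Wald CIs and p-values, plus variance rows."""
        z = stats.norm.ppf(1 - alpha / 2)
        se = self.bse
        df = pd.DataFrame(
            {
                "coefficient": self.params,
                "se": se,
                "ci_low": self.params - z * se,
                "ci_high": self.params + z * se,
                "p_value": 2 * stats.norm.sf(np.abs(self.params / se)),
            }
        )
        for name, est, ci in (
            ("var_clinic", self.sigma2_clinic, self.sigma2_clinic_ci),
            ("var_participant", self.sigma2_participant, self.sigma2_participant_ci),
        ):
            df.loc[name] = [est, np.nan, *(ci if ci else (np.nan, np.nan)), np.nan]
        return df


def _prepare(data: pd.DataFrame):
    data = data.sort_values(["clinic_id", "participant_id", "month_index"], kind="stable")
    part_codes, _ = pd.factorize(data["participant_id"], sort=False)
    obs_starts = np.flatnonzero(np.r_[True, np.diff(part_codes) != 0])
    clinic_of_part = (
        data["clinic_id"].to_numpy()[obs_starts]
    )
    clin_codes, _ = pd.factorize(clinic_of_part, sort=False)
    part_starts = np.flatnonzero(np.r_[True, np.diff(clin_codes) != 0])
    return data, part_codes, obs_starts, clin_codes, part_starts


def _loglike_grad(theta, X, y_sign, y, obs_starts, part_starts, clin_of_part,
                  xc, lwc, xp, lwp, free_mask, fixed_logsd):
    """Marginal log-likelihood and gradient for (beta, log sd_c, log sd_p)."""
    p = X.shape[1]
    beta = theta[:p]
    logsd = fixed_logsd.copy()
    logsd[free_mask] = theta[p:]
    sd_c, sd_p = np.exp(logsd)
    u = sd_c * xc  # (nc,)
    v = sd_p * xp  # (np,)

    eta = X @ beta
    a = eta[:, None, None] + u[None, :, None] + v[None, None, :]
    # log Bernoulli likelihood per obs/node pair, stable form
    ll = -np.logaddexp(0.0, y_sign[:, None, None] * a)
    A = np.add.reduceat(ll, obs_starts, axis=0)            # (P, nc, np)
    logT = special.logsumexp(A + lwp[None, None, :], axis=2)  # (P, nc)
    S = np.add.reduceat(logT, part_starts, axis=0)         # (C, nc)
    logZ = special.logsumexp(S + lwc[None, :], axis=1)     # (C,)
    total = float(logZ.sum())

    # posterior node weights
    Wc = np.exp(S + lwc[None, :] - logZ[:, None])          # (C, nc)
    Wp = np.exp(A + lwp[None, None, :] - logT[:, :, None])  # (P, nc, np)
    W = Wc[clin_of_part][:, :, None] * Wp                  # (P, nc, np)

    obs_part = np.repeat(np.arange(len(obs_starts)),
                         np.diff(np.r_[obs_starts, len(eta)]))
    resid = (y[:, None, None] - special.expit(a)) * W[obs_part]  # (n, nc, np)
    g_obs = resid.sum(axis=(1, 2))
    grad_beta = X.T @ g_obs
    # d a / d log sd = the node value itself (u or v)
    grad_logsd = np.array([
        float((resid * u[None, :, None]).sum()),
        float((resid * v[None, None, :]).sum()),
    ])
    grad = np.concatenate([grad_beta, grad_logsd[free_mask]])
    return total, grad


def fit_three_level_logit(
    data: pd.DataFrame,
    include_interaction: bool = True,
    quad_clinic: int = 9,
    quad_participant: int = 25,
    fix_variances: tuple[float | None, float | None] = (None, None),
    maxiter: int = 500,
) -> ThreeLevelLogitFit:
    """Fit the three-level logistic trend model by maximum likelihood.

    Parameters
    ----------
    data
        One row per classifiable participant-month with columns
        ``clinic_id``, ``participant_id``, ``month_index``, ``arm``
        (control/intervention or 0/1) and ``good`` (bool/0/1).
    include_interaction
        Include month x arm interaction terms (only when both arms occur).
    quad_clinic, quad_participant
        Gauss-Hermite node counts for the clinic and participant integrals.
    fix_variances
        Optionally pin one or both variance components (e.g. ``(0.0, 0.0)``
        reduces the model to ordinary logistic regression).

    Notes
    -----
    Single-clinic data fall back to a two-level model (clinic variance
    fixed at 0) with a warning.  Non-convergence is flagged on the result
    and warned about, never silent.
    """
    required = {"clinic_id", "participant_id", "month_index", "arm", "good"}
    if not required.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    data, part_codes, obs_starts, clin_codes, part_starts = _prepare(data)
    n_clinics = int(clin_codes.max()) + 1
    n_participants = len(obs_starts)
    fix_c, fix_p = fix_variances
    if n_clinics == 1 and fix_c is None:
        warnings.warn("single clinic: falling back to a two-level model "
                      "(clinic variance fixed at 0)", stacklevel=2)
        fix_c = 0.0

    design = _build_design(data, include_interaction)
    X = design.X
    y = data["good"].to_numpy().astype(float)
    y_sign = np.where(y > 0, -1.0, 1.0)

    xc, lwc = _gh_nodes(quad_clinic)
    xp, lwp = _gh_nodes(quad_participant)

    free_mask = np.array([fix_c is None, fix_p is None])
    fixed_logsd = np.array([
        0.5 * np.log(fix_c) if (fix_c not in (None,) and fix_c > 0) else (-20.0 if fix_c == 0 else 0.0),
        0.5 * np.log(fix_p) if (fix_p not in (None,) and fix_p > 0) else (-20.0 if fix_p == 0 else 0.0),
    ])

    # start from a plain logistic fit (attenuated but in the right region)
    from statsmodels.api import GLM, families

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta0 = GLM(y, X, family=families.Binomial()).fit().params
    start = np.concatenate([beta0, np.array([np.log(0.5), np.log(1.5)])[free_mask]])

    args = (X, y_sign, y, obs_starts, part_starts, clin_codes,
            xc, lwc, xp, lwp, free_mask, fixed_logsd)

    def negloglike(theta):
        ll, g = _loglike_grad(theta, *args)
        return -ll, -g

    p = X.shape[1]
    bounds = [(None, None)] * p + [(np.log(1e-4), np.log(25.0))] * int(free_mask.sum())
    res = optimize.minimize(negloglike, start, jac=True, method="L-BFGS-B",
                            bounds=bounds, options={"maxiter": maxiter, "ftol": 1e-11})
    if not res.success:
        warnings.warn(f"three-level logit did not converge: {res.message}", stacklevel=2)

    theta_hat = res.x
    # Hessian by central differences of the analytic gradient
    k = len(theta_hat)
    H = np.empty((k, k))
    for j in range(k):
        h = 1e-5 * (1.0 + abs(theta_hat[j]))
        tp_ = theta_hat.copy(); tp_[j] += h
        tm_ = theta_hat.copy(); tm_[j] -= h
        _, gp = _loglike_grad(tp_, *args)
        _, gm = _loglike_grad(tm_, *args)
        H[:, j] = -(gp - gm) / (2 * h)
    H = (H + H.T) / 2
    try:
        cov_all = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_all = np.linalg.pinv(H)

    beta_hat = theta_hat[:p]
    logsd_hat = fixed_logsd.copy()
    logsd_hat[free_mask] = theta_hat[p:]
    sigma2 = np.exp(2 * logsd_hat)
    if fix_c == 0:
        sigma2[0] = 0.0
    if fix_p == 0:
        sigma2[1] = 0.0

    z = stats.norm.ppf(0.975)
    sigma_ci: list[tuple[float, float] | None] = [None, None]
    free_idx = np.flatnonzero(free_mask)
    for pos, comp in enumerate(free_idx):
        se_logsd = np.sqrt(max(cov_all[p + pos, p + pos], 0.0))
        # clip the exponent: a boundary variance has an enormous log-sd SE
        lo = np.exp(np.clip(2 * (logsd_hat[comp] - z * se_logsd), -700, 700))
        hi = np.exp(np.clip(2 * (logsd_hat[comp] + z * se_logsd), -700, 700))
        sigma_ci[comp] = (float(lo), float(hi))

    ll_hat, _ = _loglike_grad(theta_hat, *args)
    return ThreeLevelLogitFit(
        params=pd.Series(beta_hat, index=design.columns),
        cov=pd.DataFrame(cov_all[:p, :p], index=design.columns, columns=design.columns),
        sigma2_clinic=float(sigma2[0]),
        sigma2_participant=float(sigma2[1]),
        sigma2_clinic_ci=sigma_ci[0],
        sigma2_participant_ci=sigma_ci[1],
        loglike=float(ll_hat),
        converged=bool(res.success),
        n_obs=len(y),
        n_participants=n_participants,
        n_clinics=n_clinics,
        design=design,
    )


def marginal_probability(eta: float, sigma2_clinic: float, sigma2_participant: float,
                         n_nodes: int = 64) -> float:
    """Population-averaged P(good) at linear predictor ``eta``.

    Integrates expit(eta + u + v) over u ~ N(0, sigma2_clinic) and
    v ~ N(0, sigma2_participant) with ``n_nodes`` Gauss-Hermite nodes per
    dimension.
    """
    x, lw = _gh_nodes(n_nodes)
    u = np.sqrt(sigma2_clinic) * x
    v = np.sqrt(sigma2_participant) * x
    w = np.exp(lw)
    vals = special.expit(eta + u[:, None] + v[None, :])
    return float(w @ vals @ w)


def marginal_predictions(fit: ThreeLevelLogitFit, arm, month: int,
                         n_nodes: int = 64, alpha: float = 0.05):
    """Marginal predicted probability for one (arm, month) cell, with CI.

    The CI propagates fixed-effect uncertainty through the (monotone)
    marginalization: a Wald interval on the linear predictor is mapped
    through the marginal inverse-logit.  Variance-component uncertainty is
    not propagated.
    """
    x_row = fit.design.row(month, arm)
    eta = float(x_row @ fit.params.to_numpy())
    se = float(np.sqrt(x_row @ fit.cov.to_numpy() @ x_row))
    z = stats.norm.ppf(1 - alpha / 2)
    prob = marginal_probability(eta, fit.sigma2_clinic, fit.sigma2_participant, n_nodes)
    lo = marginal_probability(eta - z * se, fit.sigma2_clinic, fit.sigma2_participant, n_nodes)
    hi = marginal_probability(eta + z * se, fit.sigma2_clinic, fit.sigma2_participant, n_nodes)
    return prob, (lo, hi)


def margins_table(fit: ThreeLevelLogitFit, n_nodes: int = 64) -> pd.DataFrame:
    """Figure-2-style margins: one row per (month, arm) with probability and CI."""
    arms = [ARM_CONTROL, ARM_INTERVENTION] if fit.design.has_arm else [ARM_CONTROL]
    rows = []
    for month in fit.design.months:
        for arm in arms:
            prob, (lo, hi) = marginal_predictions(fit, arm, month, n_nodes)
            rows.append({"month_index": month, "arm": arm,
                         "predicted_probability": prob, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class InteractionTest:
    """Joint Wald chi-square test of all month x arm interaction terms."""

    statistic: float
    df: int
    p_value: float


def time_contrasts(fit: ThreeLevelLogitFit, alpha: float = 0.05
                   ) -> tuple[pd.DataFrame, InteractionTest | None]:
    """Per-month log-odds contrasts vs. month 1, plus the joint interaction test.

    The month-1 contrast is identically 0 (reference category).  Returns a
    frame (month_index, estimate, se, ci_low, ci_high, p_value) and, when
    the fit includes interaction terms, their joint Wald test.
    """
    z = stats.norm.ppf(1 - alpha / 2)
    rows = [{"month_index": fit.design.months[0], "estimate": 0.0, "se": 0.0,
             "ci_low": 0.0, "ci_high": 0.0, "p_value": np.nan}]
    for m in fit.design.months[1:]:
        name = f"month_{m}"
        est = float(fit.params[name])
        se = float(fit.bse[name])
        rows.append({"month_index": m, "estimate": est, "se": se,
                     "ci_low": est - z * se, "ci_high": est + z * se,
                     "p_value": float(2 * stats.norm.sf(abs(est / se)))})
    contrasts = pd.DataFrame(rows)

    test = None
    inter = [c for c in fit.params.index if c.endswith(":arm")]
    if inter:
        c = fit.params[inter].to_numpy()
        V = fit.cov.loc[inter, inter].to_numpy()
        stat = float(c @ np.linalg.solve(V, c))
        test = InteractionTest(statistic=stat, df=len(inter),
                               p_value=float(stats.chi2.sf(stat, len(inter))))
    return contrasts, test
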