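"""Proportional-hazards diagnostics: Schoenfeld residuals and log(-log) curves.

The proportionality assumption is assessed the way it is routinely done
for Cox models, applied separately within each cohort: a score-type test
of zero correlation between the scaled Schoenfeld residuals and a
transform of event time (Grambsch–Therneau), and Kaplan–Meier
log-minus-log survival curves per covariate level, exported as
plot-ready tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coxcore import CoxFit, SurvivalDataset

__all__ = ["PHTestResult", "schoenfeld_residuals", "ph_test", "km_log_minus_log"]

TRANSFORMS = ("identity", "km", "rank", "log")


@dataclass
class PHTestResult:
    """Per-covariate and global tests of the proportional-hazards assumption.

    ``table`` has one row per covariate with the residual-time
    correlation, the 1-df chi-square statistic and its p-value;
    ``global_chi2``/``global_p`` test all covariates jointly on p df.
    """

    table: pd.DataFrame
    global_chi2: float
    global_p: float
    df: int
    transform: str


def _risk_means(fit: CoxFit, data: SurvivalDataset, want_var: bool = False):
    """Per-event covariate values, risk-set weighted means (and variances).

    Risk set at an event time is every subject with time >= that time
    (Breslow-style weighting by exp(linear predictor)).  With
    ``want_var`` the per-event risk-set covariance matrices
    V(t) = S2/S0 - xbar xbar' are returned as well."""
    X = data.covariates[list(fit.coef.index)].to_numpy(dtype=float)
    eta = X @ fit.coef.to_numpy() + data.offset
    order = np.argsort(data.time, kind="stable")
    t = data.time[order]
    d = data.event[order]
    Xs = X[order]
    w = np.exp(eta[order] - eta.max())
    S0 = np.cumsum(w[::-1])[::-1]
    wX = w[:, None] * Xs
    S1 = np.cumsum(wX[::-1], axis=0)[::-1]
    new_block = np.r_[True, t[1:] != t[:-1]]
    block_start_of = np.flatnonzero(new_block)[np.cumsum(new_block) - 1]
    ev = np.flatnonzero(d == 1)
    anchors = block_start_of[ev]
    xbar = S1[anchors] / S0[anchors][:, None]
    if not want_var:
        return t[ev], Xs[ev], xbar
    S2 = np.cumsum((wX[:, :, None] * Xs[:, None, :])[::-1], axis=0)[::-1]
    V = S2[anchors] / S0[anchors][:, None, None] - xbar[:, :, None] * xbar[:, None, :]
    return t[ev], Xs[ev], xbar, V


def schoenfeld_residuals(
    fit: CoxFit,
    data: SurvivalDataset,
    scaled: bool = True,
) -> pd.DataFrame:
    """Schoenfeld residuals at each observed event, ordered by event time.

    The unscaled residual for an event is the subject's covariate vector
    minus the risk-set weighted mean at that time; summed over events at
    the fitted coefficients they reproduce the score equation, i.e. zero.
    With ``scaled=True`` the Grambsch–Therneau scaling is applied:
    beta_hat + m * r V(beta_hat)^{-1}, with m the number of events and V
    the inverse information — the scaled residual at time t estimates a
    time-varying coefficient beta(t).
    """
    if not fit.converged:
        raise ValueError("fit did not converge; residuals are meaningless")
    t_ev, x_ev, xbar = _risk_means(fit, data)
    resid = x_ev - xbar
    if scaled:
        m = resid.shape[0]
        resid = fit.coef.to_numpy()[None, :] + m * resid @ fit.vcov.to_numpy()
    out = pd.DataFrame(resid, columns=list(fit.coef.index))
    out.insert(0, "time", t_ev)
    return out


def _transform_time(t: np.ndarray, data: SurvivalDataset, transform: str) -> np.ndarray:
    if transform == "identity":
        return t.astype(float)
    if transform == "log":
        return np.log(t)
    if transform == "rank":
        return stats.rankdata(t, method="average")
    if transform == "km":
        # left-continuous Kaplan-Meier of the whole sample evaluated at the
        # event times: g(t) = 1 - S(t-)
        from lifelines import KaplanMeierFitter

        km = KaplanMeierFitter().fit(data.time, data.event)
        s_minus = km.survival_function_at_times(t - 1e-12).to_numpy()
        return 1.0 - s_minus
    raise ValueError(f"unknown time transform: {transform!r} (use one of {TRANSFORMS})")


def ph_test(
    fit: CoxFit,
    data: SurvivalDataset,
    transform: str = "km",
) -> PHTestResult:
    """Grambsch–Therneau score test for non-proportional hazards.

    For each covariate, tests zero correlation between its Schoenfeld
    residuals and the (centered) transformed event time; under
    proportional hazards the statistic is chi-square with 1 df.  The
    global statistic pools all covariates (p df).  The score-test
    variance uses the exact per-event risk-set covariances, with the
    correction for the estimated regression coefficients.
    """
    t_ev, x_ev, xbar, Vk = _risk_means(fit, data, want_var=True)
    resid = x_ev - xbar  # unscaled residuals
    m, p = resid.shape
    g = _transform_time(t_ev, data, transform)
    g = g - g.mean()
    if float(g @ g) == 0.0:
        raise ValueError("degenerate time transform: all events at one time")

    u = g @ resid  # p-vector of transform-weighted residual sums
    # Var(u) = sum g^2 V(t) - (sum g V)(sum V)^{-1}(sum g V): the second term
    # accounts for beta having been estimated from the same data
    sum_V = Vk.sum(axis=0)
    sum_gV = (g[:, None, None] * Vk).sum(axis=0)
    sum_ggV = ((g**2)[:, None, None] * Vk).sum(axis=0)

    # per-covariate 1-df tests, each using its own diagonal elements
    var_j = np.diag(sum_ggV) - np.diag(sum_gV) ** 2 / np.diag(sum_V)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = np.where(var_j > 0, u**2 / var_j, 0.0)
    pvals = stats.chi2.sf(chi, df=1)

    Vinv = fit.vcov.to_numpy()
    sres = m * resid @ Vinv
    with np.errstate(invalid="ignore"):
        rho = np.array(
            [np.corrcoef(g, sres[:, j])[0, 1] if sres[:, j].std() > 0 else 0.0 for j in range(p)]
        )
    var_g = sum_ggV - sum_gV @ np.linalg.solve(sum_V, sum_gV)
    global_chi2 = float(u @ np.linalg.solve(var_g, u))
    global_p = float(stats.chi2.sf(global_chi2, df=p))
    table = pd.DataFrame(
        {"rho": rho, "chi2": chi, "p": pvals}, index=list(fit.coef.index)
    )
    return PHTestResult(
        table=table,
        global_chi2=global_chi2,
        global_p=global_p,
        df=p,
        transform=transform,
    )


def km_log_minus_log(
    data: SurvivalDataset,
    covariate: str,
    levels=None,
) -> dict:
    """Kaplan–Meier log(-log S) curves per level of one covariate.

    Returns a mapping level -> DataFrame(time, survival, loglog); the
    log(-log) transform is defined only where 0 < S < 1, so rows outside
    that range carry NaN.  Under proportional hazards the curves of two
    levels are vertically parallel.  A level whose subjects are all
    censored yields S = 1 everywhere and an empty transform (with a
    warning).
    """
    from lifelines import KaplanMeierFitter

    if covariate not in data.covariates.columns:
        raise KeyError(f"no covariate named {covariate!r}")
    values = data.covariates[covariate].to_numpy()
    if levels is None:
        levels = np.unique(values)
    out = {}
    for lev in levels:
        mask = values == lev
        if not mask.any():
            raise ValueError(f"no subjects at level {lev!r}")
        km = KaplanMeierFitter().fit(data.time[mask], data.event[mask])
        sf = km.survival_function_.iloc[:, 0]
        # drop the t=0 anchor row; keep observed times
        sf = sf[sf.index > 0]
        s = sf.to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            loglog = np.where((s > 0) & (s < 1), np.log(-np.log(s)), np.nan)
        df = pd.DataFrame({"time": sf.index.to_numpy(), "survival": s, "loglog": loglog})
        if data.event[mask].sum() == 0:
            warnings.warn(
                f"level {lev!r} of {covariate!r} has no events: survival is "
                "identically 1 and log(-log S) is undefined everywhere",
                UserWarning,
                stacklevel=2,
            )
            df = df.iloc[0:0]
        out[lev] = df
    return out
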