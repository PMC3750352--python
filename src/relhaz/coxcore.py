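"""Semi-parametric proportional-hazards engine with offsets and strata.

This module is the numerical foundation of the package: a Cox partial
likelihood with per-subject fixed offsets (linear-predictor terms whose
coefficient is frozen at 1) and optional strata (subgroups with their own
unspecified baseline hazard but shared regression coefficients).  Offsets
are what make the two-stage relative-survival estimator possible — the
expected-model contribution ``beta_e . z_e`` enters the relative-group
partial likelihood as a constant per subject — and strata are what the
stratified two-population model is built on.

The baseline hazard is never estimated: all inference is through the
partial likelihood, so only the ranks of the follow-up times matter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

REFERENCE = "reference"
RELATIVE = "relative"

__all__ = [
    "REFERENCE",
    "RELATIVE",
    "SurvivalDataset",
    "TiesPolicy",
    "CoxFit",
    "NonIdentifiableError",
    "log_partial_likelihood",
    "score_and_information",
    "fit_cox",
    "fit_stratified_cox",
    "wald_summary",
]


class NonIdentifiableError(ValueError):
    """The partial likelihood carries no information about a coefficient."""


@dataclass(frozen=True)
class TiesPolicy:
    """How tied event times are handled in the partial likelihood.

    ``breslow`` (default) treats every event at a tied time as sharing the
    full risk-set denominator — the direct generalization of the untied
    likelihood.  ``efron`` progressively down-weights the tied events'
    own contribution to the denominator and is more accurate when ties
    are heavy.
    """

    method: str = "breslow"

    def __post_init__(self) -> None:
        if self.method not in ("breslow", "efron"):
            raise ValueError(f"unknown ties method: {self.method!r}")


@dataclass
class SurvivalDataset:
    """Right-censored survival data for one or two labelled cohorts.

    Parameters
    ----------
    time:
        Follow-up times, nonnegative, in any consistent unit (only ranks
        enter the partial likelihood).
    event:
        1 if the failure was observed, 0 if censored.
    covariates:
        DataFrame of per-subject explanatory variables; column names are
        the covariate names and must be unique.  Complete cases only —
        missing values must be excluded (and counted) upstream.
    group:
        Optional per-subject label, ``"reference"`` or ``"relative"``.
    offset:
        Per-subject fixed addition to the linear predictor (default 0).
    strata:
        Optional integer stratum label; risk sets never cross strata.
    subject_id:
        Opaque per-subject label (default: the row number).
    """

    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame
    group: np.ndarray | None = None
    offset: np.ndarray | None = None
    strata: np.ndarray | None = None
    subject_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if not isinstance(self.covariates, pd.DataFrame):
            self.covariates = pd.DataFrame(self.covariates)
        self.covariates = self.covariates.reset_index(drop=True)
        n = self.time.shape[0]
        if self.event.shape[0] != n or len(self.covariates) != n:
            raise ValueError("time, event and covariates must have equal length")
        if np.any(self.time < 0) or np.any(~np.isfinite(self.time)):
            raise ValueError("all times must be finite and >= 0")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")
        self.event = self.event.astype(int)
        if self.covariates.columns.duplicated().any():
            raise ValueError("covariate names must be unique")
        if self.covariates.isna().any().any():
            raise ValueError(
                "covariates contain missing values; apply complete-case "
                "exclusion before constructing the dataset"
            )
        if self.offset is None:
            self.offset = np.zeros(n)
        else:
            self.offset = np.asarray(self.offset, dtype=float)
            if self.offset.shape[0] != n:
                raise ValueError("offset length mismatch")
        if self.group is not None:
            self.group = np.asarray(self.group, dtype=object)
            bad = set(np.unique(self.group)) - {REFERENCE, RELATIVE}
            if bad:
                raise ValueError(f"unknown group labels: {sorted(bad)}")
        if self.strata is not None:
            self.strata = np.asarray(self.strata)
            if self.strata.shape[0] != n:
                raise ValueError("strata length mismatch")
        if self.subject_id is None:
            self.subject_id = np.arange(n)
        else:
            self.subject_id = np.asarray(self.subject_id, dtype=object)

    # -- convenience -------------------------------------------------

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates.columns)

    def subset(self, mask: np.ndarray) -> "SurvivalDataset":
        mask = np.asarray(mask)
        return SurvivalDataset(
            time=self.time[mask],
            event=self.event[mask],
            covariates=self.covariates.loc[mask].reset_index(drop=True),
            group=None if self.group is None else self.group[mask],
            offset=self.offset[mask],
            strata=None if self.strata is None else self.strata[mask],
            subject_id=self.subject_id[mask],
        )

    def group_subset(self, label: str) -> "SurvivalDataset":
        if self.group is None:
            raise ValueError("dataset carries no group labels")
        return self.subset(self.group == label)

    def with_covariates(self, names: Sequence[str]) -> "SurvivalDataset":
        missing = [c for c in names if c not in self.covariates.columns]
        if missing:
            raise KeyError(f"covariates not in dataset: {missing}")
        return SurvivalDataset(
            time=self.time,
            event=self.event,
            covariates=self.covariates[list(names)].copy(),
            group=self.group,
            offset=self.offset,
            strata=self.strata,
            subject_id=self.subject_id,
        )

    def with_offset(self, offset: np.ndarray) -> "SurvivalDataset":
        return SurvivalDataset(
            time=self.time,
            event=self.event,
            covariates=self.covariates,
            group=self.group,
            offset=np.asarray(offset, dtype=float),
            strata=self.strata,
            subject_id=self.subject_id,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "time": self.time,
                "event": self.event,
            }
        )
        if self.group is not None:
            df["group"] = self.group
        for c in self.covariates.columns:
            df[c] = self.covariates[c].to_numpy()
        return df


@dataclass
class CoxFit:
    """Result of a partial-likelihood fit.

    ``coef`` and ``vcov`` are indexed by covariate name; ``vcov`` is the
    inverse observed information at the maximum.  ``loglik_null`` is the
    partial log-likelihood at beta = 0 with the same offsets, so
    ``loglik >= loglik_null`` always holds at a true maximum.
    """

    coef: pd.Series
    vcov: pd.DataFrame
    loglik: float
    loglik_null: float
    n_events: int
    n_subjects: int
    iterations: int
    converged: bool
    ties: TiesPolicy = field(default_factory=TiesPolicy)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov.to_numpy())), index=self.coef.index)

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        return wald_summary(self, level=level)


# ----------------------------------------------------------------------
# partial likelihood internals
# ----------------------------------------------------------------------


def _strata_indices(data: SurvivalDataset) -> list[np.ndarray]:
    if data.strata is None:
        return [np.arange(data.n)]
    out = []
    for s in np.unique(data.strata):
        idx = np.flatnonzero(data.strata == s)
        if data.event[idx].sum() == 0:
            logger.warning(
                "stratum %r has no events and contributes nothing to the fit", s
            )
            continue
        out.append(idx)
    return out


def _stratum_quantities(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    beta: np.ndarray,
    method: str,
    want_derivs: bool,
):
    """Log partial likelihood (and optionally score/information) for one stratum.

    Risk set at an event time t is every subject with time >= t, so a
    subject censored exactly at an event time is still at risk there.
    The linear predictor is shifted by its maximum before exponentiation;
    the shift cancels exactly in every term.
    """
    n, p = X.shape
    eta = X @ beta + offset
    shift = eta.max()
    order = np.argsort(time, kind="stable")
    t = time[order]
    d = event[order]
    Xs = X[order]
    eta_s = eta[order] - shift
    w = np.exp(eta_s)

    # reverse cumulative sums: S0[i] = sum of w over subjects with sort pos >= i
    S0 = np.cumsum(w[::-1])[::-1]
    wX = w[:, None] * Xs
    S1 = np.cumsum(wX[::-1], axis=0)[::-1]
    S2 = None
    if want_derivs:
        wXX = wX[:, :, None] * Xs[:, None, :]
        S2 = np.cumsum(wXX[::-1], axis=0)[::-1]

    # tie blocks share one risk set, anchored at the block's first sort position
    new_block = np.r_[True, t[1:] != t[:-1]]
    block_start_of = np.flatnonzero(new_block)[np.cumsum(new_block) - 1]

    ev = np.flatnonzero(d == 1)
    if ev.size == 0:
        raise ValueError("no events in stratum: the partial likelihood is empty")
    anchors = block_start_of[ev]

    loglik = 0.0
    U = np.zeros(p)
    I = np.zeros((p, p))

    if method == "breslow":
        s0 = S0[anchors]
        loglik = float(eta_s[ev].sum() - np.log(s0).sum())
        if want_derivs:
            mu = S1[anchors] / s0[:, None]
            U = Xs[ev].sum(axis=0) - mu.sum(axis=0)
            V = S2[anchors] / s0[:, None, None] - mu[:, :, None] * mu[:, None, :]
            I = V.sum(axis=0)
        return loglik, U, I

    # Efron: iterate over tie blocks holding at least one event
    for start in np.unique(anchors):
        in_block = ev[anchors == start]
        nd = in_block.size
        s0, s1 = S0[start], S1[start]
        s2 = S2[start] if want_derivs else None
        D0 = w[in_block].sum()
        D1 = wX[in_block].sum(axis=0)
        loglik += float(eta_s[in_block].sum())
        if want_derivs:
            D2 = (wX[in_block][:, :, None] * Xs[in_block][:, None, :]).sum(axis=0)
            U += Xs[in_block].sum(axis=0)
        for l in range(nd):
            f = l / nd
            den = s0 - f * D0
            loglik -= float(np.log(den))
            if want_derivs:
                m1 = (s1 - f * D1) / den
                U -= m1
                I += (s2 - f * D2) / den - np.outer(m1, m1)
    return loglik, U, I


def _accumulate_arrays(time, event, X, offset, idx_list, beta, ties, want_derivs):
    loglik = 0.0
    U = np.zeros(X.shape[1])
    I = np.zeros((X.shape[1], X.shape[1]))
    for idx in idx_list:
        ll, u, i = _stratum_quantities(
            time[idx], event[idx], X[idx], offset[idx], beta, ties.method, want_derivs
        )
        loglik += ll
        U += u
        I += i
    return loglik, U, I


def _accumulate(
    data: SurvivalDataset,
    beta: np.ndarray,
    ties: TiesPolicy,
    want_derivs: bool,
):
    X = data.covariates.to_numpy(dtype=float)
    if beta.shape[0] != X.shape[1]:
        raise ValueError(
            f"beta has length {beta.shape[0]} but data has {X.shape[1]} covariates"
        )
    if data.n_events == 0:
        raise ValueError("no events in data: the partial likelihood is empty")
    return _accumulate_arrays(
        data.time, data.event, X, data.offset, _strata_indices(data), beta, ties, want_derivs
    )


# ----------------------------------------------------------------------
# public operations
# ----------------------------------------------------------------------


def log_partial_likelihood(
    beta: np.ndarray | Sequence[float],
    data: SurvivalDataset,
    ties: TiesPolicy | None = None,
) -> float:
    """Cox partial log-likelihood at ``beta`` with the dataset's offsets.

    Each observed failure contributes its linear predictor minus the log
    of the sum of exp(linear predictor) over its risk set (all subjects,
    within the same stratum, whose time is >= the failure time).
    """
    ties = ties or TiesPolicy()
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    ll, _, _ = _accumulate(data, beta, ties, want_derivs=False)
    return ll


def score_and_information(
    beta: np.ndarray | Sequence[float],
    data: SurvivalDataset,
    ties: TiesPolicy | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient and observed information of the partial log-likelihood."""
    ties = ties or TiesPolicy()
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    _, U, I = _accumulate(data, beta, ties, want_derivs=True)
    return U, I


def _check_identifiable(data: SurvivalDataset) -> None:
    X = data.covariates.to_numpy(dtype=float)
    ptp = X.max(axis=0) - X.min(axis=0)
    const = [c for c, r in zip(data.covariates.columns, ptp) if r == 0.0]
    if const:
        raise NonIdentifiableError(
            f"constant covariates in fitted sample: {const}; "
            "the partial likelihood does not depend on their coefficients"
        )


def fit_cox(
    data: SurvivalDataset,
    ties: TiesPolicy | None = None,
    init: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 100,
    coef_bound: float = 15.0,
) -> CoxFit:
    """Maximize the partial likelihood by Newton–Raphson with step-halving.

    If ``data.strata`` is set, risk sets are formed within strata and the
    stratum-specific partial log-likelihoods are summed (one shared
    coefficient vector).  A fitted coefficient with absolute value above
    ``coef_bound`` is flagged as non-convergence — the symptom of a
    monotone likelihood (e.g. a covariate perfectly separating events).
    """
    ties = ties or TiesPolicy()
    if data.n_events == 0:
        raise ValueError("no events in data: nothing to fit")
    _check_identifiable(data)
    return _fit_arrays(
        data.time,
        data.event,
        data.covariates.to_numpy(dtype=float),
        data.offset,
        _strata_indices(data),
        data.covariate_names,
        ties,
        init=init,
        tol=tol,
        max_iter=max_iter,
        coef_bound=coef_bound,
    )


def _fit_arrays(
    time,
    event,
    X,
    offset,
    idx_list,
    names,
    ties,
    init=None,
    tol: float = 1e-9,
    max_iter: int = 100,
    coef_bound: float = 15.0,
) -> CoxFit:
    """Newton core on raw arrays; callers are responsible for validation."""
    p = X.shape[1]
    beta = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()

    def _acc(b, want):
        return _accumulate_arrays(time, event, X, offset, idx_list, b, ties, want)

    ll, U, I = _acc(beta, True)
    iterations = 0
    while iterations < max_iter and np.max(np.abs(U)) >= tol:
        iterations += 1
        try:
            step = np.linalg.solve(I, U)
        except np.linalg.LinAlgError as exc:
            raise NonIdentifiableError(
                "singular information matrix; covariates may be collinear"
            ) from exc
        new_beta = beta + step
        new_ll, new_U, new_I = _acc(new_beta, True)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll - 1e-12) and halvings < 40:
            step /= 2.0
            halvings += 1
            new_beta = beta + step
            new_ll, new_U, new_I = _acc(new_beta, True)
        if halvings >= 40:
            break  # cannot improve: stop at the current iterate
        beta, ll, U, I = new_beta, new_ll, new_U, new_I
    converged = bool(np.max(np.abs(U)) < tol)

    if np.any(np.abs(beta) > coef_bound):
        converged = False
        warnings.warn(
            "coefficient magnitude exceeds bound; likely monotone likelihood "
            "(infinite maximum), estimates are unreliable",
            RuntimeWarning,
            stacklevel=2,
        )

    try:
        vcov = np.linalg.inv(I)
    except np.linalg.LinAlgError as exc:
        raise NonIdentifiableError("singular information matrix at the maximum") from exc

    ll_null, _, _ = _acc(np.zeros(p), False)
    names = list(names)
    return CoxFit(
        coef=pd.Series(beta, index=names),
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        loglik=float(ll),
        loglik_null=float(ll_null),
        n_events=int(event.sum()),
        n_subjects=int(len(time)),
        iterations=iterations,
        converged=converged,
        ties=ties,
    )


def fit_stratified_cox(
    data: SurvivalDataset,
    ties: TiesPolicy | None = None,
    **kwargs,
) -> CoxFit:
    """Fit one coefficient vector across strata with stratum-specific baselines.

    Thin wrapper over :func:`fit_cox` that requires stratum labels; risk
    sets never cross strata, and strata without events are dropped from
    the likelihood (with a log message).
    """
    if data.strata is None:
        raise ValueError("fit_stratified_cox requires stratum labels")
    return fit_cox(data, ties=ties, **kwargs)


def wald_summary(fit: CoxFit, level: float = 0.95) -> pd.DataFrame:
    """Per-coefficient hazard ratios, Wald confidence intervals and p-values.

    CI = exp(coef +/- z * SE) at the requested level; p is the two-sided
    normal test of coef / SE.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = fit.se
    coef = fit.coef
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = coef / se
    p = 2.0 * stats.norm.sf(np.abs(zval))
    return pd.DataFrame(
        {
            "coef": coef,
            "se": se,
            "hr": np.exp(coef),
            "ci_low": np.exp(coef - z * se),
            "ci_high": np.exp(coef + z * se),
            "p": p,
        },
        index=coef.index,
    )
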