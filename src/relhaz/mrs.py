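"""Multiplicative-regression model for relative survival (MRS).

Two-stage estimator for comparing risk-factor effects between a
reference cohort and a relative cohort:

1. *Expected model*: a Cox fit on the reference cohort alone gives
   coefficients ``beta_e`` over the expected-model covariates.
2. *Relative model*: a Cox fit on the relative cohort in which the
   expected linear predictor ``beta_e . z_e`` enters as a fixed
   per-subject offset. For a covariate also in the expected model, the
   fitted ``beta_r`` is a log weighting factor — exp(beta_r) is the
   ratio of the relative group's hazard ratio to the reference group's,
   so beta_r = 0 means the covariate acts identically in both groups.
   For a covariate absent from the expected model, exp(beta_r) is simply
   that covariate's hazard ratio within the relative group.

Because ``beta_e`` is itself estimated (not read off a life table), its
sampling noise must be propagated: ``run_mc_bootstrap`` repeats the
relative fit B times, each time (a) redrawing the expected coefficients
from their asymptotic multivariate normal and (b) resampling the
relative cohort with replacement, and summarizes the B draws into SDs,
confidence intervals and Wald p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coxcore import (
    CoxFit,
    NonIdentifiableError,
    SurvivalDataset,
    TiesPolicy,
    _fit_arrays,
    fit_cox,
    wald_summary,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExpectedFit",
    "MCBootstrapConfig",
    "RelativeFit",
    "fit_expected_model",
    "relative_offsets",
    "fit_relative_point",
    "run_mc_bootstrap",
    "backward_select",
    "mrs_report",
]


@dataclass
class ExpectedFit:
    """Expected-hazard Cox model fitted on the reference cohort."""

    coef_e: pd.Series
    vcov_e: pd.DataFrame
    source_fit: CoxFit | None = None

    @property
    def covariates(self) -> list[str]:
        return list(self.coef_e.index)


@dataclass(frozen=True)
class MCBootstrapConfig:
    """Settings for the Monte-Carlo + bootstrap variance procedure.

    ``B`` iterations; ``ci_method`` is ``"percentile"`` (quantiles of the
    draws) or ``"normal"`` (point estimate +/- z * SD of draws);
    ``max_refit_failures`` caps how many non-converging resamples may be
    dropped and replaced before the run aborts.
    """

    B: int = 1000
    seed: int = 0
    ci_level: float = 0.95
    ci_method: str = "percentile"
    max_refit_failures: int = 50

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("B must be >= 2")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.ci_method not in ("percentile", "normal"):
            raise ValueError(f"unknown ci_method: {self.ci_method!r}")
        if self.max_refit_failures < 0:
            raise ValueError("max_refit_failures must be >= 0")


@dataclass
class RelativeFit:
    """MRS point estimates plus the B Monte-Carlo/bootstrap draws.

    ``coef_r_point`` is the relative fit at the expected point estimate;
    the draws serve only to measure dispersion.  ``p`` is the two-sided
    normal test of ``coef_r_point / sd``.
    """

    coef_r_point: pd.Series
    draws: pd.DataFrame
    mean: pd.Series
    sd: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p: pd.Series
    ci_level: float
    ci_method: str
    n_failed_refits: int
    point_fit: CoxFit | None = None

    @property
    def B(self) -> int:
        return len(self.draws)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef_r_point,
                "sd": self.sd,
                "hr": np.exp(self.coef_r_point),
                "ci_low": np.exp(self.ci_low),
                "ci_high": np.exp(self.ci_high),
                "p": self.p,
            }
        )


def fit_expected_model(
    reference_data: SurvivalDataset,
    covariates_e: Sequence[str],
    ties: TiesPolicy | None = None,
    **fit_kwargs,
) -> ExpectedFit:
    """Fit the expected-hazard Cox model on the reference cohort.

    ``reference_data`` must contain reference-group subjects only (pass
    ``data.group_subset("reference")`` if labels are attached); the
    variance matrix comes from the observed information.
    """
    covariates_e = list(covariates_e)
    if not covariates_e:
        raise ValueError("the expected model needs at least one covariate")
    if reference_data.group is not None and (reference_data.group != "reference").any():
        raise ValueError("reference_data must contain only reference-group subjects")
    fit = fit_cox(reference_data.with_covariates(covariates_e), ties=ties, **fit_kwargs)
    return ExpectedFit(coef_e=fit.coef, vcov_e=fit.vcov, source_fit=fit)


def relative_offsets(
    relative_data: SurvivalDataset,
    expected: ExpectedFit | pd.Series,
) -> np.ndarray:
    """Per-subject offsets ``beta_e . z_e`` for the relative cohort.

    Every expected-model covariate must be present (by name) in the
    relative data; subjects' values of those covariates are dotted with
    the expected coefficients.
    """
    coef_e = expected.coef_e if isinstance(expected, ExpectedFit) else expected
    missing = [c for c in coef_e.index if c not in relative_data.covariates.columns]
    if missing:
        raise KeyError(
            f"expected-model covariates missing from relative data: {missing}"
        )
    Z = relative_data.covariates[list(coef_e.index)].to_numpy(dtype=float)
    return Z @ coef_e.to_numpy(dtype=float)


def fit_relative_point(
    relative_data: SurvivalDataset,
    expected: ExpectedFit,
    covariates_r: Sequence[str],
    ties: TiesPolicy | None = None,
    coef_e: pd.Series | None = None,
    **fit_kwargs,
) -> CoxFit:
    """Relative-model Cox fit with the expected coefficients held fixed.

    Equivalent to a Cox fit on the relative cohort whose offsets are
    ``beta_e . z_e``; the returned coefficients are the relative-model
    ``beta_r``.  ``coef_e`` overrides the expected point estimate (used
    internally by the Monte-Carlo step).
    """
    covariates_r = list(covariates_r)
    if not covariates_r:
        raise ValueError("the relative model needs at least one covariate")
    if relative_data.group is not None and (relative_data.group != "relative").any():
        raise ValueError("relative_data must contain only relative-group subjects")
    offs = relative_offsets(relative_data, coef_e if coef_e is not None else expected)
    data = relative_data.with_offset(relative_data.offset + offs)
    return fit_cox(data.with_covariates(covariates_r), ties=ties, **fit_kwargs)


def _mvn_root(vcov: np.ndarray, jitter: float = 1e-10) -> np.ndarray:
    """Symmetric square root tolerant of a semidefinite variance matrix."""
    v = np.asarray(vcov, dtype=float)
    v = 0.5 * (v + v.T) + jitter * np.eye(v.shape[0])
    vals, vecs = np.linalg.eigh(v)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def run_mc_bootstrap(
    relative_data: SurvivalDataset,
    expected: ExpectedFit,
    covariates_r: Sequence[str],
    config: MCBootstrapConfig | None = None,
    ties: TiesPolicy | None = None,
    mvn: bool = True,
    resample: bool = True,
) -> RelativeFit:
    """B-iteration Monte-Carlo + bootstrap uncertainty for the relative model.

    Each iteration draws expected coefficients from
    MVN(coef_e, vcov_e) — the expected-model sampling noise — and refits
    the relative model on a with-replacement resample of the relative
    cohort — the sample-to-sample fluctuation.  Two independent seeded
    streams drive the two sources, so either can be switched off
    (``mvn=False`` freezes the expected coefficients; ``resample=False``
    keeps the original sample) to isolate one variance component.

    Iterations whose refit fails (e.g. a resample with a constant
    covariate or a monotone likelihood) are dropped, counted and
    replaced, up to ``max_refit_failures`` extra attempts.
    """
    config = config or MCBootstrapConfig()
    covariates_r = list(covariates_r)
    point = fit_relative_point(relative_data, expected, covariates_r, ties=ties)

    ss = np.random.SeedSequence(config.seed)
    s_mvn, s_boot = ss.spawn(2)
    rng_mvn = np.random.default_rng(s_mvn)
    rng_boot = np.random.default_rng(s_boot)

    coef_e = expected.coef_e.to_numpy(dtype=float)
    root = _mvn_root(expected.vcov_e.to_numpy())
    p_e = coef_e.shape[0]
    n_r = relative_data.n

    # pre-extract arrays once; each refit then avoids re-validating a dataset
    ties_ = ties or TiesPolicy()
    time = relative_data.time
    event = relative_data.event
    Z_e = relative_data.covariates[list(expected.coef_e.index)].to_numpy(dtype=float)
    X_r = relative_data.covariates[covariates_r].to_numpy(dtype=float)
    base_off = relative_data.offset

    draws = []
    failures = 0
    while len(draws) < config.B:
        beta_star = coef_e + (root @ rng_mvn.standard_normal(p_e) if mvn else 0.0)
        idx = rng_boot.integers(0, n_r, size=n_r) if resample else np.arange(n_r)
        Xb = X_r[idx]
        try:
            if (Xb.max(axis=0) - Xb.min(axis=0)).min() == 0.0:
                raise NonIdentifiableError("constant covariate in resample")
            fit = _fit_arrays(
                time[idx],
                event[idx],
                Xb,
                base_off[idx] + Z_e[idx] @ beta_star,
                [np.arange(n_r)],
                covariates_r,
                ties_,
            )
            if not fit.converged:
                raise NonIdentifiableError("refit did not converge")
        except (ValueError, np.linalg.LinAlgError) as exc:
            failures += 1
            logger.debug("bootstrap refit %d failed: %s", len(draws) + failures, exc)
            if failures > config.max_refit_failures:
                raise RuntimeError(
                    f"{failures} bootstrap refits failed (cap "
                    f"{config.max_refit_failures}); last error: {exc}"
                ) from exc
            continue
        draws.append(fit.coef.to_numpy())

    draws = pd.DataFrame(np.vstack(draws), columns=covariates_r)
    mean = draws.mean()
    sd = draws.std(ddof=1)
    alpha = 1.0 - config.ci_level
    if config.ci_method == "percentile":
        ci_low = draws.quantile(alpha / 2.0)
        ci_high = draws.quantile(1.0 - alpha / 2.0)
    else:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        ci_low = point.coef - z * sd
        ci_high = point.coef + z * sd
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = point.coef / sd
    p = pd.Series(2.0 * stats.norm.sf(np.abs(zval)), index=point.coef.index)
    return RelativeFit(
        coef_r_point=point.coef,
        draws=draws,
        mean=mean,
        sd=sd,
        ci_low=ci_low,
        ci_high=ci_high,
        p=p,
        ci_level=config.ci_level,
        ci_method=config.ci_method,
        n_failed_refits=failures,
        point_fit=point,
    )


def backward_select(
    data: SurvivalDataset,
    candidates: Sequence[str],
    screen_alpha: float = 0.20,
    keep_alpha: float = 0.05,
    forced: Sequence[str] = (),
    ties: TiesPolicy | None = None,
) -> list[str]:
    """Two-stage covariate selection: univariable screen, then backward Wald.

    Stage 1 keeps each non-forced candidate whose univariable Wald
    p-value is below ``screen_alpha``.  Stage 2 repeatedly refits the
    multivariable model and drops the non-forced covariate with the
    largest Wald p-value >= ``keep_alpha`` until every remaining
    covariate passes or is forced.  Forced covariates bypass both
    stages.  The dataset's offsets are honoured throughout, so the
    procedure applies equally to plain and offset (relative-model) fits.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    forced = list(forced)
    unknown = [c for c in forced if c not in candidates]
    if unknown:
        raise ValueError(f"forced covariates not among candidates: {unknown}")

    kept = []
    for c in candidates:
        if c in forced:
            kept.append(c)
            continue
        fit = fit_cox(data.with_covariates([c]), ties=ties)
        if wald_summary(fit)["p"].iloc[0] < screen_alpha:
            kept.append(c)

    while kept:
        droppable = [c for c in kept if c not in forced]
        if not droppable:
            break
        fit = fit_cox(data.with_covariates(kept), ties=ties)
        pvals = wald_summary(fit)["p"]
        worst = pvals[droppable].idxmax()
        if pvals[worst] >= keep_alpha:
            kept.remove(worst)
        else:
            break
    return kept


def mrs_report(
    expected: ExpectedFit,
    relative: RelativeFit,
    level: float = 0.95,
) -> pd.DataFrame:
    """Combined report: expected-model HRs beside relative-model results.

    One row per covariate, grouped into three blocks — covariates in the
    expected model only, in both models (where the relative HR column is
    the weighting factor), and in the relative model only.
    """
    exp_tab = wald_summary(expected.source_fit, level=level) if expected.source_fit else None
    rel_tab = relative.summary()
    rows = []
    rel_names = set(rel_tab.index)
    exp_names = list(expected.coef_e.index)
    for name in exp_names:
        block = "both" if name in rel_names else "expected_only"
        row = {"covariate": name, "block": block}
        if exp_tab is not None:
            row.update(
                hr_expected=exp_tab.loc[name, "hr"],
                ci_low_expected=exp_tab.loc[name, "ci_low"],
                ci_high_expected=exp_tab.loc[name, "ci_high"],
                p_expected=exp_tab.loc[name, "p"],
            )
        rows.append(row)
    for name in rel_tab.index:
        if name in exp_names:
            continue
        rows.append({"covariate": name, "block": "relative_only"})
    out = pd.DataFrame(rows).set_index("covariate")
    for col in ("hr", "ci_low", "ci_high", "p"):
        out[f"{col}_relative"] = rel_tab[col].reindex(out.index)
    order = {"expected_only": 0, "both": 1, "relative_only": 2}
    return out.sort_values("block", key=lambda s: s.map(order), kind="stable")
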