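"""Stratified Cox model (SCM) with covariate-role subvectors.

One partial likelihood over both cohorts, with the group as stratum
(each group keeps its own unspecified baseline hazard) and the covariate
vector decomposed into four roles:

* ``e`` — enters the reference hazard only (zeroed for relative-group
  subjects);
* ``c`` — common effect in both groups;
* ``s`` — a flag on a ``c`` covariate adding a separate relative-group
  effect through an interaction column ``value * 1[group = relative]``;
* ``r`` — enters the relative hazard only (zeroed for reference-group
  subjects).

For a covariate with roles c+s the hazard ratio is exp(beta_c) in the
reference group and exp(beta_c + beta_s) in the relative group, so
exp(beta_s) is the weighting factor between the two groups' hazard
ratios — the same quantity the multiplicative relative-survival model
estimates, obtained here from a single joint fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coxcore import (
    REFERENCE,
    RELATIVE,
    CoxFit,
    SurvivalDataset,
    TiesPolicy,
    fit_stratified_cox,
    wald_summary,
)

__all__ = ["RoleMap", "SCMFit", "build_stratified_design", "fit_scm", "group_hazard_ratios"]

_SEP_SUFFIX = ":relative"


@dataclass(frozen=True)
class RoleMap:
    """Assignment of each covariate to the e / c / s / r subvectors.

    ``roles`` maps covariate name to ``"e"``, ``"c"``, ``"cs"`` (or
    ``"s"``, shorthand for common-with-separate-effect) or ``"r"``.
    A separate effect is only meaningful on a common covariate, so the
    s-flag always implies base role c.
    """

    roles: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.roles:
            raise ValueError("role map needs at least one covariate")
        norm = {}
        for name, role in dict(self.roles).items():
            role = role.lower().replace("+", "")
            if role in ("s", "cs", "sc"):
                norm[name] = "cs"
            elif role in ("e", "c", "r"):
                norm[name] = role
            else:
                raise ValueError(f"unknown role {role!r} for covariate {name!r}")
        object.__setattr__(self, "roles", norm)

    def names(self, *roles: str) -> list[str]:
        return [n for n, r in self.roles.items() if r in roles]

    @property
    def e(self) -> list[str]:
        return self.names("e")

    @property
    def c(self) -> list[str]:
        """All common covariates, separate-effect ones included."""
        return self.names("c", "cs")

    @property
    def s(self) -> list[str]:
        return self.names("cs")

    @property
    def r(self) -> list[str]:
        return self.names("r")


def build_stratified_design(data: SurvivalDataset, roles: RoleMap) -> SurvivalDataset:
    """Expand covariates by role and set strata to the group label.

    Column order is e-block (zeroed for relative subjects), c-block
    (unchanged), s-block (interaction columns ``name:relative`` =
    value * group indicator), r-block (zeroed for reference subjects).
    Strata are 0 for the reference group and 1 for the relative group.
    """
    if data.group is None:
        raise ValueError("data must carry group labels")
    groups = set(np.unique(data.group))
    if groups != {REFERENCE, RELATIVE}:
        raise ValueError(f"data must contain both groups, found {sorted(groups)}")
    missing = [n for n in roles.roles if n not in data.covariates.columns]
    if missing:
        raise KeyError(f"role-mapped covariates absent from data: {missing}")

    is_rel = (data.group == RELATIVE).astype(float)
    cols = {}
    for name in roles.e:
        cols[name] = data.covariates[name].to_numpy(dtype=float) * (1.0 - is_rel)
    for name in roles.c:
        cols[name] = data.covariates[name].to_numpy(dtype=float)
    for name in roles.s:
        cols[name + _SEP_SUFFIX] = data.covariates[name].to_numpy(dtype=float) * is_rel
    for name in roles.r:
        v = data.covariates[name].to_numpy(dtype=float)
        if v[is_rel == 1.0].std() == 0.0 and v[is_rel == 0.0].std() > 0.0:
            warnings.warn(
                f"relative-only covariate {name!r} varies in the reference group "
                "but not in the relative group; its role may be mis-assigned",
                UserWarning,
                stacklevel=2,
            )
        cols[name] = v * is_rel

    return SurvivalDataset(
        time=data.time,
        event=data.event,
        covariates=pd.DataFrame(cols),
        group=data.group,
        offset=data.offset,
        strata=is_rel.astype(int),
        subject_id=data.subject_id,
    )


@dataclass
class SCMFit:
    """Joint stratified fit with role-block accessors."""

    fit: CoxFit
    roles: RoleMap
    stratum_events: dict

    @property
    def coef(self) -> pd.Series:
        return self.fit.coef

    @property
    def vcov(self) -> pd.DataFrame:
        return self.fit.vcov

    def block(self, role: str) -> pd.Series:
        """Coefficients of one role block (``"e"``, ``"c"``, ``"s"`` or ``"r"``)."""
        if role == "s":
            names = [n + _SEP_SUFFIX for n in self.roles.s]
        else:
            names = getattr(self.roles, role)
        return self.fit.coef[names]

    def weighting(self, name: str) -> float:
        """Log weighting factor (separate effect) of a c+s covariate."""
        return float(self.fit.coef[name + _SEP_SUFFIX])

    def weighting_se(self, name: str) -> float:
        return float(np.sqrt(self.fit.vcov.loc[name + _SEP_SUFFIX, name + _SEP_SUFFIX]))

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        return wald_summary(self.fit, level=level)


def fit_scm(
    data: SurvivalDataset,
    roles: RoleMap,
    ties: TiesPolicy | None = None,
    **fit_kwargs,
) -> SCMFit:
    """Build the role-expanded design and fit the stratified partial likelihood."""
    design = build_stratified_design(data, roles)
    for label in (REFERENCE, RELATIVE):
        if data.event[data.group == label].sum() == 0:
            raise ValueError(f"the {label} stratum has no events")
    fit = fit_stratified_cox(design, ties=ties, **fit_kwargs)
    ev = {
        REFERENCE: int(data.event[data.group == REFERENCE].sum()),
        RELATIVE: int(data.event[data.group == RELATIVE].sum()),
    }
    return SCMFit(fit=fit, roles=roles, stratum_events=ev)


def _row(coef: float, se: float, level: float, p: float | None = None) -> dict:
    z = stats.norm.ppf(0.5 + level / 2.0)
    if p is None:
        p = 2.0 * stats.norm.sf(abs(coef / se)) if se > 0 else np.nan
    return {
        "hr": np.exp(coef),
        "ci_low": np.exp(coef - z * se),
        "ci_high": np.exp(coef + z * se),
        "p": p,
    }


def group_hazard_ratios(scm: SCMFit, level: float = 0.95) -> dict[str, pd.DataFrame]:
    """Per-group hazard-ratio tables from the joint fit.

    The reference table reports exp(beta_e) and exp(beta_c); the
    relative table reports exp(beta_c) for common-only covariates,
    composed hazard ratios exp(beta_c + beta_s) for separate-effect
    covariates (variance by the delta method from the joint covariance:
    var_c + var_s + 2 cov) and exp(beta_r).  For a separate-effect
    covariate the relative-table p-value tests the *difference* between
    groups, i.e. beta_s = 0.
    """
    coef = scm.fit.coef
    vcov = scm.fit.vcov
    roles = scm.roles
    ref_rows, rel_rows = {}, {}
    for name in roles.e:
        ref_rows[name] = {"block": "e", **_row(coef[name], np.sqrt(vcov.loc[name, name]), level)}
    for name in roles.c:
        se = np.sqrt(vcov.loc[name, name])
        ref_rows[name] = {
            "block": "c+s" if name in roles.s else "c",
            **_row(coef[name], se, level),
        }
        if name in roles.s:
            sname = name + _SEP_SUFFIX
            comp = coef[name] + coef[sname]
            var = (
                vcov.loc[name, name]
                + vcov.loc[sname, sname]
                + 2.0 * vcov.loc[name, sname]
            )
            se_s = np.sqrt(vcov.loc[sname, sname])
            p_diff = 2.0 * stats.norm.sf(abs(coef[sname] / se_s)) if se_s > 0 else np.nan
            rel_rows[name] = {
                "block": "c+s",
                **_row(comp, np.sqrt(var), level, p=p_diff),
            }
        else:
            rel_rows[name] = {"block": "c", **_row(coef[name], se, level)}
    for name in roles.r:
        rel_rows[name] = {"block": "r", **_row(coef[name], np.sqrt(vcov.loc[name, name]), level)}

    ref = pd.DataFrame.from_dict(ref_rows, orient="index")
    rel = pd.DataFrame.from_dict(rel_rows, orient="index")
    ref.index.name = rel.index.name = "covariate"
    return {REFERENCE: ref, RELATIVE: rel}
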