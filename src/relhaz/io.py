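"""Cohort CSV reading/writing, analysis configuration and report files.

The on-disk schema is a plain delimited file with one header row and one
row per subject: a follow-up time column, a 0/1 event column, a group
column holding the two cohort labels, and any number of covariate
columns.  Rows with a missing value in any modeled column are excluded
(complete-case analysis) and the exclusions are counted per group, since
reporting how many subjects were dropped is part of the analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .coxcore import REFERENCE, RELATIVE, SurvivalDataset, TiesPolicy
from .mrs import MCBootstrapConfig, fit_expected_model, mrs_report, run_mc_bootstrap
from .scm import RoleMap, fit_scm, group_hazard_ratios

logger = logging.getLogger(__name__)

__all__ = [
    "ColumnMapping",
    "AnalysisConfig",
    "read_cohort_csv",
    "write_cohort_csv",
    "run_mrs_cli",
    "run_scm_cli",
]


@dataclass(frozen=True)
class ColumnMapping:
    """Which CSV columns hold what, and how group labels map to cohorts."""

    time: str = "time"
    event: str = "event"
    group: str = "group"
    reference_label: str = REFERENCE
    relative_label: str = RELATIVE
    subject_id: str | None = "subject_id"
    covariates: tuple | None = None  # None: every remaining column


def read_cohort_csv(
    path,
    mapping: ColumnMapping | None = None,
) -> tuple[SurvivalDataset, dict]:
    """Read a subject-level cohort CSV with complete-case exclusion.

    Returns the dataset plus an exclusion report: per-group counts of
    rows dropped for missing modeled values, with percentages.  Negative
    times, event codes outside {0, 1} and missing mapped columns are
    errors.
    """
    mapping = mapping or ColumnMapping()
    df = pd.read_csv(path)
    needed = [mapping.time, mapping.event, mapping.group]
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing mapped columns in {path}: {missing_cols}")
    if mapping.covariates is None:
        skip = set(needed) | {mapping.subject_id}
        covariates = [c for c in df.columns if c not in skip]
    else:
        covariates = list(mapping.covariates)
        absent = [c for c in covariates if c not in df.columns]
        if absent:
            raise ValueError(f"covariate columns absent from {path}: {absent}")

    ev = df[mapping.event]
    bad_ev = ev.dropna()[~ev.dropna().isin((0, 1))]
    if len(bad_ev):
        raise ValueError(
            f"event column {mapping.event!r} contains values outside {{0,1}}: "
            f"{sorted(bad_ev.unique())}"
        )
    if (df[mapping.time].dropna() < 0).any():
        raise ValueError(f"time column {mapping.time!r} contains negative values")
    labels = {mapping.reference_label: REFERENCE, mapping.relative_label: RELATIVE}
    unknown = set(df[mapping.group].dropna().unique()) - set(labels)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(map(str, unknown))}")

    modeled = needed + covariates
    complete = df[modeled].notna().all(axis=1)
    exclusions = {"total_rows": len(df), "excluded": int((~complete).sum()), "by_group": {}}
    for raw, canon in labels.items():
        grp = df[mapping.group] == raw
        n_grp = int(grp.sum())
        n_excl = int((grp & ~complete).sum())
        exclusions["by_group"][canon] = {
            "rows": n_grp,
            "excluded": n_excl,
            "excluded_pct": round(100.0 * n_excl / n_grp, 2) if n_grp else 0.0,
        }
        if n_excl:
            logger.info(
                "%s group: %d of %d rows excluded (%.1f%%) for missing values",
                canon, n_excl, n_grp, 100.0 * n_excl / n_grp,
            )
    kept = df[complete].reset_index(drop=True)
    subject_id = (
        kept[mapping.subject_id].to_numpy()
        if mapping.subject_id and mapping.subject_id in kept.columns
        else None
    )
    data = SurvivalDataset(
        time=kept[mapping.time].to_numpy(dtype=float),
        event=kept[mapping.event].to_numpy(),
        covariates=kept[covariates].astype(float),
        group=kept[mapping.group].map(labels).to_numpy(dtype=object),
        subject_id=subject_id,
    )
    return data, exclusions


def write_cohort_csv(data: SurvivalDataset, path) -> None:
    """Write a dataset in the same schema :func:`read_cohort_csv` expects."""
    data.to_dataframe().to_csv(path, index=False)


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one analysis run.

    Built from a YAML/JSON file; referenced columns are checked at read
    time, not here.
    """

    data_path: str
    out_dir: str = "relhaz_out"
    mapping: ColumnMapping = field(default_factory=ColumnMapping)
    expected_covariates: tuple = ()
    relative_covariates: tuple = ()
    roles: dict = field(default_factory=dict)
    bootstrap: MCBootstrapConfig = field(default_factory=MCBootstrapConfig)
    ties: TiesPolicy = field(default_factory=TiesPolicy)
    ci_level: float = 0.95
    screen_alpha: float = 0.20
    keep_alpha: float = 0.05
    forced: tuple = ()

    @classmethod
    def from_file(cls, path, **overrides) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cols = raw.get("columns", {})
        labels = raw.get("labels", {})
        mapping = ColumnMapping(
            time=cols.get("time", "time"),
            event=cols.get("event", "event"),
            group=cols.get("group", "group"),
            reference_label=labels.get("reference", REFERENCE),
            relative_label=labels.get("relative", RELATIVE),
            subject_id=cols.get("subject_id", "subject_id"),
            covariates=tuple(cols["covariates"]) if "covariates" in cols else None,
        )
        boot = raw.get("bootstrap", {})
        sel = raw.get("selection", {})
        cfg = cls(
            data_path=raw.get("data", ""),
            out_dir=raw.get("out_dir", "relhaz_out"),
            mapping=mapping,
            expected_covariates=tuple(raw.get("mrs", {}).get("expected", ())),
            relative_covariates=tuple(raw.get("mrs", {}).get("relative", ())),
            roles=dict(raw.get("scm", {}).get("roles", {})),
            bootstrap=MCBootstrapConfig(
                B=int(boot.get("B", 1000)),
                seed=int(boot.get("seed", 0)),
                ci_level=float(boot.get("ci_level", 0.95)),
                ci_method=boot.get("ci_method", "percentile"),
            ),
            ties=TiesPolicy(raw.get("ties", "breslow")),
            ci_level=float(raw.get("ci_level", 0.95)),
            screen_alpha=float(sel.get("screen_alpha", 0.20)),
            keep_alpha=float(sel.get("keep_alpha", 0.05)),
            forced=tuple(sel.get("forced", ())),
        )
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg


def _provenance(config: AnalysisConfig, exclusions: dict, extra: dict) -> dict:
    return {
        "data": str(config.data_path),
        "seed": config.bootstrap.seed,
        "B": config.bootstrap.B,
        "ties": config.ties.method,
        "ci_level": config.bootstrap.ci_level,
        "ci_method": config.bootstrap.ci_method,
        "screen_alpha": config.screen_alpha,
        "keep_alpha": config.keep_alpha,
        "exclusions": exclusions,
        **extra,
    }


def run_mrs_cli(config: AnalysisConfig) -> dict:
    """Fit the MRS end to end and write report, draws and provenance files.

    Returns the paths written.  The report mirrors the combined layout:
    expected-model hazard ratios beside the relative-model results, with
    covariates grouped into expected-only / both / relative-only blocks.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data, exclusions = read_cohort_csv(config.data_path, config.mapping)
    reference = data.group_subset(REFERENCE)
    relative = data.group_subset(RELATIVE)
    expected = fit_expected_model(reference, config.expected_covariates, ties=config.ties)
    rel = run_mc_bootstrap(
        relative,
        expected,
        config.relative_covariates,
        config=config.bootstrap,
        ties=config.ties,
    )
    report = mrs_report(expected, rel, level=config.ci_level)
    paths = {
        "report": out / "mrs_report.csv",
        "report_txt": out / "mrs_report.txt",
        "draws": out / "mrs_draws.csv",
        "provenance": out / "mrs_provenance.json",
    }
    report.to_csv(paths["report"])
    paths["report_txt"].write_text(report.to_string(float_format="%.4f") + "\n")
    rel.draws.to_csv(paths["draws"], index=False)
    prov = _provenance(
        config,
        exclusions,
        {
            "model": "mrs",
            "expected_covariates": list(config.expected_covariates),
            "relative_covariates": list(config.relative_covariates),
            "n_failed_refits": rel.n_failed_refits,
        },
    )
    paths["provenance"].write_text(json.dumps(prov, indent=2) + "\n")
    return {k: str(v) for k, v in paths.items()}


def run_scm_cli(config: AnalysisConfig) -> dict:
    """Fit the stratified model and write the two per-group report tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data, exclusions = read_cohort_csv(config.data_path, config.mapping)
    roles = RoleMap(config.roles)
    scm = fit_scm(data, roles, ties=config.ties)
    tables = group_hazard_ratios(scm, level=config.ci_level)
    paths = {
        "reference": Path(out / "scm_reference.csv"),
        "relative": Path(out / "scm_relative.csv"),
        "report_txt": Path(out / "scm_report.txt"),
        "provenance": Path(out / "scm_provenance.json"),
    }
    tables[REFERENCE].to_csv(paths["reference"])
    tables[RELATIVE].to_csv(paths["relative"])
    txt = (
        "Reference stratum\n" + tables[REFERENCE].to_string(float_format="%.4f")
        + "\n\nRelative stratum\n" + tables[RELATIVE].to_string(float_format="%.4f")
        + "\n"
    )
    paths["report_txt"].write_text(txt)
    prov = _provenance(
        config,
        exclusions,
        {
            "model": "scm",
            "roles": dict(roles.roles),
            "stratum_events": scm.stratum_events,
        },
    )
    paths["provenance"].write_text(json.dumps(prov, indent=2) + "\n")
    return {k: str(v) for k, v in paths.items()}
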