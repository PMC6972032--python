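"""The full analysis suite over a panel dataset.

Reproduces the study design: an "individual" model with all three
comorbidities (obesity, DM, CVD) entered jointly as time-dependent
covariates; three pairwise combination models where each pair is
re-coded into mutually exclusive exposure groups (first-only,
second-only, both) against the doubly-unexposed reference, adjusting
for the third comorbidity; a triple combination model (all three
versus none); and exploratory sex and race stratification of the
individual model.  Every model shares the person-based adjustment set
(baseline age, sex, race, education, cohort, mean-centered birth year,
time-dependent hip injury) and reports adjusted hazard ratios for the
six living-state transitions; death transitions are estimated but
suppressed from default reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as hio
from .assessment import (
    DEFAULT_GRID,
    PrevalenceCurve,
    expected_prevalence,
    observed_prevalence,
    plot_prevalence,
    prevalence_table,
)
from .fitting import (
    REPORTED_TRANSITIONS,
    FittedModel,
    HazardRatioRow,
    fit_mle,
    hazard_ratio_table,
    transition_count_table,
)
from .model import CovariateSpec, InputError, TransitionStructure, default_structure

COMBO_MODELS: dict[str, tuple[str, str, str]] = {
    # model name -> (first, second, adjusted-for third)
    "obesity_cvd": ("obesity", "cvd", "dm"),
    "obesity_dm": ("obesity", "dm", "cvd"),
    "cvd_dm": ("cvd", "dm", "obesity"),
}

STRATA_VARS = {"sex": ("male", {1.0: "men", 0.0: "women"}),
               "race": ("black", {1.0: "black", 0.0: "white"})}


@dataclass(frozen=True)
class AnalysisPlan:
    """Which models, strata and adjustments to run."""

    models: tuple[str, ...] = ("individual", "obesity_cvd", "obesity_dm", "cvd_dm", "triple")
    strata: tuple[str, ...] = ("overall", "sex", "race")
    adjustment: tuple[str, ...] = (
        "age_base_c", "male", "black", "educ_lt12", "cohort_orig", "byear_c", "hip_injury",
    )
    comorbidities: tuple[str, ...] = ("obesity", "dm", "cvd")
    ci_level: float = 0.95
    age_changepoint: bool = True
    age_threshold: float = 65.0
    grid: tuple[float, ...] = DEFAULT_GRID
    include_death_rows: bool = False


@dataclass
class ModelReport:
    """One fitted model with its output table and assessment curves."""

    model: str
    stratum: str
    n_subjects: int
    fitted: FittedModel
    table: list[HazardRatioRow]
    observed: PrevalenceCurve
    expected: PrevalenceCurve
    dropped_covariates: list[str] = field(default_factory=list)


@dataclass
class ReportBundle:
    """Everything run_analysis produces, in memory."""

    plan: AnalysisPlan
    reports: list[ModelReport]
    log: list[str]

    def get(self, model: str, stratum: str = "overall") -> ModelReport:
        for r in self.reports:
            if r.model == model and r.stratum == stratum:
                return r
        raise KeyError(f"no report for model={model!r} stratum={stratum!r}")

    def table_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.reports:
            for hr in r.table:
                rows.append({
                    "model": r.model,
                    "stratum": r.stratum,
                    "group": hr.group,
                    "transition": "->".join(hr.transition),
                    "transition_label": hr.transition_label,
                    "contrast": hr.covariate,
                    "n_exposed": hr.n_exposed,
                    "n_unexposed": hr.n_unexposed,
                    "aHR": hr.ahr,
                    "ci_lower": hr.ci_lower,
                    "ci_upper": hr.ci_upper,
                    "significant": hr.significant,
                    "estimable": hr.estimable,
                    "note": hr.note,
                })
        return pd.DataFrame(rows)


def derive_combination_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Add mutually exclusive combination-exposure indicator columns.

    Recomputed at every visit from the component comorbidities
    (time-dependent like their components).  For each pair (x, y):
    ``x_only``/``y_only``/``x_and_y`` against the both-absent
    reference; for the triple model: ``all_three`` and
    ``partial_comorbidity`` (exactly one or two present) against the
    none-of-the-three reference.
    """
    df = df.copy()
    for name, (x, y, _) in COMBO_MODELS.items():
        df[f"{x}_only_{name}"] = df[x] * (1 - df[y])
        df[f"{y}_only_{name}"] = (1 - df[x]) * df[y]
        df[f"both_{name}"] = df[x] * df[y]
    count = df["obesity"] + df["dm"] + df["cvd"]
    df["all_three"] = (count == 3).astype(float)
    df["partial_comorbidity"] = ((count >= 1) & (count <= 2)).astype(float)
    return df


def _model_covariates(model: str, plan: AnalysisPlan) -> tuple[list[str], list[str]]:
    """(covariate list, reported contrasts) for one model of the plan."""
    adj = list(plan.adjustment)
    if model == "individual":
        covs = adj + list(plan.comorbidities)
        contrasts = list(plan.comorbidities)
    elif model in COMBO_MODELS:
        x, y, third = COMBO_MODELS[model]
        groups = [f"{x}_only_{model}", f"{y}_only_{model}", f"both_{model}"]
        covs = adj + [third] + groups
        contrasts = groups
    elif model == "triple":
        covs = adj + ["partial_comorbidity", "all_three"]
        contrasts = ["all_three"]
    else:
        raise InputError(f"unknown model {model!r}")
    return covs, contrasts


def _covariate_kinds(names: Sequence[str]) -> tuple[str, ...]:
    static = {"age_base_c", "male", "black", "educ_lt12", "cohort_orig", "byear_c"}
    return tuple("static" if n in static else "time-dependent" for n in names)


def run_analysis(
    panel: pd.DataFrame | str | Path,
    plan: AnalysisPlan | None = None,
    out_dir: str | Path | None = None,
    structure: TransitionStructure | None = None,
) -> ReportBundle:
    """Fit every model of the plan and emit the report bundle.

    ``panel`` is a long-format panel frame or file path.  Covariates
    constant within a fitted subset (e.g. the stratifying variable
    inside a stratum) are dropped with a log entry rather than passed
    to a singular fit.  Writes per-model tables, prevalence figures and
    a run log when ``out_dir`` is given.
    """
    plan = plan or AnalysisPlan()
    structure = structure or default_structure()
    df = pd.read_csv(panel) if not isinstance(panel, pd.DataFrame) else panel.copy()
    df = derive_combination_columns(df)
    log: list[str] = []
    reports: list[ModelReport] = []

    jobs: list[tuple[str, str, pd.DataFrame]] = []
    for model in plan.models:
        for stratum in plan.strata:
            if stratum == "overall":
                jobs.append((model, "overall", df))
            elif model == "individual":  # stratified runs: individual model only
                var, labels = STRATA_VARS[stratum]
                for val, lab in labels.items():
                    jobs.append((model, lab, df[df[var] == val]))

    for model, stratum, sub in jobs:
        if sub.empty:
            log.append(f"{model}/{stratum}: no subjects in stratum, skipped")
            continue
        covs, contrasts = _model_covariates(model, plan)
        if stratum in ("men", "women"):
            covs = [c for c in covs if c != "male"]
        if stratum in ("black", "white"):
            covs = [c for c in covs if c != "black"]
        dropped = [c for c in covs if sub[c].nunique() <= 1]
        if dropped:
            log.append(f"{model}/{stratum}: dropped constant covariates {dropped}")
            covs = [c for c in covs if c not in dropped]
        cohort = hio.dataframe_to_cohort(sub)
        spec = CovariateSpec(tuple(covs), _covariate_kinds(covs))
        fitted = fit_mle(
            cohort, structure, spec,
            age_changepoint=plan.age_changepoint,
            age_threshold=plan.age_threshold,
        )
        log.append(
            f"{model}/{stratum}: n={len(cohort)} loglik={fitted.loglik:.3f} "
            f"converged={fitted.converged} frozen={fitted.frozen_transitions}"
        )
        counts = {c: transition_count_table(cohort, c) for c in contrasts}
        transitions = list(REPORTED_TRANSITIONS)
        if plan.include_death_rows:
            transitions += [tr for tr in structure.transitions if tr[1] == "E"]
        table = hazard_ratio_table(
            fitted, contrasts, counts=counts, ci_level=plan.ci_level,
            transitions=transitions,
        )
        obs = observed_prevalence(cohort, plan.grid)
        exp = expected_prevalence(fitted.params, cohort, plan.grid, plan.age_threshold)
        reports.append(ModelReport(model, stratum, len(cohort), fitted, table, obs, exp, dropped))

    bundle = ReportBundle(plan, reports, log)
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: ReportBundle, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    bundle.table_frame().to_csv(out / "hazard_ratios.csv", index=False)
    manifest = {}
    for r in bundle.reports:
        key = f"{r.model}__{r.stratum}"
        prevalence_table(r.observed, r.expected).to_csv(
            out / f"prevalence_{key}.csv", index=False
        )
        plot_prevalence(r.observed, r.expected, out / f"prevalence_{key}.svg",
                        title=f"{r.model} ({r.stratum})")
        manifest[key] = r.fitted.manifest()
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    (out / "run_log.txt").write_text("\n".join(bundle.log) + "\n")


def sensitivity_min_followups(
    panel: pd.DataFrame | str | Path,
    plan: AnalysisPlan | None = None,
    min_visits: int = 2,
    out_dir: str | Path | None = None,
) -> tuple[ReportBundle, pd.DataFrame]:
    """Refit the plan on subjects with at least ``min_visits`` follow-ups.

    ``min_visits`` counts post-baseline visits.  Returns the subset
    bundle and a side-by-side aHR comparison against the full-data fit
    (empty comparison when ``min_visits`` is 0, where the subset is the
    full data).
    """
    plan = plan or AnalysisPlan()
    df = pd.read_csv(panel) if not isinstance(panel, pd.DataFrame) else panel.copy()
    n_followups = df.groupby("subject_id")["t_years"].transform("count") - 1
    if min_visits > int(n_followups.max()):
        raise InputError(
            f"min_visits={min_visits} exceeds the maximum follow-up count "
            f"({int(n_followups.max())}); the subset would be empty"
        )
    sub = df[n_followups >= min_visits]
    if sub.empty:
        raise InputError("follow-up restriction leaves no subjects")
    bundle_sub = run_analysis(sub, plan, out_dir=None)
    if min_visits <= 0:
        comparison = pd.DataFrame()
    else:
        bundle_full = run_analysis(df, plan, out_dir=None)
        a = bundle_full.table_frame().rename(columns={
            "aHR": "aHR_full", "ci_lower": "ci_lower_full", "ci_upper": "ci_upper_full"})
        b = bundle_sub.table_frame().rename(columns={
            "aHR": "aHR_subset", "ci_lower": "ci_lower_subset", "ci_upper": "ci_upper_subset"})
        keys = ["model", "stratum", "transition", "contrast"]
        comparison = a[keys + ["aHR_full", "ci_lower_full", "ci_upper_full"]].merge(
            b[keys + ["aHR_subset", "ci_lower_subset", "ci_upper_subset"]], on=keys
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            comparison["log_ahr_shift"] = np.log(
                comparison["aHR_subset"] / comparison["aHR_full"]
            )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_bundle(bundle_sub, out / "subset")
        comparison.to_csv(out / "sensitivity_comparison.csv", index=False)
    return bundle_sub, comparison
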