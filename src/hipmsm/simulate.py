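"""Synthetic cohort generation by exact continuous-time simulation.

Emulates the structure of a community-based OA cohort: ~6-year visit
spacing over an ~19-year horizon, a 45/19/25/11% baseline state mix
(A/B/C/D), one-third African American, 39% men, baseline age ~
N(62.2, 9.8) truncated at 45, baseline obesity 40% / DM 14% / CVD 22% /
hip injury 6%, monotone DM and CVD paths with reversible obesity,
per-visit dropout, and death-registry-style exact death times observed
through the follow-up horizon even after dropout.

Subjects are simulated exactly: within each constant-intensity segment
(between covariate-updating visits and across the age-65 crossing) the
sojourn in state ``s`` is Exponential(-Q[s,s]) and the destination is
categorical over the outgoing intensities, so simulated panel
frequencies converge to the matrix-exponential transition probabilities
— the central simulator/engine consistency property.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as hio
from .likelihood import PanelObservation, SubjectHistory
from .model import (
    LIVING_STATES,
    STATE_INDEX,
    STATES,
    CovariateSpec,
    InputError,
    ModelParameters,
    TransitionStructure,
    build_intensity_matrix,
    default_structure,
)

AGE_CENTER = 62.2
BYEAR_CENTER = 1935.0
SCALE_DECADE = 10.0

COVARIATE_NAMES: tuple[str, ...] = (
    "age_base_c", "male", "black", "educ_lt12", "cohort_orig", "byear_c",
    "obesity", "dm", "cvd", "hip_injury",
)
COVARIATE_KINDS: tuple[str, ...] = (
    "static", "static", "static", "static", "static", "static",
    "time-dependent", "time-dependent", "time-dependent", "time-dependent",
)


def default_covariates() -> CovariateSpec:
    """The person-based adjustment set plus the three comorbidities.

    Continuous covariates are centered and scaled to decades
    (``age_base_c`` = (baseline age - 62.2)/10, ``byear_c`` =
    (birth year - 1935)/10) so coefficients are per-decade log-HRs and
    the reference person is a cohort-average 62-year-old.
    """
    return CovariateSpec(COVARIATE_NAMES, COVARIATE_KINDS)


def default_truth(covariates: CovariateSpec | None = None,
                  structure: TransitionStructure | None = None) -> ModelParameters:
    """Default generating parameters for synthetic cohorts.

    Baseline intensities (per person-year, reference person under 65)
    are calibrated so roughly a quarter of state-A starters transition
    to OA/symptom states and ~40% die over the 19-year horizon.
    Comorbidity log-HRs are set to literature-scale point estimates
    (e.g. obesity on A->C at ln 1.33); demographic coefficients default
    to zero.  Intensities multiply by the ``gamma`` factors from age 65.
    """
    structure = structure or default_structure()
    covariates = covariates or default_covariates()
    ln = np.log
    q0 = {
        ("A", "B"): 0.020, ("A", "C"): 0.026, ("B", "D"): 0.035,
        ("C", "A"): 0.090, ("C", "D"): 0.020, ("D", "B"): 0.060,
        ("A", "E"): 0.015, ("B", "E"): 0.022, ("C", "E"): 0.019, ("D", "E"): 0.030,
    }
    beta = {
        "obesity": {("A", "C"): ln(1.33), ("C", "D"): ln(1.46), ("A", "B"): ln(0.88),
                    ("B", "D"): ln(0.93), ("C", "A"): ln(0.88), ("D", "B"): ln(0.85)},
        "dm": {("C", "A"): ln(0.74), ("D", "B"): ln(0.64), ("C", "D"): ln(1.49),
               ("A", "B"): ln(1.06), ("A", "C"): ln(1.05), ("B", "D"): ln(1.29)},
        "cvd": {("C", "A"): ln(0.61), ("D", "B"): ln(0.74), ("A", "B"): ln(1.34),
                ("A", "C"): ln(1.25), ("C", "D"): ln(1.07), ("B", "D"): ln(1.08)},
    }
    gamma = {
        ("A", "B"): 0.30, ("B", "D"): 0.30, ("C", "D"): 0.30,
        ("A", "E"): ln(2.0), ("B", "E"): ln(2.0), ("C", "E"): ln(2.0), ("D", "E"): ln(2.0),
    }
    return ModelParameters.from_dicts(structure, covariates, q0, beta, gamma)


def comorbidity_only_truth(null: bool = False) -> ModelParameters:
    """Generating truth restricted to the three comorbidity covariates.

    Same baseline intensities and age-65 multipliers as
    :func:`default_truth`; demographic covariates (whose default effects
    are zero anyway) are omitted, which keeps recovery and calibration
    simulations well-specified under a much smaller fitted model.  With
    ``null=True`` every comorbidity effect is set to HR = 1.
    """
    full = default_truth()
    names = ("obesity", "dm", "cvd")
    idx = [full.covariates.names.index(n) for n in names]
    spec = CovariateSpec(names, ("time-dependent",) * len(names))
    beta = np.zeros((full.structure.n_transitions, len(names))) if null else full.beta[:, idx]
    return ModelParameters(full.structure, spec, full.log_q0.copy(), beta, full.gamma.copy())


@dataclass
class CohortConfig:
    """Synthetic-generator truth: demographics, schedule, intensities.

    Every probability is per-visit; incidences apply between successive
    visits among the still-unaffected.  ``truth`` holds the exact
    generating :class:`ModelParameters`; the defaults mirror the study
    conditions the generator emulates.
    """

    n_subjects: int = 2000
    seed: int = 20200120
    frac_black: float = 0.33
    frac_male: float = 0.39
    frac_educ_lt12: float = 0.37
    frac_cohort_orig: float = 0.71
    age_mean: float = 62.2
    age_sd: float = 9.8
    age_min: float = 45.0
    baseline_state_probs: tuple[float, float, float, float] = (0.45, 0.19, 0.25, 0.11)
    baseline_obesity: float = 0.40
    baseline_dm: float = 0.14
    baseline_cvd: float = 0.22
    baseline_hip_injury: float = 0.06
    incidence_dm: float = 0.09
    incidence_cvd: float = 0.12
    obesity_onset: float = 0.10
    obesity_remission: float = 0.06
    incidence_hip_injury: float = 0.03
    n_followups: int = 3
    spacing_mean: float = 6.0
    spacing_sd: float = 1.2
    spacing_min: float = 2.0
    dropout: float = 0.22
    horizon: float = 19.0
    age_threshold: float = 65.0
    truth: ModelParameters = field(default_factory=default_truth)

    def __post_init__(self) -> None:
        if abs(sum(self.baseline_state_probs) - 1.0) > 1e-9:
            raise InputError("baseline_state_probs must sum to 1")
        for name in ("frac_black", "frac_male", "frac_educ_lt12", "frac_cohort_orig",
                     "baseline_obesity", "baseline_dm", "baseline_cvd",
                     "baseline_hip_injury", "incidence_dm", "incidence_cvd",
                     "obesity_onset", "obesity_remission", "incidence_hip_injury",
                     "dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name}={v} outside [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        tr = self.truth
        d["truth"] = {
            "transitions": ["->".join(t) for t in tr.structure.transitions],
            "covariates": list(tr.covariates.names),
            "log_q0": tr.log_q0.tolist(),
            "beta": tr.beta.tolist(),
            "gamma": tr.gamma.tolist() if tr.gamma is not None else None,
        }
        return d


@dataclass
class TruthManifest:
    """The exact config and parameters behind a generated cohort."""

    config: dict

    def to_json(self) -> str:
        return json.dumps(self.config, indent=2, sort_keys=True)


# ----------------------------------------------------------------------
def _visit_times(config: CohortConfig, rng: np.random.Generator) -> list[float]:
    """Scheduled visit times (baseline + follow-ups), capped at the horizon."""
    times = [0.0]
    t = 0.0
    for _ in range(config.n_followups):
        gap = max(config.spacing_min, rng.normal(config.spacing_mean, config.spacing_sd))
        t += gap
        if t > config.horizon:
            break
        times.append(t)
    return times


def simulate_covariate_path(
    config: CohortConfig,
    n_visits: int,
    rng: np.random.Generator,
) -> list[dict[str, float]]:
    """Time-dependent comorbidity values at each visit.

    DM, CVD and hip injury are absorbing once present (develop, never
    resolve); obesity toggles with separate onset and remission
    probabilities per visit.
    """
    obesity = float(rng.random() < config.baseline_obesity)
    dm = float(rng.random() < config.baseline_dm)
    cvd = float(rng.random() < config.baseline_cvd)
    injury = float(rng.random() < config.baseline_hip_injury)
    path = [{"obesity": obesity, "dm": dm, "cvd": cvd, "hip_injury": injury}]
    for _ in range(1, n_visits):
        if obesity:
            obesity = 0.0 if rng.random() < config.obesity_remission else 1.0
        else:
            obesity = float(rng.random() < config.obesity_onset)
        if not dm:
            dm = float(rng.random() < config.incidence_dm)
        if not cvd:
            cvd = float(rng.random() < config.incidence_cvd)
        if not injury:
            injury = float(rng.random() < config.incidence_hip_injury)
        path.append({"obesity": obesity, "dm": dm, "cvd": cvd, "hip_injury": injury})
    return path


def _segment_breaks(
    visit_times: Sequence[float], baseline_age: float, horizon: float, age_threshold: float
) -> list[float]:
    breaks = sorted(set(t for t in visit_times if 0.0 <= t < horizon) | {horizon})
    cross = age_threshold - baseline_age
    if 0.0 < cross < horizon:
        breaks = sorted(set(breaks) | {cross})
    if breaks[0] != 0.0:
        breaks = [0.0] + breaks
    return breaks


def simulate_subject(
    subject_id: str,
    baseline_state: str,
    baseline_age: float,
    static_cov: dict[str, float],
    visit_times: Sequence[float],
    cov_path: Sequence[dict[str, float]],
    truth: ModelParameters,
    rng: np.random.Generator,
    *,
    horizon: float = 19.0,
    age_threshold: float = 65.0,
) -> SubjectHistory:
    """Exact CTMC simulation of one subject's state path.

    Within each constant-intensity segment (delimited by covariate-
    updating visits and the age-65 crossing) sojourns are competing
    exponentials.  States are recorded at visit times; death is recorded
    at its exact event time up to the horizon; visits after death are
    discarded.
    """
    space = truth.structure.state_space
    breaks = _segment_breaks(visit_times, baseline_age, horizon, age_threshold)
    state = STATE_INDEX[baseline_state]
    i_death = space.index("E")
    death_time: float | None = None
    visit_states: dict[float, int] = {}
    visits = sorted(t for t in visit_times if t < horizon)

    def cov_at(t: float) -> dict[str, float]:
        k = 0
        for j, vt in enumerate(visit_times):
            if vt <= t + 1e-12:
                k = j
        return {**static_cov, **cov_path[k]}

    for a, b in zip(breaks, breaks[1:]):
        if death_time is not None:
            break
        Q = build_intensity_matrix(
            truth, cov_at(a), (baseline_age + a) >= age_threshold
        )
        t = a
        while True:
            rate = -Q[state, state]
            if rate <= 0:
                t_next, jumps = b, False
            else:
                soj = rng.exponential(1.0 / rate)
                if t + soj >= b:
                    t_next, jumps = b, False
                else:
                    t_next, jumps = t + soj, True
            for vt in visits:
                if t <= vt < t_next:
                    visit_states[vt] = state
            t = t_next
            if not jumps:
                break
            probs = np.clip(Q[state], 0.0, None)
            probs[state] = 0.0
            probs = probs / probs.sum()
            state = int(rng.choice(len(probs), p=probs))
            if state == i_death:
                death_time = t
                break

    observations = []
    for j, vt in enumerate(visits):
        if vt not in visit_states:
            continue  # at or after death
        observations.append(
            PanelObservation(
                t=vt,
                age=baseline_age + vt,
                state=STATES[visit_states[vt]],
                covariates={**static_cov, **cov_path[j]},
            )
        )
    return SubjectHistory(subject_id, observations, death_time)


# ----------------------------------------------------------------------
def generate_cohort(
    config: CohortConfig,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, TruthManifest]:
    """Generate a full synthetic cohort as a long-format panel frame.

    Deterministic under (config, seed): the same configuration always
    produces byte-identical output files.  Optionally writes
    ``panel.csv``, ``truth.json`` and ``summary.txt`` to ``out_dir``.
    """
    rng = np.random.default_rng(config.seed)
    truth = config.truth
    rows: list[SubjectHistory] = []
    width = max(5, len(str(max(config.n_subjects, 1))))
    for i in range(config.n_subjects):
        sid = f"S{i:0{width}d}"
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd),
                            config.age_min, None))
        cohort_orig = float(rng.random() < config.frac_cohort_orig)
        base_year = rng.uniform(1991.0, 1997.0) if cohort_orig else rng.uniform(2003.0, 2004.0)
        static_cov = {
            "age_base_c": (age - AGE_CENTER) / SCALE_DECADE,
            "male": float(rng.random() < config.frac_male),
            "black": float(rng.random() < config.frac_black),
            "educ_lt12": float(rng.random() < config.frac_educ_lt12),
            "cohort_orig": cohort_orig,
            "byear_c": ((base_year - age) - BYEAR_CENTER) / SCALE_DECADE,
        }
        scheduled = _visit_times(config, rng)
        retained = [scheduled[0]]
        for vt in scheduled[1:]:
            if rng.random() < config.dropout:
                break
            retained.append(vt)
        cov_path = simulate_covariate_path(config, len(retained), rng)
        baseline_state = LIVING_STATES[
            int(rng.choice(4, p=np.asarray(config.baseline_state_probs)))
        ]
        rows.append(
            simulate_subject(
                sid, baseline_state, age, static_cov, retained, cov_path, truth,
                rng, horizon=config.horizon, age_threshold=config.age_threshold,
            )
        )
    df = hio.cohort_to_dataframe(rows)
    if df.empty:
        df = pd.DataFrame(
            columns=list(hio.RESERVED_COLUMNS) + list(truth.covariates.names)
        )
    manifest = TruthManifest(config.to_dict())
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        hio.write_panel(df, out / "panel.csv")
        (out / "truth.json").write_text(manifest.to_json() + "\n")
        (out / "summary.txt").write_text(cohort_summary(df) + "\n")
    return df, manifest


def cohort_summary(df: pd.DataFrame) -> str:
    """Human-readable per-visit summary of a generated panel."""
    if df.empty:
        return "empty cohort"
    lines = []
    n0 = df[df.t_years == 0].shape[0]
    lines.append(f"subjects: {n0}")
    n_dead = df.groupby("subject_id")["death_time_years"].first().notna().sum()
    lines.append(f"deaths observed: {n_dead}")
    for v, grp in df.groupby(df.groupby("subject_id").cumcount()):
        frac = grp["state"].value_counts(normalize=True).reindex(list(LIVING_STATES)).fillna(0)
        comorb = {c: grp[c].mean() for c in ("obesity", "dm", "cvd") if c in grp}
        lines.append(
            f"visit {v}: n={len(grp)}, mean t={grp.t_years.mean():.1f}y, "
            + " ".join(f"{s}={frac[s]:.2f}" for s in LIVING_STATES)
            + "  " + " ".join(f"{c}={p:.2f}" for c, p in comorb.items())
        )
    return "\n".join(lines)


# ----------------------------------------------------------------------
def simulate_endpoint(
    segments: Sequence[tuple[np.ndarray, float]],
    start_state: int,
    n_chains: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized exact simulation of many chains over a piecewise path.

    Returns (final state index per chain, absolute death time per chain,
    NaN when alive at the end).  Used as the Monte-Carlo oracle for
    transition probabilities and death densities: it shares no code with
    the matrix-exponential machinery.
    """
    n = segments[0][0].shape[0] if segments else 5
    state = np.full(n_chains, start_state, dtype=int)
    death_time = np.full(n_chains, np.nan)
    t_abs = 0.0
    for Q, dur in segments:
        Q = np.asarray(Q, dtype=float)
        rates = -np.diag(Q)
        jump_p = np.clip(Q, 0.0, None)
        np.fill_diagonal(jump_p, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            jump_p = jump_p / rates[:, None]
        cum_p = np.cumsum(np.nan_to_num(jump_p), axis=1)
        remaining = np.full(n_chains, float(dur))
        active = (rates[state] > 0) & np.isnan(death_time)
        while np.any(active):
            idx = np.nonzero(active)[0]
            r = rates[state[idx]]
            soj = rng.exponential(1.0 / r)
            done = soj >= remaining[idx]
            remaining[idx] -= soj
            moved = idx[~done]
            if len(moved):
                cp = cum_p[state[moved]]
                u = rng.random(len(moved)) * cp[:, -1]
                dest = (u[:, None] <= cp).argmax(axis=1)
                state[moved] = dest
                newly_dead = moved[rates[dest] == 0]
                if len(newly_dead):
                    death_time[newly_dead] = (
                        t_abs + dur - remaining[newly_dead]
                    )
            active[:] = False
            still = moved[rates[state[moved]] > 0]
            active[still] = remaining[still] > 0
        t_abs += dur
    return state, death_time
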