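"""Interval-censored panel likelihood with exact death times.

Living states are observed only at visit times (panel observation), so
each consecutive pair of visits contributes the transition-probability
entry ``P[s0, s1]`` over the interval — transitions through intermediate
states are integrated out by the matrix exponential.  Deaths are
ascertained exactly (death-registry style), so a death at time ``t_d``
after a last visit in state ``s`` contributes the density

    sum_k P[s, k](t_last, t_d) * q_{k,E}(t_d)      (k over living states)

i.e. survival in any living state up to the death instant times the
instantaneous death intensity from that state.

Time-dependent covariates are carried forward from the interval-start
visit (last observation carried forward); an interval is additionally
split at the instant the subject turns 65 so the age-changepoint
intensities apply piecewise.  The age-65 indicator uses the half-open
convention: a segment starting exactly at the 65th birthday is "65+".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .model import (
    DEATH_STATE,
    LIVING_STATES,
    InputError,
    ModelParameters,
    TransitionStructure,
    build_intensity_matrix,
    path_probability,
)

DEFAULT_AGE_THRESHOLD = 65.0

#: Comorbidity indicators that may develop but never resolve.
MONOTONE_COVARIATES = ("dm", "cvd")


@dataclass(frozen=True)
class PanelObservation:
    """One subject-visit row: time, age, living state, covariates in effect."""

    t: float
    age: float
    state: str
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.t < 0:
            raise InputError(f"observation time {self.t} < 0")
        if self.state not in LIVING_STATES:
            raise InputError(
                f"panel state must be one of {LIVING_STATES}, got {self.state!r}"
                " (death is recorded via death_time, not as a visit)"
            )


@dataclass
class SubjectHistory:
    """A subject's ordered panel observations plus optional exact death time."""

    subject_id: str
    observations: list[PanelObservation]
    death_time: float | None = None

    def __post_init__(self) -> None:
        ts = [o.t for o in self.observations]
        if any(t1 <= t0 for t0, t1 in zip(ts, ts[1:])):
            raise InputError(f"subject {self.subject_id}: observation times not strictly increasing")
        if self.death_time is not None and ts and self.death_time <= ts[-1]:
            raise InputError(
                f"subject {self.subject_id}: death_time {self.death_time} "
                f"not after last observation {ts[-1]}"
            )
        self._validate_monotone()

    def _validate_monotone(self) -> None:
        for name in MONOTONE_COVARIATES:
            prev = None
            for o in self.observations:
                if name not in o.covariates:
                    continue
                val = o.covariates[name]
                if prev is not None and val < prev:
                    raise InputError(
                        f"subject {self.subject_id}: covariate {name!r} decreases "
                        f"over time ({prev} -> {val}); it may only develop, not resolve"
                    )
                prev = val

    @property
    def n_timepoints(self) -> int:
        """Observations plus the death event if present."""
        return len(self.observations) + (self.death_time is not None)

    @property
    def baseline_age(self) -> float:
        o = self.observations[0]
        return o.age - o.t


class Segment(NamedTuple):
    """A stretch of constant intensities inside one observation interval."""

    duration: float
    covariates: Mapping[str, float]
    age_ge_65: bool


def segment_interval(
    history: SubjectHistory,
    t0: float,
    t1: float,
    age_threshold: float = DEFAULT_AGE_THRESHOLD,
) -> list[Segment]:
    """Split [t0, t1) into constant-intensity segments.

    Covariates recorded at the visit at ``t0`` are carried forward over
    the whole interval; the only internal break is the instant the
    subject reaches the age threshold.  A subject turning 65 exactly at
    ``t1`` stays "under 65" throughout (half-open convention).
    """
    if t1 <= t0:
        raise InputError(f"interval end {t1} must exceed start {t0}")
    obs = None
    for o in history.observations:
        if abs(o.t - t0) < 1e-9:
            obs = o
            break
    if obs is None:
        raise InputError(f"subject {history.subject_id}: t0={t0} is not an observation time")
    length = t1 - t0
    to_cross = age_threshold - obs.age  # years until the threshold
    if to_cross <= 0:
        return [Segment(length, obs.covariates, True)]
    if to_cross >= length:
        return [Segment(length, obs.covariates, False)]
    return [
        Segment(to_cross, obs.covariates, False),
        Segment(length - to_cross, obs.covariates, True),
    ]


def _plan_probability(params: ModelParameters, plan: Sequence[Segment]) -> np.ndarray:
    return path_probability(
        (build_intensity_matrix(params, seg.covariates, seg.age_ge_65), seg.duration)
        for seg in plan
    )


def interval_loglik(
    params: ModelParameters,
    history: SubjectHistory,
    t0: float,
    s0: str,
    t1: float,
    s1: str,
    age_threshold: float = DEFAULT_AGE_THRESHOLD,
) -> float:
    """Log probability of observing state s1 at t1 given s0 at t0.

    Returns ``-inf`` when the panel pair has zero probability under the
    transition structure (a likelihood impossibility — e.g. an observed
    recovery into a state unreachable from s0).
    """
    for s in (s0, s1):
        if s not in LIVING_STATES:
            raise InputError(f"panel states must be living states, got {s!r}")
    plan = segment_interval(history, t0, t1, age_threshold)
    P = _plan_probability(params, plan)
    space = params.structure.state_space
    p = P[space.index(s0), space.index(s1)]
    if p <= 0.0:
        return -np.inf
    return float(np.log(p))


def death_loglik(
    params: ModelParameters,
    history: SubjectHistory,
    t_last: float,
    s_last: str,
    t_death: float,
    age_threshold: float = DEFAULT_AGE_THRESHOLD,
) -> float:
    """Log density of an exactly observed death at ``t_death``.

    Sums over the unknown living state occupied just before death:
    survive from (t_last, s_last) to any living k, times the
    instantaneous death intensity from k at the death instant.
    Covariates at the death instant are those of the last pre-death
    visit (no visit occurs at death).
    """
    if t_death <= t_last:
        raise InputError("death time must exceed the last observation time")
    plan = segment_interval(history, t_last, t_death, age_threshold)
    P = _plan_probability(params, plan)
    space = params.structure.state_space
    # age flag at the death instant: has the subject crossed the threshold?
    flag_death = plan[-1].age_ge_65
    Qd = build_intensity_matrix(params, plan[-1].covariates, flag_death)
    i_death = space.index(DEATH_STATE)
    i0 = space.index(s_last)
    dens = 0.0
    for k in space.states:
        if k in space.absorbing:
            continue
        ik = space.index(k)
        dens += P[i0, ik] * Qd[ik, i_death]
    if dens <= 0.0:
        return -np.inf
    return float(np.log(dens))


def subject_loglik(
    params: ModelParameters,
    history: SubjectHistory,
    age_threshold: float = DEFAULT_AGE_THRESHOLD,
) -> float:
    """Sum of consecutive-pair interval terms plus the death term."""
    ll = 0.0
    obs = history.observations
    for o0, o1 in zip(obs, obs[1:]):
        ll += interval_loglik(params, history, o0.t, o0.state, o1.t, o1.state, age_threshold)
    if history.death_time is not None:
        last = obs[-1]
        ll += death_loglik(params, history, last.t, last.state, history.death_time, age_threshold)
    return ll


def total_loglik(
    params: ModelParameters,
    cohort: Sequence[SubjectHistory],
    age_threshold: float = DEFAULT_AGE_THRESHOLD,
) -> float:
    """Cohort log-likelihood: independent sum over subjects.

    Subjects with fewer than two time points (counting an exact death as
    one) carry no transition information and are skipped with a warning.
    """
    ll = 0.0
    skipped = [h.subject_id for h in cohort if h.n_timepoints < 2]
    if skipped:
        warnings.warn(
            f"{len(skipped)} subject(s) with <2 time points contribute no "
            f"information and were excluded: {skipped[:5]}...",
            stacklevel=2,
        )
    for h in cohort:
        if h.n_timepoints < 2:
            continue
        ll += subject_loglik(params, h, age_threshold)
    return ll


def find_impossible_pairs(
    cohort: Sequence[SubjectHistory],
    structure: TransitionStructure,
) -> list[tuple[str, float, str, float, str]]:
    """Panel pairs with zero probability under the transition structure.

    A pair (s0, s1) is impossible when s1 is unreachable from s0 through
    any chain of allowed transitions (e.g. D at one visit and A at the
    next in the default structure, where recovery from rHOA does not
    exist).  Such records make the likelihood identically ``-inf``; the
    fitter reports them as a diagnostic rather than dropping them.
    """
    reach = structure.reachable()
    bad = []
    for h in cohort:
        for o0, o1 in zip(h.observations, h.observations[1:]):
            if o1.state not in reach[o0.state]:
                bad.append((h.subject_id, o0.t, o0.state, o1.t, o1.state))
        if h.death_time is not None and h.observations:
            last = h.observations[-1]
            if DEATH_STATE not in reach[last.state]:
                bad.append((h.subject_id, last.t, last.state, h.death_time, DEATH_STATE))
    return bad
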