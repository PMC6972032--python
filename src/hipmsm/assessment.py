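"""Observed versus expected state prevalence over follow-up.

The model is assessed qualitatively, as is standard for panel
multi-state models: at each grid time the observed state distribution
(each living subject carried forward from their most recent visit,
deaths counted in E from their exact death time, subjects past their
last visit and not known dead removed from the denominator) is compared
with the model-expected distribution (each subject's baseline state
propagated through their own covariate path).  No formal
goodness-of-fit statistic is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .likelihood import DEFAULT_AGE_THRESHOLD, SubjectHistory
from .model import (
    STATES,
    InputError,
    ModelParameters,
    build_intensity_matrix,
    transition_probability,
)

DEFAULT_GRID = tuple(float(t) for t in range(0, 19))


@dataclass
class PrevalenceCurve:
    """Observed and expected per-state proportions on a time grid."""

    times: np.ndarray                 # (G,)
    observed: np.ndarray | None       # (G, 5) proportions, rows sum to 1
    expected: np.ndarray | None       # (G, 5)
    at_risk: np.ndarray               # (G,) denominator counts

    state_names = STATES


def _in_denominator(h: SubjectHistory, t: float) -> bool:
    if h.death_time is not None and h.death_time <= t:
        return True
    return bool(h.observations) and h.observations[-1].t >= t


def observed_prevalence(
    cohort: Sequence[SubjectHistory],
    grid: Sequence[float] = DEFAULT_GRID,
) -> PrevalenceCurve:
    """Empirical state distribution at each grid time.

    A living subject's state at ``t`` is their most recent visit state
    at or before ``t`` (carried forward); dead subjects occupy E from
    their death time onward; subjects censored before ``t`` drop out of
    the denominator.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise InputError("empty prevalence grid")
    G = len(grid)
    counts = np.zeros((G, len(STATES)))
    for h in cohort:
        ts = np.array([o.t for o in h.observations])
        for g, t in enumerate(grid):
            if not _in_denominator(h, t):
                continue
            if h.death_time is not None and h.death_time <= t:
                counts[g, STATES.index("E")] += 1
            else:
                k = int(np.searchsorted(ts, t, side="right")) - 1
                if k < 0:
                    continue  # grid time before baseline visit
                counts[g, STATES.index(h.observations[k].state)] += 1
    at_risk = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        observed = counts / at_risk[:, None]
    return PrevalenceCurve(grid, observed, None, at_risk)


def expected_prevalence(
    params: ModelParameters,
    cohort: Sequence[SubjectHistory],
    grid: Sequence[float] = DEFAULT_GRID,
    age_threshold: float = DEFAULT_AGE_THRESHOLD,
) -> PrevalenceCurve:
    """Model-expected state distribution at each grid time.

    Each subject's baseline state is propagated through the transition
    probabilities along their own covariate path (visit-carried-forward
    covariates, age-65 split; last covariates extended beyond the last
    visit), and occupancy vectors are averaged over the observed-
    prevalence denominator at each grid time.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise InputError("empty prevalence grid")
    G = len(grid)
    total = np.zeros((G, len(STATES)))
    at_risk = np.zeros(G)
    for h in cohort:
        occ = _occupancy_path(params, h, grid, age_threshold)
        for g in range(G):
            if _in_denominator(h, grid[g]):
                total[g] += occ[g]
                at_risk[g] += 1
    with np.errstate(invalid="ignore"):
        expected = total / at_risk[:, None]
    return PrevalenceCurve(grid, None, expected, at_risk)


def _occupancy_path(
    params: ModelParameters,
    h: SubjectHistory,
    grid: np.ndarray,
    age_threshold: float,
) -> np.ndarray:
    """State-occupancy distribution of one subject at each grid time."""
    base = h.observations[0]
    baseline_age = base.age - base.t
    tmax = float(max(grid.max(), base.t))
    # breakpoints: visit times (covariate updates) + the age-65 crossing
    breaks = {o.t for o in h.observations} | {tmax}
    cross = base.t + (age_threshold - baseline_age)
    if base.t < cross < tmax:
        breaks.add(cross)
    breaks = sorted(b for b in breaks if b >= base.t)
    ts = [o.t for o in h.observations]

    def Q_at(t: float) -> np.ndarray:
        k = max(0, int(np.searchsorted(np.asarray(ts), t + 1e-12)) - 1)
        z = h.observations[k].covariates
        return build_intensity_matrix(params, z, (baseline_age + t) >= age_threshold)

    # cumulative products at breakpoints, then interpolate per grid time
    n = len(STATES)
    occ = np.zeros((len(grid), n))
    start = np.zeros(n)
    start[STATES.index(base.state)] = 1.0
    P_cum = np.eye(n)
    seg_start = base.t
    bi = 0
    order = np.argsort(grid)
    for gi in order:
        t = grid[gi]
        if t <= base.t:
            occ[gi] = start
            continue
        while bi < len(breaks) - 1 and breaks[bi + 1] <= t:
            a, b = breaks[bi], breaks[bi + 1]
            P_cum = P_cum @ transition_probability(Q_at(a), b - a)
            seg_start = b
            bi += 1
        P = P_cum
        if t > seg_start:
            P = P_cum @ transition_probability(Q_at(seg_start), t - seg_start)
        occ[gi] = start @ P
    return occ


def prevalence_table(obs: PrevalenceCurve, exp: PrevalenceCurve):
    """Combined observed/expected table as a pandas frame."""
    import pandas as pd

    data = {"t_years": obs.times, "at_risk": obs.at_risk}
    for i, s in enumerate(STATES):
        data[f"observed_{s}"] = obs.observed[:, i]
        data[f"expected_{s}"] = exp.expected[:, i]
    return pd.DataFrame(data)


def plot_prevalence(obs: PrevalenceCurve, exp: PrevalenceCurve, path=None, title=""):
    """Per-state panel figure of observed vs expected prevalence."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(STATES), figsize=(16, 3), sharey=True)
    for i, (s, ax) in enumerate(zip(STATES, axes)):
        ax.plot(obs.times, obs.observed[:, i], "o-", label="observed", ms=3)
        ax.plot(exp.times, exp.expected[:, i], "--", label="expected")
        ax.set_title(f"state {s}")
        ax.set_xlabel("years since baseline")
    axes[0].set_ylabel("prevalence")
    axes[0].legend(frameon=False)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
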