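"""Maximum-likelihood estimation and hazard-ratio reporting.

Estimation works on the unconstrained scale (log intensities, raw
covariate coefficients) with the analytic score from the vectorized
engine.  L-BFGS-B does the bulk of the work; a few Newton steps with
the finite-difference observed information polish the optimum so the
reported gradient max-norm is genuinely small.  Wald 95% intervals come
from the inverse observed information on the log scale, matching the
usual multi-state-model convention of reporting per-transition adjusted
hazard ratios ``exp(beta)``.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from ._engine import LikelihoodEngine
from .likelihood import DEFAULT_AGE_THRESHOLD, SubjectHistory, find_impossible_pairs
from .model import (
    DEATH_STATE,
    STATE_LABELS,
    CovariateSpec,
    InputError,
    ModelParameters,
    TransitionStructure,
)

#: The six living-state transitions reported in the output tables
#: (death transitions are modeled but suppressed from default reports).
REPORTED_TRANSITIONS: tuple[tuple[str, str], ...] = (
    ("A", "B"), ("C", "D"),  # development of rHOA
    ("A", "C"), ("B", "D"),  # development of symptoms
    ("C", "A"), ("D", "B"),  # resolution of symptoms
)

TRANSITION_GROUPS: dict[tuple[str, str], str] = {
    ("A", "B"): "Development of rHOA",
    ("C", "D"): "Development of rHOA",
    ("A", "C"): "Development of symptoms",
    ("B", "D"): "Development of symptoms",
    ("C", "A"): "Resolution of symptoms",
    ("D", "B"): "Resolution of symptoms",
}


class FitError(RuntimeError):
    """Raised when the data make the requested fit impossible."""


def transition_label(r: str, s: str) -> str:
    lab_r = STATE_LABELS.get(r, r)
    lab_s = STATE_LABELS.get(s, s)
    return f"{lab_r} to {lab_s[0].lower() + lab_s[1:]}"


# ----------------------------------------------------------------------
def _pair_counts_and_persontime(
    cohort: Sequence[SubjectHistory],
    structure: TransitionStructure,
) -> tuple[dict[tuple[str, str], int], dict[str, float]]:
    """Observed successive-pair counts and person-time by interval-start state."""
    counts: dict[tuple[str, str], int] = {tr: 0 for tr in structure.transitions}
    time_in: dict[str, float] = {}
    for h in cohort:
        obs = h.observations
        for o0, o1 in zip(obs, obs[1:]):
            time_in[o0.state] = time_in.get(o0.state, 0.0) + (o1.t - o0.t)
            if (o0.state, o1.state) in counts:
                counts[(o0.state, o1.state)] += 1
        if h.death_time is not None and obs:
            last = obs[-1]
            time_in[last.state] = time_in.get(last.state, 0.0) + (h.death_time - last.t)
            if (last.state, DEATH_STATE) in counts:
                counts[(last.state, DEATH_STATE)] += 1
    return counts, time_in


def crude_initial_values(
    cohort: Sequence[SubjectHistory],
    structure: TransitionStructure,
    covariates: CovariateSpec | None = None,
    *,
    floor: float = 1e-3,
    age_changepoint: bool = True,
) -> ModelParameters:
    """Crude-rate starting values: observed pairs / person-time at risk.

    ``q_rs = (# successive pairs r->s) / (time with last-observed state
    r)``; transitions with no observed pairs (or no person-time in the
    source state) start at a small floor.  All covariate and changepoint
    coefficients start at zero.
    """
    if not cohort:
        raise InputError("cohort is empty")
    if covariates is None:
        covariates = CovariateSpec()
    counts, time_in = _pair_counts_and_persontime(cohort, structure)
    T = structure.n_transitions
    log_q0 = np.full(T, np.log(floor))
    for i, (r, s) in enumerate(structure.transitions):
        tt = time_in.get(r, 0.0)
        if counts[(r, s)] > 0 and tt > 0:
            log_q0[i] = np.log(counts[(r, s)] / tt)
        else:
            warnings.warn(
                f"no observed {r}->{s} pairs; initializing at floor {floor}/yr",
                stacklevel=2,
            )
    beta = np.zeros((T, covariates.n_covariates))
    gamma = np.zeros(T) if age_changepoint else None
    return ModelParameters(structure, covariates, log_q0, beta, gamma)


# ----------------------------------------------------------------------
@dataclass
class FittedModel:
    """MLE result: estimates, observed information, diagnostics."""

    params: ModelParameters
    loglik: float
    theta: np.ndarray                  # full packed vector (engine order)
    free: np.ndarray                   # bool mask of estimated entries
    param_names: list[str]
    information: np.ndarray | None     # observed information over free entries
    vcov: np.ndarray | None            # inverse information (None if singular)
    converged: bool
    convergence: dict = field(default_factory=dict)
    frozen_transitions: list[tuple[str, str]] = field(default_factory=list)
    age_threshold: float = DEFAULT_AGE_THRESHOLD

    @property
    def information_pd(self) -> bool:
        if self.information is None:
            return False
        try:
            np.linalg.cholesky((self.information + self.information.T) / 2)
            return True
        except np.linalg.LinAlgError:
            return False

    def _free_index(self, name: str) -> int | None:
        if name not in self.param_names:
            return None
        full_i = self.param_names.index(name)
        if not self.free[full_i]:
            return None
        return int(np.cumsum(self.free)[full_i] - 1)

    def beta_and_se(self, covariate: str, r: str, s: str) -> tuple[float, float]:
        """Point estimate and Wald SE of one log hazard ratio (SE NaN if
        frozen or the information matrix is singular)."""
        k = self.params.covariates.names.index(covariate)
        ti = self.params.structure.transition_index(r, s)
        b = float(self.params.beta[ti, k])
        fi = self._free_index(f"beta[{r}->{s},{covariate}]")
        if fi is None or self.vcov is None:
            return b, float("nan")
        var = self.vcov[fi, fi]
        if not np.isfinite(var) or var <= 0:
            return b, float("nan")
        return b, float(np.sqrt(var))

    def manifest(self) -> dict:
        """Machine-readable run summary (config hash, fit diagnostics)."""
        cfg = {
            "transitions": ["->".join(tr) for tr in self.params.structure.transitions],
            "covariates": list(self.params.covariates.names),
            "age_changepoint": self.params.gamma is not None,
            "age_threshold": self.age_threshold,
        }
        blob = json.dumps(cfg, sort_keys=True).encode()
        return {
            "config_hash": hashlib.sha256(blob).hexdigest()[:16],
            "config": cfg,
            "loglik": self.loglik,
            "converged": self.converged,
            "convergence": self.convergence,
            "frozen_transitions": ["->".join(tr) for tr in self.frozen_transitions],
        }


def _fd_information(engine, theta, free, h=1e-4):
    """Observed information: central finite differences of the analytic score."""
    idx = np.nonzero(free)[0]
    F = len(idx)
    H = np.zeros((F, F))
    for j, fj in enumerate(idx):
        tp = theta.copy()
        tp[fj] += h
        _, gp = engine.negloglik_grad(tp)
        tm = theta.copy()
        tm[fj] -= h
        _, gm = engine.negloglik_grad(tm)
        H[:, j] = (gp[idx] - gm[idx]) / (2 * h)
    return (H + H.T) / 2.0


def fit_mle(
    cohort: Sequence[SubjectHistory],
    structure: TransitionStructure,
    covariates: CovariateSpec | None = None,
    *,
    init: ModelParameters | None = None,
    age_changepoint: bool = True,
    age_threshold: float = DEFAULT_AGE_THRESHOLD,
    floor: float = 1e-3,
    gtol: float = 1e-5,
    maxiter: int = 2000,
    compute_information: bool = True,
) -> FittedModel:
    """Maximum-likelihood fit of the multi-state model to panel data.

    Transitions without a single supporting observed pair are frozen at
    the crude-rate floor (their covariate effects at zero) with a
    warning rather than estimated.  Observed panel pairs that are
    impossible under the transition structure abort the fit with a
    diagnostic listing the offending subjects.  The optimizer is
    deterministic given (data, init).
    """
    if covariates is None:
        covariates = CovariateSpec()
    bad = find_impossible_pairs(cohort, structure)
    if bad:
        lines = [f"  subject {sid}: {s0}@t={t0:g} -> {s1}@t={t1:g}" for sid, t0, s0, t1, s1 in bad[:10]]
        raise FitError(
            "structurally impossible observed transitions "
            f"({len(bad)} record(s)):\n" + "\n".join(lines)
        )
    T = structure.n_transitions
    mask = covariates.mask_array(T)
    Kx = covariates.n_covariates + (1 if age_changepoint else 0)
    coef_mask = np.ones((T, Kx), dtype=bool)
    coef_mask[:, : covariates.n_covariates] = mask
    engine = LikelihoodEngine(
        cohort,
        structure,
        covariates.names,
        coef_mask=coef_mask,
        age_changepoint=age_changepoint,
        age_threshold=age_threshold,
    )
    if init is None:
        init = crude_initial_values(
            cohort, structure, covariates, floor=floor, age_changepoint=age_changepoint
        )
    C0 = np.zeros((T, Kx))
    C0[:, : covariates.n_covariates] = init.beta
    if age_changepoint and init.gamma is not None:
        C0[:, -1] = init.gamma
    theta = engine.pack(init.log_q0, C0)
    names = engine.param_names()

    # freeze transitions with no direct observed-pair support
    counts, _ = _pair_counts_and_persontime(cohort, structure)
    frozen_transitions = [tr for tr in structure.transitions if counts[tr] == 0]
    free = np.ones(len(theta), dtype=bool)
    for tr in frozen_transitions:
        warnings.warn(
            f"transition {tr[0]}->{tr[1]} has no observed pairs; frozen at floor",
            stacklevel=2,
        )
        ti = structure.transition_index(*tr)
        theta[ti] = np.log(floor)
        for i, nm in enumerate(names):
            if nm.startswith((f"beta[{tr[0]}->{tr[1]},", f"gamma[{tr[0]}->{tr[1]}]")):
                free[i] = False
                theta[i] = 0.0
        free[ti] = False

    def run_lbfgs(active: np.ndarray, start: np.ndarray, iters: int):
        aidx = np.nonzero(active)[0]

        def fun(x):
            th = start.copy()
            th[aidx] = x
            nll, g = engine.negloglik_grad(th)
            return nll, g[aidx]

        bnds = [(-16.0, 4.0) if i < T else (-8.0, 8.0) for i in aidx]
        res = minimize(
            fun, start[aidx], jac=True, method="L-BFGS-B", bounds=bnds,
            options={"maxiter": iters, "ftol": 1e-13, "gtol": 1e-7,
                     "maxcor": 25, "maxls": 50},
        )
        out = start.copy()
        out[aidx] = res.x
        return out, res

    # warm-up: baseline intensities only (smooth everywhere), then all
    # free parameters from that point — avoids line-search excursions into
    # the saturated region on the first full-dimensional steps
    idx = np.nonzero(free)[0]
    if covariates.n_covariates or age_changepoint:
        warm = free.copy()
        warm[T:] = False
        theta, _ = run_lbfgs(warm, theta, 200)
    theta, res = run_lbfgs(free, theta, maxiter)
    lo = np.where(np.arange(len(theta)) < T, -16.0, -8.0)
    hi = np.where(np.arange(len(theta)) < T, 4.0, 8.0)

    def proj_gnorm(th, g):
        """Max-norm of the bound-projected gradient (0 at an active bound
        whose constraint blocks further descent)."""
        if not len(idx):
            return 0.0
        gp = g[idx].copy()
        at_lo = th[idx] <= lo[idx] + 1e-10
        at_hi = th[idx] >= hi[idx] - 1e-10
        gp[at_lo] = np.minimum(gp[at_lo], 0.0)
        gp[at_hi] = np.maximum(gp[at_hi], 0.0)
        return float(np.max(np.abs(gp)))

    nll, g = engine.negloglik_grad(theta)
    gnorm = proj_gnorm(theta, g)
    newton_steps = 0
    info = None
    # Newton polish: drives the gradient max-norm to the convergence target
    for _ in range(8):
        if gnorm < gtol:
            break
        info = _fd_information(engine, theta, free)
        # Newton step on the inactive set only: coordinates pinned at a
        # bound (with the gradient pushing outward) stay put
        at_lo = theta[idx] <= lo[idx] + 1e-10
        at_hi = theta[idx] >= hi[idx] - 1e-10
        blocked = (at_lo & (g[idx] > 0)) | (at_hi & (g[idx] < 0))
        act = ~blocked
        step = np.zeros(len(idx))
        try:
            step[act] = np.linalg.solve(info[np.ix_(act, act)], g[idx][act])
        except np.linalg.LinAlgError:
            break
        cap = np.max(np.abs(step))
        if cap > 1.0:  # bounded polish steps: the quadratic model is local
            step = step / cap
        scale = 1.0
        improved = False
        for _ in range(25):
            trial = theta.copy()
            trial[idx] = np.clip(theta[idx] - scale * step, lo[idx], hi[idx])
            nll_t, g_t = engine.negloglik_grad(trial)
            if np.isfinite(nll_t) and nll_t < nll + 1e-10:
                gn_t = proj_gnorm(trial, g_t)
                if nll_t < nll or gn_t < gnorm:
                    theta, nll, g, gnorm = trial, nll_t, g_t, gn_t
                    improved = True
                    newton_steps += 1
                    break
            scale /= 2.0
        if not improved:
            break

    converged = bool(gnorm < gtol)
    vcov = None
    if compute_information and len(idx):
        if info is None or newton_steps > 0:
            info = _fd_information(engine, theta, free)
        try:
            vcov = np.linalg.inv(info)
            if np.any(np.diag(vcov) <= 0):
                vcov = None
        except np.linalg.LinAlgError:
            vcov = None
    elif not len(idx):
        info = np.zeros((0, 0))
        vcov = np.zeros((0, 0))

    log_q0, C = engine.unpack(theta)
    fitted_params = ModelParameters(
        structure,
        covariates,
        log_q0,
        C[:, : covariates.n_covariates],
        C[:, -1] if age_changepoint else None,
    )
    return FittedModel(
        params=fitted_params,
        loglik=-nll,
        theta=theta,
        free=free,
        param_names=names,
        information=info,
        vcov=vcov,
        converged=converged,
        convergence={
            "iterations": int(res.nit),
            "newton_steps": newton_steps,
            "grad_max_norm": gnorm,
            "status": "converged" if converged else "max-gradient not reached",
            "optimizer_message": str(res.message),
        },
        frozen_transitions=frozen_transitions,
        age_threshold=age_threshold,
    )


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class HazardRatioRow:
    """One table row: adjusted hazard ratio for a contrast on a transition."""

    transition: tuple[str, str]
    transition_label: str
    group: str
    covariate: str
    n_exposed: int | None
    n_unexposed: int | None
    ahr: float | None
    ci_lower: float | None
    ci_upper: float | None
    significant: bool | None
    estimable: bool
    note: str = ""


def wald_ci(beta: float, se: float, ci_level: float = 0.95) -> tuple[float, float, float]:
    """aHR with Wald interval on the log scale: exp(beta -/+ z * se)."""
    z = norm.ppf(0.5 + ci_level / 2.0)
    return float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


def hazard_ratio_table(
    fitted: FittedModel,
    contrasts: Sequence[str],
    *,
    counts: Mapping[str, Mapping[tuple[str, str], tuple[int, int]]] | None = None,
    ci_level: float = 0.95,
    transitions: Sequence[tuple[str, str]] = REPORTED_TRANSITIONS,
) -> list[HazardRatioRow]:
    """Per-transition adjusted hazard ratios with Wald CIs.

    Emits one row per (reported transition, contrast); death transitions
    are suppressed unless explicitly passed in ``transitions``.
    ``counts`` optionally maps contrast -> transition -> (n exposed,
    n unexposed) as produced by :func:`transition_count_table`.
    Transitions frozen during fitting, or an uninvertible information
    matrix, yield non-estimable rows with a note instead of intervals.
    """
    rows = []
    for tr in transitions:
        if tr not in fitted.params.structure.transitions:
            raise InputError(f"transition {tr} not in model structure")
        for cov in contrasts:
            n_exp = n_unexp = None
            if counts is not None and cov in counts:
                n_exp, n_unexp = counts[cov].get(tr, (None, None))
            note = ""
            if tr in fitted.frozen_transitions:
                rows.append(HazardRatioRow(tr, transition_label(*tr),
                                           TRANSITION_GROUPS.get(tr, ""), cov, n_exp,
                                           n_unexp, None, None, None, None, False,
                                           "not estimable: transition frozen (no events)"))
                continue
            b, se = fitted.beta_and_se(cov, *tr)
            if not np.isfinite(se):
                note = "CI unavailable: singular information matrix"
                rows.append(HazardRatioRow(tr, transition_label(*tr),
                                           TRANSITION_GROUPS.get(tr, ""), cov, n_exp,
                                           n_unexp, float(np.exp(b)), None, None, None,
                                           True, note))
                continue
            ahr, lo, hi = wald_ci(b, se, ci_level)
            rows.append(HazardRatioRow(tr, transition_label(*tr),
                                       TRANSITION_GROUPS.get(tr, ""), cov, n_exp,
                                       n_unexp, ahr, lo, hi,
                                       bool(lo > 1.0 or hi < 1.0), True, note))
    return rows


def transition_count_table(
    cohort: Sequence[SubjectHistory],
    exposure: str,
    *,
    transitions: Sequence[tuple[str, str]] = REPORTED_TRANSITIONS,
) -> dict[tuple[str, str], tuple[int, int]]:
    """Successive-pair counts per transition, exposed vs unexposed.

    Classification uses the binary exposure value in effect at the
    interval-start visit (carried forward, like the likelihood).
    """
    out = {tr: [0, 0] for tr in transitions}
    for h in cohort:
        for o0, o1 in zip(h.observations, h.observations[1:]):
            if exposure not in o0.covariates:
                raise InputError(f"exposure {exposure!r} missing at t={o0.t} "
                                 f"for subject {h.subject_id}")
            val = o0.covariates[exposure]
            if val not in (0, 1, 0.0, 1.0):
                raise InputError(f"exposure {exposure!r} must be binary, got {val!r}")
            tr = (o0.state, o1.state)
            if tr in out:
                out[tr][0 if val else 1] += 1
    return {tr: (v[0], v[1]) for tr, v in out.items()}
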