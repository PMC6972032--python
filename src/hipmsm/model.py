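"""State space, transition structure and intensity machinery.

The progression model tracks a person's hip status through five states:

* ``A`` — no radiographic hip OA (rHOA) and no hip symptoms
* ``B`` — asymptomatic rHOA (KLG >= 2, no symptoms)
* ``C`` — hip symptoms only (no rHOA)
* ``D`` — symptomatic hip OA (rHOA and symptoms in the same hip)
* ``E`` — death, the unique absorbing state

Movements between states are governed by a continuous-time Markov chain
with generator (intensity) matrix ``Q``.  Off-diagonal entry ``Q[r, s]``
is the instantaneous rate (per person-year) of moving from state ``r``
to ``s``; each row sums to zero and the death row is identically zero.
Direct jumps A<->D and C<->B are structural zeros in the default model:
those panel patterns are still possible through intermediate states.

Covariates act log-linearly on every allowed intensity,

    q_rs(z) = q_rs0 * exp(beta_rs' z + gamma_rs * 1{age >= 65}),

so that ``exp(beta)`` is a transition-specific hazard ratio and
``gamma_rs`` implements a piecewise-exponential intensity change at age
65 (time-inhomogeneity with a single changepoint).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.linalg import expm


class InputError(ValueError):
    """Invalid user-supplied data (bad covariates, times, schema...)."""


class ParameterError(ValueError):
    """Invalid model parameters (non-finite, wrong shape...)."""


STATES: tuple[str, ...] = ("A", "B", "C", "D", "E")
STATE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STATES)}
DEATH_STATE = "E"
LIVING_STATES: tuple[str, ...] = ("A", "B", "C", "D")

#: The ten allowed instantaneous transitions of the hip-OA model:
#: six among living states plus death from every living state.
DEFAULT_TRANSITIONS: tuple[tuple[str, str], ...] = (
    ("A", "B"), ("A", "C"), ("B", "D"), ("C", "A"), ("C", "D"), ("D", "B"),
    ("A", "E"), ("B", "E"), ("C", "E"), ("D", "E"),
)

STATE_LABELS: dict[str, str] = {
    "A": "No rHOA/symptoms (A)",
    "B": "rHOA (B)",
    "C": "Symptoms only (C)",
    "D": "sxHOA (D)",
    "E": "Death (E)",
}


@dataclass(frozen=True)
class StateSpace:
    """The ordered state labels and the absorbing subset."""

    states: tuple[str, ...] = STATES
    absorbing: frozenset[str] = frozenset({DEATH_STATE})

    def __post_init__(self) -> None:
        if len(self.states) != len(set(self.states)):
            raise InputError("duplicate state labels")
        for s in self.absorbing:
            if s not in self.states:
                raise InputError(f"absorbing state {s!r} not in state list")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise InputError(f"unknown state {state!r}") from None


@dataclass(frozen=True)
class TransitionStructure:
    """An ordered set of allowed directed transitions.

    The engine accepts any structure over any state space; the packaged
    default is the five-state hip-OA structure with ten transitions.
    """

    transitions: tuple[tuple[str, str], ...] = DEFAULT_TRANSITIONS
    state_space: StateSpace = field(default_factory=StateSpace)

    def __post_init__(self) -> None:
        seen = set()
        for r, s in self.transitions:
            self.state_space.index(r)
            self.state_space.index(s)
            if r == s:
                raise InputError(f"self-transition {r}->{s} not allowed")
            if r in self.state_space.absorbing:
                raise InputError(f"transition out of absorbing state {r}")
            if (r, s) in seen:
                raise InputError(f"duplicate transition {r}->{s}")
            seen.add((r, s))
        # every non-absorbing state needs an exit
        sources = {r for r, _ in self.transitions}
        for s in self.state_space.states:
            if s not in self.state_space.absorbing and s not in sources:
                raise InputError(f"non-absorbing state {s} has no outgoing transition")

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    @property
    def n_states(self) -> int:
        return self.state_space.n_states

    def index_pairs(self) -> np.ndarray:
        """(T, 2) integer array of (from, to) state indices."""
        idx = self.state_space.index
        return np.array([(idx(r), idx(s)) for r, s in self.transitions], dtype=int)

    def transition_index(self, r: str, s: str) -> int:
        try:
            return self.transitions.index((r, s))
        except ValueError:
            raise InputError(f"transition {r}->{s} not in structure") from None

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.transitions

    def reachable(self) -> dict[str, frozenset[str]]:
        """Transitive closure: states reachable from each state in positive time.

        Every state reaches itself (staying put has positive probability
        for living states; absorbing states never leave).
        """
        states = self.state_space.states
        adj = {s: {s} for s in states}
        for r, s in self.transitions:
            adj[r].add(s)
        # Floyd–Warshall-style closure on a handful of states
        changed = True
        while changed:
            changed = False
            for r in states:
                new = set(adj[r])
                for m in adj[r]:
                    new |= adj[m]
                if new != adj[r]:
                    adj[r] = new
                    changed = True
        return {s: frozenset(v) for s, v in adj.items()}


@dataclass(frozen=True)
class CovariateSpec:
    """Named covariates entering the log-linear intensity model.

    Covariates are numeric with 0 as the reference level, so baseline
    intensities ``q0`` are the rates for a reference-level person under
    age 65.  ``kinds`` marks each as ``"static"`` (fixed at baseline) or
    ``"time-dependent"`` (re-recorded at every visit and carried forward
    across the following interval).  ``mask`` (transitions x covariates)
    switches individual coefficients off; ``None`` means all on.
    """

    names: tuple[str, ...] = ()
    kinds: tuple[str, ...] = ()
    mask: tuple[tuple[bool, ...], ...] | None = None

    def __post_init__(self) -> None:
        if self.kinds and len(self.kinds) != len(self.names):
            raise InputError("kinds must align with names")
        for k in self.kinds:
            if k not in ("static", "time-dependent"):
                raise InputError(f"unknown covariate kind {k!r}")

    @property
    def n_covariates(self) -> int:
        return len(self.names)

    def mask_array(self, n_transitions: int) -> np.ndarray:
        if self.mask is None:
            return np.ones((n_transitions, self.n_covariates), dtype=bool)
        m = np.asarray(self.mask, dtype=bool)
        if m.shape != (n_transitions, self.n_covariates):
            raise InputError(
                f"mask shape {m.shape} != ({n_transitions}, {self.n_covariates})"
            )
        return m


@dataclass
class ModelParameters:
    """Complete parameter set for one model.

    Attributes
    ----------
    structure
        Allowed-transition structure (length T).
    covariates
        Covariate specification (length K).
    log_q0
        (T,) log baseline intensities, events per person-year.
    beta
        (T, K) log hazard ratios; entries outside the covariate mask are
        fixed at zero.
    gamma
        (T,) log intensity multipliers applied while age >= 65, or
        ``None`` for a time-homogeneous model.
    """

    structure: TransitionStructure
    covariates: CovariateSpec
    log_q0: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray | None = None

    def __post_init__(self) -> None:
        T = self.structure.n_transitions
        K = self.covariates.n_covariates
        self.log_q0 = np.asarray(self.log_q0, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float).reshape(T, K) if K else np.zeros((T, 0))
        if self.log_q0.shape != (T,):
            raise ParameterError(f"log_q0 must have shape ({T},)")
        if self.gamma is not None:
            self.gamma = np.asarray(self.gamma, dtype=float)
            if self.gamma.shape != (T,):
                raise ParameterError(f"gamma must have shape ({T},)")
        for arr, name in ((self.log_q0, "log_q0"), (self.beta, "beta")):
            if not np.all(np.isfinite(arr)):
                raise ParameterError(f"non-finite entries in {name}")
        if self.gamma is not None and not np.all(np.isfinite(self.gamma)):
            raise ParameterError("non-finite entries in gamma")
        mask = self.covariates.mask_array(T)
        self.beta = np.where(mask, self.beta, 0.0)

    @classmethod
    def from_dicts(
        cls,
        structure: TransitionStructure,
        covariates: CovariateSpec,
        q0: Mapping[tuple[str, str], float],
        beta: Mapping[str, Mapping[tuple[str, str], float]] | None = None,
        gamma: Mapping[tuple[str, str], float] | None = None,
    ) -> "ModelParameters":
        """Build parameters from per-transition dictionaries.

        ``q0`` maps every allowed transition to its baseline rate
        (natural scale).  ``beta`` maps covariate name -> {transition:
        log-HR}; unspecified entries are 0.  ``gamma`` maps transition ->
        age-65 log multiplier (``None`` disables the changepoint).
        """
        T = structure.n_transitions
        log_q0 = np.empty(T)
        for i, tr in enumerate(structure.transitions):
            if tr not in q0:
                raise ParameterError(f"missing baseline intensity for {tr[0]}->{tr[1]}")
            if q0[tr] <= 0:
                raise ParameterError(f"baseline intensity for {tr} must be positive")
            log_q0[i] = np.log(q0[tr])
        B = np.zeros((T, covariates.n_covariates))
        for name, trans_map in (beta or {}).items():
            if name not in covariates.names:
                raise ParameterError(f"unknown covariate {name!r} in beta")
            k = covariates.names.index(name)
            for tr, val in trans_map.items():
                B[structure.transition_index(*tr), k] = val
        G = None
        if gamma is not None:
            G = np.zeros(T)
            for tr, val in gamma.items():
                G[structure.transition_index(*tr)] = val
        return cls(structure, covariates, log_q0, B, G)

    def hazard_ratio(self, covariate: str, r: str, s: str) -> float:
        """exp(beta) for one covariate on one transition."""
        k = self.covariates.names.index(covariate)
        return float(np.exp(self.beta[self.structure.transition_index(r, s), k]))


def build_intensity_matrix(
    params: ModelParameters,
    z: Mapping[str, float],
    age_ge_65: bool = False,
) -> np.ndarray:
    """Covariate-specific generator matrix Q (units 1/year).

    ``Q[r, s] = exp(log_q0 + beta' z + gamma * age_ge_65)`` on allowed
    transitions, structural zeros elsewhere, diagonal balancing each row
    to zero; absorbing rows are identically zero.
    """
    spec = params.covariates
    zvec = np.empty(spec.n_covariates)
    for k, name in enumerate(spec.names):
        if name not in z:
            raise InputError(f"missing covariate value for {name!r}")
        zvec[k] = z[name]
    if not np.all(np.isfinite(zvec)):
        raise InputError("non-finite covariate value")
    n = params.structure.n_states
    eta = params.log_q0 + (params.beta @ zvec if spec.n_covariates else 0.0)
    if params.gamma is not None and age_ge_65:
        eta = eta + params.gamma
    q = np.exp(eta)
    Q = np.zeros((n, n))
    pairs = params.structure.index_pairs()
    Q[pairs[:, 0], pairs[:, 1]] = q
    np.fill_diagonal(Q, 0.0)
    Q[np.arange(n), np.arange(n)] = -Q.sum(axis=1)
    return Q


def validate_intensity_matrix(Q: np.ndarray, atol: float = 1e-10) -> None:
    """Raise ParameterError unless Q is a valid generator."""
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ParameterError("Q must be square")
    if not np.all(np.isfinite(Q)):
        raise ParameterError("Q has non-finite entries")
    off = Q - np.diag(np.diag(Q))
    if np.any(off < -atol):
        raise ParameterError("negative off-diagonal intensity")
    if np.any(np.abs(Q.sum(axis=1)) > atol * max(1.0, np.max(np.abs(Q)))):
        raise ParameterError("rows of Q must sum to zero")


def transition_probability(Q: np.ndarray, dt: float) -> np.ndarray:
    """Interval transition probabilities P = expm(Q * dt).

    Uses scaling-and-squaring/Pade matrix exponentiation, which remains
    accurate for non-symmetric (and even defective) generators.
    """
    if dt < 0:
        raise InputError(f"dt must be non-negative, got {dt}")
    validate_intensity_matrix(Q)
    if dt == 0:
        return np.eye(Q.shape[0])
    P = expm(np.asarray(Q, dtype=float) * dt)
    # clip tiny negative round-off without disturbing real mass
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def path_probability(segments: Iterable[tuple[np.ndarray, float]]) -> np.ndarray:
    """Ordered product of per-segment transition probabilities.

    ``segments`` is a sequence of (Q, dt) pairs describing a
    piecewise-constant intensity path (covariate changes, the age-65
    crossing).  An empty sequence yields the identity.
    """
    P: np.ndarray | None = None
    for Q, dt in segments:
        Pk = transition_probability(Q, dt)
        P = Pk if P is None else P @ Pk
    if P is None:
        return np.eye(len(STATES))
    return P


def default_structure() -> TransitionStructure:
    """The packaged five-state hip-OA transition structure."""
    return TransitionStructure()
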