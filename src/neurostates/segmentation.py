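"""Median-threshold symbolization and the discrete-emission HMM.

Two movement signals (accelerometer magnitude "ACL" and pose speed "DLC")
are reduced to a four-letter symbol stream by comparing each value against
its session median.  A 3-state hidden Markov model over that stream is
estimated by Baum-Welch, decoded by Viterbi, and its states mapped to the
canonical roles ``sleep`` / ``dmn`` / ``active`` from their emission
signatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _hmmcore
from ._seeds import child_rng
from .errors import (
    DecodingError,
    EstimationError,
    InvalidInputError,
    InvalidParameterError,
)

#: Symbol alphabet; index order is fixed and used everywhere downstream.
SYMBOLS = ("LoLo", "HiHi", "LoHi", "HiLo")
SYMBOL_INDEX = {s: i for i, s in enumerate(SYMBOLS)}

#: Canonical state roles in state-index order 1..3.
ROLES = ("sleep", "dmn", "active")

#: Example-session transition matrix (rows: from-state 1..3).
EXAMPLE_TRANSITION = np.array(
    [
        [0.98, 0.01, 0.01],
        [0.01, 0.87, 0.12],
        [0.04, 0.06, 0.90],
    ]
)

#: Example-session emission matrix (columns in SYMBOLS order
#: LoLo, HiHi, LoHi, HiLo).
EXAMPLE_EMISSION = np.array(
    [
        [0.98, 0.00, 0.01, 0.01],
        [0.01, 0.21, 0.00, 0.78],
        [0.08, 0.59, 0.29, 0.04],
    ]
)

#: Manual scoring vocabulary and its grouping into the three behavioral sets.
BEHAVIOR_LABELS = (
    "curled-up sleeping posture",
    "quiet awake",
    "eating/drinking",
    "grooming",
    "in/near nest box",
    "locomotion",
    "exploration",
)
LABEL_TO_SET = {
    "curled-up sleeping posture": 1,
    "quiet awake": 2,
    "eating/drinking": 2,
    "grooming": 2,
    "in/near nest box": 2,
    "locomotion": 3,
    "exploration": 3,
}

_EMISSION_FLOOR = 1e-12


def _check_stochastic(mat: np.ndarray, name: str, tol: float = 1e-9) -> None:
    mat = np.asarray(mat, dtype=float)
    if np.any(mat < 0):
        raise InvalidParameterError(f"{name} has negative entries")
    sums = mat.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=tol):
        raise InvalidParameterError(
            f"rows of {name} must sum to 1 within {tol}; got sums {sums}"
        )


@dataclass
class SymbolSequence:
    """Categorical stream over :data:`SYMBOLS` with a fixed step duration."""

    symbols: np.ndarray  # integer codes into SYMBOLS
    step_duration: float = 0.5

    def __post_init__(self):
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        if self.symbols.size < 1:
            raise InvalidInputError("symbol sequence must be non-empty")
        if self.symbols.min() < 0 or self.symbols.max() >= len(SYMBOLS):
            raise InvalidInputError("symbol codes must index the 4-letter alphabet")

    def __len__(self):
        return self.symbols.size

    @property
    def names(self):
        return [SYMBOLS[i] for i in self.symbols]


@dataclass
class HMMParams:
    """Initial distribution, transition matrix, emission matrix, roles."""

    pi: np.ndarray
    A: np.ndarray
    B: np.ndarray
    roles: dict = field(default_factory=dict)
    log_likelihood: float | None = None
    loglik_history: np.ndarray | None = None

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        _check_stochastic(self.pi[None, :], "pi")
        _check_stochastic(self.A, "A")
        _check_stochastic(self.B, "B")
        if self.A.shape[0] != self.A.shape[1] or self.A.shape[0] != self.B.shape[0]:
            raise InvalidParameterError("A must be square and share rows with B")

    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    def to_dict(self) -> dict:
        return {
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "roles": dict(self.roles),
            "log_likelihood": self.log_likelihood,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParams":
        return cls(
            pi=np.asarray(d["pi"], float),
            A=np.asarray(d["A"], float),
            B=np.asarray(d["B"], float),
            roles={int(k): v for k, v in d.get("roles", {}).items()},
            log_likelihood=d.get("log_likelihood"),
        )


@dataclass
class StateSequence:
    """Decoded path (1-based states) with its path log-likelihood."""

    states: np.ndarray
    log_likelihood: float
    step_duration: float = 0.5

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)

    def __len__(self):
        return self.states.size


def example_params() -> HMMParams:
    """The printed example-session parameters with canonical roles."""
    pi = np.array([1 / 3, 1 / 3, 1 / 3])
    return HMMParams(
        pi=pi,
        A=EXAMPLE_TRANSITION.copy(),
        B=EXAMPLE_EMISSION.copy(),
        roles={1: "sleep", 2: "dmn", 3: "active"},
    )


# ---------------------------------------------------------------------------
# symbolization
# ---------------------------------------------------------------------------

def symbolize(acl, dlc, step_duration: float = 0.5) -> SymbolSequence:
    """Map paired sensor steps onto {LoLo, HiHi, LoHi, HiLo}.

    A step is "Hi" on a sensor iff its value strictly exceeds that sensor's
    session median (ties count as Lo, so constant signals are inactive).
    The first letter refers to ACL, the second to DLC.
    """
    acl = np.asarray(getattr(acl, "values", acl), dtype=float)
    dlc = np.asarray(getattr(dlc, "values", dlc), dtype=float)
    if acl.shape != dlc.shape or acl.ndim != 1:
        raise InvalidInputError(
            f"sensor series must be 1-d and equal length; got {acl.shape} vs {dlc.shape}"
        )
    hi_a = acl > np.median(acl)
    hi_d = dlc > np.median(dlc)
    codes = np.empty(acl.size, dtype=np.int64)
    codes[~hi_a & ~hi_d] = SYMBOL_INDEX["LoLo"]
    codes[hi_a & hi_d] = SYMBOL_INDEX["HiHi"]
    codes[~hi_a & hi_d] = SYMBOL_INDEX["LoHi"]
    codes[hi_a & ~hi_d] = SYMBOL_INDEX["HiLo"]
    return SymbolSequence(codes, step_duration=step_duration)


# ---------------------------------------------------------------------------
# estimation and decoding
# ---------------------------------------------------------------------------

def _em_fit(obs, pi, A, B, tol, max_iter):
    """Run EM from one start point; returns params and loglik history."""
    history = []
    prev = -np.inf
    for _ in range(max_iter):
        ll, gamma0, A_num, B_num = _hmmcore.em_step(obs, pi, A, B)
        history.append(ll)
        # M-step with flooring to keep the log domain alive
        pi = np.maximum(gamma0, _EMISSION_FLOOR)
        pi /= pi.sum()
        A = np.maximum(A_num, _EMISSION_FLOOR)
        A /= A.sum(axis=1, keepdims=True)
        B = np.maximum(B_num, _EMISSION_FLOOR)
        B /= B.sum(axis=1, keepdims=True)
        if ll - prev < tol and np.isfinite(prev):
            break
        prev = ll
    return pi, A, B, np.asarray(history)


def fit_hmm(
    symbols: SymbolSequence,
    n_states: int = 3,
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> HMMParams:
    """Baum-Welch maximum-likelihood fit with random restarts.

    Each restart draws all rows of ``pi``, ``A`` and ``B`` from a flat
    Dirichlet; the restart with the highest final log-likelihood wins.  The
    per-iteration log-likelihood is non-decreasing (up to the 1e-12 emission
    floor) and is retained on the result as ``loglik_history``.
    """
    obs = symbols.symbols if isinstance(symbols, SymbolSequence) else np.asarray(symbols, np.int64)
    n_symbols = len(SYMBOLS)
    if obs.size < n_states:
        raise EstimationError(
            f"sequence of length {obs.size} too short for {n_states} states"
        )
    rng = child_rng(seed, "hmm_init")
    best = None
    for _ in range(n_restarts):
        pi0 = rng.dirichlet(np.ones(n_states))
        A0 = rng.dirichlet(np.ones(n_states), size=n_states)
        B0 = rng.dirichlet(np.ones(n_symbols), size=n_states)
        pi, A, B, history = _em_fit(obs, pi0, A0, B0, tol, max_iter)
        if best is None or history[-1] > best[3][-1]:
            best = (pi, A, B, history)
    pi, A, B, history = best
    return HMMParams(
        pi=pi,
        A=A,
        B=B,
        log_likelihood=float(history[-1]),
        loglik_history=history,
    )


def sequence_log_likelihood(symbols, params: HMMParams) -> float:
    """Total log-likelihood of a symbol stream under ``params``."""
    obs = symbols.symbols if isinstance(symbols, SymbolSequence) else np.asarray(symbols, np.int64)
    ll, _, _, _ = _hmmcore.em_step(obs, params.pi, params.A, params.B)
    return float(ll)


def viterbi(symbols: SymbolSequence, params: HMMParams) -> StateSequence:
    """Globally most probable state path under ``params``.

    Computed in log space; ties break deterministically toward the lower
    state index.  A symbol with zero probability under every state makes the
    path undefined and raises :class:`DecodingError` naming the step.
    """
    obs = symbols.symbols if isinstance(symbols, SymbolSequence) else np.asarray(symbols, np.int64)
    step = symbols.step_duration if isinstance(symbols, SymbolSequence) else 0.5
    col_max = params.B[:, obs].max(axis=0)
    dead = np.nonzero(col_max <= 0.0)[0]
    if dead.size:
        raise DecodingError(
            f"symbol at step {int(dead[0])} has zero probability under all states"
        )
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.pi)
        log_A = np.log(params.A)
        log_B = np.log(params.B)
    path, ll = _hmmcore.viterbi_path(obs, log_pi, log_A, log_B)
    return StateSequence(states=path + 1, log_likelihood=float(ll), step_duration=step)


# ---------------------------------------------------------------------------
# canonical labeling, dwell times, manual-label overlap
# ---------------------------------------------------------------------------

def canonicalize_states(params: HMMParams) -> HMMParams:
    """Permute states into the canonical sleep / dmn / active order.

    ``sleep`` is the state with the largest LoLo emission; among the
    remaining two, ``dmn`` has the larger HiLo emission; the last state is
    ``active``.  Ties break toward the lower original state index.  The
    permutation is applied consistently to pi, A and B.
    """
    B = params.B
    sleep = int(np.argmax(B[:, SYMBOL_INDEX["LoLo"]]))
    rest = [i for i in range(params.n_states) if i != sleep]
    dmn = rest[int(np.argmax(B[rest, SYMBOL_INDEX["HiLo"]]))]
    rest2 = [i for i in rest if i != dmn]
    order = [sleep, dmn] + rest2
    perm = np.asarray(order)
    roles = {i + 1: ROLES[i] if i < len(ROLES) else f"state{i + 1}" for i in range(params.n_states)}
    return HMMParams(
        pi=params.pi[perm],
        A=params.A[np.ix_(perm, perm)],
        B=params.B[perm],
        roles=roles,
        log_likelihood=params.log_likelihood,
        loglik_history=params.loglik_history,
    )


def _run_lengths(states: np.ndarray):
    """(state, run_length) pairs including boundary runs."""
    change = np.nonzero(np.diff(states))[0]
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [states.size]))
    return states[starts], ends - starts


def dwell_times(path: StateSequence, step_duration: float | None = None) -> dict:
    """Mean uninterrupted run length per state, in seconds."""
    states = path.states if isinstance(path, StateSequence) else np.asarray(path, np.int64)
    if states.size == 0:
        raise InvalidInputError("empty state path")
    if step_duration is None:
        step_duration = path.step_duration if isinstance(path, StateSequence) else 0.5
    run_states, run_lens = _run_lengths(states)
    out = {}
    for s in np.unique(states):
        sel = run_states == s
        out[int(s)] = float(run_lens[sel].mean() * step_duration)
    return out


def map_labels_to_sets(labels) -> np.ndarray:
    """Map 7-name manual labels onto behavioral sets 1..3."""
    sets = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        if lab not in LABEL_TO_SET:
            raise InvalidInputError(f"unknown behavior label {lab!r}")
        sets[i] = LABEL_TO_SET[lab]
    return sets


def overlap_matrix(path, labels):
    """Fraction of each decoded state's steps falling in each manual set.

    ``labels`` may be integer sets 1..3 or names from the 7-label
    vocabulary.  Entry (i, j) is the fraction of steps decoded as state i+1
    whose manual set is j+1; rows sum to 1.  Also returns the per-state
    composition over the raw labels supplied.
    """
    states = path.states if isinstance(path, StateSequence) else np.asarray(path, np.int64)
    raw = list(labels)
    if raw and isinstance(raw[0], str):
        sets = map_labels_to_sets(raw)
    else:
        sets = np.asarray(raw, dtype=np.int64)
    if sets.size != states.size:
        raise InvalidInputError(
            f"path length {states.size} != label length {sets.size}"
        )
    mat = np.zeros((3, 3))
    for i in range(3):
        sel = states == i + 1
        n = sel.sum()
        if n:
            for j in range(3):
                mat[i, j] = np.sum(sets[sel] == j + 1) / n
    composition = {}
    for i in range(3):
        sel = states == i + 1
        n = sel.sum()
        comp = {}
        if n and raw and isinstance(raw[0], str):
            for lab in BEHAVIOR_LABELS:
                frac = sum(1 for k in np.nonzero(sel)[0] if raw[k] == lab) / n
                if frac:
                    comp[lab] = frac
        composition[i + 1] = comp
    return mat, composition
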