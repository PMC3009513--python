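"""Labelled hidden Markov models and the classical decoding algorithms.

A labelled HMM is a tuple (A, E, Sigma, x0) together with a label function
mapping each state to a sequence feature (e.g. "membrane", "cytoplasmic").
The start state x0 is silent: a path x_0, x_1, ..., x_n emits y_1, ..., y_n
in states x_1..x_n, so

    Pr[x, y] = prod_{i=1..n} a_{x_{i-1} x_i} * e_{x_i y_i}.

This module provides the model container plus the standard unconstrained
algorithms: forward/backward with per-column scaling, Viterbi, posterior
state marginals, and conditional path sampling (forward filtering /
backward sampling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "HMM",
    "ObservationSequence",
    "StatePath",
    "ForwardTable",
    "BackwardTable",
    "joint_probability",
    "forward",
    "backward",
    "viterbi",
    "posterior_state_probs",
    "sample_path_posterior",
]

_ROW_TOL = 1e-9


@dataclass(frozen=True)
class HMM:
    """A labelled hidden Markov model.

    Parameters
    ----------
    transitions
        ``(m, m)`` row-stochastic matrix ``A``; ``A[i, j]`` is the
        probability of moving from state ``i`` to state ``j``.  A row may
        be all-zero only for a designated dead ("dump") state.
    emissions
        ``(m, |Sigma|)`` row-stochastic matrix ``E``; ``E[k, s]`` is the
        probability that state ``k`` emits symbol ``alphabet[s]``.
    alphabet
        Ordered emission symbols.
    start_state
        Index of the silent start state ``x0``.
    labels
        Per-state feature label; many states may share a label.
    state_names
        Optional per-state identifiers (for I/O and error messages).
    """

    transitions: np.ndarray
    emissions: np.ndarray
    alphabet: tuple[str, ...]
    start_state: int
    labels: tuple[str, ...]
    state_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.transitions, dtype=float)
        E = np.asarray(self.emissions, dtype=float)
        object.__setattr__(self, "transitions", A)
        object.__setattr__(self, "emissions", E)
        object.__setattr__(self, "alphabet", tuple(self.alphabet))
        object.__setattr__(self, "labels", tuple(self.labels))
        if self.state_names is not None:
            object.__setattr__(self, "state_names", tuple(self.state_names))
        m = A.shape[0]
        if A.shape != (m, m):
            raise ValueError("transition matrix must be square")
        if E.shape != (m, len(self.alphabet)):
            raise ValueError(
                f"emission matrix shape {E.shape} does not match "
                f"{m} states x {len(self.alphabet)} symbols"
            )
        if len(self.labels) != m:
            raise ValueError("need one label per state")
        if self.state_names is not None and len(self.state_names) != m:
            raise ValueError("need one state name per state")
        if not (0 <= self.start_state < m):
            raise ValueError(f"start state {self.start_state} out of range")
        if np.any(A < -1e-15) or np.any(A > 1 + 1e-12):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if np.any(E < -1e-15) or np.any(E > 1 + 1e-12):
            raise ValueError("emission probabilities must lie in [0, 1]")
        rows = A.sum(axis=1)
        for i, s in enumerate(rows):
            # all-zero rows are tolerated (dead/"dump" states)
            if s != 0.0 and abs(s - 1.0) > _ROW_TOL:
                raise ValueError(self._rowname(i) + f": transition row sums to {s!r}, not 1")
        erows = E.sum(axis=1)
        for i, s in enumerate(erows):
            if abs(s - 1.0) > _ROW_TOL:
                raise ValueError(self._rowname(i) + f": emission row sums to {s!r}, not 1")

    def _rowname(self, i: int) -> str:
        if self.state_names is not None:
            return f"state {self.state_names[i]!r}"
        return f"state {i}"

    @property
    def m(self) -> int:
        return self.transitions.shape[0]

    @property
    def symbol_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.alphabet)}

    @property
    def label_set(self) -> tuple[str, ...]:
        """Distinct labels, in order of first appearance."""
        seen: dict[str, None] = {}
        for z in self.labels:
            seen.setdefault(z)
        return tuple(seen)

    def states_with_label(self, label: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels, dtype=object) == label)

    @property
    def start_label(self) -> str:
        return self.labels[self.start_state]

    def encode(self, symbols: Sequence[str]) -> np.ndarray:
        """Map a symbol sequence to alphabet indices, rejecting foreigners."""
        idx = self.symbol_index
        try:
            return np.array([idx[s] for s in symbols], dtype=np.intp)
        except KeyError as e:
            raise ValueError(f"symbol {e.args[0]!r} not in model alphabet") from None


@dataclass(frozen=True)
class ObservationSequence:
    """An emitted sequence y = y_1..y_n over the model alphabet."""

    symbols: str
    id: str | None = None

    def __post_init__(self) -> None:
        if len(self.symbols) < 1:
            raise ValueError("observation sequence must be non-empty")

    @property
    def n(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class StatePath:
    """A state path x_0, x_1, ..., x_n (x_0 is the silent start state)."""

    states: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(int(s) for s in self.states))

    @property
    def n(self) -> int:
        return len(self.states) - 1

    def __iter__(self):
        return iter(self.states)

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, i):
        return self.states[i]


def _as_symbols(y) -> str:
    return y.symbols if isinstance(y, ObservationSequence) else str(y)


@dataclass
class ForwardTable:
    """Scaled forward vectors.

    ``scaled[i]`` is phi_i normalized to sum 1 (phi_i(k) = Pr[y_1..y_i and
    x_i = k]); the true vector is ``scaled[i] * exp(cum_log[i])``.  If the
    (possibly constrained) event has probability 0, vectors from the first
    failing column on are all-zero and ``log_probability`` is ``-inf``.
    """

    scaled: np.ndarray  # (n+1, m); row 0 is the start-state indicator
    cum_log: np.ndarray  # (n+1,)

    @property
    def n(self) -> int:
        return self.scaled.shape[0] - 1

    @property
    def log_probability(self) -> float:
        return float(self.cum_log[-1])

    @property
    def probability(self) -> float:
        return math.exp(self.log_probability) if np.isfinite(self.cum_log[-1]) else 0.0


@dataclass
class BackwardTable:
    """Scaled backward vectors beta_i(k) = Pr[emit y_i..y_n | start in k].

    ``scaled[i]`` for i in 1..n+1; true beta_i = scaled[i] * exp(cum_log[i]).
    Row ``n+1`` is the all-ones boundary.  Row 0 is unused.
    """

    scaled: np.ndarray  # (n+2, m)
    cum_log: np.ndarray  # (n+2,)


def joint_probability(hmm: HMM, y, x: StatePath | Sequence[int], log: bool = False) -> float:
    """Joint probability Pr[x, y] = prod_i a_{x_{i-1} x_i} e_{x_i y_i}."""
    sym = _as_symbols(y)
    states = tuple(x) if not isinstance(x, StatePath) else x.states
    if len(states) != len(sym) + 1:
        raise ValueError(
            f"path length {len(states)} does not match sequence length {len(sym)} + 1"
        )
    if states[0] != hmm.start_state:
        raise ValueError("path must begin at the model start state")
    yi = hmm.encode(sym)
    logp = 0.0
    for i in range(1, len(states)):
        a = hmm.transitions[states[i - 1], states[i]]
        e = hmm.emissions[states[i], yi[i - 1]]
        if a == 0.0 or e == 0.0:
            return -math.inf if log else 0.0
        logp += math.log(a) + math.log(e)
    return logp if log else math.exp(logp)


def forward(hmm: HMM, y) -> ForwardTable:
    """Forward algorithm with per-column scaling; O(n m^2)."""
    yi = hmm.encode(_as_symbols(y))
    n, m = len(yi), hmm.m
    scaled = np.zeros((n + 1, m))
    cum_log = np.full(n + 1, -np.inf)
    scaled[0, hmm.start_state] = 1.0
    cum_log[0] = 0.0
    A, E = hmm.transitions, hmm.emissions
    dead = False
    for i in range(1, n + 1):
        if dead:
            continue
        v = (scaled[i - 1] @ A) * E[:, yi[i - 1]]
        tot = v.sum()
        if tot == 0.0:
            dead = True
            continue
        scaled[i] = v / tot
        cum_log[i] = cum_log[i - 1] + math.log(tot)
    return ForwardTable(scaled=scaled, cum_log=cum_log)


def backward(hmm: HMM, y) -> BackwardTable:
    yi = hmm.encode(_as_symbols(y))
    n, m = len(yi), hmm.m
    scaled = np.zeros((n + 2, m))
    cum_log = np.full(n + 2, -np.inf)
    scaled[n + 1] = 1.0 / m
    cum_log[n + 1] = math.log(m)
    A, E = hmm.transitions, hmm.emissions
    for i in range(n, 0, -1):
        v = A @ (E[:, yi[i - 1]] * scaled[i + 1])
        tot = v.sum()
        if tot == 0.0:
            # no continuation emits the suffix from any state
            scaled[i] = 0.0
            cum_log[i] = 0.0
            continue
        scaled[i] = v / tot
        cum_log[i] = cum_log[i + 1] + math.log(tot)
    return BackwardTable(scaled=scaled, cum_log=cum_log)


def log_dot_identity(ft: ForwardTable, bt: BackwardTable, i: int) -> float:
    """log Pr[y] recovered as log dot(phi_i, beta_{i+1}); for testing."""
    d = float(ft.scaled[i] @ bt.scaled[i + 1])
    if d == 0.0 or not np.isfinite(ft.cum_log[i]):
        return -math.inf
    return float(ft.cum_log[i] + bt.cum_log[i + 1] + math.log(d))


def viterbi(hmm: HMM, y) -> tuple[StatePath, float]:
    """Most probable state path; argmax ties broken by lowest state index."""
    yi = hmm.encode(_as_symbols(y))
    n, m = len(yi), hmm.m
    with np.errstate(divide="ignore"):
        la = np.log(hmm.transitions)
        le = np.log(hmm.emissions)
    dp = la[hmm.start_state] + le[:, yi[0]]
    ptr = np.zeros((n, m), dtype=np.intp)
    for i in range(1, n):
        cand = dp[:, None] + la  # (from, to)
        ptr[i] = np.argmax(cand, axis=0)
        dp = cand[ptr[i], np.arange(m)] + le[:, yi[i]]
    best = int(np.argmax(dp))
    logp = float(dp[best])
    states = [0] * (n + 1)
    states[n] = best
    for i in range(n - 1, 0, -1):
        states[i] = int(ptr[i + 1 - 1][states[i + 1]])
    states[0] = hmm.start_state
    path = StatePath(tuple(states))
    return path, (math.exp(logp) if np.isfinite(logp) else 0.0)


def posterior_state_probs(hmm: HMM, y) -> np.ndarray:
    """Per-position posteriors Pr[x_i = k | y], i = 1..n, as an (n, m) array.

    Entry (i-1, k) is proportional to phi_i(k) * beta_{i+1}(k); each row is
    normalized to sum 1.
    """
    ft = forward(hmm, y)
    if not np.isfinite(ft.log_probability):
        raise ValueError("Pr[y] = 0: posterior undefined")
    bt = backward(hmm, y)
    n = ft.n
    gamma = ft.scaled[1 : n + 1] * bt.scaled[2 : n + 2]
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma


def sample_path_posterior(hmm: HMM, y, rng_seed) -> StatePath:
    """Draw a path from Pr[x | y] by forward filtering / backward sampling."""
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    ft = forward(hmm, y)
    if not np.isfinite(ft.log_probability):
        raise ValueError("Pr[y] = 0: cannot sample a conditional path")
    n, m = ft.n, hmm.m
    states = [0] * (n + 1)
    w = ft.scaled[n].copy()
    states[n] = int(rng.choice(m, p=w / w.sum()))
    A = hmm.transitions
    for i in range(n - 1, 0, -1):
        w = ft.scaled[i] * A[:, states[i + 1]]
        states[i] = int(rng.choice(m, p=w / w.sum()))
    states[0] = hmm.start_state
    return StatePath(tuple(states))
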