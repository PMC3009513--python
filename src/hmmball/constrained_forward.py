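"""Constrained forward passes: probability of a labelling, a footprint, and
of balls of labellings.

All computations share one device: run the forward algorithm on a *grouped*
model.  For a footprint f = f_1..f_k we make k groups of states G_1..G_k
(G_i = states labelled f_i) and allow transitions only from G_i to G_i or
G_{i+1}; a path from G_1 at position 1 to G_k at position n has made exactly
the k-1 label changes of the footprint.  Restricting each group to a window
of sequence positions then selects subsets of labellings:

* exact windows (group i occupies positions b_{i-1}..b_i - 1)  -> the
  probability of one labelling;
* unbounded windows                                            -> the
  probability of the footprint;
* windows widened by a radius r (group i active on positions
  b_{i-1} - r .. b_i + r - 1)                                  -> the
  probability of the border-shift ball B(λ, r).

The border-shift-sum ball adds a budget coordinate d in 0..r that is
charged |actual - reference| each time a border is placed; the generalized
Hamming ball runs on a product automaton of (state, accumulated distance)
pairs charged H[reference label, state label] at every emission.

Probabilities are accumulated with per-column scaling, so returned values
are exact in log space even when the linear-scale probability underflows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .distances import (
    LabelDistanceMatrix,
    Labelling,
    borders_of,
    footprint_of,
)
from .hmm_core import HMM, ObservationSequence, _as_symbols

__all__ = [
    "GroupedBallEngine",
    "GroupedTables",
    "labelling_probability",
    "footprint_probability",
    "ball_prob_border_shift",
    "ball_prob_border_shift_sum",
    "ball_prob_generalized_hamming",
]

NEG_INF = -math.inf


def _maybe_exp(logp: float, log: bool) -> float:
    if log:
        return logp
    return math.exp(logp) if np.isfinite(logp) else 0.0


def _centre_parts(hmm: HMM, y, lam) -> tuple[tuple[str, ...], tuple[int, ...], int]:
    n = len(_as_symbols(y))
    if len(tuple(lam)) != n + 1:
        raise ValueError("labelling length must be n+1 for a sequence of length n")
    return footprint_of(lam), borders_of(lam), n


@dataclass
class GroupedTables:
    """Cached scaled forward/backward tables of a windowed grouped model.

    True phi_i = phi[i] * exp(cum_f[i]); true beta_i = beta[i] * exp(cum_b[i]).
    """

    phi: np.ndarray  # (n+1, k, m)
    cum_f: np.ndarray  # (n+1,)
    beta: np.ndarray  # (n+2, k, m)
    cum_b: np.ndarray  # (n+2,)
    log_prob: float


class GroupedBallEngine:
    """Forward/backward machinery over the grouped, windowed model.

    Instances are bound to one (hmm, sequence, footprint); windows vary per
    call so that ball centres sharing a footprint (as in local search) can
    reuse the construction.
    """

    def __init__(self, hmm: HMM, y, footprint: Sequence[str]):
        self.hmm = hmm
        self.yi = hmm.encode(_as_symbols(y))
        self.n = len(self.yi)
        self.footprint = tuple(footprint)
        self.k = len(self.footprint)
        m = hmm.m
        self.group_mask = np.zeros((self.k, m), dtype=bool)
        labels = np.asarray(hmm.labels, dtype=object)
        for g, f in enumerate(self.footprint):
            self.group_mask[g] = labels == f
        self.feasible = bool(self.group_mask.any(axis=1).all()) and self.k <= self.n
        self.A = hmm.transitions
        self.E = hmm.emissions
        # em[i-1, s] = e_s(y_i)
        self.em = self.E[:, self.yi].T

    # -- window constructions -------------------------------------------------

    def _ext_borders(self, borders: Sequence[int]) -> tuple[int, ...]:
        return (1,) + tuple(borders) + (self.n + 1,)

    def windows_exact(self, borders: Sequence[int]) -> np.ndarray:
        ext = self._ext_borders(borders)
        return np.array([(ext[g], ext[g + 1] - 1) for g in range(self.k)], dtype=int)

    def windows_ball(self, borders: Sequence[int], r: int) -> np.ndarray:
        ext = self._ext_borders(borders)
        return np.array(
            [(max(1, ext[g] - r), min(self.n, ext[g + 1] + r - 1)) for g in range(self.k)],
            dtype=int,
        )

    def windows_full(self) -> np.ndarray:
        return np.array([(1, self.n)] * self.k, dtype=int)

    def active_row(self, windows: np.ndarray, i: int) -> np.ndarray:
        return (windows[:, 0] <= i) & (i <= windows[:, 1])

    # -- forward / backward ---------------------------------------------------

    def _first_column(self, windows: np.ndarray) -> np.ndarray:
        v = np.zeros((self.k, self.hmm.m))
        if self.active_row(windows, 1)[0]:
            v[0] = self.A[self.hmm.start_state] * self.em[0] * self.group_mask[0]
        return v

    def _step(self, phi_prev: np.ndarray, i: int, windows: np.ndarray) -> np.ndarray:
        """Unscaled column i (i >= 2) from the scaled column i-1."""
        P = phi_prev @ self.A
        v = P.copy()
        v[1:] += P[:-1]
        v *= self.em[i - 1]
        v *= self.group_mask
        v[~self.active_row(windows, i)] = 0.0
        return v

    def forward(self, windows: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        n, k, m = self.n, self.k, self.hmm.m
        phi = np.zeros((n + 1, k, m))
        cum = np.full(n + 1, NEG_INF)
        cum[0] = 0.0
        phi[0, 0, self.hmm.start_state] = 1.0
        if not self.feasible:
            return phi, cum, NEG_INF
        dead = False
        for i in range(1, n + 1):
            if dead:
                continue
            v = self._first_column(windows) if i == 1 else self._step(phi[i - 1], i, windows)
            tot = v.sum()
            if tot == 0.0:
                dead = True
                continue
            phi[i] = v / tot
            cum[i] = cum[i - 1] + math.log(tot)
        final = phi[n, k - 1].sum()
        if dead or final == 0.0:
            return phi, cum, NEG_INF
        return phi, cum, float(cum[n] + math.log(final))

    def backward(self, windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n, k, m = self.n, self.k, self.hmm.m
        beta = np.zeros((n + 2, k, m))
        cum = np.full(n + 2, NEG_INF)
        beta[n + 1, k - 1] = 1.0 / m
        cum[n + 1] = math.log(m)
        for i in range(n, 0, -1):
            w = beta[i + 1] * self.em[i - 1] * self.group_mask
            w[~self.active_row(windows, i)] = 0.0
            u = w.copy()
            u[:-1] += w[1:]
            v = u @ self.A.T
            tot = v.sum()
            if tot == 0.0:
                beta[i] = 0.0
                cum[i] = 0.0
                continue
            beta[i] = v / tot
            cum[i] = cum[i + 1] + math.log(tot)
        return beta, cum

    def tables(self, windows: np.ndarray) -> GroupedTables:
        phi, cum_f, logp = self.forward(windows)
        beta, cum_b = self.backward(windows)
        return GroupedTables(phi=phi, cum_f=cum_f, beta=beta, cum_b=cum_b, log_prob=logp)

    def forward_span(
        self, phi_start: np.ndarray | None, i0: int, i1: int, windows: np.ndarray
    ) -> tuple[np.ndarray | None, float]:
        """Recompute scaled columns i0+1..i1 only (phi_start = column i0).

        Returns the scaled column i1 and the accumulated local log
        normalizer, or (None, -inf) if the mass dies in the span.
        """
        local = 0.0
        phi = phi_start
        for i in range(i0 + 1, i1 + 1):
            v = self._first_column(windows) if i == 1 else self._step(phi, i, windows)
            tot = v.sum()
            if tot == 0.0:
                return None, NEG_INF
            phi = v / tot
            local += math.log(tot)
        return phi, local

    def log_prob_from_tables(self, tables: GroupedTables) -> float:
        return tables.log_prob


# -- public operations --------------------------------------------------------


def labelling_probability(hmm: HMM, y, lam, log: bool = False) -> float:
    """Probability that the model emits y along a path with labelling λ.

    Requires λ_0 = label of the start state (else the set of matching paths
    is empty and the result is 0); an infeasible footprint also gives 0.
    """
    f, borders, n = _centre_parts(hmm, y, lam)
    if tuple(lam)[0] != hmm.start_label:
        return _maybe_exp(NEG_INF, log)
    eng = GroupedBallEngine(hmm, y, f)
    _, _, logp = eng.forward(eng.windows_exact(borders))
    return _maybe_exp(logp, log)


def footprint_probability(hmm: HMM, y, footprint: Sequence[str], log: bool = False) -> float:
    """Summed probability of all labellings of y with the given footprint."""
    f = tuple(footprint)
    if any(f[i] == f[i + 1] for i in range(len(f) - 1)):
        raise ValueError("a footprint may not repeat consecutive labels")
    eng = GroupedBallEngine(hmm, y, f)
    _, _, logp = eng.forward(eng.windows_full())
    return _maybe_exp(logp, log)


def ball_prob_border_shift(hmm: HMM, y, lam, r: int, log: bool = False) -> float:
    """Probability of the border-shift ball B(λ, r).

    Group i of the centre's footprint is allowed on positions
    b_{i-1} - r .. b_i + r - 1 (clamped to [1, n]); the layered transition
    structure preserves the footprint, so exactly the labellings whose every
    border lies within r of the centre's contribute.
    """
    if r < 0:
        raise ValueError("radius must be non-negative")
    f, borders, n = _centre_parts(hmm, y, lam)
    eng = GroupedBallEngine(hmm, y, f)
    _, _, logp = eng.forward(eng.windows_ball(borders, r))
    return _maybe_exp(logp, log)


def ball_prob_border_shift_sum(hmm: HMM, y, lam, r: int, log: bool = False) -> float:
    """Probability of the border-shift-sum ball (total displacement <= r).

    Same windowed grouped model as the max-shift ball, with an extra budget
    coordinate d: placing border i at position p charges |p - b_i|, and
    transitions that would push d beyond r are absent.
    """
    if r < 0:
        raise ValueError("radius must be non-negative")
    f, borders, n = _centre_parts(hmm, y, lam)
    eng = GroupedBallEngine(hmm, y, f)
    if not eng.feasible:
        return _maybe_exp(NEG_INF, log)
    k, m = eng.k, hmm.m
    windows = eng.windows_ball(borders, r)
    A, em, gmask = eng.A, eng.em, eng.group_mask

    phi = np.zeros((k, r + 1, m))
    if eng.active_row(windows, 1)[0]:
        phi[0, 0] = A[hmm.start_state] * em[0] * gmask[0]
    tot = phi.sum()
    if tot == 0.0:
        return _maybe_exp(NEG_INF, log)
    phi /= tot
    cum = math.log(tot)
    for i in range(2, n + 1):
        P = (phi.reshape(k * (r + 1), m) @ A).reshape(k, r + 1, m)
        new = P.copy()  # stay within the group: no border placed, no charge
        for g in range(1, k):
            c = abs(i - borders[g - 1])
            if c <= r:
                new[g, c:] += P[g - 1, : r + 1 - c]
        new *= em[i - 1]
        new *= gmask[:, None, :]
        new[~eng.active_row(windows, i)] = 0.0
        tot = new.sum()
        if tot == 0.0:
            return _maybe_exp(NEG_INF, log)
        phi = new / tot
        cum += math.log(tot)
    final = phi[k - 1].sum()
    if final == 0.0:
        return _maybe_exp(NEG_INF, log)
    return _maybe_exp(cum + math.log(final), log)


def ball_prob_generalized_hamming(
    hmm: HMM, y, lam, r: int, H: LabelDistanceMatrix, log: bool = False
) -> float:
    """Probability of the generalized-Hamming ball around λ.

    Product automaton with states (model state, accumulated distance d);
    emitting position i in a state labelled z charges H[λ_i, z]; d may not
    exceed r.  λ_0 is exempt (the start state emits nothing).
    """
    if r < 0:
        raise ValueError("radius must be non-negative")
    sym = _as_symbols(y)
    n = len(sym)
    lam_t = tuple(lam)
    if len(lam_t) != n + 1:
        raise ValueError("labelling length must be n+1 for a sequence of length n")
    yi = hmm.encode(sym)
    m = hmm.m
    A, E = hmm.transitions, hmm.emissions
    state_h_col = np.array([H.index(z) for z in hmm.labels], dtype=np.intp)
    ref_rows = np.array([H.index(z) for z in lam_t[1:]], dtype=np.intp)
    # charge[i-1, s] = H[λ_i, label(s)]
    charge = H.matrix[ref_rows][:, state_h_col]

    phi = np.zeros((r + 1, m))
    base = A[hmm.start_state] * E[:, yi[0]]
    for v in np.unique(charge[0]):
        if v <= r:
            cols = charge[0] == v
            phi[v, cols] = base[cols]
    tot = phi.sum()
    if tot == 0.0:
        return _maybe_exp(NEG_INF, log)
    phi /= tot
    cum = math.log(tot)
    for i in range(2, n + 1):
        base = (phi @ A) * E[:, yi[i - 1]]
        new = np.zeros_like(phi)
        h = charge[i - 1]
        for v in np.unique(h):
            if v > r:
                continue
            cols = h == v
            if v == 0:
                new[:, cols] += base[:, cols]
            else:
                new[v:, cols] += base[:-v, cols]
        tot = new.sum()
        if tot == 0.0:
            return _maybe_exp(NEG_INF, log)
        phi = new / tot
        cum += math.log(tot)
    return _maybe_exp(cum, log)
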