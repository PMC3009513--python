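"""Decoders that search for high-probability ball centres.

Two strategies:

* :func:`local_search` — steepest-ascent hill climbing over border
  positions for the border-shift ball.  Each iteration scores the 2(k-1)
  neighbours that move a single border one position left or right; moving
  border j only changes the active state groups at O(1) positions, so a
  neighbour's ball probability is obtained by recomputing O(r) forward
  columns against cached forward/backward tables instead of a full pass.
  :func:`decode_with_restarts` orchestrates multiple starts sampled from
  the posterior path distribution.

* :func:`regular_ball_dp` — an exact dynamic program for balls of *state
  paths* (each state its own label) whose centre is (2r+1)-regular, i.e.
  every maximal state run lasts at least 2r+1 positions.  Storing the best
  weakly regular ball F[j, s] ending in state s at position j gives a
  Viterbi-like O(n m^2) recursion; at r=0 it is exactly Viterbi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constrained_forward import GroupedBallEngine, GroupedTables, ball_prob_border_shift
from .distances import Labelling, borders_of, footprint_of, labelling_from_parts
from .hmm_core import HMM, StatePath, _as_symbols

__all__ = [
    "local_search",
    "neighbour_ball_logprobs",
    "decode_with_restarts",
    "regular_ball_dp",
    "RegularBallResult",
    "path_ball_log_probability",
]

NEG_INF = -math.inf
_REL_TOL = 1e-12  # minimal relative improvement for an accepted move


def _valid_moves(borders: tuple[int, ...], n: int) -> list[tuple[int, int]]:
    """Single-border +-1 moves that keep every feature non-empty."""
    ext = (1,) + borders + (n + 1,)
    moves = []
    for j in range(len(borders)):
        for delta in (-1, +1):  # leftward first: deterministic tie-breaking
            bn = borders[j] + delta
            if bn <= ext[j] or bn >= ext[j + 2] or bn < 2 or bn > n:
                continue
            moves.append((j, delta))
    return moves


def _neighbour_logprob(
    eng: GroupedBallEngine,
    tables: GroupedTables,
    borders: tuple[int, ...],
    r: int,
    j: int,
    bn: int,
) -> float:
    """Ball log probability of the neighbour with border j moved to bn.

    Active windows differ from the current centre's only at positions in
    [min(b, bn) - r, max(b, bn) + r - 1], so we restart the forward sweep
    from the cached column just before that span and close it with the
    cached backward column just after.
    """
    b = borders[j]
    nb = borders[:j] + (bn,) + borders[j + 1 :]
    windows = eng.windows_ball(nb, r)
    n, k = eng.n, eng.k
    p0 = min(b, bn) - r - 1
    p1 = max(b, bn) + r - 1
    if p0 < 1 or not np.isfinite(tables.cum_f[p0]):
        p0 = 0
        phi_start = None
    else:
        phi_start = tables.phi[p0]
    if p1 >= n:
        phi_end, local = eng.forward_span(phi_start, p0, n, windows)
        if phi_end is None:
            return NEG_INF
        fin = phi_end[k - 1].sum()
        if fin == 0.0:
            return NEG_INF
        return float(tables.cum_f[p0] + local + math.log(fin))
    phi_end, local = eng.forward_span(phi_start, p0, p1, windows)
    if phi_end is None:
        return NEG_INF
    d = float((phi_end * tables.beta[p1 + 1]).sum())
    if d == 0.0 or not np.isfinite(tables.cum_b[p1 + 1]):
        return NEG_INF
    return float(tables.cum_f[p0] + local + tables.cum_b[p1 + 1] + math.log(d))


def neighbour_ball_logprobs(hmm: HMM, y, lam, r: int) -> dict[tuple[int, int], float]:
    """Incrementally evaluated ball log probabilities of all +-1 border moves.

    Keys are (border index, delta).  Exposed mainly so the incremental
    arithmetic can be audited against from-scratch recomputation.
    """
    f, borders = footprint_of(lam), borders_of(lam)
    n = len(_as_symbols(y))
    eng = GroupedBallEngine(hmm, y, f)
    tables = eng.tables(eng.windows_ball(borders, r))
    return {
        (j, delta): _neighbour_logprob(eng, tables, borders, r, j, borders[j] + delta)
        for j, delta in _valid_moves(borders, n)
    }


def _local_search_log(
    hmm: HMM,
    y,
    lam_init,
    r: int,
    max_iters: int = 80,
    callback=None,
    use_cache: bool = True,
) -> tuple[Labelling, float]:
    lam_t = tuple(lam_init)
    label0 = lam_t[0]
    f, borders = footprint_of(lam_t), borders_of(lam_t)
    n = len(_as_symbols(y))
    eng = GroupedBallEngine(hmm, y, f)
    tables = eng.tables(eng.windows_ball(borders, r))
    cur = tables.log_prob
    lam_cur = Labelling(lam_t)
    if len(f) == 1 or max_iters <= 0:
        return lam_cur, cur
    for it in range(max_iters):
        best_move, best_lp = None, NEG_INF
        for j, delta in _valid_moves(borders, n):
            bn = borders[j] + delta
            if use_cache:
                lp = _neighbour_logprob(eng, tables, borders, r, j, bn)
            else:
                nb = borders[:j] + (bn,) + borders[j + 1 :]
                _, _, lp = eng.forward(eng.windows_ball(nb, r))
            if lp > best_lp:
                best_move, best_lp = (j, bn), lp
        # accept only a strict relative improvement
        if best_move is None or not best_lp > cur + _REL_TOL:
            break
        j, bn = best_move
        borders = borders[:j] + (bn,) + borders[j + 1 :]
        tables = eng.tables(eng.windows_ball(borders, r))
        cur = tables.log_prob
        if callback is not None:
            callback(it, borders, cur)
    lam_cur = labelling_from_parts(label0, f, borders, n)
    return lam_cur, cur


def local_search(
    hmm: HMM,
    y,
    lam_init,
    r: int,
    max_iters: int = 80,
    callback=None,
    use_cache: bool = True,
) -> tuple[Labelling, float]:
    """Hill-climb border positions to maximize the border-shift ball.

    Steepest ascent over all valid single-border +-1 moves; ties prefer the
    smallest border index and leftward over rightward.  Stops when no move
    improves the ball probability (relative tolerance 1e-12) or after
    ``max_iters`` accepted moves.  Returns the final centre and its ball
    probability; ``max_iters <= 0`` returns the start unchanged.
    """
    lam, logp = _local_search_log(hmm, y, lam_init, r, max_iters, callback, use_cache)
    return lam, (math.exp(logp) if np.isfinite(logp) else 0.0)


def decode_with_restarts(
    hmm: HMM,
    y,
    r: int,
    n_starts: int = 10,
    init: str = "sample",
    seed=None,
    init_labelling=None,
    max_iters: int = 80,
) -> tuple[Labelling, float]:
    """Best ball centre over multiple local searches.

    ``init="sample"`` draws start labellings from the conditional path
    distribution Pr[x | y] (forward filtering / backward sampling), the
    strategy that worked best in practice: a sample is likely to fall
    inside a high-probability ball, leaving local search only the border
    refinement.  ``init="given"`` starts every search from
    ``init_labelling``.  Deterministic given ``seed``.
    """
    from .distances import labelling_from_path
    from .hmm_core import sample_path_posterior

    if init not in ("sample", "given"):
        raise ValueError("init must be 'sample' or 'given'")
    if init == "given" and init_labelling is None:
        raise ValueError("init='given' requires init_labelling")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    best_lam, best_lp = None, NEG_INF
    for _ in range(max(1, n_starts)):
        if init == "sample":
            start = labelling_from_path(hmm, sample_path_posterior(hmm, y, rng))
        else:
            start = init_labelling
        lam, lp = _local_search_log(hmm, y, start, r, max_iters)
        if best_lam is None or lp > best_lp:
            best_lam, best_lp = lam, lp
    return best_lam, (math.exp(best_lp) if np.isfinite(best_lp) else 0.0)


@dataclass
class RegularBallResult:
    """Output of the exact regular-ball dynamic program."""

    centre: StatePath | None
    probability: float
    log_probability: float
    log_F: np.ndarray | None = None


def path_ball_log_probability(hmm: HMM, y, path, r: int) -> float:
    """Border-shift ball log probability of a state path (paths-as-labels).

    Relabels the model so that each state is its own label and scores the
    path's labelling with the windowed grouped forward pass; independent of
    the DP below, so it doubles as a consistency check on its output.
    """
    ident = HMM(
        transitions=hmm.transitions,
        emissions=hmm.emissions,
        alphabet=hmm.alphabet,
        start_state=hmm.start_state,
        labels=tuple(str(i) for i in range(hmm.m)),
        state_names=hmm.state_names,
    )
    lam = tuple(str(s) for s in path)
    return ball_prob_border_shift(ident, y, lam, r, log=True)


def regular_ball_dp(hmm: HMM, y, r: int, keep_table: bool = False) -> RegularBallResult:
    """Most probable (2r+1)-regular ball of state paths.

    F[j, s] holds the probability of the best weakly (2r+1)-regular ball up
    to position j whose centre ends in state s (weakly: the final run needs
    only r+1 positions).  F[j, s] either extends the final run by one
    position or places a border at position j - r, paying
    Q(s, s', j) = sum over member border placements in [j-2r, j] of the
    probability of emitting y_{j-2r}..y_j in s' then s with one forced
    s' -> s transition, starting from s' at position j-2r-1.  Values at
    j = n - r are closed by extending the final state to position n, which
    enforces strong regularity.  Runtime O(n m^2), as for Viterbi.
    """
    if r < 0:
        raise ValueError("radius must be non-negative")
    sym = _as_symbols(y)
    yi = hmm.encode(sym)
    n, m = len(yi), hmm.m
    if n < 2 * r + 1:
        raise ValueError(f"need n >= 2r+1 (= {2 * r + 1}) for a (2r+1)-regular path")
    A, E = hmm.transitions, hmm.emissions
    em = E[:, yi].T  # (n, m): em[i-1, s] = e_s(y_i)
    diag_a = np.diag(A).copy()
    with np.errstate(divide="ignore"):
        log_diag = np.log(diag_a)
        log_em = np.log(em)
        log_A0 = np.log(A[hmm.start_state])

    logF = np.full((n + 1, m), NEG_INF)
    choice = np.zeros((n + 1, m), dtype=np.int8)  # 0 = extend, 1 = border
    bstate = np.zeros((n + 1, m), dtype=np.intp)
    logF[1] = log_A0 + log_em[0]
    win = 2 * r + 1
    for j in range(2, n - r + 1):
        ext = logF[j - 1] + log_diag + log_em[j - 1]
        logF[j] = ext
        if j >= 3 * r + 2:
            # Q over the window of positions j-2r..j, all (s', s) at once
            W = em[j - win : j]  # (2r+1, m)
            D = diag_a * W
            L = np.ones((win, m))
            if win > 1:
                L[1:] = np.cumprod(D[:-1], axis=0)
                R = np.ones((win, m))
                R[:-1] = np.cumprod(D[1:][::-1], axis=0)[::-1]
            else:
                R = np.ones((win, m))
            Q = A * (L.T @ (W * R))
            np.fill_diagonal(Q, 0.0)  # a border must change state
            with np.errstate(divide="ignore"):
                cand = logF[j - win][:, None] + np.log(Q)
            src = np.argmax(cand, axis=0)
            bval = cand[src, np.arange(m)]
            take = bval > ext
            logF[j, take] = bval[take]
            choice[j, take] = 1
            bstate[j, take] = src[take]
    tail = r * log_diag + log_em[n - r : n].sum(axis=0) if r > 0 else np.zeros(m)
    total = logF[n - r] + tail
    best_s = int(np.argmax(total))
    best_log = float(total[best_s])
    if not np.isfinite(best_log):
        return RegularBallResult(None, 0.0, NEG_INF, logF if keep_table else None)

    states = np.zeros(n + 1, dtype=int)
    pos_hi, j, s = n, n - r, best_s
    while True:
        if j == 1:
            states[1 : pos_hi + 1] = s
            break
        if choice[j, s] == 0:
            j -= 1
            continue
        sp = int(bstate[j, s])
        states[j - r : pos_hi + 1] = s
        pos_hi = j - r - 1
        j -= win
        s = sp
    states[0] = hmm.start_state
    path = StatePath(tuple(int(x) for x in states))
    prob = math.exp(best_log) if np.isfinite(best_log) else 0.0
    return RegularBallResult(path, prob, best_log, logF if keep_table else None)
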