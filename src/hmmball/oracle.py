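"""Brute-force reference implementations for validating the fast algorithms.

Everything here enumerates all m^n state paths, so it is only usable on toy
instances; an :class:`EnumerationBudget` refuses anything larger.  The
oracles are installable (and reachable from the CLI) because they are handy
for debugging model files, but their real role is as independent checks in
the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .distances import BallSpec, ball_contains
from .hmm_core import HMM, StatePath, joint_probability

__all__ = [
    "EnumerationBudget",
    "enumerate_path_probabilities",
    "enumerate_labelling_probabilities",
    "brute_ball_probability",
    "brute_best_regular_ball",
]


@dataclass(frozen=True)
class EnumerationBudget:
    """Guard rails for exhaustive enumeration."""

    max_total_paths: int = 1_000_000

    def check(self, m: int, n: int) -> None:
        if m**n > self.max_total_paths:
            raise ValueError(
                f"enumeration of {m}^{n} paths exceeds the budget of "
                f"{self.max_total_paths}; use the dynamic programs instead"
            )


_DEFAULT_BUDGET = EnumerationBudget()


def enumerate_path_probabilities(
    hmm: HMM, y, budget: EnumerationBudget = _DEFAULT_BUDGET
) -> list[tuple[tuple[int, ...], float]]:
    """All m^n paths with their joint probabilities (zeros included)."""
    sym = y.symbols if hasattr(y, "symbols") else str(y)
    n, m = len(sym), hmm.m
    budget.check(m, n)
    out = []
    for tail in itertools.product(range(m), repeat=n):
        path = (hmm.start_state,) + tail
        out.append((path, joint_probability(hmm, sym, path)))
    return out


def enumerate_labelling_probabilities(
    hmm: HMM, y, budget: EnumerationBudget = _DEFAULT_BUDGET
) -> dict[tuple[str, ...], float]:
    """Map each labelling (λ_0..λ_n) to the summed probability of its paths."""
    sums: dict[tuple[str, ...], float] = {}
    for path, p in enumerate_path_probabilities(hmm, y, budget):
        lam = tuple(hmm.labels[s] for s in path)
        sums[lam] = sums.get(lam, 0.0) + p
    return sums


def brute_ball_probability(
    hmm: HMM, y, spec: BallSpec, budget: EnumerationBudget = _DEFAULT_BUDGET
) -> float:
    """Sum of labelling probabilities over enumerated ball members."""
    total = 0.0
    for lam, p in enumerate_labelling_probabilities(hmm, y, budget).items():
        if p > 0.0 and ball_contains(spec, lam):
            total += p
    return total


def _runs(states: tuple[int, ...]) -> list[tuple[int, int]]:
    """(state, run length) over emission positions 1..n."""
    out = []
    for s, grp in itertools.groupby(states[1:]):
        out.append((s, sum(1 for _ in grp)))
    return out


def brute_best_regular_ball(
    hmm: HMM, y, r: int, budget: EnumerationBudget = _DEFAULT_BUDGET
) -> tuple[StatePath | None, float]:
    """Exhaustive maximization over (2r+1)-regular centre paths.

    Each path is treated as its own labelling (every state its own label);
    a centre's ball probability is the sum of joint probabilities of paths
    with the same state footprint and every border within r.  Returns
    ``(None, 0.0)`` when no regular path exists.  Ties go to the first
    centre in lexicographic path order.
    """
    sym = y.symbols if hasattr(y, "symbols") else str(y)
    paths = enumerate_path_probabilities(hmm, sym, budget)
    annotated = []
    for path, p in paths:
        runs = _runs(path)
        fp = tuple(s for s, _ in runs)
        borders = []
        pos = 1
        for _, ln in runs[:-1]:
            pos += ln
            borders.append(pos)
        annotated.append((path, p, fp, tuple(borders), runs))
    best_path, best_prob = None, 0.0
    for path, _, fp, borders, runs in annotated:
        if any(ln < 2 * r + 1 for _, ln in runs):
            continue
        ball = 0.0
        for _, p2, fp2, borders2, _ in annotated:
            if p2 > 0.0 and fp2 == fp and all(
                abs(a - b) <= r for a, b in zip(borders, borders2)
            ):
                ball += p2
        if ball > best_prob:
            best_path, best_prob = path, ball
    if best_path is None:
        return None, 0.0
    return StatePath(best_path), best_prob
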