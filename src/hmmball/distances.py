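"""Labellings, footprints, borders, and distance measures between labellings.

A labelling λ = λ_0, λ_1, ..., λ_n assigns a feature label to each emission
position of a sequence (λ_0 is the label of the silent start state and is
excluded from all comparisons below).  Its *footprint* is the run-length
compression f_1, ..., f_k of λ_1..λ_n, and its *borders* b_1 < ... < b_{k-1}
are the first positions (1-based) carrying each new feature label.

Three distances between labellings of the same sequence:

* border shift       -- max_i |b_i(λ) - b_i(λ')|, infinite for unequal
                        footprints;
* border shift sum   -- sum_i |b_i(λ) - b_i(λ')|, infinite for unequal
                        footprints;
* generalized Hamming -- sum_{i=1..n} H[λ_i, λ'_i] for a non-negative
                        integer label-distance matrix H.

The ball B_d(λ, r) = {λ' : d(λ, λ') <= r} is the object whose probability
the rest of the package computes and optimizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Labelling",
    "LabelDistanceMatrix",
    "BallSpec",
    "footprint_of",
    "borders_of",
    "labelling_from_parts",
    "labelling_from_path",
    "border_shift_distance",
    "border_shift_sum_distance",
    "generalized_hamming_distance",
    "ball_contains",
]


@dataclass(frozen=True)
class Labelling:
    """Per-position labels λ_0..λ_n (position 0 = start state, silent)."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) < 2:
            raise ValueError("a labelling needs at least one emission position")

    @property
    def n(self) -> int:
        return len(self.labels) - 1

    @property
    def emitted(self) -> tuple[str, ...]:
        """Labels at emission positions 1..n."""
        return self.labels[1:]

    def footprint(self) -> tuple[str, ...]:
        return footprint_of(self)

    def borders(self) -> tuple[int, ...]:
        return borders_of(self)

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, i):
        return self.labels[i]


def _emitted(lam) -> tuple[str, ...]:
    if isinstance(lam, Labelling):
        return lam.emitted
    lam = tuple(lam)
    return lam[1:]


def footprint_of(lam) -> tuple[str, ...]:
    """Run-length-compressed labels of positions 1..n (λ_0 excluded)."""
    em = _emitted(lam)
    f = [em[0]]
    for z in em[1:]:
        if z != f[-1]:
            f.append(z)
    return tuple(f)


def borders_of(lam) -> tuple[int, ...]:
    """1-based positions of the first emission of each new feature.

    A labelling with k features has k-1 borders; b_i is the first position
    labelled f_{i+1}.
    """
    em = _emitted(lam)
    return tuple(i + 1 for i in range(1, len(em)) if em[i] != em[i - 1])


def labelling_from_parts(
    label0: str, footprint: Sequence[str], borders: Sequence[int], n: int
) -> Labelling:
    """Rebuild a labelling from (footprint, borders, n); inverse of the above."""
    footprint = tuple(footprint)
    borders = tuple(borders)
    if len(borders) != len(footprint) - 1:
        raise ValueError("need exactly k-1 borders for a k-feature footprint")
    ext = (1,) + borders + (n + 1,)
    if any(ext[i] >= ext[i + 1] for i in range(len(ext) - 1)):
        raise ValueError("borders must be strictly increasing within [2, n]")
    out = [label0]
    for g, f in enumerate(footprint):
        out.extend([f] * (ext[g + 1] - ext[g]))
    return Labelling(tuple(out))


def labelling_from_path(hmm, path) -> Labelling:
    """Map a state path through the model's label function."""
    states = tuple(path)
    return Labelling(tuple(hmm.labels[s] for s in states))


def _border_shifts(lam, lam2) -> list[int] | None:
    em1, em2 = _emitted(lam), _emitted(lam2)
    if len(em1) != len(em2):
        raise ValueError("labellings must cover sequences of equal length")
    if footprint_of(lam) != footprint_of(lam2):
        return None
    b1, b2 = borders_of(lam), borders_of(lam2)
    return [abs(a - b) for a, b in zip(b1, b2)]


def border_shift_distance(lam, lam2) -> float:
    """Maximum absolute border displacement; inf for unequal footprints."""
    shifts = _border_shifts(lam, lam2)
    if shifts is None:
        return math.inf
    return max(shifts, default=0)


def border_shift_sum_distance(lam, lam2) -> float:
    """Total absolute border displacement; inf for unequal footprints."""
    shifts = _border_shifts(lam, lam2)
    if shifts is None:
        return math.inf
    return sum(shifts)


@dataclass(frozen=True)
class LabelDistanceMatrix:
    """Non-negative integer distances between labels.

    ``matrix[i, j]`` is the penalty for predicting label ``labels[j]`` where
    the reference has ``labels[i]``.
    """

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        M = np.asarray(self.matrix)
        if not np.issubdtype(M.dtype, np.integer):
            Mr = np.rint(M)
            if not np.array_equal(Mr, M):
                raise ValueError("label distances must be integers")
            M = Mr.astype(int)
        if M.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match the label list")
        if np.any(M < 0):
            raise ValueError("label distances must be non-negative")
        object.__setattr__(self, "matrix", M)

    @classmethod
    def hamming(cls, labels: Iterable[str]) -> "LabelDistanceMatrix":
        """0 on the diagonal, 1 off it: plain Hamming distance."""
        labels = tuple(labels)
        M = np.ones((len(labels), len(labels)), dtype=int)
        np.fill_diagonal(M, 0)
        return cls(labels, M)

    @classmethod
    def zero(cls, labels: Iterable[str]) -> "LabelDistanceMatrix":
        labels = tuple(labels)
        return cls(labels, np.zeros((len(labels), len(labels)), dtype=int))

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in distance matrix") from None

    def distance(self, a: str, b: str) -> int:
        return int(self.matrix[self.index(a), self.index(b)])


def generalized_hamming_distance(lam, lam2, H: LabelDistanceMatrix) -> int:
    """Sum of H[λ_i, λ'_i] over emission positions 1..n."""
    em1, em2 = _emitted(lam), _emitted(lam2)
    if len(em1) != len(em2):
        raise ValueError("labellings must cover sequences of equal length")
    return sum(H.distance(a, b) for a, b in zip(em1, em2))


@dataclass(frozen=True)
class BallSpec:
    """A ball B_d(centre, radius) under one of the three metrics."""

    centre: Labelling
    radius: int
    metric: str = "border_shift"  # border_shift | border_shift_sum | generalized_hamming
    H: LabelDistanceMatrix | None = None

    _METRICS = ("border_shift", "border_shift_sum", "generalized_hamming")

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be non-negative")
        if self.metric not in self._METRICS:
            raise ValueError(f"metric must be one of {self._METRICS}")
        if self.metric == "generalized_hamming" and self.H is None:
            raise ValueError("generalized_hamming requires a label distance matrix H")

    def distance(self, lam2) -> float:
        if self.metric == "border_shift":
            return border_shift_distance(self.centre, lam2)
        if self.metric == "border_shift_sum":
            return border_shift_sum_distance(self.centre, lam2)
        return generalized_hamming_distance(self.centre, lam2, self.H)


def ball_contains(spec: BallSpec, lam2) -> bool:
    """Membership predicate λ' in B_d(centre, r)."""
    return spec.distance(lam2) <= spec.radius
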