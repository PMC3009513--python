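"""Seeded synthetic models and data.

Two generators: fully random labelled HMMs (for enumeration-scale property
checks) and a toy membrane-protein topology model.  The toy model mimics
the structure of alpha-helical transmembrane topology: cytoplasmic ("i")
and non-cytoplasmic ("o") loops alternate, separated by transmembrane
helices ("M") whose length is at least 15 residues with mean 21 — the
biological constraint that makes the number of plausible footprints small
and border placement the interesting question.  Emissions use a reduced
4-letter residue alphabet (H hydrophobic, P polar, R positively charged,
A everything else); helices are hydrophobic-rich, cytoplasmic loops are
enriched for positive residues (the positive-inside rule), non-cytoplasmic
loops are polar.

The toy model is a structural stand-in for a trained topology HMM such as
Phobius, not a reproduction of one: it has no signal-peptide track and its
parameters are chosen for plausibility, not fitted to proteins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distances import (
    Labelling,
    border_shift_distance,
    borders_of,
    footprint_of,
    labelling_from_path,
)
from .hmm_core import HMM, ObservationSequence, StatePath

__all__ = [
    "ToyTopologyModelSpec",
    "SimulatedDataset",
    "SimRecord",
    "random_hmm",
    "toy_topology_hmm",
    "simulate_dataset",
    "evaluate_prediction",
    "accuracy",
]

_LABEL_POOL = "ABCDEFGH"


def random_hmm(m: int, alphabet_size: int, num_labels: int, seed) -> HMM:
    """A random valid labelled HMM (Dirichlet rows), deterministic per seed.

    Labels are assigned cyclically then shuffled so that every one of the
    ``num_labels`` labels is carried by at least one state (requires
    ``m >= num_labels``).
    """
    if num_labels > m:
        raise ValueError("cannot use more labels than states")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A = rng.dirichlet(np.ones(m), size=m)
    E = rng.dirichlet(np.ones(alphabet_size), size=m)
    alphabet = tuple("abcdefghijklmnopqrstuvwxyz"[:alphabet_size])
    lab_assign = [_LABEL_POOL[i % num_labels] for i in range(m)]
    labels = tuple(np.array(lab_assign, dtype=object)[rng.permutation(m)])
    return HMM(
        transitions=A,
        emissions=E,
        alphabet=alphabet,
        start_state=0,
        labels=labels,
    )


@dataclass(frozen=True)
class ToyTopologyModelSpec:
    """Parameters of the toy transmembrane-topology model.

    ``min_membrane_run`` is enforced structurally with a chain of membrane
    states; the geometric tail on the last chain state sets the mean run
    length to ``mean_membrane_run``.  ``mean_loop_run`` controls the
    geometric loop lengths (residues; chosen as a plausible loop scale, not
    fitted to data).
    """

    min_membrane_run: int = 15
    mean_membrane_run: float = 21.0
    mean_loop_run: float = 25.0
    alphabet: tuple[str, ...] = ("H", "P", "R", "A")
    # emission rows per label: hydrophobic-rich helix, positive-inside
    # cytoplasm, polar outside
    membrane_emissions: tuple[float, ...] = (0.70, 0.10, 0.05, 0.15)
    cytoplasmic_emissions: tuple[float, ...] = (0.15, 0.30, 0.35, 0.20)
    noncytoplasmic_emissions: tuple[float, ...] = (0.15, 0.50, 0.10, 0.25)


def toy_topology_hmm(spec: ToyTopologyModelSpec | None = None) -> HMM:
    """Build the toy 3-label topology model (labels "i", "M", "o").

    States: a silent start (label "i", never revisited), one cytoplasmic
    and one non-cytoplasmic loop state, and two directed membrane tracks of
    ``min_membrane_run`` chained states each (inside->out and out->inside),
    so every sampled membrane run lasts at least the minimum and loops
    alternate sides.
    """
    spec = spec or ToyTopologyModelSpec()
    L = spec.min_membrane_run
    extra = spec.mean_membrane_run - L
    if extra < 0:
        raise ValueError("mean membrane run must be >= the minimum run")
    p_stay_m = extra / (extra + 1.0)  # geometric tail: mean extra residues
    p_stay_loop = 1.0 - 1.0 / spec.mean_loop_run

    names = ["start", "i", "o"]
    labels = ["i", "i", "o"]
    io_track = [f"Mio{t}" for t in range(1, L + 1)]  # i -> o
    oi_track = [f"Moi{t}" for t in range(1, L + 1)]  # o -> i
    names += io_track + oi_track
    labels += ["M"] * (2 * L)
    idx = {nm: i for i, nm in enumerate(names)}
    m = len(names)
    A = np.zeros((m, m))
    A[idx["start"], idx["i"]] = 0.5
    A[idx["start"], idx["o"]] = 0.5
    A[idx["i"], idx["i"]] = p_stay_loop
    A[idx["i"], idx["Mio1"]] = 1.0 - p_stay_loop
    A[idx["o"], idx["o"]] = p_stay_loop
    A[idx["o"], idx["Moi1"]] = 1.0 - p_stay_loop
    for t in range(1, L):
        A[idx[f"Mio{t}"], idx[f"Mio{t + 1}"]] = 1.0
        A[idx[f"Moi{t}"], idx[f"Moi{t + 1}"]] = 1.0
    A[idx[f"Mio{L}"], idx[f"Mio{L}"]] = p_stay_m
    A[idx[f"Mio{L}"], idx["o"]] = 1.0 - p_stay_m
    A[idx[f"Moi{L}"], idx[f"Moi{L}"]] = p_stay_m
    A[idx[f"Moi{L}"], idx["i"]] = 1.0 - p_stay_m

    e_by_label = {
        "M": np.array(spec.membrane_emissions),
        "i": np.array(spec.cytoplasmic_emissions),
        "o": np.array(spec.noncytoplasmic_emissions),
    }
    E = np.vstack([e_by_label[z] for z in labels])
    E[idx["start"]] = 1.0 / len(spec.alphabet)  # silent; row never used
    return HMM(
        transitions=A,
        emissions=E,
        alphabet=spec.alphabet,
        start_state=idx["start"],
        labels=tuple(labels),
        state_names=tuple(names),
    )


@dataclass(frozen=True)
class SimRecord:
    sequence: ObservationSequence
    labelling: Labelling
    path: StatePath


@dataclass(frozen=True)
class SimulatedDataset:
    records: tuple[SimRecord, ...]
    seed: int | None = None

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def simulate_dataset(hmm: HMM, n_seqs: int, length_range: tuple[int, int], seed) -> SimulatedDataset:
    """Sample (sequence, true labelling, true path) triples from the model.

    Lengths are drawn uniformly from the inclusive ``length_range``;
    regenerable bit-exactly from the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = length_range
    if not (1 <= lo <= hi):
        raise ValueError("length range must satisfy 1 <= lo <= hi")
    A, E = hmm.transitions, hmm.emissions
    m, S = hmm.m, len(hmm.alphabet)
    records = []
    for j in range(n_seqs):
        n = int(rng.integers(lo, hi + 1))
        states = [hmm.start_state]
        syms = []
        for _ in range(n):
            nxt = int(rng.choice(m, p=A[states[-1]]))
            states.append(nxt)
            syms.append(hmm.alphabet[int(rng.choice(S, p=E[nxt]))])
        path = StatePath(tuple(states))
        records.append(
            SimRecord(
                sequence=ObservationSequence("".join(syms), id=f"sim{j}"),
                labelling=labelling_from_path(hmm, path),
                path=path,
            )
        )
    return SimulatedDataset(tuple(records), seed=seed if isinstance(seed, int) else None)


def _segments(lam, label: str) -> list[tuple[int, int]]:
    """1-based inclusive (start, end) intervals of emissions carrying label."""
    f = footprint_of(lam)
    b = borders_of(lam)
    n = len(tuple(lam)) - 1
    ext = (1,) + b + (n + 1,)
    return [(ext[g], ext[g + 1] - 1) for g, z in enumerate(f) if z == label]


def evaluate_prediction(
    true_lam,
    pred_lam,
    measure: str = "tau",
    tau: int = 5,
    min_overlap: int = 5,
    segment_label: str = "M",
) -> bool:
    """Is a predicted labelling correct under a tolerance measure?

    ``measure="tau"``: correct iff the border shift distance to the truth
    is at most ``tau`` (implies equal footprints).  This is the stringent
    measure: every border must be individually close.

    ``measure="overlap"``: correct iff the footprints are equal and each
    predicted ``segment_label`` segment overlaps its true counterpart in at
    least ``min_overlap`` positions — the conventional topology-prediction
    criterion, which tolerates large border displacements as long as the
    segments still intersect.
    """
    if measure == "tau":
        return border_shift_distance(true_lam, pred_lam) <= tau
    if measure == "overlap":
        if footprint_of(true_lam) != footprint_of(pred_lam):
            return False
        seg_t = _segments(true_lam, segment_label)
        seg_p = _segments(pred_lam, segment_label)
        for (s1, e1), (s2, e2) in zip(seg_t, seg_p):
            overlap = min(e1, e2) - max(s1, s2) + 1
            if overlap < min_overlap:
                return False
        return True
    raise ValueError("measure must be 'tau' or 'overlap'")


def accuracy(truths, preds, measure: str = "tau", **kw) -> float:
    """Fraction of predictions counted correct under the chosen measure."""
    truths, preds = list(truths), list(preds)
    if len(truths) != len(preds):
        raise ValueError("need one prediction per truth")
    if not truths:
        raise ValueError("empty dataset")
    hits = sum(evaluate_prediction(t, p, measure=measure, **kw) for t, p in zip(truths, preds))
    return hits / len(truths)
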