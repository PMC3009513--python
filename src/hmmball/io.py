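"""Readers and writers for model and labelling files.

Formats:

* HMM JSON: ``{"alphabet": [...], "states": [{"id", "label", "emissions":
  {symbol: prob}}, ...], "start_state": id, "transitions": [{"from", "to",
  "p"}, ...]}``.  Unlisted transitions/emissions are zero.
* Sequences: FASTA (via Biopython); every record is decoded independently.
* Labellings: either one ``seq_id<TAB>label-string`` line per sequence
  (single characters per position, optionally expanded through a
  ``# char_map:`` header), or an interval table with 1-based inclusive
  ``seq_id, start, end, label`` rows.
* Label distance matrices: TSV with a label header row.

All TSVs are tab-delimited; lines starting with ``#`` are headers/comments.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .distances import LabelDistanceMatrix, Labelling
from .hmm_core import HMM, ObservationSequence

__all__ = [
    "read_hmm_json",
    "write_hmm_json",
    "read_fasta",
    "write_fasta",
    "read_labelling_strings",
    "write_labelling_strings",
    "read_intervals",
    "write_intervals",
    "intervals_to_labels",
    "labels_to_intervals",
    "read_label_matrix",
    "write_label_matrix",
    "attach_start",
]


def read_hmm_json(path) -> HMM:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        alphabet = tuple(doc["alphabet"])
        states = doc["states"]
        start_id = doc["start_state"]
        transitions = doc["transitions"]
    except KeyError as e:
        raise ValueError(f"HMM JSON is missing required key {e.args[0]!r}") from None
    names = [s["id"] for s in states]
    if len(set(names)) != len(names):
        raise ValueError("duplicate state ids in HMM JSON")
    idx = {nm: i for i, nm in enumerate(names)}
    m, S = len(names), len(alphabet)
    sym_idx = {s: i for i, s in enumerate(alphabet)}
    E = np.zeros((m, S))
    for s in states:
        for sym, p in s.get("emissions", {}).items():
            if sym not in sym_idx:
                raise ValueError(f"state {s['id']!r}: emission symbol {sym!r} not in alphabet")
            E[idx[s["id"]], sym_idx[sym]] = p
    A = np.zeros((m, m))
    for t in transitions:
        for key in ("from", "to"):
            if t[key] not in idx:
                raise ValueError(f"transition references unknown state {t[key]!r}")
        A[idx[t["from"]], idx[t["to"]]] = t["p"]
    if start_id not in idx:
        raise ValueError(f"start_state {start_id!r} is not a listed state")
    return HMM(
        transitions=A,
        emissions=E,
        alphabet=alphabet,
        start_state=idx[start_id],
        labels=tuple(s["label"] for s in states),
        state_names=tuple(names),
    )


def write_hmm_json(hmm: HMM, path) -> None:
    names = hmm.state_names or tuple(str(i) for i in range(hmm.m))
    doc = {
        "alphabet": list(hmm.alphabet),
        "states": [
            {
                "id": names[i],
                "label": hmm.labels[i],
                "emissions": {
                    sym: float(hmm.emissions[i, j])
                    for j, sym in enumerate(hmm.alphabet)
                    if hmm.emissions[i, j] != 0.0
                },
            }
            for i in range(hmm.m)
        ],
        "start_state": names[hmm.start_state],
        "transitions": [
            {"from": names[i], "to": names[j], "p": float(hmm.transitions[i, j])}
            for i in range(hmm.m)
            for j in range(hmm.m)
            if hmm.transitions[i, j] != 0.0
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_fasta(path) -> list[ObservationSequence]:
    return [ObservationSequence(str(rec.seq), id=rec.id) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: Iterable[ObservationSequence], path) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(seqs):
            fh.write(f">{s.id or f'seq{i}'}\n")
            for j in range(0, len(s.symbols), 60):
                fh.write(s.symbols[j : j + 60] + "\n")


# -- labelling strings --------------------------------------------------------


def read_labelling_strings(path) -> dict[str, tuple[str, ...]]:
    """Per-sequence label tuples (positions 1..n) from a label-string TSV."""
    char_map: dict[str, str] = {}
    out: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if body.startswith("char_map:"):
                    for pair in body[len("char_map:") :].strip().split(","):
                        c, _, name = pair.strip().partition("=")
                        char_map[c] = name
                continue
            sid, _, s = line.partition("\t")
            if not s:
                raise ValueError(f"malformed labelling line: {line!r}")
            out[sid] = tuple(char_map.get(c, c) for c in s)
    return out


def write_labelling_strings(items: Mapping[str, Sequence[str]], path) -> None:
    labels = sorted({z for v in items.values() for z in v})
    if all(len(z) == 1 for z in labels):
        char_of = {z: z for z in labels}
        header = None
    else:
        pool = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
        if len(labels) > len(pool):
            raise ValueError("too many distinct labels for the string format")
        char_of = {z: pool[i] for i, z in enumerate(labels)}
        header = "# char_map: " + ",".join(f"{c}={z}" for z, c in char_of.items())
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        for sid, v in items.items():
            fh.write(sid + "\t" + "".join(char_of[z] for z in v) + "\n")


# -- interval tables ----------------------------------------------------------


def read_intervals(path) -> dict[str, list[tuple[int, int, str]]]:
    out: dict[str, list[tuple[int, int, str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"interval rows need 4 columns, got: {line!r}")
            sid, start, end, label = parts
            out.setdefault(sid, []).append((int(start), int(end), label))
    return out


def write_intervals(items: Mapping[str, Sequence[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("#seq_id\tstart\tend\tlabel\n")
        for sid, v in items.items():
            for start, end, label in labels_to_intervals(v):
                fh.write(f"{sid}\t{start}\t{end}\t{label}\n")


def intervals_to_labels(intervals: Sequence[tuple[int, int, str]], n: int) -> tuple[str, ...]:
    """Expand 1-based inclusive intervals to per-position labels 1..n."""
    ivs = sorted(intervals)
    out: list[str] = []
    pos = 1
    for start, end, label in ivs:
        if start != pos or end < start:
            raise ValueError(f"intervals must tile 1..{n} contiguously (gap at {pos})")
        out.extend([label] * (end - start + 1))
        pos = end + 1
    if pos != n + 1:
        raise ValueError(f"intervals cover 1..{pos - 1}, expected 1..{n}")
    return tuple(out)


def labels_to_intervals(labels: Sequence[str]) -> list[tuple[int, int, str]]:
    out = []
    start = 1
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[i - 1]:
            out.append((start, i, labels[i - 1]))
            start = i + 1
    return out


# -- label distance matrices --------------------------------------------------


def read_label_matrix(path) -> LabelDistanceMatrix:
    rows = []
    header = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.lstrip("#").split("\t")
            if header is None:
                header = [p for p in parts if p]
                continue
            rows.append(parts)
    if header is None or not rows:
        raise ValueError("label matrix file needs a header row and one row per label")
    labels = tuple(header)
    M = np.zeros((len(labels), len(labels)), dtype=int)
    for parts in rows:
        z = parts[0]
        if z not in labels:
            raise ValueError(f"matrix row label {z!r} not in header")
        M[labels.index(z)] = [int(x) for x in parts[1:]]
    return LabelDistanceMatrix(labels, M)


def write_label_matrix(H: LabelDistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("#\t" + "\t".join(H.labels) + "\n")
        for i, z in enumerate(H.labels):
            fh.write(z + "\t" + "\t".join(str(int(x)) for x in H.matrix[i]) + "\n")


def attach_start(hmm: HMM, per_position_labels: Sequence[str]) -> Labelling:
    """Prefix the model's start-state label to per-position labels 1..n."""
    return Labelling((hmm.start_label,) + tuple(per_position_labels))
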