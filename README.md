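# hmmball — robust decoding of labelled HMMs with balls of labellings

Hidden Markov models annotate biological sequences by assigning a feature
label (for a membrane protein: cytoplasmic loop `i`, transmembrane helix
`M`, non-cytoplasmic loop `o`) to every position. The classical decoders
are brittle about *boundaries*: the Viterbi path optimizes a single path
that may carry a tiny fraction of the probability mass, and posterior
decoding ignores segment structure altogether. `hmmball` instead works
with **balls of labellings**: sets of annotations that agree on the
overall segment structure (the *footprint*) and place each segment
boundary within a tolerance `r` of a reference.

For a labelled HMM `M = (A, E, Σ, x0)` with label function `ℓ`, a sequence
`y`, and a distance `d` between labellings, the ball around a centre `λ`
is `B_d(λ, r) = {λ' : d(λ, λ') ≤ r}` and its conditional probability is

    Pr[B_d(λ, r) | y, M] = Σ_{λ' ∈ B_d(λ, r)} Pr[λ' | y, M].

The decoding objective is the centre `λ*` maximizing this mass: the
annotation most likely to be *nearly* right. Supported distances:

* **border shift** — `max_i |b_i(λ) - b_i(λ')|` over corresponding
  borders, infinite for unequal footprints;
* **border shift sum** — the L1 counterpart `Σ_i |b_i(λ) - b_i(λ')|`;
* **generalized Hamming** — `Σ_i H[λ_i, λ'_i]` for a non-negative integer
  label-distance matrix `H`.

All ball probabilities are computed exactly by constrained forward passes
on a grouped model (one group of states per footprint entry, with
per-position activity windows; budgeted variants for the shift-sum and
Hamming balls). Finding the best centre is NP-hard, so the package
provides

* `local_search` / `decode_with_restarts` — steepest-ascent refinement of
  border positions, with cached forward/backward tables so each neighbour
  costs only `O(r)` columns, started from samples of `Pr[path | y]`; and
* `regular_ball_dp` — an exact `O(nm²)` dynamic program for balls of
  *state paths* whose centre keeps every state for at least `2r+1`
  positions (at `r = 0` it reduces to Viterbi).

## Worked example

A toy three-label membrane-topology model ships with the package
(helices ≥ 15 residues, mean 21, loops alternating sides, 4-letter
reduced residue alphabet):

```python
import math
from hmmball import (toy_topology_hmm, simulate_dataset, decode_with_restarts,
                     viterbi, labelling_from_path, forward, ball_prob_border_shift)
from hmmball.distances import border_shift_distance

hmm = toy_topology_hmm()
rec = simulate_dataset(hmm, 1, (110, 110), seed=8).records[0]

lam, _ = decode_with_restarts(hmm, rec.sequence, r=5, n_starts=10, seed=0)
vit = labelling_from_path(hmm, viterbi(hmm, rec.sequence)[0])

print("true borders   ", rec.labelling.borders())
print("ball decoder   ", lam.borders())
print("Viterbi        ", vit.borders())
lp = ball_prob_border_shift(hmm, rec.sequence, lam, 5, log=True)
print("conditional ball mass %.3f"
      % math.exp(lp - forward(hmm, rec.sequence).log_probability))
print("max border shift: ball", border_shift_distance(rec.labelling, lam),
      "| Viterbi", border_shift_distance(rec.labelling, vit))
```

prints

```
true borders    (22, 53, 75, 100, 105)
ball decoder    (21, 55, 75, 102, 105)
Viterbi         (22, 53, 75)
conditional ball mass 0.395
max border shift: ball 2 | Viterbi inf
```

On this sequence the Viterbi path misses the final short helix entirely
(wrong footprint, hence distance ∞), while the ball decoder recovers the
correct five-segment topology with every border within 2 positions; about
40% of the model's conditional probability mass lies within border shift 5
of its answer.

The same operations are scriptable: `hmmball simulate`, `hmmball decode`,
`hmmball prob`, `hmmball eval`, `hmmball oracle` (see `hmmball --help`).

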