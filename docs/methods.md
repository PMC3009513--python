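# Methods

## Model and conventions

A labelled HMM is `(A, E, Σ, x0)` with a label function `ℓ` on states.
The start state `x0` is silent: a path `x_0..x_n` emits `y_1..y_n` in
states `x_1..x_n`, and `Pr[x, y] = Π_i a_{x_{i-1} x_i} e_{x_i y_i}`.
Positions are 1-based; interval I/O is 1-based inclusive. Transition and
emission rows must be stochastic to 1e-9 (an all-zero transition row is
tolerated for a designated dead state).

The labelling of a path is `λ_i = ℓ(x_i)`. Because `x_0` emits nothing
and its label is a model artifact, **position 0 is excluded** from
footprints, borders and all distances; `labelling_probability` still
requires `λ_0` to equal the start state's label (otherwise no path
matches and the probability is 0), while ball probabilities ignore `λ_0`
(the member set does not depend on it).

Border `b_i` is the first position labelled `f_{i+1}`, so a k-feature
labelling has k−1 borders in `[2, n]`. The border-shift distance is the
maximum absolute border displacement (∞ for unequal footprints); the
shift-sum distance is its L1 counterpart — the natural choice that makes
`sum ≥ max` and therefore nests the two balls. The generalized Hamming
distance sums integer label penalties `H[λ_i, λ'_i]` over positions 1..n.

## Constrained forward passes

All labelling/footprint/ball probabilities run one engine: a grouped
model with one group `G_i` per footprint entry (the states labelled
`f_i`), transitions restricted to `G_i → {G_i, G_{i+1}}`, and a
per-position activity window for each group. The window choices are:

* exact windows (`G_i` on `b_{i-1}..b_i − 1`) — probability of the
  labelling itself;
* unbounded windows — probability of the footprint (a path must start in
  `G_1` and finish in `G_k`, forcing all k−1 label changes);
* windows widened by r (`G_i` on `b_{i-1} − r .. b_i + r − 1`, clamped
  to `[1, n]` with the conventions `b_0 = 1`, `b_k = n+1`) — the
  border-shift ball. The layered structure makes skipping a group
  impossible, so footprint preservation needs no special-casing even
  when short features make windows overlap; the "dump" state for
  footprint-violating mass is not materialized, the mass is simply not
  collected.

Because r = 0 windows *are* the exact windows, the identity
`ball(λ, 0) = labelling probability` holds to machine precision, and
`r ≥ n` reproduces the footprint probability identically.

The shift-sum ball adds a budget coordinate `d ∈ 0..r`: placing border i
at position p charges `|p − b_i|` at the moment of the group transition;
transitions that would exceed r are absent. The generalized Hamming ball
runs on the product automaton of (state, accumulated distance), charging
`H[reference label at the position, label of the destination state]` at
every emission; `λ_0` is exempt.

Columns are rescaled to sum 1 at every position with the log normalizer
accumulated, so results are exact in log space for arbitrarily long
sequences; every probability-returning function takes `log=True`. A
constrained event of probability zero yields 0.0 (log −inf), not an
error.

## Local search

Steepest ascent over the 2(k−1) single-border ±1 moves of the
border-shift ball; a move is skipped if it would empty a feature or push
a border outside `[2, n]`. Ties prefer the smallest border index and
leftward over rightward, for determinism. A move is accepted only if it
improves the ball probability by more than a relative 1e-12; iteration
stops at convergence or after `max_iters` accepted moves (default 80).

Moving border j from b to b′ changes the group windows only at positions
`min(b,b′) − r` and `max(b,b′) + r − 1`, so a neighbour's probability is
computed by restarting the forward sweep from the cached scaled column at
`min(b,b′) − r − 1` and closing it with the cached backward column at
`max(b,b′) + r`, i.e. O(r) columns per neighbour instead of O(n). The
cache-free path (`use_cache=False`) exists for auditing and the test
suite verifies the two agree at every neighbour of every accepted step.

`decode_with_restarts` draws start labellings from `Pr[path | y]` by
forward filtering / backward sampling and keeps the best converged
centre. Sampling is the preferred initializer because a draw is likely
to land inside a high-mass ball, leaving only border refinement to the
search; all randomness flows through one seeded generator.

## Exact DP for regular path balls

For balls of state paths (each state its own label) whose centre is
(2r+1)-regular — every maximal state run at least 2r+1 positions —
`F[j, s]` stores the probability of the best *weakly* regular ball up to
position j ending in state s (final run only ≥ r+1; this pins every
member path to state s at position j, which is what makes the recursion
well-defined). `F[j, s]` either extends the final run
(`F[j−1, s]·a_ss·e_s(y_j)`) or places a border at `j − r`:

    F[j, s] = max(F[j−1, s]·a_ss·e_s(y_j),
                  max_{s' ≠ s} F[j−2r−1, s']·Q(s, s', j))   for j ≥ 3r+2,

where `Q(s, s', j)` sums, over member border placements
`b' ∈ [j−2r, j]`, the probability of emitting `y_{j−2r}..y_j` in s' then
s with the single forced s'→s transition at b', conditioned on being in
s' at position j−2r−1. The `j ≥ 3r+2` guard ensures the completed s' run
reaches length 2r+1. Q is evaluated for all state pairs at once with
exclusive prefix/suffix products over the 2r+1-wide window (O(m²r) per
position here; an amortized O(1) update per pair is possible but
unnecessary at these problem sizes — the DP is already Viterbi-like in
practice). Values at `j = n − r` are closed by multiplying the
self-transition and emission factors through position n, enforcing
strong regularity; single-run centres are covered by the base case grown
through the extension term. At r = 0 the recursion is exactly Viterbi.
The off-by-one conventions of the window were fixed by requiring
agreement with exhaustive search at r = 1 on instances small enough to
enumerate; the suite keeps that check, plus an independent
paths-as-labels recomputation of the returned centre's ball probability.

## Synthetic data

`random_hmm` draws Dirichlet(1) transition/emission rows with labels
assigned cyclically then shuffled — dense, unstructured models that are
the hard case for the grouped constructions, used at enumeration scale
(m ≤ 4, |Σ| = 2, n ≤ 9) so every quantity can be checked against
exhaustive path enumeration.

`toy_topology_hmm` emulates the structure of transmembrane-topology
models: labels `i`/`M`/`o`; two directed chains of 15 membrane states
enforce the 15-residue minimum helix length structurally, with a
geometric tail tuned so the mean helix length is 21; loops alternate
sides with geometric lengths of mean 25 residues (a plausible loop
scale, chosen once); emissions use a reduced 4-letter alphabet
(hydrophobic-rich helices, positive-inside cytoplasmic loops, polar
outside). What it does **not** model: real amino-acid composition,
signal peptides, trained parameters, or length distributions of real
proteins — so passing results demonstrate correctness of the algorithms
and the qualitative behaviour of the decoders (boundary placement under
a well-specified model), not performance on real proteins.

Two correctness measures for predictions: `tau` (correct iff border
shift distance to the truth ≤ τ, default 5 — stringent, every border
individually close) and `overlap` (correct iff footprints match and each
predicted membrane segment overlaps the true one in ≥ 5 positions — the
conventional, laxer topology criterion, applied to membrane segments
only).

## Problem sizes and numerical choices

The verification scales were chosen so exhaustive enumeration remains
the independent oracle: 50 random models for conservation and ball
agreement (r ∈ {0,1,2}, all three metrics, tolerance 1e-9 relative),
limit identities at 1e-12 relative, 10 instances for the regular-ball DP
(r = 1 vs brute force, r = 0 vs Viterbi), 50,000 draws for sampling
calibration (3 standard errors per path), and 100 simulated topology
sequences of 70–130 residues (10 sampled starts, r = 5) for the
decoder comparison. Argmax ties everywhere break to the lowest state
index; accepted local-search moves must improve by a relative 1e-12.

## Limitations

Ball optimization over labellings is NP-hard, so `decode_with_restarts`
is a heuristic: it fixes the footprint of each start and only moves
borders, relying on sampling to propose footprints. The exact DP applies
to balls of paths, not labellings, and requires long state runs
(n ≥ 2r+1). The shift-sum ball costs a factor r over the max-shift ball
and useful radii tend to be larger for it, as the L1 distance grows with
the number of borders. Training, generalized/semi-Markov emissions and
continuous alphabets are out of scope.
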