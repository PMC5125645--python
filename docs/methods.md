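# Methods

## The prediction problem

Soft-constrained RNA folding adds a per-nucleotide pseudo-free energy derived
from SHAPE probing reactivities to the nearest-neighbor thermodynamic score,
and this markedly improves secondary-structure prediction — but it requires a
probing experiment for every sequence. This package removes that requirement
by *simulating* the reactivities: given any candidate structure, each
position's structural context (unpaired, stacked, or helix-end) determines a
reactivity distribution to draw from, so a plausible SHAPE profile can be
generated for the candidate itself. An evolutionary algorithm then searches
structure space scoring each candidate by

    fitness(ω) = E(δ, ω) + PE(δ, ω)

where `E` is the thermodynamic free energy of structure ω on sequence δ and
`PE` is the pseudo-free energy computed from the candidate's own simulated
profile. The chicken-and-egg problem (simulation needs a structure; we are
predicting the structure) is resolved by maintaining a *population* of
candidates rather than a single guess.

## Pipeline

1. **Pair probabilities.** A partition-function engine produces the
   equilibrium base-pair probability matrix `P = [p_ij]` (upper-triangular,
   1-based). Entries below a floor `eps` (default 0.05, i.e. one-decimal
   rounding to zero) are stored as exact zeros; stem enumeration tests cells
   against zero exactly, and partition-function engines otherwise emit tiny
   positive values everywhere. The floor is applied once, when the matrix is
   built.

2. **Potential stems.** A potential stem is a maximal anti-diagonal run of
   nonzero cells `(r+k, c-k)`, `k = 0..l-1`, whose diagonally preceding and
   following cells are zero or off-matrix. Each nonzero cell lies on exactly
   one maximal run, so one scan per anti-diagonal enumerates the full set in
   O(n²). Stems shorter than 3 pairs are dropped from the catalog (they are
   the least stable and would otherwise dominate sampling); fragments shorter
   than 3 may still *arise later* from trimming, which is deliberate — the
   cutoff governs the catalog only.

3. **Initial population.** `m` structures (default `m = n`, the sequence
   length) are each assembled from `k` stems (default `k = max(1, n//5)`)
   drawn from a roulette wheel weighted by the stem's summed probability
   `p_s`. A drawn stem is trimmed against the partial structure: pairs that
   reuse an occupied nucleotide are removed, as are pairs that would cross an
   existing pair — without the crossing rule the assembled pair set would not
   be a valid pseudoknot-free structure. A draw counts toward `k` only if it
   contributes at least one pair; a capped number of draws (`50k`) guarantees
   termination, returning the partial structure when `k` mutually compatible
   contributions simply do not exist (routine on short sequences, logged at
   INFO level).

4. **Fitness.** For each new structure a reactivity profile is simulated
   (or a fixed experimental profile substituted), converted per site by
   `dG_i = m·ln(SR(i)+1) + b` with defaults `m = 2.6`, `b = -0.8` kcal/mol,
   and aggregated as `PE = 2·Σ_stacked dG_i + Σ_helix-end dG_i`; unpaired and
   missing positions contribute nothing. A structure's profile and fitness
   are computed once, at creation, and cached for its lifetime. This caching
   is load-bearing: the stopping rule compares best fitness across
   generations for equality, which would almost surely never hold if
   surviving structures were re-simulated every generation.

5. **Evolution.** Every member is mutated once per generation: one helix
   (maximal run of consecutive pairs) chosen uniformly at random is deleted
   and a roulette-drawn catalog stem, trimmed against the remainder, is
   inserted. Attempts repeat until the mutant is at least as fit as the
   parent or an attempt cap (20) is reached, in which case the last candidate
   is passed on regardless — elitist selection will discard it if poor. The
   next generation is the `m` lowest-fitness records among parents and
   mutants (ties: parents first, then insertion order, so trajectories are
   deterministic under a fixed seed). The loop stops when the best fitness is
   unchanged between two consecutive generations, within 1e-6 kcal/mol, or at
   a cap of 100 generations.

   The improve-or-give-up direction of the mutation retry deserves a note:
   read literally, an acceptance test of the form "repeat until the mutant is
   *no better*" would stop at the first non-improving candidate, which is the
   opposite of improving the structure. We therefore loop until an
   *improving* candidate is found (with the cap as a guard). Elitist survivor
   selection makes the algorithm robust to either reading — a bad mutant
   never displaces a good parent.

## Structural classes and the helix-end convention

Positions are classified from the decomposition of the pair set into maximal
runs of consecutive pairs. Both nucleotides of a run's first and last pair
are `HELIX_END`; nucleotides of interior pairs are `STACKED`; everything else
is `UNPAIRED`. Consequences worth stating: a 1-pair run yields two helix-end
positions and no stacked ones; a 2-pair run yields four helix-end positions
(both its pairs are terminal). The convention is isolated in
`rna_model.classify_positions` so it can be swapped wholesale.

## Engines

`ViennaEngine` adapts the ViennaRNA Python bindings: McCaskill pair
probabilities with backend defaults (37 °C, default dangles), and
`eval_structure` for the free energy of the *given* structure (not the MFE
structure). The backend version is recorded in every run report.

`BuiltinEngine` is a deterministic, deliberately minimal model used where the
thermodynamic backend is unnecessary (fixture-driven tests, fully
reproducible runs): canonical pairs {AU, UA, GC, CG, GU, UG}, minimum hairpin
of 3 unpaired bases, one stacking constant (−2.0 kcal/mol per stacked pair)
and one hairpin penalty (+3.0 kcal/mol per hairpin-closing pair); all other
loops are free. Its pair probabilities come from an exact inside–outside
recursion over this same energy function, so they are the true equilibrium
probabilities *of the simplified model* — verified in the test suite against
brute-force enumeration of every structure at small n. It is labelled
non-thermodynamic and should not be used for biological conclusions.

`FileEngine` serves a precomputed matrix from a TSV file (engine-free runs);
energy evaluation is delegated to the built-in model.

## Reactivity distributions

The literature fits separate distributions per structural class on large
ribosomal-RNA probing datasets but the parameters are not standardised. The
packaged defaults (`data/shape_distributions.yaml`) encode the qualitative
consensus: a heavy-right-tailed generalized extreme value distribution for
unpaired positions (genextreme shape −0.25, loc 0.55, scale 0.45; mean ≈ 1)
and low-mean exponentials for stacked (scale 0.07) and helix-end (scale 0.25)
positions. These are the package's own choice of realistic values, versioned
in the YAML rather than hard-coded, and `shape_sim.fit_distribution_set`
re-derives all three by maximum likelihood from any user-supplied
(structure, reactivity) training pair. Sampled values are truncated at zero,
reactivities being nonnegative by definition. The test suite always
configures its own distributions explicitly.

What the simulator does *not* model: probing noise and replicate variance,
sequence-dependent reactivity biases, missing-data patterns of real
experiments. Tests passing under the simulator therefore demonstrate the
machinery (classification, sampling, energy bookkeeping, search), not
accuracy on real probing data.

## Scoring

Predictions are scored against references at base-pair level with exact pair
identity (no ±1 slip): `Sn = TP/(TP+FN)`, `PPV = TP/(TP+FP)`,
`Accuracy = (Sn+PPV)/2`. When a denominator is zero the metric is 1 only in
the doubly-empty case and 0 otherwise. Benchmarks apply the same formulas to
replicate-mean counts, which may be fractional. PPV over an empty pair subset
(in the MFE-overlap analysis) is reported as 0 with an explicit empty flag.
Pseudoknotted reference files are accepted with a configurable policy,
default: drop the crossing pairs with a logged warning, since the predictor
is pseudoknot-free by construction.

## Numerical and degenerate-input choices

- Stopping tolerance 1e-6 kcal/mol (exact float equality is fragile).
- Survivor-selection ties: parents before mutants, then insertion order.
- A mutation call on a structure with no pairs returns it unchanged with a
  warning.
- An empty stem catalog raises an error that names the two knobs to relax
  (probability floor, minimum stem length).
- Matrix files round-trip at full float precision (`repr`), `.shape` files
  use −999 as the missing sentinel, negative experimental reactivities are
  clamped to zero with a warning.
- All randomness flows through one `numpy` Generator per run; replicate
  benchmarks spawn child seeds from a master seed via `SeedSequence`.

## Problem sizes

The shipped tests and the acceptance script run the full pipeline on short
sequences (n = 14–30), fixture matrices with planted ground truth, and
replicate counts of 10–50; these sizes exercise every code path while keeping
the default suite fast. The method itself has no size-specific constants
beyond `k = n/5` and `m = n`, and degrades on very long sequences for the
reasons inherent to its sampling scheme: the pool of short stems grows much
faster than the pool of long ones, so trimming fragments long stems and
accuracy drops — a known limitation, not addressed here.

## Known limitations

- No pseudoknots, by construction, and no crossover operator (mutation +
  elitism only).
- The built-in engine is not a thermodynamic model; quantitative energies
  are meaningful only relative to themselves.
- Default reactivity distributions are plausible but not fitted to a
  published probing compendium; re-fit before drawing biological conclusions.
- Search is stochastic; different seeds can return different structures of
  equal or near-equal fitness.
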