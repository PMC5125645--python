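# esdfold

Evolutionary RNA secondary-structure prediction guided by **simulated SHAPE
data**.

SHAPE probing (selective 2′-hydroxyl acylation analyzed by primer extension)
measures a per-nucleotide reactivity that tracks structural flexibility;
converted to a pseudo-free energy and added to the thermodynamic score, it
substantially improves secondary-structure prediction — at the cost of one
wet-lab experiment per sequence. `esdfold` removes that cost: reactivities
are *simulated* from each candidate structure using class-conditional
distributions (unpaired / stacked / helix-end nucleotides react differently),
and an evolutionary algorithm searches for the structure ω of sequence δ
minimising

    fitness(ω) = E(δ, ω) + PE(δ, ω)

where `E` is the nearest-neighbor free energy and

    PE(δ, ω) = 2·Σ_{i ∈ stacked} ΔG_i + Σ_{i ∈ helix-end} ΔG_i,
    ΔG_i = m·ln(SR(i) + 1) + b        (m = 2.6, b = −0.8 kcal/mol)

with `SR(i)` the reactivity at position i. Candidate structures are built
from **potential stems** — maximal anti-diagonal runs of nonzero cells in the
base-pair probability matrix — sampled by a roulette wheel weighted by each
stem's summed probability. Each generation, every structure has one helix
replaced by a freshly drawn stem; the best `m` of parents and mutants survive
(elitist selection), and the search stops when the best fitness is unchanged
across two consecutive generations.

The package is aimed at RNA bioinformaticians who want soft-constrained
folding without probing data, and at method developers who need the
individual pieces (stem enumeration, reactivity simulation, pseudo-energy
scoring, base-pair accuracy metrics) as a library.

## Worked example

The 14-nt sequence `GUGCACGACGCCGU` has five maximal potential stems in its
probability matrix at the one-decimal floor of 0.05:

```bash
python examples/02_stem_enumeration.py
```

```
5 maximal potential stems at probability floor 0.05:
  start (1,9)  length 2 bp  weight p_s = 0.155
  start (1,11)  length 3 bp  weight p_s = 0.454
  start (1,12)  length 1 bp  weight p_s = 0.242
  start (3,11)  length 2 bp  weight p_s = 0.737
  start (5,14)  length 3 bp  weight p_s = 0.723
```

Each stem is a candidate helix `(r,c), (r+1,c−1), …`; its weight is the
probability mass it covers, which sets its share of the roulette wheel. Only
stems of length ≥ 3 enter the assembly catalog.

Predicting the structure:

```bash
python examples/01_predict_structure.py
```

```
sequence   GUGCACGACGCCGU
structure  ....(((....)))
fitness    -6.334 kcal/mol = E -0.300 + PE -6.034
converged after 5 generations
```

The winner pairs the 3-bp stem starting at (5,14); the fitness splits into
the thermodynamic term `E` and the pseudo-energy term `PE` earned by its
paired nucleotides' low simulated reactivities.

Or from the shell, with all outputs written to files:

```bash
esd-fold predict --fasta seq.fasta --engine external --seed 42 --out run/pred
# run/pred.dbn   best structure (dot-bracket)
# run/pred.shape simulated reactivity profile of the best structure
# run/pred.json  fitness decomposition, generations, engine version, seed
```

`esd-fold score` compares a prediction with a reference (CT, BPSEQ or
dot-bracket) and reports TP/FP/FN, sensitivity `Sn = TP/(TP+FN)`, positive
predictive value `PPV = TP/(TP+FP)` and `Accuracy = (Sn+PPV)/2`;
`esd-fold benchmark` repeats predictions over a manifest with seeds spawned
from a master seed and tabulates replicate means ± sd. (Some published
benchmark tables print Sn and PPV in the transposed order relative to these
definitions; `esdfold` reports the formulas exactly as defined above —
Accuracy is unaffected either way.)

## Layout

- `src/esdfold/rna_model.py` — sequences, structures, formats (FASTA, CT,
  BPSEQ, dot-bracket), structural classification
- `src/esdfold/pairing_engine.py` — probability matrices, ViennaRNA adapter,
  built-in Boltzmann/Nussinov fallback, matrix TSV I/O
- `src/esdfold/stem_catalog.py` — maximal-stem enumeration, roulette wheel
- `src/esdfold/assembly.py` — overlap/crossing trimming, population assembly
- `src/esdfold/shape_sim.py` — reactivity distributions, simulation,
  pseudo-energies, `.shape` I/O, ML re-fitting
- `src/esdfold/evolution.py` — fitness, mutation, elitist selection, stopping
- `src/esdfold/evaluation.py` — accuracy metrics, replicate benchmarks,
  MFE-overlap analysis
- `src/esdfold/fixtures.py` — synthetic matrices with planted ground truth
- `docs/methods.md` — model, parameters, conventions and limitations
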