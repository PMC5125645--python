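"""Predict the secondary structure of a short RNA with simulated SHAPE data.

Builds the base-pair probability matrix with ViennaRNA, enumerates potential
stems, evolves a population of candidate structures and prints the winner.
"""

from esdfold import EvolutionConfig, RnaSequence, run

seq = RnaSequence("example", "GUGCACGACGCCGU")
result = run(seq, engine="external", config=EvolutionConfig(seed=42))

print(f"sequence   {seq.residues}")
print(f"structure  {result.best.structure.to_dotbracket()}")
print(
    f"fitness    {result.best.fitness.total:.3f} kcal/mol "
    f"= E {result.best.fitness.energy:.3f} + PE {result.best.fitness.pseudo:.3f}"
)
print(f"converged after {result.generations} generations")
# The fitness is the sum of the thermodynamic free energy E of the structure
# and the SHAPE pseudo-free energy PE computed from reactivities simulated
# from the structure itself; lower is better.
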