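"""Enumerate the maximal potential stems of a base-pair probability matrix.

A potential stem is a maximal anti-diagonal run of nonzero cells; its weight
is the sum of the pairing probabilities it covers, which later drives
roulette-wheel selection.
"""

from esdfold import RnaSequence, ViennaEngine, find_potential_stems

seq = RnaSequence("example", "GUGCACGACGCCGU")
matrix = ViennaEngine().pair_probabilities(seq, floor=0.05)

stems = find_potential_stems(matrix)
print(f"{len(stems)} maximal potential stems at probability floor 0.05:")
for s in stems:
    print(
        f"  start ({s.r},{s.c})  length {s.length} bp  weight p_s = {s.weight:.3f}"
    )
# Each line is one candidate helix: pairs (r,c), (r+1,c-1), ... Only stems of
# length >= 3 enter the catalog used to assemble structures.
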