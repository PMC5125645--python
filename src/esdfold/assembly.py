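"""Assembly of initial populations by iterated roulette stem selection.

Each structure is grown by drawing stems from the catalog's roulette wheel
until ``k`` distinct stems have contributed pairs.  A drawn stem is first
trimmed against the partial structure: pairs that reuse an occupied
nucleotide are removed (the overlap rule), and pairs that would cross an
existing pair are removed as well, since the predicted structures are
pseudoknot-free by definition.  What survives — possibly several short
fragments — is added whole.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .rna_model import SecondaryStructure
from .stem_catalog import Stem, StemCatalog, roulette_draw

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PopulationConfig:
    """Population size ``m`` and stems-per-structure ``k``.

    Defaults follow the method's calibration: ``m = n`` (sequence length) and
    ``k = max(1, n // 5)``.
    """

    pop_size: int
    stems_per_structure: int

    def __post_init__(self) -> None:
        if self.pop_size < 1:
            raise ValueError("pop_size must be >= 1")
        if self.stems_per_structure < 1:
            raise ValueError("stems_per_structure must be >= 1")

    @classmethod
    def for_length(cls, n: int) -> "PopulationConfig":
        return cls(pop_size=n, stems_per_structure=max(1, n // 5))


def trim_stem(
    stem: Stem, structure: SecondaryStructure
) -> list[list[tuple[int, int]]]:
    """Pairs of ``stem`` compatible with ``structure``, as maximal runs.

    A pair is dropped if either nucleotide is already paired in the structure,
    or if it crosses any existing pair.  The survivors are grouped into
    maximal consecutive runs (which may be shorter than the catalog cutoff, or
    empty).
    """
    occupied = {idx for pair in structure.pairs for idx in pair}
    existing = structure.sorted_pairs()

    def compatible(i: int, j: int) -> bool:
        if i in occupied or j in occupied:
            return False
        return not any((a < i < b < j) or (i < a < j < b) for a, b in existing)

    runs: list[list[tuple[int, int]]] = []
    current: list[tuple[int, int]] = []
    for i, j in stem.pairs:
        if compatible(i, j):
            current.append((i, j))
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    return runs


def build_structure(
    catalog: StemCatalog,
    n: int,
    k: int,
    rng: np.random.Generator,
    max_draws: int | None = None,
) -> SecondaryStructure:
    """Assemble one structure from ``k`` roulette-drawn (trimmed) stems.

    A draw counts toward ``k`` only if it contributes at least one pair after
    trimming.  If ``k`` contributions cannot be collected within ``max_draws``
    attempts (default ``50 * k``) the structure built so far is returned and
    the shortfall logged.  On short sequences this is routine rather than
    exceptional — ``k = n/5`` can exceed the number of mutually compatible
    stems — so the log level is informational.
    """
    if max_draws is None:
        max_draws = 50 * k
    structure = SecondaryStructure(n=n)
    contributions = 0
    for _ in range(max_draws):
        if contributions >= k:
            break
        stem = roulette_draw(catalog, rng)
        runs = trim_stem(stem, structure)
        added = [pair for run in runs for pair in run]
        if added:
            structure = structure.union(added)
            contributions += 1
    else:
        if contributions < k:
            logger.info(
                "assembled only %d of %d stems within %d draws", contributions, k, max_draws
            )
    return structure


def initial_population(
    catalog: StemCatalog,
    n: int,
    config: PopulationConfig,
    rng: np.random.Generator,
) -> list[SecondaryStructure]:
    """Independently assemble ``pop_size`` structures of ``k`` stems each."""
    return [
        build_structure(catalog, n, config.stems_per_structure, rng)
        for _ in range(config.pop_size)
    ]
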