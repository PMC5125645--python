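"""Enumeration of maximal potential stems and roulette-wheel sampling.

A potential stem is a maximal run of nonzero cells along an anti-diagonal of
the base-pair probability matrix: cells ``(r+k, c-k)`` for ``k = 0..l-1``, all
nonzero, with the diagonally preceding cell ``(r-1, c+1)`` and following cell
``(r+l, c-l)`` zero or outside the (strict upper-triangular) matrix.  Every
nonzero cell belongs to exactly one maximal stem, so a single scan per
anti-diagonal enumerates them all.

The stem weight ``p_s`` — the sum of its pair probabilities — drives
fitness-proportionate (roulette-wheel) sampling during structure assembly and
mutation.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .pairing_engine import BasePairProbMatrix


class EmptyCatalogError(ValueError):
    """No stems to sample from — relax the probability floor or min length."""


@dataclass(frozen=True)
class Stem:
    """A run of consecutive base pairs ``(r+k, c-k)``, k = 0..length-1."""

    r: int
    c: int
    length: int
    weight: float  # sum of the pair probabilities over the run

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"stem length {self.length} < 1")
        if self.r + (self.length - 1) >= self.c - (self.length - 1):
            raise ValueError(f"stem {self} extends past the matrix diagonal")
        if self.weight <= 0.0:
            raise ValueError(f"stem weight {self.weight} must be positive")

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return [(self.r + k, self.c - k) for k in range(self.length)]


def find_potential_stems(matrix: BasePairProbMatrix) -> list[Stem]:
    """All maximal potential stems of a floored probability matrix.

    The returned set partitions the nonzero cells: each cell lies in exactly
    one stem.  Stems are ordered by (r, c).
    """
    nz = matrix.nonzero()
    stems: list[Stem] = []
    for (i, j) in sorted(nz):
        if (i - 1, j + 1) in nz:
            continue  # an earlier cell on this anti-diagonal starts the run
        length = 0
        weight = 0.0
        while (i + length, j - length) in nz:
            weight += nz[(i + length, j - length)]
            length += 1
        stems.append(Stem(r=i, c=j, length=length, weight=weight))
    return stems


@dataclass(frozen=True)
class StemCatalog:
    """Length-filtered stem set with prefix sums for roulette sampling."""

    stems: tuple[Stem, ...]
    cumulative_weights: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "cumulative_weights",
            tuple(np.cumsum([s.weight for s in self.stems])),
        )

    def __len__(self) -> int:
        return len(self.stems)

    @property
    def total_weight(self) -> float:
        return self.cumulative_weights[-1] if self.stems else 0.0


def filter_by_length(stems: list[Stem], min_len: int = 3) -> StemCatalog:
    """Keep stems with at least ``min_len`` pairs (order preserved).

    Short stems (1-2 pairs) are the least stable and, left in the pool, are
    drawn often and degrade assembled structures; the default cutoff of 3
    removes them.  Trimmed remnants produced later during assembly may still
    be shorter — the cutoff applies to the catalog only.
    """
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    return StemCatalog(stems=tuple(s for s in stems if s.length >= min_len))


def build_catalog(
    matrix: BasePairProbMatrix, min_len: int = 3
) -> StemCatalog:
    return filter_by_length(find_potential_stems(matrix), min_len=min_len)


def roulette_draw(catalog: StemCatalog, rng: np.random.Generator) -> Stem:
    """Draw a stem with probability proportional to its weight ``p_s``."""
    if not catalog.stems:
        raise EmptyCatalogError(
            "stem catalog is empty; lower the probability floor (eps) or "
            "the minimum stem length"
        )
    u = rng.random() * catalog.total_weight
    idx = bisect_right(catalog.cumulative_weights, u)
    return catalog.stems[min(idx, len(catalog.stems) - 1)]
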