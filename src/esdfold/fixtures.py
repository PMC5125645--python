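"""Synthetic probability-matrix and structure fixtures with known ground truth.

These generators plant anti-diagonal stem runs (and optional isolated noise
cells) in a probability matrix so that the maximal-stem decomposition is
known by construction, letting every downstream module be tested without a
thermodynamic engine.  Noise cells are placed only where they can neither
extend a planted run nor merge with another noise cell, so the ground-truth
stem set is exactly: the planted stems plus one length-1 stem per noise cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .pairing_engine import BasePairProbMatrix
from .rna_model import SecondaryStructure, StructuralClass
from .stem_catalog import Stem


@dataclass(frozen=True)
class PlantedStem:
    r: int
    c: int
    length: int
    prob: float  # per-pair probability

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("planted stem length must be >= 1")
        if not (0.0 < self.prob <= 1.0):
            raise ValueError(f"planted probability {self.prob} not in (0, 1]")

    @property
    def cells(self) -> list[tuple[int, int]]:
        return [(self.r + k, self.c - k) for k in range(self.length)]

    def as_stem(self) -> Stem:
        return Stem(r=self.r, c=self.c, length=self.length,
                    weight=self.prob * self.length)


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture: planted stems + background noise on an n×n matrix."""

    n: int
    stems: tuple[PlantedStem, ...] = ()
    noise_cells: int = 0
    noise_range: tuple[float, float] = (0.1, 0.9)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "stems",
            tuple(
                s if isinstance(s, PlantedStem) else PlantedStem(*s)
                for s in self.stems
            ),
        )
        all_cells: set[tuple[int, int]] = set()
        for s in self.stems:
            for i, j in s.cells:
                if not (1 <= i < j <= self.n):
                    raise ValueError(f"planted cell ({i},{j}) outside matrix n={self.n}")
            if all_cells & set(s.cells):
                raise ValueError("planted stems overlap in matrix cells")
            all_cells |= set(s.cells)
        # planted stems must form a valid structure together: no shared
        # nucleotides, no crossing pairs
        all_pairs = [p for s in self.stems for p in s.cells]
        used: set[int] = set()
        for i, j in all_pairs:
            if i in used or j in used:
                raise ValueError(f"planted stems share nucleotide in pair ({i},{j})")
            used.update((i, j))
        for a in range(len(all_pairs)):
            for b in range(a + 1, len(all_pairs)):
                (i, j), (s_, t) = all_pairs[a], all_pairs[b]
                if (i < s_ < j < t) or (s_ < i < t < j):
                    raise ValueError(
                        f"planted pairs ({i},{j}) and ({s_},{t}) cross"
                    )
        # a planted stem must not be the diagonal continuation of another,
        # or the two would merge into one maximal run
        for s in self.stems:
            head, tail = (s.r - 1, s.c + 1), (s.r + s.length, s.c - s.length)
            if head in all_cells or tail in all_cells:
                raise ValueError(f"planted stem {s} extends another planted stem")
        lo, hi = self.noise_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"noise range {self.noise_range} not within (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FixtureSpec":
        d = yaml.safe_load(Path(path).read_text())
        return cls(
            n=d["n"],
            stems=tuple(
                PlantedStem(s["r"], s["c"], s["length"], s["prob"])
                for s in d.get("stems", [])
            ),
            noise_cells=d.get("noise_cells", 0),
            noise_range=tuple(d.get("noise_range", (0.1, 0.9))),
            seed=d.get("seed", 0),
        )

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "n": self.n,
            "stems": [
                {"r": s.r, "c": s.c, "length": s.length, "prob": s.prob}
                for s in self.stems
            ],
            "noise_cells": self.noise_cells,
            "noise_range": list(self.noise_range),
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _diagonal_neighbors(cell: tuple[int, int]) -> list[tuple[int, int]]:
    i, j = cell
    return [(i - 1, j + 1), (i + 1, j - 1)]


def make_matrix(spec: FixtureSpec) -> tuple[BasePairProbMatrix, list[Stem]]:
    """Materialise the fixture matrix and its ground-truth maximal stem set.

    Returns ``(matrix, truth)`` where ``truth`` lists every maximal stem the
    enumeration must find: the planted stems plus a length-1 stem per noise
    cell, ordered by (r, c).
    """
    rng = np.random.default_rng(spec.seed)
    entries: dict[tuple[int, int], float] = {}
    blocked: set[tuple[int, int]] = set()
    for s in spec.stems:
        for cell in s.cells:
            entries[cell] = s.prob
            blocked.add(cell)
            blocked.update(_diagonal_neighbors(cell))
    truth = [s.as_stem() for s in spec.stems]

    if spec.noise_cells:
        candidates = [
            (i, j)
            for i in range(1, spec.n + 1)
            for j in range(i + 1, spec.n + 1)
            if (i, j) not in blocked
        ]
        rng.shuffle(candidates)
        placed = 0
        for cell in candidates:
            if placed >= spec.noise_cells:
                break
            if cell in blocked:
                continue  # adjacent to an earlier noise cell
            lo, hi = spec.noise_range
            p = float(rng.uniform(lo, hi))
            entries[cell] = p
            truth.append(Stem(r=cell[0], c=cell[1], length=1, weight=p))
            blocked.add(cell)
            blocked.update(_diagonal_neighbors(cell))
            placed += 1

    truth.sort(key=lambda s: (s.r, s.c))
    return BasePairProbMatrix(n=spec.n, p=entries), truth


def make_structure_with_truth(
    spec: FixtureSpec,
) -> tuple[SecondaryStructure, list[StructuralClass]]:
    """Structure from the planted stems plus hand-constructed class labels.

    The labels are built directly from each planted stem's geometry — first
    and last pair helix-end, interior pairs stacked — independently of
    ``classify_positions``, so the two can be compared as oracle and subject.
    """
    pairs: set[tuple[int, int]] = set()
    labels = [StructuralClass.UNPAIRED] * spec.n
    for s in spec.stems:
        cells = s.cells
        pairs.update(cells)
        for k, (i, j) in enumerate(cells):
            cls = (
                StructuralClass.HELIX_END
                if k == 0 or k == s.length - 1
                else StructuralClass.STACKED
            )
            labels[i - 1] = cls
            labels[j - 1] = cls
    return SecondaryStructure(n=spec.n, pairs=frozenset(pairs)), labels
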