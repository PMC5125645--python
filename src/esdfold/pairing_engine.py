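"""Base-pair probability matrices and free-energy evaluation.

Two engines implement the same contract: :class:`ViennaEngine` adapts the
ViennaRNA partition-function machinery (McCaskill probabilities and
nearest-neighbor energy evaluation of a fixed structure), and
:class:`BuiltinEngine` is a deterministic, deliberately simplified
Boltzmann-weighted Nussinov-style model so that the predictor and its tests
run without the thermodynamic backend.  The built-in model is NOT a
thermodynamic parameterisation — it knows one stacking constant and one
hairpin penalty.

Probabilities below a configurable floor ``eps`` are stored as exact zeros
when a matrix is built: stem enumeration tests cells against zero exactly,
while partition-function engines emit arbitrarily small values everywhere.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .rna_model import RnaSequence, SecondaryStructure

#: default probability floor — one-decimal rounding to 0.0
DEFAULT_PROB_FLOOR = 0.05

CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)


class EngineUnavailableError(RuntimeError):
    """Raised when the requested pairing engine cannot run."""


class MatrixFormatError(ValueError):
    """Raised for malformed probability-matrix files."""


@dataclass(frozen=True)
class BasePairProbMatrix:
    """Sparse upper-triangular matrix of pairing probabilities ``p[i,j]``.

    Entries are 1-based with ``i < j``; an absent entry is an exact zero.
    """

    n: int
    p: Mapping[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[tuple[int, int], float] = {}
        for (i, j), prob in self.p.items():
            if not (1 <= i < j <= self.n):
                raise MatrixFormatError(
                    f"entry ({i},{j}) not upper-triangular within n={self.n}"
                )
            if not (0.0 <= prob <= 1.0):
                raise MatrixFormatError(f"p[{i},{j}]={prob} outside [0,1]")
            if prob > 0.0:
                clean[(i, j)] = float(prob)
        object.__setattr__(self, "p", clean)

    @classmethod
    def from_entries(
        cls,
        n: int,
        entries: Mapping[tuple[int, int], float] | Iterable[tuple[int, int, float]],
        floor: float = 0.0,
    ) -> "BasePairProbMatrix":
        """Build a matrix, zeroing every entry strictly below ``floor``."""
        if isinstance(entries, Mapping):
            items = entries.items()
        else:
            items = {(i, j): p for i, j, p in entries}.items()
        kept = {ij: p for ij, p in items if p >= floor and p > 0.0}
        return cls(n=n, p=kept)

    def __getitem__(self, ij: tuple[int, int]) -> float:
        return self.p.get(ij, 0.0)

    def nonzero(self) -> dict[tuple[int, int], float]:
        return dict(self.p)

    def row_sums(self) -> np.ndarray:
        """Total pairing probability per position (index 0 = position 1)."""
        sums = np.zeros(self.n)
        for (i, j), prob in self.p.items():
            sums[i - 1] += prob
            sums[j - 1] += prob
        return sums


def write_matrix(path: str | Path, matrix: BasePairProbMatrix) -> None:
    """Write a matrix as TSV triples ``i j p`` under a ``# n=<size>`` header."""
    lines = [f"# n={matrix.n}"]
    for (i, j), prob in sorted(matrix.p.items()):
        lines.append(f"{i}\t{j}\t{prob!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_matrix(path: str | Path) -> BasePairProbMatrix:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("# n="):
        raise MatrixFormatError(f"{path}: missing '# n=<size>' header")
    try:
        n = int(lines[0].split("=", 1)[1])
    except ValueError:
        raise MatrixFormatError(f"{path}: unparseable size in header {lines[0]!r}")
    entries: dict[tuple[int, int], float] = {}
    for lineno, ln in enumerate(lines[1:], start=2):
        if not ln.strip() or ln.startswith("#"):
            continue
        cols = ln.split("\t")
        if len(cols) != 3:
            raise MatrixFormatError(f"{path}:{lineno}: expected 3 columns")
        try:
            i, j, prob = int(cols[0]), int(cols[1]), float(cols[2])
        except ValueError:
            raise MatrixFormatError(f"{path}:{lineno}: non-numeric row {ln!r}")
        if i >= j:
            raise MatrixFormatError(f"{path}:{lineno}: i={i} >= j={j}")
        if not (0.0 <= prob <= 1.0):
            raise MatrixFormatError(f"{path}:{lineno}: p={prob} outside [0,1]")
        if (i, j) in entries:
            raise MatrixFormatError(f"{path}:{lineno}: duplicate entry ({i},{j})")
        entries[(i, j)] = prob
    return BasePairProbMatrix(n=n, p=entries)


class EnergyModel(ABC):
    """Contract shared by all pairing/energy engines."""

    name: str
    version: str

    @abstractmethod
    def pair_probabilities(
        self, seq: RnaSequence, floor: float = DEFAULT_PROB_FLOOR
    ) -> BasePairProbMatrix:
        """Equilibrium base-pair probabilities, floored to exact zeros."""

    @abstractmethod
    def energy(self, seq: RnaSequence, structure: SecondaryStructure) -> float:
        """Free energy (kcal/mol) of the given structure; lower = more stable."""


class ViennaEngine(EnergyModel):
    """Adapter around the ViennaRNA Python bindings (partition function + eval).

    Probabilities come from the McCaskill partition function with backend
    defaults; ``energy`` evaluates the supplied structure (not the MFE one).
    """

    name = "viennarna"

    def __init__(self) -> None:
        try:
            import RNA  # type: ignore
        except ImportError as exc:  # pragma: no cover - depends on install
            raise EngineUnavailableError(
                "ViennaRNA Python bindings are not installed; install the "
                "'ViennaRNA' package, or use the built-in engine "
                "(--engine builtin) or a matrix file (--engine file:<path>)."
            ) from exc
        self._rna = RNA
        self.version = RNA.__version__

    def pair_probabilities(
        self, seq: RnaSequence, floor: float = DEFAULT_PROB_FLOOR
    ) -> BasePairProbMatrix:
        fc = self._rna.fold_compound(seq.residues)
        fc.pf()
        bpp = fc.bpp()  # 1-based (n+1)x(n+1) list of lists
        n = len(seq)
        entries = {
            (i, j): bpp[i][j]
            for i in range(1, n + 1)
            for j in range(i + 1, n + 1)
            if bpp[i][j] > 0.0
        }
        return BasePairProbMatrix.from_entries(n, entries, floor=floor)

    def energy(self, seq: RnaSequence, structure: SecondaryStructure) -> float:
        fc = self._rna.fold_compound(seq.residues)
        return float(fc.eval_structure(structure.to_dotbracket()))


@dataclass(frozen=True)
class BuiltinEnergyParams:
    """Parameters of the simplified built-in model (kcal/mol).

    ``stack_energy`` is the bonus per stacked pair inside a helix;
    ``hairpin_penalty`` is charged once per hairpin-closing pair (a pair with
    no pair nested inside it); all other loops are free.  ``rt`` is k_B·T at
    37 °C; ``min_hairpin`` the minimum number of unpaired bases in a hairpin.
    """

    stack_energy: float = -2.0
    hairpin_penalty: float = 3.0
    rt: float = 0.6163
    min_hairpin: int = 3


class BuiltinEngine(EnergyModel):
    """Deterministic fallback engine: Boltzmann-weighted Nussinov-style model.

    Canonical pairs (Watson-Crick + wobble) only.  The partition function uses
    exactly the same two energy terms as :meth:`energy`, so the probabilities
    are the exact equilibrium probabilities *of this simplified model*.
    """

    name = "builtin"
    version = "1.0"

    def __init__(self, params: BuiltinEnergyParams | None = None) -> None:
        self.params = params or BuiltinEnergyParams()

    # -- energy of a fixed structure -------------------------------------

    def energy(self, seq: RnaSequence, structure: SecondaryStructure) -> float:
        e = 0.0
        pairs = structure.sorted_pairs()
        for run in structure.runs():
            e += self.params.stack_energy * (len(run) - 1)
        for i, j in pairs:
            if not any(i < a and b < j for a, b in pairs):
                e += self.params.hairpin_penalty  # innermost pair closes a hairpin
        return e

    # -- partition function / pair probabilities --------------------------

    def _allowed(self, seq: RnaSequence) -> np.ndarray:
        n = len(seq)
        allowed = np.zeros((n + 2, n + 2), dtype=bool)
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                allowed[i, j] = (seq[i], seq[j]) in CANONICAL_PAIRS
        return allowed

    def pair_probabilities(
        self, seq: RnaSequence, floor: float = DEFAULT_PROB_FLOOR
    ) -> BasePairProbMatrix:
        n = len(seq)
        p = self.params
        beta = 1.0 / p.rt
        w_stack = math.exp(-beta * p.stack_energy)
        w_hairpin = math.exp(-beta * p.hairpin_penalty)
        allowed = self._allowed(seq)

        # Inside: Q[i,j] = partition function of interval i..j (Q=1 if empty);
        # Qb[i,j] = partition over structures in which (i,j) is a pair.
        Q = np.ones((n + 2, n + 2))
        Qb = np.zeros((n + 2, n + 2))
        for span in range(1, n):
            for i in range(1, n - span + 1):
                j = i + span
                if allowed[i, j]:
                    qb = 0.0
                    if j - i - 1 >= p.min_hairpin:
                        qb += w_hairpin  # empty interior = hairpin loop
                    if i + 1 < j - 1:
                        qb += w_stack * Qb[i + 1, j - 1]  # helical stack
                        # interior holds >=1 pair but not the exact stack pair
                        qb += Q[i + 1, j - 1] - 1.0 - Qb[i + 1, j - 1]
                    Qb[i, j] = qb
                # Q: either i unpaired, or i pairs some k
                q = Q[i + 1, j]
                for k in range(i + 1, j + 1):
                    if Qb[i, k] != 0.0:
                        q += Qb[i, k] * Q[k + 1, j]
                Q[i, j] = q
        Z = Q[1, n]

        # Outside: O[i,j] = weight of all exterior completions given (i,j)
        # paired; summed over the innermost enclosing pair (a,b) or none.
        # The stack correction applies when (a,b) = (i-1,j+1) with empty
        # flanks, where Qb[a,b] gave that configuration the extra w_stack.
        O = np.zeros((n + 2, n + 2))
        pair_list = [
            (i, j)
            for span in range(n - 1, 0, -1)
            for i in range(1, n - span + 1)
            if Qb[i, i + span] != 0.0
            for j in (i + span,)
        ]
        for i, j in pair_list:  # decreasing span order
            o = Q[1, i - 1] * Q[j + 1, n]  # empty intervals give Q = 1
            for a in range(1, i):
                for b in range(j + 1, n + 1):
                    if not allowed[a, b] or O[a, b] == 0.0:
                        continue
                    term = Q[a + 1, i - 1] * Q[j + 1, b - 1]
                    if a == i - 1 and b == j + 1:
                        term += w_stack - 1.0
                    o += O[a, b] * term
            O[i, j] = o

        entries: dict[tuple[int, int], float] = {}
        for i, j in pair_list:
            prob = Qb[i, j] * O[i, j] / Z
            if prob > 0.0:
                entries[(i, j)] = min(prob, 1.0)
        return BasePairProbMatrix.from_entries(n, entries, floor=floor)


class FileEngine(EnergyModel):
    """Engine backed by a precomputed matrix file; energy from a delegate.

    Useful for fixture-driven runs: probabilities come from the file, while
    free-energy evaluation is delegated (default: built-in model).
    """

    name = "file"

    def __init__(
        self, path: str | Path, energy_delegate: EnergyModel | None = None
    ) -> None:
        self._matrix = read_matrix(path)
        self._delegate = energy_delegate or BuiltinEngine()
        self.version = f"file:{Path(path).name}"

    def pair_probabilities(
        self, seq: RnaSequence, floor: float = DEFAULT_PROB_FLOOR
    ) -> BasePairProbMatrix:
        if self._matrix.n != len(seq):
            raise MatrixFormatError(
                f"matrix is {self._matrix.n}x{self._matrix.n} but sequence "
                f"has length {len(seq)}"
            )
        return BasePairProbMatrix.from_entries(
            self._matrix.n, self._matrix.p, floor=floor
        )

    def energy(self, seq: RnaSequence, structure: SecondaryStructure) -> float:
        return self._delegate.energy(seq, structure)


def get_engine(spec: str) -> EnergyModel:
    """Resolve an engine spec: ``external``/``vienna``, ``builtin`` or ``file:<path>``."""
    if spec in ("external", "vienna", "viennarna"):
        return ViennaEngine()
    if spec == "builtin":
        return BuiltinEngine()
    if spec.startswith("file:"):
        return FileEngine(spec[len("file:"):])
    raise ValueError(f"unknown engine {spec!r}")
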