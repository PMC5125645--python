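"""Core domain types for RNA sequences and pseudoknot-free secondary structures.

Coordinates are 1-based and inclusive throughout the package; file-format
readers convert on the way in.  A secondary structure is a set of base pairs
``(i, j)`` with ``i < j`` in which no index is used twice and no two pairs
cross, i.e. for any two pairs either one nests inside the other or they are
side by side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_RESIDUES = frozenset("ACGU")


class RnaValidationError(ValueError):
    """Raised when a sequence or structure violates a domain invariant."""


class StructureParseError(ValueError):
    """Raised when a structure file or dot-bracket string cannot be parsed."""


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence over {A, C, G, U}, positions numbered from 1."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        normalized = self.residues.upper().replace("T", "U")
        if not normalized:
            raise RnaValidationError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(normalized, start=1):
            if ch not in _VALID_RESIDUES:
                raise RnaValidationError(
                    f"record {self.id!r}: invalid residue {ch!r} at position {pos}"
                )
        object.__setattr__(self, "residues", normalized)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> str:
        """Residue at 1-based position ``i``."""
        if not 1 <= i <= len(self.residues):
            raise IndexError(f"position {i} out of range 1..{len(self.residues)}")
        return self.residues[i - 1]


class StructuralClass(Enum):
    """Per-nucleotide structural context used by the SHAPE simulator.

    ``HELIX_END`` marks both nucleotides of a terminal base pair of a maximal
    run of consecutive pairs (a helix); ``STACKED`` marks nucleotides of
    interior pairs of such a run; everything else is ``UNPAIRED``.
    """

    UNPAIRED = "unpaired"
    STACKED = "stacked"
    HELIX_END = "helix_end"


def _pairs_cross(a: tuple[int, int], b: tuple[int, int]) -> bool:
    (i, j), (s, t) = a, b
    return (i < s < j < t) or (s < i < t < j)


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free set of base pairs over a sequence of length ``n``."""

    n: int
    pairs: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(self.pairs))
        seen: dict[int, tuple[int, int]] = {}
        for i, j in self.pairs:
            if not (1 <= i < j <= self.n):
                raise RnaValidationError(f"pair ({i},{j}) out of range for n={self.n}")
            for idx in (i, j):
                if idx in seen:
                    raise RnaValidationError(
                        f"index {idx} in both pairs {seen[idx]} and ({i},{j})"
                    )
                seen[idx] = (i, j)
        ordered = self.sorted_pairs()
        for a in range(len(ordered)):
            for b in range(a + 1, len(ordered)):
                if _pairs_cross(ordered[a], ordered[b]):
                    raise RnaValidationError(
                        f"crossing pairs {ordered[a]} and {ordered[b]} (pseudoknot)"
                    )

    def sorted_pairs(self) -> list[tuple[int, int]]:
        return sorted(self.pairs)

    def partner_of(self, i: int) -> int | None:
        for a, b in self.pairs:
            if a == i:
                return b
            if b == i:
                return a
        return None

    def runs(self) -> list[list[tuple[int, int]]]:
        """Maximal runs of consecutive pairs (i,j),(i+1,j-1),... — the helices."""
        pair_set = self.pairs
        out: list[list[tuple[int, int]]] = []
        for i, j in self.sorted_pairs():
            if (i - 1, j + 1) in pair_set:
                continue  # not a run start
            run = [(i, j)]
            while (run[-1][0] + 1, run[-1][1] - 1) in pair_set:
                run.append((run[-1][0] + 1, run[-1][1] - 1))
            out.append(run)
        return out

    def to_dotbracket(self) -> str:
        db = ["."] * self.n
        for i, j in self.pairs:
            db[i - 1] = "("
            db[j - 1] = ")"
        return "".join(db)

    def union(self, extra: Iterable[tuple[int, int]]) -> "SecondaryStructure":
        return SecondaryStructure(self.n, self.pairs | frozenset(extra))


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read all records of a FASTA file as validated, T→U-normalized sequences."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise RnaValidationError(f"{path}: no FASTA records found")
    return [RnaSequence(id=rec.id, residues=str(rec.seq)) for rec in records]


def parse_dotbracket(db: str, n: int | None = None) -> SecondaryStructure:
    """Parse a dot-bracket string into a structure via matching parentheses."""
    if n is not None and len(db) != n:
        raise StructureParseError(f"dot-bracket length {len(db)} != declared n={n}")
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureParseError(f"unmatched ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif ch != ".":
            raise StructureParseError(f"invalid character {ch!r} at position {pos}")
    if stack:
        raise StructureParseError(f"unmatched '(' at position {stack[-1]}")
    return SecondaryStructure(n=len(db), pairs=frozenset(pairs))


def _structure_from_partners(
    partners: dict[int, int], n: int, *, on_crossing: str, source: str
) -> SecondaryStructure:
    """Build a structure from a symmetric partner map, applying the crossing policy."""
    pairs: set[tuple[int, int]] = set()
    for i, j in partners.items():
        if j == 0:
            continue
        if not (1 <= j <= n):
            raise StructureParseError(f"{source}: partner {j} of {i} out of range 1..{n}")
        if partners.get(j, 0) != i:
            raise StructureParseError(
                f"{source}: conflicting partners — {i}↔{j} but {j}↔{partners.get(j, 0)}"
            )
        pairs.add((min(i, j), max(i, j)))
    ordered = sorted(pairs)
    crossing: set[tuple[int, int]] = set()
    for a in range(len(ordered)):
        for b in range(a + 1, len(ordered)):
            if _pairs_cross(ordered[a], ordered[b]):
                crossing.add(ordered[a])
                crossing.add(ordered[b])
    if crossing:
        if on_crossing == "error":
            raise StructureParseError(
                f"{source}: {len(crossing)} pairs involved in crossings (pseudoknot)"
            )
        logger.warning(
            "%s: dropping %d crossing (pseudoknotted) pairs", source, len(crossing)
        )
        pairs -= crossing
    return SecondaryStructure(n=n, pairs=frozenset(pairs))


def read_reference_structure(
    path: str | Path,
    fmt: str | None = None,
    *,
    on_crossing: str = "drop",
) -> SecondaryStructure:
    """Read a reference structure from a CT, BPSEQ or dot-bracket (.dbn) file.

    ``fmt`` is one of ``ct``, ``bpseq``, ``dbn``; when omitted it is inferred
    from the file suffix.  Reference databases may contain pseudoknots; the
    ``on_crossing`` policy is ``drop`` (default, with a logged warning) or
    ``error``.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if on_crossing not in ("drop", "error"):
        raise ValueError(f"unknown crossing policy {on_crossing!r}")
    text = path.read_text()
    if fmt == "ct":
        return _read_ct(text, on_crossing=on_crossing, source=str(path))
    if fmt == "bpseq":
        return _read_bpseq(text, on_crossing=on_crossing, source=str(path))
    if fmt in ("dbn", "db", "dot"):
        return _read_dbn(text, source=str(path))
    raise ValueError(f"unknown structure format {fmt!r}")


def _read_ct(text: str, *, on_crossing: str, source: str) -> SecondaryStructure:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise StructureParseError(f"{source}: empty CT file")
    header = lines[0].split()
    try:
        n = int(header[0])
    except (IndexError, ValueError):
        raise StructureParseError(f"{source}: CT header must start with the length")
    partners: dict[int, int] = {}
    for ln in lines[1 : n + 1]:
        cols = ln.split()
        if len(cols) < 6:
            raise StructureParseError(f"{source}: CT row with <6 columns: {ln!r}")
        idx, partner = int(cols[0]), int(cols[4])
        partners[idx] = partner
    if len(partners) != n:
        raise StructureParseError(
            f"{source}: expected {n} CT rows, found {len(partners)}"
        )
    return _structure_from_partners(partners, n, on_crossing=on_crossing, source=source)


def _read_bpseq(text: str, *, on_crossing: str, source: str) -> SecondaryStructure:
    partners: dict[int, int] = {}
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        cols = ln.split()
        if len(cols) != 3:
            raise StructureParseError(f"{source}: BPSEQ row must have 3 columns: {ln!r}")
        idx, partner = int(cols[0]), int(cols[2])
        if idx in partners:
            raise StructureParseError(f"{source}: duplicate BPSEQ index {idx}")
        partners[idx] = partner
    n = max(partners) if partners else 0
    if set(partners) != set(range(1, n + 1)):
        raise StructureParseError(f"{source}: BPSEQ indices are not 1..{n}")
    return _structure_from_partners(partners, n, on_crossing=on_crossing, source=source)


def _read_dbn(text: str, *, source: str) -> SecondaryStructure:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    body = [ln for ln in lines if not ln.startswith((">", "#", ";"))]
    if not body:
        raise StructureParseError(f"{source}: no dot-bracket line found")
    db = body[-1]  # sequence line (if any) precedes the structure line
    return parse_dotbracket(db)


def write_dbn(
    path: str | Path,
    structure: SecondaryStructure,
    sequence: RnaSequence | None = None,
    header: str = "structure",
) -> None:
    lines = [f">{header}"]
    if sequence is not None:
        lines.append(sequence.residues)
    lines.append(structure.to_dotbracket())
    Path(path).write_text("\n".join(lines) + "\n")


def classify_positions(structure: SecondaryStructure) -> list[StructuralClass]:
    """Label every position unpaired, stacked or helix-end.

    Returns a list of length ``n`` whose entry ``i-1`` is the class of
    position ``i``.  The decomposition into maximal runs of consecutive pairs
    is the helix definition: both nucleotides of a run's first and last pair
    are helix ends (a 1-pair run gives two helix-end positions, a 2-pair run
    four); nucleotides of interior pairs are stacked.
    """
    labels = [StructuralClass.UNPAIRED] * structure.n
    for run in structure.runs():
        terminal = {run[0], run[-1]}
        for pair in run:
            cls = (
                StructuralClass.HELIX_END
                if pair in terminal
                else StructuralClass.STACKED
            )
            for idx in pair:
                labels[idx - 1] = cls
    return labels
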