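"""Core record type: an RNA sequence paired with its secondary structure.

The classifier operates on stem-loop secondary structures, not on raw
sequences: every record carries a Vienna dot-bracket string of the same
length as the sequence.  Structures must be pseudoknot-free (balanced,
properly nested brackets), which is what single-structure folding tools
such as UNAfold/mfold and RNAfold emit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SEQUENCE_ALPHABET = frozenset("ACGUN")
STRUCTURE_ALPHABET = frozenset(".()")
LABELS = ("positive", "negative")

#: Minimum record length accepted anywhere in the package.
MIN_LENGTH = 5


class HairpinError(ValueError):
    """Base class for all data errors raised by this package."""


class StructureError(HairpinError):
    """A sequence/structure pair failed validation.

    Parameters
    ----------
    message : str
        Human-readable description of the problem.
    record_id : str, optional
        Identifier of the offending record, when known.
    line : int, optional
        1-based line number in the source file, when parsing.
    """

    def __init__(self, message: str, record_id: str | None = None,
                 line: int | None = None):
        self.record_id = record_id
        self.line = line
        prefix = ""
        if record_id is not None:
            prefix += f"record {record_id!r}: "
        if line is not None:
            prefix += f"line {line}: "
        super().__init__(prefix + message)


def normalize_sequence(sequence: str) -> str:
    """Uppercase and map T to U (miRBase mixes DNA and RNA alphabets)."""
    return sequence.upper().replace("T", "U")


def check_balanced(structure: str) -> None:
    """Raise :class:`StructureError` unless brackets are balanced and nested."""
    depth = 0
    for pos, ch in enumerate(structure, start=1):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise StructureError(
                    f"unbalanced structure: unmatched ')' at position {pos}")
    if depth != 0:
        raise StructureError(
            f"unbalanced structure: {depth} unmatched '(' remain")


@dataclass(frozen=True)
class RnaRecord:
    """One RNA sequence with its dot-bracket secondary structure.

    Validation happens at construction: the sequence is normalized
    (uppercase, T->U), lengths must match, the structure must be balanced,
    and the alphabet is restricted to A/C/G/U/N and ``.()``.
    """

    id: str
    sequence: str
    structure: str
    label: str | None = field(default=None)

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        seq, struct = self.sequence, self.structure
        if len(seq) != len(struct):
            raise StructureError(
                f"length mismatch: sequence {len(seq)} nt vs structure "
                f"{len(struct)} chars", record_id=self.id)
        if len(seq) < MIN_LENGTH:
            raise StructureError(
                f"record too short ({len(seq)} nt, minimum {MIN_LENGTH})",
                record_id=self.id)
        bad = set(seq) - SEQUENCE_ALPHABET
        if bad:
            raise StructureError(
                f"illegal sequence character(s) {sorted(bad)}",
                record_id=self.id)
        bad = set(struct) - STRUCTURE_ALPHABET
        if bad:
            raise StructureError(
                f"illegal structure character(s) {sorted(bad)}",
                record_id=self.id)
        try:
            check_balanced(struct)
        except StructureError as exc:
            raise StructureError(str(exc), record_id=self.id) from None
        if self.label is not None and self.label not in LABELS:
            raise StructureError(
                f"label must be one of {LABELS}, got {self.label!r}",
                record_id=self.id)

    def __len__(self) -> int:
        return len(self.sequence)
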