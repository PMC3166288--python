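"""FASTA input/output and protein sequence cleaning.

Coordinates throughout the package are 1-based inclusive. Headers are the
full text after ``>`` up to end of line, untokenized, so batch output names
stay faithful to the input.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

#: The 20 standard one-letter amino-acid codes.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

Source = Union[str, Path, IO[str]]


class FastaParseError(ValueError):
    """Malformed FASTA text (e.g. sequence data before any header)."""


class SequenceValidationError(ValueError):
    """A record violates the sequence contract (empty, non-standard...)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein sequence with provenance of any cleaning applied.

    ``removed_positions`` lists ``(original 1-based position, character)``
    for every character stripped by :func:`clean_sequence`; it is empty for
    records straight out of :func:`read_fasta`.
    """

    name: str
    residues: str
    removed_positions: tuple[tuple[int, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.name:
            raise SequenceValidationError("record name must be non-empty")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_standard(self) -> bool:
        """True if every residue is one of the 20 standard codes."""
        return all(c in STANDARD_RESIDUES for c in self.residues)


def _as_text_stream(source: Source) -> IO[str]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8")
    return source


def read_fasta(source: Source) -> list[SequenceRecord]:
    """Parse FASTA text into records, order preserved, residues uppercased.

    No cleaning is applied: ambiguous characters survive verbatim (modulo
    case) so that :func:`clean_sequence` can report their coordinates.

    Raises
    ------
    FastaParseError
        If sequence data appears before any ``>`` header (the offending
        line number is named).
    SequenceValidationError
        If a record has a header but no sequence.
    """
    stream = _as_text_stream(source)
    close = isinstance(source, (str, Path))
    records: list[SequenceRecord] = []
    name: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if name is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise SequenceValidationError(f"record {name!r} has an empty sequence")
        records.append(SequenceRecord(name=name, residues=seq))

    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].strip()
                if not name:
                    raise FastaParseError(f"line {lineno}: empty FASTA header")
                chunks = []
            else:
                if name is None:
                    raise FastaParseError(
                        f"line {lineno}: sequence data before any '>' header"
                    )
                chunks.append(line.strip().upper())
        flush()
    finally:
        if close:
            stream.close()
    return records


def read_fasta_str(text: str) -> list[SequenceRecord]:
    """Convenience wrapper: parse FASTA from an in-memory string."""
    return read_fasta(io.StringIO(text))


def clean_sequence(record: SequenceRecord) -> SequenceRecord:
    """Strip ambiguous characters, logging original coordinates.

    Anything outside the 20 standard codes (B/Z/J/X/U/O, gaps, ``*``,
    whitespace, digits) is removed, not substituted. Positions in the
    returned record refer to the cleaned sequence; ``removed_positions``
    keeps the original 1-based coordinate of every removal. Idempotent.

    Raises
    ------
    SequenceValidationError
        If nothing remains after cleaning.
    """
    kept: list[str] = []
    removed: list[tuple[int, str]] = list(record.removed_positions)
    for pos, ch in enumerate(record.residues, start=1):
        if ch in STANDARD_RESIDUES:
            kept.append(ch)
        else:
            removed.append((pos, ch))
    if not kept:
        raise SequenceValidationError(
            f"record {record.name!r} is empty after cleaning"
        )
    return SequenceRecord(
        name=record.name, residues="".join(kept), removed_positions=tuple(removed)
    )


def write_fasta(records: Iterable[SequenceRecord], sink: Union[str, Path, IO[str]],
                width: int = 60) -> None:
    """Write records as FASTA with 60-column wrapped sequence lines."""
    stream = sink if hasattr(sink, "write") else open(sink, "w", encoding="utf-8")
    close = not hasattr(sink, "write")
    try:
        for rec in records:
            stream.write(f">{rec.name}\n")
            for i in range(0, len(rec.residues), width):
                stream.write(rec.residues[i:i + width] + "\n")
    finally:
        if close:
            stream.close()
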