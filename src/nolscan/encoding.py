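"""Sparse binary window encoding over a reduced amino-acid alphabet.

Each 13-residue sliding window becomes a one-hot feature vector: 13
positions x 12 residue groups = 156 bits, plus an optional trailing
13 x 3 block when a per-residue 3-state secondary-structure string
(H/E/C) is supplied.

The 12-group partition used by the original detector is not published;
the default here keeps the basic residues K/R — the dominant NoLS
signal — as their own group and merges standard physicochemical classes.
Any alternative 12-group partition can be supplied; the alphabet is
serialized with every trained model so predictions stay reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import Parameters, DEFAULT_PARAMETERS
from .sequence_io import STANDARD_RESIDUES, SequenceRecord

#: Allowed 3-state secondary-structure codes (helix / strand / coil).
STRUCTURE_STATES = "HEC"


class EncodingError(ValueError):
    """A window cannot be encoded (non-standard residue, bad structure)."""


class SequenceTooShortError(ValueError):
    """Sequence shorter than one window; caller must report no prediction."""


@dataclass(frozen=True)
class ReducedAlphabet:
    """An ordered partition of the 20 standard residues into 12 groups."""

    name: str
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.groups) != 12:
            raise ValueError(f"expected 12 groups, got {len(self.groups)}")
        seen = "".join(self.groups)
        if sorted(seen) != sorted(STANDARD_RESIDUES):
            raise ValueError(
                "groups must partition the 20 standard residues exactly once"
            )

    @property
    def size(self) -> int:
        return len(self.groups)

    def group_index(self) -> dict[str, int]:
        """Residue -> group column mapping."""
        return {res: g for g, members in enumerate(self.groups) for res in members}

    def to_dict(self) -> dict:
        return {"name": self.name, "groups": list(self.groups)}

    @classmethod
    def from_dict(cls, d: dict) -> "ReducedAlphabet":
        return cls(name=d["name"], groups=tuple(d["groups"]))


#: Default 12-group partition: basic {K,R} kept distinct, acidic, hydroxyl,
#: amide, aliphatic, aromatic classes merged, small/special residues alone.
DEFAULT_ALPHABET = ReducedAlphabet(
    name="basic12",
    groups=("KR", "DE", "ST", "NQ", "ILV", "FY", "A", "G", "P", "C", "M", "HW"),
)


@dataclass(frozen=True)
class WindowFeatures:
    """One-hot features for a single window; ``start`` is 1-based."""

    start: int
    bits: np.ndarray

    @property
    def length(self) -> int:
        return int(self.bits.shape[0])


def feature_length(alphabet: ReducedAlphabet = DEFAULT_ALPHABET,
                   with_structure: bool = False,
                   window_length: int = 13) -> int:
    """156 for the plain encoding, 195 with the structure channel."""
    per_pos = alphabet.size + (len(STRUCTURE_STATES) if with_structure else 0)
    return window_length * per_pos


def windows(record: SequenceRecord,
            window_length: int = DEFAULT_PARAMETERS.window_length
            ) -> list[tuple[int, str]]:
    """All sliding windows (step 1) as ``(1-based start, 13-mer)`` pairs.

    Raises
    ------
    SequenceTooShortError
        If the sequence is shorter than ``window_length``.
    """
    L = len(record.residues)
    if L < window_length:
        raise SequenceTooShortError(
            f"record {record.name!r}: length {L} < window length {window_length}"
        )
    seq = record.residues
    return [(i + 1, seq[i:i + window_length]) for i in range(L - window_length + 1)]


def encode_window(window: str,
                  alphabet: ReducedAlphabet = DEFAULT_ALPHABET,
                  structure: str | None = None,
                  start: int = 1,
                  window_length: int = 13) -> WindowFeatures:
    """Sparse binary encoding of one window.

    The amino-acid block comes first: bit ``p * 12 + g`` is set iff the
    residue at window position ``p`` (0-based) belongs to group ``g``.
    When ``structure`` is given, a trailing 13 x 3 one-hot block over
    H/E/C follows.
    """
    if len(window) != window_length:
        raise EncodingError(
            f"window must have length {window_length}, got {len(window)}"
        )
    idx = alphabet.group_index()
    n_aa = window_length * alphabet.size
    n_struct = window_length * len(STRUCTURE_STATES) if structure is not None else 0
    bits = np.zeros(n_aa + n_struct, dtype=np.float64)
    for p, res in enumerate(window):
        g = idx.get(res)
        if g is None:
            raise EncodingError(
                f"non-standard residue {res!r} at window position {p + 1}"
            )
        bits[p * alphabet.size + g] = 1.0
    if structure is not None:
        if len(structure) != window_length:
            raise EncodingError(
                f"structure string must have length {window_length}, "
                f"got {len(structure)}"
            )
        for p, state in enumerate(structure):
            s = STRUCTURE_STATES.find(state)
            if s < 0:
                raise EncodingError(
                    f"invalid structure state {state!r} at window position {p + 1}"
                )
            bits[n_aa + p * len(STRUCTURE_STATES) + s] = 1.0
    return WindowFeatures(start=start, bits=bits)


def encode_sequence(record: SequenceRecord,
                    alphabet: ReducedAlphabet = DEFAULT_ALPHABET,
                    structure: str | None = None,
                    params: Parameters = DEFAULT_PARAMETERS) -> np.ndarray:
    """Feature matrix for all windows of a record, row i = window start i+1.

    ``structure``, when given, must be a per-residue 3-state string of the
    same length as the sequence; each window takes its aligned slice.
    """
    if structure is not None and len(structure) != len(record.residues):
        raise EncodingError(
            f"structure string length {len(structure)} != "
            f"sequence length {len(record.residues)}"
        )
    wins = windows(record, params.window_length)
    rows = []
    for start, win in wins:
        struct_win = None
        if structure is not None:
            struct_win = structure[start - 1:start - 1 + params.window_length]
        rows.append(
            encode_window(win, alphabet, struct_win, start=start,
                          window_length=params.window_length).bits
        )
    return np.vstack(rows)
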