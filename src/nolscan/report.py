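"""clinod-style plain-text prediction reports.

Five cumulative output levels, each strictly extending the previous:

========  ==========================================================
MINIMAL   sequence name and number of NoLSs predicted
SHORT     plus start and end position of each NoLS
MEDIUM    plus the sequence of each NoLS (the default)
FULL      plus the predictor score for each residue in the sequence
COMPLETE  plus the input sequence itself
========  ==========================================================

Per-residue scores are printed one value per line with 2 decimals so the
stream is unambiguous to parse.
"""

from __future__ import annotations

from enum import Enum

from .params import DEFAULT_PARAMETERS, Parameters
from .segment_caller import (
    CandidateSegmentProfile,
    NoLSInterval,
    residue_profile,
)
from .sequence_io import SequenceRecord


class OutputFormat(Enum):
    MINIMAL = "MINIMAL"
    SHORT = "SHORT"
    MEDIUM = "MEDIUM"
    FULL = "FULL"
    COMPLETE = "COMPLETE"

    @property
    def level(self) -> int:
        return list(OutputFormat).index(self)

    @classmethod
    def parse(cls, name: str) -> "OutputFormat":
        try:
            return cls[name.upper()]
        except KeyError:
            raise ValueError(
                f"unknown output format {name!r}; choose from "
                f"{', '.join(f.value for f in cls)}"
            ) from None


DEFAULT_FORMAT = OutputFormat.MEDIUM


def render_block(record: SequenceRecord,
                 intervals: list[NoLSInterval],
                 segments: CandidateSegmentProfile | None = None,
                 fmt: OutputFormat = DEFAULT_FORMAT,
                 wrap: int = 60) -> str:
    """One report block for one sequence, per the format level.

    ``segments`` is required for FULL/COMPLETE (it supplies the
    per-residue score stream).
    """
    lines = [f"> {record.name}"]
    if fmt is OutputFormat.COMPLETE:
        for i in range(0, len(record.residues), wrap):
            lines.append(record.residues[i:i + wrap])
    lines.append(f"NOLS_segment_number: {len(intervals)}")
    if fmt.level >= OutputFormat.SHORT.level:
        lines.append("NOLS_segments_positions: "
                     + ", ".join(str(iv) for iv in intervals))
    if fmt.level >= OutputFormat.MEDIUM.level:
        lines.append("NOLS_segments: "
                     + ", ".join(iv.sequence for iv in intervals))
    if fmt.level >= OutputFormat.FULL.level:
        if segments is None:
            raise ValueError(f"{fmt.value} output requires the score profile")
        profile = residue_profile(segments, len(record.residues))
        lines.extend(f"{score:.2f}" for score in profile)
    return "\n".join(line.rstrip() for line in lines) + "\n"


def parse_positions_line(block: str) -> list[NoLSInterval]:
    """Recover the interval list from a SHORT-or-higher report block."""
    for line in block.splitlines():
        if line.startswith("NOLS_segments_positions:"):
            payload = line.split(":", 1)[1].strip()
            if not payload:
                return []
            out = []
            for token in payload.split(","):
                start, end = token.strip().split("-")
                out.append(NoLSInterval(int(start), int(end)))
            return out
    raise ValueError("no NOLS_segments_positions line in block")


def render_batch(results: list[tuple[SequenceRecord, list[NoLSInterval],
                                     CandidateSegmentProfile | None]],
                 fmt: OutputFormat = DEFAULT_FORMAT,
                 skip_negatives: bool = False) -> str:
    """Concatenate blocks in input order, optionally omitting negatives."""
    blocks = []
    for record, intervals, segments in results:
        if skip_negatives and not intervals:
            continue
        blocks.append(render_block(record, intervals, segments, fmt))
    return "".join(blocks)
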