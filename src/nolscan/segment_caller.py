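"""Segment calling: from per-window scores to predicted NoLS intervals.

A candidate segment spans 20 residues (13-residue window + 8 consecutive
windows - 1) and its score is the arithmetic mean of the 8 window scores
covering it. Segments scoring at least 0.8 are positive; maximal runs of
consecutive positive segment starts merge into one predicted interval, so
every called interval is at least 20 residues long and overlapping or
directly adjacent positive segments never produce duplicate calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import DEFAULT_PARAMETERS, Parameters
from .sequence_io import SequenceRecord


@dataclass(frozen=True)
class WindowScoreProfile:
    """Per-window scores aligned to window starts 1..L-12."""

    sequence_name: str
    length: int
    scores: tuple[float, ...]
    too_short: bool = False

    def __post_init__(self) -> None:
        expected = max(0, self.length - 12) if not self.too_short else 0
        if len(self.scores) != expected:
            raise ValueError(
                f"profile for {self.sequence_name!r}: expected {expected} "
                f"scores for length {self.length}, got {len(self.scores)}"
            )
        if any(not 0.0 <= s <= 1.0 for s in self.scores):
            raise ValueError("window scores must lie in [0, 1]")


@dataclass(frozen=True)
class CandidateSegmentProfile:
    """Mean-of-8-windows scores, one per 20-residue segment start."""

    sequence_name: str
    length: int
    segment_scores: tuple[float, ...]


@dataclass(frozen=True)
class NoLSInterval:
    """A 1-based inclusive residue range, optionally carrying its residues."""

    start: int
    end: int
    sequence: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid interval {self.start}-{self.end}")
        if self.sequence and len(self.sequence) != len(self):
            raise ValueError(
                f"interval {self.start}-{self.end} spans {len(self)} residues "
                f"but carries a {len(self.sequence)}-residue sequence"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        return f"{self.start}-{self.end}"


def candidate_scores(profile: WindowScoreProfile,
                     params: Parameters = DEFAULT_PARAMETERS
                     ) -> CandidateSegmentProfile:
    """Average each run of 8 consecutive window scores into a segment score.

    Defined only where all 8 windows exist; sequences shorter than 20
    residues yield an empty profile (no candidate segment possible).
    """
    k = params.consecutive_windows
    n_seg = max(0, len(profile.scores) - k + 1)
    if n_seg == 0:
        return CandidateSegmentProfile(profile.sequence_name, profile.length, ())
    s = np.asarray(profile.scores, dtype=np.float64)
    means = np.convolve(s, np.ones(k) / k, mode="valid")
    return CandidateSegmentProfile(
        profile.sequence_name, profile.length,
        tuple(float(m) for m in means),
    )


def call_nols(segments: CandidateSegmentProfile,
              record: SequenceRecord | None = None,
              params: Parameters = DEFAULT_PARAMETERS) -> list[NoLSInterval]:
    """Call NoLS intervals from candidate segment scores.

    Every segment scoring >= threshold (inclusive, "at least 0.8") is
    positive; a maximal run of positive starts a..b becomes the interval
    [a, b + 19]. Returns an empty list when nothing reaches threshold.
    """
    seg_len = params.segment_length
    positive = [i + 1 for i, s in enumerate(segments.segment_scores)
                if s >= params.score_threshold]
    intervals: list[NoLSInterval] = []
    cur: tuple[int, int] | None = None

    def flush() -> None:
        if cur is None:
            return
        seq = record.residues[cur[0] - 1:cur[1]] if record is not None else ""
        intervals.append(NoLSInterval(cur[0], cur[1], seq))

    for start in positive:
        end = start + seg_len - 1
        if cur is not None and start <= cur[1] + 1:  # overlap or touch
            cur = (cur[0], end)
        else:
            flush()
            cur = (start, end)
    flush()
    return intervals


def predict(record: SequenceRecord, model, structure: str | None = None,
            params: Parameters = DEFAULT_PARAMETERS
            ) -> tuple[list[NoLSInterval], CandidateSegmentProfile]:
    """Full pipeline for one record: score, average, call.

    Thin convenience over score_windows -> candidate_scores -> call_nols;
    returns the called intervals and the segment profile (for reporting).
    """
    from .neural_model import score_windows

    profile = score_windows(model, record, structure, params)
    segments = candidate_scores(profile, params)
    return call_nols(segments, record, params), segments


def residue_profile(segments: CandidateSegmentProfile,
                    length: int | None = None) -> list[float]:
    """Per-residue score list of exactly sequence length.

    Residue i (1 <= i <= L-19) takes the score of the segment starting at
    i; trailing residues repeat the final segment score so every residue
    has a value. Sequences too short for any segment get an all-zero
    profile (score undefined).
    """
    L = segments.length if length is None else length
    if not segments.segment_scores:
        return [0.0] * L
    scores = list(segments.segment_scores)
    return scores + [scores[-1]] * (L - len(scores))


def plot_profile(segments: CandidateSegmentProfile, params: Parameters
                 = DEFAULT_PARAMETERS, path: str | None = None):
    """Line chart of the 20-residue segment score per position, with the
    calling band (threshold..1) shaded as the NoLS candidate region.

    Requires matplotlib; returns the figure (also written to ``path`` as
    PNG/SVG when given).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    prof = residue_profile(segments)
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(range(1, len(prof) + 1), prof, lw=1.2)
    ax.axhspan(params.score_threshold, 1.0, color="pink", alpha=0.5,
               label="NoLS candidate segment region")
    ax.set_xlabel("residue position")
    ax.set_ylabel("mean NoLS window score")
    ax.set_ylim(0, 1.02)
    ax.set_title(segments.sequence_name)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
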