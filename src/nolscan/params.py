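"""Prediction and evaluation parameters.

The defaults are the published operating point of the NoLS detector:
13-residue windows over a 12-group reduced alphabet, a candidate segment
is 8 consecutive windows (20 residues), called when the mean window score
reaches 0.8, and benchmark matching requires the overlap to cover at least
60% of the shorter interval.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Parameters:
    """Operating parameters of the detector and its evaluation.

    Attributes
    ----------
    window_length:
        Residues per scored window (13).
    alphabet_size:
        Number of reduced amino-acid groups (12).
    consecutive_windows:
        Windows averaged into one candidate segment (8).
    score_threshold:
        Minimum mean window score for a segment to be called (0.8,
        inclusive).
    min_overlap_fraction:
        Fraction of the shorter interval that must be covered for a
        predicted/experimental pair to match (0.6).
    max_test_nols_length:
        Longest experimental NoLS admitted to benchmarking, inclusive
        residue length (50).
    strict_length_filter:
        If True, drop intervals of exactly ``max_test_nols_length``
        (strict "<" reading); default keeps them ("<=").
    """

    window_length: int = 13
    alphabet_size: int = 12
    consecutive_windows: int = 8
    score_threshold: float = 0.8
    min_overlap_fraction: float = 0.6
    max_test_nols_length: int = 50
    strict_length_filter: bool = False

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        if not 0.0 < self.score_threshold <= 1.0:
            raise ValueError("score_threshold must be in (0, 1]")
        if not 0.0 < self.min_overlap_fraction <= 1.0:
            raise ValueError("min_overlap_fraction must be in (0, 1]")

    @property
    def segment_length(self) -> int:
        """Residue span of one candidate segment (13 + 8 - 1 = 20)."""
        return self.window_length + self.consecutive_windows - 1


DEFAULT_PARAMETERS = Parameters()
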