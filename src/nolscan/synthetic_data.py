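"""Synthetic proteins with planted NoLS-like motifs.

Real NoLSs are short basic-residue-rich stretches; the generator mimics
that one property and nothing else: motif residues are drawn i.i.d. from
a lysine/arginine-enriched categorical distribution (K+R mass 0.55 by
default) planted into an i.i.d. background, with ground-truth intervals
returned alongside. This gives training, segment-calling and end-to-end
tests a fully deterministic, download-free corpus; it does not emulate
positional structure, secondary structure, or divergent (e.g.
trypanosome-style) targeting signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .segment_caller import NoLSInterval
from .sequence_io import SequenceRecord, write_fasta

#: Canonical residue order used for the categorical distributions.
RESIDUE_ORDER = "ACDEFGHIKLMNPQRSTVWY"


def _kr_enriched(kr_mass: float = 0.55) -> np.ndarray:
    """K/R get ``kr_mass`` total; the other 18 residues share the rest."""
    p = np.full(20, (1.0 - kr_mass) / 18.0)
    p[RESIDUE_ORDER.index("K")] = kr_mass * 0.55
    p[RESIDUE_ORDER.index("R")] = kr_mass * 0.45
    return p


@dataclass(frozen=True)
class MotifModel:
    """Distributions defining planted motifs and the background.

    Motif lengths are uniform on [min_length, max_length] residues;
    ``motif_probs``/``background_probs`` are categoricals over
    ``RESIDUE_ORDER``. Defaults: lengths 15-40, K+R mass 0.55 inside
    motifs, uniform background.
    """

    min_length: int = 15
    max_length: int = 40
    motif_probs: tuple[float, ...] = tuple(_kr_enriched())
    background_probs: tuple[float, ...] = tuple(np.full(20, 0.05))

    def __post_init__(self) -> None:
        if self.min_length < 13:
            raise ValueError("motif length must be >= 13 (one window)")
        if self.max_length < self.min_length:
            raise ValueError("max_length < min_length")
        for name in ("motif_probs", "background_probs"):
            p = np.asarray(getattr(self, name))
            if p.shape != (20,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a 20-residue distribution")

    @property
    def kr_motif_mass(self) -> float:
        i = (RESIDUE_ORDER.index("K"), RESIDUE_ORDER.index("R"))
        return self.motif_probs[i[0]] + self.motif_probs[i[1]]


DEFAULT_MOTIF_MODEL = MotifModel()


def _rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _draw(n: int, probs: Sequence[float], rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(RESIDUE_ORDER), size=n, p=list(probs)))


def generate_protein(length: int,
                     motif_model: MotifModel = DEFAULT_MOTIF_MODEL,
                     n_motifs: int = 1,
                     seed: Union[int, np.random.Generator] = 0,
                     name: str = "synthetic"
                     ) -> tuple[SequenceRecord, list[NoLSInterval]]:
    """One synthetic protein with ``n_motifs`` non-overlapping motifs.

    Background residues are drawn i.i.d. from the background
    distribution, motif residues from the motif distribution; returned
    intervals are the ground truth (1-based inclusive). Deterministic
    given the seed.

    Raises
    ------
    ValueError
        If the motifs cannot be placed without overlap.
    """
    if length < 20:
        raise ValueError("protein length must be >= 20")
    rng = _rng(seed)
    lengths = [int(rng.integers(motif_model.min_length,
                                motif_model.max_length + 1))
               for _ in range(n_motifs)]
    if sum(lengths) > length:
        raise ValueError(
            f"{n_motifs} motifs of total length {sum(lengths)} cannot fit "
            f"in a {length}-residue protein without overlap"
        )
    # rejection-sample non-overlapping placements
    starts: list[int] = []
    for _ in range(1000):
        cand = sorted(
            (int(rng.integers(1, length - ln + 2)), ln)
            for ln in lengths
        )
        if all(cand[i][0] + cand[i][1] <= cand[i + 1][0]
               for i in range(len(cand) - 1)):
            starts = cand
            break
    else:
        raise ValueError("could not place motifs without overlap")

    seq = list(_draw(length, motif_model.background_probs, rng))
    truth: list[NoLSInterval] = []
    for start, ln in starts:
        motif = _draw(ln, motif_model.motif_probs, rng)
        seq[start - 1:start - 1 + ln] = motif
        truth.append(NoLSInterval(start, start + ln - 1, motif))
    return SequenceRecord(name=name, residues="".join(seq)), truth


@dataclass(frozen=True)
class TrainingSet:
    """Labeled 13-mer window corpus with a flagged held-out split."""

    windows: tuple[str, ...]
    labels: tuple[int, ...]           # 1 = motif window, 0 = background
    heldout: tuple[bool, ...]

    def split(self) -> tuple[list[str], list[str], list[str], list[str]]:
        """(train positives, train negatives, heldout pos, heldout neg)."""
        tp = [w for w, y, h in zip(self.windows, self.labels, self.heldout)
              if y == 1 and not h]
        tn = [w for w, y, h in zip(self.windows, self.labels, self.heldout)
              if y == 0 and not h]
        hp = [w for w, y, h in zip(self.windows, self.labels, self.heldout)
              if y == 1 and h]
        hn = [w for w, y, h in zip(self.windows, self.labels, self.heldout)
              if y == 0 and h]
        return tp, tn, hp, hn


def generate_training_set(n_pos: int, n_neg: int,
                          motif_model: MotifModel = DEFAULT_MOTIF_MODEL,
                          seed: Union[int, np.random.Generator] = 0,
                          window_length: int = 13,
                          heldout_fraction: float = 0.2) -> TrainingSet:
    """Labeled window corpus mirroring positive/negative set construction.

    Positive windows are 13-mers sampled from within freshly drawn
    motifs; negative windows are sampled from background-only synthetic
    proteins. Class counts are exact; a ``heldout_fraction`` slice of
    each class is flagged held-out (never to be used for fitting).
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both class counts must be >= 1")
    rng = _rng(seed)
    positives: list[str] = []
    for _ in range(n_pos):
        ln = int(rng.integers(motif_model.min_length,
                              motif_model.max_length + 1))
        motif = _draw(ln, motif_model.motif_probs, rng)
        off = int(rng.integers(0, ln - window_length + 1))
        positives.append(motif[off:off + window_length])
    negatives: list[str] = []
    while len(negatives) < n_neg:
        prot = _draw(200, motif_model.background_probs, rng)
        for _ in range(10):
            if len(negatives) >= n_neg:
                break
            off = int(rng.integers(0, len(prot) - window_length + 1))
            negatives.append(prot[off:off + window_length])

    windows = (*positives, *negatives)
    labels = (1,) * n_pos + (0,) * n_neg
    n_hp = int(round(heldout_fraction * n_pos))
    n_hn = int(round(heldout_fraction * n_neg))
    hold_pos = rng.permutation(n_pos) < n_hp
    hold_neg = rng.permutation(n_neg) < n_hn
    heldout = tuple(bool(b) for b in (*hold_pos, *hold_neg))
    return TrainingSet(windows=windows, labels=labels, heldout=heldout)


def write_corpus(records: Sequence[SequenceRecord],
                 truths: Sequence[Sequence[NoLSInterval]],
                 fasta_path: Union[str, Path],
                 truth_path: Union[str, Path]) -> None:
    """Write generated proteins as FASTA plus a truth TSV (name, start, end)."""
    write_fasta(records, fasta_path)
    with open(truth_path, "w", encoding="utf-8") as fh:
        fh.write("name\tstart\tend\n")
        for rec, intervals in zip(records, truths):
            for iv in intervals:
                fh.write(f"{rec.name}\t{iv.start}\t{iv.end}\n")
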