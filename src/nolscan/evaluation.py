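"""Interval-overlap benchmarking of NoLS predictions.

An experimental NoLS counts as detected when some predicted interval
covers at least 60% of the shorter of the two; a predicted interval is a
true positive when it reaches that criterion against some experimental
NoLS in the same protein (many-to-many matching, no one-to-one
assignment). Specificity is per-protein: the fraction of proteins with no
false-positive predicted segment.

The package ships a benchmark of 31 experimentally determined NoLSs in 27
eukaryotic and viral proteins, together with the intervals reported by
the original human-trained NoD detector on those proteins, so the
published cross-species accuracy summary can be recomputed from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Sequence, Union

import pandas as pd

from .params import DEFAULT_PARAMETERS, Parameters
from .segment_caller import NoLSInterval

#: Display order of the benchmark's taxon / viral-host groups.
GROUP_ORDER = (
    "mammals", "amoeba", "molluscs", "trypanosomes", "plants",
    "viruses_mammalian_host", "viruses_plant_host",
    "viruses_avian_host", "viruses_fish_host",
)


@dataclass(frozen=True)
class EvaluationRecord:
    """One protein: experimental and predicted NoLS interval sets."""

    organism: str
    group: str
    protein_accession: str
    protein_name: str
    experimental_nols: tuple[NoLSInterval, ...]
    predicted_nols: tuple[NoLSInterval, ...] = ()

    def __post_init__(self) -> None:
        if not self.experimental_nols:
            raise ValueError(
                f"{self.protein_accession}: experimental NoLS list is empty"
            )


@dataclass(frozen=True)
class RecordClassification:
    """Per-record outcome of the overlap criterion."""

    detected: tuple[bool, ...]   # one flag per experimental NoLS
    is_tp: tuple[bool, ...]      # one flag per predicted interval

    @property
    def n_detected(self) -> int:
        return sum(self.detected)

    @property
    def n_missed(self) -> int:
        return len(self.detected) - self.n_detected

    @property
    def n_tp(self) -> int:
        return sum(self.is_tp)

    @property
    def n_fp(self) -> int:
        return len(self.is_tp) - self.n_tp

    @property
    def has_false_positive(self) -> bool:
        return self.n_fp > 0


def overlap_fraction(a: NoLSInterval, b: NoLSInterval) -> float:
    """|intersection| / min(|a|, |b|), with 1-based inclusive lengths.

    Symmetric; 1.0 whenever one interval contains the other; 0.0 when
    disjoint.
    """
    inter = min(a.end, b.end) - max(a.start, b.start) + 1
    if inter <= 0:
        return 0.0
    return inter / min(len(a), len(b))


def length_filter(interval: NoLSInterval,
                  params: Parameters = DEFAULT_PARAMETERS) -> bool:
    """Keep an experimental NoLS for benchmarking?

    The benchmark admits only short, confidently mapped NoLSs. Default is
    inclusive length <= 50; ``params.strict_length_filter`` switches to
    the strict "<" reading.
    """
    if params.strict_length_filter:
        return len(interval) < params.max_test_nols_length
    return len(interval) <= params.max_test_nols_length


def classify(record: EvaluationRecord,
             min_overlap: float = DEFAULT_PARAMETERS.min_overlap_fraction
             ) -> RecordClassification:
    """Apply the overlap criterion many-to-many within one protein."""
    detected = tuple(
        any(overlap_fraction(exp, pred) >= min_overlap
            for pred in record.predicted_nols)
        for exp in record.experimental_nols
    )
    is_tp = tuple(
        any(overlap_fraction(exp, pred) >= min_overlap
            for exp in record.experimental_nols)
        for pred in record.predicted_nols
    )
    return RecordClassification(detected=detected, is_tp=is_tp)


@dataclass
class MetricsTable:
    """Per-group and overall accuracy of NoLS predictions.

    ``frame`` holds raw fractions (one row per group, plus ``overall``):
    distinct_protein_count, nols_count, tp_count (detected experimental
    NoLSs), fp_count, sensitivity, ppv (NaN where no predictions exist),
    specificity. ``rounded`` / ``overall_percent`` give the conventional
    presentation (2 decimals per group, integer percent overall).
    """

    frame: pd.DataFrame

    @property
    def overall(self) -> pd.Series:
        return self.frame.loc["overall"]

    def rounded(self) -> pd.DataFrame:
        out = self.frame.copy()
        for col in ("sensitivity", "ppv", "specificity"):
            out[col] = out[col].round(2)
        return out

    def overall_percent(self) -> dict[str, float]:
        """Overall sensitivity/PPV/specificity as integer percentages."""
        row = self.overall
        return {
            k: round(100 * row[k])
            for k in ("sensitivity", "ppv", "specificity")
        }

    def to_tsv(self, sink: Union[str, Path, IO[str]]) -> None:
        self.frame.to_csv(sink, sep="\t", na_rep="N/A",
                          index_label="group", float_format="%.6g")


def _aggregate(records: Sequence[EvaluationRecord],
               classifications: Sequence[RecordClassification]) -> dict:
    proteins = {r.protein_accession for r in records}
    n_nols = sum(len(r.experimental_nols) for r in records)
    n_detected = sum(c.n_detected for c in classifications)
    n_tp_pred = sum(c.n_tp for c in classifications)
    n_fp = sum(c.n_fp for c in classifications)
    clean = sum(1 for c in classifications if not c.has_false_positive)
    n_pred = n_tp_pred + n_fp
    return {
        "distinct_protein_count": len(proteins),
        "nols_count": n_nols,
        "tp_count": n_detected,
        "fp_count": n_fp,
        "sensitivity": n_detected / n_nols if n_nols else float("nan"),
        "ppv": n_tp_pred / n_pred if n_pred else float("nan"),
        "specificity": clean / len(proteins),
    }


def compute_metrics(records: Sequence[EvaluationRecord],
                    min_overlap: float = DEFAULT_PARAMETERS.min_overlap_fraction,
                    params: Parameters = DEFAULT_PARAMETERS,
                    by: str = "group") -> MetricsTable:
    """Aggregate the overlap criterion into a per-group accuracy table.

    Experimental NoLSs failing :func:`length_filter` are excluded before
    matching. ``by`` selects the grouping key (``"group"`` or
    ``"organism"``); group rows appear in first-seen order (or
    ``GROUP_ORDER`` where applicable) followed by an ``overall`` row.
    Order of ``records`` does not affect any metric.
    """
    if not records:
        raise ValueError("no records to evaluate")
    filtered: list[EvaluationRecord] = []
    for r in records:
        kept = tuple(e for e in r.experimental_nols if length_filter(e, params))
        if not kept:
            continue
        filtered.append(EvaluationRecord(
            organism=r.organism, group=r.group,
            protein_accession=r.protein_accession, protein_name=r.protein_name,
            experimental_nols=kept, predicted_nols=r.predicted_nols,
        ))
    classifications = [classify(r, min_overlap) for r in filtered]

    keys = [getattr(r, by) for r in filtered]
    ordered: list[str] = [g for g in GROUP_ORDER if g in keys] if by == "group" \
        else []
    for k in keys:
        if k not in ordered:
            ordered.append(k)

    rows = {}
    for key in ordered:
        sel = [i for i, k in enumerate(keys) if k == key]
        rows[key] = _aggregate([filtered[i] for i in sel],
                               [classifications[i] for i in sel])
    rows["overall"] = _aggregate(filtered, classifications)
    return MetricsTable(frame=pd.DataFrame.from_dict(rows, orient="index"))


def _parse_interval(text: str) -> NoLSInterval:
    start, end = text.strip().split("-")
    return NoLSInterval(int(start), int(end))


def _parse_interval_list(text: str) -> tuple[NoLSInterval, ...]:
    text = text.strip()
    if not text:
        return ()
    return tuple(_parse_interval(t) for t in text.split(";"))


def load_benchmark(path: Union[str, Path, None] = None
                   ) -> list[EvaluationRecord]:
    """Load the packaged multi-organism NoLS benchmark.

    Returns one record per distinct protein (27 proteins, 31 experimental
    NoLSs, 28 predicted intervals). ``path`` overrides the packaged file
    with a TSV of the same layout: organism, group, accession, name,
    experimental ("start-end", one per row), predicted (";"-separated
    list, empty when the detector reported no NoLS).
    """
    if path is None:
        src = resources.files("nolscan.data").joinpath("nols_benchmark.tsv")
        df = pd.read_csv(src.open("r"), sep="\t", keep_default_na=False)
    else:
        df = pd.read_csv(path, sep="\t", keep_default_na=False)

    records: list[EvaluationRecord] = []
    by_acc: dict[str, dict] = {}
    for _, row in df.iterrows():
        acc = row["accession"]
        entry = by_acc.setdefault(acc, {
            "organism": row["organism"], "group": row["group"],
            "name": row["name"], "experimental": [],
            "predicted": _parse_interval_list(row["predicted"]),
        })
        entry["experimental"].append(_parse_interval(row["experimental"]))
        pred = _parse_interval_list(row["predicted"])
        if pred != entry["predicted"]:
            raise ValueError(
                f"{acc}: inconsistent predicted intervals across rows"
            )
    for acc, entry in by_acc.items():
        records.append(EvaluationRecord(
            organism=entry["organism"], group=entry["group"],
            protein_accession=acc, protein_name=entry["name"],
            experimental_nols=tuple(entry["experimental"]),
            predicted_nols=entry["predicted"],
        ))
    return records
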