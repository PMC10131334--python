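"""Directional log2 fold-change scoring against reference intervals.

A patient value above its upper reference bound is an increase, below the
lower bound a decrease, and anything in between (bounds included) is
unchanged.  The fold change is taken against the *violated* bound —
log2(value / upper) for increases, log2(value / lower) for decreases — so the
score is 0 exactly at the bound, continuous across it, and invariant under a
common rescaling of value and bounds.  Zero concentrations (patient or
reference) are disregarded rather than scored, because a fold change against
or from zero is undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .reference import (
    AgeCategory,
    PatientSample,
    ReferenceRangeTable,
)

__all__ = [
    "ChangeScore",
    "ScoreSet",
    "score_biomarker",
    "score_sample",
    "cap_scores",
    "filter_small_changes",
    "write_scores_tsv",
    "read_scores_tsv",
    "DEFAULT_CAP",
    "DEFAULT_SMALL_CHANGE_EPS",
]

DEFAULT_CAP = 3.0
DEFAULT_SMALL_CHANGE_EPS = 0.05

#: Statuses a biomarker can end up with after scoring.
STATUSES = ("scored", "unchanged", "no_reference", "zero_disregarded", "missing")


@dataclass(frozen=True)
class ChangeScore:
    """Scored change for one biomarker of one sample.

    ``direction`` is −1 / 0 / +1; ``log2fc`` is the uncapped fold change
    (None unless scored or unchanged); ``capped_log2fc`` clamps it to
    [−cap, +cap] for visualization and profile comparison.
    """

    chebi_id: str
    direction: int
    log2fc: float | None
    capped_log2fc: float | None
    status: str

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


def score_biomarker(
    value: float | None,
    lower: float,
    upper: float,
    chebi_id: str = "",
    cap: float = DEFAULT_CAP,
) -> ChangeScore:
    """Score one concentration against its reference interval.

    Rules: missing value → ``missing``; value of 0 or a violated bound of 0 →
    ``zero_disregarded``; in-range (bounds inclusive) → ``unchanged`` with
    log2fc 0; otherwise ``scored`` with log2fc against the violated bound.
    """
    if lower > upper:
        raise ValueError(f"{chebi_id}: lower {lower} > upper {upper}")
    if lower < 0:
        raise ValueError(f"{chebi_id}: negative lower bound")
    if value is None:
        return ChangeScore(chebi_id, 0, None, None, "missing")
    if value < 0:
        raise ValueError(f"{chebi_id}: negative concentration {value}")
    if value == 0:
        return ChangeScore(chebi_id, 0, None, None, "zero_disregarded")
    if value > upper:
        if upper == 0:
            return ChangeScore(chebi_id, 0, None, None, "zero_disregarded")
        fc = math.log2(value / upper)
        return ChangeScore(chebi_id, +1, fc, _clamp(fc, cap), "scored")
    if value < lower:
        # lower > value > 0 here, so the violated bound is strictly positive
        fc = math.log2(value / lower)
        return ChangeScore(chebi_id, -1, fc, _clamp(fc, cap), "scored")
    return ChangeScore(chebi_id, 0, 0.0, 0.0, "unchanged")


def _clamp(x: float, cap: float) -> float:
    return max(-cap, min(cap, x))


@dataclass
class ScoreSet:
    """All change scores for one patient sample, with panel bookkeeping."""

    patient_label: str
    age_months: int
    scores: list[ChangeScore]

    def __iter__(self):
        return iter(self.scores)

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def n_with_reference(self) -> int:
        """Measured biomarkers for which a reference interval was found."""
        return sum(s.status in ("scored", "unchanged", "zero_disregarded") for s in self.scores)

    @property
    def n_altered(self) -> int:
        """Biomarkers outside their reference interval."""
        return sum(s.direction != 0 for s in self.scores)

    @property
    def n_no_reference(self) -> int:
        return sum(s.status == "no_reference" for s in self.scores)

    def summary(self) -> dict[str, int]:
        return {
            "biomarkers_measured": len(self.scores),
            "biomarkers_with_reference": self.n_with_reference,
            "altered_biomarkers": self.n_altered,
            "no_reference": self.n_no_reference,
        }


def score_sample(
    sample: PatientSample,
    ranges: ReferenceRangeTable,
    categories: Sequence[AgeCategory] | None = None,
    cap: float = DEFAULT_CAP,
) -> ScoreSet:
    """Score every measured biomarker of a sample.

    The reference interval is looked up in the patient's specific age
    category, falling back to the overarching category; biomarkers with no
    interval in either get status ``no_reference``.
    """
    if categories is not None and tuple(categories) != ranges.categories:
        raise ValueError("categories disagree with the reference table's stratification")
    scores = []
    for chebi, value in sample.measurements.items():
        bounds = ranges.lookup(chebi, sample.age_months)
        if bounds is None:
            scores.append(ChangeScore(chebi, 0, None, None, "no_reference"))
        else:
            scores.append(score_biomarker(value, bounds[0], bounds[1], chebi, cap=cap))
    return ScoreSet(sample.label, sample.age_months, scores)


def cap_scores(
    scores: Iterable[ChangeScore], cap: float = DEFAULT_CAP
) -> list[ChangeScore]:
    """Clamp every log2FC to [−cap, +cap]; the raw log2fc is preserved."""
    if cap <= 0:
        raise ValueError(f"cap must be positive, got {cap}")
    out = []
    for s in scores:
        capped = None if s.log2fc is None else _clamp(s.log2fc, cap)
        out.append(replace(s, capped_log2fc=capped))
    return out


def filter_small_changes(
    scores: Iterable[ChangeScore], eps: float = DEFAULT_SMALL_CHANGE_EPS
) -> list[ChangeScore]:
    """Drop small changes (|log2FC| strictly below ``eps``) and all non-scored entries.

    Values exactly at ±eps are retained.  Unchanged, missing, unreferenced and
    zero-disregarded entries are removed as well: the result is the set of
    changes worth showing in an overlap visualization.
    """
    if eps < 0:
        raise ValueError(f"eps must be >= 0, got {eps}")
    return [
        s
        for s in scores
        if s.status == "scored" and s.log2fc is not None and not (-eps < s.log2fc < eps)
    ]


_SCORE_COLUMNS = ["biomarker_id", "direction", "log2fc", "capped_log2fc", "status"]


def write_scores_tsv(scores: Iterable[ChangeScore], path: str | Path) -> None:
    rows = [
        {
            "biomarker_id": s.chebi_id,
            "direction": s.direction,
            "log2fc": "" if s.log2fc is None else repr(s.log2fc),
            "capped_log2fc": "" if s.capped_log2fc is None else repr(s.capped_log2fc),
            "status": s.status,
        }
        for s in scores
    ]
    pd.DataFrame(rows, columns=_SCORE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_scores_tsv(path: str | Path) -> list[ChangeScore]:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"biomarker_id": str, "status": str},
        float_precision="round_trip",
    )
    out = []
    for _, row in df.iterrows():
        out.append(
            ChangeScore(
                chebi_id=row["biomarker_id"],
                direction=int(row["direction"]),
                log2fc=None if pd.isna(row["log2fc"]) else float(row["log2fc"]),
                capped_log2fc=None
                if pd.isna(row["capped_log2fc"])
                else float(row["capped_log2fc"]),
                status=row["status"],
            )
        )
    return out
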