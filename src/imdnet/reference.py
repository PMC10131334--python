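"""Patient panels, age-stratified reference intervals and identifier bookkeeping.

Clinical metabolite panels report concentrations in μmol/mmol creatinine and
patient age in months.  Biomarkers are keyed by ChEBI identifiers (Wikidata
QIDs where no ChEBI entry exists) and linked to HMDB accessions through a
curated mapping table.  Reference intervals are stratified into age
categories, with an overarching 0–16 y category used as a fallback whenever a
specific (biomarker, category) interval is missing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "BiomarkerAnnotation",
    "AnnotationRegistry",
    "AgeCategory",
    "DEFAULT_AGE_CATEGORIES",
    "validate_age_categories",
    "resolve_age_category",
    "load_age_categories",
    "ReferenceRangeTable",
    "PatientSample",
    "PanelLoadResult",
    "load_patient_samples",
    "write_patient_samples",
    "map_chebi_to_hmdb",
    "normalize_biomarker_id",
]

_CHEBI_RE = re.compile(r"^(?:CHEBI:)?(\d+)$", re.IGNORECASE)
_HMDB_RE = re.compile(r"^(?:HMDB)?(\d{4,7})$", re.IGNORECASE)
_WIKIDATA_RE = re.compile(r"^Q\d+$", re.IGNORECASE)


def normalize_biomarker_id(raw: str) -> str:
    """Normalize a biomarker identifier to a full CURIE.

    Bare numbers are taken as ChEBI accessions; ``Q``-prefixed identifiers
    as Wikidata QIDs.  Raises :class:`ValueError` for anything else.
    """
    token = str(raw).strip()
    if not token:
        raise ValueError("empty biomarker identifier")
    m = _CHEBI_RE.match(token)
    if m:
        return f"CHEBI:{m.group(1)}"
    if _WIKIDATA_RE.match(token):
        return token.upper()
    raise ValueError(f"unrecognized biomarker identifier: {raw!r}")


def normalize_hmdb_id(raw: str) -> str:
    """Normalize an HMDB accession to the 7-digit ``HMDB0000000`` form."""
    token = str(raw).strip()
    m = _HMDB_RE.match(token)
    if not m:
        raise ValueError(f"unrecognized HMDB identifier: {raw!r}")
    return f"HMDB{int(m.group(1)):07d}"


@dataclass(frozen=True)
class BiomarkerAnnotation:
    """Identifier bundle for one measurable metabolite.

    At least one of ``chebi_id`` / ``wikidata_id`` must be present; panels are
    annotated with ChEBI identifiers, or Wikidata QIDs when no ChEBI entry
    exists.
    """

    chebi_id: str | None
    hmdb_id: str | None = None
    wikidata_id: str | None = None
    display_name: str = ""

    def __post_init__(self) -> None:
        if not self.chebi_id and not self.wikidata_id:
            raise ValueError(
                f"annotation {self.display_name!r} needs a ChEBI or Wikidata ID"
            )

    @property
    def key(self) -> str:
        return self.chebi_id or self.wikidata_id  # type: ignore[return-value]


class AnnotationRegistry:
    """Collection of biomarker annotations keyed by primary (ChEBI) ID."""

    def __init__(self, annotations: Iterable[BiomarkerAnnotation] = ()) -> None:
        self._by_key: dict[str, BiomarkerAnnotation] = {}
        for ann in annotations:
            self.add(ann)

    def add(self, ann: BiomarkerAnnotation) -> None:
        if ann.key in self._by_key:
            raise ValueError(f"duplicate annotation for {ann.key}")
        self._by_key[ann.key] = ann

    def __contains__(self, key: str) -> bool:
        return key in self._by_key

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self):
        return iter(self._by_key.values())

    def get(self, key: str) -> BiomarkerAnnotation | None:
        return self._by_key.get(key)

    def hmdb_for(self, chebi_id: str) -> str | None:
        ann = self._by_key.get(chebi_id)
        return ann.hmdb_id if ann is not None else None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationRegistry":
        """Load a mapping TSV with columns chebi_id, hmdb_id, wikidata_id, name."""
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        reg = cls()
        for _, row in df.iterrows():
            chebi = normalize_biomarker_id(row["chebi_id"]) if row.get("chebi_id") else None
            hmdb = normalize_hmdb_id(row["hmdb_id"]) if row.get("hmdb_id") else None
            wikidata = row.get("wikidata_id") or None
            reg.add(
                BiomarkerAnnotation(
                    chebi_id=chebi,
                    hmdb_id=hmdb,
                    wikidata_id=wikidata,
                    display_name=row.get("name", ""),
                )
            )
        return reg

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "chebi_id": a.chebi_id or "",
                "hmdb_id": a.hmdb_id or "",
                "wikidata_id": a.wikidata_id or "",
                "name": a.display_name,
            }
            for a in sorted(self, key=lambda a: a.key)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def map_chebi_to_hmdb(chebi_id: str, mapping: AnnotationRegistry) -> str | None:
    """Total ChEBI→HMDB lookup: returns None for unmapped identifiers."""
    return mapping.hmdb_for(chebi_id)


@dataclass(frozen=True)
class AgeCategory:
    """Half-open age band [min, max) in months; ``max_months=None`` is open-ended."""

    label: str
    min_months: int
    max_months: int | None
    is_overarching: bool = False

    def __post_init__(self) -> None:
        if self.min_months < 0:
            raise ValueError(f"{self.label}: min_months must be >= 0")
        if self.max_months is not None and self.max_months <= self.min_months:
            raise ValueError(f"{self.label}: min must be < max")

    def contains(self, age_months: int) -> bool:
        if age_months < self.min_months:
            return False
        return self.max_months is None or age_months < self.max_months


#: Default stratification: four non-overlapping bands plus the overarching
#: 0–16 y fallback band used when a specific interval is missing.
DEFAULT_AGE_CATEGORIES: tuple[AgeCategory, ...] = (
    AgeCategory("0-1y", 0, 12),
    AgeCategory("1-5y", 12, 60),
    AgeCategory("5-16y", 60, 192),
    AgeCategory("16+y", 192, None),
    AgeCategory("0-16y", 0, 192, is_overarching=True),
)


def validate_age_categories(categories: Sequence[AgeCategory]) -> None:
    """Require exactly one overarching band and non-overlapping specific bands."""
    overarching = [c for c in categories if c.is_overarching]
    if len(overarching) != 1:
        raise ValueError(f"expected exactly 1 overarching category, got {len(overarching)}")
    specific = sorted(
        (c for c in categories if not c.is_overarching), key=lambda c: c.min_months
    )
    for a, b in zip(specific, specific[1:]):
        if a.max_months is None or b.min_months < a.max_months:
            raise ValueError(f"overlapping age categories: {a.label} and {b.label}")


def resolve_age_category(
    age_months: int, categories: Sequence[AgeCategory]
) -> AgeCategory:
    """Return the non-overarching category containing ``age_months``."""
    validate_age_categories(categories)
    for cat in categories:
        if not cat.is_overarching and cat.contains(age_months):
            return cat
    raise ValueError(f"age {age_months} months outside all age categories")


def overarching_category(categories: Sequence[AgeCategory]) -> AgeCategory:
    for cat in categories:
        if cat.is_overarching:
            return cat
    raise ValueError("no overarching age category defined")


def load_age_categories(path: str | Path) -> tuple[AgeCategory, ...]:
    """Read age categories from a YAML list of {label, min_months, max_months, overarching}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cats = tuple(
        AgeCategory(
            label=entry["label"],
            min_months=int(entry["min_months"]),
            max_months=None if entry.get("max_months") in (None, "") else int(entry["max_months"]),
            is_overarching=bool(entry.get("overarching", False)),
        )
        for entry in raw
    )
    validate_age_categories(cats)
    return cats


class ReferenceRangeTable:
    """Per-(biomarker, age category) lower/upper concentration bounds.

    Lookup first tries the patient's specific age category, then falls back to
    the overarching category.  Intervals with lower == upper are legal but
    flagged in :attr:`degenerate`.
    """

    def __init__(
        self,
        entries: Mapping[tuple[str, str], tuple[float, float]],
        categories: Sequence[AgeCategory] = DEFAULT_AGE_CATEGORIES,
    ) -> None:
        validate_age_categories(categories)
        self.categories = tuple(categories)
        self.entries: dict[tuple[str, str], tuple[float, float]] = {}
        self.degenerate: set[tuple[str, str]] = set()
        labels = {c.label for c in categories}
        for (chebi, label), (lo, hi) in entries.items():
            if label not in labels:
                raise ValueError(f"unknown age category label {label!r}")
            if lo < 0:
                raise ValueError(f"negative lower bound for {chebi}/{label}")
            if lo > hi:
                raise ValueError(f"lower > upper for {chebi}/{label}")
            if lo == hi:
                self.degenerate.add((chebi, label))
            self.entries[(chebi, label)] = (float(lo), float(hi))

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, chebi_id: str, age_months: int) -> tuple[float, float] | None:
        """Bounds for a biomarker at an age, falling back to the overarching band."""
        specific = resolve_age_category(age_months, self.categories)
        hit = self.entries.get((chebi_id, specific.label))
        if hit is not None:
            return hit
        fallback = overarching_category(self.categories)
        return self.entries.get((chebi_id, fallback.label))

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        categories: Sequence[AgeCategory] = DEFAULT_AGE_CATEGORIES,
    ) -> "ReferenceRangeTable":
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"biomarker_id": str, "age_category_label": str},
            float_precision="round_trip",
        )
        entries = {}
        for _, row in df.iterrows():
            key = (normalize_biomarker_id(row["biomarker_id"]), row["age_category_label"])
            if key in entries:
                raise ValueError(f"duplicate reference entry for {key}")
            entries[key] = (float(row["lower"]), float(row["upper"]))
        return cls(entries, categories)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            # repr keeps the shortest exact decimal form so re-reading is lossless
            {"biomarker_id": chebi, "age_category_label": label, "lower": repr(lo), "upper": repr(hi)}
            for (chebi, label), (lo, hi) in sorted(self.entries.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class PatientSample:
    """One patient's panel: measurements in μmol/mmol creatinine, age in months.

    Missing measurements are kept as ``None`` (never coerced to 0); zeros are
    legal here and handled downstream by the scoring rules.
    """

    label: str
    age_months: int
    measurements: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chebi, value in self.measurements.items():
            if value is not None and value < 0:
                raise ValueError(f"{self.label}/{chebi}: negative concentration")


@dataclass
class PanelLoadResult:
    """Samples plus a report of biomarker IDs absent from the registry."""

    samples: list[PatientSample]
    unknown_ids: dict[str, list[str]] = field(default_factory=dict)  # chebi -> patient labels

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)


_LONG_COLUMNS = ["patient_label", "age_months", "biomarker_id", "concentration"]


def load_patient_samples(
    path: str | Path, registry: AnnotationRegistry | None = None
) -> PanelLoadResult:
    """Read a patient panel TSV (long or wide layout).

    Long layout: columns patient_label, age_months, biomarker_id,
    concentration (empty cell = missing).  Wide layout: patient_label,
    age_months, then one column per biomarker ID.  Unknown biomarker IDs are
    retained on the samples and collected into ``unknown_ids`` — never dropped
    silently.  Duplicate (patient, biomarker) rows are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if cols[:2] != ["patient_label", "age_months"]:
        raise ValueError(
            f"{path}: first two columns must be patient_label, age_months (got {cols[:2]})"
        )
    if cols == _LONG_COLUMNS:
        long = df
    else:  # wide: remaining headers are biomarker IDs
        long = df.melt(
            id_vars=["patient_label", "age_months"],
            var_name="biomarker_id",
            value_name="concentration",
        )

    samples: dict[str, PatientSample] = {}
    unknown: dict[str, list[str]] = {}
    for i, row in long.iterrows():
        label = str(row["patient_label"])
        try:
            chebi = normalize_biomarker_id(row["biomarker_id"])
        except ValueError as exc:
            raise ValueError(f"{path} row {i}: {exc}") from exc
        raw = row["concentration"]
        value = None if (pd.isna(raw) or str(raw).strip() == "") else float(raw)
        sample = samples.get(label)
        if sample is None:
            sample = samples[label] = PatientSample(label, int(row["age_months"]))
        elif sample.age_months != int(row["age_months"]):
            raise ValueError(f"{path}: inconsistent age for patient {label}")
        if chebi in sample.measurements:
            raise ValueError(f"{path}: duplicate measurement ({label}, {chebi})")
        if value is not None and value < 0:
            raise ValueError(f"{path} row {i}: negative concentration")
        sample.measurements[chebi] = value
        if registry is not None and chebi not in registry:
            unknown.setdefault(chebi, []).append(label)
    return PanelLoadResult(list(samples.values()), unknown)


def write_patient_samples(samples: Iterable[PatientSample], path: str | Path) -> None:
    """Write samples in the long TSV layout; missing values become empty cells."""
    rows = []
    for sample in samples:
        for chebi, value in sample.measurements.items():
            rows.append(
                {
                    "patient_label": sample.label,
                    "age_months": sample.age_months,
                    "biomarker_id": chebi,
                    "concentration": "" if value is None else repr(value),
                }
            )
    pd.DataFrame(rows, columns=_LONG_COLUMNS).to_csv(path, sep="\t", index=False)
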