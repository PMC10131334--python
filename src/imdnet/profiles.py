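"""Theoretical disease biomarker profiles on the ordinal −3…+3 scale.

Databases of inborn errors of metabolism annotate expected biomarker changes
qualitatively with arrow glyphs (↑↑↑ for a strong increase, ↓ for a mild
decrease, ranges like ↑-↑↑, and "n" for normal).  These are converted to a
fixed ordinal scale so patient fold-change profiles and theoretical disease
profiles can be compared numerically.  Profiles are keyed by HGNC gene
symbol, carry HMDB biomarker accessions, and are stratified by age category
and sample matrix (urine here).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .reference import normalize_hmdb_id

__all__ = [
    "ORDINAL_VALUES",
    "ARROW_TO_ORDINAL",
    "parse_arrow",
    "DiseaseProfile",
    "load_profiles",
    "write_profiles",
    "DiseaseBiomarkerMatrix",
    "build_matrix",
]

#: The only legal cell values of a disease×biomarker matrix.
ORDINAL_VALUES = frozenset(
    (-3.0, -2.5, -2.0, -1.5, -1.0, 0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
)

#: Arrow-glyph → ordinal conversion table (14 tokens).  Range tokens use an
#: ASCII hyphen after normalization; "n to 1"/"n to 2" are opaque tokens kept
#: at their printed values.
ARROW_TO_ORDINAL: dict[str, float] = {
    "↑↑↑": 3.0,
    "↑↑": 2.0,
    "↑": 1.0,
    "↑-↑↑": 1.5,
    "↑↑-↑↑↑": 2.5,
    "n to 1": 0.5,
    "n to 2": 1.5,
    "↓↓↓": -3.0,
    "↓↓": -2.0,
    "↓": -1.0,
    "↓-↓↓": -1.5,
    "↓↓-↓↓↓": -2.5,
    "n": 0.0,
    "+ -": 0.0,
}

_WS_RE = re.compile(r"\s+")


def _normalize_token(notation: str) -> str:
    # trim, collapse internal whitespace, unify unicode minus with hyphen
    token = _WS_RE.sub(" ", str(notation).strip())
    token = token.replace("−", "-")  # −
    token = token.replace(" - ", "-").replace("- ", "-").replace(" -", "-")
    # "+-" / "+ -" variants all mean "normal"; keep canonical spaced form
    if token in ("+-", "+ -"):
        return "+ -"
    return token


def parse_arrow(notation: str) -> float:
    """Convert one arrow-notation token to its ordinal value.

    Unrecognized tokens raise :class:`ValueError` naming the token — a glyph
    outside the conversion table must never silently become 0.
    """
    token = _normalize_token(notation)
    try:
        return ARROW_TO_ORDINAL[token]
    except KeyError:
        raise ValueError(f"unrecognized biomarker change notation: {notation!r}") from None


@dataclass
class DiseaseProfile:
    """Theoretical biomarker changes for one disorder.

    ``markers`` maps age-category label → {hmdb_id → ordinal value}.
    """

    gene_symbol: str
    disorder_name: str = ""
    omim_id: str | None = None
    matrix_type: str = "urine"
    markers: dict[str, dict[str, float]] = field(default_factory=dict)

    def markers_for(self, age_label: str) -> dict[str, float]:
        return self.markers.get(age_label, {})


_PROFILE_COLUMNS = [
    "gene",
    "disorder",
    "omim",
    "matrix",
    "age_category",
    "hmdb_id",
    "notation",
]


def load_profiles(
    path: str | Path, matrix_type: str | None = "urine"
) -> list[DiseaseProfile]:
    """Load disease profiles from TSV, parsing arrows and validating numerics.

    The ``notation`` column holds either an arrow token or a pre-converted
    numeric value; numerics outside the ordinal set and unknown tokens raise
    with a row reference.  Rows whose sample matrix differs from
    ``matrix_type`` are excluded (pass ``None`` to keep all).  Duplicate
    (gene, biomarker, age category) rows are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    profiles: dict[str, DiseaseProfile] = {}
    seen: set[tuple[str, str, str]] = set()
    for i, row in df.iterrows():
        if matrix_type is not None and row["matrix"] != matrix_type:
            continue
        gene = row["gene"]
        hmdb = normalize_hmdb_id(row["hmdb_id"])
        age = row["age_category"]
        key = (gene, hmdb, age)
        if key in seen:
            raise ValueError(f"{path} row {i}: duplicate profile entry {key}")
        seen.add(key)
        raw = row["notation"].strip()
        try:
            value = float(raw.replace("−", "-"))
        except ValueError:
            try:
                value = parse_arrow(raw)
            except ValueError as exc:
                raise ValueError(f"{path} row {i}: {exc}") from None
        else:
            if value not in ORDINAL_VALUES:
                raise ValueError(
                    f"{path} row {i}: numeric value {value} outside the ordinal scale"
                )
        profile = profiles.get(gene)
        if profile is None:
            profile = profiles[gene] = DiseaseProfile(
                gene_symbol=gene,
                disorder_name=row["disorder"],
                omim_id=row["omim"] or None,
                matrix_type=row["matrix"],
            )
        profile.markers.setdefault(age, {})[hmdb] = value
    return list(profiles.values())


def write_profiles(profiles: Iterable[DiseaseProfile], path: str | Path) -> None:
    """Serialize profiles as TSV with numeric (pre-converted) notation cells."""
    rows = []
    for p in sorted(profiles, key=lambda p: p.gene_symbol):
        for age in sorted(p.markers):
            for hmdb, value in sorted(p.markers[age].items()):
                rows.append(
                    {
                        "gene": p.gene_symbol,
                        "disorder": p.disorder_name,
                        "omim": p.omim_id or "",
                        "matrix": p.matrix_type,
                        "age_category": age,
                        "hmdb_id": hmdb,
                        "notation": value,
                    }
                )
    pd.DataFrame(rows, columns=_PROFILE_COLUMNS).to_csv(path, sep="\t", index=False)


@dataclass
class DiseaseBiomarkerMatrix:
    """Disease × biomarker ordinal matrix for one age category.

    Rows are HGNC gene symbols, columns HMDB accessions sorted
    lexicographically (so serializations are byte-stable); cells default to 0
    for biomarkers a disorder does not list, which keeps Euclidean distances
    defined on the full column set.
    """

    data: pd.DataFrame
    age_category: str

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def biomarkers(self) -> list[str]:
        return list(self.data.columns)

    def row(self, gene: str) -> pd.Series:
        return self.data.loc[gene]

    def to_tsv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene")
        if sidecar is not None:
            with open(sidecar, "w") as fh:
                json.dump(
                    {
                        "age_category": self.age_category,
                        "n_diseases": len(self.genes),
                        "n_biomarkers": len(self.biomarkers),
                    },
                    fh,
                    indent=2,
                )

    @classmethod
    def from_tsv(cls, path: str | Path, age_category: str) -> "DiseaseBiomarkerMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene")
        return cls(df.astype(float), age_category)


def build_matrix(
    profiles: Sequence[DiseaseProfile], age_category: str
) -> DiseaseBiomarkerMatrix:
    """Assemble the disease×biomarker matrix for one age category.

    Disorders without any biomarker data for the category are dropped; the
    column set is the union of biomarkers across the retained disorders.
    """
    if not profiles:
        raise ValueError("empty profile collection")
    retained = [p for p in profiles if p.markers_for(age_category)]
    if not retained:
        raise ValueError(f"no disorder has biomarker data for category {age_category!r}")
    columns = sorted({h for p in retained for h in p.markers_for(age_category)})
    rows = {
        p.gene_symbol: [p.markers_for(age_category).get(h, 0.0) for h in columns]
        for p in retained
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=columns, dtype=float)
    bad = set(df.values.ravel()) - ORDINAL_VALUES
    if bad:
        raise ValueError(f"matrix cells outside the ordinal scale: {sorted(bad)}")
    return DiseaseBiomarkerMatrix(df, age_category)
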