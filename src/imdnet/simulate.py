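"""Synthetic study generator with known ground truth.

Emulates the structure of a targeted urine-metabolomics study of inherited
metabolic disorders: a panel of ~88 biomarkers, age-stratified reference
intervals with an overarching 0–16 y fallback, small annotated pathway
models (a linear degradation chain, a branched chain and a cycle, plus a
biomarker-collection pathway), and patients whose impaired enzyme causes
substrate accumulation upstream of the block and product depletion
downstream of it.

The disease mechanism is multiplicative on concentration: a severity ``s``
shifts the direct substrate's mean by ``+s`` on the log2 scale relative to
its upper reference bound (one step further upstream by ``+s/2``) and the
direct product by ``−s`` relative to the lower bound (one step downstream by
``−s/2``).  Measurement noise is log-normal (Gaussian with sd ``noise_sd``
on the log2 scale), matching the fold-change semantics of the scoring model.
Unrelated markers are drawn at the geometric mid-point of their reference
interval, so with no noise they are exactly unchanged.

Everything is deterministic under ``SimulationConfig.seed``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from math import sqrt
from pathlib import Path
from typing import Sequence

import numpy as np

from .pathways import Interaction, PathwayModel, write_gpml, write_pathway_json
from .profiles import ORDINAL_VALUES, DiseaseProfile, write_profiles
from .reference import (
    DEFAULT_AGE_CATEGORIES,
    AgeCategory,
    AnnotationRegistry,
    BiomarkerAnnotation,
    PatientSample,
    ReferenceRangeTable,
    write_patient_samples,
)

__all__ = [
    "DiseaseSpec",
    "SimulationConfig",
    "GroundTruth",
    "SyntheticStudy",
    "generate_pathway_fixtures",
    "generate_reference_ranges",
    "generate_mapping",
    "generate_profiles_from_truth",
    "simulate_patient",
    "round_to_ordinal",
]

_CHEBI_BASE = 900001
_HMDB_BASE = 900001


@dataclass(frozen=True)
class DiseaseSpec:
    """A simulated disorder: one impaired enzyme with a severity multiplier.

    ``severity`` is the log2-scale shift applied to the direct substrate of
    the impaired reaction (2.0 ⇒ the substrate sits 4-fold above its upper
    reference bound before noise).
    """

    gene: str
    enzyme: str
    severity: float = 2.0
    omim_id: str | None = None

    def __post_init__(self) -> None:
        if self.severity <= 0:
            raise ValueError("severity must be > 0")


def _default_diseases() -> tuple[DiseaseSpec, ...]:
    return tuple(
        DiseaseSpec(gene=enz, enzyme=enz, severity=2.0, omim_id=omim)
        for enz, omim in (
            ("ENZA2", "OMIM:910002"),
            ("ENZA3", "OMIM:910003"),
            ("ENZB1", "OMIM:920001"),
            ("ENZB2", "OMIM:920002"),
            ("ENZC2", "OMIM:930002"),
            ("ENZC4", "OMIM:930004"),
        )
    )


@dataclass
class SimulationConfig:
    """Study-shaped defaults: 88 markers, 6 disorders, 16-patient cohort."""

    n_markers: int = 88
    age_categories: tuple[AgeCategory, ...] = DEFAULT_AGE_CATEGORIES
    diseases: tuple[DiseaseSpec, ...] = field(default_factory=_default_diseases)
    noise_sd: float = 0.1
    seed: int = 0
    ref_dropout: float = 0.1
    lower_factor: float = 0.5
    upper_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_markers < 14:
            raise ValueError("need at least 14 markers to populate the pathway fixtures")
        if not 0 <= self.ref_dropout < 1:
            raise ValueError("ref_dropout must be in [0, 1)")


def _chebi(i: int) -> str:
    return f"CHEBI:{_CHEBI_BASE + i}"


def _hmdb(i: int) -> str:
    return f"HMDB{_HMDB_BASE + i:07d}"


def marker_ids(config: SimulationConfig) -> list[str]:
    return [_chebi(i) for i in range(config.n_markers)]


def generate_pathway_fixtures(config: SimulationConfig) -> list[PathwayModel]:
    """Build the four fixture pathways over the first 14 panel markers.

    WPSYN1: linear chain m0→m1→m2→m3→m4 (enzymes ENZA1..ENZA4).
    WPSYN2: branched chain m5→m6, m6→m7, m6→m8 (ENZB1..ENZB3).
    WPSYN3: five-metabolite cycle c0→…→c4→c0 (ENZC1..ENZC5).
    WPSYN0: a biomarker-collection pathway holding a subset of the others'
    metabolites (no reactions), emulating overlapping pathway content.
    """
    m = marker_ids(config)

    def chain_model(pid, title, mets, enzymes, edges, prefix, omims):
        proteins = {(e, f"P{prefix}{i:03d}") for i, e in enumerate(enzymes, start=1)}
        interactions = [
            Interaction(
                substrates=(sub,),
                products=(prod,),
                catalysts=(enz,),
                rhea_id=f"RHEA:{50000 + abs(zlib.crc32((pid + enz).encode())) % 9999}",
                directed=True,
            )
            for sub, prod, enz in edges
        ]
        return PathwayModel(
            pathway_id=pid,
            title=title,
            metabolite_nodes=set(mets),
            protein_nodes=proteins,
            interactions=interactions,
            disorders=set(omims),
            metabolite_labels={c: f"metabolite {c.split(':')[1]}" for c in mets},
        )

    chain = chain_model(
        "WPSYN1",
        "Synthetic degradation chain",
        m[0:5],
        [f"ENZA{i}" for i in range(1, 5)],
        [(m[i], m[i + 1], f"ENZA{i + 1}") for i in range(4)],
        "A",
        ["OMIM:910002", "OMIM:910003"],
    )
    branched = chain_model(
        "WPSYN2",
        "Synthetic branched pathway",
        m[5:9],
        [f"ENZB{i}" for i in range(1, 4)],
        [(m[5], m[6], "ENZB1"), (m[6], m[7], "ENZB2"), (m[6], m[8], "ENZB3")],
        "B",
        ["OMIM:920001", "OMIM:920002"],
    )
    c = m[9:14]
    cycle = chain_model(
        "WPSYN3",
        "Synthetic metabolic cycle",
        c,
        [f"ENZC{i}" for i in range(1, 6)],
        [(c[i], c[(i + 1) % 5], f"ENZC{i + 1}") for i in range(5)],
        "C",
        ["OMIM:930002", "OMIM:930004"],
    )
    hub = PathwayModel(
        pathway_id="WPSYN0",
        title="Synthetic biomarker collection",
        metabolite_nodes={m[0], m[2], m[5], m[7], m[9], m[11]},
        metabolite_labels={k: f"metabolite {k.split(':')[1]}" for k in (m[0], m[2], m[5], m[7], m[9], m[11])},
    )
    return [hub, chain, branched, cycle]


def generate_mapping(config: SimulationConfig) -> AnnotationRegistry:
    """ChEBI→HMDB mapping covering every synthetic panel marker."""
    reg = AnnotationRegistry()
    for i in range(config.n_markers):
        reg.add(
            BiomarkerAnnotation(
                chebi_id=_chebi(i),
                hmdb_id=_hmdb(i),
                display_name=f"synthetic metabolite {i + 1:03d}",
            )
        )
    return reg


def generate_reference_ranges(config: SimulationConfig) -> ReferenceRangeTable:
    """Age-stratified intervals: lower = baseline/2, upper = baseline×2.

    A fraction ``ref_dropout`` of (marker, specific category) entries is
    omitted to exercise the overarching fallback; the overarching entry is
    always present.
    """
    rng = np.random.default_rng([config.seed, 1])
    entries: dict[tuple[str, str], tuple[float, float]] = {}
    specific = [c for c in config.age_categories if not c.is_overarching]
    overarching = [c for c in config.age_categories if c.is_overarching][0]
    for i in range(config.n_markers):
        chebi = _chebi(i)
        baseline = float(2.0 ** rng.uniform(-1.0, 7.0))
        bounds = (baseline * config.lower_factor, baseline * config.upper_factor)
        entries[(chebi, overarching.label)] = bounds
        for cat in specific:
            if rng.uniform() >= config.ref_dropout:
                entries[(chebi, cat.label)] = bounds
    return ReferenceRangeTable(entries, config.age_categories)


@dataclass
class GroundTruth:
    """What a simulated patient was generated from."""

    gene: str
    pathway_id: str
    shifts: dict[str, float]  # chebi -> log2 mean shift against the violated bound

    @property
    def directions(self) -> dict[str, int]:
        return {c: (1 if s > 0 else -1) for c, s in self.shifts.items()}


def _shifts_for(
    disease: DiseaseSpec, pathways: Sequence[PathwayModel]
) -> tuple[str, dict[str, float]]:
    """Log2 shifts implied by an impaired enzyme: substrates and one step
    upstream accumulate, products and one step downstream deplete."""
    for pw in pathways:
        if disease.enzyme not in pw.protein_symbols:
            continue
        preds: dict[str, set[str]] = {}
        succs: dict[str, set[str]] = {}
        for ix in pw.interactions:
            for sub in ix.substrates:
                for prod in ix.products:
                    succs.setdefault(sub, set()).add(prod)
                    preds.setdefault(prod, set()).add(sub)
        shifts: dict[str, float] = {}

        def put(chebi: str, value: float) -> None:
            if abs(value) > abs(shifts.get(chebi, 0.0)):
                shifts[chebi] = value

        s = disease.severity
        for ix in pw.interactions:
            if disease.enzyme not in ix.catalysts:
                continue
            for sub in ix.substrates:
                put(sub, +s)
                for up in preds.get(sub, ()):
                    put(up, +s / 2)
            for prod in ix.products:
                put(prod, -s)
                for down in succs.get(prod, ()):
                    put(down, -s / 2)
        # the block's own substrate/product take precedence over neighbor shifts
        for ix in pw.interactions:
            if disease.enzyme in ix.catalysts:
                for sub in ix.substrates:
                    shifts[sub] = +s
                for prod in ix.products:
                    shifts[prod] = -s
        return pw.pathway_id, shifts
    raise ValueError(f"impaired enzyme {disease.enzyme} not found in any fixture pathway")


def round_to_ordinal(x: float) -> float:
    """Nearest value on the ordinal −3…+3 scale (ties toward larger magnitude)."""
    x = max(-3.0, min(3.0, x))
    return min(sorted(ORDINAL_VALUES), key=lambda v: (abs(v - x), -abs(v)))


class SyntheticStudy:
    """Bundle of all fixtures generated from one configuration."""

    def __init__(self, config: SimulationConfig | None = None) -> None:
        self.config = config or SimulationConfig()
        self.pathways = generate_pathway_fixtures(self.config)
        self.mapping = generate_mapping(self.config)
        self.ranges = generate_reference_ranges(self.config)
        self._truths = {
            d.gene: _shifts_for(d, self.pathways) for d in self.config.diseases
        }

    def disease(self, gene: str) -> DiseaseSpec:
        for d in self.config.diseases:
            if d.gene == gene:
                return d
        raise ValueError(f"unknown disease gene {gene!r}")

    def ground_truth(self, gene: str) -> GroundTruth:
        pathway_id, shifts = self._truths[self.disease(gene).gene]
        return GroundTruth(gene=gene, pathway_id=pathway_id, shifts=dict(shifts))

    def simulate_patient(
        self,
        gene: str,
        label: str = "sim",
        age_months: int = 30,
        rng: np.random.Generator | None = None,
    ) -> tuple[PatientSample, GroundTruth]:
        """Draw one noisy patient panel for a disorder.

        With ``noise_sd == 0`` the direct substrate's log2FC against its upper
        bound equals the severity exactly, and unrelated markers are exactly
        unchanged.
        """
        truth = self.ground_truth(gene)
        if rng is None:
            rng = np.random.default_rng(
                [self.config.seed, 2, zlib.crc32(f"{gene}|{label}".encode())]
            )
        measurements: dict[str, float | None] = {}
        for chebi in marker_ids(self.config):
            bounds = self.ranges.lookup(chebi, age_months)
            assert bounds is not None  # overarching entries are always generated
            lower, upper = bounds
            eps = rng.normal(0.0, self.config.noise_sd) if self.config.noise_sd else 0.0
            shift = truth.shifts.get(chebi)
            if shift is None:
                value = sqrt(lower * upper) * 2.0**eps
            elif shift > 0:
                value = upper * 2.0 ** (shift + eps)
            else:
                value = lower * 2.0 ** (shift + eps)
            measurements[chebi] = value
        return PatientSample(label, age_months, measurements), truth

    def simulate_cohort(
        self, per_disease: Sequence[int] = (1, 4, 5, 1, 1, 4)
    ) -> list[tuple[PatientSample, GroundTruth]]:
        """Cohort shaped like the study: 16 patients over 6 disorders and 4 age bands."""
        if len(per_disease) != len(self.config.diseases):
            raise ValueError("per_disease must give one count per configured disease")
        ages = [6, 30, 100, 200]  # one representative age per band
        out = []
        n = 0
        for disease, count in zip(self.config.diseases, per_disease):
            for _ in range(count):
                out.append(
                    self.simulate_patient(
                        disease.gene, label=f"P{n + 1:02d}", age_months=ages[n % 4]
                    )
                )
                n += 1
        return out

    def profiles(self) -> list[DiseaseProfile]:
        return generate_profiles_from_truth(self.config, study=self)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the full study as TSV/JSON/GPML; byte-identical under one seed."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "pathways").mkdir(exist_ok=True)
        paths: dict[str, Path] = {}

        cohort = self.simulate_cohort()
        paths["patients"] = outdir / "patients.tsv"
        write_patient_samples([s for s, _ in cohort], paths["patients"])
        paths["ranges"] = outdir / "ranges.tsv"
        self.ranges.to_tsv(paths["ranges"])
        paths["mapping"] = outdir / "mapping.tsv"
        self.mapping.to_tsv(paths["mapping"])
        paths["profiles"] = outdir / "profiles.tsv"
        write_profiles(self.profiles(), paths["profiles"])
        paths["truth"] = outdir / "ground_truth.tsv"
        with open(paths["truth"], "w") as fh:
            fh.write("patient_label\tgene\tpathway_id\n")
            for sample, truth in cohort:
                fh.write(f"{sample.label}\t{truth.gene}\t{truth.pathway_id}\n")
        for pw in self.pathways:
            write_pathway_json(pw, outdir / "pathways" / f"{pw.pathway_id}.json")
            write_gpml(pw, outdir / "pathways" / f"{pw.pathway_id}.gpml")
        return paths


def simulate_patient(
    gene: str,
    config: SimulationConfig | None = None,
    label: str = "sim",
    age_months: int = 30,
) -> tuple[PatientSample, GroundTruth]:
    """Convenience wrapper building a fresh :class:`SyntheticStudy`."""
    return SyntheticStudy(config).simulate_patient(gene, label=label, age_months=age_months)


def generate_profiles_from_truth(
    config: SimulationConfig | None = None, study: SyntheticStudy | None = None
) -> list[DiseaseProfile]:
    """Theoretical profiles listing each disorder's truly affected markers.

    Ordinal values are the simulated log2 mean shifts rounded to the ordinal
    scale; the same profile is listed for every specific age category.
    """
    study = study or SyntheticStudy(config)
    specific = [c.label for c in study.config.age_categories if not c.is_overarching]
    profiles = []
    for disease in study.config.diseases:
        truth = study.ground_truth(disease.gene)
        by_hmdb = {
            study.mapping.hmdb_for(chebi): round_to_ordinal(shift)
            for chebi, shift in truth.shifts.items()
        }
        profiles.append(
            DiseaseProfile(
                gene_symbol=disease.gene,
                disorder_name=f"{disease.gene} deficiency (synthetic)",
                omim_id=disease.omim_id,
                matrix_type="urine",
                markers={label: dict(by_hmdb) for label in specific},
            )
        )
    return profiles
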