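"""Panel loading, age-category resolution and identifier mapping."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imdnet.reference import (
    DEFAULT_AGE_CATEGORIES,
    AgeCategory,
    AnnotationRegistry,
    BiomarkerAnnotation,
    ReferenceRangeTable,
    load_patient_samples,
    map_chebi_to_hmdb,
    normalize_biomarker_id,
    resolve_age_category,
    validate_age_categories,
    write_patient_samples,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestIdentifiers:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("CHEBI:17368", "CHEBI:17368"),
            ("17368", "CHEBI:17368"),
            ("chebi:42", "CHEBI:42"),
            ("Q12345", "Q12345"),
        ],
    )
    def test_normalization_to_curie(self, raw, expected):
        assert normalize_biomarker_id(raw) == expected

    @pytest.mark.parametrize("raw", ["", "HMDB0000076x", "uracil", "CHEBI:"])
    def test_malformed_ids_rejected(self, raw):
        with pytest.raises(ValueError):
            normalize_biomarker_id(raw)

    def test_annotation_requires_chebi_or_wikidata(self):
        with pytest.raises(ValueError):
            BiomarkerAnnotation(chebi_id=None, wikidata_id=None, display_name="x")
        # Wikidata-only annotations are legal (markers without a ChEBI entry)
        BiomarkerAnnotation(chebi_id=None, wikidata_id="Q123")


class TestChebiToHmdb:
    def test_mapped_and_unmapped_lookups_are_total(self):
        reg = AnnotationRegistry(
            [BiomarkerAnnotation("CHEBI:16842", hmdb_id="HMDB0000076", display_name="dihydrouracil")]
        )
        assert map_chebi_to_hmdb("CHEBI:16842", reg) == "HMDB0000076"
        assert map_chebi_to_hmdb("CHEBI:99999", reg) is None

    def test_empty_mapping_returns_none_for_anything(self):
        reg = AnnotationRegistry()
        assert map_chebi_to_hmdb("CHEBI:1", reg) is None

    def test_mapping_tsv_round_trip(self, tmp_path):
        reg = AnnotationRegistry(
            [
                BiomarkerAnnotation("CHEBI:16842", hmdb_id="HMDB0000076", display_name="a"),
                BiomarkerAnnotation("CHEBI:17368", display_name="b"),
            ]
        )
        reg.to_tsv(tmp_path / "map.tsv")
        back = AnnotationRegistry.from_tsv(tmp_path / "map.tsv")
        assert back.hmdb_for("CHEBI:16842") == "HMDB0000076"
        assert back.hmdb_for("CHEBI:17368") is None


class TestAgeCategories:
    def test_six_months_falls_in_first_band(self):
        assert resolve_age_category(6, DEFAULT_AGE_CATEGORIES).label == "0-1y"

    def test_two_hundred_months_is_adult_band(self):
        assert resolve_age_category(200, DEFAULT_AGE_CATEGORIES).label == "16+y"

    def test_exactly_one_overarching_required(self):
        with pytest.raises(ValueError):
            validate_age_categories([AgeCategory("0-1y", 0, 12)])

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError):
            validate_age_categories(
                [
                    AgeCategory("a", 0, 24),
                    AgeCategory("b", 12, 60),
                    AgeCategory("all", 0, 192, is_overarching=True),
                ]
            )

    @given(st.integers(min_value=0, max_value=1200))
    @settings(max_examples=300, derandomize=True)
    def test_resolution_is_a_partition(self, age):
        """Every age maps to exactly one non-overarching category."""
        hits = [
            c
            for c in DEFAULT_AGE_CATEGORIES
            if not c.is_overarching and c.contains(age)
        ]
        assert len(hits) == 1
        assert resolve_age_category(age, DEFAULT_AGE_CATEGORIES) == hits[0]


class TestReferenceRanges:
    def test_overarching_fallback_when_specific_entry_missing(self):
        table = ReferenceRangeTable(
            {
                ("CHEBI:1", "1-5y"): (1.0, 2.0),
                ("CHEBI:1", "0-16y"): (0.5, 4.0),
                ("CHEBI:2", "0-16y"): (3.0, 6.0),
            }
        )
        assert table.lookup("CHEBI:1", 30) == (1.0, 2.0)  # specific hit
        assert table.lookup("CHEBI:1", 6) == (0.5, 4.0)  # fallback
        assert table.lookup("CHEBI:2", 100) == (3.0, 6.0)  # only overarching
        assert table.lookup("CHEBI:3", 6) is None

    def test_invalid_bounds_rejected_and_degenerate_flagged(self):
        with pytest.raises(ValueError):
            ReferenceRangeTable({("CHEBI:1", "0-16y"): (2.0, 1.0)})
        table = ReferenceRangeTable({("CHEBI:1", "0-16y"): (2.0, 2.0)})
        assert ("CHEBI:1", "0-16y") in table.degenerate

    def test_tsv_round_trip(self, tmp_path):
        table = ReferenceRangeTable(
            {("CHEBI:1", "0-1y"): (0.25, 1.5), ("CHEBI:1", "0-16y"): (0.1, 2.0)}
        )
        table.to_tsv(tmp_path / "r.tsv")
        back = ReferenceRangeTable.from_tsv(tmp_path / "r.tsv")
        assert back.entries == table.entries


class TestPatientSamples:
    LONG = (
        "patient_label\tage_months\tbiomarker_id\tconcentration\n"
        "A\t6\tCHEBI:17368\t12.5\n"
        "A\t6\tCHEBI:16842\t\n"
        "A\t6\tCHEBI:15676\t0.4\n"
        "B\t30\tCHEBI:17368\t3.0\n"
        "B\t30\tCHEBI:16842\t1.0\n"
        "B\t30\tCHEBI:15676\t2.0\n"
    )

    def test_long_layout_parse(self, tmp_path):
        result = load_patient_samples(_write(tmp_path, "p.tsv", self.LONG))
        assert len(result) == 2
        a = result.samples[0]
        assert a.label == "A" and a.age_months == 6
        assert a.measurements["CHEBI:17368"] == 12.5
        assert a.measurements["CHEBI:16842"] is None  # null preserved, not 0

    def test_wide_layout_parse(self, tmp_path):
        wide = (
            "patient_label\tage_months\tCHEBI:17368\tCHEBI:16842\n"
            "A\t6\t12.5\t\nB\t30\t3.0\t1.0\n"
        )
        result = load_patient_samples(_write(tmp_path, "w.tsv", wide))
        assert {s.label for s in result} == {"A", "B"}
        assert result.samples[0].measurements["CHEBI:16842"] is None

    def test_duplicate_measurement_is_an_error(self, tmp_path):
        bad = (
            "patient_label\tage_months\tbiomarker_id\tconcentration\n"
            "A\t6\tCHEBI:1\t1.0\nA\t6\tCHEBI:1\t2.0\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            load_patient_samples(_write(tmp_path, "d.tsv", bad))

    def test_malformed_id_names_the_row(self, tmp_path):
        bad = (
            "patient_label\tage_months\tbiomarker_id\tconcentration\n"
            "A\t6\turacil\t1.0\n"
        )
        with pytest.raises(ValueError, match="row 0"):
            load_patient_samples(_write(tmp_path, "m.tsv", bad))

    def test_unknown_ids_reported_not_dropped(self, tmp_path):
        reg = AnnotationRegistry([BiomarkerAnnotation("CHEBI:17368")])
        result = load_patient_samples(_write(tmp_path, "p.tsv", self.LONG), reg)
        # every measurement is either annotated or in the unknown report
        n_rows = sum(len(s.measurements) for s in result.samples)
        n_known = sum(
            1 for s in result.samples for c in s.measurements if reg.get(c) is not None
        )
        n_unknown = sum(len(labels) for labels in result.unknown_ids.values())
        assert n_known + n_unknown == n_rows
        assert set(result.unknown_ids) == {"CHEBI:16842", "CHEBI:15676"}
        assert len(result.samples[0].measurements) == 3  # retained

    def test_write_read_round_trip_preserves_nulls(self, tmp_path):
        result = load_patient_samples(_write(tmp_path, "p.tsv", self.LONG))
        write_patient_samples(result.samples, tmp_path / "out.tsv")
        back = load_patient_samples(tmp_path / "out.tsv")
        assert [(s.label, s.age_months, s.measurements) for s in back.samples] == [
            (s.label, s.age_months, s.measurements) for s in result.samples
        ]
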