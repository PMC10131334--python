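"""Profile distances, disorder clustering and patient→disease matching."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imdnet.matching import (
    heatmap_frame,
    hierarchical_cluster,
    match_patient,
    patient_vector,
    profile_distance,
)
from imdnet.profiles import DiseaseBiomarkerMatrix, DiseaseProfile, build_matrix
from imdnet.reference import AnnotationRegistry, BiomarkerAnnotation
from imdnet.scoring import ChangeScore

ordinals = st.sampled_from([-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0])


def _series(values, cols=None):
    cols = cols or [f"HMDB{i:07d}" for i in range(1, len(values) + 1)]
    return pd.Series(values, index=cols, dtype=float)


class TestProfileDistance:
    def test_hand_computed_distances(self):
        assert profile_distance(_series([3, 0, 0]), _series([0, 3, 0])) == pytest.approx(
            math.sqrt(18)
        )
        assert profile_distance(_series([1, 1]), _series([-1, -1])) == pytest.approx(
            math.sqrt(8)
        )

    def test_zero_iff_identical(self):
        v = _series([1, -2, 0.5])
        assert profile_distance(v, v.copy()) == 0.0
        assert profile_distance(v, _series([1, -2, 0])) > 0

    def test_mismatched_columns_rejected(self):
        with pytest.raises(ValueError):
            profile_distance(_series([1, 2]), _series([1, 2], cols=["HMDB1", "HMDB9"]))

    @given(
        st.lists(ordinals, min_size=3, max_size=3),
        st.lists(ordinals, min_size=3, max_size=3),
        st.lists(ordinals, min_size=3, max_size=3),
    )
    @settings(max_examples=300, derandomize=True)
    def test_metric_axioms(self, a, b, c):
        va, vb, vc = _series(a), _series(b), _series(c)
        dab = profile_distance(va, vb)
        assert dab >= 0
        assert dab == pytest.approx(profile_distance(vb, va))
        assert dab <= profile_distance(va, vc) + profile_distance(vc, vb) + 1e-9


def _matrix(rows: dict[str, list[float]], cols: list[str]) -> DiseaseBiomarkerMatrix:
    return DiseaseBiomarkerMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=cols, dtype=float), "0-1y"
    )


class TestHierarchicalCluster:
    COLS = ["HMDB0000001", "HMDB0000002", "HMDB0000003"]

    def test_identical_rows_merge_at_height_zero(self):
        m = _matrix({"A": [2, 0, 0], "B": [2, 0, 0], "C": [0, 3, 0]}, self.COLS)
        result = hierarchical_cluster(m)
        assert result.merge_heights()[0] == 0.0
        assert result.flat_clusters(0.5)["A"] == result.flat_clusters(0.5)["B"]

    def test_outlier_merges_last(self):
        """Verified against brute-force agglomeration of the 3×3 distance matrix."""
        m = _matrix({"A": [2, 0, 0], "B": [2, 1, 0], "C": [-3, -3, 3]}, self.COLS)
        # pairwise distances: d(A,B)=1, d(A,C)=sqrt(25+9+9), d(B,C)=sqrt(25+16+9)
        # brute force merges {A,B} first, C joins at complete-linkage height d(B,C)
        result = hierarchical_cluster(m)
        z = result.linkage
        assert {result.labels[int(z[0, 0])], result.labels[int(z[0, 1])]} == {"A", "B"}
        assert z[1, 2] == pytest.approx(math.sqrt(25 + 16 + 9))

    def test_row_permutation_invariance(self):
        rows = {"A": [2, 0, 0], "B": [2, 1, 0], "C": [-3, -3, 3]}
        r1 = hierarchical_cluster(_matrix(rows, self.COLS))
        r2 = hierarchical_cluster(
            _matrix(dict(reversed(list(rows.items()))), self.COLS)
        )
        assert r1.leaf_order == r2.leaf_order
        np.testing.assert_allclose(r1.merge_heights(), r2.merge_heights())

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(_matrix({"A": [1, 0, 0]}, self.COLS))

    def test_unknown_linkage_rejected(self):
        m = _matrix({"A": [1, 0, 0], "B": [0, 1, 0]}, self.COLS)
        with pytest.raises(ValueError):
            hierarchical_cluster(m, method="ward")


def _reg(n=6):
    return AnnotationRegistry(
        [
            BiomarkerAnnotation(f"CHEBI:{i}", hmdb_id=f"HMDB{i:07d}")
            for i in range(1, n + 1)
        ]
    )


def _score(chebi, fc):
    return ChangeScore(chebi, 1 if fc > 0 else -1, fc, max(-3.0, min(3.0, fc)), "scored")


class TestMatchPatient:
    COLS = ["HMDB0000001", "HMDB0000002", "HMDB0000003"]

    def test_exact_profile_matches_at_distance_zero(self):
        m = _matrix({"D1": [2, 2, 0], "D2": [0, 0, 3]}, self.COLS)
        scores = [_score("CHEBI:1", 2.0), _score("CHEBI:2", 2.0)]
        report = match_patient(scores, m, _reg())
        assert report.nearest_genes == ["D1"]
        assert report.ranked_diseases[0][1] == 0.0

    def test_all_zero_patient_matches_smallest_norm_row(self):
        m = _matrix({"BIG": [3, 3, 3], "SMALL": [1, 0, 0], "MID": [2, 2, 0]}, self.COLS)
        report = match_patient([], m, _reg())
        # oracle: exhaustive norm scan
        norms = {"BIG": math.sqrt(27), "SMALL": 1.0, "MID": math.sqrt(8)}
        assert report.nearest_genes == [min(norms, key=norms.get)]

    def test_dpyd_like_patient_matches_uracil_thymine_profile(self):
        """A patient with uracil↑↑ and thymine↑↑ lands on the profile elevating both."""
        uracil, thymine, dhu = "HMDB0000300", "HMDB0000262", "HMDB0000076"
        m = DiseaseBiomarkerMatrix(
            pd.DataFrame.from_dict(
                {"DPYD": [2.0, 2.0, 0.0], "DPYS": [1.0, 0.0, 3.0], "UPB1": [1.0, 0.0, 0.0]},
                orient="index",
                columns=[thymine, uracil, dhu],
                dtype=float,
            ),
            "0-1y",
        )
        reg = AnnotationRegistry(
            [
                BiomarkerAnnotation("CHEBI:17568", hmdb_id=uracil),
                BiomarkerAnnotation("CHEBI:17821", hmdb_id=thymine),
                BiomarkerAnnotation("CHEBI:16842", hmdb_id=dhu),
            ]
        )
        scores = [_score("CHEBI:17568", 2.1), _score("CHEBI:17821", 1.9)]
        report = match_patient(scores, m, reg)
        # oracle: exhaustive distance computation over all three rows
        v = pd.Series({thymine: 1.9, uracil: 2.1, dhu: 0.0})
        expected = min(
            m.genes, key=lambda g: ((v - m.row(g).reindex(v.index)) ** 2).sum()
        )
        assert report.nearest_genes == [expected] == ["DPYD"]

    @given(st.data())
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_rank1_equals_exhaustive_argmin(self, data):
        n_genes = data.draw(st.integers(2, 5))
        rows = {
            f"G{i}": data.draw(st.lists(ordinals, min_size=3, max_size=3))
            for i in range(n_genes)
        }
        m = _matrix(rows, self.COLS)
        fcs = data.draw(
            st.lists(st.floats(-3, 3, allow_nan=False), min_size=3, max_size=3)
        )
        scores = [_score(f"CHEBI:{i + 1}", fc) for i, fc in enumerate(fcs) if fc != 0]
        report = match_patient(scores, m, _reg())
        v, _, _ = patient_vector(scores, m, _reg())
        best = min(
            (math.dist(v.to_numpy(), m.row(g).to_numpy()), g) for g in m.genes
        )
        assert report.ranked_diseases[0][1] == pytest.approx(best[0])
        assert best[1] in report.nearest_genes

    def test_tied_nearest_genes_joined_with_slash(self):
        m = _matrix({"DPYS": [1, 0, 0], "UPB1": [1, 0, 0]}, self.COLS)
        report = match_patient([_score("CHEBI:1", 1.0)], m, _reg())
        assert report.nearest_label == "DPYS/UPB1"

    def test_additional_biomarkers_disjoint_from_nearest_profile(self):
        m = _matrix({"D1": [2, 0, 0], "D2": [0, 3, 3]}, self.COLS)
        scores = [
            _score("CHEBI:1", 2.0),
            _score("CHEBI:3", 1.5),  # altered, zero in nearest profile D1
            _score("CHEBI:6", 2.5),  # mapped but absent from matrix columns
        ]
        report = match_patient(scores, m, _reg())
        assert report.nearest_genes == ["D1"]
        assert report.additional_biomarkers == {"HMDB0000003", "HMDB0000006"}
        assert not report.additional_biomarkers & {"HMDB0000001"}

    def test_unmapped_markers_counted_not_dropped_silently(self):
        m = _matrix({"D1": [2, 0, 0]}, self.COLS)
        reg = AnnotationRegistry([BiomarkerAnnotation("CHEBI:1", hmdb_id="HMDB0000001")])
        scores = [_score("CHEBI:1", 2.0), _score("CHEBI:42", 3.0)]
        report = match_patient(scores, m, reg)
        assert "CHEBI:42" in report.excluded_markers

    def test_distances_non_decreasing_in_rank(self, study, matrix):
        sample, _ = study.simulate_patient("ENZB1", label="rank-check")
        from imdnet.scoring import cap_scores, filter_small_changes, score_sample

        scores = filter_small_changes(cap_scores(score_sample(sample, study.ranges).scores))
        report = match_patient(scores, matrix, study.mapping, k=6)
        dists = [d for _, d in report.ranked_diseases]
        assert dists == sorted(dists)

    def test_empty_matrix_rejected(self):
        empty = DiseaseBiomarkerMatrix(pd.DataFrame(dtype=float), "0-1y")
        with pytest.raises(ValueError):
            match_patient([], empty, _reg())


def test_heatmap_frame_appends_patient_row():
    m = _matrix({"D1": [2, 0, 0], "D2": [0, 3, 0]}, TestMatchPatient.COLS)
    frame = heatmap_frame(m, [_score("CHEBI:1", 1.0)], _reg(), patient_label="patient I")
    assert list(frame.index) == ["D1", "D2", "patient I"]
    assert frame.loc["patient I", "HMDB0000001"] == 1.0
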