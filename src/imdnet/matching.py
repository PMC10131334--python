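"""Match patient change profiles against theoretical disease profiles.

The patient's capped log2 fold changes are projected onto the biomarker
columns of a disease×biomarker ordinal matrix (via the ChEBI→HMDB mapping)
and compared to every disorder row by Euclidean distance.  Disorders are
also clustered agglomeratively on the same distance for heatmap-style
inspection; the patient is overlaid as an extra row rather than folded into
the dendrogram, unless joint clustering is requested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .profiles import DiseaseBiomarkerMatrix
from .reference import AnnotationRegistry
from .scoring import ChangeScore

__all__ = [
    "profile_distance",
    "ClusterResult",
    "hierarchical_cluster",
    "MatchReport",
    "match_patient",
    "patient_vector",
    "heatmap_frame",
    "plot_heatmap",
]

LINKAGE_METHODS = ("complete", "average", "single")


def profile_distance(a: pd.Series, b: pd.Series) -> float:
    """Euclidean distance between two ordinal vectors on the same column set."""
    if set(a.index) != set(b.index):
        raise ValueError("profile vectors are aligned on different biomarker sets")
    bb = b.reindex(a.index)
    return float(np.linalg.norm(a.to_numpy(dtype=float) - bb.to_numpy(dtype=float)))


@dataclass
class ClusterResult:
    """Agglomerative clustering of disorder rows.

    ``linkage`` is a scipy linkage matrix over ``labels`` (input row order);
    ``leaf_order`` gives the deterministic dendrogram leaf sequence.
    """

    labels: list[str]
    linkage: np.ndarray
    method: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def flat_clusters(self, height: float) -> dict[str, int]:
        assignment = hierarchy.fcluster(self.linkage, t=height, criterion="distance")
        return dict(zip(self.labels, (int(c) for c in assignment)))


def hierarchical_cluster(
    matrix: DiseaseBiomarkerMatrix, method: str = "complete"
) -> ClusterResult:
    """Cluster disorder rows on pairwise Euclidean distance.

    Complete linkage is the default; ``average`` and ``single`` are also
    supported.  Requires at least two disorders.
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(f"method must be one of {LINKAGE_METHODS}, got {method!r}")
    if len(matrix.genes) < 2:
        raise ValueError("clustering needs at least 2 disorders")
    # sort rows so the tree does not depend on input row order
    df = matrix.data.sort_index()
    condensed = pdist(df.to_numpy(dtype=float), metric="euclidean")
    z = hierarchy.linkage(condensed, method=method)
    return ClusterResult(labels=list(df.index), linkage=z, method=method)


@dataclass
class MatchReport:
    """Ranked disorder matches for one patient profile.

    ``ranked_diseases`` is ordered by distance (ties broken by gene symbol);
    ``nearest_genes`` holds every gene tied at the minimum distance, printed
    joined by "/".  ``additional_biomarkers`` are patient-altered markers that
    the nearest profile does not list as changed — candidate blind spots.
    ``excluded_markers`` counts altered markers that could not enter the
    comparison (no HMDB mapping, or absent from the matrix columns).
    """

    patient_label: str
    ranked_diseases: list[tuple[str, float]]
    additional_biomarkers: set[str]
    excluded_markers: set[str] = field(default_factory=set)
    cluster_assignment: int | None = None

    @property
    def nearest_genes(self) -> list[str]:
        if not self.ranked_diseases:
            return []
        best = self.ranked_diseases[0][1]
        return [g for g, d in self.ranked_diseases if d == best]

    @property
    def nearest_label(self) -> str:
        return "/".join(self.nearest_genes)

    def to_dict(self) -> dict:
        return {
            "patient_label": self.patient_label,
            "nearest": self.nearest_label,
            "ranked_diseases": [
                {"gene": g, "distance": d} for g, d in self.ranked_diseases
            ],
            "additional_biomarkers": sorted(self.additional_biomarkers),
            "excluded_markers": sorted(self.excluded_markers),
            "cluster_assignment": self.cluster_assignment,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [{"gene": g, "rank": i + 1, "distance": d} for i, (g, d) in enumerate(self.ranked_diseases)]
        ).to_csv(path, sep="\t", index=False)


def patient_vector(
    scores: Iterable[ChangeScore],
    matrix: DiseaseBiomarkerMatrix,
    mapping: AnnotationRegistry,
) -> tuple[pd.Series, set[str], set[str]]:
    """Project capped patient scores onto the matrix's biomarker columns.

    Returns (vector over matrix columns, altered HMDB ids in the comparison,
    altered markers excluded from it).  Scores should already be capped and
    small-change filtered.
    """
    vector = pd.Series(0.0, index=matrix.biomarkers)
    altered: set[str] = set()
    excluded: set[str] = set()
    for s in scores:
        if s.capped_log2fc is None or s.capped_log2fc == 0:
            continue
        hmdb = mapping.hmdb_for(s.chebi_id)
        if hmdb is None:
            excluded.add(s.chebi_id)
        elif hmdb in vector.index:
            vector[hmdb] = s.capped_log2fc
            altered.add(hmdb)
        else:
            excluded.add(hmdb)
    return vector, altered, excluded


def match_patient(
    scores: Iterable[ChangeScore],
    matrix: DiseaseBiomarkerMatrix,
    mapping: AnnotationRegistry,
    k: int = 3,
    patient_label: str = "patient",
    cluster_height: float | None = None,
) -> MatchReport:
    """Rank disorders by Euclidean distance to the patient's capped profile.

    ``additional_biomarkers`` collects the patient's altered markers that are
    zero in (or absent from) the nearest profile.  With ``cluster_height``
    set, the patient is additionally assigned to the flat cluster (at that
    dendrogram height) of its nearest disorder.
    """
    if not matrix.genes:
        raise ValueError("empty disease biomarker matrix")
    vector, altered, excluded = patient_vector(scores, matrix, mapping)
    distances = sorted(
        ((gene, profile_distance(vector, matrix.row(gene))) for gene in matrix.genes),
        key=lambda item: (item[1], item[0]),
    )
    ranked = distances[: max(k, 1)]
    nearest_gene = ranked[0][0]
    nearest_row = matrix.row(nearest_gene)
    nonzero_in_nearest = {h for h in matrix.biomarkers if nearest_row[h] != 0}
    additional = (altered - nonzero_in_nearest) | {
        m for m in excluded if m.startswith("HMDB")
    }
    assignment = None
    if cluster_height is not None and len(matrix.genes) >= 2:
        clusters = hierarchical_cluster(matrix).flat_clusters(cluster_height)
        assignment = clusters[nearest_gene]
    return MatchReport(
        patient_label=patient_label,
        ranked_diseases=ranked,
        additional_biomarkers=additional,
        excluded_markers=excluded,
        cluster_assignment=assignment,
    )


def heatmap_frame(
    matrix: DiseaseBiomarkerMatrix,
    scores: Iterable[ChangeScore] | None = None,
    mapping: AnnotationRegistry | None = None,
    patient_label: str = "patient",
) -> pd.DataFrame:
    """Disorders (+ optional patient row) × biomarkers frame for heatmap plotting."""
    df = matrix.data.copy()
    if scores is not None:
        if mapping is None:
            raise ValueError("a ChEBI→HMDB mapping is required to overlay a patient")
        vector, _, _ = patient_vector(scores, matrix, mapping)
        df.loc[patient_label] = vector
    return df


def plot_heatmap(
    frame: pd.DataFrame,
    path: str | Path,
    method: str = "complete",
) -> None:
    """Render a clustered heatmap PNG (optional; needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order: Sequence[int]
    if len(frame) >= 2:
        z = hierarchy.linkage(pdist(frame.to_numpy(dtype=float)), method=method)
        order = hierarchy.leaves_list(z)
    else:
        order = range(len(frame))
    data = frame.iloc[list(order)]
    fig, ax = plt.subplots(
        figsize=(max(6, 0.3 * len(frame.columns)), max(4, 0.3 * len(frame)))
    )
    im = ax.imshow(data.to_numpy(dtype=float), cmap="RdBu_r", vmin=-3, vmax=3, aspect="auto")
    ax.set_xticks(range(len(data.columns)), data.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(data)), data.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="ordinal change / capped log2FC")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
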