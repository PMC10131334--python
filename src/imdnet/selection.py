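"""Greedy maximum-unique-coverage selection of pathways for visualization.

Candidate pathways are ranked by how many of the patient's changed biomarkers
they contain; at most three are then selected greedily, each pick being the
pathway that adds the most not-yet-covered changed markers.  Selection stops
early when no remaining pathway adds anything.  Ties are broken
lexicographically on pathway ID, and manual overrides can force specific
pathways into specific positions (mirroring expert curation of a patient's
visualization).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .pathways import MarkerPathwayIndex

__all__ = [
    "rank_pathways",
    "PathwaySelection",
    "select_top",
    "select_exhaustive",
    "write_selection_tsv",
    "MAX_PATHWAYS",
]

MAX_PATHWAYS = 3


def rank_pathways(
    changed: Iterable[str], index: MarkerPathwayIndex
) -> list[tuple[str, int]]:
    """Pathways sorted by matching changed-marker count (desc), ties by ID.

    Pathways with no matching marker are omitted.
    """
    changed = set(changed)
    counts = [
        (pid, len(model.metabolite_nodes & changed))
        for pid, model in index.pathways.items()
    ]
    return sorted(
        ((pid, n) for pid, n in counts if n > 0), key=lambda kv: (-kv[1], kv[0])
    )


@dataclass
class PathwaySelection:
    """Result of (greedy) pathway selection.

    ``selected`` holds ≤ max_pathways (pathway_id, newly covered markers)
    pairs in pick order; the newly-covered sets are pairwise disjoint.
    ``uncovered`` is everything changed that no selected pathway contains.
    """

    selected: list[tuple[str, frozenset[str]]]
    uncovered: frozenset[str]
    manual_overrides: list[str] = field(default_factory=list)

    @property
    def pathway_ids(self) -> list[str]:
        return [pid for pid, _ in self.selected]

    @property
    def covered(self) -> frozenset[str]:
        out: set[str] = set()
        for _, newly in self.selected:
            out |= newly
        return frozenset(out)


def select_top(
    changed: Iterable[str],
    index: MarkerPathwayIndex,
    max_pathways: int = MAX_PATHWAYS,
    overrides: Sequence[str] = (),
) -> PathwaySelection:
    """Greedy unique-coverage selection of at most ``max_pathways`` pathways.

    The first pick is the pathway containing the most changed markers; each
    subsequent pick maximizes the number of newly covered markers.  Zero
    marginal gain stops the selection.  ``overrides`` are forced into the
    leading positions in the given order (they must exist in the index) and
    consume their coverage before greedy picks continue.
    """
    if max_pathways < 1:
        raise ValueError("max_pathways must be >= 1")
    changed = set(changed)
    selected: list[tuple[str, frozenset[str]]] = []
    covered: set[str] = set()
    for pid in overrides:
        if pid not in index.pathways:
            raise ValueError(f"override pathway {pid} not in index")
        if len(selected) >= max_pathways:
            break
        newly = frozenset(index.markers_of(pid) & changed - covered)
        selected.append((pid, newly))
        covered |= newly
    taken = {pid for pid, _ in selected}
    while len(selected) < max_pathways:
        best_pid, best_gain = None, frozenset()
        for pid in sorted(index.pathways):
            if pid in taken:
                continue
            gain = frozenset(index.markers_of(pid) & changed - covered)
            if len(gain) > len(best_gain):
                best_pid, best_gain = pid, gain
        if best_pid is None or not best_gain:
            break
        selected.append((best_pid, best_gain))
        covered |= best_gain
        taken.add(best_pid)
    return PathwaySelection(
        selected=selected,
        uncovered=frozenset(changed - covered),
        manual_overrides=list(overrides),
    )


def select_exhaustive(
    changed: Iterable[str],
    index: MarkerPathwayIndex,
    max_pathways: int = MAX_PATHWAYS,
) -> PathwaySelection:
    """Exact maximum-unique-coverage selection by exhaustive search.

    Intended for small instances (a brute-force cross-check of the greedy
    rule): maximizes total covered changed markers over all subsets of at
    most ``max_pathways`` pathways; among maxima prefers fewer pathways, then
    the ordering whose per-pick marginal gains are lexicographically largest
    (so the reported pick order matches the greedy convention).
    """
    changed = set(changed)
    pids = sorted(index.pathways)
    best_cover: set[str] = set()
    best_subset: tuple[str, ...] = ()
    for r in range(1, max_pathways + 1):
        for subset in combinations(pids, r):
            cover = set()
            for pid in subset:
                cover |= index.markers_of(pid) & changed
            if len(cover) > len(best_cover) or (
                len(cover) == len(best_cover)
                and best_subset
                and (len(subset), subset) < (len(best_subset), best_subset)
            ):
                best_cover, best_subset = cover, subset
    # drop members adding nothing, order picks greedily within the subset
    best_order: list[tuple[str, frozenset[str]]] = []
    remaining = list(best_subset)
    covered: set[str] = set()
    while remaining:
        remaining.sort(
            key=lambda pid: (-len(index.markers_of(pid) & changed - covered), pid)
        )
        pid = remaining.pop(0)
        newly = frozenset(index.markers_of(pid) & changed - covered)
        if not newly:
            break
        best_order.append((pid, newly))
        covered |= newly
    return PathwaySelection(
        selected=best_order, uncovered=frozenset(changed - covered)
    )


def write_selection_tsv(
    selection: PathwaySelection, index: MarkerPathwayIndex, path: str | Path
) -> None:
    """Selection report: one row per pick plus an uncovered-markers row."""
    rows = []
    for rank, (pid, newly) in enumerate(selection.selected, start=1):
        rows.append(
            {
                "rank": rank,
                "pathway_id": pid,
                "title": index.pathways[pid].title,
                "covered_count": len(newly),
                "newly_covered": ";".join(sorted(newly)),
            }
        )
    rows.append(
        {
            "rank": "",
            "pathway_id": "(uncovered)",
            "title": "",
            "covered_count": len(selection.uncovered),
            "newly_covered": ";".join(sorted(selection.uncovered)),
        }
    )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
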