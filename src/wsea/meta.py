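"""Cross-dataset consistency of top-ranked pathways.

Enrichment methods are compared on related datasets by tabulating which
pathways recur among each dataset's ten best-ranked results: a method
that keeps finding the same pathways across similar experiments is more
consistent than one whose top lists are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

from .enrichment import rank_and_report

__all__ = ["TopKTable", "top_k_table", "cross_tabulate", "consistency_score"]


@dataclass
class TopKTable:
    """Per-dataset ordered top-k pathway lists."""

    lists: dict[str, list[str]]
    k: int = 10

    def __post_init__(self) -> None:
        for ds, ids in self.lists.items():
            if len(ids) > self.k:
                raise ValueError(f"dataset {ds!r}: list longer than k={self.k}")
            if len(ids) != len(set(ids)):
                raise ValueError(f"dataset {ds!r}: duplicate pathway ids")

    @property
    def datasets(self) -> list[str]:
        return list(self.lists)


def top_k_table(
    results_by_dataset: Mapping[str, pd.DataFrame],
    k: int = 10,
    p_cutoff: float | None = None,
) -> TopKTable:
    """Build a :class:`TopKTable` from per-dataset enrichment results.

    Each result table is re-ranked deterministically, optionally
    filtered at ``p_cutoff`` (the convention for the unweighted tests),
    then capped at ``k`` entries.
    """
    lists = {
        ds: rank_and_report(res, top_k=k, p_cutoff=p_cutoff)["set_id"].tolist()
        for ds, res in results_by_dataset.items()
    }
    return TopKTable(lists=lists, k=k)


def cross_tabulate(table: TopKTable, min_datasets: int = 2) -> pd.DataFrame:
    """Pathways recurring in the top lists of at least ``min_datasets`` datasets.

    Returns a DataFrame with columns ``set_id``, ``n_datasets`` and
    ``datasets`` (comma-joined, in input order), sorted by recurrence
    count descending then set_id.
    """
    if len(table.lists) < 2:
        raise ValueError("cross-tabulation needs at least 2 datasets")
    presence: dict[str, list[str]] = {}
    for ds, ids in table.lists.items():
        for set_id in ids:
            presence.setdefault(set_id, []).append(ds)
    rows = [
        {"set_id": sid, "n_datasets": len(dss), "datasets": ",".join(dss)}
        for sid, dss in presence.items()
        if len(dss) >= min_datasets
    ]
    df = pd.DataFrame(rows, columns=["set_id", "n_datasets", "datasets"])
    return df.sort_values(
        by=["n_datasets", "set_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


@dataclass(frozen=True)
class ConsistencySummary:
    """Mean pairwise top-k overlap plus a recurrence-level histogram."""

    mean_pairwise_overlap: float
    recurrence_counts: dict[int, int] = field(default_factory=dict)


def consistency_score(table: TopKTable) -> ConsistencySummary:
    """Quantify cross-dataset agreement of the top-k lists.

    Mean pairwise overlap is ``|A ∩ B| / k`` averaged over all dataset
    pairs; recurrence_counts maps "appears in exactly r datasets" to the
    number of pathways doing so.
    """
    if len(table.lists) < 2:
        raise ValueError("consistency needs at least 2 datasets")
    sets = {ds: set(ids) for ds, ids in table.lists.items()}
    overlaps = [
        len(sets[a] & sets[b]) / table.k for a, b in combinations(sets, 2)
    ]
    recurrence: dict[str, int] = {}
    for ids in table.lists.values():
        for sid in ids:
            recurrence[sid] = recurrence.get(sid, 0) + 1
    counts: dict[int, int] = {}
    for r in recurrence.values():
        counts[r] = counts.get(r, 0) + 1
    return ConsistencySummary(
        mean_pairwise_overlap=float(sum(overlaps) / len(overlaps)),
        recurrence_counts=dict(sorted(counts.items())),
    )
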