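"""Gene-set collections, probe→gene maps, and probe-level statistic collapsing.

Gene sets are read and written in the tab-delimited GMT convention: one set
per line, ``set_id <TAB> name <TAB> member ...``.  Gene identifiers are
opaque strings; no organism- or database-specific logic lives here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "read_probe_map",
    "collapse_probes",
]


@dataclass(frozen=True)
class GeneSet:
    """A named pathway: a short identifier, a display name, and its members."""

    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """An ordered collection of :class:`GeneSet` with unique identifiers."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate set identifiers: {dupes}")
        self._by_id = {s.set_id: s for s in self.sets}

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._by_id[set_id]

    def __contains__(self, set_id: str) -> bool:
        return set_id in self._by_id

    @property
    def universe(self) -> frozenset[str]:
        """All gene identifiers appearing in any set."""
        out: set[str] = set()
        for s in self.sets:
            out |= s.members
        return frozenset(out)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file into a :class:`GeneSetCollection`.

    Each non-empty line must have at least three tab-separated fields:
    set identifier, display name, and one or more member gene IDs.
    Duplicate members within a line are silently de-duplicated (set
    semantics); a duplicate set identifier across lines is an error.
    """
    sets: list[GeneSet] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields "
                    f"(id, name, members...), got {len(fields)}"
                )
            set_id, name, *members = fields
            members = [m for m in members if m]
            sets.append(GeneSet(set_id=set_id, name=name, members=frozenset(members)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection in GMT format (members sorted for determinism)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.set_id, s.name, *sorted(s.members)]) + "\n")


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column headerless TSV (probe TAB gene) into a probe→gene map.

    A probe may map to at most one gene; a probe appearing twice is an
    error (many-to-many probe mappings are deliberately unsupported).
    """
    mapping: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields"
                )
            probe, gene = fields
            if probe in mapping:
                raise ValueError(
                    f"{path}: line {lineno}: probe {probe!r} mapped more than once"
                )
            mapping[probe] = gene
    return mapping


def collapse_probes(
    probe_stats: pd.DataFrame, probe_map: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse probe-level fold changes and p-values to gene level.

    Multiple probes interrogating one gene are summarised by the mean of
    their linear-scale fold changes and the minimum of their p-values.
    Probes absent from the map are dropped (count logged).

    Parameters
    ----------
    probe_stats
        DataFrame indexed by probe ID with columns ``fold_change`` and
        ``p_value``.
    probe_map
        probe ID → gene ID.

    Returns
    -------
    DataFrame indexed by gene ID with columns ``fold_change`` and
    ``p_value``, sorted by gene ID.
    """
    required = {"fold_change", "p_value"}
    if not required.issubset(probe_stats.columns):
        raise ValueError(f"probe_stats must have columns {sorted(required)}")
    mapped = probe_stats.index.to_series().map(dict(probe_map))
    n_unmapped = int(mapped.isna().sum())
    if n_unmapped:
        logger.warning(
            "dropping %d of %d probes with no gene mapping",
            n_unmapped,
            len(probe_stats),
        )
    kept = probe_stats.loc[mapped.notna()]
    if kept.empty:
        raise ValueError("no probes in probe_stats are present in the probe map")
    genes = mapped.dropna()
    out = kept.groupby(genes).agg(
        fold_change=("fold_change", "mean"), p_value=("p_value", "min")
    )
    out.index.name = "gene_id"
    return out.sort_index()
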