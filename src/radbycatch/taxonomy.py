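"""Offline taxonomy: taxid → ranked lineage, and rank-level set queries.

Replaces live taxonomy lookups with a lineage table loaded from TSV
(:func:`radbycatch.formats.read_lineage_table`). Lookup is total: an
unknown taxid resolves to an all-sentinel lineage and is counted, never
dropped silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .formats import BlastHit

logger = logging.getLogger(__name__)

#: The eight ranks every lineage carries, outermost first.
RANKS = (
    "superkingdom",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: Sentinel label for "rank unknown".
UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class Lineage:
    """Ranked taxonomy labels for one taxon id.

    Every rank in :data:`RANKS` has an entry; missing ranks hold
    :data:`UNKNOWN`.
    """

    taxid: str
    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.taxid:
            raise ValueError("taxid must be non-empty")
        missing = set(RANKS) - set(self.labels)
        if missing:
            raise ValueError(f"lineage for {self.taxid} missing ranks: {sorted(missing)}")
        object.__setattr__(self, "labels", dict(self.labels))

    @property
    def phylum(self) -> str:
        return self.labels["phylum"]

    @property
    def genus(self) -> str:
        return self.labels["genus"]

    @property
    def species(self) -> str:
        return self.labels["species"]


def unknown_lineage(taxid: str) -> Lineage:
    """All-sentinel lineage for a taxid absent from the store."""
    return Lineage(taxid=taxid, labels={rank: UNKNOWN for rank in RANKS})


class LineageStore:
    """In-memory mapping taxid → :class:`Lineage` with total lookup."""

    def __init__(self, entries: Mapping[str, Lineage] | None = None) -> None:
        self._entries: dict[str, Lineage] = dict(entries or {})
        self.unknown_lookups = 0

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, taxid: str) -> bool:
        return taxid in self._entries

    def add(self, lineage: Lineage) -> None:
        self._entries[lineage.taxid] = lineage

    def lineages(self) -> Iterable[Lineage]:
        return self._entries.values()

    def resolve(self, taxid: str) -> Lineage:
        """Return the stored lineage, or an all-sentinel one if absent.

        Never raises; unknown lookups are logged and counted in
        ``unknown_lookups`` so the run summary can report the rate.
        """
        lineage = self._entries.get(taxid)
        if lineage is None:
            self.unknown_lookups += 1
            logger.warning("taxid %r not in lineage store; reporting as unknown", taxid)
            return unknown_lineage(taxid)
        return lineage


def distinct_labels_at_rank(
    store: LineageStore,
    hits: Iterable[BlastHit],
    rank: str,
    min_pident: float,
) -> set[str]:
    """Non-sentinel labels at ``rank`` among hits with pident strictly above ``min_pident``.

    The strict inequality matches the "greater than" reading of the
    ambiguity floor. Hits resolving to the sentinel are excluded from the
    returned set (unknown is not evidence of conflict) but are logged.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels: set[str] = set()
    sentinel_hits = 0
    for hit in hits:
        if hit.pident > min_pident:
            label = store.resolve(hit.staxid).labels[rank]
            if label == UNKNOWN:
                sentinel_hits += 1
            else:
                labels.add(label)
    if sentinel_hits:
        logger.debug(
            "%d hit(s) above pident %s resolved to sentinel at rank %s",
            sentinel_hits,
            min_pident,
            rank,
        )
    return labels
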