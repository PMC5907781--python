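"""Taxonomic classification of per-query hit sets under identity thresholds.

The rules, in order, for one query's hits:

1. no hits at all → ``no_hit``;
2. hits above the ambiguity floor (default 80, strict ``>``) span more
   than one phylum, superkingdom, or kingdom → ``ambiguous``;
3. the best hit's identity is below the threshold (``>=`` is inclusive)
   → ``below_threshold``;
4. the best hit's lineage has no phylum → ``unresolvable``;
5. otherwise ``classified``, carrying the best hit's phylum / genus /
   species.

The ambiguity floor is decoupled from the sweep threshold, so the set of
ambiguous queries does not move during a threshold sweep.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats import BlastHit, PathLike
from .taxonomy import UNKNOWN, LineageStore, distinct_labels_at_rank

#: The identity thresholds swept in the headline analysis.
DEFAULT_THRESHOLDS = (70.0, 80.0, 85.0, 90.0, 95.0, 97.0)

#: Hits above this identity (strict) participate in the ambiguity check.
DEFAULT_AMBIGUITY_FLOOR = 80.0

STATUSES = ("classified", "ambiguous", "below_threshold", "no_hit", "unresolvable")

#: Statuses other than ``classified``, in reporting order.
NON_CLASSIFIED_STATUSES = ("ambiguous", "below_threshold", "no_hit", "unresolvable")

CLASSIFICATION_TSV_COLUMNS = (
    "qseqid",
    "status",
    "phylum",
    "genus",
    "species",
    "best_pident",
    "threshold",
)


@dataclass(frozen=True)
class Classification:
    """Per-query outcome of the classification rules at one threshold."""

    qseqid: str
    status: str
    phylum: str = UNKNOWN
    genus: str = UNKNOWN
    species: str = UNKNOWN
    best_pident: float | None = None
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "classified":
            if self.phylum == UNKNOWN:
                raise ValueError("classified query must carry a phylum")
            if self.best_pident is None or self.best_pident < self.threshold:
                raise ValueError(
                    "classified query must have best_pident >= threshold"
                )
        if self.status == "no_hit" and self.best_pident is not None:
            raise ValueError("no_hit query cannot carry a best_pident")


@dataclass(frozen=True)
class SweepResult:
    """Per-phylum classified counts and status totals across thresholds."""

    thresholds: tuple[float, ...]
    counts: Mapping[tuple[float, str], int]
    status_totals: Mapping[tuple[float, str], int]
    n_queries: int

    def count(self, threshold: float, phylum: str) -> int:
        return self.counts.get((threshold, phylum), 0)

    def phyla(self) -> list[str]:
        return sorted({phylum for _, phylum in self.counts})

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: threshold, phylum, count."""
        rows = [
            {"threshold": t, "phylum": p, "count": self.count(t, p)}
            for t in self.thresholds
            for p in self.phyla()
        ]
        return pd.DataFrame(rows, columns=["threshold", "phylum", "count"])


def best_hit(hits: Sequence[BlastHit]) -> BlastHit | None:
    """The closest-matching hit for one query, or None if there are no hits.

    Maximizes (bitscore, pident, −evalue), then breaks remaining ties by
    lexicographically smallest sseqid, then smallest staxid — a fixed
    chain so output is deterministic across runs and platforms.
    """
    if not hits:
        return None
    qseqids = {h.qseqid for h in hits}
    if len(qseqids) > 1:
        raise ValueError(f"hits span multiple queries: {sorted(qseqids)}")
    return min(
        hits, key=lambda h: (-h.bitscore, -h.pident, h.evalue, h.sseqid, h.staxid)
    )


def classify_query(
    hits: Sequence[BlastHit],
    store: LineageStore,
    threshold: float,
    ambiguity_floor: float = DEFAULT_AMBIGUITY_FLOOR,
) -> Classification:
    """Classify one query's hit set at ``threshold`` (see module rules)."""
    if not 0.0 <= threshold <= 100.0:
        raise ValueError(f"threshold out of [0,100]: {threshold}")
    if not hits:
        return Classification(qseqid="", status="no_hit", threshold=threshold)
    qseqid = hits[0].qseqid
    for rank in ("phylum", "superkingdom", "kingdom"):
        if len(distinct_labels_at_rank(store, hits, rank, ambiguity_floor)) > 1:
            best = best_hit(hits)
            return Classification(
                qseqid=qseqid,
                status="ambiguous",
                best_pident=best.pident,
                threshold=threshold,
            )
    best = best_hit(hits)
    if best.pident < threshold:
        return Classification(
            qseqid=qseqid,
            status="below_threshold",
            best_pident=best.pident,
            threshold=threshold,
        )
    lineage = store.resolve(best.staxid)
    if lineage.phylum == UNKNOWN:
        return Classification(
            qseqid=qseqid,
            status="unresolvable",
            best_pident=best.pident,
            threshold=threshold,
        )
    return Classification(
        qseqid=qseqid,
        status="classified",
        phylum=lineage.phylum,
        genus=lineage.genus,
        species=lineage.species,
        best_pident=best.pident,
        threshold=threshold,
    )


def group_hits_by_query(hits: Iterable[BlastHit]) -> dict[str, list[BlastHit]]:
    """Group hits by qseqid, preserving first-appearance order of queries."""
    grouped: dict[str, list[BlastHit]] = {}
    for hit in hits:
        grouped.setdefault(hit.qseqid, []).append(hit)
    return grouped


def classify_all(
    hits_by_query: Mapping[str, Sequence[BlastHit]],
    store: LineageStore,
    threshold: float,
    ambiguity_floor: float = DEFAULT_AMBIGUITY_FLOOR,
) -> list[Classification]:
    """Classify every query in a grouped hit table, preserving order.

    Queries mapped to an empty hit list come out as ``no_hit`` with their
    qseqid filled in.
    """
    out: list[Classification] = []
    for qseqid, hits in hits_by_query.items():
        cls = classify_query(list(hits), store, threshold, ambiguity_floor)
        if cls.status == "no_hit":
            cls = Classification(
                qseqid=qseqid, status="no_hit", threshold=threshold
            )
        out.append(cls)
    return out


def sweep(
    hits_by_query: Mapping[str, Sequence[BlastHit]],
    store: LineageStore,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    ambiguity_floor: float = DEFAULT_AMBIGUITY_FLOOR,
) -> SweepResult:
    """Classify every query at every threshold and tally per-phylum counts.

    At each threshold, per-phylum classified counts plus the totals of
    each non-classified status sum to the number of queries (partition
    invariant).
    """
    thresholds = tuple(float(t) for t in thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])) or not thresholds:
        raise ValueError(f"thresholds must be non-empty and strictly increasing: {thresholds}")
    counts: dict[tuple[float, str], int] = {}
    status_totals: dict[tuple[float, str], int] = {
        (t, s): 0 for t in thresholds for s in NON_CLASSIFIED_STATUSES
    }
    for t in thresholds:
        for cls in classify_all(hits_by_query, store, t, ambiguity_floor):
            if cls.status == "classified":
                key = (t, cls.phylum)
                counts[key] = counts.get(key, 0) + 1
            else:
                status_totals[(t, cls.status)] += 1
    return SweepResult(
        thresholds=thresholds,
        counts=counts,
        status_totals=status_totals,
        n_queries=len(hits_by_query),
    )


# ---------------------------------------------------------------------------
# TSV / CSV surface consumed by the community module and the CLI


def write_classifications(
    classifications: Iterable[Classification], path: PathLike
) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(CLASSIFICATION_TSV_COLUMNS)
        for c in classifications:
            writer.writerow(
                (
                    c.qseqid,
                    c.status,
                    c.phylum,
                    c.genus,
                    c.species,
                    "" if c.best_pident is None else f"{c.best_pident:.3f}",
                    f"{c.threshold:g}",
                )
            )


def read_classifications(path: PathLike) -> list[Classification]:
    out: list[Classification] = []
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != CLASSIFICATION_TSV_COLUMNS:
            raise ValueError(f"{path}: malformed classification TSV header")
        for row in reader:
            out.append(
                Classification(
                    qseqid=row[0],
                    status=row[1],
                    phylum=row[2],
                    genus=row[3],
                    species=row[4],
                    best_pident=float(row[5]) if row[5] else None,
                    threshold=float(row[6]),
                )
            )
    return out


def write_sweep(result: SweepResult, path: PathLike) -> None:
    """Write the sweep as long-format CSV (threshold, phylum, count)."""
    result.to_dataframe().to_csv(path, index=False)
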