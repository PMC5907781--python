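"""Aggregate per-query classifications into community summaries.

Three structures:

* :func:`phylum_count_table` — samples × phyla-of-interest counts with a
  Total column (the headline per-sample table);
* :func:`shared_presence_matrix` — across-sample loci with a metagenomic
  classification, present/absent per sample;
* :func:`genus_community_matrix` — one Chordata column plus one column
  per parasite genus, feeding rarefaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import Classification
from .formats import Locus, PathLike
from .taxonomy import UNKNOWN

#: Headline table column set.
DEFAULT_PHYLA_OF_INTEREST = ("Chordata", "Platyhelminthes", "Nematoda", "Apicomplexa")

#: Phyla counted as blood parasites in the genus-level community matrix.
DEFAULT_PARASITE_PHYLA = ("Platyhelminthes", "Nematoda", "Apicomplexa")

HOST_PHYLUM = "Chordata"


@dataclass(frozen=True)
class CommunityMatrix:
    """Samples × taxa table of non-negative integer counts."""

    samples: tuple[str, ...]
    taxa: tuple[str, ...]
    counts: np.ndarray  # shape (len(samples), len(taxa)), dtype int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (len(self.samples), len(self.taxa)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.samples)} samples x {len(self.taxa)} taxa"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        if (counts < 0).any():
            raise ValueError("negative counts")
        object.__setattr__(self, "counts", counts)

    def row(self, sample: str) -> np.ndarray:
        return self.counts[self.samples.index(sample)]

    def cell(self, sample: str, taxon: str) -> int:
        return int(self.counts[self.samples.index(sample), self.taxa.index(taxon)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.samples), columns=list(self.taxa)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CommunityMatrix":
        return cls(
            samples=tuple(str(s) for s in df.index),
            taxa=tuple(str(t) for t in df.columns),
            counts=df.to_numpy(dtype=np.int64),
        )


@dataclass(frozen=True)
class PresenceMatrix:
    """Loci (rows) × samples (columns) presence/absence with per-locus phylum."""

    loci: tuple[str, ...]
    samples: tuple[str, ...]
    presence: np.ndarray  # bool, shape (len(loci), len(samples))
    phyla: tuple[str, ...]  # one label per locus row

    def __post_init__(self) -> None:
        presence = np.asarray(self.presence, dtype=bool)
        if presence.shape != (len(self.loci), len(self.samples)):
            raise ValueError("presence shape does not match loci x samples")
        if len(self.phyla) != len(self.loci):
            raise ValueError("one phylum label required per locus row")
        if len(self.loci) and not presence.any(axis=1).all():
            raise ValueError("a locus row must be present in at least one sample")
        object.__setattr__(self, "presence", presence)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.presence.astype(int), index=list(self.loci), columns=list(self.samples)
        )
        df.insert(0, "phylum", list(self.phyla))
        return df


def _common_threshold(classifications: Iterable[Classification]) -> float | None:
    thresholds = {c.threshold for c in classifications}
    if len(thresholds) > 1:
        raise ValueError(f"mixed classification thresholds: {sorted(thresholds)}")
    return thresholds.pop() if thresholds else None


def phylum_count_table(
    by_sample: Mapping[str, Sequence[Classification]],
    phyla_of_interest: Sequence[str] = DEFAULT_PHYLA_OF_INTEREST,
) -> CommunityMatrix:
    """Per-sample counts of queries classified to each phylum of interest.

    The final ``Total`` column records each sample's total query count,
    classified or not. All classifications must carry one threshold.
    """
    _common_threshold(c for group in by_sample.values() for c in group)
    samples = tuple(by_sample)
    taxa = tuple(phyla_of_interest) + ("Total",)
    counts = np.zeros((len(samples), len(taxa)), dtype=np.int64)
    col = {p: j for j, p in enumerate(phyla_of_interest)}
    for i, sample in enumerate(samples):
        group = by_sample[sample]
        counts[i, -1] = len(group)
        for c in group:
            if c.status == "classified" and c.phylum in col:
                counts[i, col[c.phylum]] += 1
    return CommunityMatrix(samples=samples, taxa=taxa, counts=counts)


def shared_presence_matrix(
    loci: Sequence[Locus],
    classification_by_locus: Mapping[str, Classification],
    samples: Sequence[str],
    min_samples: int = 2,
    min_members: int = 1,
    host_phylum: str = HOST_PHYLUM,
) -> PresenceMatrix:
    """Presence/absence of metagenomic loci across samples.

    Rows are loci whose classification is ``classified`` to a
    non-host, non-sentinel phylum; a cell is present iff any member of
    the locus came from that sample. ``min_samples`` (default 2) keeps
    only loci present in at least that many samples; ``min_members``
    filters on the number of member sequences instead (both readings of
    "two or more representatives" are exposed).
    """
    sample_set = set(samples)
    kept_ids: list[str] = []
    kept_phyla: list[str] = []
    rows: list[np.ndarray] = []
    for locus in loci:
        cls = classification_by_locus.get(locus.locus_id)
        if cls is None or cls.status != "classified":
            continue
        if cls.phylum == host_phylum or cls.phylum == UNKNOWN:
            continue
        for member_sample in locus.sample_ids:
            if member_sample not in sample_set:
                raise ValueError(
                    f"locus {locus.locus_id}: member sample {member_sample!r} "
                    f"not in the sample list"
                )
        if len(locus.members) < min_members:
            continue
        row = np.array(
            [sample in locus.sample_ids for sample in samples], dtype=bool
        )
        if row.sum() < min_samples:
            continue
        kept_ids.append(locus.locus_id)
        kept_phyla.append(cls.phylum)
        rows.append(row)
    presence = (
        np.array(rows, dtype=bool)
        if rows
        else np.zeros((0, len(samples)), dtype=bool)
    )
    return PresenceMatrix(
        loci=tuple(kept_ids),
        samples=tuple(samples),
        presence=presence,
        phyla=tuple(kept_phyla),
    )


def genus_community_matrix(
    by_sample: Mapping[str, Sequence[Classification]],
    threshold: float = 90.0,
    parasite_phyla: Sequence[str] = DEFAULT_PARASITE_PHYLA,
) -> CommunityMatrix:
    """Samples × (Chordata + parasite genera) counts for rarefaction.

    All host-classified queries pool into one ``Chordata`` column; each
    genus among the parasite phyla gets its own column; parasite queries
    with a sentinel genus pool into ``<phylum>_unassigned`` so totals are
    conserved (nothing lost to pooling).
    """
    seen = _common_threshold(c for group in by_sample.values() for c in group)
    if seen is not None and seen != threshold:
        raise ValueError(
            f"classifications were computed at threshold {seen}, expected {threshold}"
        )
    parasite_set = set(parasite_phyla)
    genus_labels: set[str] = set()
    for group in by_sample.values():
        for c in group:
            if c.status == "classified" and c.phylum in parasite_set:
                genus_labels.add(
                    f"{c.phylum}_unassigned" if c.genus == UNKNOWN else c.genus
                )
    taxa = (HOST_PHYLUM,) + tuple(sorted(genus_labels))
    col = {t: j for j, t in enumerate(taxa)}
    samples = tuple(by_sample)
    counts = np.zeros((len(samples), len(taxa)), dtype=np.int64)
    for i, sample in enumerate(samples):
        for c in by_sample[sample]:
            if c.status != "classified":
                continue
            if c.phylum == HOST_PHYLUM:
                counts[i, 0] += 1
            elif c.phylum in parasite_set:
                label = f"{c.phylum}_unassigned" if c.genus == UNKNOWN else c.genus
                counts[i, col[label]] += 1
    return CommunityMatrix(samples=samples, taxa=taxa, counts=counts)


def write_presence_csv(matrix: PresenceMatrix, path: PathLike) -> None:
    matrix.to_dataframe().to_csv(path, index=True, index_label="locus")
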