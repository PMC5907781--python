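"""File dialects the pipeline touches.

Readers and writers for FASTA, pyRAD-style ``*.loci`` files, 13-column
BLAST tabular hit TSVs, ranked-lineage TSVs, and community-matrix CSVs.
Per-sample ``*.edit`` files are plain FASTA and go through
:func:`read_fasta` / :func:`write_fasta`.

Coordinate conventions: hit-table coordinates (``qstart`` .. ``send``) are
1-based inclusive, following alignment-tool convention; everything emitted
by :mod:`radbycatch.simulate` is 0-based half-open. The boundary between
the two conventions is here, at the type level.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO, Union

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_VALID_BASES = frozenset("ACGTN")

#: Column order of the hit-table dialect: the 12 standard tabular columns
#: with a subject-taxon-id column appended. No header line.
BLAST_TAB_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
    "staxids",
)

LINEAGE_COLUMNS = (
    "taxid",
    "superkingdom",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named nucleotide sequence (query or reference).

    ``id`` must be non-empty and whitespace-free; ``sequence`` is stored
    uppercase over the alphabet {A, C, G, T, N} and must be non-empty.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id: {self.id!r}")
        if not self.sequence:
            raise ValueError(f"empty sequence for id {self.id!r}")
        seq = self.sequence.upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters: {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Locus:
    """One across-sample RAD locus: an ordered group of member sequences.

    ``members`` are ``(sample_id, sequence)`` pairs in file order.
    """

    locus_id: str
    members: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"locus {self.locus_id!r} has no members")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(sample for sample, _ in self.members)


@dataclass(frozen=True)
class BlastHit:
    """One row of an alignment hit table (one subject taxon per hit).

    ``qstart``/``qend``/``sstart``/``send`` are 1-based inclusive.
    """

    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    staxid: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.pident <= 100.0:
            raise ValueError(f"pident out of [0,100]: {self.pident}")
        if self.length <= 0:
            raise ValueError(f"alignment length must be positive: {self.length}")
        if self.mismatch < 0 or self.gapopen < 0:
            raise ValueError("mismatch/gapopen must be non-negative")
        if self.qstart > self.qend:
            raise ValueError(f"qstart > qend ({self.qstart} > {self.qend})")
        if self.evalue < 0:
            raise ValueError(f"negative evalue: {self.evalue}")


def _open_text(path: PathLike, mode: str = "rt") -> TextIO:
    # plain-gzip pass-through only
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into a list of records, in file order.

    Multi-line sequences are concatenated and uppercased. An empty file
    yields an empty list; sequence data before any ``>`` header is a
    :class:`FormatError`.
    """
    with _open_text(path) as handle:
        # SimpleFastaParser silently skips leading junk; enforce the contract.
        first = None
        for line in handle:
            if line.strip():
                first = line
                break
        if first is None:
            return []
        if not first.startswith(">"):
            raise FormatError(
                f"{path}: sequence data before any '>' header: {first.strip()!r}"
            )
        handle.seek(0)
        records = [
            SequenceRecord(id=title.split()[0], sequence=seq.replace(" ", ""))
            for title, seq in SimpleFastaParser(handle)
        ]
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: PathLike, width: int = 80
) -> None:
    """Write records as FASTA, one header per record, wrapped at ``width``.

    Raises on duplicate ids so that ``read_fasta`` round-trips exactly.
    """
    seen: set[str] = set()
    with _open_text(path, "wt") as handle:
        for rec in records:
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# pyRAD-style *.loci

_SEPARATOR_TAG = re.compile(r"\|(\d+)\|\s*$")


def read_loci(path: PathLike) -> list[Locus]:
    """Parse a pyRAD-style ``*.loci`` file.

    Member lines are ``<name><whitespace><sequence>``; a locus block is
    terminated by a separator line whose first two non-blank characters
    are ``//``. A trailing ``|N|`` tag on the separator supplies the
    locus id, otherwise the 0-based block index is used. Alignment gap
    characters ``-`` are stripped from member sequences; a leading ``>``
    on member names (as written by pyRAD) is stripped.

    A trailing block with no separator is accepted as the final locus
    with a warning. A separator with no preceding members is a
    :class:`FormatError`.
    """
    loci: list[Locus] = []
    members: list[tuple[str, str]] = []
    block_index = 0
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("//"):
                if not members:
                    raise FormatError(
                        f"{path}:{lineno}: locus separator with no member sequences"
                    )
                tag = _SEPARATOR_TAG.search(line)
                locus_id = tag.group(1) if tag else str(block_index)
                loci.append(Locus(locus_id=locus_id, members=tuple(members)))
                members = []
                block_index += 1
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(
                    f"{path}:{lineno}: member line needs a name and a sequence: "
                    f"{line!r}"
                )
            name = fields[0].lstrip(">")
            sequence = fields[1].replace("-", "").upper()
            members.append((name, sequence))
    if members:
        logger.warning(
            "%s: trailing locus block without '//' separator; accepted as final locus",
            path,
        )
        loci.append(Locus(locus_id=str(block_index), members=tuple(members)))
    return loci


def write_loci(loci: Iterable[Locus], path: PathLike) -> None:
    """Emit the ``*.loci`` dialect that :func:`read_loci` parses.

    Numeric locus ids are preserved via the ``|N|`` separator tag, so a
    write → read cycle reproduces membership, order, and numeric ids.
    """
    with _open_text(path, "wt") as handle:
        for locus in loci:
            for sample, seq in locus.members:
                handle.write(f"{sample}\t{seq}\n")
            if locus.locus_id.isdigit():
                handle.write(f"//\t|{locus.locus_id}|\n")
            else:
                handle.write("//\n")


def extract_locus_representatives(loci: Sequence[Locus]) -> list[SequenceRecord]:
    """Take the first member sequence of each locus as its representative.

    Record ids are ``locus_<locus_id>``; file order is preserved.
    """
    return [
        SequenceRecord(id=f"locus_{locus.locus_id}", sequence=locus.members[0][1])
        for locus in loci
    ]


# ---------------------------------------------------------------------------
# BLAST tabular hit TSV (13 columns, no header)


def read_blast_tab(path: PathLike) -> list[BlastHit]:
    """Parse a 13-column tabular hit TSV into :class:`BlastHit` rows.

    A ``staxids`` cell containing ``;``-separated ids yields one hit per
    id, duplicating the row's other fields. Malformed rows raise
    :class:`FormatError` naming the line number.
    """
    hits: list[BlastHit] = []
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != len(BLAST_TAB_COLUMNS):
                raise FormatError(
                    f"{path}: line {lineno}: expected {len(BLAST_TAB_COLUMNS)} "
                    f"tab-separated columns, found {len(fields)}"
                )
            try:
                pident = float(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: unparseable pident {fields[2]!r}"
                ) from exc
            try:
                length, mismatch, gapopen = (int(f) for f in fields[3:6])
                qstart, qend, sstart, send = (int(f) for f in fields[6:10])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            for staxid in fields[12].split(";"):
                staxid = staxid.strip()
                if not staxid:
                    raise FormatError(
                        f"{path}: line {lineno}: empty taxon id in staxids cell"
                    )
                hits.append(
                    BlastHit(
                        qseqid=fields[0],
                        sseqid=fields[1],
                        pident=pident,
                        length=length,
                        mismatch=mismatch,
                        gapopen=gapopen,
                        qstart=qstart,
                        qend=qend,
                        sstart=sstart,
                        send=send,
                        evalue=evalue,
                        bitscore=bitscore,
                        staxid=staxid,
                    )
                )
    return hits


def write_blast_tab(hits: Iterable[BlastHit], path: PathLike) -> None:
    """Write hits in the 13-column dialect (one taxon id per row)."""
    with _open_text(path, "wt") as handle:
        for h in hits:
            handle.write(
                "\t".join(
                    (
                        h.qseqid,
                        h.sseqid,
                        f"{h.pident:.3f}",
                        str(h.length),
                        str(h.mismatch),
                        str(h.gapopen),
                        str(h.qstart),
                        str(h.qend),
                        str(h.sstart),
                        str(h.send),
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                        h.staxid,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Lineage TSV


def read_lineage_table(path: PathLike):
    """Read the 9-column lineage TSV into a :class:`~radbycatch.taxonomy.LineageStore`.

    Header line required; empty cells mean "rank unknown". Duplicate
    taxid rows: last wins, with a warning.
    """
    from .taxonomy import RANKS, UNKNOWN, Lineage, LineageStore

    entries: dict[str, Lineage] = {}
    with _open_text(path) as handle:
        header = handle.readline()
        if not header or tuple(header.rstrip("\n").split("\t")) != LINEAGE_COLUMNS:
            raise FormatError(
                f"{path}: missing or malformed header; expected "
                + "\t".join(LINEAGE_COLUMNS)
            )
        for lineno, raw in enumerate(handle, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != len(LINEAGE_COLUMNS):
                raise FormatError(
                    f"{path}: line {lineno}: expected {len(LINEAGE_COLUMNS)} "
                    f"columns, found {len(fields)}"
                )
            taxid = fields[0].strip()
            if not taxid:
                raise FormatError(f"{path}: line {lineno}: empty taxid")
            labels = {
                rank: (cell.strip() or UNKNOWN)
                for rank, cell in zip(RANKS, fields[1:])
            }
            if taxid in entries:
                logger.warning(
                    "%s: line %d: duplicate taxid %r; last row wins", path, lineno, taxid
                )
            entries[taxid] = Lineage(taxid=taxid, labels=labels)
    return LineageStore(entries)


def write_lineage_table(lineages, path: PathLike) -> None:
    """Write lineages as the 9-column TSV with header."""
    from .taxonomy import RANKS, UNKNOWN

    with _open_text(path, "wt") as handle:
        handle.write("\t".join(LINEAGE_COLUMNS) + "\n")
        for lin in lineages:
            cells = [lin.taxid] + [
                "" if lin.labels[rank] == UNKNOWN else lin.labels[rank]
                for rank in RANKS
            ]
            handle.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Community-matrix CSV


def write_community_csv(matrix, path: PathLike) -> None:
    """Write a CommunityMatrix as CSV: first column ``sample``, then taxa."""
    matrix.to_dataframe().to_csv(path, index=True, index_label="sample")


def read_community_csv(path: PathLike):
    """Read a community-matrix CSV written by :func:`write_community_csv`."""
    from .community import CommunityMatrix

    df = pd.read_csv(path, index_col="sample")
    return CommunityMatrix.from_dataframe(df)
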