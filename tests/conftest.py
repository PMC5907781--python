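from __future__ import annotations

import pytest

from radbycatch.formats import BlastHit
from radbycatch.taxonomy import RANKS, UNKNOWN, Lineage, LineageStore


def make_lineage(taxid: str, **labels: str) -> Lineage:
    full = {rank: UNKNOWN for rank in RANKS}
    full.update(labels)
    return Lineage(taxid=taxid, labels=full)


@pytest.fixture
def lineage_store() -> LineageStore:
    """A small offline taxonomy spanning kingdoms and phyla."""
    store = LineageStore()
    store.add(
        make_lineage(
            "9606",
            superkingdom="Eukaryota",
            kingdom="Metazoa",
            phylum="Chordata",
            genus="Homo",
            species="Homo sapiens",
        )
    )
    store.add(
        make_lineage(
            "6182",
            superkingdom="Eukaryota",
            kingdom="Metazoa",
            phylum="Platyhelminthes",
            genus="Schistosoma",
            species="Schistosoma mansoni",
        )
    )
    store.add(
        make_lineage(
            "6279",
            superkingdom="Eukaryota",
            kingdom="Metazoa",
            phylum="Nematoda",
            genus="Brugia",
            species="Brugia malayi",
        )
    )
    store.add(
        make_lineage(
            "5821",
            superkingdom="Eukaryota",
            kingdom="Chromista",
            phylum="Apicomplexa",
            genus="Plasmodium",
            species="Plasmodium berghei",
        )
    )
    store.add(
        make_lineage(
            "562",
            superkingdom="Bacteria",
            phylum="Proteobacteria",
            genus="Escherichia",
            species="Escherichia coli",
        )
    )
    # known superkingdom, sentinel everything below
    store.add(make_lineage("777", superkingdom="Eukaryota"))
    return store


@pytest.fixture
def make_hit():
    """Factory for hits with sensible defaults; override what matters."""

    def _make(
        qseqid: str = "q1",
        staxid: str = "9606",
        pident: float = 95.0,
        bitscore: float = 190.0,
        sseqid: str | None = None,
        evalue: float = 1e-30,
        length: int = 100,
    ) -> BlastHit:
        return BlastHit(
            qseqid=qseqid,
            sseqid=sseqid if sseqid is not None else f"ref_{staxid}",
            pident=pident,
            length=length,
            mismatch=round(length * (1 - pident / 100)),
            gapopen=0,
            qstart=1,
            qend=length,
            sstart=1,
            send=length,
            evalue=evalue,
            bitscore=bitscore,
            staxid=staxid,
        )

    return _make
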