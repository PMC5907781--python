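"""In-silico ddRAD: synthetic, truth-labelled inputs for every pipeline stage.

Generates random genomes, double-digests them at restriction recognition
sites, size-selects the fragments, emits (optionally mutated) reads, and
fabricates the 13-column alignment-hit tables those reads would produce —
so the downstream classification, community, and rarefaction stages can
be exercised end to end with known ground truth and no network access.

All coordinates here are 0-based half-open. All randomness flows through
``numpy.random.Generator`` seeded explicitly; fixed seed → bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats import (
    BlastHit,
    PathLike,
    SequenceRecord,
    write_blast_tab,
    write_fasta,
    write_lineage_table,
)
from .taxonomy import RANKS, UNKNOWN, Lineage

TERMINUS = "terminus"

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_ALTERNATIVES = {
    b: [x for x in "ACGT" if x != b] for b in "ACGT"
}


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: recognition site and top-strand cut offset.

    ``cut_offset`` is measured from the recognition-site start. The two
    defaults below are palindromic, so top-strand scanning covers both
    strands; non-palindromic recognition sequences are accepted but
    logged by :func:`digest`.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition or set(self.recognition) - set("ACGT"):
            raise ValueError(f"bad recognition sequence {self.recognition!r}")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(
                f"cut_offset {self.cut_offset} outside recognition site"
            )

    @property
    def is_palindromic(self) -> bool:
        comp = str.maketrans("ACGT", "TGCA")
        return self.recognition == self.recognition.translate(comp)[::-1]


ECORI = Enzyme(name="EcoRI", recognition="GAATTC", cut_offset=1)
MSPI = Enzyme(name="MspI", recognition="CCGG", cut_offset=1)
DEFAULT_ENZYMES = (ECORI, MSPI)


@dataclass(frozen=True)
class RestrictionFragment:
    """One digest interval on a source sequence (0-based half-open)."""

    source_id: str
    start: int
    end: int
    left_end: str
    right_end: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty fragment [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth label for one emitted read."""

    read_id: str
    taxid: str
    phylum: str
    genus: str
    species: str
    mutations: int


@dataclass(frozen=True)
class PlantedTaxon:
    """Lineage planted on a simulated source genome."""

    taxid: str
    phylum: str
    genus: str
    species: str
    superkingdom: str = "Eukaryota"
    kingdom: str = "Metazoa"

    def to_lineage(self) -> Lineage:
        labels = {rank: UNKNOWN for rank in RANKS}
        labels.update(
            superkingdom=self.superkingdom,
            kingdom=self.kingdom,
            phylum=self.phylum,
            genus=self.genus,
            species=self.species,
        )
        return Lineage(taxid=self.taxid, labels=labels)


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_genome(
    length: int,
    gc_fraction: float,
    seed: int | np.random.Generator,
    name: str = "genome",
) -> SequenceRecord:
    """Random genome with the requested expected GC proportion."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction out of [0,1]: {gc_fraction}")
    rng = _as_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    draws = rng.choice(4, size=length, p=[at, gc, gc, at])  # A C G T
    sequence = _BASES[draws].tobytes().decode("ascii")
    return SequenceRecord(id=name, sequence=sequence)


def _site_occurrences(sequence: str, motif: str) -> list[int]:
    # overlapping occurrences all counted
    out = []
    pos = sequence.find(motif)
    while pos != -1:
        out.append(pos)
        pos = sequence.find(motif, pos + 1)
    return out


def digest(
    genome: SequenceRecord, enzymes: Sequence[Enzyme] = DEFAULT_ENZYMES
) -> list[RestrictionFragment]:
    """Cut a genome at every recognition site of every enzyme.

    Cut positions are ``site_start + cut_offset``; the fragments between
    consecutive cuts (including both genome termini) tile the genome
    exactly. Each internal boundary is labelled with its cutting enzyme;
    the outermost ends are labelled ``terminus``. Cuts that would land on
    a genome boundary are ignored (no empty fragments). If two enzymes
    cut at the same position, the first in ``enzymes`` labels it.
    """
    if not enzymes:
        raise ValueError("at least one enzyme required")
    seq = genome.sequence
    length = len(seq)
    cut_enzyme: dict[int, str] = {}
    for enzyme in enzymes:
        if not enzyme.is_palindromic:
            import logging

            logging.getLogger(__name__).info(
                "enzyme %s recognition %s is not palindromic; scanning top strand only",
                enzyme.name,
                enzyme.recognition,
            )
        for site in _site_occurrences(seq, enzyme.recognition):
            cut = site + enzyme.cut_offset
            if 0 < cut < length:
                cut_enzyme.setdefault(cut, enzyme.name)
    cuts = sorted(cut_enzyme)
    bounds = [0] + cuts + [length]
    fragments = []
    for start, end in zip(bounds, bounds[1:]):
        fragments.append(
            RestrictionFragment(
                source_id=genome.id,
                start=start,
                end=end,
                left_end=cut_enzyme.get(start, TERMINUS),
                right_end=cut_enzyme.get(end, TERMINUS),
            )
        )
    return fragments


def fragment_sequence(fragment: RestrictionFragment, genome: SequenceRecord) -> str:
    if fragment.source_id != genome.id:
        raise ValueError(
            f"fragment source {fragment.source_id!r} != genome id {genome.id!r}"
        )
    return genome.sequence[fragment.start : fragment.end]


def ddrad_select(
    fragments: Iterable[RestrictionFragment],
    min_len: int = 200,
    max_len: int = 300,
    require_ends: tuple[str, str] = ("EcoRI", "MspI"),
) -> list[RestrictionFragment]:
    """Size selection + library-chemistry end rule.

    Keeps fragments whose length is within [min_len, max_len] (inclusive)
    and whose two ends are exactly one of each required enzyme, in either
    orientation. Fragments touching a genome terminus never pass.
    """
    wanted = frozenset(require_ends)
    if len(wanted) != 2:
        raise ValueError("require_ends must name two distinct enzymes")
    return [
        f
        for f in fragments
        if min_len <= len(f) <= max_len and {f.left_end, f.right_end} == wanted
    ]


def emit_reads(
    fragments: Sequence[RestrictionFragment],
    genomes: Mapping[str, SequenceRecord],
    taxa: Mapping[str, PlantedTaxon],
    read_len: int = 125,
    sub_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    id_prefix: str = "read",
) -> tuple[list[SequenceRecord], list[TruthRecord]]:
    """One single-end read per fragment: its first ``read_len`` bases.

    Substitutions are planted i.i.d. at ``sub_rate`` per base, never to
    the same base; realized mutation counts go into the truth records.
    """
    if not 0.0 <= sub_rate < 0.5:
        raise ValueError(f"sub_rate out of [0, 0.5): {sub_rate}")
    rng = _as_rng(seed)
    reads: list[SequenceRecord] = []
    truths: list[TruthRecord] = []
    for i, frag in enumerate(fragments):
        genome = genomes[frag.source_id]
        taxon = taxa[frag.source_id]
        template = fragment_sequence(frag, genome)[:read_len]
        bases = list(template)
        mutations = 0
        if sub_rate > 0.0:
            mask = rng.random(len(bases)) < sub_rate
            for j in np.nonzero(mask)[0]:
                bases[j] = _ALTERNATIVES[bases[j]][rng.integers(3)]
                mutations += 1
        read_id = f"{id_prefix}_{i}"
        reads.append(SequenceRecord(id=read_id, sequence="".join(bases)))
        truths.append(
            TruthRecord(
                read_id=read_id,
                taxid=taxon.taxid,
                phylum=taxon.phylum,
                genus=taxon.genus,
                species=taxon.species,
                mutations=mutations,
            )
        )
    return reads, truths


def synth_hit_table(
    reads: Sequence[SequenceRecord],
    truths: Sequence[TruthRecord],
    decoys: Mapping[str, Sequence[tuple[str, float]]] | None = None,
) -> list[BlastHit]:
    """Fabricate the hit table an aligner would produce for these reads.

    Each read gets one "true" hit against its source taxon at
    ``pident = 100 * (1 - mutations / read_length)``; ``decoys`` maps
    read ids to extra ``(staxid, pident)`` hits against other taxa, used
    to exercise the ambiguity rule. Bitscore is monotone in pident by
    construction (``bitscore = 2 * pident``); evalue decreases with
    pident.
    """
    if len(reads) != len(truths):
        raise ValueError("reads and truths must align one-to-one")
    decoys = decoys or {}
    hits: list[BlastHit] = []

    def _hit(read: SequenceRecord, sseqid: str, staxid: str, pident: float) -> BlastHit:
        n = len(read)
        mismatch = round(n * (1.0 - pident / 100.0))
        return BlastHit(
            qseqid=read.id,
            sseqid=sseqid,
            pident=round(pident, 3),
            length=n,
            mismatch=mismatch,
            gapopen=0,
            qstart=1,
            qend=n,
            sstart=1,
            send=n,
            evalue=10.0 ** (-pident / 10.0),
            bitscore=round(2.0 * pident, 1),
            staxid=staxid,
        )

    for read, truth in zip(reads, truths):
        if truth.read_id != read.id:
            raise ValueError(f"truth record {truth.read_id} does not match read {read.id}")
        pident = 100.0 * (1.0 - truth.mutations / len(read))
        hits.append(_hit(read, f"ref_{truth.taxid}", truth.taxid, pident))
        for staxid, decoy_pident in decoys.get(read.id, ()):
            hits.append(_hit(read, f"decoy_{staxid}", staxid, decoy_pident))
    return hits


# ---------------------------------------------------------------------------
# Scenario builder: host + parasites, multiple samples

DEFAULT_TAXA = (
    PlantedTaxon(taxid="9001", phylum="Chordata", genus="Sauria", species="Sauria synthetica"),
    PlantedTaxon(taxid="9101", phylum="Platyhelminthes", genus="Schistosoma", species="Schistosoma simulatum"),
    PlantedTaxon(taxid="9102", phylum="Nematoda", genus="Strongyloides", species="Strongyloides fictus"),
    PlantedTaxon(
        taxid="9103",
        phylum="Apicomplexa",
        genus="Plasmodium",
        species="Plasmodium exemplum",
        kingdom="Chromista",
    ),
)


@dataclass
class SimulatedSample:
    sample_id: str
    reads: list[SequenceRecord]
    truths: list[TruthRecord]
    hits: list[BlastHit]


@dataclass
class SimulatedDataset:
    """Everything one in-silico experiment produced, truth included."""

    taxa: tuple[PlantedTaxon, ...]
    genomes: dict[str, SequenceRecord]
    selected_fragments: dict[str, list[RestrictionFragment]]
    samples: dict[str, SimulatedSample]

    def lineages(self) -> list[Lineage]:
        return [t.to_lineage() for t in self.taxa]


def simulate_dataset(
    seed: int,
    n_samples: int = 3,
    host_length: int = 150_000,
    parasite_length: int = 60_000,
    gc_fraction: float = 0.5,
    sub_rate: float = 0.0,
    read_len: int = 125,
    min_len: int = 200,
    max_len: int = 300,
    parasite_keep_prob: float = 0.7,
    taxa: Sequence[PlantedTaxon] = DEFAULT_TAXA,
    decoys: Mapping[str, Sequence[tuple[str, float]]] | None = None,
) -> SimulatedDataset:
    """Host + parasite genomes → digested, size-selected, mutated reads.

    The first taxon is the host (its genome uses ``host_length``); every
    sample receives reads from all of the host's selected fragments plus
    an independent Bernoulli(``parasite_keep_prob``) subset of each
    parasite's fragments, so samples differ but share loci.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    root = np.random.SeedSequence(seed)
    genome_seeds, sample_seeds = root.spawn(2)
    genome_children = genome_seeds.spawn(len(taxa))

    genomes: dict[str, SequenceRecord] = {}
    selected: dict[str, list[RestrictionFragment]] = {}
    taxa_by_source: dict[str, PlantedTaxon] = {}
    for i, (taxon, child) in enumerate(zip(taxa, genome_children)):
        length = host_length if i == 0 else parasite_length
        genome = random_genome(
            length, gc_fraction, np.random.default_rng(child), name=f"src_{taxon.taxid}"
        )
        genomes[genome.id] = genome
        taxa_by_source[genome.id] = taxon
        selected[genome.id] = ddrad_select(
            digest(genome), min_len=min_len, max_len=max_len
        )

    host_source = f"src_{taxa[0].taxid}"
    samples: dict[str, SimulatedSample] = {}
    for s, child in enumerate(sample_seeds.spawn(n_samples), start=1):
        rng = np.random.default_rng(child)
        sample_id = f"sample{s}"
        fragments = list(selected[host_source])
        for source_id, frags in selected.items():
            if source_id == host_source:
                continue
            keep = rng.random(len(frags)) < parasite_keep_prob
            fragments.extend(f for f, k in zip(frags, keep) if k)
        reads, truths = emit_reads(
            fragments,
            genomes,
            taxa_by_source,
            read_len=read_len,
            sub_rate=sub_rate,
            seed=rng,
            id_prefix=sample_id,
        )
        hits = synth_hit_table(reads, truths, decoys=decoys)
        samples[sample_id] = SimulatedSample(
            sample_id=sample_id, reads=reads, truths=truths, hits=hits
        )
    return SimulatedDataset(
        taxa=tuple(taxa),
        genomes=genomes,
        selected_fragments=selected,
        samples=samples,
    )


def write_truth_table(truths: Iterable[TruthRecord], path: PathLike) -> None:
    with open(path, "w") as handle:
        handle.write("read_id\ttaxid\tphylum\tgenus\tspecies\tmutations\n")
        for t in truths:
            handle.write(
                f"{t.read_id}\t{t.taxid}\t{t.phylum}\t{t.genus}\t{t.species}\t{t.mutations}\n"
            )


def write_dataset(dataset: SimulatedDataset, outdir: PathLike) -> dict[str, Path]:
    """Write references, per-sample reads/hits/truth, and the lineage TSV.

    Returns a name → path map of everything written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    refs = outdir / "references.fasta"
    write_fasta(dataset.genomes.values(), refs)
    paths["references"] = refs
    lineage = outdir / "lineage.tsv"
    write_lineage_table(dataset.lineages(), lineage)
    paths["lineage"] = lineage
    for sample_id, sample in dataset.samples.items():
        reads_path = outdir / f"{sample_id}.reads.fasta"
        write_fasta(sample.reads, reads_path)
        paths[f"{sample_id}.reads"] = reads_path
        hits_path = outdir / f"{sample_id}.hits.tsv"
        write_blast_tab(sample.hits, hits_path)
        paths[f"{sample_id}.hits"] = hits_path
        truth_path = outdir / f"{sample_id}.truth.tsv"
        write_truth_table(sample.truths, truth_path)
        paths[f"{sample_id}.truth"] = truth_path
    return paths
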