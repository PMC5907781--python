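from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radbycatch.classify import classify_query, group_hits_by_query
from radbycatch.formats import SequenceRecord, read_blast_tab, write_blast_tab
from radbycatch.simulate import (
    DEFAULT_ENZYMES,
    ECORI,
    MSPI,
    TERMINUS,
    Enzyme,
    PlantedTaxon,
    RestrictionFragment,
    ddrad_select,
    digest,
    emit_reads,
    fragment_sequence,
    random_genome,
    simulate_dataset,
    synth_hit_table,
)
from radbycatch.taxonomy import LineageStore

HOST = PlantedTaxon(taxid="9001", phylum="Chordata", genus="Sauria", species="S. s")
WORM = PlantedTaxon(
    taxid="9101", phylum="Platyhelminthes", genus="Schistosoma", species="S. x"
)


def store_for(*taxa: PlantedTaxon) -> LineageStore:
    store = LineageStore()
    for t in taxa:
        store.add(t.to_lineage())
    return store


class TestEnzymes:
    def test_defaults(self):
        assert ECORI.recognition == "GAATTC" and ECORI.cut_offset == 1
        assert MSPI.recognition == "CCGG" and MSPI.cut_offset == 1
        assert ECORI.is_palindromic and MSPI.is_palindromic

    def test_invalid_offset(self):
        with pytest.raises(ValueError):
            Enzyme("x", "ACGT", 5)

    def test_invalid_recognition(self):
        with pytest.raises(ValueError):
            Enzyme("x", "ACGU", 1)


class TestRandomGenome:
    def test_deterministic(self):
        a = random_genome(500, 0.4, seed=11)
        b = random_genome(500, 0.4, seed=11)
        assert a == b

    def test_gc_zero_is_at_only(self):
        g = random_genome(1000, 0.0, seed=1)
        assert set(g.sequence) <= {"A", "T"}

    def test_gc_one_is_gc_only(self):
        g = random_genome(1000, 1.0, seed=1)
        assert set(g.sequence) <= {"G", "C"}

    def test_gc_within_3_binomial_sd(self):
        # [DERIVED] binomial bound at length 1e5, p=0.5
        n = 100_000
        g = random_genome(n, 0.5, seed=7)
        gc = sum(1 for b in g.sequence if b in "GC") / n
        sd = (0.5 * 0.5 / n) ** 0.5
        assert abs(gc - 0.5) <= 3 * sd

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            random_genome(0, 0.5, seed=1)
        with pytest.raises(ValueError):
            random_genome(10, 1.5, seed=1)


class TestDigest:
    def test_worked_example(self):
        # [DERIVED] GAATTC at 0-based 2 cuts at 3; CCGG at 10 cuts at 11
        genome = SequenceRecord("g", "AAGAATTCAACCGGTT")
        frags = digest(genome, DEFAULT_ENZYMES)
        assert [(f.start, f.end, f.left_end, f.right_end) for f in frags] == [
            (0, 3, TERMINUS, "EcoRI"),
            (3, 11, "EcoRI", "MspI"),
            (11, 16, "MspI", TERMINUS),
        ]

    def test_no_sites_single_fragment(self):
        genome = SequenceRecord("g", "AAAATTTT")
        (frag,) = digest(genome, DEFAULT_ENZYMES)
        assert (frag.start, frag.end) == (0, 8)
        assert frag.left_end == frag.right_end == TERMINUS

    def test_overlapping_occurrences_all_counted(self):
        enz = Enzyme("tri", "AAA", 1)
        frags = digest(SequenceRecord("g", "CAAAAC"), [enz])
        # AAA at 1 and 2 -> cuts {2, 3}
        assert [(f.start, f.end) for f in frags] == [(0, 2), (2, 3), (3, 6)]

    def test_boundary_cut_ignored(self):
        # CCGG at position 0 would cut at 1; at the very end cut==L is dropped
        enz = Enzyme("end", "GG", 2)
        frags = digest(SequenceRecord("g", "AAGG"), [enz])
        assert [(f.start, f.end) for f in frags] == [(0, 4)]

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), length=st.integers(50, 5000))
    def test_tiling(self, seed, length):
        genome = random_genome(length, 0.6, seed=seed)
        frags = digest(genome, DEFAULT_ENZYMES)
        assert frags[0].start == 0 and frags[-1].end == length
        assert all(a.end == b.start for a, b in zip(frags, frags[1:]))
        rebuilt = "".join(fragment_sequence(f, genome) for f in frags)
        assert rebuilt == genome.sequence

    def test_internal_boundaries_are_cut_sites(self):
        genome = random_genome(5000, 0.6, seed=3)
        frags = digest(genome, DEFAULT_ENZYMES)
        for frag in frags[1:]:
            enzyme = {e.name: e for e in DEFAULT_ENZYMES}[frag.left_end]
            site_start = frag.start - enzyme.cut_offset
            assert (
                genome.sequence[site_start : site_start + len(enzyme.recognition)]
                == enzyme.recognition
            )


def frag(length, left="EcoRI", right="MspI", source="g", start=0):
    return RestrictionFragment(
        source_id=source, start=start, end=start + length, left_end=left, right_end=right
    )


class TestSizeSelection:
    def test_window_inclusive(self):
        frags = [frag(150), frag(200), frag(250), frag(300), frag(301)]
        kept = ddrad_select(frags)
        assert [len(f) for f in kept] == [200, 250, 300]

    def test_end_rule_one_of_each(self):
        assert ddrad_select([frag(250, "EcoRI", "EcoRI")]) == []
        assert ddrad_select([frag(250, "MspI", "EcoRI")]) != []

    def test_termini_never_pass(self):
        assert ddrad_select([frag(250, TERMINUS, "MspI")]) == []
        assert ddrad_select([frag(250, TERMINUS, TERMINUS)]) == []

    def test_bad_require_ends(self):
        with pytest.raises(ValueError):
            ddrad_select([], require_ends=("EcoRI", "EcoRI"))


class TestEmitReads:
    def setup_method(self):
        self.genome = random_genome(2000, 0.5, seed=5, name="src_9001")
        self.frags = [
            RestrictionFragment("src_9001", 0, 250, "EcoRI", "MspI"),
            RestrictionFragment("src_9001", 250, 330, "MspI", "EcoRI"),
        ]
        self.genomes = {"src_9001": self.genome}
        self.taxa = {"src_9001": HOST}

    def test_zero_sub_rate_exact_prefixes(self):
        reads, truths = emit_reads(
            self.frags, self.genomes, self.taxa, read_len=125, sub_rate=0.0, seed=1
        )
        assert reads[0].sequence == self.genome.sequence[:125]
        assert all(t.mutations == 0 for t in truths)

    def test_short_fragment_whole(self):
        reads, _ = emit_reads(
            self.frags, self.genomes, self.taxa, read_len=125, sub_rate=0.0, seed=1
        )
        assert len(reads[1]) == 80

    def test_one_truth_per_read(self):
        reads, truths = emit_reads(
            self.frags, self.genomes, self.taxa, seed=1
        )
        assert [r.id for r in reads] == [t.read_id for t in truths]
        assert truths[0].phylum == "Chordata"

    def test_deterministic(self):
        a = emit_reads(self.frags, self.genomes, self.taxa, sub_rate=0.2, seed=9)
        b = emit_reads(self.frags, self.genomes, self.taxa, sub_rate=0.2, seed=9)
        assert a == b

    def test_mutations_never_to_same_base(self):
        reads, truths = emit_reads(
            self.frags, self.genomes, self.taxa, read_len=125, sub_rate=0.3, seed=2
        )
        template = self.genome.sequence[:125]
        diffs = sum(1 for a, b in zip(template, reads[0].sequence) if a != b)
        assert diffs == truths[0].mutations

    def test_mean_identity_within_3_sd(self):
        # [DERIVED] binomial: B bases at sub_rate 0.1
        genome = random_genome(200_000, 0.5, seed=8, name="src_9001")
        frags = [
            RestrictionFragment("src_9001", i, i + 100, "EcoRI", "MspI")
            for i in range(0, 100_000, 100)
        ]
        reads, truths = emit_reads(
            frags,
            {"src_9001": genome},
            {"src_9001": HOST},
            read_len=100,
            sub_rate=0.1,
            seed=3,
        )
        total_bases = sum(len(r) for r in reads)
        total_mut = sum(t.mutations for t in truths)
        p = total_mut / total_bases
        sd = (0.1 * 0.9 / total_bases) ** 0.5
        assert abs(p - 0.1) <= 3 * sd

    def test_bad_sub_rate(self):
        with pytest.raises(ValueError):
            emit_reads(self.frags, self.genomes, self.taxa, sub_rate=0.6, seed=1)


class TestSynthHitTable:
    def make(self, sub_rate=0.0, decoys=None):
        genome = random_genome(3000, 0.5, seed=4, name="src_9001")
        frags = [RestrictionFragment("src_9001", i, i + 250, "EcoRI", "MspI") for i in (0, 300, 600)]
        reads, truths = emit_reads(
            frags,
            {"src_9001": genome},
            {"src_9001": HOST},
            read_len=125,
            sub_rate=sub_rate,
            seed=6,
        )
        return reads, truths, synth_hit_table(reads, truths, decoys=decoys)

    def test_clean_reads_hit_at_100(self):
        _, _, hits = self.make()
        assert all(h.pident == 100.0 for h in hits)
        assert all(h.staxid == "9001" for h in hits)

    def test_pident_reflects_mutations(self):
        reads, truths, hits = self.make(sub_rate=0.05)
        for read, truth, hit in zip(reads, truths, hits):
            assert hit.pident == pytest.approx(
                100 * (1 - truth.mutations / len(read)), abs=1e-3
            )

    def test_decoy_at_85_makes_query_ambiguous(self):
        reads, truths, hits = self.make(decoys={"read_0": [("9101", 85.0)]})
        store = store_for(HOST, WORM)
        grouped = group_hits_by_query(hits)
        assert classify_query(grouped["read_0"], store, 97).status == "ambiguous"
        assert classify_query(grouped["read_1"], store, 97).status == "classified"

    def test_decoy_below_floor_stays_classifiable(self):
        _, _, hits = self.make(decoys={"read_0": [("9101", 79.0)]})
        store = store_for(HOST, WORM)
        grouped = group_hits_by_query(hits)
        cls = classify_query(grouped["read_0"], store, 97)
        assert cls.status == "classified" and cls.phylum == "Chordata"

    def test_bitscore_monotone_in_pident(self):
        _, _, hits = self.make(sub_rate=0.1, decoys={"read_0": [("9101", 85.0)]})
        ranked = sorted(hits, key=lambda h: h.pident)
        scores = [h.bitscore for h in ranked]
        assert scores == sorted(scores)

    def test_tsv_round_trip(self, tmp_path):
        _, _, hits = self.make(decoys={"read_0": [("9101", 85.0)]})
        p = tmp_path / "hits.tsv"
        write_blast_tab(hits, p)
        got = read_blast_tab(p)
        assert [(h.qseqid, h.staxid, h.pident) for h in got] == [
            (h.qseqid, h.staxid, h.pident) for h in hits
        ]


class TestScenario:
    def test_bit_for_bit_determinism(self):
        a = simulate_dataset(seed=123, host_length=30_000, parasite_length=15_000)
        b = simulate_dataset(seed=123, host_length=30_000, parasite_length=15_000)
        for sid in a.samples:
            assert a.samples[sid].reads == b.samples[sid].reads
            assert a.samples[sid].hits == b.samples[sid].hits
        assert a.genomes == b.genomes

    def test_seed_changes_output(self):
        a = simulate_dataset(seed=1, host_length=30_000, parasite_length=15_000)
        b = simulate_dataset(seed=2, host_length=30_000, parasite_length=15_000)
        assert a.genomes != b.genomes

    def test_samples_share_host_fragments(self):
        ds = simulate_dataset(
            seed=5, host_length=60_000, parasite_length=20_000, parasite_keep_prob=0.5
        )
        host_counts = {
            sid: sum(1 for t in s.truths if t.phylum == "Chordata")
            for sid, s in ds.samples.items()
        }
        expected = len(ds.selected_fragments["src_9001"])
        assert all(v == expected for v in host_counts.values())

    def test_lineage_covers_all_planted_taxa(self):
        ds = simulate_dataset(seed=5, host_length=30_000, parasite_length=15_000)
        taxids = {lin.taxid for lin in ds.lineages()}
        for sample in ds.samples.values():
            assert {t.taxid for t in sample.truths} <= taxids
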