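# radbycatch

Mine metagenomic "bycatch" from reduced-representation (ddRAD) sequencing
data. Host-targeted RAD libraries incidentally capture parasite and
microbial DNA; this package extracts representative locus sequences from
clustered RADseq output, classifies them taxonomically from alignment hit
tables under identity thresholds and an ambiguity-discard rule, and
summarizes the results as count tables, presence/absence matrices,
genus-level community matrices, and rarefaction curves. A built-in
in-silico ddRAD simulator (restriction digest, size selection, mutated
reads, truth-labelled hit tables) makes the whole pipeline testable
offline — no reference database or network access required.

## Pipeline

1. **Sequence preparation** — parse pyRAD-style `*.loci` files (and plain
   FASTA / `*.edit` files) and take the first sequence of each locus as
   its representative (`radbycatch extract`).
2. **Alignment (external)** — compare representatives to a nucleotide
   reference database with a discontiguous-megablast-style search,
   writing 13-column tabular output: the 12 standard columns plus subject
   taxon ids (`qseqid sseqid pident length mismatch gapopen qstart qend
   sstart send evalue bitscore staxids`). This step is out of process.
3. **Classification** (`radbycatch classify` / `sweep`) — per query:
   discard as *ambiguous* any query whose hits above 80% identity span
   more than one kingdom or phylum; otherwise assign the phylum / genus /
   species of the closest-matching hit if its identity meets the
   threshold (default 97; the sweep uses 70/80/85/90/95/97). Taxon ids
   resolve through an offline lineage TSV, not a live service.
4. **Community summaries** (`radbycatch community`) — per-sample phylum
   count tables, cross-host shared-locus presence/absence matrices, and
   genus-level community matrices (Chordata pooled, one column per
   parasite genus; default threshold 90).
5. **Rarefaction** (`radbycatch rarefy`) — exact hypergeometric expected
   richness E[S_n] = Σᵢ [1 − C(N−Nᵢ, n)/C(N, n)], evaluated in log space
   so totals in the millions are fine.

## CLI

```sh
# locus representatives -> FASTA
radbycatch extract loci_file.loci representatives.fasta

# classify a hit table at one threshold
radbycatch classify --hits sample.hits.tsv --lineage lineage.tsv \
    --threshold 97 --out sample.classifications.tsv

# per-phylum counts across the identity-threshold sweep
radbycatch sweep --hits sample.hits.tsv --lineage lineage.tsv --out sweep.csv

# community matrices from per-sample classification TSVs
radbycatch community s1=s1.tsv s2=s2.tsv \
    --phyla-out phylum_counts.csv --genus-out genus_matrix.csv

# rarefaction curves for each sample of a community matrix
radbycatch rarefy --matrix genus_matrix.csv --out curves.csv

# synthetic data, or the whole pipeline end to end on synthetic data
radbycatch simulate --config config.yaml --out simdir/
radbycatch demo --config config.yaml --out rundir/
```

`demo` runs simulate → classify → sweep → community → rarefy from a
single YAML config (all keys optional; see `radbycatch.cli.RunConfig`
for the full list and defaults, e.g. `seed`, `thresholds`, `sub_rate`,
`insert_min`/`insert_max`, `read_len`). Reruns with the same config and
seed are byte-identical. Logs go to stderr; results go to files.

Example config:

```yaml
seed: 42
n_samples: 3
sub_rate: 0.02
classify_threshold: 97
community_threshold: 90
```

## Simulator

`radbycatch.simulate` generates random genomes for a host (Chordata) and
three planted parasites (Platyhelminthes, Nematoda, Apicomplexa), digests
them with EcoRI (G^AATTC) + MspI (C^CGG), keeps 200–300 bp fragments with
one end per enzyme, emits 125 bp single-end reads with an optional
substitution rate, and fabricates the matching hit table, lineage TSV,
and per-read truth records. Decoy hits at chosen identities can be
planted to exercise the ambiguity rule. Everything is deterministic per
seed.

## File formats

- **FASTA** — multi-line, 80-column wrap; `.gz` pass-through.
- **`*.loci`** — member lines `<name><whitespace><sequence>`; separator
  lines start with `//`, an optional trailing `|N|` tag carries the
  locus id; `-` gap characters are stripped on read.
- **Hit TSV** — 13 tab-separated columns, no header; a `;`-separated
  `staxids` cell expands to one hit per taxon id. Coordinates are
  1-based inclusive.
- **Lineage TSV** — header
  `taxid superkingdom kingdom phylum class order family genus species`;
  empty cells mean "rank unknown"; duplicate taxids: last wins.
- **Community CSV** — first column `sample`, remaining columns taxon
  labels, integer cells.
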