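"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: classification is
re-derived with plain set logic, rarefaction by exhaustive subset
enumeration or Monte-Carlo subsampling.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np

from radbycatch.formats import BlastHit
from radbycatch.taxonomy import UNKNOWN, LineageStore


def brute_force_status(
    hits: Sequence[BlastHit],
    store: LineageStore,
    threshold: float,
    floor: float = 80.0,
) -> str:
    """Re-derive a query's classification status by direct enumeration."""
    if len(hits) == 0:
        return "no_hit"
    for rank in ("superkingdom", "kingdom", "phylum"):
        labels = set()
        for h in hits:
            if h.pident > floor:
                label = store.resolve(h.staxid).labels[rank]
                if label != UNKNOWN:
                    labels.add(label)
        if len(labels) > 1:
            return "ambiguous"
    # best hit: highest bitscore, then pident, then lowest evalue, then ids
    ranked = sorted(
        hits, key=lambda h: (h.bitscore, h.pident, -h.evalue), reverse=True
    )
    top_key = (ranked[0].bitscore, ranked[0].pident, -ranked[0].evalue)
    tied = [h for h in ranked if (h.bitscore, h.pident, -h.evalue) == top_key]
    best = sorted(tied, key=lambda h: (h.sseqid, h.staxid))[0]
    if best.pident < threshold:
        return "below_threshold"
    if store.resolve(best.staxid).labels["phylum"] == UNKNOWN:
        return "unresolvable"
    return "classified"


def brute_force_best(hits: Sequence[BlastHit], store: LineageStore) -> BlastHit:
    ranked = sorted(
        hits, key=lambda h: (h.bitscore, h.pident, -h.evalue), reverse=True
    )
    top_key = (ranked[0].bitscore, ranked[0].pident, -ranked[0].evalue)
    tied = [h for h in ranked if (h.bitscore, h.pident, -h.evalue) == top_key]
    return sorted(tied, key=lambda h: (h.sseqid, h.staxid))[0]


def enumerate_expected_richness(counts: Sequence[int], n: int) -> float:
    """Mean richness over ALL C(N, n) subsamples, by explicit enumeration."""
    individuals = [
        taxon for taxon, count in enumerate(counts) for _ in range(count)
    ]
    combos = list(itertools.combinations(individuals, n))
    if not combos:
        return 0.0
    return sum(len(set(c)) for c in combos) / len(combos)


def monte_carlo_richness(
    counts: Sequence[int], n: int, replicates: int, rng: np.random.Generator
) -> tuple[float, float]:
    """(mean, standard error) of richness over random subsamples of size n."""
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    draws = rng.multivariate_hypergeometric(counts, n, size=replicates)
    richness = (draws > 0).sum(axis=1)
    return float(richness.mean()), float(richness.std(ddof=1) / np.sqrt(replicates))
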