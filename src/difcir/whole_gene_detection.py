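"""Detection of eccDNA carrying whole genes.

Most differentially produced circles carry gene fragments; this module finds
the exceptions — circles that fully contain a gene body — and summarises
their recurrence across samples.  Containment is inclusive at both ends on
the half-open convention: a circle whose coordinates equal the gene's
carries the full gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .formats_io import CircleCall, GeneModel

__all__ = ["WholeGeneHit", "find_whole_gene_circles"]


@dataclass(frozen=True)
class WholeGeneHit:
    """A gene fully contained in >= 1 circle, with the samples showing it."""

    gene_id: str
    gene_length: int
    samples_with_hit: frozenset[str]

    @property
    def n_samples(self) -> int:
        return len(self.samples_with_hit)


def find_whole_gene_circles(
    calls_by_sample: dict[str, list[CircleCall]],
    genes: list[GeneModel],
    min_samples: int = 2,
) -> tuple[list[WholeGeneHit], pd.DataFrame]:
    """Find genes wholly carried by a circle in >= min_samples samples.

    Gene g is hit in sample s when some circle of s satisfies
    ``chrom == g.chrom and start <= g.start and end >= g.end``.  Returns the
    hits with at least ``min_samples`` supporting samples, sorted by
    n_samples descending then gene_id, plus the full Boolean gene x sample
    presence matrix (1 = the sample has a circle carrying the whole gene),
    restricted to genes hit in at least one sample.
    """
    # genes nested inside a circle = envelop query on a per-chromosome gene tree
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)

    hits: dict[str, set[str]] = {}
    for sid, calls in calls_by_sample.items():
        for c in calls:
            tree = trees.get(c.chrom)
            if tree is None:
                continue
            for iv in tree.envelop(c.start, c.end + 1):  # inclusive end
                g = iv.data
                if c.start <= g.start and c.end >= g.end:
                    hits.setdefault(g.gene_id, set()).add(sid)

    length_of = {g.gene_id: g.length for g in genes}
    order = [g.gene_id for g in genes if g.gene_id in hits]
    sample_ids = list(calls_by_sample)
    presence = pd.DataFrame(
        [[int(s in hits[gid]) for s in sample_ids] for gid in order],
        index=order,
        columns=sample_ids,
        dtype=int,
    )
    selected = [
        WholeGeneHit(
            gene_id=gid,
            gene_length=length_of[gid],
            samples_with_hit=frozenset(hits[gid]),
        )
        for gid in order
        if len(hits[gid]) >= min_samples
    ]
    selected.sort(key=lambda h: (-h.n_samples, h.gene_id))
    return selected, presence
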