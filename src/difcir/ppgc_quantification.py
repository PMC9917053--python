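"""Per-gene circle quantification: the PpGC (Produced-per-Gene Circles) matrix.

Circles are annotated against gene bodies by >= 1 bp interval overlap; every
circle contributes its full split-read count to every gene it overlaps (no
apportioning).  The genes x samples matrix of split-read sums is then scaled
for gene length by the factor L_Max / L_i — L_Max the longest gene retained
in the table, L_i the gene's body length — and equalized by log2(x + 1),
matching the count-unit treatment of RNA-seq pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .formats_io import CircleCall, GeneModel, SampleSheet

__all__ = [
    "PpGCTable",
    "annotate_circles",
    "compute_ppgc",
    "scale_by_gene_length",
    "equalize",
]


@dataclass
class PpGCTable:
    """Genes x samples matrix of per-gene circle production.

    ``stage`` tracks the transform applied: ``raw`` (split-read sums),
    ``scaled`` (x L_Max/L_i) or ``equalized`` (log2(x+1) of the previous
    stage).  ``gene_lengths`` is aligned with ``gene_ids``; ``l_max`` is the
    scaling numerator once scaling has been applied.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)
    stage: str
    gene_lengths: np.ndarray  # bp, aligned with gene_ids
    l_max: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_lengths = np.asarray(self.gene_lengths)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match gene/sample ids")
        if len(self.gene_lengths) != len(self.gene_ids):
            raise ValueError("gene_lengths misaligned with gene_ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


def annotate_circles(
    calls: list[CircleCall], genes: list[GeneModel]
) -> list[tuple[CircleCall, str]]:
    """Pair every circle with every gene body it overlaps by >= 1 bp.

    A circle overlapping k genes yields k pairs; circles overlapping no gene
    yield none.  Pairs keep call order, then annotation order of the genes.
    """
    trees: dict[str, IntervalTree] = {}
    gene_rank = {g.gene_id: i for i, g in enumerate(genes)}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)

    pairs: list[tuple[CircleCall, str]] = []
    for c in calls:
        tree = trees.get(c.chrom)
        if tree is None:
            continue
        hits = sorted(
            (iv.data for iv in tree.overlap(c.start, c.end)),
            key=gene_rank.__getitem__,
        )
        pairs.extend((c, gid) for gid in hits)
    return pairs


def compute_ppgc(
    pairs: list[tuple[CircleCall, str]],
    samples: SampleSheet,
    genes: list[GeneModel],
) -> PpGCTable:
    """Unify circles by gene into the raw PpGC matrix.

    Cell (g, s) is the split-read sum of all circles of sample s overlapping
    gene g.  Genes with zero total across all samples are dropped; gene order
    follows the annotation, sample order the sample sheet.
    """
    sample_ids = samples.sample_ids
    sample_idx = {s: i for i, s in enumerate(sample_ids)}
    gene_idx = {g.gene_id: i for i, g in enumerate(genes)}
    lengths = np.array([g.length for g in genes])

    values = np.zeros((len(genes), len(sample_ids)))
    for call, gid in pairs:
        if call.sample_id not in sample_idx:
            raise ValueError(f"sample {call.sample_id!r} not in sample sheet")
        values[gene_idx[gid], sample_idx[call.sample_id]] += call.split_reads

    nonzero = values.sum(axis=1) > 0
    return PpGCTable(
        gene_ids=[g.gene_id for g, keep in zip(genes, nonzero) if keep],
        sample_ids=sample_ids,
        values=values[nonzero],
        stage="raw",
        gene_lengths=lengths[nonzero],
    )


def scale_by_gene_length(
    table: PpGCTable,
    *,
    annotation: list[GeneModel] | None = None,
) -> PpGCTable:
    """Scale every gene's row by L_Max / L_i.

    L_Max defaults to the longest gene retained in the table ("found in the
    dataset"); pass ``annotation`` to take the maximum over the whole gene
    annotation instead.  The longest gene's row is unchanged; no value
    shrinks.
    """
    if table.stage != "raw":
        raise ValueError(f"scaling expects a raw table, got stage={table.stage!r}")
    lengths = np.asarray(table.gene_lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive for scaling")
    if annotation is not None:
        l_max = max(g.length for g in annotation)
    else:
        l_max = int(lengths.max())
    factors = l_max / lengths
    return replace(table, values=table.values * factors[:, None],
                   stage="scaled", l_max=int(l_max))


def equalize(table: PpGCTable) -> PpGCTable:
    """Equalize values by the log2(x + 1) transform (variance stabilisation)."""
    if np.any(table.values < 0):
        raise ValueError("equalize requires non-negative values")
    return replace(table, values=np.log2(table.values + 1.0), stage="equalized")
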