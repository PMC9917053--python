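"""Democratic voting for Common PpGCs (CPpGCs) within a single group.

Genes that consistently produce circles in a group — but need not differ
between groups — are found by voting: each sample votes for a gene when its
equalized PpGC value reaches a data-derived threshold, the floor of the mode
of the group's empirical PpGC distribution; genes reaching a vote quorum
(default 4) are CPpGCs.  This characterises a group's genic eccDNA profile
even when no comparison group exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ppgc_quantification import PpGCTable

__all__ = [
    "VoteResult",
    "vote_threshold",
    "vote_cppgc",
    "cppgc_overlap",
]


@dataclass(frozen=True)
class VoteResult:
    """One gene's vote tally against the group threshold."""

    gene_id: str
    votes: int
    threshold: float
    is_cppgc: bool


def vote_threshold(
    table: PpGCTable,
    group_samples: list[str],
    *,
    bin_width: float = 0.5,
    smooth_window: int = 3,
) -> int:
    """Data-derived vote threshold: floor of the mode of the PpGC distribution.

    Pools all nonzero equalized PpGC values of the group's samples, histograms
    them with fixed ``bin_width``, smooths with a centered ``smooth_window``
    moving average, and returns the floor of the center of the highest
    smoothed bin (leftmost on ties).  Zeros are excluded: a zero-inflated
    mode would pin the threshold at 0 and make voting vacuous.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd and positive")
    cols = [table.sample_ids.index(s) for s in group_samples]
    if not cols:
        raise ValueError("group has no samples")
    pooled = table.values[:, cols].ravel()
    pooled = pooled[pooled > 0]
    if pooled.size == 0:
        raise ValueError("all PpGC values are zero; no distribution to threshold")

    n_bins = max(1, int(math.ceil(pooled.max() / bin_width)))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    hist, _ = np.histogram(pooled, bins=edges)
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(hist.astype(float), kernel, mode="same")
    # smoothing a narrow peak ties it with its neighbours; resolve ties by
    # the raw count, then leftmost
    candidates = np.flatnonzero(smoothed == smoothed.max())
    mode_bin = int(candidates[np.argmax(hist[candidates])])
    center = edges[mode_bin] + bin_width / 2
    return int(math.floor(center))


def vote_cppgc(
    table: PpGCTable,
    group_samples: list[str],
    threshold: float,
    min_votes: int = 4,
    *,
    strict: bool = False,
) -> list[VoteResult]:
    """Tally votes per gene and flag CPpGCs.

    A sample votes for a gene when its equalized value is >= threshold
    (> with ``strict``); a gene with at least ``min_votes`` votes is a
    CPpGC.  Results are sorted by votes descending, then gene_id.
    """
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if min_votes < 1:
        raise ValueError("min_votes must be >= 1")
    cols = [table.sample_ids.index(s) for s in group_samples]
    block = table.values[:, cols]
    votes = (block > threshold).sum(axis=1) if strict else (block >= threshold).sum(axis=1)
    results = [
        VoteResult(
            gene_id=gid,
            votes=int(v),
            threshold=float(threshold),
            is_cppgc=bool(v >= min_votes),
        )
        for gid, v in zip(table.gene_ids, votes)
    ]
    results.sort(key=lambda r: (-r.votes, r.gene_id))
    return results


def cppgc_overlap(
    results_a: list[VoteResult], results_b: list[VoteResult]
) -> tuple[set[str], set[str], set[str]]:
    """Partition CPpGC gene ids of two groups into (only_a, only_b, common)."""
    set_a = {r.gene_id for r in results_a if r.is_cppgc}
    set_b = {r.gene_id for r in results_b if r.is_cppgc}
    return set_a - set_b, set_b - set_a, set_a & set_b
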