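"""Differential per-gene circle production (DPpGC calling) between two groups.

For each gene the equalized PpGC values are averaged per group; the log2
fold change is the difference of group means (the values are already on the
log2 scale), and significance comes from the two-sided two-sample Student's
t-test with pooled variance.  A gene is an up-DPpGC in a group when
|log2 FC| >= theta (default 1) in that group's favour and p <= alpha
(default 0.05); p-values are reported raw, with Benjamini-Hochberg
correction available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import SampleSheet
from .ppgc_quantification import PpGCTable

__all__ = [
    "DifferentialParams",
    "DifferentialRecord",
    "pooled_ttest",
    "difcir",
    "records_to_frame",
    "compare_scaling_ranks",
    "length_bias_regression",
]


@dataclass(frozen=True)
class DifferentialParams:
    """Selection thresholds for DPpGC calling.

    theta: minimum |log2 fold change| (difference of equalized group means).
    alpha: maximum p-value.
    multiple_testing: "none" (raw p, the default) or "bh".
    welch: use Welch's unequal-variance t-test instead of pooled variance.
    """

    theta: float = 1.0
    alpha: float = 0.05
    multiple_testing: str = "none"
    welch: bool = False

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.multiple_testing not in {"none", "bh"}:
            raise ValueError(f"unknown multiple_testing: {self.multiple_testing!r}")


@dataclass(frozen=True)
class DifferentialRecord:
    """Per-gene differential result on the equalized scale."""

    gene_id: str
    mean_a: float
    mean_b: float
    log2fc: float  # mean_a - mean_b
    p_value: float
    direction: str  # up_in_A | up_in_B | none
    rank: int  # 1-based within direction


def pooled_ttest(
    a: np.ndarray, b: np.ndarray, *, welch: bool = False
) -> np.ndarray:
    """Row-wise two-sided two-sample Student's t-test p-values.

    ``a``, ``b`` are (n_genes, n_samples) blocks.  Pooled-variance (classical
    Student) by default, Welch optional.  Degenerate rows — zero variance in
    both groups — get p = 1 when the means agree (no evidence) and p = 0 when
    they differ (the t statistic diverges).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 samples for a t-test")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            se2 = va / na + vb / nb
            df = se2**2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        else:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            se2 = sp2 * (1.0 / na + 1.0 / nb)
            df = np.full(a.shape[0], na + nb - 2, dtype=float)
        t = (ma - mb) / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)

    degenerate = se2 == 0
    p[degenerate & (ma == mb)] = 1.0
    p[degenerate & (ma != mb)] = 0.0
    return p


def difcir(
    table: PpGCTable,
    samples: SampleSheet,
    params: DifferentialParams = DifferentialParams(),
) -> list[DifferentialRecord]:
    """Call DPpGCs from an equalized PpGC table.

    The sample sheet must define exactly two groups (>= 2 samples each);
    group A is the first label in sheet order, group B the second.  Records
    are returned as the up_in_A block, then up_in_B, then the non-selected
    genes, each block sorted by (p ascending, |log2fc| descending, gene_id)
    with 1-based ranks within its direction.
    """
    if table.stage != "equalized":
        raise ValueError(f"difcir expects an equalized table, got {table.stage!r}")
    labels = samples.group_labels
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    ga, gb = labels
    idx = {s: j for j, s in enumerate(table.sample_ids)}
    try:
        cols_a = [idx[s] for s in samples.samples_in(ga)]
        cols_b = [idx[s] for s in samples.samples_in(gb)]
    except KeyError as exc:
        raise ValueError(f"sample {exc.args[0]!r} missing from PpGC table") from None
    if min(len(cols_a), len(cols_b)) < 2:
        raise ValueError("each group needs >= 2 samples")

    a, b = table.values[:, cols_a], table.values[:, cols_b]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = mean_a - mean_b
    p = pooled_ttest(a, b, welch=params.welch)
    if params.multiple_testing == "bh":
        p = stats.false_discovery_control(p, method="bh")

    sig = p <= params.alpha
    direction = np.where(
        sig & (log2fc >= params.theta), "up_in_A",
        np.where(sig & (-log2fc >= params.theta), "up_in_B", "none"),
    )

    records: list[DifferentialRecord] = []
    for dirn in ("up_in_A", "up_in_B", "none"):
        members = [
            i for i in range(len(table.gene_ids)) if direction[i] == dirn
        ]
        members.sort(
            key=lambda i: (p[i], -abs(log2fc[i]), table.gene_ids[i])
        )
        for rank, i in enumerate(members, start=1):
            records.append(
                DifferentialRecord(
                    gene_id=table.gene_ids[i],
                    mean_a=float(mean_a[i]),
                    mean_b=float(mean_b[i]),
                    log2fc=float(log2fc[i]),
                    p_value=float(p[i]),
                    direction=dirn,
                    rank=rank,
                )
            )
    return records


def records_to_frame(records: list[DifferentialRecord]) -> pd.DataFrame:
    """Tabulate records with the volcano-plot quantities (-log10 p, |log2FC|)."""
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "mean_a": [r.mean_a for r in records],
            "mean_b": [r.mean_b for r in records],
            "log2fc": [r.log2fc for r in records],
            "p_value": [r.p_value for r in records],
            "neg_log10_p": [
                -math.log10(r.p_value) if r.p_value > 0 else math.inf
                for r in records
            ],
            "abs_log2fc": [abs(r.log2fc) for r in records],
            "direction": [r.direction for r in records],
            "rank": [r.rank for r in records],
        }
    )


def compare_scaling_ranks(
    with_scaling: list[DifferentialRecord],
    without_scaling: list[DifferentialRecord],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Compare DPpGC ranks between the gene-length-scaled and unscaled runs.

    Considers selected genes only (direction != none).  Returns a per-gene
    table (rank in each run, rank delta, membership in {both, scaled-only,
    unscaled-only}) and summary counts of ascending / descending / equal
    ranks among genes found by both runs.
    """
    sel_s = {r.gene_id: r for r in with_scaling if r.direction != "none"}
    sel_u = {r.gene_id: r for r in without_scaling if r.direction != "none"}
    rows = []
    for gid in sorted(set(sel_s) | set(sel_u)):
        rs = sel_s.get(gid)
        ru = sel_u.get(gid)
        membership = (
            "both" if rs and ru else "scaled-only" if rs else "unscaled-only"
        )
        delta = (rs.rank - ru.rank) if rs and ru else np.nan
        rows.append(
            {
                "gene_id": gid,
                "rank_scaled": rs.rank if rs else np.nan,
                "rank_unscaled": ru.rank if ru else np.nan,
                "rank_delta": delta,
                "membership": membership,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "rank_scaled", "rank_unscaled", "rank_delta", "membership"],
    )
    both = df[df["membership"] == "both"]["rank_delta"]
    summary = {
        "ascending": int((both < 0).sum()),   # improved (smaller) rank with scaling
        "descending": int((both > 0).sum()),
        "equal": int((both == 0).sum()),
    }
    return df, summary


def length_bias_regression(
    records: list[DifferentialRecord], gene_lengths: dict[str, int]
) -> tuple[float, float]:
    """Regress -log10(p) of the selected up-DPpGCs on gene length.

    Gene-length scaling should leave significance uncorrelated with gene
    length; a near-zero slope and R^2 confirm that.  Requires >= 3 selected
    records.  Returns (slope, r_squared).
    """
    pts = [
        (gene_lengths[r.gene_id], -math.log10(r.p_value))
        for r in records
        if r.direction != "none" and r.p_value > 0
    ]
    if len(pts) < 3:
        raise ValueError("length-bias regression needs >= 3 significant records")
    x, y = zip(*pts)
    if len(set(y)) == 1:  # linregress r is nan for constant response
        return 0.0, 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2)
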