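"""Synthetic circle-call datasets with known ground truth.

Every pipeline stage is testable without the original sequencing data: the
generator lays out genes on artificial chromosomes, produces per-sample
circle calls with configurable per-gene production rates, group-specific
spike multipliers, nucleosome-periodic length peaks (160/320/480 bp),
mitochondrial calls, intergenic noise, and sub-``d_min`` jittered duplicate
calls that exercise junction merging — while book-keeping the true per-gene
split-read totals, circle counts, MtDNA totals and whole-gene hits.

Defaults mirror the study design the method targets: two groups of 8
samples, per-gene Poisson circle production, geometric split-read counts.

Circle placement uses a 50 bp start grid inside each gene (sampled without
replacement), so distinct generated circles are never linkable at the
default merge distance of 10 bp — only the deliberate jittered duplicates
merge.  Ground truth is therefore exact under merging.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .formats_io import (
    CircleCall,
    GeneModel,
    SampleSheet,
    write_circle_calls,
    write_sample_sheet,
)

__all__ = ["SimulationConfig", "SyntheticDataset", "generate_dataset", "worked_toy_dataset"]

_SLOT = 50  # bp between candidate circle starts; > default d_min by design


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic circle-call generator.

    baseline_rate is the expected number of circles per gene per sample;
    spike_genes maps gene_id -> {group label: rate multiplier} for planted
    group effects (multiplicative on the production rate).  Split-read
    counts follow a shifted geometric law with success probability
    ``split_read_geom_p`` and minimum ``split_read_min``.  Circle lengths
    mix Gaussian peaks at ``length_peaks`` (weights ``length_peak_weights``)
    with an exponential tail of scale ``length_tail_scale``.  ``noise`` is
    the expected number of intergenic circles per sample per chromosome;
    ``near_duplicate_rate`` the per-circle probability of emitting a second
    call jittered by < 10 bp at both endpoints.
    """

    n_genes: int = 200
    gene_length_range: tuple[int, int] = (1_000, 20_000)
    genes_per_chrom: int = 25
    intergenic_gap: int = 50_000
    n_samples_per_group: int = 8
    group_labels: tuple[str, str] = ("TS", "TA")
    baseline_rate: float = 2.0
    spike_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    split_read_geom_p: float = 0.5
    split_read_min: int = 1
    length_peaks: tuple[int, ...] = (160, 320, 480)
    length_peak_weights: tuple[float, ...] = (0.45, 0.20, 0.10)
    length_peak_sd: float = 15.0
    length_tail_scale: float = 2_000.0
    mito_rate: float = 5.0
    noise: float = 1.0
    near_duplicate_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.mito_rate < 0 or self.noise < 0:
            raise ValueError("rates must be >= 0")
        if not (0 <= self.near_duplicate_rate <= 1):
            raise ValueError("near_duplicate_rate must lie in [0, 1]")
        if len(self.length_peaks) != len(self.length_peak_weights):
            raise ValueError("length_peaks and length_peak_weights misaligned")
        if sum(self.length_peak_weights) > 1:
            raise ValueError("length_peak_weights must sum to <= 1")
        if self.split_read_min < 1:
            raise ValueError("split_read_min must be >= 1")


@dataclass
class SyntheticDataset:
    """Generated inputs plus ground-truth tables.

    calls_by_sample holds the raw calls (genic + noise + mitochondrial) as
    the pipeline would read them from disk.  Truth tables:

    - ppgc_raw: genes x samples split-read totals a noise-free pipeline run
      recovers exactly (duplicates merge back into their parent circle).
    - circle_counts: unique (merged) circles per sample, incl. noise/mito-free
      genic circles, intergenic noise, one entry per mito cluster.
    - mt_split_reads: per-sample raw MtDNA split-read totals.
    - spiked: gene_id -> {group: multiplier} actually planted.
    - whole_gene_samples: gene_id -> set of samples with a circle fully
      containing the gene.
    """

    config: SimulationConfig
    genes: list[GeneModel]
    sample_sheet: SampleSheet
    calls_by_sample: dict[str, list[CircleCall]]
    ppgc_raw: pd.DataFrame
    circle_counts: pd.Series
    mt_split_reads: pd.Series
    spiked: dict[str, dict[str, float]]
    whole_gene_samples: dict[str, set[str]]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write circle-call BEDs, gene BED, sample sheet and truth tables."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for sid, calls in self.calls_by_sample.items():
            p = out / f"{sid}.circles.bed"
            write_circle_calls(calls, p)
            paths[sid] = p
        gene_bed = out / "genes.bed"
        with open(gene_bed, "w") as fh:
            for g in self.genes:
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\n")
        paths["genes"] = gene_bed
        sheet = out / "samples.tsv"
        write_sample_sheet(self.sample_sheet, sheet)
        paths["samples"] = sheet
        truth = out / "truth_ppgc_raw.tsv"
        self.ppgc_raw.to_csv(truth, sep="\t", index_label="gene_id")
        paths["truth_ppgc_raw"] = truth
        return paths


def _draw_length(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    u = rng.random()
    acc = 0.0
    for peak, w in zip(cfg.length_peaks, cfg.length_peak_weights):
        acc += w
        if u < acc:
            return max(_SLOT, int(round(rng.normal(peak, cfg.length_peak_sd))))
    return max(_SLOT, int(round(rng.exponential(cfg.length_tail_scale))))


def _draw_split_reads(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    return cfg.split_read_min - 1 + int(rng.geometric(cfg.split_read_geom_p))


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a seeded multi-sample dataset with exact ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # --- genome layout -----------------------------------------------------
    genes: list[GeneModel] = []
    lo, hi = cfg.gene_length_range
    chrom_ends: dict[str, int] = {}
    for i in range(cfg.n_genes):
        chrom = f"chr{i // cfg.genes_per_chrom + 1}"
        cursor = chrom_ends.get(chrom, cfg.intergenic_gap)
        length = int(rng.integers(lo, hi + 1))
        genes.append(
            GeneModel(gene_id=f"G{i + 1:04d}", chrom=chrom, start=cursor, end=cursor + length)
        )
        chrom_ends[chrom] = cursor + length + cfg.intergenic_gap

    sample_ids = [
        f"{lab}{k + 1:02d}"
        for lab in cfg.group_labels
        for k in range(cfg.n_samples_per_group)
    ]
    sheet = SampleSheet(
        groups={
            sid: (cfg.group_labels[0] if sid.startswith(cfg.group_labels[0]) else cfg.group_labels[1])
            for sid in sample_ids
        }
    )

    # --- circles -----------------------------------------------------------
    ppgc = pd.DataFrame(
        0.0, index=[g.gene_id for g in genes], columns=sample_ids
    )
    calls_by_sample: dict[str, list[CircleCall]] = {s: [] for s in sample_ids}
    circle_counts = pd.Series(0, index=sample_ids, dtype=int)
    mt_totals = pd.Series(0, index=sample_ids, dtype=int)
    whole_gene: dict[str, set[str]] = {}
    pad_max = min(200, cfg.intergenic_gap // 4)

    for sid in sample_ids:
        group = sheet.groups[sid]
        calls = calls_by_sample[sid]
        for g in genes:
            rate = cfg.baseline_rate * cfg.spike_genes.get(g.gene_id, {}).get(group, 1.0)
            k = int(rng.poisson(rate))
            if k == 0:
                continue
            n_slots = max(1, (g.length - _SLOT) // _SLOT)
            k = min(k, n_slots)
            slots = rng.choice(n_slots, size=k, replace=False)
            for slot in slots:
                length = _draw_length(rng, cfg)
                if length >= g.length:
                    # circle larger than the gene: emit a whole-gene carrier
                    pad_l = int(rng.integers(2 * _SLOT, pad_max + 2 * _SLOT))
                    pad_r = int(rng.integers(1, pad_max))
                    start, end = g.start - pad_l, g.end + pad_r
                    whole_gene.setdefault(g.gene_id, set()).add(sid)
                else:
                    start = g.start + int(slot) * _SLOT
                    end = min(start + length, g.end)
                sr = _draw_split_reads(rng, cfg)
                calls.append(CircleCall(g.chrom, start, end, sr, sid))
                ppgc.at[g.gene_id, sid] += sr
                circle_counts[sid] += 1
                if rng.random() < cfg.near_duplicate_rate:
                    # jitter both endpoints by < 10 bp: merges back into parent
                    js = int(rng.integers(-9, 10))
                    je = int(rng.integers(-9, 10))
                    dup_sr = _draw_split_reads(rng, cfg)
                    calls.append(
                        CircleCall(g.chrom, start + js, end + je, dup_sr, sid)
                    )
                    ppgc.at[g.gene_id, sid] += dup_sr

        # intergenic noise: one candidate region per chromosome, in the gap
        # upstream of the first gene (guaranteed gene-free)
        for chrom in chrom_ends:
            n_noise = int(rng.poisson(cfg.noise))
            for _ in range(n_noise):
                start = int(rng.integers(1_000, cfg.intergenic_gap - 3_000))
                length = min(_draw_length(rng, cfg), 2_000)
                calls.append(
                    CircleCall(chrom, start, start + length, _draw_split_reads(rng, cfg), sid)
                )
                circle_counts[sid] += 1

        n_mito = int(rng.poisson(cfg.mito_rate))
        for _ in range(n_mito):
            start = int(rng.integers(0, 15_000))
            end = min(start + _draw_length(rng, cfg), 16_569)
            sr = _draw_split_reads(rng, cfg)
            calls.append(CircleCall("chrM", start, max(end, start + _SLOT), sr, sid))
            mt_totals[sid] += sr

        rng.shuffle(calls)  # file order carries no information

    ppgc = ppgc.loc[ppgc.sum(axis=1) > 0]
    return SyntheticDataset(
        config=cfg,
        genes=genes,
        sample_sheet=sheet,
        calls_by_sample=calls_by_sample,
        ppgc_raw=ppgc,
        circle_counts=circle_counts,
        mt_split_reads=mt_totals,
        spiked=dict(cfg.spike_genes),
        whole_gene_samples=whole_gene,
    )


# ---------------------------------------------------------------------------
# Worked toy dataset
# ---------------------------------------------------------------------------

_TOY_GENES = [
    GeneModel("G1", "chr1", 1_000, 11_000),   # L = 10000
    GeneModel("G2", "chr1", 20_000, 25_000),  # L = 5000
    GeneModel("G3", "chr2", 1_000, 21_000),   # L = 20000 (longest -> L_Max)
    GeneModel("G4", "chr2", 30_000, 32_000),  # L = 2000, never circled
    GeneModel("G5", "chr3", 500, 1_500),      # L = 1000, whole-gene target
    GeneModel("G6", "chr3", 5_000, 9_000),    # L = 4000
    GeneModel("G7", "chr3", 12_000, 12_800),  # L = 800, CPpGC-not-DPpGC
    GeneModel("G8", "chr3", 20_000, 36_000),  # L = 16000
]

# per-sample split reads of the planted recurrent circles
_TOY_SR = {
    #        S1  S2  S3  S4   S5  S6  S7  S8
    "G1": (8, 8, 9, 9, 2, 2, 3, 3),     # up in TS
    "G3": (4, 4, 4, 4, 4, 4, 4, 4),     # flat
    "G6": (2, 2, 2, 3, 9, 9, 10, 10),   # up in TA
    "G8": (3, 3, 3, 3, 3, 3, 3, 3),     # flat
}


def worked_toy_dataset() -> SyntheticDataset:
    """Deterministic hand-written micro-dataset covering every stage.

    3 chromosomes, 8 genes, 2 groups x 4 samples, ~45 raw calls.  The calls
    are laid out so each processing rule fires at least once with a
    hand-checkable outcome:

    - sample S1 carries a circle of length exactly 100000 (kept at the
      length cap), one of 101000 (dropped), a mergeable jittered pair in G3
      (endpoint distances < 10), a non-mergeable pair at endpoint distance
      exactly 10 whose members then fail the 2-split-read floor, and a
      mitochondrial call;
    - G1 is planted up in TS, G6 up in TA (the only two DPpGCs);
    - G7 is high in every TA sample but only two TS samples: a CPpGC in TA
      only, invisible to the differential test;
    - G5 is wholly contained in a circle in samples S1, S2 and S5;
    - G4 never produces a circle and must drop out of the PpGC table.
    """
    samples = [f"S{i}" for i in range(1, 9)]
    sheet = SampleSheet(groups={s: ("TS" if i < 4 else "TA") for i, s in enumerate(samples)})
    calls: dict[str, list[CircleCall]] = {s: [] for s in samples}

    for j, sid in enumerate(samples):
        calls[sid].append(CircleCall("chr1", 2_000, 2_160, _TOY_SR["G1"][j], sid))
        calls[sid].append(CircleCall("chr2", 5_000, 5_160, _TOY_SR["G3"][j], sid))
        calls[sid].append(CircleCall("chr3", 6_000, 6_320, _TOY_SR["G6"][j], sid))
        calls[sid].append(CircleCall("chr3", 25_000, 25_160, _TOY_SR["G8"][j], sid))

    # G7: every TA sample plus two TS samples
    for sid in ("S1", "S2", "S5", "S6", "S7", "S8"):
        calls[sid].append(CircleCall("chr3", 12_100, 12_300, 60, sid))
    # G5 whole-gene carriers
    for sid, sr in (("S1", 2), ("S2", 2), ("S5", 3)):
        calls[sid].append(CircleCall("chr3", 400, 1_600, sr, sid))

    # S1 structural edge cases
    calls["S1"] += [
        CircleCall("chr1", 0, 100_000, 2, "S1"),        # length == L_max: kept; spans G1+G2
        CircleCall("chr1", 200_000, 301_000, 5, "S1"),  # length 101000 > L_max: dropped
        CircleCall("chrM", 0, 16_000, 7, "S1"),         # mitochondrial
        CircleCall("chr1", 20_100, 20_400, 1, "S1"),    # |dstart| == 10 vs next:
        CircleCall("chr1", 20_110, 20_400, 1, "S1"),    #   not merged; each < JT_min
        CircleCall("chr2", 1_200, 1_500, 1, "S1"),      # jittered pair: merges to
        CircleCall("chr2", 1_205, 1_496, 2, "S1"),      #   [1200,1500) sr=3, in G3
    ]
    calls["S3"].append(CircleCall("chr3", 45_000, 45_200, 5, "S3"))  # intergenic
    calls["S5"].append(CircleCall("chrM", 100, 300, 4, "S5"))

    # hand-computed raw PpGC truth (after filter -> merge -> JT_min=2)
    ppgc = pd.DataFrame(
        {
            "S1": {"G1": 10, "G2": 2, "G3": 7, "G5": 2, "G6": 2, "G7": 60, "G8": 3},
            "S2": {"G1": 8, "G3": 4, "G5": 2, "G6": 2, "G7": 60, "G8": 3},
            "S3": {"G1": 9, "G3": 4, "G6": 2, "G8": 3},
            "S4": {"G1": 9, "G3": 4, "G6": 3, "G8": 3},
            "S5": {"G1": 2, "G3": 4, "G5": 3, "G6": 9, "G7": 60, "G8": 3},
            "S6": {"G1": 2, "G3": 4, "G6": 9, "G7": 60, "G8": 3},
            "S7": {"G1": 3, "G3": 4, "G6": 10, "G7": 60, "G8": 3},
            "S8": {"G1": 3, "G3": 4, "G6": 10, "G7": 60, "G8": 3},
        }
    ).fillna(0).loc[["G1", "G2", "G3", "G5", "G6", "G7", "G8"], samples]

    counts = pd.Series(
        {"S1": 8, "S2": 6, "S3": 5, "S4": 4, "S5": 6, "S6": 5, "S7": 5, "S8": 5}
    )
    mt = pd.Series({s: 0 for s in samples})
    mt["S1"], mt["S5"] = 7, 4

    return SyntheticDataset(
        config=SimulationConfig(
            n_genes=8, n_samples_per_group=4, group_labels=("TS", "TA"), seed=0
        ),
        genes=list(_TOY_GENES),
        sample_sheet=sheet,
        calls_by_sample=calls,
        ppgc_raw=ppgc,
        circle_counts=counts,
        mt_split_reads=mt,
        spiked={"G1": {"TS": 4.0}, "G6": {"TA": 4.0}},
        whole_gene_samples={"G5": {"S1", "S2", "S5"}},
    )
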