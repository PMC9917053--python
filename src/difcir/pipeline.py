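"""End-to-end orchestration: process -> quantify -> differential -> democratic
-> whole-genes, with a run manifest and per-stage audit logging.

Stage outputs are plain TSV/BED files, so any stage can be re-entered from
the previous stage's files; the manifest records parameters, input checksums
and the package version for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .circle_processing import (
    ProcessingParams,
    count_mt_split_reads,
    count_unique_eccdna,
    process_sample,
)
from .democratic_voting import cppgc_overlap, vote_cppgc, vote_threshold
from .differential import (
    DifferentialParams,
    compare_scaling_ranks,
    difcir,
    records_to_frame,
)
from .formats_io import (
    SampleSheet,
    read_circle_calls,
    read_gene_annotation,
    read_sample_sheet,
    write_circle_calls,
    write_table,
)
from .ppgc_quantification import (
    annotate_circles,
    compute_ppgc,
    equalize,
    scale_by_gene_length,
)
from .whole_gene_detection import find_whole_gene_circles

logger = logging.getLogger("difcir")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one run needs; defaults follow the method's published
    parameterisation (L_max = 100 kb, D_min = 10 bp, JT_min = 2, theta = 1,
    alpha = 0.05, min_votes = 4, whole genes in >= 2 samples)."""

    circle_files: dict[str, str]  # sample_id -> path
    annotation_path: str
    annotation_format: str = "bed"  # bed | gtf
    sample_sheet_path: str | None = None
    sample_groups: dict[str, str] = field(default_factory=dict)
    dialect: str = "generic-bed"
    coordinate_base: int = 0  # 0 = BED half-open input, 1 = 1-based inclusive
    processing: ProcessingParams = field(default_factory=ProcessingParams)
    differential: DifferentialParams = field(default_factory=DifferentialParams)
    scaling: bool = True
    lmax_from: str = "table"  # table | annotation
    min_votes: int = 4
    vote_bin_width: float = 0.5
    min_samples_whole_gene: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for fld in ("circle_files", "annotation_path"):
            if fld not in raw:
                raise ValueError(f"pipeline config is missing required field {fld!r}")
        if "processing" in raw:
            raw["processing"] = ProcessingParams(
                **{**raw["processing"],
                   **({"mito_names": frozenset(raw["processing"]["mito_names"])}
                      if "mito_names" in raw["processing"] else {})}
            )
        if "differential" in raw:
            raw["differential"] = DifferentialParams(**raw["differential"])
        return cls(**raw)

    def resolve_sheet(self) -> SampleSheet:
        if self.sample_sheet_path:
            return read_sample_sheet(self.sample_sheet_path)
        if self.sample_groups:
            return SampleSheet(groups=dict(self.sample_groups))
        raise ValueError("pipeline config needs sample_sheet_path or sample_groups")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage, writing all result tables under ``out_dir``.

    Returns a result bundle: processed calls, the three PpGC stages, the
    differential records of the scaled and unscaled runs, the per-group vote
    results and overlap, whole-gene hits, and the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sheet = config.resolve_sheet()
    genes = read_gene_annotation(config.annotation_path, config.annotation_format)
    labels = sheet.group_labels

    # --- process -----------------------------------------------------------
    processed: dict[str, list] = {}
    summary_rows = []
    for sid, path in config.circle_files.items():
        raw = read_circle_calls(
            path, config.dialect, sid, one_based=config.coordinate_base == 1
        )
        kept, mito = process_sample(raw, config.processing)
        processed[sid] = kept
        write_circle_calls(kept, out / f"{sid}.processed.bed")
        summary_rows.append(
            {
                "sample_id": sid,
                "raw_calls": len(raw),
                "mito_calls": len(mito),
                "unique_eccdna": len(kept),
                "mt_split_reads": count_mt_split_reads(mito),
            }
        )
        logger.info(
            "process %s: %d raw -> %d unique eccDNA (%d mito calls)",
            sid, len(raw), len(kept), len(mito),
        )
    summary = pd.DataFrame(summary_rows)
    write_table(summary, out / "sample_summary.tsv")

    # --- quantify ----------------------------------------------------------
    pairs = [
        p for sid in processed for p in annotate_circles(processed[sid], genes)
    ]
    raw_table = compute_ppgc(pairs, sheet, genes)
    logger.info("quantify: %d genes with circles", len(raw_table.gene_ids))
    scaled = scale_by_gene_length(
        raw_table, annotation=genes if config.lmax_from == "annotation" else None
    )
    eq_scaled = equalize(scaled)
    eq_unscaled = equalize(raw_table)
    for tbl, name in ((raw_table, "raw"), (scaled, "scaled"), (eq_scaled, "equalized")):
        write_table(
            tbl.to_frame().reset_index(names="gene_id"), out / f"ppgc_{name}.tsv"
        )

    # --- differential (scaled + no-scaling variant) ------------------------
    main_eq = eq_scaled if config.scaling else eq_unscaled
    records = difcir(main_eq, sheet, config.differential)
    records_unscaled = difcir(eq_unscaled, sheet, config.differential)
    rec_df = records_to_frame(records)
    for dirn, lab in (("up_in_A", labels[0]), ("up_in_B", labels[1])):
        write_table(
            rec_df[rec_df["direction"] == dirn], out / f"up_dppgc_{lab}.tsv"
        )
    write_table(rec_df, out / "differential_all.tsv")
    rank_cmp, rank_summary = compare_scaling_ranks(
        difcir(eq_scaled, sheet, config.differential), records_unscaled
    )
    write_table(rank_cmp, out / "scaling_rank_comparison.tsv")
    n_up_a = int((rec_df["direction"] == "up_in_A").sum())
    n_up_b = int((rec_df["direction"] == "up_in_B").sum())
    logger.info("differential: %d up in %s, %d up in %s", n_up_a, labels[0], n_up_b, labels[1])

    # --- democratic --------------------------------------------------------
    votes = {}
    for lab in labels:
        members = sheet.samples_in(lab)
        thr = vote_threshold(main_eq, members, bin_width=config.vote_bin_width)
        results = vote_cppgc(main_eq, members, thr, config.min_votes)
        votes[lab] = results
        write_table(
            pd.DataFrame(
                {
                    "gene_id": [r.gene_id for r in results],
                    "votes": [r.votes for r in results],
                    "threshold": [r.threshold for r in results],
                    "is_cppgc": [int(r.is_cppgc) for r in results],
                }
            ),
            out / f"votes_{lab}.tsv",
        )
        logger.info(
            "democratic %s: threshold %d, %d CPpGCs",
            lab, thr, sum(r.is_cppgc for r in results),
        )
    only_a, only_b, common = cppgc_overlap(votes[labels[0]], votes[labels[1]])
    write_table(
        pd.DataFrame(
            [(g, "only_" + labels[0]) for g in sorted(only_a)]
            + [(g, "only_" + labels[1]) for g in sorted(only_b)]
            + [(g, "common") for g in sorted(common)],
            columns=["gene_id", "membership"],
        ),
        out / "cppgc_overlap.tsv",
    )

    # --- whole genes -------------------------------------------------------
    hits, presence = find_whole_gene_circles(
        processed, genes, config.min_samples_whole_gene
    )
    write_table(
        pd.DataFrame(
            {
                "gene_id": [h.gene_id for h in hits],
                "gene_length": [h.gene_length for h in hits],
                "n_samples": [h.n_samples for h in hits],
                "samples": [",".join(sorted(h.samples_with_hit)) for h in hits],
            }
        ),
        out / "whole_gene_hits.tsv",
    )
    write_table(presence.reset_index(names="gene_id"), out / "whole_gene_presence.tsv")
    logger.info("whole-genes: %d genes in >= %d samples", len(hits), config.min_samples_whole_gene)

    # --- manifest ----------------------------------------------------------
    manifest = {
        "version": __version__,
        "parameters": {
            "processing": {
                "l_max": config.processing.l_max,
                "d_min": config.processing.d_min,
                "jt_min": config.processing.jt_min,
                "mito_names": sorted(config.processing.mito_names),
            },
            "differential": dataclasses.asdict(config.differential),
            "scaling": config.scaling,
            "lmax_from": config.lmax_from,
            "min_votes": config.min_votes,
            "vote_bin_width": config.vote_bin_width,
            "min_samples_whole_gene": config.min_samples_whole_gene,
            "coordinate_base": config.coordinate_base,
        },
        "inputs": {
            str(p): _sha256(p)
            for p in [*config.circle_files.values(), config.annotation_path]
        },
        "groups": {lab: sheet.samples_in(lab) for lab in labels},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "processed": processed,
        "summary": summary,
        "ppgc_raw": raw_table,
        "ppgc_scaled": scaled,
        "ppgc_equalized": eq_scaled,
        "ppgc_equalized_unscaled": eq_unscaled,
        "differential": records,
        "differential_unscaled": records_unscaled,
        "rank_comparison": (rank_cmp, rank_summary),
        "votes": votes,
        "cppgc_overlap": (only_a, only_b, common),
        "whole_gene_hits": hits,
        "whole_gene_presence": presence,
        "manifest": manifest,
    }
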