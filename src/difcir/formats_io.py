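"""Readers and writers for all on-disk artifacts.

Circle calls arrive as BED-like TSV (one file per sample), gene models as
BED4+ or GENCODE-style GTF, sample-to-group assignments as a two-column
sample sheet.  All internal coordinates are 0-based half-open (BED
convention); GTF input is converted at this boundary.  Strand is ignored
throughout: circular-junction observations are unstranded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

__all__ = [
    "CircleCall",
    "GeneModel",
    "SampleSheet",
    "CIRCLE_FINDER_COLUMNS",
    "read_circle_calls",
    "read_gene_annotation",
    "read_sample_sheet",
    "write_sample_sheet",
    "write_circle_calls",
    "write_table",
    "read_table",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CircleCall:
    """One detected eccDNA junction.

    Coordinates are 0-based half-open; ``length`` is ``end - start`` in bp.
    ``split_reads`` is the number of reads spanning the circular junction,
    the primary quantitative signal of the method.
    """

    chrom: str
    start: int
    end: int
    split_reads: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"circle end must exceed start: got [{self.start}, {self.end}) "
                f"on {self.chrom}"
            )
        if self.split_reads < 0:
            raise ValueError(f"negative split-read count: {self.split_reads}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene interval with optional exon sub-intervals (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    gene_name: str = ""
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id}: end must exceed start "
                f"([{self.start}, {self.end}))"
            )
        for (a, b) in self.exons:
            if not (self.start <= a < b <= self.end):
                raise ValueError(
                    f"gene {self.gene_id}: exon [{a}, {b}) outside gene body"
                )
        if not self.gene_name:
            object.__setattr__(self, "gene_name", self.gene_id)

    @property
    def length(self) -> int:
        """Gene body length L_i in bp (annotation span, not summed exons)."""
        return self.end - self.start


@dataclass
class SampleSheet:
    """Ordered sample -> group mapping.

    Group labels keep first-appearance order; differential analysis requires
    exactly two groups with >= 2 samples each (validated where needed, not
    here, so the sheet can also describe single-group datasets).
    """

    groups: dict[str, str] = field(default_factory=dict)  # sample_id -> group

    def __post_init__(self) -> None:
        if len(set(self.groups)) != len(self.groups):  # dict enforces, belt+braces
            raise ValueError("duplicate sample_id in sample sheet")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups)

    @property
    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups.values():
            seen.setdefault(g)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]


# ---------------------------------------------------------------------------
# Circle-call tables
# ---------------------------------------------------------------------------

#: Default column mapping for the Circle_finder "microDNA" dialect.  The
#: tool's junction tables lead with the interval (chrom, start, end) and the
#: junction-tag/split-read count in the fourth column; later columns vary by
#: version and are ignored.  Override when a different build puts the count
#: elsewhere.
CIRCLE_FINDER_COLUMNS: dict[str, int] = {
    "chrom": 0,
    "start": 1,
    "end": 2,
    "split_reads": 3,
}


def _looks_like_header(fields: Sequence[str]) -> bool:
    """A first row where BOTH coordinate columns are non-integer is a header.

    A single bad coordinate is a malformed data row, not a header, and must
    be reported as an error rather than silently skipped.
    """
    def _is_int(i: int) -> bool:
        try:
            int(fields[i])
        except (ValueError, IndexError):
            return False
        return True

    return not _is_int(1) and not _is_int(2)


def read_circle_calls(
    path: str | Path,
    dialect: str = "generic-bed",
    sample_id: str = "",
    *,
    one_based: bool = False,
    columns: Mapping[str, int] | None = None,
) -> list[CircleCall]:
    """Read one sample's circle calls from a BED-like TSV.

    Parameters
    ----------
    path
        TSV file; ``generic-bed`` expects >= 4 columns
        (chrom, start, end, split_reads), header optional and auto-detected.
    dialect
        ``generic-bed`` or ``circle-finder`` (Circle_finder microDNA tables;
        column mapping given by ``columns``, default
        :data:`CIRCLE_FINDER_COLUMNS`).
    sample_id
        Label attached to every returned call.
    one_based
        If True, input coordinates are 1-based inclusive and are converted
        to the internal 0-based half-open convention.
    """
    path = Path(path)
    if dialect == "generic-bed":
        colmap = {"chrom": 0, "start": 1, "end": 2, "split_reads": 3}
    elif dialect == "circle-finder":
        colmap = dict(columns or CIRCLE_FINDER_COLUMNS)
    else:
        raise ValueError(f"unknown circle-call dialect: {dialect!r}")
    needed = max(colmap.values()) + 1

    calls: list[CircleCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if lineno == 1 and _looks_like_header(fields):
                continue
            if len(fields) < needed:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {needed} columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[colmap["chrom"]]
                start = int(fields[colmap["start"]])
                end = int(fields[colmap["end"]])
                split_reads = int(fields[colmap["split_reads"]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from None
            if one_based:
                start -= 1
            try:
                calls.append(CircleCall(chrom, start, end, split_reads, sample_id))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return calls


def write_circle_calls(calls: Iterable[CircleCall], path: str | Path) -> None:
    """Write calls as headerless generic BED4 (chrom, start, end, split_reads)."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.split_reads}\n")


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------

def _genes_from_bed(path: Path) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if lineno == 1 and _looks_like_header(fields):
                continue
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED4+ requires >= 4 columns")
            chrom, start, end, gene_id = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if end <= start:
                raise ValueError(f"{path}:{lineno}: gene {gene_id} has end <= start")
            model = GeneModel(gene_id=gene_id, chrom=chrom, start=start, end=end)
            prev = genes.get(gene_id)
            if prev is not None and (prev.chrom, prev.start, prev.end) != (chrom, start, end):
                raise ValueError(
                    f"{path}:{lineno}: duplicate gene_id {gene_id!r} with "
                    f"conflicting coordinates"
                )
            genes[gene_id] = model
    return list(genes.values())


def _genes_from_gtf(path: Path) -> list[GeneModel]:
    # In-memory DB; merge strategy tolerates GENCODE's duplicated attributes.
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons_by_gene: dict[str, list[tuple[int, int]]] = {}
    for exon in db.features_of_type("exon"):
        gid = exon.attributes.get("gene_id", [None])[0]
        if gid is None:
            raise ValueError(f"{path}: exon feature without gene_id attribute")
        # GTF is 1-based inclusive; convert to 0-based half-open.
        exons_by_gene.setdefault(gid, []).append((exon.start - 1, exon.end))

    genes: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        gid = gene.attributes.get("gene_id", [None])[0]
        if gid is None:
            raise ValueError(f"{path}: gene feature without gene_id attribute")
        name = gene.attributes.get("gene_name", [gid])[0]
        start, end = gene.start - 1, gene.end
        if end <= start:
            raise ValueError(f"{path}: gene {gid} has end <= start")
        if gid in genes:
            prev = genes[gid]
            if (prev.chrom, prev.start, prev.end) != (gene.seqid, start, end):
                raise ValueError(
                    f"{path}: duplicate gene_id {gid!r} with conflicting coordinates"
                )
            continue
        exons = tuple(sorted(set(exons_by_gene.get(gid, []))))
        genes[gid] = GeneModel(
            gene_id=gid, chrom=gene.seqid, start=start, end=end,
            gene_name=name, exons=exons,
        )
    return list(genes.values())


def read_gene_annotation(path: str | Path, format: str = "bed") -> list[GeneModel]:
    """Read gene models from BED4+ (``bed``) or GENCODE-style GTF (``gtf``).

    BED input yields genes with empty exon lists; GTF attaches ``exon``
    features to their ``gene_id`` and converts coordinates from 1-based
    inclusive to 0-based half-open.
    """
    path = Path(path)
    if format == "bed":
        return _genes_from_bed(path)
    if format == "gtf":
        return _genes_from_gtf(path)
    raise ValueError(f"unknown annotation format: {format!r}")


# ---------------------------------------------------------------------------
# Sample sheets
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a two-column TSV (sample_id, group), header optional."""
    groups: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and fields[0].lower() in {"sample", "sample_id"}:
                continue
            sid, grp = fields[0], fields[1]
            if sid in groups:
                raise ValueError(f"{path}:{lineno}: duplicate sample_id {sid!r}")
            groups[sid] = grp
    return SampleSheet(groups=groups)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sid, grp in sheet.groups.items():
            fh.write(f"{sid}\t{grp}\n")


# ---------------------------------------------------------------------------
# Generic result tables
# ---------------------------------------------------------------------------

def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with header.

    Column order is preserved as given (deterministic); floats are rendered
    in repr form, which keeps >= 6 significant digits and round-trips exactly
    through :func:`read_table`.
    """
    records.to_csv(path, sep="\t", index=False, float_format=None)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", **kwargs)
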