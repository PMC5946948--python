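"""Domain types and readers/writers for the formats the pipeline touches.

All internal coordinates are 1-based inclusive, matching the convention of
chromosome-scale genome reports ("nt 22,200,001 to nt 23,200,000").  BED's
0-based half-open intervals are converted at the read/write boundary and
nowhere else.

The telocentric convention used throughout: chromosome coordinate 1 is the
centromere end, so a scaffold's ``rel_position`` (relative distance from the
centromere, in [0, 1]) increases with its ``order_index``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneRecord",
    "SequenceRecord",
    "ScaffoldPlacement",
    "ChromosomeAssembly",
    "ParseError",
    "ValidationError",
    "UnplacedScaffoldError",
    "read_genes",
    "write_genes",
    "read_fasta",
    "write_fasta",
    "write_agp",
    "read_agp",
    "project_to_chromosome",
]

DEFAULT_GAP_LENGTH = 1000

_VALID_STRANDS = {"+", "-", "unknown"}
_ALPHABET = set("ACGTN")


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed data violates a structural invariant."""


class UnplacedScaffoldError(KeyError):
    """A gene sits on a scaffold that the assembly does not place."""


@dataclass(frozen=True)
class GeneRecord:
    """An annotated gene interval; analyses use ``start`` as the gene's point position."""

    gene_id: str
    seq_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"gene {self.gene_id}: start {self.start} < 1")
        if self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A, C, G, T, N} (uppercase)."""

    seq_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if seq is not self.sequence:
            object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValidationError(
                f"sequence {self.seq_id}: invalid characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ScaffoldPlacement:
    """One scaffold placed on a chromosome, ordered outward from the centromere."""

    scaffold_id: str
    chrom_id: str
    order_index: int  # 1 = nearest the centromere
    orientation: str  # "+" or "-"
    evidence: str  # "fish" or "synteny"
    rel_position: float  # relative distance from centromere, in [0, 1]

    def __post_init__(self) -> None:
        if self.orientation not in {"+", "-"}:
            raise ValidationError(f"bad orientation {self.orientation!r}")
        if self.evidence not in {"fish", "synteny"}:
            raise ValidationError(f"bad evidence {self.evidence!r}")
        if not 0.0 <= self.rel_position <= 1.0:
            raise ValidationError(f"rel_position {self.rel_position} outside [0, 1]")
        if self.order_index < 1:
            raise ValidationError(f"order_index {self.order_index} < 1")


@dataclass
class ChromosomeAssembly:
    """An ordered set of scaffold placements joined by fixed-length N gaps."""

    chrom_id: str
    placements: list[ScaffoldPlacement]
    gap_length: int = DEFAULT_GAP_LENGTH

    def __post_init__(self) -> None:
        for p in self.placements:
            if p.chrom_id != self.chrom_id:
                raise ValidationError(
                    f"placement {p.scaffold_id} carries chrom {p.chrom_id}, "
                    f"assembly is {self.chrom_id}"
                )
        indices = [p.order_index for p in self.placements]
        if indices != list(range(1, len(indices) + 1)):
            raise ValidationError(
                f"{self.chrom_id}: order_index must be contiguous from 1, got {indices}"
            )
        rels = [p.rel_position for p in self.placements]
        if any(b < a for a, b in zip(rels, rels[1:])):
            raise ValidationError(
                f"{self.chrom_id}: rel_position must be non-decreasing with order"
            )

    def total_length(self, scaffold_lengths: Mapping[str, int]) -> int:
        n = len(self.placements)
        return (
            sum(scaffold_lengths[p.scaffold_id] for p in self.placements)
            + self.gap_length * max(n - 1, 0)
        )


# ---------------------------------------------------------------------------
# Gene annotation I/O


def read_genes(path: str | Path, format: str) -> list[GeneRecord]:
    """Read gene records from a GFF3 or BED file, in file order.

    BED's 0-based half-open coordinates become 1-based inclusive on read.
    """
    if format == "gff3":
        return _read_gff3(path)
    if format == "bed":
        return _read_bed(path)
    raise ValueError(f"unknown annotation format {format!r}")


def _read_gff3(path: str | Path) -> list[GeneRecord]:
    import gffutils

    try:
        db = gffutils.create_db(str(path), ":memory:", force=True)
    except Exception as exc:  # gffutils raises various types on malformed input
        raise ParseError(f"{path}: {exc}") from exc
    records = []
    for feat in db.all_features():
        strand = feat.strand if feat.strand in {"+", "-"} else "unknown"
        records.append(
            GeneRecord(
                gene_id=feat.id,
                seq_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=strand,
            )
        )
    return records


def _read_bed(path: str | Path) -> list[GeneRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else f"bed_{lineno}"
            strand = fields[5] if len(fields) > 5 and fields[5] in {"+", "-"} else "unknown"
            try:
                records.append(
                    GeneRecord(
                        gene_id=name,
                        seq_id=fields[0],
                        start=start0 + 1,
                        end=end0,
                        strand=strand,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_genes(
    records: Iterable[GeneRecord], path: str | Path, format: str
) -> None:
    """Write gene records as GFF3 or BED, sorted by (seq_id, start)."""
    records = sorted(records, key=lambda r: (r.seq_id, r.start))
    with open(path, "w") as fh:
        if format == "gff3":
            fh.write("##gff-version 3\n")
            for r in records:
                strand = r.strand if r.strand in {"+", "-"} else "."
                fh.write(
                    f"{r.seq_id}\tcafskit\tgene\t{r.start}\t{r.end}\t.\t{strand}\t.\t"
                    f"ID={r.gene_id}\n"
                )
        elif format == "bed":
            for r in records:
                strand = r.strand if r.strand in {"+", "-"} else "."
                fh.write(
                    f"{r.seq_id}\t{r.start - 1}\t{r.end}\t{r.gene_id}\t0\t{strand}\n"
                )
        else:
            raise ValueError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# FASTA I/O (Biopython-backed, 60-column wrap)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    return [
        SequenceRecord(seq_id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        SeqRecord(Seq(r.sequence), id=r.seq_id, description="")
        for r in sorted(records, key=lambda r: r.seq_id)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# AGP v2.1


def write_agp(
    assembly: ChromosomeAssembly, scaffold_lengths: Mapping[str, int]
) -> str:
    """Serialize an assembly as AGP v2.1 text.

    Component (W) rows alternate with gap (N) rows; gaps are typed
    ``scaffold`` with linkage ``yes`` and evidence ``map``, since scaffold
    adjacency here comes from FISH/synteny mapping.
    """
    for p in assembly.placements:
        if p.scaffold_id not in scaffold_lengths:
            raise KeyError(f"unknown scaffold id {p.scaffold_id!r}")
    out = io.StringIO()
    out.write("##agp-version\t2.1\n")
    pos = 1
    part = 1
    for i, p in enumerate(assembly.placements):
        if i > 0:
            gap_end = pos + assembly.gap_length - 1
            out.write(
                f"{assembly.chrom_id}\t{pos}\t{gap_end}\t{part}\tN\t"
                f"{assembly.gap_length}\tscaffold\tyes\tmap\n"
            )
            pos = gap_end + 1
            part += 1
        length = scaffold_lengths[p.scaffold_id]
        comp_end = pos + length - 1
        out.write(
            f"{assembly.chrom_id}\t{pos}\t{comp_end}\t{part}\tW\t"
            f"{p.scaffold_id}\t1\t{length}\t{p.orientation}\n"
        )
        pos = comp_end + 1
        part += 1
    return out.getvalue()


def read_agp(text: str) -> tuple[ChromosomeAssembly, dict[str, int]]:
    """Parse AGP v2.1 text back into an assembly; inverse of :func:`write_agp`.

    Object coordinates must be contiguous.  A single gap length is required
    across the object (the pipeline's fixed-gap convention).
    """
    placements: list[ScaffoldPlacement] = []
    lengths: dict[str, int] = {}
    chrom_id: str | None = None
    gap_length: int | None = None
    expected_start = 1
    rows: list[tuple] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise ParseError(f"AGP line {lineno}: expected 9 columns")
        obj, obj_start, obj_end, _part, comp_type = fields[:5]
        obj_start, obj_end = int(obj_start), int(obj_end)
        if chrom_id is None:
            chrom_id = obj
        elif obj != chrom_id:
            raise ValidationError(
                f"AGP line {lineno}: multiple objects per call not supported "
                f"({chrom_id!r} vs {obj!r})"
            )
        if obj_start != expected_start:
            raise ValidationError(
                f"AGP line {lineno}: object start {obj_start}, expected "
                f"{expected_start} (non-contiguous coordinates)"
            )
        expected_start = obj_end + 1
        rows.append((lineno, comp_type, obj_start, obj_end, fields))
    if chrom_id is None:
        raise ParseError("empty AGP input")

    n_comp = 0
    total_span = rows[-1][3]
    for lineno, comp_type, obj_start, obj_end, fields in rows:
        if comp_type in {"N", "U"}:
            glen = int(fields[5])
            if glen != obj_end - obj_start + 1:
                raise ValidationError(f"AGP line {lineno}: gap length mismatch")
            if gap_length is not None and glen != gap_length:
                raise ValidationError(
                    f"AGP line {lineno}: mixed gap lengths {gap_length} vs {glen}"
                )
            gap_length = glen
        elif comp_type == "W":
            scaffold_id, comp_beg, comp_end, orientation = fields[5:9]
            length = int(comp_end) - int(comp_beg) + 1
            if length != obj_end - obj_start + 1:
                raise ValidationError(f"AGP line {lineno}: component span mismatch")
            n_comp += 1
            lengths[scaffold_id] = length
            placements.append(
                ScaffoldPlacement(
                    scaffold_id=scaffold_id,
                    chrom_id=chrom_id,
                    order_index=n_comp,
                    orientation="-" if orientation == "-" else "+",
                    evidence="fish",
                    rel_position=min(obj_end / total_span, 1.0),
                )
            )
        else:
            raise ParseError(f"AGP line {lineno}: unsupported component type {comp_type!r}")
    assembly = ChromosomeAssembly(
        chrom_id=chrom_id,
        placements=placements,
        gap_length=gap_length if gap_length is not None else DEFAULT_GAP_LENGTH,
    )
    return assembly, lengths


# ---------------------------------------------------------------------------
# Coordinate projection


def scaffold_offsets(
    assembly: ChromosomeAssembly, scaffold_lengths: Mapping[str, int]
) -> dict[str, int]:
    """Cumulative chromosome offset (bp before scaffold start) per scaffold."""
    offsets = {}
    pos = 0
    for i, p in enumerate(assembly.placements):
        if i > 0:
            pos += assembly.gap_length
        offsets[p.scaffold_id] = pos
        pos += scaffold_lengths[p.scaffold_id]
    return offsets


_FLIP = {"+": "-", "-": "+", "unknown": "unknown"}


def project_to_chromosome(
    gene: GeneRecord,
    assembly: ChromosomeAssembly,
    scaffold_lengths: Mapping[str, int],
) -> GeneRecord:
    """Lift a gene from scaffold coordinates to chromosome coordinates.

    Reverse-placed scaffolds reflect the interval within the scaffold and
    flip the strand — the geometric consequence of reverse-complementing the
    scaffold when the chromosome sequence is built.
    """
    by_id = {p.scaffold_id: p for p in assembly.placements}
    placement = by_id.get(gene.seq_id)
    if placement is None:
        raise UnplacedScaffoldError(gene.seq_id)
    offset = scaffold_offsets(assembly, scaffold_lengths)[gene.seq_id]
    length = scaffold_lengths[gene.seq_id]
    if placement.orientation == "+":
        start, end, strand = gene.start, gene.end, gene.strand
    else:
        start = length - gene.end + 1
        end = length - gene.start + 1
        strand = _FLIP[gene.strand]
    return GeneRecord(
        gene_id=gene.gene_id,
        seq_id=assembly.chrom_id,
        start=start + offset,
        end=end + offset,
        strand=strand,
    )
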