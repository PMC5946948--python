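"""Assembly summary statistics.

* Nxx table: for threshold t%, the Nt length is the length of the record at
  which the descending cumulative sum first reaches t% of the total, and the
  Nt count is that record's rank.
* Contig splitting: scaffolds are cut at maximal N-runs of at least
  ``min_n_run`` bases; pieces shorter than 100 bp are excluded from contig
  statistics.
* k-mer genome size: genome size = K_num / Peak_depth, with Peak_depth the
  expected (canonical) k-mer depth of the histogram's main coverage
  component and K_num the k-mer instances in that component; the low-depth
  error slope (depths below the first local minimum) is excluded from both.
* Per-chromosome summary: size (kb), scaffold count, gene count, and gene
  density per 10 Mb rounded to the nearest integer (ties away from zero),
  plus a totals row whose density is recomputed from the totals.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import ChromosomeAssembly, GeneRecord, SequenceRecord, ValidationError

__all__ = [
    "NxxTable",
    "KmerSpectrum",
    "ChromosomeSummaryRow",
    "nxx_table",
    "split_contigs",
    "kmer_spectrum",
    "estimate_genome_size",
    "chromosome_summary",
    "summary_from_counts",
    "MONOPTERUS_CHROMOSOME_TABLE",
]

#: Published per-chromosome statistics of the swamp eel (Monopterus albus)
#: chromosome-scale assembly: (chromosome, size in kb, scaffold count, gene
#: count).  Gene densities are never stored — they are recomputed.
MONOPTERUS_CHROMOSOME_TABLE: list[tuple[str, float, int, int]] = [
    ("1", 75_908.7, 33, 2_264),
    ("2", 65_103.9, 32, 2_133),
    ("3", 51_637.3, 21, 1_872),
    ("4", 51_162.1, 30, 1_791),
    ("5", 50_080.0, 27, 1_517),
    ("6", 48_093.1, 27, 1_659),
    ("7", 42_410.1, 29, 1_500),
    ("8", 41_999.7, 30, 1_456),
    ("9", 41_928.7, 23, 1_241),
    ("10", 34_690.8, 30, 1_262),
    ("11", 29_285.5, 23, 1_086),
    ("12", 22_774.4, 23, 879),
]


# ---------------------------------------------------------------------------
# Nxx statistics


@dataclass(frozen=True)
class NxxRow:
    threshold: int  # percent
    length: int  # bp
    count: int  # rank of the record achieving the threshold


@dataclass
class NxxTable:
    rows: list[NxxRow]
    longest: int
    total_size: int
    n_records_100bp: int
    n_records_2kb: int

    def to_tsv(self) -> str:
        lines = ["stat\tsize_bp\tnumber"]
        for r in self.rows:
            lines.append(f"N{r.threshold}\t{r.length}\t{r.count}")
        lines.append(f"longest\t{self.longest}\t")
        lines.append(f"total\t{self.total_size}\t")
        lines.append(f"n_ge_100bp\t\t{self.n_records_100bp}")
        lines.append(f"n_ge_2kb\t\t{self.n_records_2kb}")
        return "\n".join(lines) + "\n"


def nxx_table(
    lengths: Sequence[int], thresholds: Sequence[int] = (50, 60, 70, 80, 90)
) -> NxxTable:
    if not lengths:
        raise ValueError("empty length list")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    srt = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    csum = np.cumsum(srt)
    total = int(csum[-1])
    rows = []
    for t in thresholds:
        target = total * t / 100
        idx = int(np.searchsorted(csum, target, side="left"))
        rows.append(NxxRow(threshold=int(t), length=int(srt[idx]), count=idx + 1))
    return NxxTable(
        rows=rows,
        longest=int(srt[0]),
        total_size=total,
        n_records_100bp=int((srt >= 100).sum()),
        n_records_2kb=int((srt >= 2000).sum()),
    )


# ---------------------------------------------------------------------------
# Contig splitting


def split_contigs(
    scaffold_seq: SequenceRecord | str, min_n_run: int = 10, min_contig: int = 100
) -> list[int]:
    """Contig lengths after cutting at maximal N-runs of >= min_n_run bases;
    pieces shorter than min_contig are dropped.  Order follows the scaffold."""
    seq = scaffold_seq.sequence if isinstance(scaffold_seq, SequenceRecord) else scaffold_seq
    pieces = re.split(f"N{{{min_n_run},}}", seq.upper())
    return [len(p) for p in pieces if len(p) >= min_contig]


# ---------------------------------------------------------------------------
# k-mer spectrum and genome size


@dataclass
class KmerSpectrum:
    k: int
    histogram: dict[int, int]  # depth -> number of distinct k-mers at that depth
    k_num: int  # total k-mer instances

    def to_tsv(self) -> str:
        lines = [f"{d}\t{c}" for d, c in sorted(self.histogram.items())]
        return "\n".join(lines) + "\n"

    def _dense(self) -> np.ndarray:
        if not self.histogram:
            raise ValueError("empty k-mer histogram")
        max_d = max(self.histogram)
        counts = np.zeros(max_d + 1, dtype=np.int64)
        for d, c in self.histogram.items():
            counts[d] = c
        return counts

    @property
    def first_valley(self) -> int:
        """First local minimum of the histogram: the boundary between the
        low-depth error slope and the main coverage component."""
        counts = self._dense()
        max_d = len(counts) - 1
        d = 1
        while d < max_d and counts[d + 1] < counts[d]:
            d += 1
        if d == max_d:
            raise ValueError(
                "monotonically decreasing k-mer histogram: no interior mode "
                "(coverage too low or all k-mers erroneous)"
            )
        return d

    @property
    def peak_depth(self) -> int:
        """Modal depth of the main component (diagnostic; the estimator
        uses the component's expected depth)."""
        counts = self._dense()
        v = self.first_valley
        return int(v + np.argmax(counts[v:]))

    @property
    def expected_depth(self) -> float:
        """Expected k-mer depth of the main coverage component (depths at
        or above the first valley)."""
        counts = self._dense()
        v = self.first_valley
        depths = np.arange(v, len(counts))
        mass = counts[v:]
        return float((depths * mass).sum() / mass.sum())

    @property
    def main_component_k_num(self) -> int:
        """K-mer instances in the main component (error slope excluded)."""
        counts = self._dense()
        v = self.first_valley
        depths = np.arange(v, len(counts))
        return int((depths * counts[v:]).sum())


_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


def _kmer_codes(reads: list[str], k: int) -> np.ndarray:
    """Canonical integer codes of every N-free k-mer window of every read."""
    by_len: dict[int, list[str]] = {}
    for r in reads:
        if len(r) >= k:
            by_len.setdefault(len(r), []).append(r)
    chunks = []
    for L, group in sorted(by_len.items()):
        mat = _CODE[
            np.frombuffer("".join(group).encode("ascii"), dtype=np.uint8)
        ].reshape(len(group), L)
        n_kmers = L - k + 1
        valid_base = mat != 255
        bases = np.where(valid_base, mat, 0).astype(np.uint64)
        fwd = np.zeros((len(group), n_kmers), dtype=np.uint64)
        rev = np.zeros_like(fwd)
        for j in range(k):
            fwd = fwd * 4 + bases[:, j : j + n_kmers]
            rev = rev * 4 + (3 - bases[:, k - 1 - j : k - 1 - j + n_kmers])
        canonical = np.minimum(fwd, rev)
        # a window is valid iff it contains no N
        cum_invalid = np.concatenate(
            [np.zeros((len(group), 1), dtype=np.int32),
             np.cumsum(~valid_base, axis=1, dtype=np.int32)],
            axis=1,
        )
        ok = (cum_invalid[:, k:] - cum_invalid[:, :-k]) == 0
        chunks.append(canonical[ok])
    if not chunks:
        return np.array([], dtype=np.uint64)
    return np.concatenate(chunks)


def kmer_spectrum(reads: list[str] | str | Path, k: int = 17) -> KmerSpectrum:
    """Depth histogram of canonical k-mers over a read set.

    Every k-base window of every read is counted (1-bp sliding window) in
    canonical form (the lexicographic minimum of the k-mer and its reverse
    complement); windows containing N are skipped.  ``reads`` may be a list
    of sequences or a FASTQ path.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if 4**k > 2**63:
        raise ValueError(f"k = {k} too large for 64-bit k-mer codes")
    if isinstance(reads, (str, Path)):
        from Bio import SeqIO

        reads = [str(rec.seq) for rec in SeqIO.parse(str(reads), "fastq")]
    codes = _kmer_codes(reads, k)
    if codes.size == 0:
        return KmerSpectrum(k=k, histogram={}, k_num=0)
    _, depth = np.unique(codes, return_counts=True)
    depths, n_at_depth = np.unique(depth, return_counts=True)
    return KmerSpectrum(
        k=k,
        histogram={int(d): int(c) for d, c in zip(depths, n_at_depth)},
        k_num=int(codes.size),
    )


def estimate_genome_size(spectrum: KmerSpectrum) -> float:
    """Genome size in bp: K_num / Peak_depth.

    Peak_depth is the expected k-mer depth of the main coverage
    component, and K_num counts the k-mer instances in that component:
    the low-depth error slope (depths below the histogram's first local
    minimum) is excluded from both.  Erroneous k-mers inflate the raw
    instance total without contributing depth to true genomic k-mers, so
    keeping them in the numerator would bias the estimate upward by
    roughly 1/(1-e)^k at per-base error rate e; excluding the slope from
    both terms makes the ratio estimate the number of distinct genomic
    k-mers, which equals the genome size up to edge effects.
    """
    return spectrum.main_component_k_num / spectrum.expected_depth


# ---------------------------------------------------------------------------
# Per-chromosome summary (Table-2 shape)


@dataclass(frozen=True)
class ChromosomeSummaryRow:
    chrom_id: str
    size_kb: float
    n_scaffolds: int
    n_genes: int
    density_per_10mb: int


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _density(n_genes: int, size_kb: float) -> int:
    return _round_half_away(n_genes / size_kb * 1e4)


def summary_from_counts(
    rows: Iterable[tuple[str, float, int, int]],
) -> tuple[list[ChromosomeSummaryRow], ChromosomeSummaryRow]:
    """Summary rows from (chrom_id, size_kb, n_scaffolds, n_genes) tuples,
    plus a totals row whose density is recomputed from the totals."""
    out = [
        ChromosomeSummaryRow(
            chrom_id=c,
            size_kb=round(size_kb, 1),
            n_scaffolds=n_scaf,
            n_genes=n_genes,
            density_per_10mb=_density(n_genes, size_kb),
        )
        for c, size_kb, n_scaf, n_genes in rows
    ]
    if not out:
        raise ValueError("no chromosomes")
    tot_kb = sum(r.size_kb for r in out)
    tot_scaf = sum(r.n_scaffolds for r in out)
    tot_genes = sum(r.n_genes for r in out)
    totals = ChromosomeSummaryRow(
        chrom_id="Total",
        size_kb=round(tot_kb, 1),
        n_scaffolds=tot_scaf,
        n_genes=tot_genes,
        density_per_10mb=_density(tot_genes, tot_kb),
    )
    return out, totals


def chromosome_summary(
    assemblies: Sequence[ChromosomeAssembly],
    genes: Sequence[GeneRecord],
    scaffold_lengths: Mapping[str, int],
) -> tuple[list[ChromosomeSummaryRow], ChromosomeSummaryRow]:
    """Per-chromosome size/scaffold/gene summary from built assemblies and
    chromosome-projected gene records."""
    known = {a.chrom_id for a in assemblies}
    gene_counts: dict[str, int] = {c: 0 for c in known}
    for g in genes:
        if g.seq_id not in known:
            raise ValidationError(f"gene {g.gene_id} on unknown chromosome {g.seq_id!r}")
        gene_counts[g.seq_id] += 1
    rows = [
        (
            a.chrom_id,
            a.total_length(scaffold_lengths) / 1e3,
            len(a.placements),
            gene_counts[a.chrom_id],
        )
        for a in assemblies
    ]
    return summary_from_counts(rows)


def summary_to_tsv(
    rows: list[ChromosomeSummaryRow], totals: ChromosomeSummaryRow
) -> str:
    lines = ["chromosome\tsize_kb\tn_scaffolds\tn_genes\tdensity_per_10mb"]
    for r in list(rows) + [totals]:
        lines.append(
            f"{r.chrom_id}\t{r.size_kb:.1f}\t{r.n_scaffolds}\t{r.n_genes}\t"
            f"{r.density_per_10mb}"
        )
    return "\n".join(lines) + "\n"
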