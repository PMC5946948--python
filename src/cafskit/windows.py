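"""Sliding-window gene-count and GC tracks.

The standard track for this pipeline uses a 1-Mb window and 100-kb step:
windows start at 1, 1+step, 1+2·step, …, and only windows fully contained in
the sequence are emitted, so every window has the same footprint and gene
counts stay comparable across windows.

A gene is assigned to every window containing its *start* coordinate (point
semantics), which is the quantity the permutation null model shuffles.
Midpoint or overlap assignment can be selected per call for sensitivity
checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import GeneRecord, SequenceRecord, ValidationError

__all__ = ["WindowSpec", "WindowTrack", "make_windows", "count_genes_in_windows",
           "gc_track", "combine_tracks", "track_to_tsv", "track_to_bedgraph"]

MB = 1_000_000
KB = 1_000


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: window size and step, both in bp."""

    window_size: int = MB
    step: int = 100 * KB

    def __post_init__(self) -> None:
        if not (self.window_size >= self.step >= 1):
            raise ValueError(
                f"need window_size >= step >= 1, got {self.window_size}/{self.step}"
            )

    def n_windows(self, seq_len: int) -> int:
        if seq_len < self.window_size:
            return 0
        return (seq_len - self.window_size) // self.step + 1


@dataclass
class WindowTrack:
    """Per-window gene counts (and optionally GC fractions) for one sequence."""

    seq_id: str
    spec: WindowSpec
    starts: np.ndarray  # 1-based window start coordinates
    gene_counts: np.ndarray | None = None
    gc_fractions: np.ndarray | None = None  # NaN where the window is all N

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.spec.window_size - 1


def make_windows(seq_len: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Enumerate fully-contained windows as 1-based inclusive (start, end) pairs."""
    starts = window_starts(seq_len, spec)
    return [(int(s), int(s) + spec.window_size - 1) for s in starts]


def window_starts(seq_len: int, spec: WindowSpec) -> np.ndarray:
    n = spec.n_windows(seq_len)
    return 1 + spec.step * np.arange(n, dtype=np.int64)


def count_genes_in_windows(
    genes: list[GeneRecord] | np.ndarray,
    seq_len: int,
    spec: WindowSpec,
    seq_id: str = "",
    assign: str = "start",
) -> WindowTrack:
    """Count genes per sliding window.

    ``assign`` selects the position a gene contributes at: its start
    coordinate (default), its interval midpoint, or — with ``"overlap"`` —
    every window its interval intersects.
    """
    if isinstance(genes, np.ndarray):
        positions = np.asarray(genes, dtype=np.int64)
        starts_arr = ends_arr = positions
    else:
        if genes and not seq_id:
            seq_id = genes[0].seq_id
        starts_arr = np.array([g.start for g in genes], dtype=np.int64)
        ends_arr = np.array([g.end for g in genes], dtype=np.int64)
        if assign == "start":
            positions = starts_arr
        elif assign == "midpoint":
            positions = (starts_arr + ends_arr) // 2
        elif assign == "overlap":
            positions = starts_arr
        else:
            raise ValueError(f"unknown assignment mode {assign!r}")
    if positions.size and positions.max() > seq_len:
        raise ValidationError(
            f"gene position beyond sequence end ({seq_len} bp) on {seq_id!r}"
        )
    win_starts = window_starts(seq_len, spec)
    win_ends = win_starts + spec.window_size - 1
    if assign == "overlap" and not isinstance(genes, np.ndarray):
        # a gene counts in every window its interval [start, end] intersects
        order = np.sort(starts_arr)
        order_end = np.sort(ends_arr)
        # intersects window iff gene.start <= win_end and gene.end >= win_start
        n_start_ok = np.searchsorted(order, win_ends, side="right")
        n_end_before = np.searchsorted(order_end, win_starts, side="left")
        counts = n_start_ok - n_end_before
    else:
        pos_sorted = np.sort(positions)
        counts = np.searchsorted(pos_sorted, win_ends, side="right") - np.searchsorted(
            pos_sorted, win_starts - 1, side="right"
        )
    return WindowTrack(
        seq_id=seq_id,
        spec=spec,
        starts=win_starts,
        gene_counts=counts.astype(np.int64),
    )


_GC_BYTES = (ord("G"), ord("C"), ord("g"), ord("c"))
_N_BYTES = (ord("N"), ord("n"))
_ACGT_BYTES = tuple(ord(c) for c in "ACGTacgt")


def gc_track(seq: SequenceRecord, spec: WindowSpec) -> WindowTrack:
    """Per-window GC fraction, (G+C)/(A+C+G+T); N bases never enter the
    denominator, and an all-N window gets NaN (excluded from correlations)."""
    arr = np.frombuffer(seq.sequence.encode("ascii"), dtype=np.uint8)
    is_gc = np.isin(arr, _GC_BYTES)
    is_acgt = np.isin(arr, _ACGT_BYTES)
    if not np.all(is_acgt | np.isin(arr, _N_BYTES)):
        raise ValidationError(f"{seq.seq_id}: non-ACGTN character in sequence")
    cum_gc = np.concatenate([[0], np.cumsum(is_gc)])
    cum_acgt = np.concatenate([[0], np.cumsum(is_acgt)])
    starts = window_starts(seq.length, spec)
    lo = starts - 1  # 0-based slice bounds
    hi = lo + spec.window_size
    gc = (cum_gc[hi] - cum_gc[lo]).astype(float)
    denom = (cum_acgt[hi] - cum_acgt[lo]).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom > 0, gc / np.maximum(denom, 1), np.nan)
    return WindowTrack(seq_id=seq.seq_id, spec=spec, starts=starts, gc_fractions=frac)


def combine_tracks(count_track: WindowTrack, gc: WindowTrack) -> WindowTrack:
    """Merge a gene-count track and a GC track computed under the same spec."""
    if count_track.spec != gc.spec or len(count_track) != len(gc):
        raise ValueError("tracks computed under different window specs")
    return WindowTrack(
        seq_id=count_track.seq_id,
        spec=count_track.spec,
        starts=count_track.starts,
        gene_counts=count_track.gene_counts,
        gc_fractions=gc.gc_fractions,
    )


def track_to_tsv(track: WindowTrack) -> str:
    """Tabular export: start, end, gene_count, gc per window."""
    lines = ["start\tend\tgene_count\tgc"]
    ends = track.ends
    for i, s in enumerate(track.starts):
        count = "" if track.gene_counts is None else str(int(track.gene_counts[i]))
        if track.gc_fractions is None or np.isnan(track.gc_fractions[i]):
            gcv = ""
        else:
            gcv = f"{track.gc_fractions[i]:.6f}"
        lines.append(f"{int(s)}\t{int(ends[i])}\t{count}\t{gcv}")
    return "\n".join(lines) + "\n"


def track_to_bedgraph(track: WindowTrack, measure: str) -> str:
    """bedGraph export of one measure ('gene_count' or 'gc'), 0-based half-open."""
    values = track.gene_counts if measure == "gene_count" else track.gc_fractions
    if values is None:
        raise ValueError(f"track has no {measure} values")
    lines = []
    ends = track.ends
    for i, s in enumerate(track.starts):
        v = values[i]
        if isinstance(v, float) and np.isnan(v):
            continue
        lines.append(f"{track.seq_id}\t{int(s) - 1}\t{int(ends[i])}\t{v}")
    return "\n".join(lines) + "\n"
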